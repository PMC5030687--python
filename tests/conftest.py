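import numpy as np
import pytest

from recombarrier import simdata
from recombarrier.variants import Alignment, call_snps


@pytest.fixture(scope="session")
def study_sim():
    """One full-size default-regime simulation (the barrier regime)."""
    cfg = simdata.study_config(seed=1)
    aln, matrix, truth = simdata.simulate_dataset(cfg)
    return cfg, aln, matrix, truth


@pytest.fixture(scope="session")
def study_snps(study_sim):
    _, aln, _, _ = study_sim
    return call_snps(aln)


@pytest.fixture(scope="session")
def well_separated_sim():
    """One full-size well-separated simulation (population recovery)."""
    cfg = simdata.well_separated_config(seed=1)
    aln, matrix, truth = simdata.simulate_dataset(cfg)
    return cfg, aln, matrix, truth


def random_alignment(rng: np.random.Generator, n: int, length: int,
                     alphabet: str = "nt", gap_rate: float = 0.0) -> Alignment:
    states = "ACGT" if alphabet == "nt" else "ACDEFGHIKLMNPQRSTVWY"
    rows = rng.integers(0, len(states), size=(n, length))
    seqs = []
    for row in rows:
        chars = [states[s] for s in row]
        if gap_rate > 0:
            for j in np.flatnonzero(rng.random(length) < gap_rate):
                chars[j] = "-"
        seqs.append("".join(chars))
    return Alignment(names=[f"g{i}" for i in range(n)], sequences=seqs,
                     alphabet=alphabet)


def clade_i_subclades(labels):
    """The deep-subclade labels of clade I in the bundled study structure
    (populations p5+p6 versus p7, the two sides of the clade I crown)."""
    return {
        g: ("IA" if pop in ("p5", "p6") else "IB")
        for g, (clade, pop, _) in labels.items()
        if clade == "I"
    }
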