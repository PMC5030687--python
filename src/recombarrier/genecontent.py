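"""Accessory-genome analyses.

Gene-content distance and amino-acid distance for independent genome
pairs, the log-log turnover regression and its rate-ratio reading, genomic
fluidity, pan-genome accumulation curves, and clade-specific gene sets.

The ortholog copy-number matrix is an input (ortholog inference itself is
out of scope); the bundled simulator produces truth matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import phylo

__all__ = [
    "GeneContentMatrix",
    "TurnoverFit",
    "FluidityResult",
    "PanGenomeCurve",
    "gene_content_distance",
    "amino_acid_distance",
    "select_independent_pairs",
    "fit_turnover",
    "genomic_fluidity",
    "pan_genome_curve",
    "clade_specific_genes",
]


@dataclass
class GeneContentMatrix:
    """Genomes x ortholog families, integer copy numbers.

    ``intervals`` optionally places families on the replicon (0-based
    half-open); ``categories`` optionally tags families (e.g. ``"phage"``).
    """

    genomes: list[str]
    families: list[str]
    data: np.ndarray
    intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int64)
        if self.data.shape != (len(self.genomes), len(self.families)):
            raise ValueError("matrix shape does not match genome/family lists")
        if self.data.size and self.data.min() < 0:
            raise ValueError("copy numbers must be non-negative")

    def row(self, genome: str) -> np.ndarray:
        try:
            return self.data[self.genomes.index(genome)]
        except ValueError:
            raise KeyError(f"unknown genome id {genome!r}") from None

    def presence(self) -> np.ndarray:
        return self.data >= 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.genomes, columns=self.families)

    def write_tsv(self, path, annotations_path=None) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="genome")
        if annotations_path is not None:
            rows = []
            for fam in self.families:
                start, end = self.intervals.get(fam, (None, None))
                rows.append(
                    {
                        "family": fam,
                        "start": start,
                        "end": end,
                        "category": self.categories.get(fam, ""),
                    }
                )
            pd.DataFrame(rows).to_csv(annotations_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, annotations_path=None) -> "GeneContentMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        intervals: dict[str, tuple[int, int]] = {}
        categories: dict[str, str] = {}
        if annotations_path is not None:
            ann = pd.read_csv(annotations_path, sep="\t")
            for _, r in ann.iterrows():
                if pd.notna(r.get("start")) and pd.notna(r.get("end")):
                    intervals[r["family"]] = (int(r["start"]), int(r["end"]))
                cat = r.get("category")
                if isinstance(cat, str) and cat:
                    categories[r["family"]] = cat
        return cls(
            genomes=list(df.index),
            families=list(df.columns),
            data=df.to_numpy(),
            intervals=intervals,
            categories=categories,
        )


def gene_content_distance(m: GeneContentMatrix, g1: str, g2: str) -> int:
    """Number of families whose copy numbers differ (0 vs >=1 included)."""
    return int(np.count_nonzero(m.row(g1) != m.row(g2)))


def amino_acid_distance(core, g1: str, g2: str) -> int:
    """Raw mismatch count over comparable (both-non-gap) core columns."""
    sub = core.subset([g1, g2])
    from .variants import _state_mask  # shared gap convention

    arr = sub.to_array()
    ok = _state_mask(sub)
    return int(np.count_nonzero((arr[0] != arr[1]) & ok[0] & ok[1]))


def select_independent_pairs(tree) -> list[tuple[str, str]]:
    """Greedy edge-disjoint pairing of leaves.

    Repeatedly accepts the closest (patristic) pair of still-unpaired
    leaves whose connecting path shares no edge with previously accepted
    paths; on a fully balanced 22-leaf genealogy this yields 11 pairs.
    Ties break lexicographically for determinism.
    """
    names, dist = phylo.patristic_distances(tree)
    candidates = sorted(
        ((dist[i, j], names[i], names[j])
         for i in range(len(names))
         for j in range(i + 1, len(names))),
        key=lambda t: (t[0], t[1], t[2]),
    )
    used_leaves: set[str] = set()
    used_edges: set[int] = set()
    pairs: list[tuple[str, str]] = []
    for _, a, b in candidates:
        if a in used_leaves or b in used_leaves:
            continue
        edges = phylo.path_edges(tree, a, b)
        if edges & used_edges:
            continue
        pairs.append((a, b))
        used_leaves.update((a, b))
        used_edges.update(edges)
    return pairs


@dataclass
class TurnoverFit:
    """OLS of log10(gene-content diff) on log10(amino-acid diff)."""

    intercept: float
    slope: float
    rate_ratio: float
    pairs: list[tuple[str, str]]
    content_diffs: list[int]
    aa_diffs: list[int]
    per_pair_ratios: list[float]
    n_excluded: int
    trend_rho: float
    trend_p: float

    def summary(self) -> str:
        return (
            f"log10(content) = {self.intercept:.3f} + {self.slope:.3f} * log10(aa); "
            f"rate ratio 10^intercept = {self.rate_ratio:.2f} "
            f"(fitted content diff at aa diff = 1); "
            f"ratio-vs-distance Spearman rho = {self.trend_rho:.3f} "
            f"(p = {self.trend_p:.3g}); {self.n_excluded} zero-metric pair(s) excluded"
        )


def fit_turnover(
    pairs: list[tuple[str, str]],
    content_diffs: list[int],
    aa_diffs: list[int],
    pseudocount: bool = False,
) -> TurnoverFit:
    """Turnover regression over independent pairs.

    Pairs with a zero in either metric are excluded (and counted) unless
    ``pseudocount`` adds 1 to every count. The reported rate ratio is
    ``10**intercept`` — the fitted gene-content difference at one
    amino-acid difference.
    """
    if pseudocount:
        content = [c + 1 for c in content_diffs]
        aa = [a + 1 for a in aa_diffs]
        keep = list(range(len(pairs)))
    else:
        content, aa, keep = [], [], []
        for i, (c, a) in enumerate(zip(content_diffs, aa_diffs)):
            if c > 0 and a > 0:
                content.append(c)
                aa.append(a)
                keep.append(i)
    n_excluded = len(pairs) - len(keep)
    if len(keep) < 3:
        raise ValueError(f"need >=3 usable pairs, got {len(keep)}")
    x = np.log10(aa)
    y = np.log10(content)
    slope, intercept = np.polyfit(x, y, 1)
    ratios = [c / a for c, a in zip(content, aa)]
    if len(set(ratios)) > 1 and len(set(aa)) > 1:
        rho, p = stats.spearmanr(aa, ratios)
    else:
        rho, p = 0.0, 1.0
    return TurnoverFit(
        intercept=float(intercept),
        slope=float(slope),
        rate_ratio=float(10.0 ** intercept),
        pairs=[pairs[i] for i in keep],
        content_diffs=content,
        aa_diffs=aa,
        per_pair_ratios=ratios,
        n_excluded=n_excluded,
        trend_rho=float(rho),
        trend_p=float(p),
    )


@dataclass
class FluidityResult:
    phi: float
    n_genomes: int
    n_pairs: int


def genomic_fluidity(m: GeneContentMatrix) -> FluidityResult:
    """Genomic fluidity: mean over unordered pairs of the fraction of the
    pair's gene families unique to one of its genomes.

    phi = (2 / N(N-1)) * sum over pairs (U_k + U_l) / (M_k + M_l), with
    presence meaning copy number >= 1 (copy number itself is ignored).
    """
    pres = m.presence()
    n = len(m.genomes)
    if n < 2:
        raise ValueError("need >=2 genomes")
    sizes = pres.sum(axis=1)
    if (sizes == 0).any():
        empty = [m.genomes[i] for i in np.flatnonzero(sizes == 0)]
        raise ValueError(f"genome(s) with zero families: {empty}")
    total = 0.0
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            unique = np.count_nonzero(pres[i] != pres[j])
            total += unique / (sizes[i] + sizes[j])
            n_pairs += 1
    return FluidityResult(phi=total / n_pairs, n_genomes=n, n_pairs=n_pairs)


@dataclass
class PanGenomeCurve:
    """Mean cumulative distinct-family counts over genome permutations."""

    means: np.ndarray
    n_permutations: int
    seed: int
    tail_slope: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_genomes": np.arange(1, len(self.means) + 1),
             "mean_families": self.means}
        )


def pan_genome_curve(m: GeneContentMatrix, P: int = 100, seed: int = 0
                     ) -> PanGenomeCurve:
    """Pan-genome accumulation curve over genome-order permutations.

    When all n! orders number at most P they are enumerated exhaustively
    (the exact mean curve); otherwise P seeded random permutations are
    averaged. The tail slope (mean gain from the penultimate to the final
    genome) summarises whether gene discovery has plateaued.
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    from itertools import permutations
    from math import factorial

    rng = np.random.default_rng(seed)
    pres = m.presence()
    n = len(m.genomes)
    if factorial(n) <= P:
        orders = list(permutations(range(n)))
    else:
        orders = [rng.permutation(n) for _ in range(P)]
    sums = np.zeros(n)
    for order in orders:
        seen = np.zeros(pres.shape[1], dtype=bool)
        for step, g in enumerate(order):
            seen |= pres[g]
            sums[step] += seen.sum()
    means = sums / len(orders)
    tail = float(means[-1] - means[-2]) if n >= 2 else 0.0
    return PanGenomeCurve(means=means, n_permutations=len(orders), seed=seed,
                          tail_slope=tail)


def clade_specific_genes(m: GeneContentMatrix, clades: dict[str, str]
                         ) -> dict[tuple[str, str], list[str]]:
    """Families present in every member of clade A and absent from every
    member of clade B, for each ordered clade pair (A, B)."""
    labels = sorted(set(clades.values()))
    members = {
        c: [i for i, g in enumerate(m.genomes) if clades.get(g) == c]
        for c in labels
    }
    for c, idx in members.items():
        if not idx:
            raise ValueError(f"clade {c!r} has no members in the matrix")
    pres = m.presence()
    out: dict[tuple[str, str], list[str]] = {}
    for a in labels:
        for b in labels:
            if a == b:
                continue
            core_a = pres[members[a]].all(axis=0)
            absent_b = ~pres[members[b]].any(axis=0)
            out[(a, b)] = [f for f, keep in zip(m.families, core_a & absent_b) if keep]
    return out
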