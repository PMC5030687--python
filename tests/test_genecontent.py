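import itertools
import math

import dendropy
import numpy as np
import pytest

from recombarrier import simdata
from recombarrier.genecontent import (
    GeneContentMatrix,
    amino_acid_distance,
    clade_specific_genes,
    fit_turnover,
    gene_content_distance,
    genomic_fluidity,
    pan_genome_curve,
    select_independent_pairs,
)
from recombarrier.phylo import path_edges
from recombarrier.variants import Alignment


def _matrix(rows, genomes=None):
    rows = np.asarray(rows)
    genomes = genomes or [f"g{i}" for i in range(rows.shape[0])]
    fams = [f"f{j}" for j in range(rows.shape[1])]
    return GeneContentMatrix(genomes, fams, rows)


def test_gene_content_distance_counts_copy_number_changes():
    m = _matrix([[1, 0, 2], [1, 1, 1]])
    assert gene_content_distance(m, "g0", "g0") == 0
    assert gene_content_distance(m, "g0", "g1") == 2
    with pytest.raises(KeyError):
        gene_content_distance(m, "g0", "nope")


@pytest.mark.parametrize("seed", [0, 1])
def test_gene_content_distance_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    m = _matrix(rng.integers(0, 3, size=(5, 30)))
    for a, b in itertools.combinations(m.genomes, 2):
        expected = sum(x != y for x, y in zip(m.row(a), m.row(b)))
        assert gene_content_distance(m, a, b) == expected
        assert gene_content_distance(m, b, a) == expected  # symmetry


def test_amino_acid_distance_counts_and_symmetry():
    seq_a = "A" * 100
    seq_b = "A" * 95 + "KLMNP"
    aln = Alignment(["x", "y"], [seq_a, seq_b], alphabet="aa")
    assert amino_acid_distance(aln, "x", "y") == 5
    assert amino_acid_distance(aln, "y", "x") == 5


def test_independent_pairs_on_balanced_quartet():
    tree = dendropy.Tree.get(data="((a:1,b:1):1,(c:1,d:1):1);",
                             schema="newick")
    assert sorted(select_independent_pairs(tree)) == [("a", "b"), ("c", "d")]


def test_independent_pairs_study_tree_yields_eleven(study_sim):
    _, _, _, truth = study_sim
    pairs = select_independent_pairs(truth.true_tree)
    assert len(pairs) == 11
    # edge-disjointness by explicit path intersection
    used = set()
    for a, b in pairs:
        edges = path_edges(truth.true_tree, a, b)
        assert not (edges & used)
        used |= edges
    paired = {g for pair in pairs for g in pair}
    assert len(paired) == 22


def test_fit_turnover_exact_line():
    pairs = [("a", "b"), ("c", "d"), ("e", "f"), ("g", "h")]
    aa = [10, 100, 1000, 50]
    content = [10 * x for x in aa]
    fit = fit_turnover(pairs, content, aa)
    assert fit.intercept == pytest.approx(1.0)
    assert fit.slope == pytest.approx(1.0)
    assert fit.rate_ratio == pytest.approx(10.0)
    assert fit.n_excluded == 0


def test_fit_turnover_excludes_zero_pairs():
    pairs = [("a", "b"), ("c", "d"), ("e", "f"), ("g", "h")]
    fit = fit_turnover(pairs, [10, 100, 1000, 5], [1, 10, 100, 0])
    assert fit.n_excluded == 1
    assert len(fit.pairs) == 3
    with pytest.raises(ValueError):
        fit_turnover(pairs[:3], [0, 10, 10], [0, 1, 1])


def test_fit_turnover_pseudocount_keeps_all_pairs():
    pairs = [("a", "b"), ("c", "d"), ("e", "f")]
    fit = fit_turnover(pairs, [10, 100, 0], [1, 10, 0], pseudocount=True)
    assert fit.n_excluded == 0
    assert len(fit.pairs) == 3


def test_fluidity_limits_and_hand_example():
    assert genomic_fluidity(_matrix([[1, 1, 0], [1, 1, 0]])).phi == 0.0
    assert genomic_fluidity(_matrix([[1, 1, 0, 0], [0, 0, 1, 1]])).phi == 1.0
    # genomes {A,B}, {B,C}, {C,D}: pair terms 2/4, 4/4, 2/4, whose mean
    # (the fluidity formula: 2/(N(N-1)) times their sum) is 2/3
    m = _matrix([[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 1, 1]])
    assert genomic_fluidity(m).phi == pytest.approx(2 / 3)
    with pytest.raises(ValueError):
        genomic_fluidity(_matrix([[1, 0], [0, 0]]))


@pytest.mark.parametrize("seed", [2, 3])
def test_fluidity_matches_formula_brute_force(seed):
    rng = np.random.default_rng(seed)
    m = _matrix(rng.integers(0, 2, size=(6, 40)) +
                rng.integers(0, 2, size=(6, 40)))
    pres = m.data >= 1
    if not pres.all(axis=1).any():
        pres[:, 0] = True
        m.data[:, 0] = 1
    n = 6
    total = 0.0
    for k, l in itertools.combinations(range(n), 2):
        u = np.count_nonzero(pres[k] != pres[l])
        total += u / (pres[k].sum() + pres[l].sum())
    expected = total * 2 / (n * (n - 1))
    assert genomic_fluidity(m).phi == pytest.approx(expected)


def test_pan_genome_flat_for_identical_genomes():
    m = _matrix([[1, 1, 0]] * 4)
    curve = pan_genome_curve(m, P=10, seed=0)
    assert curve.means.tolist() == [2.0, 2.0, 2.0, 2.0]
    assert curve.tail_slope == 0.0


def test_pan_genome_unique_families_increment_by_one():
    m = _matrix(np.eye(4, dtype=int))
    curve = pan_genome_curve(m, P=10, seed=0)
    assert curve.means.tolist() == [1.0, 2.0, 3.0, 4.0]


def test_pan_genome_mean_equals_exhaustive_enumeration():
    rng = np.random.default_rng(4)
    m = _matrix(rng.integers(0, 2, size=(4, 12)))
    curve = pan_genome_curve(m, P=100, seed=0)  # 4! = 24 <= P: exhaustive
    assert curve.n_permutations == math.factorial(4)
    pres = m.data >= 1
    sums = np.zeros(4)
    for order in itertools.permutations(range(4)):
        seen = np.zeros(12, dtype=bool)
        for step, g in enumerate(order):
            seen |= pres[g]
            sums[step] += seen.sum()
    np.testing.assert_allclose(curve.means, sums / 24)


@pytest.mark.parametrize("seed", [5, 6])
def test_pan_genome_curve_is_non_decreasing(seed):
    rng = np.random.default_rng(seed)
    m = _matrix(rng.integers(0, 2, size=(7, 50)))
    curve = pan_genome_curve(m, P=20, seed=seed)
    assert (np.diff(curve.means) >= -1e-12).all()


def test_clade_specific_counts_and_symmetry():
    rows = np.ones((8, 10), dtype=int)
    rows[4:, [0, 1, 2]] = 0  # 3 families A-specific
    rows[:4, [3, 4]] = 0     # 2 families B-specific
    m = _matrix(rows)
    clades = {g: ("A" if i < 4 else "B") for i, g in enumerate(m.genomes)}
    res = clade_specific_genes(m, clades)
    assert len(res[("A", "B")]) == 3
    assert len(res[("B", "A")]) == 2
    swapped = {g: ("B" if c == "A" else "A") for g, c in clades.items()}
    res2 = clade_specific_genes(m, swapped)
    assert len(res2[("A", "B")]) == 2 and len(res2[("B", "A")]) == 3
    with pytest.raises(ValueError):
        clade_specific_genes(m, {g: "A" for g in m.genomes} | {"zzz": "B"})


def test_turnover_recovery_from_simulation():
    """Gene turnover simulated at 10x the substitution rate is recovered
    near 10, and a 1x simulation estimates well below it."""
    estimates = {}
    for ratio in (1.0, 10.0):
        cfg = simdata.turnover_config(seed=11, rate_ratio=ratio,
                                      core_length=25_000)
        tree = simdata.simulate_genealogy(cfg)
        aln, _, _ = simdata.simulate_core(cfg, tree)
        m, _ = simdata.simulate_gene_content(cfg, tree)
        pairs = select_independent_pairs(tree)
        cd = [gene_content_distance(m, a, b) for a, b in pairs]
        ad = [amino_acid_distance(aln, a, b) for a, b in pairs]
        estimates[ratio] = fit_turnover(pairs, cd, ad).rate_ratio
    assert estimates[1.0] < estimates[10.0]
    assert 5.0 <= estimates[10.0] <= 20.0
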