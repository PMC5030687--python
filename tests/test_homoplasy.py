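import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recombarrier import simdata
from recombarrier.homoplasy import (
    BarrierTestResult,
    CladePartition,
    barrier_test,
    classify_homoplasies,
    detect_homoplasies,
)
from recombarrier.variants import Alignment, call_snps

from conftest import clade_i_subclades


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


EIGHT_LEAF = "(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1);"
NAMES = list("abcdefgh")
PARTITION = CladePartition(
    clades={g: ("X" if g in "abcd" else "Y") for g in NAMES},
    subclades={"a": "XA", "b": "XA", "c": "XB", "d": "XB"},
)


def _aln(columns):
    """Build an alignment from a list of per-genome column strings."""
    seqs = ["".join(col[i] for col in columns) for i in range(len(NAMES))]
    return Alignment(NAMES, seqs)


def test_partition_validation():
    with pytest.raises(ValueError):
        CladePartition(clades={"a": "X"}, subclades={"b": "S"})
    with pytest.raises(ValueError):
        CladePartition(clades={"a": "X", "b": "Y"},
                       subclades={"a": "S", "b": "S"})


def test_clade_private_allele_not_flagged():
    # minor allele spans the (a,b) cherry exactly: one change suffices
    v = call_snps(_aln(["CCAAAAAA", "AAAAAAAA", "ACAAAAAA"]))
    sites = detect_homoplasies(v, _tree(EIGHT_LEAF))
    assert [s.position for s in sites] == []


def test_disjoint_subtree_sharing_flagged_k2():
    # minor allele on a and e: two disjoint subtrees, k = 2
    v = call_snps(_aln(["CAAACAAA", "AAAAAAAA"]))
    sites = detect_homoplasies(v, _tree(EIGHT_LEAF))
    assert len(sites) == 1
    assert sites[0].k == 2
    assert sites[0].carriers == frozenset({"a", "e"})


def test_classification_spans():
    v = call_snps(_aln([
        "CAAACAAA",  # carriers a,e -> clades X and Y: between
        "CACAAAAA",  # carriers a,c -> subclades XA and XB: within X
        "CCCAAAAA",  # carriers a,b,c: also cross-subclade (k=2)
    ]))
    sites = detect_homoplasies(v, _tree(EIGHT_LEAF))
    counts = classify_homoplasies(sites, PARTITION)
    assert counts.n_between == 1
    assert counts.n_within_per_clade == {"X": 2}


def test_derived_polarisation_recovers_consensus_transfer():
    """A clade-consensus allele transferred across clades is between-clade
    under derived polarisation but invisible to the minor-allele rule."""
    # X-consensus 'C' (derived) transferred into e: minor allele is the
    # Y-remainder 'A' side once |C| = 5 > |A| = 3
    col = "CCCCCAAA"
    v = call_snps(_aln([col]))
    sites = detect_homoplasies(v, _tree(EIGHT_LEAF), ancestral={0: "A"})
    assert len(sites) == 1
    by_minor = classify_homoplasies(sites, PARTITION, method="minor")
    by_derived = classify_homoplasies(sites, PARTITION, method="derived")
    assert by_minor.n_between == 0
    assert by_derived.n_between == 1


def test_reversion_hole_not_counted_as_within():
    """A clade-wide derived allele with one reversion hole spans both
    subclades at near-consensus; the minority guard excludes it, while a
    genuine transferred fragment (minority in the receiving subclade)
    still counts."""
    big = _tree("(((a:1,(b:1,c:1):1):1,(d:1,(e:1,f:1):1):1):1,"
                "((u:1,(v:1,w:1):1):1,(x:1,(y:1,z:1):1):1):1);")
    names = list("abcdefuvwxyz")
    part = CladePartition(
        clades={g: ("X" if g in "abcdef" else "Y") for g in names},
        subclades={g: ("XA" if g in "abc" else "XB") for g in "abcdef"},
    )

    def one_site(col):
        seqs = [c for c in col]
        v = call_snps(Alignment(names, seqs))
        sites = detect_homoplasies(v, big, ancestral={0: "A"})
        return classify_homoplasies(sites, part)

    # derived C = all of X except f: near-consensus in both subclades
    counts = one_site("CCCCCAAAAAAA")
    assert counts.n_between == 0 and counts.n_within == 0
    # derived C = XB's d,e plus one XA member: minority in XA -> within
    counts2 = one_site("CAACCAAAAAAA")
    assert counts2.n_within == 1
    # derived C = X consensus plus one Y member: between regardless
    counts3 = one_site("CCCCCCAAAAAC")
    assert counts3.n_between == 1


def test_genome_missing_from_tree_raises():
    v = call_snps(_aln(["CAAACAAA"]))
    small = _tree("((a:1,b:1):1,(c:1,d:1):1);")
    with pytest.raises(KeyError):
        detect_homoplasies(v, small)


def test_between_clade_tracts_are_detected(study_sim):
    """Every between-clade classified site in a barrier-free simulation is
    covered by a logged between-clade tract or a recurrent mutation; and
    in a simulation with a complete barrier, tract-free between-clade
    calls can only be recurrent mutations."""
    cfg = simdata.equal_intensity_config(seed=5)
    aln, _, truth = simdata.simulate_dataset(cfg)
    snps = call_snps(aln)
    anc = {int(p): truth.root_sequence[p] for p in snps.positions}
    part = CladePartition({g: truth.labels[g][0] for g in aln.names},
                          clade_i_subclades(truth.labels))
    sites = detect_homoplasies(snps, truth.true_tree, ancestral=anc)
    counts = classify_homoplasies(sites, part)
    assert counts.n_between > 0
    subs_per_site = {}
    for events in truth.substitutions.values():
        for pos, _ in events:
            subs_per_site[pos] = subs_per_site.get(pos, 0) + 1
    for site in counts.between_sites:
        covered = any(
            e.start <= site.position < e.end and e.category == "between_clade"
            for e in truth.recomb_events
        )
        recurrent = subs_per_site.get(site.position, 0) > 1
        assert covered or recurrent, site.position


def test_barrier_test_matches_brute_force_binomial():
    """The study counts: 8 between-clade vs 14 cross-subclade homoplasies
    at divergence ratio 10."""
    res = barrier_test(8, 14, 10.0)
    p0 = 10.0 / 11.0
    expected = sum(
        math.comb(22, x) * p0 ** x * (1 - p0) ** (22 - x) for x in range(9)
    )
    assert res.p_value == pytest.approx(expected, abs=1e-12)
    assert res.null_proportion == pytest.approx(p0)
    assert "deficit" in res.direction


def test_barrier_test_even_split():
    res = barrier_test(5, 5, 1.0)
    assert res.p_value == pytest.approx(0.623, abs=5e-4)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    n_between=st.integers(0, 25),
    n_within=st.integers(0, 25),
    R=st.floats(0.1, 50.0),
)
def test_barrier_test_matches_enumeration(n_between, n_within, R):
    if n_between + n_within == 0:
        with pytest.raises(ValueError):
            barrier_test(n_between, n_within, R)
        return
    res = barrier_test(n_between, n_within, R)
    N = n_between + n_within
    p0 = R / (1 + R)
    expected = sum(
        math.comb(N, x) * p0 ** x * (1 - p0) ** (N - x)
        for x in range(n_between + 1)
    )
    assert res.p_value == pytest.approx(expected, rel=1e-9, abs=1e-12)
    assert 0.0 <= res.p_value <= 1.0


def test_barrier_test_rejects_bad_inputs():
    with pytest.raises(ValueError):
        barrier_test(0, 0, 10.0)
    with pytest.raises(ValueError):
        barrier_test(1, 1, 0.0)


def test_result_summary_mentions_counts():
    assert "8 between-clade" in barrier_test(8, 14, 10.0).summary()
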