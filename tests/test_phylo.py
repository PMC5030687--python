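import itertools

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from recombarrier import phylo
from recombarrier.phylo import (
    CharacterMatrix,
    bootstrap_support,
    collapse_low_support,
    fitch_length,
    fitch_lengths,
    neighbor_joining,
    parsimony_tree,
    read_newick,
    total_fitch_length,
    write_newick,
)
from recombarrier.variants import DistanceMatrix


def _random_ultrametric(rng, n):
    taxa = [f"t{i}" for i in range(n)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        taxon_namespace=ns, rng=rng)
    return tree


def _random_additive_distances(seed, n):
    """Distances from a random binary tree with strictly positive lengths."""
    rng = np.random.default_rng(seed)
    taxa = [f"t{i}" for i in range(n)]
    ns = dendropy.TaxonNamespace(taxa)
    import random

    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        taxon_namespace=ns, rng=random.Random(seed))
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(rng.uniform(0.1, 1.0))
    names, mat = phylo.patristic_distances(tree)
    return tree, DistanceMatrix(names, mat)


def test_nj_three_taxon_closed_form():
    names = ["a", "b", "c"]
    d = DistanceMatrix(names, np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]],
                                       dtype=float))
    tree = neighbor_joining(d)
    lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lengths["a"] == pytest.approx(1.0)
    assert lengths["b"] == pytest.approx(2.0)
    assert lengths["c"] == pytest.approx(3.0)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_nj_recovers_additive_trees_exactly(seed):
    source, d = _random_additive_distances(seed, 6)
    recovered = neighbor_joining(d)
    ns = source.taxon_namespace
    recovered = dendropy.Tree.get(data=recovered.as_string(schema="newick"),
                                  schema="newick", taxon_namespace=ns)
    source.deroot()
    recovered.deroot()
    assert treecompare.symmetric_difference(source, recovered,
                                            is_bipartitions_updated=False) == 0
    _, mat = phylo.patristic_distances(recovered)
    np.testing.assert_allclose(mat, d.values, atol=1e-9)


def test_nj_identical_taxa_form_zero_length_cherry():
    names = ["a", "b", "c", "d"]
    vals = np.array([[0, 0, 2, 2], [0, 0, 2, 2], [2, 2, 0, 2], [2, 2, 2, 0]],
                    dtype=float)
    tree = neighbor_joining(DistanceMatrix(names, vals))
    lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lengths["a"] == pytest.approx(0.0)
    assert lengths["b"] == pytest.approx(0.0)


def test_nj_matches_independent_implementation():
    """Cross-check the topology against scikit-bio's neighbour joining."""
    skbio = pytest.importorskip("skbio")
    _, d = _random_additive_distances(9, 7)
    noisy = d.values + np.random.default_rng(9).uniform(0, 0.05, d.values.shape)
    noisy = (noisy + noisy.T) / 2
    np.fill_diagonal(noisy, 0.0)
    ours = neighbor_joining(DistanceMatrix(d.names, noisy))
    theirs = skbio.tree.nj(skbio.DistanceMatrix(noisy, ids=d.names))
    ns = dendropy.TaxonNamespace(d.names)
    t1 = dendropy.Tree.get(data=ours.as_string(schema="newick"),
                           schema="newick", taxon_namespace=ns)
    t2 = dendropy.Tree.get(data=str(theirs).replace("root", ""),
                           schema="newick", taxon_namespace=ns)
    assert treecompare.symmetric_difference(t1, t2) == 0


def test_nj_rejects_undefined_distances():
    vals = np.zeros((3, 3))
    vals[0, 1] = vals[1, 0] = np.nan
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(["a", "b", "c"], vals))


# ---------------------------------------------------------------------------
# Fitch parsimony


SIX_LEAF = "((a:1,b:1):1,((c:1,d:1):1,(e:1,f:1):1):1);"


def _fitch_brute_force(tree, character):
    """Exhaustive minimum over all internal labelings."""
    tree = dendropy.Tree.get(data=tree, schema="newick") \
        if isinstance(tree, str) else tree
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    states = sorted(set(character.values()))
    best = None
    for labeling in itertools.product(states, repeat=len(internal)):
        assign = dict(zip(map(id, internal), labeling))
        changes = 0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            s = character[node.taxon.label] if node.is_leaf() \
                else assign[id(node)]
            p = assign[id(node.parent_node)]
            changes += s != p
        if best is None or changes < best:
            best = changes
    return best


def test_fitch_simple_cases():
    tree = read_newick_str("((a:1,b:1):1,(c:1,d:1):1);")
    assert fitch_length(tree, {"a": 0, "b": 0, "c": 0, "d": 0}) == 0
    assert fitch_length(tree, {"a": 0, "b": 0, "c": 1, "d": 1}) == 1
    assert fitch_length(tree, {"a": 0, "b": 1, "c": 0, "d": 1}) == 2


def test_fitch_equals_exhaustive_on_all_binary_patterns():
    tree = read_newick_str(SIX_LEAF)
    leaves = ["a", "b", "c", "d", "e", "f"]
    for bits in range(64):
        character = {l: (bits >> i) & 1 for i, l in enumerate(leaves)}
        expected = _fitch_brute_force(SIX_LEAF, character)
        assert fitch_length(tree, character) == expected, character


def test_fitch_missing_leaf_raises():
    tree = read_newick_str("((a:1,b:1):1,(c:1,d:1):1);")
    with pytest.raises(KeyError):
        fitch_length(tree, {"a": 0, "b": 0, "c": 1})


def read_newick_str(s):
    return dendropy.Tree.get(data=s, schema="newick")


# ---------------------------------------------------------------------------
# Parsimony search


def test_parsimony_tree_unanimous_split():
    taxa = ["a", "b", "c", "d", "e", "f"]
    data = np.array([[0] * 5, [0] * 5, [0] * 5, [1] * 5, [1] * 5, [1] * 5])
    tree = parsimony_tree(CharacterMatrix(taxa, data))
    matrix = CharacterMatrix(taxa, data)
    assert total_fitch_length(tree, matrix) == 5  # one change per character


def test_parsimony_four_taxa_majority_split_wins():
    """2 characters for split ab|cd vs 1 for ac|bd: the search must find
    the same optimum as exhaustive enumeration of the 3 topologies."""
    taxa = ["a", "b", "c", "d"]
    data = np.array([[0, 0, 0], [0, 0, 1], [1, 1, 0], [1, 1, 1]])
    matrix = CharacterMatrix(taxa, data)
    best = parsimony_tree(matrix)
    topologies = ["((a,b),(c,d));", "((a,c),(b,d));", "((a,d),(b,c));"]
    scores = [
        total_fitch_length(read_newick_str(t), matrix) for t in topologies
    ]
    assert total_fitch_length(best, matrix) == min(scores) == 4


def test_parsimony_groups_ct_signature_matrix(study_sim):
    """Leaves sharing a CT signature form connected subtrees."""
    cfg, _, matrix, truth = study_sim
    region = [f for f in matrix.families if f.startswith("reg")]
    cols = [matrix.families.index(f) for f in region]
    # noise-free signatures: rebuild from config
    sigs = cfg.ct_spec.signatures
    cts = sorted({ct for ct in cfg.ct_spec.labels.values()})
    taxa = list(matrix.genomes)
    data = np.array([
        np.minimum(sigs[cfg.ct_spec.labels[g]], 2) for g in taxa
    ])
    tree = parsimony_tree(CharacterMatrix(taxa, data, region))
    for ct in cts:
        members = {g for g in taxa if cfg.ct_spec.labels[g] == ct}
        if len(members) < 2:
            continue
        mrca_ok = False
        all_leaves = set(taxa)
        for node in tree.postorder_node_iter():
            if node.parent_node is None:
                continue
            side = {l.taxon.label for l in node.leaf_iter()}
            if side == members or side == all_leaves - members:
                mrca_ok = True
                break
        assert mrca_ok, f"{ct} not monophyletic"


def test_parsimony_all_constant_raises():
    taxa = ["a", "b", "c", "d"]
    with pytest.raises(ValueError):
        parsimony_tree(CharacterMatrix(taxa, np.ones((4, 3), dtype=int)))


@pytest.mark.parametrize("seed", [0, 1])
def test_parsimony_search_not_worse_than_nj_topology(seed):
    rng = np.random.default_rng(seed)
    taxa = [f"t{i}" for i in range(8)]
    data = rng.integers(0, 2, size=(8, 20))
    matrix = CharacterMatrix(taxa, data)
    # Hamming distances -> NJ topology as a reference point
    d = np.array([[np.count_nonzero(data[i] != data[j]) for j in range(8)]
                  for i in range(8)], dtype=float)
    nj = neighbor_joining(DistanceMatrix(taxa, d))
    assert total_fitch_length(parsimony_tree(matrix), matrix) <= \
        total_fitch_length(nj, matrix)


# ---------------------------------------------------------------------------
# Bootstrap and Newick


def test_bootstrap_unanimous_split_gets_full_support():
    taxa = ["a", "b", "c", "d", "e", "f"]
    data = np.array([[0] * 8, [0] * 8, [0] * 8, [1] * 8, [1] * 8, [1] * 8])
    tree = bootstrap_support(CharacterMatrix(taxa, data), B=100, seed=0)
    supports = [float(n.label) for n in tree.postorder_internal_node_iter()
                if n.label is not None]
    assert supports and all(s == 100.0 for s in supports)


def test_bootstrap_supports_within_range(study_sim):
    cfg, _, matrix, _ = study_sim
    region = [f for f in matrix.families if f.startswith("reg")]
    cols = [matrix.families.index(f) for f in region]
    m = CharacterMatrix(list(matrix.genomes),
                        np.minimum(matrix.data[:, cols], 2), region)
    tree = bootstrap_support(m, B=20, seed=3)
    supports = [float(n.label) for n in tree.postorder_internal_node_iter()
                if n.label is not None]
    assert supports and all(0.0 <= s <= 100.0 for s in supports)
    collapsed = collapse_low_support(tree, threshold=50)
    remaining = [float(n.label) for n in collapsed.postorder_internal_node_iter()
                 if n.label is not None]
    assert all(s >= 50.0 for s in remaining)


def test_bootstrap_rejects_zero_replicates():
    taxa = ["a", "b", "c", "d"]
    m = CharacterMatrix(taxa, np.eye(4, dtype=int))
    with pytest.raises(ValueError):
        bootstrap_support(m, B=0)


def test_newick_round_trip(tmp_path, study_sim):
    _, _, _, truth = study_sim
    path = tmp_path / "tree.nwk"
    write_newick(truth.true_tree, path)
    back = read_newick(path)
    ns = truth.true_tree.taxon_namespace
    back = dendropy.Tree.get(data=back.as_string(schema="newick"),
                             schema="newick", taxon_namespace=ns)
    assert treecompare.symmetric_difference(truth.true_tree, back) == 0


def test_newick_two_leaf_and_malformed(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("(a:1,b:1);\n")
    tree = read_newick(p)
    assert {l.taxon.label for l in tree.leaf_node_iter()} == {"a", "b"}
    bad = tmp_path / "bad.nwk"
    bad.write_text("((a:1,b:1;\n")
    with pytest.raises(Exception):
        read_newick(bad)
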