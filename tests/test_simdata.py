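import json

import numpy as np
import pytest

from recombarrier import simdata
from recombarrier.genecontent import GeneContentMatrix
from recombarrier.simdata import (
    CladeSpec,
    Hotspot,
    PopulationSpec,
    SimulationConfig,
    emit_dataset,
    replay_core,
    replay_gene_content,
    simulate_core,
    simulate_dataset,
    simulate_genealogy,
    simulate_gene_content,
    study_config,
)
from recombarrier.variants import read_alignment


def _two_leaf_config(depth=0.3, **kw):
    clade = CladeSpec("A", depth, [PopulationSpec("p", 2, depth)])
    return SimulationConfig(seed=0, clades=[clade], core_length=1000, **kw)


def test_two_leaf_genealogy_depth():
    tree = simulate_genealogy(_two_leaf_config(depth=0.3))
    for leaf in tree.leaf_node_iter():
        depth = 0.0
        node = leaf
        while node.parent_node is not None:
            depth += node.edge.length
            node = node.parent_node
    assert depth == pytest.approx(0.3)


def test_empty_population_spec_rejected():
    with pytest.raises(ValueError):
        simulate_genealogy(SimulationConfig(seed=0, clades=[]))


def test_study_genealogy_structure():
    """22 leaves, ultrametric at the clade split depth, with each of the
    seven populations forming a monophyletic subtree."""
    cfg = study_config(seed=0)
    tree = simulate_genealogy(cfg)
    leaves = list(tree.leaf_node_iter())
    assert len(leaves) == 22
    # ultrametric: every root-to-leaf path equals the clade split depth
    for leaf in leaves:
        depth, node = 0.0, leaf
        while node.parent_node is not None:
            depth += node.edge.length
            node = node.parent_node
        assert depth == pytest.approx(cfg.clade_split_depth)
    labels = cfg.labels()
    all_names = {l.taxon.label for l in leaves}
    pops = {pop for _, pop, _ in labels.values()}
    assert len(pops) == 7
    for pop in pops:
        members = {g for g, (_, p, _) in labels.items() if p == pop}
        found = any(
            {l.taxon.label for l in node.leaf_iter()} == members
            for node in tree.preorder_internal_node_iter()
        )
        assert found, f"population {pop} is not a subtree"


def test_genealogy_deterministic():
    t1 = simulate_genealogy(study_config(seed=4)).as_string(schema="newick")
    t2 = simulate_genealogy(study_config(seed=4)).as_string(schema="newick")
    assert t1 == t2


def test_core_without_mutation_or_recombination_is_constant():
    cfg = _two_leaf_config(substitution_rate=0.0)
    tree = simulate_genealogy(cfg)
    aln, events, _ = simulate_core(cfg, tree)
    assert events == []
    assert aln.sequences[0] == aln.sequences[1]


def test_no_between_clade_events_when_count_zero(study_sim):
    _, _, _, truth = study_sim
    assert truth.recomb_events  # the regime does recombine
    assert all(e.category != "between_clade" for e in truth.recomb_events)


def test_core_replay_oracle(study_sim):
    """Reapplying the truth log from the root reproduces every leaf
    sequence exactly."""
    cfg, aln, _, truth = study_sim
    replayed = replay_core(cfg, truth)
    for name, seq in zip(aln.names, aln.sequences):
        assert replayed[name] == seq


def test_gene_content_replay_oracle(study_sim):
    cfg, _, matrix, truth = study_sim
    rebuilt = replay_gene_content(cfg, truth.true_tree, truth.gene_events)
    pre = truth.pre_signature_matrix
    assert rebuilt.families == pre.families
    assert (rebuilt.data == pre.data).all()
    non_region = [i for i, f in enumerate(matrix.families)
                  if not f.startswith("reg")]
    assert (matrix.data[:, non_region] == rebuilt.data).all()


def test_gene_content_static_outside_region():
    cfg = study_config(seed=2, signature_noise=0.0, with_region_transfer=False)
    cfg.gain_rate = cfg.loss_rate = cfg.dup_rate = 0.0
    tree = simulate_genealogy(cfg)
    matrix, events = simulate_gene_content(cfg, tree)
    assert events == []
    non_region = [i for i, f in enumerate(matrix.families)
                  if not f.startswith("reg")]
    assert (matrix.data[:, non_region] == matrix.data[0, non_region]).all()


def test_region_transfer_gives_exact_donor_signature():
    cfg = study_config(seed=3, signature_noise=0.25)
    tree = simulate_genealogy(cfg)
    matrix, _ = simulate_gene_content(cfg, tree)
    recipient = cfg.region_transfer.recipient
    signature = np.array(cfg.ct_spec.signatures[cfg.region_transfer.donor_ct])
    region_cols = [i for i, f in enumerate(matrix.families)
                   if f.startswith("reg")]
    row = matrix.data[matrix.genomes.index(recipient), region_cols]
    assert (row == signature).all()


def test_gene_universe_exhaustion_raises():
    cfg = study_config(seed=0, core_length=10_000)
    cfg.gene_universe = cfg.root_gene_count + 5
    tree = simulate_genealogy(cfg)
    with pytest.raises(RuntimeError, match="universe"):
        simulate_gene_content(cfg, tree)


def test_emit_dataset_round_trip(tmp_path, study_sim):
    cfg, aln, matrix, truth = study_sim
    paths = emit_dataset(aln, matrix, truth, tmp_path, cfg)
    back = read_alignment(paths["alignment"])
    assert back.names == aln.names and back.sequences == aln.sequences
    m2 = GeneContentMatrix.read_tsv(paths["matrix"], paths["families"])
    assert m2.genomes == matrix.genomes
    assert (m2.data == matrix.data).all()
    assert m2.intervals == matrix.intervals
    bed = open(paths["hotspot"]).read().split("\t")
    assert int(bed[1]) == cfg.hotspot.start
    assert int(bed[2]) == cfg.hotspot.end  # 0-based half-open
    manifest = json.load(open(paths["manifest"]))
    assert manifest["seed"] == cfg.seed


def test_identical_config_gives_byte_identical_outputs(tmp_path):
    digests = []
    for sub in ("a", "b"):
        cfg = study_config(seed=9, core_length=10_000)
        aln, matrix, truth = simulate_dataset(cfg)
        paths = emit_dataset(aln, matrix, truth, tmp_path / sub, cfg)
        digests.append(
            tuple(open(p, "rb").read() for p in sorted(paths.values()))
        )
    assert digests[0] == digests[1]


def test_between_clade_divergence_matches_theory():
    """Mean between-clade divergence ~ 2 * mu * split depth within three
    standard errors over 20 replicates (hotspot disabled)."""
    estimates = []
    for seed in range(20):
        cfg = study_config(seed=200 + seed)
        cfg.hotspot = None
        cfg.gain_rate = cfg.loss_rate = cfg.dup_rate = 0.0
        tree = simulate_genealogy(cfg)
        aln, _, truth = simulate_core(cfg, tree)
        arr = aln.to_array()
        clades = {g: truth.labels[g][0] for g in aln.names}
        i_idx = [i for i, g in enumerate(aln.names) if clades[g] == "I"]
        v_idx = [i for i, g in enumerate(aln.names) if clades[g] == "V"]
        divs = [
            np.mean(arr[i] != arr[j]) for i in i_idx[:3] for j in v_idx[:3]
        ]
        estimates.append(np.mean(divs))
    expected = 2 * 0.0038 * 0.76
    se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
    assert abs(np.mean(estimates) - expected) < 3 * se + 1e-4


def test_config_round_trips_through_dict():
    cfg = study_config(seed=5)
    back = SimulationConfig.from_dict(
        json.loads(json.dumps(cfg.to_dict()))
    )
    assert back.config_hash() == cfg.config_hash()


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(seed=0, core_length=0)
    with pytest.raises(ValueError):
        SimulationConfig(seed=0, alphabet="rna")
    with pytest.raises(ValueError):
        SimulationConfig(seed=0, hotspot=Hotspot(500, 2000, 2.0),
                         core_length=1000)
    with pytest.raises(ValueError):
        SimulationConfig(seed=0, recomb_counts={"sideways": 1.0})
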