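"""Forward simulator of incipient clade divergence with recombination.

Generates the three inputs the analysis pipeline consumes — a core-genome
alignment, a gene-family copy-number matrix and a strain label table —
together with a complete ground-truth log (true genealogy, every
substitution, recombination tract and gene event), so downstream inference
can be scored against known truth.

The model, in outline:

* an ultrametric genealogy with two (or more) clades, each containing
  labelled populations (:func:`simulate_genealogy`);
* sites evolve under a single-parameter uniform-exchange substitution
  model, with an optional hotspot interval whose rate is multiplied
  (:func:`simulate_core`);
* homologous recombination is applied post hoc between leaf sequences:
  donor tracts (geometric lengths, uniform starts) overwrite recipient
  sequence, with separate expected event counts for within-population,
  between-population-within-clade and between-clade donor/recipient pairs;
* gene content evolves by gain (infinitely-many-genes: every gain is a
  previously unused family), loss and duplication along the same genealogy
  (:func:`simulate_gene_content`); a designated block of "region" families
  is then overwritten by per-compatibility-type signatures, emulating a
  hotspot region whose gene content tracks the social compatibility type
  (CT) rather than the core phylogeny.

All randomness flows from ``config.seed`` through per-stage child seeds, so
identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .genecontent import GeneContentMatrix
from .phylo import write_newick
from .variants import Alignment, alphabet_states, write_alignment

CATEGORIES = ("within_population", "between_population_within_clade", "between_clade")

__all__ = [
    "PopulationSpec",
    "CladeSpec",
    "Hotspot",
    "CTSpec",
    "RegionTransfer",
    "SimulationConfig",
    "RecombinationEvent",
    "TruthSet",
    "simulate_genealogy",
    "simulate_core",
    "simulate_gene_content",
    "simulate_dataset",
    "emit_dataset",
    "replay_core",
    "replay_gene_content",
    "study_config",
]


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class PopulationSpec:
    label: str
    n_leaves: int
    split_depth: float


@dataclass
class CladeSpec:
    """A clade: its crown (first within-clade split) depth and populations."""

    label: str
    crown_depth: float
    populations: list[PopulationSpec]


@dataclass
class Hotspot:
    start: int
    end: int
    rate_multiplier: float


@dataclass
class CTSpec:
    """Compatibility-type labels and per-CT region gene signatures.

    ``signatures`` maps each CT label to a copy-number vector over exactly
    the region families (0 absent / 1 single / 2 multicopy).
    """

    labels: dict[str, str]
    signatures: dict[str, list[int]]


@dataclass
class RegionTransfer:
    """Horizontal replacement of one genome's region content by a donor
    CT's signature (the A92-style incongruence generator)."""

    donor_ct: str
    recipient: str


@dataclass
class SimulationConfig:
    seed: int = 0
    clade_split_depth: float = 0.76
    clades: list[CladeSpec] = field(default_factory=list)
    core_length: int = 100_000
    alphabet: str = "nt"
    substitution_rate: float = 0.005
    hotspot: Hotspot | None = None
    recomb_counts: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in CATEGORIES}
    )
    tract_mean: float = 1000.0
    gene_universe: int = 15_000
    root_gene_count: int = 3000
    gain_rate: float = 0.0
    loss_rate: float = 0.0
    dup_rate: float = 0.0
    ct_spec: CTSpec | None = None
    signature_noise: float = 0.0
    region_transfer: RegionTransfer | None = None
    region_phage_families: int = 0
    background_phage_families: int = 0

    def __post_init__(self) -> None:
        if self.core_length <= 0:
            raise ValueError("core_length must be positive")
        for name in ("substitution_rate", "tract_mean", "gain_rate",
                     "loss_rate", "dup_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.alphabet not in ("nt", "aa"):
            raise ValueError("alphabet must be 'nt' or 'aa'")
        if self.hotspot is not None:
            h = self.hotspot
            if not (0 <= h.start < h.end <= self.core_length):
                raise ValueError("hotspot interval must lie within [0, L)")
        unknown = set(self.recomb_counts) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown recombination categories: {unknown}")
        if self.ct_spec is not None:
            lens = {len(v) for v in self.ct_spec.signatures.values()}
            if len(lens) > 1:
                raise ValueError("CT signatures must all cover the same families")

    @property
    def n_genomes(self) -> int:
        return sum(p.n_leaves for c in self.clades for p in c.populations)

    @property
    def n_region_families(self) -> int:
        if self.ct_spec is None:
            return 0
        return len(next(iter(self.ct_spec.signatures.values())))

    def genome_names(self) -> list[str]:
        names = []
        for clade in self.clades:
            for pop in clade.populations:
                for k in range(pop.n_leaves):
                    names.append(f"{clade.label}_{pop.label}_{k + 1:02d}")
        return names

    def labels(self) -> dict[str, tuple[str, str, str | None]]:
        """genome -> (clade, population, CT or None)."""
        out: dict[str, tuple[str, str, str | None]] = {}
        ct = self.ct_spec.labels if self.ct_spec else {}
        for clade in self.clades:
            for pop in clade.populations:
                for k in range(pop.n_leaves):
                    name = f"{clade.label}_{pop.label}_{k + 1:02d}"
                    out[name] = (clade.label, pop.label, ct.get(name))
        return out

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["clades"] = [
            CladeSpec(
                label=c["label"],
                crown_depth=c["crown_depth"],
                populations=[PopulationSpec(**p) for p in c["populations"]],
            )
            for c in d.get("clades", [])
        ]
        if d.get("hotspot") is not None:
            d["hotspot"] = Hotspot(**d["hotspot"])
        if d.get("ct_spec") is not None:
            d["ct_spec"] = CTSpec(**d["ct_spec"])
        if d.get("region_transfer") is not None:
            d["region_transfer"] = RegionTransfer(**d["region_transfer"])
        return cls(**d)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RecombinationEvent:
    donor: str
    recipient: str
    start: int
    end: int
    category: str

    def __post_init__(self) -> None:
        if self.donor == self.recipient:
            raise ValueError("donor must differ from recipient")
        if not (0 <= self.start < self.end):
            raise ValueError("invalid tract interval")


@dataclass
class TruthSet:
    """Full ground truth of one simulated dataset."""

    true_tree: dendropy.Tree
    root_sequence: str
    substitutions: dict[str, list[tuple[int, str]]]
    recomb_events: list[RecombinationEvent]
    gene_events: list[tuple[str, str, str]]
    labels: dict[str, tuple[str, str, str | None]]
    hotspot_interval: tuple[int, int] | None
    pre_signature_matrix: GeneContentMatrix | None = None


# ---------------------------------------------------------------------------
# Genealogy


def _caterpillar(subtrees: list[tuple[dendropy.Node, float]],
                 join_depths: list[float], counter: list[int]) -> tuple[dendropy.Node, float]:
    """Join subtrees left-to-right at the given (increasing) depths."""
    node, age = subtrees[0]
    for (other, other_age), depth in zip(subtrees[1:], join_depths):
        parent = dendropy.Node(label=f"n{counter[0]}")
        counter[0] += 1
        node.edge.length = depth - age
        other.edge.length = depth - other_age
        parent.add_child(node)
        parent.add_child(other)
        node, age = parent, depth
    return node, age


def simulate_genealogy(config: SimulationConfig) -> dendropy.Tree:
    """Deterministic ultrametric genealogy with the configured structure.

    Within a population, leaves join in a caterpillar at depths evenly
    spaced up to the population's split depth; populations within a clade
    join at depths interpolated between the deepest population split and
    the clade crown; clades join at ``clade_split_depth``. Internal nodes
    carry stable labels (``n0``, ``n1``, ...) used by the event logs.
    """
    if not config.clades or not any(c.populations for c in config.clades):
        raise ValueError("population specification is empty")
    ns = dendropy.TaxonNamespace(config.genome_names())
    counter = [0]
    clade_roots: list[tuple[dendropy.Node, float]] = []
    for clade in config.clades:
        pop_roots: list[tuple[dendropy.Node, float]] = []
        for pop in clade.populations:
            leaves = []
            for k in range(pop.n_leaves):
                leaf = dendropy.Node()
                leaf.taxon = ns.get_taxon(f"{clade.label}_{pop.label}_{k + 1:02d}")
                leaves.append((leaf, 0.0))
            if pop.n_leaves == 1:
                pop_roots.append(leaves[0])
                continue
            depths = [
                pop.split_depth * i / (pop.n_leaves - 1)
                for i in range(1, pop.n_leaves)
            ]
            pop_roots.append(_caterpillar(leaves, depths, counter))
        if len(pop_roots) == 1:
            clade_roots.append(pop_roots[0])
            continue
        max_pop = max(age for _, age in pop_roots)
        k = len(pop_roots)
        # population radiation: joins packed into the deepest 40% of the
        # span up to the crown, so every population keeps a long stem
        fracs = np.linspace(0.6, 1.0, k - 1)
        depths = [max_pop + (clade.crown_depth - max_pop) * f for f in fracs]
        clade_roots.append(_caterpillar(pop_roots, depths, counter))

    if len(clade_roots) == 1:
        root, _ = clade_roots[0]
    else:
        root, _ = _caterpillar(
            clade_roots,
            [config.clade_split_depth] * (len(clade_roots) - 1),
            counter,
        )
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    root.edge.length = None
    tree.is_rooted = True
    return tree


def _branch_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


# ---------------------------------------------------------------------------
# Core sequences


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def simulate_core(
    config: SimulationConfig, tree: dendropy.Tree
) -> tuple[Alignment, list[RecombinationEvent], TruthSet]:
    """Evolve the core alignment down *tree*, then apply recombination.

    Substitution counts per branch are Poisson with mean ``mu * t * L``
    (hotspot sites at ``rate_multiplier`` times the base rate); each
    substitution hits a uniform site and moves to a uniform alternative
    state. Recombination events are then applied between leaf sequences in
    a random order, each copying the donor's *current* tract into the
    recipient, and every event is logged with its pair category.
    """
    states = alphabet_states(config.alphabet)
    k = len(states)
    L = config.core_length
    rng = _rng(config, 1)
    root_seq = rng.integers(0, k, size=L, dtype=np.int8)

    if config.hotspot is not None:
        h = config.hotspot
        hot = np.arange(h.start, h.end)
        cold = np.concatenate([np.arange(0, h.start), np.arange(h.end, L)])
        mult = h.rate_multiplier
    else:
        hot = np.empty(0, dtype=int)
        cold = np.arange(L)
        mult = 1.0

    mu = config.substitution_rate
    seqs: dict[str, np.ndarray] = {}
    subs_log: dict[str, list[tuple[int, str]]] = {}

    stack = [(tree.seed_node, root_seq)]
    while stack:
        node, seq = stack.pop()
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            child_seq = seq.copy()
            events: list[tuple[int, str]] = []
            n_cold = rng.poisson(mu * t * len(cold))
            n_hot = rng.poisson(mu * t * mult * len(hot)) if len(hot) else 0
            sites = np.concatenate(
                [rng.choice(cold, size=n_cold), rng.choice(hot, size=n_hot)]
                if len(hot)
                else [rng.choice(cold, size=n_cold)]
            )
            rng.shuffle(sites)
            for site in sites:
                old = child_seq[site]
                new = (old + 1 + rng.integers(0, k - 1)) % k
                child_seq[site] = new
                events.append((int(site), states[new]))
            subs_log[_branch_label(child)] = events
            if child.is_leaf():
                seqs[child.taxon.label] = child_seq
            else:
                stack.append((child, child_seq))

    # recombination between leaves
    labels = config.labels()
    names = config.genome_names()
    pair_pool = {c: [] for c in CATEGORIES}
    for r in names:
        for d in names:
            if r == d:
                continue
            cr, pr, _ = labels[r]
            cd, pd_, _ = labels[d]
            if cr != cd:
                pair_pool["between_clade"].append((d, r))
            elif pr == pd_:
                pair_pool["within_population"].append((d, r))
            else:
                pair_pool["between_population_within_clade"].append((d, r))

    raw_events: list[RecombinationEvent] = []
    for cat in CATEGORIES:
        expected = float(config.recomb_counts.get(cat, 0.0))
        if expected <= 0 or not pair_pool[cat]:
            continue
        n_events = rng.poisson(expected)
        for _ in range(n_events):
            donor, recipient = pair_pool[cat][rng.integers(0, len(pair_pool[cat]))]
            length = rng.geometric(min(1.0, 1.0 / config.tract_mean))
            start = int(rng.integers(0, L))
            end = min(start + int(length), L)
            if end <= start:
                end = start + 1
            raw_events.append(RecombinationEvent(donor, recipient, start, end, cat))

    order = rng.permutation(len(raw_events))
    applied: list[RecombinationEvent] = []
    for idx in order:
        ev = raw_events[idx]
        seqs[ev.recipient][ev.start:ev.end] = seqs[ev.donor][ev.start:ev.end]
        applied.append(ev)

    alignment = Alignment(
        names=names,
        sequences=["".join(states[i] for i in seqs[n]) for n in names],
        alphabet=config.alphabet,
    )
    truth = TruthSet(
        true_tree=tree,
        root_sequence="".join(states[i] for i in root_seq),
        substitutions=subs_log,
        recomb_events=applied,
        gene_events=[],
        labels=labels,
        hotspot_interval=(
            (config.hotspot.start, config.hotspot.end) if config.hotspot else None
        ),
    )
    return alignment, applied, truth


def replay_core(
    config: SimulationConfig, truth: TruthSet
) -> dict[str, str]:
    """Reconstruct leaf sequences from the truth log alone (replay oracle)."""
    states = alphabet_states(config.alphabet)
    index = {s: i for i, s in enumerate(states)}
    root = np.array([index[c] for c in truth.root_sequence], dtype=np.int8)
    seqs: dict[str, np.ndarray] = {}
    stack = [(truth.true_tree.seed_node, root)]
    while stack:
        node, seq = stack.pop()
        for child in node.child_nodes():
            child_seq = seq.copy()
            for site, new_state in truth.substitutions[_branch_label(child)]:
                child_seq[site] = index[new_state]
            if child.is_leaf():
                seqs[child.taxon.label] = child_seq
            else:
                stack.append((child, child_seq))
    for ev in truth.recomb_events:
        seqs[ev.recipient][ev.start:ev.end] = seqs[ev.donor][ev.start:ev.end]
    return {n: "".join(states[i] for i in s) for n, s in seqs.items()}


# ---------------------------------------------------------------------------
# Gene content


def _family_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    core = [f"fam{i:05d}" for i in range(config.gene_universe)]
    region = [f"reg{i:04d}" for i in range(config.n_region_families)]
    return core, region


def simulate_gene_content(
    config: SimulationConfig, tree: dendropy.Tree
) -> tuple[GeneContentMatrix, list[tuple[str, str, str]]]:
    """Gene gain/loss/duplication down *tree*, then CT-signature overwrite.

    Rates are per time unit: ``gain_rate`` per genome (each gain draws a
    never-before-used family at copy number 1), ``loss_rate`` per present
    family (sets copy number to 0), ``dup_rate`` per present family (one
    increment per event). Region families are then replaced by the leaf's
    CT signature with per-gene presence-flip noise; an optional
    ``region_transfer`` finally replaces one genome's region content with
    the donor CT's exact signature.
    """
    rng = _rng(config, 2)
    G = config.gene_universe
    if config.root_gene_count > G:
        raise ValueError("root_gene_count exceeds gene universe")
    core_ids, region_ids = _family_ids(config)

    root_row = np.zeros(G, dtype=np.int64)
    root_row[: config.root_gene_count] = 1
    next_family = [config.root_gene_count]
    events: list[tuple[str, str, str]] = []
    rows: dict[str, np.ndarray] = {}

    stack = [(tree.seed_node, root_row)]
    while stack:
        node, row = stack.pop()
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            child_row = row.copy()
            branch = _branch_label(child)
            n_gain = rng.poisson(config.gain_rate * t)
            for _ in range(n_gain):
                if next_family[0] >= G:
                    raise RuntimeError("gene universe exhausted; raise gene_universe")
                fam = next_family[0]
                next_family[0] += 1
                child_row[fam] = 1
                events.append((branch, core_ids[fam], "gain"))
            present = np.flatnonzero(child_row)
            if config.loss_rate > 0 and len(present):
                p_loss = 1.0 - np.exp(-config.loss_rate * t)
                lost = present[rng.random(len(present)) < p_loss]
                for fam in lost:
                    child_row[fam] = 0
                    events.append((branch, core_ids[fam], "loss"))
            present = np.flatnonzero(child_row)
            if config.dup_rate > 0 and len(present):
                dups = rng.poisson(config.dup_rate * t, size=len(present))
                for fam, n_dup in zip(present, dups):
                    for _ in range(n_dup):
                        child_row[fam] += 1
                        events.append((branch, core_ids[fam], "duplication"))
            if child.is_leaf():
                rows[child.taxon.label] = child_row
            else:
                stack.append((child, child_row))

    names = config.genome_names()
    used = next_family[0]
    data = np.stack([rows[n][:used] for n in names])
    families = core_ids[:used] + region_ids
    R = config.n_region_families
    if R:
        sig_block = np.zeros((len(names), R), dtype=np.int64)
        ct_labels = config.ct_spec.labels
        for i, n in enumerate(names):
            sig = np.array(config.ct_spec.signatures[ct_labels[n]], dtype=np.int64)
            if config.signature_noise > 0:
                flip = rng.random(R) < config.signature_noise
                sig = sig.copy()
                sig[flip] = np.where(sig[flip] > 0, 0, 1)
            sig_block[i] = sig
        if config.region_transfer is not None:
            rt = config.region_transfer
            sig_block[names.index(rt.recipient)] = np.array(
                config.ct_spec.signatures[rt.donor_ct], dtype=np.int64
            )
        data = np.hstack([data, sig_block])

    intervals, categories = _annotate_families(config, families)
    matrix = GeneContentMatrix(
        genomes=names,
        families=families,
        data=data,
        intervals=intervals,
        categories=categories,
    )
    return matrix, events


def _annotate_families(config: SimulationConfig, families: list[str]):
    """Place region families inside the hotspot interval and tag phage
    families per config (structure of the study's 12-vs-8 contrast)."""
    intervals: dict[str, tuple[int, int]] = {}
    categories: dict[str, str] = {}
    region = [f for f in families if f.startswith("reg")]
    if region and config.hotspot is not None:
        start, end = config.hotspot.start, config.hotspot.end
        width = max(1, (end - start) // len(region))
        for i, fam in enumerate(region):
            s = start + i * width
            intervals[fam] = (s, min(s + width, end))
    for i, fam in enumerate(region[: config.region_phage_families]):
        categories[fam] = "phage"
    non_region = [f for f in families if not f.startswith("reg")]
    for fam in non_region[: config.background_phage_families]:
        categories[fam] = "phage"
    return intervals, categories


def replay_gene_content(
    config: SimulationConfig, tree: dendropy.Tree, events: list[tuple[str, str, str]]
) -> GeneContentMatrix:
    """Rebuild the pre-signature leaf matrix from the event log alone."""
    core_ids, region_ids = _family_ids(config)
    index = {f: i for i, f in enumerate(core_ids)}
    by_branch: dict[str, list[tuple[str, str]]] = {}
    for branch, fam, kind in events:
        by_branch.setdefault(branch, []).append((fam, kind))

    root_row = np.zeros(config.gene_universe, dtype=np.int64)
    root_row[: config.root_gene_count] = 1
    rows: dict[str, np.ndarray] = {}
    stack = [(tree.seed_node, root_row)]
    max_used = config.root_gene_count
    while stack:
        node, row = stack.pop()
        for child in node.child_nodes():
            child_row = row.copy()
            for fam, kind in by_branch.get(_branch_label(child), []):
                i = index[fam]
                max_used = max(max_used, i + 1)
                if kind == "gain":
                    child_row[i] = 1
                elif kind == "loss":
                    child_row[i] = 0
                elif kind == "duplication":
                    child_row[i] += 1
            if child.is_leaf():
                rows[child.taxon.label] = child_row
            else:
                stack.append((child, child_row))
    names = config.genome_names()
    return GeneContentMatrix(
        genomes=names,
        families=core_ids[:max_used],
        data=np.stack([rows[n][:max_used] for n in names]),
    )


# ---------------------------------------------------------------------------
# Whole-dataset convenience and emission


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[Alignment, GeneContentMatrix, TruthSet]:
    tree = simulate_genealogy(config)
    alignment, _, truth = simulate_core(config, tree)
    matrix, gene_events = simulate_gene_content(config, tree)
    truth.gene_events = gene_events
    truth.pre_signature_matrix = replay_gene_content(config, tree, gene_events)
    return alignment, matrix, truth


def emit_dataset(
    alignment: Alignment,
    matrix: GeneContentMatrix,
    truth: TruthSet,
    out_dir,
    config: SimulationConfig | None = None,
) -> dict[str, str]:
    """Write the dataset as plain-text files; returns path map.

    FASTA alignment, TSV copy-number matrix (+ family annotations), TSV
    labels, Newick true tree, JSON event logs, BED hotspot (0-based
    half-open) and a JSON manifest with the seed and a config hash.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "alignment": os.path.join(out_dir, "core_alignment.fasta"),
        "matrix": os.path.join(out_dir, "gene_content.tsv"),
        "families": os.path.join(out_dir, "gene_families.tsv"),
        "labels": os.path.join(out_dir, "labels.tsv"),
        "tree": os.path.join(out_dir, "true_tree.nwk"),
        "events": os.path.join(out_dir, "events.json"),
        "hotspot": os.path.join(out_dir, "hotspot.bed"),
        "manifest": os.path.join(out_dir, "manifest.json"),
    }
    write_alignment(alignment, paths["alignment"])
    matrix.write_tsv(paths["matrix"], annotations_path=paths["families"])
    with open(paths["labels"], "w") as fh:
        fh.write("genome\tclade\tpopulation\tct\n")
        for g, (clade, pop, ct) in truth.labels.items():
            fh.write(f"{g}\t{clade}\t{pop}\t{ct if ct is not None else ''}\n")
    write_newick(truth.true_tree, paths["tree"])
    with open(paths["events"], "w") as fh:
        json.dump(
            {
                "root_sequence": truth.root_sequence,
                "substitutions": truth.substitutions,
                "recombination": [dataclasses.asdict(e) for e in truth.recomb_events],
                "gene_events": truth.gene_events,
            },
            fh,
        )
    with open(paths["hotspot"], "w") as fh:
        if truth.hotspot_interval is not None:
            s, e = truth.hotspot_interval
            fh.write(f"replicon\t{s}\t{e}\thotspot\n")
    manifest = {
        "seed": config.seed if config is not None else None,
        "config_hash": config.config_hash() if config is not None else None,
        "n_genomes": alignment.n_genomes,
        "core_length": alignment.length,
        "n_families": len(matrix.families),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# The default study configuration


#: Table of (clade, population, CT) labels for the 22-genome study
#: structure: clade I holds populations p5-p7 (12 genomes, three of them in
#: the deeply diverged p7 subclade side), clade V populations p1-p4
#: (10 genomes). CTs follow the observed one-CT-per-phylogenetic-group
#: pattern, with two deliberate wrinkles mirroring the natural isolates:
#: one p6 genome carries the CT of the p7 group (the A92 analogue) and one
#: p3 genome shares its CT with the p2 pair (a CT spanning populations).
_STUDY_STRUCTURE = [
    ("I", "p7", 5, "ct11"),
    ("I", "p6", 5, None),  # per-genome CTs ct11, ct10, ct9, ct8, ct7
    ("I", "p5", 2, "ct6"),
    ("V", "p4", 3, "ct5"),
    ("V", "p3", 3, None),  # per-genome CTs ct4, ct3, ct2
    ("V", "p2", 2, "ct2"),
    ("V", "p1", 2, "ct1"),
]

_P6_CTS = ["ct11", "ct10", "ct9", "ct8", "ct7"]
_P3_CTS = ["ct4", "ct3", "ct2"]


def _study_ct_labels() -> dict[str, str]:
    labels: dict[str, str] = {}
    for clade, pop, n, ct in _STUDY_STRUCTURE:
        for k in range(n):
            name = f"{clade}_{pop}_{k + 1:02d}"
            if ct is not None:
                labels[name] = ct
            elif pop == "p6":
                labels[name] = _P6_CTS[k]
            else:
                labels[name] = _P3_CTS[k]
    return labels


def _study_signatures(n_region: int, seed: int) -> dict[str, list[int]]:
    """Distinct per-CT copy-number signatures over the region families.

    Drawn once from a fixed child seed: each gene absent (p=0.45),
    single-copy (0.45) or multicopy (0.10), redrawn until all CTs are
    mutually distinct in >= 25% of genes.
    """
    rng = np.random.default_rng([seed, 3])
    cts = sorted({ct for ct in _study_ct_labels().values()})
    while True:
        sigs = {
            ct: rng.choice([0, 1, 2], size=n_region, p=[0.45, 0.45, 0.10]).tolist()
            for ct in cts
        }
        ok = all(
            np.mean(np.array(sigs[a]) != np.array(sigs[b])) >= 0.25
            for i, a in enumerate(cts)
            for b in cts[i + 1 :]
        )
        if ok:
            return sigs


def _study_clades(clade_v_crown: float, pop_depth_frac: float
                  ) -> list[CladeSpec]:
    """Two clades with the 22-genome study structure.

    Clade I (12 genomes, populations p5-p7) is ten-fold more diverse than
    clade V (10 genomes, populations p1-p4): its crown sits at ten times
    clade V's crown depth.
    """
    ci = 10.0 * clade_v_crown
    cv = clade_v_crown
    clade_i = CladeSpec(
        label="I",
        crown_depth=ci,
        populations=[
            PopulationSpec("p5", 2, pop_depth_frac * ci),
            PopulationSpec("p6", 5, pop_depth_frac * ci),
            PopulationSpec("p7", 5, pop_depth_frac * ci),
        ],
    )
    clade_v = CladeSpec(
        label="V",
        crown_depth=cv,
        populations=[
            PopulationSpec("p1", 2, pop_depth_frac * cv),
            PopulationSpec("p2", 2, pop_depth_frac * cv),
            PopulationSpec("p3", 3, pop_depth_frac * cv),
            PopulationSpec("p4", 3, pop_depth_frac * cv),
        ],
    )
    return [clade_i, clade_v]


def _study_base(
    seed: int,
    core_length: int,
    clades: list[CladeSpec],
    recomb: dict[str, float],
    tract_mean: float,
    n_region_families: int,
    signature_noise: float,
    with_region_transfer: bool,
) -> SimulationConfig:
    ct = CTSpec(labels=_study_ct_labels(),
                signatures=_study_signatures(n_region_families, seed))
    transfer = (
        RegionTransfer(donor_ct="ct11", recipient="I_p6_01")
        if with_region_transfer
        else None
    )
    return SimulationConfig(
        seed=seed,
        clade_split_depth=0.76,
        clades=clades,
        core_length=core_length,
        alphabet="nt",
        # genome-wide expected between-clade divergence = 2 * 0.76 * mu *
        # (1 + hotspot_frac * (mult - 1)) = 0.75% with the 10%-at-4x hotspot
        substitution_rate=0.0038,
        hotspot=Hotspot(int(core_length * 0.60), int(core_length * 0.70), 4.0),
        recomb_counts=recomb,
        tract_mean=tract_mean,
        gene_universe=15_000,
        root_gene_count=3000,
        gain_rate=1000.0,
        loss_rate=0.35,
        dup_rate=0.05,
        ct_spec=ct,
        signature_noise=signature_noise,
        region_transfer=transfer,
        region_phage_families=12,
        background_phage_families=8,
    )


def study_config(
    seed: int = 0,
    core_length: int = 100_000,
    recomb_counts: dict[str, float] | None = None,
    n_region_families: int = 40,
    signature_noise: float = 0.02,
    with_region_transfer: bool = True,
) -> SimulationConfig:
    """The default simulation: 22 genomes with the study population structure.

    Two clades at ~0.76% expected divergence, within-clade diversities
    scaled to the clade split (clade I crown at one tenth of the split,
    clade V ten-fold less diverse again); seven populations; recombination
    overwhelmingly within populations with a complete between-clade
    barrier by default (calibrated so per-pair co-ancestry lands in the
    observed 12-25% same-population / 5-12% same-clade bands); a 10-kb
    hotspot at 4x substitution rate holding the CT-signature region
    families; gene gain/loss/duplication rates giving accessory turnover
    well above the core amino-acid substitution rate.
    """
    recomb = recomb_counts or {
        "within_population": 200.0,
        "between_population_within_clade": 40.0,
        "between_clade": 0.0,
    }
    return _study_base(
        seed, core_length, _study_clades(0.0076, 0.25), recomb, 1000.0,
        n_region_families, signature_noise, with_region_transfer,
    )


def equal_intensity_config(seed: int = 0, core_length: int = 100_000
                           ) -> SimulationConfig:
    """Barrier-absent regime for calibrating the homoplasy test.

    Event counts are set so the expected number of between-clade events
    equals the expected number of clade-I cross-subclade events: clade I's
    crown split puts 70 of the 164 ordered between-population-within-clade
    pairs across its subclades, so 28 between-population events yield ~12
    cross-subclade events, matching 12 between-clade events. With equal
    event counts, homoplasy yields are proportional to the divergence of
    the sequences exchanged — exactly the proportionality null of the
    barrier test. Tracts are short (mean 100 sites, ~1 homoplasy per
    between-clade event) to keep per-event clumping small.
    """
    recomb = {
        "within_population": 0.0,
        "between_population_within_clade": 28.0,
        "between_clade": 12.0,
    }
    return _study_base(
        seed, core_length, _study_clades(0.0076, 0.25), recomb, 100.0,
        40, 0.02, False,
    )


def well_separated_config(seed: int = 0, core_length: int = 100_000
                          ) -> SimulationConfig:
    """The population-recovery regime: same 22-genome structure as
    :func:`study_config` but with within-clade diversities scaled up
    (clade V crown 0.04, clade I 0.4; the 10-fold ratio preserved) and
    intense, short-tract within-population recombination (20-fold the
    between-population rate), so that population membership carries enough
    signal for co-ancestry clustering on a 100-kb core.

    A 100-kb alignment at the real isolates' per-site within-clade
    diversities would hold only a handful of within-clade SNPs — far less
    information than the multi-Mb alignment population inference was
    designed for — so population-recovery analyses use this regime.
    """
    recomb = {
        "within_population": 3200.0,
        "between_population_within_clade": 160.0,
        "between_clade": 0.0,
    }
    return _study_base(
        seed, core_length, _study_clades(0.04, 0.05), recomb, 250.0,
        40, 0.02, True,
    )


def turnover_config(seed: int = 0, rate_ratio: float = 10.0,
                    core_length: int = 50_000) -> SimulationConfig:
    """Gene-turnover parameter-recovery regime.

    Gene content changes by gain only (every gain is a unique family, so
    content differences accumulate linearly along paths) at
    ``rate_ratio`` times the core substitution rate mu * L; the fitted
    turnover intercept should recover ``rate_ratio``. The substitution
    rate is raised so even the shallowest independent pairs carry enough
    core differences for a stable log-log fit.
    """
    # mu and the population depths together put ~30+ differences on even
    # the shallowest independent pair, keeping the log-log fit's intercept
    # away from low-count leverage points
    mu = 1500.0 / core_length
    ct = CTSpec(labels=_study_ct_labels(), signatures=_study_signatures(10, seed))
    return SimulationConfig(
        seed=seed,
        clade_split_depth=0.76,
        clades=_study_clades(0.04, 0.5),
        core_length=core_length,
        substitution_rate=mu,
        hotspot=None,
        recomb_counts={c: 0.0 for c in CATEGORIES},
        tract_mean=1000.0,
        # headroom: total tree length of the study geometry is < 4 time units
        gene_universe=1000 + int(4.0 * rate_ratio * mu * core_length) + 1000,
        root_gene_count=1000,
        gain_rate=rate_ratio * mu * core_length,
        loss_rate=0.0,
        dup_rate=0.0,
        ct_spec=ct,
        signature_noise=0.0,
    )
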