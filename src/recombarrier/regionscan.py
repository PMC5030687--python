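"""Sliding-window diversity scans, hotspot regions and CT concordance.

Finds coordinate-localised SNP-density hotspots, then asks whether the
gene content of a detected region partitions the genomes according to
their social compatibility type (CT) rather than the core phylogeny, and
whether a gene category (e.g. phage-related genes) is enriched in the
region.

Internal coordinates are 0-based half-open; report tables carry 1-based
inclusive positions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from . import phylo
from .genecontent import GeneContentMatrix
from .variants import VariantTable

__all__ = [
    "WindowScan",
    "Region",
    "ConcordanceResult",
    "EnrichmentResult",
    "snp_density_scan",
    "detect_regions",
    "ct_concordance",
    "category_enrichment",
]


@dataclass
class WindowScan:
    window: int
    step: int
    starts: np.ndarray
    widths: np.ndarray
    densities: np.ndarray
    total_length: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_1based": self.starts + 1,
                "end_1based": self.starts + self.widths,
                "density": self.densities,
            }
        )


@dataclass
class Region:
    start: int
    end: int
    mean_density: float
    window_indices: list[int] = field(default_factory=list)

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def report_coords(self) -> tuple[int, int]:
        """1-based inclusive coordinates for human-readable reports."""
        return self.start + 1, self.end


def snp_density_scan(
    v: VariantTable,
    L: int | None = None,
    window: int = 10_000,
    step: int = 1_000,
    genomes: list[str] | None = None,
) -> WindowScan:
    """SNPs per bp in sliding windows (final partial window normalised by
    its true width). ``genomes`` restricts the scan to the sites still
    polymorphic within that subset (per-clade scans)."""
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    L = L if L is not None else v.total_sites
    if L < window:
        raise ValueError("alignment shorter than one window")
    positions = v.positions
    if genomes is not None:
        rows = [v.names.index(g) for g in genomes]
        sub = v.alleles[rows]
        poly = (sub != sub[0]).any(axis=0)
        positions = v.positions[poly]
    starts = np.arange(0, L, step)
    widths = np.minimum(window, L - starts)
    lo = np.searchsorted(positions, starts)
    hi = np.searchsorted(positions, starts + widths)
    densities = (hi - lo) / widths
    return WindowScan(window=window, step=step, starts=starts, widths=widths,
                      densities=densities, total_length=L)


def detect_regions(scan: WindowScan, k_sd: float = 3.0) -> list[Region]:
    """Merge windows with density above mean + k_sd * SD into regions."""
    if len(scan.densities) < 2:
        raise ValueError("need >=2 windows")
    sd = float(scan.densities.std())
    if sd == 0:
        return []
    threshold = float(scan.densities.mean()) + k_sd * sd
    flagged = np.flatnonzero(scan.densities > threshold)
    regions: list[Region] = []
    for idx in flagged:
        s = int(scan.starts[idx])
        e = int(scan.starts[idx] + scan.widths[idx])
        if regions and s <= regions[-1].end:
            regions[-1].end = max(regions[-1].end, e)
            regions[-1].window_indices.append(int(idx))
        else:
            regions.append(Region(start=s, end=e, mean_density=0.0,
                                  window_indices=[int(idx)]))
    for region in regions:
        region.mean_density = float(
            scan.densities[region.window_indices].mean()
        )
    return regions


@dataclass
class ConcordanceResult:
    ari: float
    region_families: list[str]
    groups: dict[str, int]
    ct_monophyly: dict[str, bool]
    incongruent: list[str]
    region_tree: dendropy.Tree | None = None

    def summary(self) -> str:
        mono = sum(self.ct_monophyly.values())
        return (
            f"region gene-content vs CT: ARI = {self.ari:.3f}; "
            f"{mono}/{len(self.ct_monophyly)} CTs monophyletic on the region "
            f"tree; incongruent genomes: "
            f"{', '.join(self.incongruent) if self.incongruent else 'none'}"
        )


def _region_families(m: GeneContentMatrix, region: Region) -> list[str]:
    fams = [
        f
        for f in m.families
        if f in m.intervals
        and m.intervals[f][0] < region.end
        and m.intervals[f][1] > region.start
    ]
    if not fams:
        raise ValueError("region contains no annotated families")
    return fams


def _is_monophyletic(tree: dendropy.Tree, members: set[str]) -> bool:
    """Unrooted monophyly: some edge splits exactly this leaf set off."""
    if len(members) <= 1:
        return True
    all_leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    for node in tree.postorder_node_iter():
        if node.parent_node is None:
            continue
        side = {l.taxon.label for l in node.leaf_iter()}
        if side == members or side == all_leaves - members:
            return True
    return False


def ct_concordance(
    m: GeneContentMatrix,
    region: Region,
    ct_labels: dict[str, str],
    core_tree: dendropy.Tree,
    bootstrap: int = 0,
    seed: int = 0,
) -> ConcordanceResult:
    """Concordance between region gene content and CT labels.

    Genomes are partitioned by identical copy-number profile over the
    region's families; the adjusted Rand index scores that partition
    against the CT labels. A parsimony tree on the region characters
    (states capped at 0/1/2 = absent/single/multicopy) gives per-CT
    monophyly flags, with optional bootstrap supports. A genome is
    incongruent when its region group (of size >= 2) has a majority CT
    different from the CT of its nearest core-tree neighbours — the
    signature of a horizontally acquired region signature.
    """
    fams = _region_families(m, region)
    cols = [m.families.index(f) for f in fams]
    block = m.data[:, cols]
    profiles: dict[tuple, int] = {}
    groups: dict[str, int] = {}
    for i, g in enumerate(m.genomes):
        key = tuple(block[i])
        profiles.setdefault(key, len(profiles))
        groups[g] = profiles[key]
    cts = [ct_labels[g] for g in m.genomes]
    ari = float(adjusted_rand_score(cts, [groups[g] for g in m.genomes]))

    region_tree = None
    monophyly: dict[str, bool] = {}
    capped = np.minimum(block, 2)
    variable = (capped.max(axis=0) != capped.min(axis=0)).any()
    if len(m.genomes) >= 4 and variable:
        matrix = phylo.CharacterMatrix(list(m.genomes), capped, fams)
        if bootstrap > 0:
            region_tree = phylo.bootstrap_support(matrix, B=bootstrap, seed=seed)
        else:
            region_tree = phylo.parsimony_tree(matrix)
        for ct in sorted(set(cts)):
            members = {g for g in m.genomes if ct_labels[g] == ct}
            monophyly[ct] = _is_monophyletic(region_tree, members)

    incongruent = _incongruent_genomes(m.genomes, groups, ct_labels, core_tree)
    return ConcordanceResult(
        ari=ari,
        region_families=fams,
        groups=groups,
        ct_monophyly=monophyly,
        incongruent=incongruent,
        region_tree=region_tree,
    )


def _incongruent_genomes(
    genomes: list[str],
    groups: dict[str, int],
    ct_labels: dict[str, str],
    core_tree: dendropy.Tree,
) -> list[str]:
    names, dist = phylo.patristic_distances(core_tree)
    index = {n: i for i, n in enumerate(names)}
    out = []
    for g in genomes:
        co = [h for h in genomes if h != g and groups[h] == groups[g]]
        if not co:
            continue  # singleton region group: no grouping evidence
        group_majority = Counter(
            ct_labels[h] for h in co + [g]
        ).most_common(1)[0][0]
        row = dist[index[g]].copy()
        row[index[g]] = np.inf
        nearest = np.flatnonzero(np.isclose(row, row.min()))
        nn_majority = Counter(
            ct_labels[names[i]] for i in nearest
        ).most_common(1)[0][0]
        if group_majority != nn_majority:
            out.append(g)
    return out


@dataclass
class EnrichmentResult:
    in_region_category: int
    in_region_other: int
    outside_category: int
    outside_other: int
    odds_ratio: float
    p_value: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": [self.in_region_category, self.outside_category],
                "other": [self.in_region_other, self.outside_other],
            },
            index=["in_region", "outside"],
        )


def category_enrichment(
    m: GeneContentMatrix,
    region: Region,
    category_tag: str = "phage",
    genome_total: int | None = None,
) -> EnrichmentResult:
    """One-sided hypergeometric (Fisher's exact) enrichment of a family
    category inside a region.

    ``genome_total`` is the genome-wide family count (defaults to the
    matrix's family count). Odds ratio uses a Haldane 0.5 correction on
    zero cells.
    """
    region_fams = set(_region_families(m, region))
    total = genome_total if genome_total is not None else len(m.families)
    if total < len(region_fams):
        raise ValueError("genome_total smaller than region family count")
    category = {f for f in m.families if m.categories.get(f) == category_tag}
    a = len(region_fams & category)
    b = len(region_fams) - a
    c = len(category - region_fams)
    d = (total - len(region_fams)) - c
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent counts for the 2x2 table")
    p = float(stats.hypergeom.sf(a - 1, total, len(category), len(region_fams)))
    cells = [a, b, c, d]
    if 0 in cells:
        a_, b_, c_, d_ = (x + 0.5 for x in cells)
    else:
        a_, b_, c_, d_ = cells
    odds = (a_ * d_) / (b_ * c_)
    return EnrichmentResult(
        in_region_category=a,
        in_region_other=b,
        outside_category=c,
        outside_other=d,
        odds_ratio=float(odds),
        p_value=p,
    )
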