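"""Homoplasic SNPs on a fixed tree and the divergence-scaled barrier test.

A SNP is homoplasic when its allele pattern needs at least two state
changes on the tree (Fitch minimal change count >= 2): recurrent mutation
or, far more often among close relatives, homologous recombination.
Homoplasies whose derived allele is shared by members of both clades
witness between-clade recombination; those shared across the two deep
subclades of one clade witness within-clade recombination at a known,
much smaller, divergence. Scaling the two counts by the divergence ratio
gives a conditional binomial test of a recombination barrier.

Polarisation matters for the classification: a transferred clade-consensus
allele leaves the *minor* allele confined to the untouched clade, so
judging sharing by the minor allele misattributes exactly the event class
the test is about. When ancestral states are available (an outgroup
reference, or the simulator's root sequence) the derived allele is used;
without them the minor-allele convention is the fallback, with that caveat.

The binomial formalisation is this package's construction: under the null
of equal recombination intensity across versus within clades, homoplasy
counts should be proportional to divergence, so conditional on
N = n_between + n_within, n_between ~ Binomial(N, R / (1 + R)); a small
lower-tail probability indicates a deficit of between-clade homoplasies —
a barrier.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .phylo import CharacterMatrix, fitch_lengths
from .variants import VariantTable

__all__ = [
    "CladePartition",
    "HomoplasySite",
    "HomoplasyCounts",
    "BarrierTestResult",
    "detect_homoplasies",
    "classify_homoplasies",
    "barrier_test",
    "homoplasy_table",
]


@dataclass
class CladePartition:
    """Genome -> clade labels, with optional nested subclade labels.

    Subclades must nest inside a single clade each (they mark the deep
    split within one clade used by the within-clade homoplasy count).
    """

    clades: dict[str, str]
    subclades: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        owner: dict[str, str] = {}
        for g, sub in self.subclades.items():
            if g not in self.clades:
                raise ValueError(f"subclade label for unknown genome {g!r}")
            clade = self.clades[g]
            if owner.setdefault(sub, clade) != clade:
                raise ValueError(f"subclade {sub!r} spans multiple clades")


@dataclass
class HomoplasySite:
    """One flagged variant site.

    ``carriers`` holds the minor allele's carriers; ``allele_carriers``
    every allele's carriers; ``derived_alleles`` the alleles differing
    from the ancestral state when one was supplied (None otherwise).
    """

    site: int
    position: int
    k: int
    minor_allele: str
    carriers: frozenset[str]
    allele_carriers: dict[str, frozenset[str]] = field(default_factory=dict)
    derived_alleles: list[str] | None = None
    multiallelic: bool = False


@dataclass
class HomoplasyCounts:
    n_between: int
    n_within_per_clade: dict[str, int]
    n_other: int
    between_sites: list[HomoplasySite] = field(default_factory=list)
    within_sites: list[HomoplasySite] = field(default_factory=list)

    @property
    def n_within(self) -> int:
        return sum(self.n_within_per_clade.values())


@dataclass
class BarrierTestResult:
    n_between: int
    n_within: int
    divergence_ratio: float
    null_proportion: float
    p_value: float
    direction: str

    def summary(self) -> str:
        return (
            f"{self.n_between} between-clade vs {self.n_within} cross-subclade "
            f"homoplasies; null P(between) = {self.null_proportion:.4f} "
            f"(divergence ratio {self.divergence_ratio:g}); one-sided lower-tail "
            f"p = {self.p_value:.3g} ({self.direction})"
        )


def _minor_allele(column: dict[str, str], reference: str | None) -> str:
    counts = Counter(column.values())
    least = min(counts.values())
    tied = sorted(a for a, c in counts.items() if c == least)
    if len(tied) == 1:
        return tied[0]
    if reference is not None and reference in column:
        non_ref = [a for a in tied if a != column[reference]]
        if non_ref:
            return non_ref[0]
    return tied[0]


def detect_homoplasies(
    v: VariantTable,
    tree: dendropy.Tree,
    reference: str | None = None,
    ancestral: Mapping[int, str] | None = None,
    include_multiallelic: bool = False,
) -> list[HomoplasySite]:
    """Flag variant sites needing >= 2 changes on *tree*.

    Biallelic sites only by default; multiallelic sites are skipped (or,
    with ``include_multiallelic``, scored on their full state set and
    flagged with ``multiallelic=True``).

    ``ancestral`` optionally maps alignment positions (0-based) to the
    ancestral state, enabling derived-allele polarisation downstream; a
    position absent from the mapping leaves that site unpolarised. With no
    ancestral information the minor allele is recorded (an exact frequency
    tie resolves to the allele not carried by *reference*, else
    lexicographically).
    """
    tree_leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    missing = [g for g in v.names if g not in tree_leaves]
    if missing:
        raise KeyError(f"genomes absent from tree: {missing}")
    if tree_leaves - set(v.names):
        tree = tree.extract_tree_with_taxa_labels(labels=v.names)

    n_alleles = np.array(
        [len(set(v.alleles[:, i].tobytes().decode())) for i in range(v.n_sites)]
    )
    results: list[HomoplasySite] = []
    for multi in (False, True):
        if multi and not include_multiallelic:
            break
        idx = np.flatnonzero(n_alleles == 2) if not multi else np.flatnonzero(
            n_alleles > 2
        )
        if len(idx) == 0:
            continue
        # recode each site's states to small integers for the Fitch scorer
        data = np.zeros((len(v.names), len(idx)), dtype=np.int64)
        for col, i in enumerate(idx):
            states = sorted(set(v.alleles[:, i].tobytes().decode()))
            recode = {s.encode(): j for j, s in enumerate(states)}
            data[:, col] = [recode[bytes(b)] for b in v.alleles[:, i]]
        ks = fitch_lengths(tree, CharacterMatrix(list(v.names), data))
        for col, i in enumerate(idx):
            if ks[col] < 2:
                continue
            column = v.site_alleles(i)
            minor = _minor_allele(column, reference)
            allele_carriers = {
                allele: frozenset(g for g, a in column.items() if a == allele)
                for allele in set(column.values())
            }
            position = int(v.positions[i])
            derived = None
            if ancestral is not None and position in ancestral:
                derived = sorted(
                    a for a in allele_carriers if a != ancestral[position]
                )
            results.append(
                HomoplasySite(
                    site=int(i),
                    position=position,
                    k=int(ks[col]),
                    minor_allele=minor,
                    carriers=allele_carriers[minor],
                    allele_carriers=allele_carriers,
                    derived_alleles=derived,
                    multiallelic=multi,
                )
            )
    results.sort(key=lambda s: s.site)
    return results


def classify_homoplasies(
    sites: list[HomoplasySite],
    partition: CladePartition,
    method: str = "auto",
) -> HomoplasyCounts:
    """Split homoplasies into between-clade, within-clade cross-subclade
    and other.

    With polarised sites (``method="derived"``; ``"auto"`` where
    available) the derived allele's carrier span decides: the site counts
    as between-clade iff some derived allele is carried in at least two
    clades; failing that, as within-clade cross-subclade iff some derived
    allele's carriers sit in one clade, intersect two of its subclades,
    and are a minority (at most half the members) in at least one of those
    subclades. The minority guard distinguishes a genuinely transferred
    fragment — a minority presence in the receiving subclade — from a
    clade-wide allele with a single reversion hole, whose carriers remain
    at near-consensus in both subclades. (Between-clade counting needs no
    guard: the receiving clade's presence is an island by construction.)
    Unpolarised sites fall back to the minor allele's carrier span
    (``method="minor"``), with the caveat that a transferred
    clade-consensus allele leaves the minor allele confined to the
    untouched clade.
    """
    if method not in ("auto", "derived", "minor"):
        raise ValueError("method must be 'auto', 'derived' or 'minor'")
    sub_sizes = Counter(partition.subclades.values())
    n_between = 0
    within: dict[str, int] = {}
    n_other = 0
    between_sites: list[HomoplasySite] = []
    within_sites: list[HomoplasySite] = []
    for site in sites:
        use_derived = site.derived_alleles is not None and method in (
            "auto", "derived",
        )
        if method == "derived" and site.derived_alleles is None:
            raise ValueError(
                f"site at position {site.position} has no ancestral state"
            )
        if use_derived:
            candidates = [site.allele_carriers[a] for a in site.derived_alleles]
        else:
            candidates = [site.carriers]
        all_carriers: set[str] = set().union(*candidates) if candidates else set()
        missing = [g for g in all_carriers if g not in partition.clades]
        if missing:
            raise KeyError(f"carriers without clade label: {missing}")
        is_between = False
        within_clade: str | None = None
        for carriers in candidates:
            clades = {partition.clades[g] for g in carriers}
            if len(clades) > 1:
                is_between = True
                break
            per_sub = Counter(
                partition.subclades[g]
                for g in carriers
                if g in partition.subclades
            )
            if len(per_sub) > 1:
                minority = any(
                    count <= sub_sizes[sub] / 2
                    for sub, count in per_sub.items()
                )
                if minority or not use_derived:
                    within_clade = next(iter(clades))
        if is_between:
            n_between += 1
            between_sites.append(site)
        elif within_clade is not None:
            within[within_clade] = within.get(within_clade, 0) + 1
            within_sites.append(site)
        else:
            n_other += 1
    return HomoplasyCounts(
        n_between=n_between,
        n_within_per_clade=within,
        n_other=n_other,
        between_sites=between_sites,
        within_sites=within_sites,
    )


def barrier_test(n_between: int, n_within: int, R: float) -> BarrierTestResult:
    """Conditional binomial test of the recombination barrier.

    Given divergence ratio R (between-clade over cross-subclade
    divergence), the null puts n_between ~ Binomial(N, R/(1+R)) with
    N = n_between + n_within; the reported p-value is the one-sided
    lower tail P(X <= n_between).
    """
    if R <= 0:
        raise ValueError("divergence ratio R must be > 0")
    N = n_between + n_within
    if N == 0:
        raise ValueError("no homoplasies to test (N = 0)")
    p0 = R / (1.0 + R)
    p = float(stats.binom.cdf(n_between, N, p0))
    direction = "deficit of between-clade homoplasies" if n_between < N * p0 \
        else "no deficit"
    return BarrierTestResult(
        n_between=n_between,
        n_within=n_within,
        divergence_ratio=float(R),
        null_proportion=p0,
        p_value=p,
        direction=direction,
    )


def homoplasy_table(sites: list[HomoplasySite],
                    partition: CladePartition | None = None) -> pd.DataFrame:
    rows = []
    for s in sites:
        row = {
            "site": s.site,
            "position_1based": s.position + 1,
            "k": s.k,
            "minor_allele": s.minor_allele,
            "carriers": ",".join(sorted(s.carriers)),
            "derived_alleles": ",".join(s.derived_alleles)
            if s.derived_alleles is not None
            else "",
            "multiallelic": s.multiallelic,
        }
        if partition is not None:
            clades = {partition.clades[g] for g in s.carriers
                      if g in partition.clades}
            row["carrier_clades"] = ",".join(sorted(clades))
        rows.append(row)
    return pd.DataFrame(rows)
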