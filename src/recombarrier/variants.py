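"""Core-alignment ingestion, SNP calling and pairwise divergence.

The unit of input is a core-genome multiple alignment: equal-length
sequences for every genome on a single replicon coordinate system.
Coordinates are 0-based half-open internally; human-readable reports use
1-based inclusive positions (``position_1based`` columns).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NT_STATES = "ACGT"
AA_STATES = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "Alignment",
    "VariantTable",
    "DistanceMatrix",
    "read_alignment",
    "write_alignment",
    "call_snps",
    "pairwise_divergence",
]


class AlignmentError(ValueError):
    """Raised for malformed alignments (unequal lengths, duplicate ids)."""


def alphabet_states(alphabet: str) -> str:
    if alphabet == "nt":
        return NT_STATES
    if alphabet == "aa":
        return AA_STATES
    raise ValueError(f"unknown alphabet {alphabet!r}; expected 'nt' or 'aa'")


@dataclass
class Alignment:
    """Equal-length sequences over a declared alphabet.

    Parameters
    ----------
    names
        Genome identifiers, unique, in order of appearance.
    sequences
        Upper-case sequence strings, all of the same length.
    alphabet
        ``"nt"`` (4 states) or ``"aa"`` (20 states).
    origin
        Replicon coordinate of column 0 (0-based).
    """

    names: list[str]
    sequences: list[str]
    alphabet: str = "nt"
    origin: int = 0
    _array: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise AlignmentError("duplicate genome ids in alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        if len(self.names) != len(self.sequences):
            raise AlignmentError("names and sequences differ in count")
        alphabet_states(self.alphabet)

    @property
    def n_genomes(self) -> int:
        return len(self.names)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def to_array(self) -> np.ndarray:
        """Byte matrix view (genomes x sites), cached."""
        if self._array is None:
            self._array = np.frombuffer(
                "".join(self.sequences).encode("ascii"), dtype="|S1"
            ).reshape(self.n_genomes, self.length)
        return self._array

    def subset(self, names: list[str]) -> "Alignment":
        idx = {n: i for i, n in enumerate(self.names)}
        missing = [n for n in names if n not in idx]
        if missing:
            raise KeyError(f"genomes not in alignment: {missing}")
        return Alignment(
            names=list(names),
            sequences=[self.sequences[idx[n]] for n in names],
            alphabet=self.alphabet,
            origin=self.origin,
        )


@dataclass
class VariantTable:
    """Polymorphic columns of an alignment.

    ``positions`` are 0-based column indices, strictly increasing;
    ``alleles`` is a (sites x genomes) byte matrix of the state each genome
    carries; ``biallelic`` flags sites with exactly two distinct states.
    """

    names: list[str]
    positions: np.ndarray
    alleles: np.ndarray
    total_sites: int
    alphabet: str = "nt"

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def biallelic_mask(self) -> np.ndarray:
        return np.array(
            [len(set(row.tobytes().decode())) == 2 for row in self.alleles.T]
            if self.alleles.size
            else [],
            dtype=bool,
        )

    def site_alleles(self, i: int) -> dict[str, str]:
        """Per-genome allele at variant site *i*."""
        col = self.alleles[:, i]
        return {n: col[j].decode() for j, n in enumerate(self.names)}

    def to_frame(self) -> pd.DataFrame:
        """TSV-ready table: site index, 1-based position, allele string."""
        allele_strings = [
            self.alleles[:, i].tobytes().decode() for i in range(self.n_sites)
        ]
        return pd.DataFrame(
            {
                "site": np.arange(self.n_sites),
                "position_1based": self.positions + 1,
                "alleles": allele_strings,
            }
        )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances; ``units`` is ``"per_site"`` or ``"count"``.

    Undefined entries (no comparable columns for a pair) are NaN, never 0.
    """

    names: list[str]
    values: np.ndarray
    units: str = "per_site"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.names), len(self.names)):
            raise ValueError("distance matrix shape does not match names")
        self.values = v

    def get(self, a: str, b: str) -> float:
        i, j = self.names.index(a), self.names.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="genome")


def read_alignment(path, alphabet: str = "nt") -> Alignment:
    """Read a FASTA multiple alignment (>=2 equal-length records)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise AlignmentError(f"alignment needs >=2 records, got {len(records)}")
    return Alignment(
        names=[r.id for r in records],
        sequences=[str(r.seq).upper() for r in records],
        alphabet=alphabet,
    )


def write_alignment(aln: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=n, description="")
        for n, s in zip(aln.names, aln.sequences)
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def _state_mask(aln: Alignment) -> np.ndarray:
    """Boolean (genomes x sites) matrix: True where the character is a
    declared alphabet state (gaps/ambiguity codes are False)."""
    arr = aln.to_array()
    states = np.frombuffer(alphabet_states(aln.alphabet).encode(), dtype="|S1")
    return np.isin(arr, states)


def call_snps(aln: Alignment, ignore_gaps: bool = True) -> VariantTable:
    """Scan every column and report the polymorphic ones.

    With ``ignore_gaps`` (default) any column containing a gap or ambiguity
    character is skipped entirely — the conservative core-alignment
    convention. Otherwise such characters are treated as one extra state.
    """
    if aln.n_genomes == 0 or aln.length == 0:
        raise AlignmentError("empty alignment")
    arr = aln.to_array()
    if ignore_gaps:
        clean = _state_mask(aln).all(axis=0)
    else:
        clean = np.ones(aln.length, dtype=bool)
    polymorphic = (arr != arr[0]).any(axis=0) & clean
    positions = np.flatnonzero(polymorphic)
    return VariantTable(
        names=list(aln.names),
        positions=positions,
        alleles=arr[:, positions].copy(),
        total_sites=aln.length,
        alphabet=aln.alphabet,
    )


def pairwise_divergence(aln: Alignment) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Pairwise divergence over comparable (both-non-gap) columns.

    Returns ``(per_site, counts)``: the per-site matrix divides each pair's
    mismatch count by its own comparable-column count; a pair with zero
    comparable columns gets NaN in the per-site matrix.
    """
    if aln.n_genomes < 2:
        raise AlignmentError("need >=2 genomes")
    arr = aln.to_array()
    ok = _state_mask(aln)
    n = aln.n_genomes
    counts = np.zeros((n, n))
    per_site = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ok[i] & ok[j]
            diffs = int(np.count_nonzero((arr[i] != arr[j]) & comparable))
            denom = int(np.count_nonzero(comparable))
            counts[i, j] = counts[j, i] = diffs
            per_site[i, j] = per_site[j, i] = diffs / denom if denom else np.nan
    return (
        DistanceMatrix(list(aln.names), per_site, units="per_site"),
        DistanceMatrix(list(aln.names), counts, units="count"),
    )


def write_variants_tsv(table: VariantTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)
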