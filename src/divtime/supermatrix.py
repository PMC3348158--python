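"""Alignment block filtering and supermatrix concatenation.

The block filter removes ambiguously aligned regions by rules on column
conservation, in the style of Gblocks: columns are classed by the
frequency of their modal (non-gap) residue, long runs of nonconserved
columns are excised, surviving segments are trimmed to start and end on
a highly conserved column, and short blocks are dropped.  Defaults match
the canonical relaxed setting used for multi-locus teleost supermatrices:
minimum block length 10 sites, at most 5 contiguous nonconserved
positions, and columns with more than 50% gaps excluded.

Concatenation takes the union of taxa over loci, pads absent
taxon-by-locus blocks with ``?``, and records a partition map plus
missing-data statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "Alignment",
    "BlockFilterParams",
    "Supermatrix",
    "read_fasta_alignment",
    "classify_positions",
    "filter_blocks",
    "concatenate",
    "missing_stats",
]

GAP_CHARS = frozenset("-?")


@dataclass(frozen=True)
class Alignment:
    """A rectangular multiple alignment: taxon names + character matrix."""

    taxa: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)  # (n_taxa, n_sites) of single chars

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise ValueError("matrix must be (n_taxa, n_sites)")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon within one alignment")

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "Alignment":
        taxa, seqs = [], []
        for name, seq in records:
            taxa.append(name)
            seqs.append(seq.upper())
        widths = {len(s) for s in seqs}
        if len(widths) > 1:
            raise ValueError(f"ragged alignment: sequence lengths {sorted(widths)}")
        matrix = np.array([list(s) for s in seqs], dtype="U1") if taxa else \
            np.empty((0, 0), dtype="U1")
        return cls(tuple(taxa), matrix)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return int(self.matrix.shape[1])

    def sequence(self, taxon: str) -> str:
        return "".join(self.matrix[self.taxa.index(taxon)])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, taxon in enumerate(self.taxa):
                fh.write(f">{taxon}\n{''.join(self.matrix[i])}\n")


def read_fasta_alignment(path) -> Alignment:
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no sequences in {path}")
    return Alignment.from_records(records)


@dataclass(frozen=True)
class BlockFilterParams:
    """Thresholds for the conservation-based block filter."""

    min_block_length: int = 10
    max_contiguous_nonconserved: int = 5
    max_gap_fraction: float = 0.5
    conserved_threshold: float = 0.5  # modal residue freq must strictly exceed
    highly_conserved_threshold: float = 0.85

    def __post_init__(self):
        if self.min_block_length < 1:
            raise ValueError("min_block_length must be >= 1")
        for name in ("max_gap_fraction", "conserved_threshold",
                     "highly_conserved_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")


def classify_positions(
    alignment: Alignment, params: BlockFilterParams = BlockFilterParams()
) -> list[str]:
    """Per-column label: nonconserved / conserved / highly_conserved /
    gap_excluded.

    A column whose gap fraction ('-' or '?') exceeds ``max_gap_fraction``
    is gap_excluded (treated as nonconserved downstream).  Otherwise the
    modal non-gap residue frequency over *all* sequences decides:
    strictly above ``highly_conserved_threshold`` -> highly_conserved,
    strictly above ``conserved_threshold`` -> conserved, else
    nonconserved.  Gap characters never count toward the modal residue.
    """
    n_taxa = alignment.n_taxa
    labels: list[str] = []
    for col in alignment.matrix.T:
        gaps = sum(1 for c in col if c in GAP_CHARS)
        if gaps / n_taxa > params.max_gap_fraction:
            labels.append("gap_excluded")
            continue
        residues = [c for c in col if c not in GAP_CHARS]
        modal = max((residues.count(r) for r in set(residues)), default=0)
        freq = modal / n_taxa
        if freq > params.highly_conserved_threshold:
            labels.append("highly_conserved")
        elif freq > params.conserved_threshold:
            labels.append("conserved")
        else:
            labels.append("nonconserved")
    return labels


def filter_blocks(
    alignment: Alignment, params: BlockFilterParams = BlockFilterParams()
) -> tuple[Alignment, float, list[tuple[int, int]]]:
    """Remove ambiguously aligned regions; keep conserved blocks.

    Rules, applied in order:

    1. every maximal run of more than ``max_contiguous_nonconserved``
       nonconserved (or gap-excluded) columns is removed;
    2. each remaining segment is trimmed so it begins and ends on a
       highly conserved column;
    3. segments shorter than ``min_block_length`` are dropped.

    Returns the filtered alignment (columns in original order), the
    retained fraction of columns, and the retained blocks as 0-based
    half-open column intervals of the input.
    """
    labels = classify_positions(alignment, params)
    n = len(labels)
    bad = [l in ("nonconserved", "gap_excluded") for l in labels]

    # 1. excise maximal bad runs longer than the allowance
    cuts: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if bad[i]:
            j = i
            while j < n and bad[j]:
                j += 1
            if j - i > params.max_contiguous_nonconserved:
                cuts.append((i, j))
            i = j
        else:
            i += 1
    segments: list[tuple[int, int]] = []
    prev = 0
    for lo, hi in cuts:
        if lo > prev:
            segments.append((prev, lo))
        prev = hi
    if n > prev:
        segments.append((prev, n))

    # 2. trim segments to highly conserved anchors; 3. length filter
    blocks: list[tuple[int, int]] = []
    for lo, hi in segments:
        while lo < hi and labels[lo] != "highly_conserved":
            lo += 1
        while hi > lo and labels[hi - 1] != "highly_conserved":
            hi -= 1
        if hi - lo >= params.min_block_length:
            blocks.append((lo, hi))

    if blocks:
        cols = np.concatenate([np.arange(lo, hi) for lo, hi in blocks])
        filtered = Alignment(alignment.taxa, alignment.matrix[:, cols])
    else:
        filtered = Alignment(alignment.taxa,
                             alignment.matrix[:, np.zeros(0, dtype=int)])
    retained = filtered.n_sites / n if n else 0.0
    return filtered, retained, blocks


@dataclass(frozen=True)
class Supermatrix:
    """Concatenated character matrix with partition bookkeeping."""

    alignment: Alignment
    partitions: dict[str, tuple[int, int]]  # locus -> 0-based half-open cols
    locus_lengths: dict[str, int]

    @property
    def n_sites(self) -> int:
        return self.alignment.n_sites

    @property
    def taxa(self) -> tuple[str, ...]:
        return self.alignment.taxa

    def slice_locus(self, locus: str) -> Alignment:
        lo, hi = self.partitions[locus]
        return Alignment(self.alignment.taxa, self.alignment.matrix[:, lo:hi])

    def partition_file_text(self) -> str:
        """RAxML-style partition lines, 1-based inclusive coordinates."""
        lines = [
            f"DNA, {locus} = {lo + 1}-{hi}"
            for locus, (lo, hi) in self.partitions.items()
        ]
        return "\n".join(lines) + "\n"


def concatenate(loci: Mapping[str, Alignment]) -> Supermatrix:
    """Concatenate per-locus alignments over the union of their taxa.

    Taxon order is the order of first appearance across loci; a taxon
    absent from a locus gets an all-``?`` block there.  Partition columns
    are 0-based half-open and tile the matrix exactly.
    """
    taxa: list[str] = []
    seen = set()
    for aln in loci.values():
        for t in aln.taxa:
            if t not in seen:
                seen.add(t)
                taxa.append(t)
    total = sum(aln.n_sites for aln in loci.values())
    matrix = np.full((len(taxa), total), "?", dtype="U1")
    partitions: dict[str, tuple[int, int]] = {}
    offset = 0
    index = {t: i for i, t in enumerate(taxa)}
    for name, aln in loci.items():
        width = aln.n_sites
        for row, taxon in enumerate(aln.taxa):
            matrix[index[taxon], offset:offset + width] = aln.matrix[row]
        partitions[name] = (offset, offset + width)
        offset += width
    return Supermatrix(
        alignment=Alignment(tuple(taxa), matrix),
        partitions=partitions,
        locus_lengths={name: aln.n_sites for name, aln in loci.items()},
    )


def missing_stats(sm: Supermatrix) -> float:
    """Fraction of '?' cells in the concatenated matrix."""
    cells = sm.alignment.matrix.size
    if cells == 0:
        return 0.0
    return float(np.count_nonzero(sm.alignment.matrix == "?")) / cells
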