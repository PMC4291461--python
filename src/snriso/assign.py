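"""Exact-match read assignment and the mismatch-tolerant variant screen.

Reads are assigned by k-mer lookup: a read matches the set of isoform groups
whose sequences contain the read's first-k bases anywhere on the forward
strand, with zero mismatches. Each read contributes to exactly one *class*
(the full matched subset); apportioning ambiguous classes across groups
happens downstream in the deconvolution step, never here.

The variant screen is the opposite regime: end-to-end placement of whole
reads against the paralog sequences allowing a bounded number of
substitutions (no indels), reporting what fraction of aligned reads carry at
least one mismatch -- a cheap signal for unannotated sequence variants.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .catalog import IsoformGroup, kmer_group_map, normalize_sequence
from .errors import AssignmentError

__all__ = [
    "KmerIndex",
    "ReadAssignment",
    "ClassCountTable",
    "ScreenReport",
    "build_index",
    "assign_reads",
    "variant_screen",
    "iter_fastq",
]


@dataclass(frozen=True)
class KmerIndex:
    """Exact-match lookup: every length-k substring of every group's sequence."""

    read_length: int
    table: dict[str, frozenset[str]]
    group_ids: tuple[str, ...]


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    matched_groups: frozenset[str]
    n_mismatches_best: int | None = None


@dataclass
class ClassCountTable:
    """Per-sample read counts keyed by matched-group-subset classes.

    Invariant: sum of class counts + n_unmapped == n_total. Reads shorter
    than the index k cannot be looked up; they are unmapped and additionally
    tallied in n_too_short.
    """

    sample_id: str
    counts: dict[frozenset[str], int] = field(default_factory=dict)
    n_total: int = 0
    n_unmapped: int = 0
    n_too_short: int = 0

    def merged_with(self, other: "ClassCountTable") -> "ClassCountTable":
        """Pool two samples' counts (class counts are sufficient statistics)."""
        counts = Counter(self.counts)
        counts.update(other.counts)
        return ClassCountTable(
            sample_id=f"{self.sample_id}+{other.sample_id}",
            counts=dict(counts),
            n_total=self.n_total + other.n_total,
            n_unmapped=self.n_unmapped + other.n_unmapped,
            n_too_short=self.n_too_short + other.n_too_short,
        )


def build_index(groups: Sequence[IsoformGroup], read_length: int) -> KmerIndex:
    """Index every k-mer of every group. k-mers containing N are excluded."""
    table = kmer_group_map(groups, read_length)
    return KmerIndex(
        read_length=read_length,
        table=table,
        group_ids=tuple(g.group_id for g in groups),
    )


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ file, gz-transparent."""
    n = 0
    try:
        with _open_text(path) as handle:
            for title, seq, _qual in FastqGeneralIterator(handle):
                n += 1
                yield title.split()[0], seq
    except ValueError as exc:
        raise AssignmentError(
            f"{path}: malformed FASTQ near record {n + 1}: {exc}"
        ) from exc


def _as_read_iter(
    reads: str | Path | Iterable[tuple[str, str]],
) -> Iterable[tuple[str, str]]:
    if isinstance(reads, (str, Path)):
        return iter_fastq(reads)
    return reads


def assign_reads(
    reads: str | Path | Iterable[tuple[str, str]],
    index: KmerIndex,
    sample_id: str = "sample",
    collect_assignments: bool = True,
) -> tuple[list[ReadAssignment], ClassCountTable]:
    """Assign each read to the subset of groups it matches exactly.

    ``reads`` is a FASTQ path (gz-transparent) or an iterable of
    (read_id, sequence) pairs. Reads longer than the index k are trimmed from
    the 3' end to k before lookup; shorter reads are unmapped. With
    ``collect_assignments=False`` only the class-count table is built, which
    is markedly faster for large simulated samples.
    """
    k = index.read_length
    table = index.table
    counts: Counter[frozenset[str]] = Counter()
    assignments: list[ReadAssignment] = []
    n_total = 0
    n_unmapped = 0
    n_too_short = 0
    for read_id, seq in _as_read_iter(reads):
        n_total += 1
        if len(seq) < k:
            n_too_short += 1
            n_unmapped += 1
            if collect_assignments:
                assignments.append(ReadAssignment(read_id, frozenset()))
            continue
        key = seq[:k]
        subset = table.get(key)
        if subset is None and (not key.isupper() or "U" in key):
            # Lowercase or RNA-alphabet input: retry after normalization.
            subset = table.get(normalize_sequence(key))
        if subset is None:
            n_unmapped += 1
            if collect_assignments:
                assignments.append(ReadAssignment(read_id, frozenset()))
        else:
            counts[subset] += 1
            if collect_assignments:
                assignments.append(ReadAssignment(read_id, subset))
    return assignments, ClassCountTable(
        sample_id=sample_id,
        counts=dict(counts),
        n_total=n_total,
        n_unmapped=n_unmapped,
        n_too_short=n_too_short,
    )


# ---------------------------------------------------------------------------
# Variant screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenReport:
    """Summary of the mismatch screen for unannotated variants.

    percent_with_mismatch uses aligned reads as denominator (primary);
    percent_of_all_reads uses every input read. When nothing aligns the
    primary percentage is None, never 0.
    """

    n_reads: int
    n_aligned: int
    n_with_mismatch: int
    max_mismatches: int

    @property
    def percent_with_mismatch(self) -> float | None:
        if self.n_aligned == 0:
            return None
        return 100.0 * self.n_with_mismatch / self.n_aligned

    @property
    def percent_of_all_reads(self) -> float | None:
        if self.n_reads == 0:
            return None
        return 100.0 * self.n_with_mismatch / self.n_reads


def variant_screen(
    reads: str | Path | Iterable[tuple[str, str]],
    groups: Sequence[IsoformGroup],
    max_mismatches: int = 2,
) -> ScreenReport:
    """Exhaustively place whole reads against all groups, counting mismatches.

    For each read the best (fewest-substitution) end-to-end placement at any
    offset of any group is found; reads whose best placement needs more than
    ``max_mismatches`` substitutions (or that do not fit any sequence) are
    unaligned. No indels are considered.
    """
    if max_mismatches < 1:
        raise AssignmentError("max_mismatches must be >= 1")
    encoded = [
        np.frombuffer(g.representative_sequence.encode(), dtype=np.uint8)
        for g in groups
    ]
    n_reads = n_aligned = n_with_mismatch = 0
    for _read_id, seq in _as_read_iter(reads):
        n_reads += 1
        read = np.frombuffer(normalize_sequence(seq).encode(), dtype=np.uint8)
        best = None
        for arr in encoded:
            if len(arr) < len(read):
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, len(read))
            mm = int((windows != read).sum(axis=1).min())
            if best is None or mm < best:
                best = mm
                if best == 0:
                    break
        if best is not None and best <= max_mismatches:
            n_aligned += 1
            if best >= 1:
                n_with_mismatch += 1
    return ScreenReport(
        n_reads=n_reads,
        n_aligned=n_aligned,
        n_with_mismatch=n_with_mismatch,
        max_mismatches=max_mismatches,
    )
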