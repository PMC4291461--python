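"""Paralog catalog: isoform groups, variable sites, and diagnostic regions.

Multi-copy snRNA genes within one subtype (U1, U2, U4, U5, ...) differ at only
a handful of nucleotide positions, and some copies are perfectly identical.
Because identical copies can never be separated by sequencing reads, the unit
of quantification is the *isoform group*: the set of gene copies sharing one
mature sequence.

For a fixed read length k, every read start position on a group's sequence has
a well-defined signature -- the subset of groups whose sequences contain that
k-mer anywhere. Runs of consecutive starts with the same signature form
*diagnostic regions*. Regions whose signature is a single group yield uniquely
mappable reads; regions with larger signatures yield the ambiguous read
classes that the deconvolution step resolves.

Matching is exact (no mismatches) and forward-strand only: snRNA references
are given in sense orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align, SeqIO

from .errors import CatalogError

NUCLEOTIDES = frozenset("ACGTN")

__all__ = [
    "ParalogGene",
    "IsoformGroup",
    "VariableSite",
    "DiagnosticRegion",
    "load_family",
    "collapse_identical",
    "build_alignment",
    "find_variable_sites",
    "diagnostic_regions",
    "normalize_sequence",
    "kmer_group_map",
]


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and map RNA U to DNA T."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class ParalogGene:
    """One snRNA gene copy: id (cytological-style label), subtype, sequence."""

    gene_id: str
    family: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise CatalogError(f"gene {self.gene_id!r}: empty sequence")
        bad = set(self.sequence) - NUCLEOTIDES
        if bad:
            raise CatalogError(
                f"gene {self.gene_id!r}: non-nucleotide characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class IsoformGroup:
    """A maximal set of gene copies sharing a byte-identical sequence."""

    group_id: str
    members: tuple[str, ...]
    representative_sequence: str


@dataclass(frozen=True)
class VariableSite:
    """An alignment column at which at least two isoform groups differ.

    ``residues`` maps group_id to the residue (or ``-`` for a gap) in that
    column. Columns are 1-based, as in all user-facing coordinates.
    """

    column_1based: int
    residues: Mapping[str, str]


@dataclass(frozen=True)
class DiagnosticRegion:
    """Maximal run of read starts on one group with a constant match signature.

    Any error-free read of length ``read_length`` starting within
    [start_min_1based, start_max_1based] on ``carrier_group`` matches exactly
    the groups in ``group_subset`` and no others in the family. Regions whose
    subset is the whole family are retained but flagged non-informative.
    """

    carrier_group: str
    group_subset: frozenset[str]
    start_min_1based: int
    start_max_1based: int
    read_length: int
    informative: bool = True

    @property
    def width(self) -> int:
        return self.start_max_1based - self.start_min_1based + 1


def load_family(fasta_path: str | Path, family_name: str) -> list[ParalogGene]:
    """Read one snRNA family from a FASTA file.

    Sequences are uppercased and U is normalized to T. Duplicate record ids,
    empty files, and non-nucleotide characters raise :class:`CatalogError`.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise CatalogError(f"{fasta_path}: no FASTA records found")
    genes: list[ParalogGene] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise CatalogError(f"{fasta_path}: duplicate gene id {rec.id!r}")
        seen.add(rec.id)
        genes.append(
            ParalogGene(
                gene_id=rec.id,
                family=family_name,
                sequence=normalize_sequence(str(rec.seq)),
            )
        )
    return genes


def _join_group_id(member_ids: Sequence[str]) -> str:
    """Join member gene ids into a compact group id.

    Ids sharing a "FAMILY:" prefix are compacted in the conventional style,
    e.g. ["U1:21D", "U1:95Ca", "U1:95Cb"] -> "U1:21D/95Ca/95Cb".
    """
    if len(member_ids) == 1:
        return member_ids[0]
    prefixes = {m.split(":", 1)[0] for m in member_ids}
    if len(prefixes) == 1 and all(":" in m for m in member_ids):
        prefix = next(iter(prefixes))
        return prefix + ":" + "/".join(m.split(":", 1)[1] for m in member_ids)
    return "/".join(member_ids)


def collapse_identical(genes: Sequence[ParalogGene]) -> list[IsoformGroup]:
    """Partition genes into isoform groups of byte-identical sequence.

    Groups are ordered by first occurrence; member order within a group
    follows input order. Idempotent in the sense that collapsing the emitted
    representatives yields the same groups.
    """
    if not genes:
        raise CatalogError("collapse_identical: no genes given")
    by_seq: dict[str, list[str]] = {}
    for g in genes:
        by_seq.setdefault(g.sequence, []).append(g.gene_id)
    return [
        IsoformGroup(
            group_id=_join_group_id(members),
            members=tuple(members),
            representative_sequence=seq,
        )
        for seq, members in by_seq.items()
    ]


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _pairwise_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def _center_star(sequences: list[str]) -> list[str]:
    """Progressive center-star alignment under +1/-1/-2 scoring.

    The longest sequence is the center; every other sequence is aligned to it
    pairwise and the center's gap insertions are merged ("once a gap, always
    a gap"). Adequate for near-identical paralog families; not a general MSA.
    """
    center_idx = max(range(len(sequences)), key=lambda i: len(sequences[i]))
    center = sequences[center_idx]
    n = len(center)
    aligner = _pairwise_aligner()

    pairwise: dict[int, tuple[str, str]] = {}
    max_ins = [0] * (n + 1)
    for i, seq in enumerate(sequences):
        if i == center_idx:
            continue
        aln = aligner.align(center, seq)[0]
        a_center, a_other = str(aln[0]), str(aln[1])
        pairwise[i] = (a_center, a_other)
        ins = [0] * (n + 1)
        pos = 0
        for c in a_center:
            if c == "-":
                ins[pos] += 1
            else:
                pos += 1
        for p in range(n + 1):
            max_ins[p] = max(max_ins[p], ins[p])

    def rebuild(a_center: str, a_other: str) -> str:
        out: list[str] = []
        block: list[str] = []
        pos = 0
        for cc, oc in zip(a_center, a_other):
            if cc == "-":
                block.append(oc)
            else:
                out.append("-" * (max_ins[pos] - len(block)) + "".join(block))
                out.append(oc)
                block = []
                pos += 1
        out.append("-" * (max_ins[pos] - len(block)) + "".join(block))
        return "".join(out)

    rows: list[str] = []
    for i, seq in enumerate(sequences):
        if i == center_idx:
            rows.append(rebuild(center, center))
        else:
            rows.append(rebuild(*pairwise[i]))
    return rows


def build_alignment(
    groups: Sequence[IsoformGroup],
    aligned_fasta: str | Path | None = None,
) -> dict[str, str]:
    """Return a gapped alignment mapping group_id to an aligned row.

    Equal-length representative sequences are returned unchanged (column i is
    position i). Otherwise a progressive pairwise scheme (match +1, mismatch
    -1, gap -2) produces the alignment. A user-supplied aligned FASTA with
    equal row lengths bypasses computation; its record ids must cover every
    group id.
    """
    if aligned_fasta is not None:
        rows = {
            rec.id: normalize_sequence(str(rec.seq))
            for rec in SeqIO.parse(str(aligned_fasta), "fasta")
        }
        lengths = {len(s) for s in rows.values()}
        if len(lengths) > 1:
            raise CatalogError(f"{aligned_fasta}: ragged aligned FASTA rows")
        missing = [g.group_id for g in groups if g.group_id not in rows]
        if missing:
            raise CatalogError(f"{aligned_fasta}: missing aligned rows for {missing}")
        return {g.group_id: rows[g.group_id] for g in groups}

    seqs = [g.representative_sequence for g in groups]
    if len({len(s) for s in seqs}) == 1:
        return {g.group_id: g.representative_sequence for g in groups}
    aligned = _center_star(seqs)
    return {g.group_id: row for g, row in zip(groups, aligned)}


def find_variable_sites(alignment: Mapping[str, str]) -> list[VariableSite]:
    """Columns of a gapped alignment where at least two groups differ.

    A gap counts as a distinct residue. Raises on ragged alignments.
    """
    if not alignment:
        return []
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) > 1:
        raise CatalogError("find_variable_sites: ragged alignment")
    n_cols = lengths.pop()
    ids = list(alignment)
    sites: list[VariableSite] = []
    for col in range(n_cols):
        residues = {gid: alignment[gid][col] for gid in ids}
        if len(set(residues.values())) >= 2:
            sites.append(VariableSite(column_1based=col + 1, residues=residues))
    return sites


# ---------------------------------------------------------------------------
# Diagnostic regions
# ---------------------------------------------------------------------------

def kmer_group_map(
    groups: Sequence[IsoformGroup], read_length: int
) -> dict[str, frozenset[str]]:
    """Map every N-free k-mer of every group to the set of groups carrying it."""
    min_len = min(len(g.representative_sequence) for g in groups)
    if read_length > min_len:
        raise CatalogError(
            f"read_length {read_length} exceeds shortest sequence ({min_len} nt)"
        )
    table: dict[str, set[str]] = {}
    for g in groups:
        seq = g.representative_sequence
        for p in range(len(seq) - read_length + 1):
            kmer = seq[p : p + read_length]
            if "N" in kmer:
                continue
            table.setdefault(kmer, set()).add(g.group_id)
    # Intern frozensets so equal signatures share one object.
    cache: dict[frozenset[str], frozenset[str]] = {}
    out: dict[str, frozenset[str]] = {}
    for kmer, gset in table.items():
        fs = frozenset(gset)
        out[kmer] = cache.setdefault(fs, fs)
    return out


def diagnostic_regions(
    groups: Sequence[IsoformGroup], read_length: int
) -> list[DiagnosticRegion]:
    """Partition every group's valid read starts into maximal signature runs.

    For each group and each valid 1-based start, the k-mer beginning there is
    looked up across all groups (all offsets, forward strand). Consecutive
    starts with identical signatures merge into one region. Starts whose
    k-mer contains N match nothing and are excluded. Regions whose signature
    is the full family are flagged ``informative=False``.
    """
    table = kmer_group_map(groups, read_length)
    all_ids = frozenset(g.group_id for g in groups)
    regions: list[DiagnosticRegion] = []
    for g in groups:
        seq = g.representative_sequence
        run_subset: frozenset[str] | None = None
        run_start = 0
        prev = 0
        for p in range(1, len(seq) - read_length + 2):  # 1-based starts
            kmer = seq[p - 1 : p - 1 + read_length]
            subset = table.get(kmer)  # None for N-containing k-mers
            if subset is not run_subset:
                if run_subset is not None:
                    regions.append(
                        DiagnosticRegion(
                            carrier_group=g.group_id,
                            group_subset=run_subset,
                            start_min_1based=run_start,
                            start_max_1based=prev,
                            read_length=read_length,
                            informative=run_subset != all_ids,
                        )
                    )
                run_subset = subset
                run_start = p
            prev = p
        if run_subset is not None:
            regions.append(
                DiagnosticRegion(
                    carrier_group=g.group_id,
                    group_subset=run_subset,
                    start_min_1based=run_start,
                    start_max_1based=prev,
                    read_length=read_length,
                    informative=run_subset != all_ids,
                )
            )
    return regions


def check_cross_family_collisions(
    families: Mapping[str, Sequence[IsoformGroup]], read_length: int
) -> list[str]:
    """Warn about k-mers shared between different families.

    Within-family uniqueness is the analysis scope; a k-mer occurring in two
    families would make family-level assignment ambiguous in a pooled run.
    Returns the offending k-mers (also emitted as warnings).
    """
    owner: dict[str, str] = {}
    collisions: list[str] = []
    for fam, groups in families.items():
        for kmer in kmer_group_map(groups, read_length):
            prev = owner.setdefault(kmer, fam)
            if prev != fam:
                collisions.append(kmer)
                warnings.warn(
                    f"k-mer shared between families {prev} and {fam}: {kmer[:16]}...",
                    stacklevel=2,
                )
    return collisions
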