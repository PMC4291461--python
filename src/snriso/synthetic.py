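"""Synthetic paralog families, mixture trajectories, and simulated reads.

Real snRNA quantification runs on public RNA-seq accessions. To make every
downstream stage testable without any download, this module generates
families with the same structure as real snRNA paralogs -- a handful of
near-identical sequences, some byte-identical (one isoform group covering
several gene copies), differing at a small number of planted sites -- plus
developmental mixture trajectories in which one group progressively takes
over, and error-bearing short reads with a complete per-read truth table.

Everything is deterministic given the seed: identical specs produce
byte-identical FASTQ and truth outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import IsoformGroup, ParalogGene, VariableSite, collapse_identical
from .errors import ValidationError

__all__ = [
    "SyntheticFamilySpec",
    "SyntheticFamily",
    "MixtureTruth",
    "ReadSimConfig",
    "generate_family",
    "generate_mixture_trajectory",
    "simulate_reads",
    "write_fastq",
]

DEFAULT_ALPHABET = "ACGT"


@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Recipe for a planted paralog family.

    ``identical_partition`` groups 1-based gene indices into cells; genes in
    one cell share a sequence (they will collapse into one isoform group),
    genes in different cells differ at >= 1 planted site. U is accepted in
    ``alphabet`` and stored as T.
    """

    n_genes: int
    seq_length: int
    n_variable_sites: int
    identical_partition: tuple[tuple[int, ...], ...]
    alphabet: str = DEFAULT_ALPHABET
    seed: int = 0
    family_name: str = "FAM"

    def __post_init__(self) -> None:
        flat = [i for cell in self.identical_partition for i in cell]
        if sorted(flat) != list(range(1, self.n_genes + 1)):
            raise ValidationError(
                "identical_partition must partition gene indices 1..n_genes"
            )
        if not (0 <= self.n_variable_sites < self.seq_length):
            raise ValidationError("need 0 <= n_variable_sites < seq_length")


@dataclass(frozen=True)
class SyntheticFamily:
    """A generated family with its collapsed groups and planted-site truth."""

    genes: tuple[ParalogGene, ...]
    groups: tuple[IsoformGroup, ...]
    alignment: dict[str, str]
    planted_sites: tuple[VariableSite, ...]

    @property
    def group_ids(self) -> tuple[str, ...]:
        return tuple(g.group_id for g in self.groups)


@dataclass(frozen=True)
class MixtureTruth:
    """Per-stage true fraction vectors over isoform groups (rows sum to 1)."""

    stage_labels: tuple[str, ...]
    fractions: np.ndarray  # shape (n_stages, n_groups)

    def frame(self, group_ids: Sequence[str]) -> pd.DataFrame:
        rows = [
            {"stage": s, "group_id": g, "fraction": float(f)}
            for s, vec in zip(self.stage_labels, self.fractions)
            for g, f in zip(group_ids, vec)
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReadSimConfig:
    """Read simulation parameters.

    Read lengths of 33-51 nt cover the range of the short-read libraries this
    pipeline targets. ``error_rate`` is an independent per-base substitution
    probability (no indels). Quality strings are constant 'I' (Phred 40) and
    never used downstream.
    """

    reads_per_sample: int
    read_length: int
    error_rate: float = 0.0
    replicates_per_stage: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reads_per_sample < 1:
            raise ValidationError("reads_per_sample must be >= 1")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValidationError("error_rate must be in [0, 1)")
        if self.replicates_per_stage < 1:
            raise ValidationError("replicates_per_stage must be >= 1")


def _residue_tuples(
    rng: np.random.Generator, n_cells: int, n_sites: int, a: int
) -> np.ndarray:
    """Residue assignments (cells x planted columns), pairwise distinct rows
    with every column varying.

    Random assignment spreads between-group differences across all planted
    columns, as in real paralog families; when the cell count is close to
    the a**n_sites capacity and rejection sampling stalls, a deterministic
    mixed-radix counting scheme (with a repair pass for constant columns)
    guarantees feasibility.
    """
    if n_sites == 0:
        return np.zeros((n_cells, 0), dtype=int)
    for _attempt in range(200):
        digits = rng.integers(0, a, size=(n_cells, n_sites))
        rows = {tuple(r) for r in digits}
        if len(rows) == n_cells and all(
            len(set(digits[:, j])) >= 2 for j in range(n_sites)
        ):
            return digits
    digits = np.zeros((n_cells, n_sites), dtype=int)
    for c in range(n_cells):
        v = c
        for j in range(n_sites):
            digits[c, j] = v % a
            v //= a
    for j in range(n_sites):
        # Constant column: bump the last cell; its value now exceeds every
        # other cell's index, so rows stay distinct.
        if len(set(digits[:, j])) < 2:
            digits[-1, j] = (digits[-1, j] + 1) % a
    return digits


def generate_family(spec: SyntheticFamilySpec) -> SyntheticFamily:
    """Plant a paralog family with known variable sites.

    A random background sequence is shared by all genes; each partition cell
    receives a distinct residue tuple at the planted columns, built so that
    (a) all cells are pairwise distinct and (b) every planted column truly
    varies -- recomputing variable columns from the emitted alignment
    recovers exactly the planted sites. Raises :class:`ValidationError` when
    the requested number of sites cannot distinguish all cells.
    """
    cells = spec.identical_partition
    n_cells = len(cells)
    a = len(set(spec.alphabet.upper().replace("U", "T")))
    alphabet = sorted(set(spec.alphabet.upper().replace("U", "T")))
    if a < 2:
        raise ValidationError("alphabet must contain >= 2 distinct residues")
    if n_cells == 1:
        if spec.n_variable_sites != 0:
            raise ValidationError(
                "a single-group family admits no variable sites; "
                "set n_variable_sites=0"
            )
    else:
        if spec.n_variable_sites < 1 or a ** spec.n_variable_sites < n_cells:
            raise ValidationError(
                f"{spec.n_variable_sites} variable sites over a {a}-letter "
                f"alphabet cannot distinguish {n_cells} groups"
            )

    rng = np.random.default_rng(spec.seed)
    background = rng.integers(0, a, size=spec.seq_length)
    columns = np.sort(
        rng.choice(spec.seq_length, size=spec.n_variable_sites, replace=False)
    )

    digits = _residue_tuples(rng, n_cells, spec.n_variable_sites, a)

    cell_seqs: list[str] = []
    for c in range(n_cells):
        arr = background.copy()
        for j, col in enumerate(columns):
            arr[col] = digits[c, j]
        cell_seqs.append("".join(alphabet[b] for b in arr))

    gene_seq: dict[int, str] = {}
    for c, cell in enumerate(cells):
        for idx in cell:
            gene_seq[idx] = cell_seqs[c]
    genes = tuple(
        ParalogGene(
            gene_id=f"{spec.family_name}:g{i}",
            family=spec.family_name,
            sequence=gene_seq[i],
        )
        for i in range(1, spec.n_genes + 1)
    )
    groups = tuple(collapse_identical(genes))
    alignment = {g.group_id: g.representative_sequence for g in groups}

    planted = tuple(
        VariableSite(
            column_1based=int(col) + 1,
            residues={
                g.group_id: g.representative_sequence[int(col)] for g in groups
            },
        )
        for col in columns
    )
    return SyntheticFamily(
        genes=genes, groups=groups, alignment=alignment, planted_sites=planted
    )


def generate_mixture_trajectory(
    n_groups: int,
    stage_labels: Sequence[str],
    alpha_schedule: Sequence[float] | str | None = None,
    dominant_index: int = 0,
    seed: int = 0,
) -> MixtureTruth:
    """Sample a developmental trajectory in which one group takes over.

    Each stage's fraction vector is drawn from a symmetric Dirichlet with
    that stage's concentration; the default schedule decreases geometrically
    from 4.0 to 0.25, moving from even expression toward a single dominant
    isoform. The largest sampled coordinate is placed at ``dominant_index``
    and stages are ordered so the dominant fraction is non-decreasing (the
    "one isoform gradually dominates" pattern, enforced by construction).
    ``alpha_schedule="uniform"`` gives exact 1/n vectors at every stage.
    """
    if not stage_labels:
        raise ValidationError("stage_labels must be non-empty")
    if n_groups < 2:
        raise ValidationError("need n_groups >= 2")
    if not (0 <= dominant_index < n_groups):
        raise ValidationError("dominant_index out of range")
    n_stages = len(stage_labels)
    if alpha_schedule == "uniform":
        fractions = np.full((n_stages, n_groups), 1.0 / n_groups)
        return MixtureTruth(tuple(stage_labels), fractions)
    if alpha_schedule is None:
        alphas = np.geomspace(4.0, 0.25, n_stages)
    else:
        alphas = np.asarray(list(alpha_schedule), dtype=float)
        if len(alphas) != n_stages:
            raise ValidationError("alpha_schedule length must match stages")
        if np.any(alphas <= 0):
            raise ValidationError("Dirichlet concentrations must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for alpha in alphas:
        v = rng.dirichlet([float(alpha)] * n_groups)
        top = int(np.argmax(v))
        v[top], v[dominant_index] = v[dominant_index], v[top]
        rows.append(v / v.sum())
    rows.sort(key=lambda v: v[dominant_index])
    return MixtureTruth(tuple(stage_labels), np.array(rows))


def simulate_reads(
    family: SyntheticFamily | Sequence[IsoformGroup],
    fractions: Sequence[float],
    config: ReadSimConfig,
    read_id_prefix: str = "read",
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw reads from an isoform-group mixture with per-read truth.

    Source groups follow ``fractions``; start positions are uniform over the
    valid 1-based starts of the source sequence; each base is independently
    substituted with probability ``error_rate``. Returns (read_id, sequence)
    pairs and a truth table with columns read_id, source_group, start_1based,
    n_errors.
    """
    groups = family.groups if isinstance(family, SyntheticFamily) else tuple(family)
    f = np.asarray(fractions, dtype=float)
    if len(f) != len(groups):
        raise ValidationError("fractions length must equal number of groups")
    if abs(f.sum() - 1.0) > 1e-9 or np.any(f < 0):
        raise ValidationError("fractions must be non-negative and sum to 1")
    k = config.read_length
    seqs = [g.representative_sequence for g in groups]
    widths = np.array([len(s) - k + 1 for s in seqs])
    if np.any(widths < 1):
        raise ValidationError(
            f"read_length {k} exceeds a group sequence length"
        )
    rng = np.random.default_rng(config.seed)
    n = config.reads_per_sample
    src = rng.choice(len(groups), size=n, p=f)
    starts0 = np.floor(rng.random(n) * widths[src]).astype(int)

    reads = [seqs[g][p : p + k] for g, p in zip(src, starts0)]
    n_errors = np.zeros(n, dtype=int)
    if config.error_rate > 0:
        base_index = {b: i for i, b in enumerate(DEFAULT_ALPHABET)}
        err_mask = rng.random((n, k)) < config.error_rate
        shifts = rng.integers(1, 4, size=(n, k))
        hit_rows = np.nonzero(err_mask.any(axis=1))[0]
        for r in hit_rows:
            chars = list(reads[r])
            cols = np.nonzero(err_mask[r])[0]
            for c in cols:
                orig = base_index.get(chars[c], 0)
                chars[c] = DEFAULT_ALPHABET[(orig + shifts[r, c]) % 4]
            reads[r] = "".join(chars)
            n_errors[r] = len(cols)

    width = len(str(n))
    read_ids = [f"{read_id_prefix}{i + 1:0{width}d}" for i in range(n)]
    truth = pd.DataFrame(
        {
            "read_id": read_ids,
            "source_group": [groups[g].group_id for g in src],
            "start_1based": starts0 + 1,
            "n_errors": n_errors,
        }
    )
    return list(zip(read_ids, reads)), truth


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write (read_id, sequence) pairs as 4-line FASTQ with constant quality."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
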