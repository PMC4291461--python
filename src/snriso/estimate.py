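"""Isoform-group fraction estimation from class counts.

The observable data are class counts: reads bucketed by the exact subset of
isoform groups they match. Families whose every group owns a uniquely
mappable region can be quantified directly from singleton classes (the
U1/U4/U5 situation). Families with ambiguous classes (the U2 situation,
where some paralogs differ only near the sequence ends) need the expected-
count model

    E[count of class c]  =  sum_g A[c, g] * s_g

where A[c, g] is the number of read start positions on group g whose k-mer
produces class c (the design matrix, derived from the diagnostic regions)
and s_g is group g's per-start read intensity. Solving the non-negative
least-squares problem min ||A s - y||_2, s >= 0 and normalizing s gives the
fraction vector. Because paralogs within one snRNA family have near-identical
lengths, per-start intensity is proportional to expression fraction; a
length-weight hook is exposed for the general case.

Structurally confounded groups (identical design-matrix columns -- no read
of this length can separate them) are merged into one lumped composite group
with a warning rather than reported individually.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.optimize

from .assign import ClassCountTable
from .catalog import DiagnosticRegion, IsoformGroup, _join_group_id
from .dominance import dominance_sd
from .errors import EstimationError

__all__ = [
    "ClassDesignMatrix",
    "FractionEstimate",
    "StageSummary",
    "build_design_matrix",
    "estimate_fractions",
    "aggregate_stage",
]

NORMALIZATION_TOL = 1e-9


@dataclass(frozen=True)
class ClassDesignMatrix:
    """Coefficient structure linking class counts to group intensities.

    A[c, g] = number of valid read starts on group g whose k-mer yields
    class c; zero whenever g is not a member of subset c.
    """

    classes: tuple[frozenset[str], ...]
    groups: tuple[str, ...]
    A: np.ndarray

    def class_index(self) -> dict[frozenset[str], int]:
        return {c: i for i, c in enumerate(self.classes)}


@dataclass(frozen=True)
class FractionEstimate:
    """Per-sample isoform-group fractions (non-negative, summing to 1)."""

    sample_id: str
    fractions: Mapping[str, float]
    n_informative_reads: int
    method: str

    def vector(self, group_order: Sequence[str] | None = None) -> np.ndarray:
        order = list(group_order) if group_order is not None else sorted(self.fractions)
        return np.array([self.fractions[g] for g in order])


@dataclass(frozen=True)
class StageSummary:
    """Across-replicate summary of fraction estimates at one stage."""

    stage_label: str
    n_samples: int
    mean_fraction: Mapping[str, float]
    sd_across_samples: Mapping[str, float] | None
    dominance_sd: float


def build_design_matrix(
    regions: Sequence[DiagnosticRegion],
    groups: Sequence[IsoformGroup],
) -> ClassDesignMatrix:
    """Accumulate region widths into the class-by-group design matrix.

    The regions must partition every group's valid (N-free) read starts:
    overlaps or gaps raise :class:`EstimationError`.
    """
    if not regions:
        raise EstimationError("no diagnostic regions given")
    read_length = regions[0].read_length
    group_ids = [g.group_id for g in groups]
    gidx = {g: i for i, g in enumerate(group_ids)}
    seq_by_group = {g.group_id: g.representative_sequence for g in groups}

    # Partition check per carrier group.
    by_carrier: dict[str, list[DiagnosticRegion]] = {}
    for r in regions:
        if r.read_length != read_length:
            raise EstimationError("regions mix read lengths")
        if r.carrier_group not in gidx:
            raise EstimationError(f"region carrier {r.carrier_group!r} not in groups")
        by_carrier.setdefault(r.carrier_group, []).append(r)
    for gid, rs in by_carrier.items():
        seq = seq_by_group[gid]
        covered: set[int] = set()
        for r in sorted(rs, key=lambda r: r.start_min_1based):
            span = set(range(r.start_min_1based, r.start_max_1based + 1))
            if covered & span:
                raise EstimationError(f"overlapping regions on group {gid!r}")
            covered |= span
        expected = {
            p
            for p in range(1, len(seq) - read_length + 2)
            if "N" not in seq[p - 1 : p - 1 + read_length]
        }
        if covered != expected:
            raise EstimationError(
                f"regions on group {gid!r} do not partition its valid starts"
            )

    classes = sorted({r.group_subset for r in regions}, key=lambda c: sorted(c))
    cidx = {c: i for i, c in enumerate(classes)}
    A = np.zeros((len(classes), len(group_ids)), dtype=int)
    for r in regions:
        A[cidx[r.group_subset], gidx[r.carrier_group]] += r.width
    keep = A.any(axis=1)
    return ClassDesignMatrix(
        classes=tuple(c for c, k in zip(classes, keep) if k),
        groups=tuple(group_ids),
        A=A[keep],
    )


def _lump_confounded(
    design: ClassDesignMatrix,
) -> tuple[np.ndarray, list[str]]:
    """Merge structurally confounded groups (identical design columns).

    Two groups with identical columns generate indistinguishable expected
    counts; only their combined intensity is identifiable, so they are
    reported as one composite group with a concatenated id.
    """
    A = design.A
    merged_cols: list[np.ndarray] = []
    merged_ids: list[list[str]] = []
    seen: dict[bytes, int] = {}
    for j, gid in enumerate(design.groups):
        key = A[:, j].tobytes()
        if key in seen:
            merged_ids[seen[key]].append(gid)
        else:
            seen[key] = len(merged_cols)
            merged_cols.append(A[:, j])
            merged_ids.append([gid])
    if len(merged_ids) < len(design.groups):
        lumped = [m for m in merged_ids if len(m) > 1]
        warnings.warn(
            "structurally confounded groups lumped together: "
            + "; ".join(_join_group_id(m) for m in lumped),
            stacklevel=3,
        )
    ids = [_join_group_id(m) for m in merged_ids]
    return np.column_stack(merged_cols), ids


def estimate_fractions(
    counts: ClassCountTable,
    design: ClassDesignMatrix,
    mode: str = "linear_system",
    length_weights: Mapping[str, float] | None = None,
) -> FractionEstimate:
    """Estimate isoform-group fractions from one sample's class counts.

    mode="unique" uses only singleton classes (every group must own one):
    f_g is proportional to count({g}) / A[{g}, g], i.e. unique reads per
    uniquely mappable start. mode="linear_system" (default) solves the
    non-negative least-squares deconvolution over all classes and reduces to
    the unique-mode answer when unique classes fully determine the system.

    ``length_weights`` converts per-start intensity to abundance for groups
    of unequal length; by default every group weighs 1 (snRNA paralogs are
    near-identical in length).
    """
    cidx = design.class_index()
    y = np.zeros(len(design.classes))
    dropped = 0
    for cls, n in counts.counts.items():
        i = cidx.get(cls)
        if i is None:
            dropped += n
        else:
            y[i] += n
    if dropped:
        warnings.warn(
            f"{counts.sample_id}: {dropped} reads in classes absent from the "
            "design matrix were dropped",
            stacklevel=2,
        )
    if y.sum() <= 0:
        raise EstimationError(f"{counts.sample_id}: zero informative reads")

    def weight(gid: str) -> float:
        return 1.0 if length_weights is None else float(length_weights[gid])

    if mode == "unique":
        raw: dict[str, float] = {}
        n_informative = 0
        for gid, j in zip(design.groups, range(len(design.groups))):
            singleton = frozenset([gid])
            i = cidx.get(singleton)
            if i is None or design.A[i, j] == 0:
                raise EstimationError(
                    f"group {gid!r} has no uniquely mappable region; "
                    "use mode='linear_system'"
                )
            raw[gid] = (y[i] / design.A[i, j]) * weight(gid)
            n_informative += int(y[i])
        if n_informative == 0:
            raise EstimationError(f"{counts.sample_id}: zero informative reads")
        total = sum(raw.values())
        if total <= 0:
            raise EstimationError(f"{counts.sample_id}: all unique counts are zero")
        fractions = {g: v / total for g, v in raw.items()}
    elif mode == "linear_system":
        A, group_ids = _lump_confounded(design)
        s, _res = scipy.optimize.nnls(A.astype(float), y)
        if length_weights is None:
            w = np.ones(len(group_ids))
        else:
            # A lumped composite id falls back to its first member's weight.
            w = np.array(
                [
                    float(
                        length_weights.get(
                            g, length_weights.get(g.split("/", 1)[0], 1.0)
                        )
                    )
                    for g in group_ids
                ]
            )
        abundance = s * w
        total = abundance.sum()
        if total <= 0:
            raise EstimationError(
                f"{counts.sample_id}: degenerate solution (all intensities zero)"
            )
        fractions = {g: float(v / total) for g, v in zip(group_ids, abundance)}
        n_informative = int(y.sum())
    else:
        raise EstimationError(f"unknown estimation mode {mode!r}")

    total = sum(fractions.values())
    if abs(total - 1.0) > NORMALIZATION_TOL:
        fractions = {g: v / total for g, v in fractions.items()}
    return FractionEstimate(
        sample_id=counts.sample_id,
        fractions=fractions,
        n_informative_reads=n_informative,
        method=mode,
    )


def aggregate_stage(
    estimates: Sequence[FractionEstimate],
    stage_label: str,
    sd_ddof: int = 1,
) -> StageSummary:
    """Summarize replicate estimates at one developmental stage.

    Mean fractions are renormalized to sum to 1; across-replicate SDs use
    the n-1 denominator and are reported only when more than one sample is
    available. The dominance SD (spread of the mean fraction vector across
    groups) is computed with the same denominator convention.
    """
    if not estimates:
        raise EstimationError(f"stage {stage_label!r}: no estimates")
    group_sets = {frozenset(e.fractions) for e in estimates}
    if len(group_sets) > 1:
        raise EstimationError(f"stage {stage_label!r}: mixed group sets")
    groups = sorted(group_sets.pop())
    mat = np.array([[e.fractions[g] for g in groups] for e in estimates])
    mean = mat.mean(axis=0)
    mean = mean / mean.sum()
    n = len(estimates)
    sds = (
        {g: float(s) for g, s in zip(groups, mat.std(axis=0, ddof=1))}
        if n > 1
        else None
    )
    return StageSummary(
        stage_label=stage_label,
        n_samples=n,
        mean_fraction={g: float(m) for g, m in zip(groups, mean)},
        sd_across_samples=sds,
        dominance_sd=dominance_sd(mean, ddof=sd_ddof) if len(groups) >= 2 else 0.0,
    )
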