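"""Dominance statistic: spread of the fraction vector across isoform groups.

At each developmental stage the fractions of a subtype's isoform groups sum
to 1. When expression is even across n groups their standard deviation is 0;
when a single group carries everything the SD is maximal -- under the sample
(n-1) convention a one-hot vector over n groups gives SD = sqrt(1/n), e.g.
0.5774 for three groups. Rising SD along the stage order is the signature of
one isoform gradually dominating the subtype.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .errors import EstimationError

if TYPE_CHECKING:  # pragma: no cover
    from .estimate import StageSummary

__all__ = ["DominanceTrajectory", "dominance_sd", "trajectory"]


@dataclass(frozen=True)
class DominanceTrajectory:
    """Per-stage dominance SD and dominant group, in stage order."""

    family: str
    stage_labels: tuple[str, ...]
    dominance_sd: tuple[float, ...]
    dominant_group: tuple[str, ...]
    monotone_trend: bool


def dominance_sd(fractions: Sequence[float], ddof: int = 1) -> float:
    """SD of a fraction vector across n >= 2 isoform groups.

    Uses the sample (n-1) denominator by default; pass ddof=0 for the
    population convention. The vector must sum to 1 (tolerance 1e-6).
    """
    f = np.asarray(fractions, dtype=float)
    if f.size < 2:
        raise EstimationError("dominance_sd needs at least 2 groups")
    if abs(f.sum() - 1.0) > 1e-6:
        raise EstimationError(f"fractions sum to {f.sum():.6g}, not 1")
    return float(f.std(ddof=ddof))


def trajectory(
    stage_summaries: Sequence["StageSummary"],
    family: str = "",
    ddof: int = 1,
) -> DominanceTrajectory:
    """Dominance SD across ordered stages, computed on stage-mean fractions.

    The dominant group per stage is the argmax of the mean fraction (ties
    broken lexicographically, with a warning). The monotone-trend flag is
    true iff the dominance SD is non-decreasing along the stage order
    (vacuously true for a single stage).
    """
    if not stage_summaries:
        raise EstimationError("trajectory: no stages given")
    group_sets = {frozenset(s.mean_fraction) for s in stage_summaries}
    if len(group_sets) > 1:
        raise EstimationError("trajectory: stages have inconsistent group sets")
    labels: list[str] = []
    sds: list[float] = []
    dominants: list[str] = []
    for summary in stage_summaries:
        labels.append(summary.stage_label)
        items = sorted(summary.mean_fraction.items())
        values = [v for _g, v in items]
        sds.append(dominance_sd(values, ddof=ddof) if len(values) >= 2 else 0.0)
        best = max(v for _g, v in items)
        winners = [g for g, v in items if v == best]
        if len(winners) > 1:
            warnings.warn(
                f"stage {summary.stage_label!r}: dominant group tie between "
                f"{winners}; choosing {winners[0]!r}",
                stacklevel=2,
            )
        dominants.append(winners[0])
    monotone = all(
        b >= a - 1e-12 for a, b in zip(sds, sds[1:])
    )
    return DominanceTrajectory(
        family=family,
        stage_labels=tuple(labels),
        dominance_sd=tuple(sds),
        dominant_group=tuple(dominants),
        monotone_trend=monotone,
    )
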