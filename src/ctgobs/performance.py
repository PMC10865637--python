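"""Diagnostic-accuracy analysis of annotation studies.

Success rate, sensitivity and specificity (annotations pooled within each
stratum) with Wilson score confidence intervals; per-participant TPR/FPR
operating points; the success-rate profile across cord-pH ranges; and the
Buderer sample-size calculation for sensitivity/specificity studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datamodel import EXPERIENCE_BANDS, HYPOXIA, NORMAL, PROFESSIONS, Study

__all__ = [
    "ProportionWithCI",
    "PerformanceSummary",
    "ParticipantPoint",
    "PhBinSummary",
    "DEFAULT_PH_BIN_THRESHOLDS",
    "wilson_interval",
    "summarize_performance",
    "significant_differences",
    "participant_points",
    "success_by_ph_bin",
    "sample_size_sens_spec",
]

#: Cord-pH cut points bounding the success-rate profile bins.
DEFAULT_PH_BIN_THRESHOLDS = (6.90, 6.98, 7.05, 7.13, 7.20, 7.28, 7.35, 7.43)


@dataclass(frozen=True)
class ProportionWithCI:
    """A binomial proportion with a two-sided Wilson score interval."""

    estimate: float
    n: int
    lower: float
    upper: float
    level: float = 0.95
    numerator: int | None = None

    def overlaps(self, other: "ProportionWithCI") -> bool:
        return self.lower <= other.upper and other.lower <= self.upper


def wilson_interval(
    count_or_estimate: float, n: int, level: float = 0.95
) -> ProportionWithCI:
    """Wilson score interval for a binomial proportion.

    The first argument is a success count when given as an integer, or the
    proportion itself when given as a float in [0, 1] (useful when only the
    published estimate is available). With ``z`` the standard-normal quantile
    at (1 + level)/2 the interval is centred at (p + z^2/2n)/(1 + z^2/n) with
    half-width z/(1 + z^2/n) * sqrt(p(1-p)/n + z^2/4n^2); bounds are clipped
    to [0, 1].
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    numerator: int | None
    if isinstance(count_or_estimate, (int, np.integer)) and not isinstance(
        count_or_estimate, bool
    ):
        numerator = int(count_or_estimate)
        if not 0 <= numerator <= n:
            raise ValueError(f"count {numerator} outside 0..{n}")
        p = numerator / n
    else:
        p = float(count_or_estimate)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"estimate {p} outside [0, 1]")
        numerator = None
    z = norm.ppf(0.5 + level / 2)
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n))
    # the bound is exactly the estimate at the degenerate proportions
    lower = 0.0 if p == 0.0 else max(0.0, centre - half)
    upper = 1.0 if p == 1.0 else min(1.0, centre + half)
    return ProportionWithCI(
        estimate=p,
        n=int(n),
        lower=lower,
        upper=upper,
        level=level,
        numerator=numerator,
    )


@dataclass(frozen=True)
class PerformanceSummary:
    """Pooled accuracy metrics for one stratum of annotations.

    ``sensitivity`` is the success rate over annotations of truly hypoxic
    cases, ``specificity`` over truly normal ones; a metric is ``None`` when
    its stratum holds no annotations (undefined, not zero).
    """

    group_label: str
    success_rate: ProportionWithCI | None
    sensitivity: ProportionWithCI | None
    specificity: ProportionWithCI | None


_GROUPINGS = {
    "none": None,
    "profession": ("profession", list(PROFESSIONS)),
    "experience_band": ("experience_band", list(EXPERIENCE_BANDS)),
}


def summarize_performance(
    study: Study, grouping: str = "none", level: float = 0.95
) -> list[PerformanceSummary]:
    """Success rate / sensitivity / specificity per stratum, pooled over annotations.

    ``grouping`` is ``none`` (one ``total`` row), ``profession`` or
    ``experience_band``. Strata with no annotations of a given truth class
    report that metric as ``None``.
    """
    if grouping not in _GROUPINGS:
        raise ValueError(f"grouping must be one of {sorted(_GROUPINGS)}, got {grouping!r}")
    df = study.merged()
    if _GROUPINGS[grouping] is None:
        blocks = [("total", df)]
    else:
        col, order = _GROUPINGS[grouping]
        blocks = [(label, df[df[col] == label]) for label in order]
    out = []
    for label, block in blocks:
        out.append(
            PerformanceSummary(
                group_label=label,
                success_rate=_pooled(block, level),
                sensitivity=_pooled(block[block["true_outcome"] == HYPOXIA], level),
                specificity=_pooled(block[block["true_outcome"] == NORMAL], level),
            )
        )
    return out


def _pooled(block: pd.DataFrame, level: float) -> ProportionWithCI | None:
    if len(block) == 0:
        return None
    return wilson_interval(int(block["correct"].sum()), len(block), level=level)


def significant_differences(
    summaries: list[PerformanceSummary],
) -> pd.DataFrame:
    """Pairwise non-overlap flags between strata, per metric.

    Implements the study's interval-based significance heuristic: two strata
    are flagged as (likely) different on a metric exactly when their
    confidence intervals do not overlap. Strata where the metric is undefined
    are excluded.
    """
    rows = []
    for metric in ("success_rate", "sensitivity", "specificity"):
        defined = [(s.group_label, getattr(s, metric)) for s in summaries]
        defined = [(g, ci) for g, ci in defined if ci is not None]
        for i in range(len(defined)):
            for j in range(i + 1, len(defined)):
                (g1, c1), (g2, c2) = defined[i], defined[j]
                rows.append(
                    {
                        "metric": metric,
                        "group_a": g1,
                        "group_b": g2,
                        "different": not c1.overlaps(c2),
                    }
                )
    return pd.DataFrame(rows, columns=["metric", "group_a", "group_b", "different"])


@dataclass(frozen=True)
class ParticipantPoint:
    """One annotator's operating point: TPR against FPR."""

    participant_id: str
    tpr: float
    fpr: float
    n_annotations: int


def participant_points(
    study: Study, min_annotations: int = 10
) -> list[ParticipantPoint]:
    """TPR/FPR operating point per participant with > ``min_annotations`` annotations.

    TPR is the fraction of truly hypoxic cases the participant called hypoxia;
    FPR is one minus the fraction of truly normal cases called normal.
    Participants who saw no hypoxic (or no normal) case have an undefined rate
    and are omitted.
    """
    df = study.merged()
    points = []
    for pid, grp in df.groupby("participant_id", sort=True):
        n = len(grp)
        if n <= min_annotations:
            continue
        hyp = grp[grp["true_outcome"] == HYPOXIA]
        nrm = grp[grp["true_outcome"] == NORMAL]
        if len(hyp) == 0 or len(nrm) == 0:
            continue
        points.append(
            ParticipantPoint(
                participant_id=str(pid),
                tpr=float(hyp["correct"].mean()),
                fpr=1.0 - float(nrm["correct"].mean()),
                n_annotations=n,
            )
        )
    return points


@dataclass(frozen=True)
class PhBinSummary:
    """Success rate over annotations whose case pH falls in [bin_lower, bin_upper)."""

    bin_lower: float
    bin_upper: float
    success_rate: ProportionWithCI | None


def success_by_ph_bin(
    study: Study,
    thresholds: tuple[float, ...] = DEFAULT_PH_BIN_THRESHOLDS,
    level: float = 0.95,
) -> list[PhBinSummary]:
    """Mean success rate across contiguous cord-pH ranges.

    ``k`` strictly increasing thresholds define ``k + 1`` half-open bins
    (-inf, t1), [t1, t2), ..., [tk, +inf) partitioning the pH axis; every
    annotation contributes to exactly one bin through its case's pH.
    """
    t = list(thresholds)
    if any(b <= a for a, b in zip(t, t[1:])):
        raise ValueError("thresholds must be strictly increasing")
    df = study.merged()
    bin_idx = np.searchsorted(t, df["ph"].to_numpy(), side="right")
    edges = [-math.inf] + t + [math.inf]
    out = []
    for i in range(len(t) + 1):
        block = df[bin_idx == i]
        out.append(
            PhBinSummary(
                bin_lower=edges[i],
                bin_upper=edges[i + 1],
                success_rate=_pooled(block, level),
            )
        )
    return out


def sample_size_sens_spec(
    se: float,
    sp: float,
    precision: float,
    prevalence: float,
    level: float = 0.95,
) -> int:
    """Cases needed to estimate sensitivity and specificity to a target precision.

    Buderer's formulas: n_se = z^2 se(1-se) / (d^2 * prev) and
    n_sp = z^2 sp(1-sp) / (d^2 * (1-prev)) with ``d`` the confidence-interval
    half-width; the larger of the two is returned, rounded to the nearest
    integer.
    """
    for name, v in (("se", se), ("sp", sp), ("precision", precision), ("prevalence", prevalence)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must be in (0, 1), got {v}")
    z = norm.ppf(0.5 + level / 2)
    n_se = z * z * se * (1.0 - se) / (precision * precision * prevalence)
    n_sp = z * z * sp * (1.0 - sp) / (precision * precision * (1.0 - prevalence))
    return int(math.floor(max(n_se, n_sp) + 0.5))
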