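"""Consensus-based interobserver agreement and reliability.

The procedure: within each profession, each case annotated by at least one
member gets the profession's most frequent label (its consensus); agreement
between two professions is then measured on the cases both have a consensus
for, using the proportion of agreement (PA, with a Wilson interval) and
Cohen's kappa (with a large-sample interval). An overall figure pools the
pairwise values by the size of their case overlap, with a seeded case-level
bootstrap for its confidence interval.

PA magnitudes are labelled on the Altman scale and kappa magnitudes on the
Landis–Koch scale; a pairwise PA is additionally marked non-significant when
the lower bound of its interval falls below 0.50 (no better than coin-flip
agreement).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from ._rng import keyed_rng
from .datamodel import HYPOXIA, NORMAL, PROFESSIONS, Study
from .performance import ProportionWithCI, wilson_interval

__all__ = [
    "ConsensusVector",
    "KappaWithCI",
    "PairwiseAgreement",
    "OverallAgreement",
    "TIE_POLICIES",
    "consensus_by_profession",
    "proportion_agreement",
    "cohen_kappa",
    "pairwise_agreements",
    "overall_agreement",
    "classify_agreement",
    "UndefinedAgreement",
]

TIE_POLICIES = ("exclude", "hypoxia", "normal")


class UndefinedAgreement(ValueError):
    """Raised when an agreement statistic has no defined value.

    Examples: two consensus vectors with no overlapping case, or a kappa
    cross-table whose marginals are both degenerate (expected agreement 1).
    """


@dataclass(frozen=True)
class ConsensusVector:
    """Per-case majority labels of one profession.

    ``labels`` covers exactly the cases annotated by at least one member of
    the profession, minus exact ties (recorded in ``tie_cases`` under the
    default ``exclude`` policy — a tie is not a consensus).
    """

    profession: str
    labels: dict[str, str]
    tie_cases: frozenset[str] = field(default_factory=frozenset)


def consensus_by_profession(
    study: Study, profession: str, tie_policy: str = "exclude"
) -> ConsensusVector:
    """Most-frequent label per case among one profession's annotators.

    ``tie_policy`` resolves exact vote ties: ``exclude`` drops the case from
    the consensus (default), ``hypoxia``/``normal`` force the tied label.
    """
    if profession not in PROFESSIONS:
        raise ValueError(f"unknown profession {profession!r}")
    if tie_policy not in TIE_POLICIES:
        raise ValueError(f"tie_policy must be one of {TIE_POLICIES}, got {tie_policy!r}")
    df = study.merged()
    df = df[df["profession"] == profession]
    labels: dict[str, str] = {}
    ties: set[str] = set()
    for cid, grp in df.groupby("case_id"):
        n_hyp = int((grp["predicted_outcome"] == HYPOXIA).sum())
        n_nrm = len(grp) - n_hyp
        if n_hyp > n_nrm:
            labels[cid] = HYPOXIA
        elif n_nrm > n_hyp:
            labels[cid] = NORMAL
        elif tie_policy == "exclude":
            ties.add(cid)
        else:
            labels[cid] = tie_policy
    return ConsensusVector(profession=profession, labels=labels, tie_cases=frozenset(ties))


def _aligned(v1: ConsensusVector, v2: ConsensusVector) -> tuple[list[str], np.ndarray, np.ndarray]:
    common = sorted(set(v1.labels) & set(v2.labels))
    a = np.array([v1.labels[c] == HYPOXIA for c in common])
    b = np.array([v2.labels[c] == HYPOXIA for c in common])
    return common, a, b


def proportion_agreement(
    v1: ConsensusVector, v2: ConsensusVector, level: float = 0.95
) -> ProportionWithCI:
    """Fraction of overlapping cases on which two consensus vectors agree."""
    common, a, b = _aligned(v1, v2)
    if not common:
        raise UndefinedAgreement(
            f"no overlapping cases between {v1.profession} and {v2.profession}"
        )
    return wilson_interval(int((a == b).sum()), len(common), level=level)


@dataclass(frozen=True)
class KappaWithCI:
    """Cohen's kappa with a large-sample confidence interval."""

    estimate: float
    n: int
    lower: float
    upper: float
    level: float = 0.95


def cohen_kappa(
    v1: ConsensusVector, v2: ConsensusVector, level: float = 0.95
) -> KappaWithCI:
    """Chance-corrected agreement between two consensus vectors.

    From the 2x2 cross-tabulation over overlapping cases,
    kappa = (p_o - p_e)/(1 - p_e) with p_o the observed and p_e the
    chance-expected agreement. The interval uses the classic large-sample
    standard error sqrt(p_o(1-p_o)) / ((1-p_e) sqrt(N)), clipped to [-1, 1].
    """
    common, x, y = _aligned(v1, v2)
    if not common:
        raise UndefinedAgreement(
            f"no overlapping cases between {v1.profession} and {v2.profession}"
        )
    n = len(common)
    a = int((x & y).sum())        # both hypoxia
    b = int((x & ~y).sum())
    c = int((~x & y).sum())
    d = int((~x & ~y).sum())      # both normal
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    if p_e >= 1.0:
        raise UndefinedAgreement(
            "expected agreement is 1 (both marginals degenerate); kappa undefined"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = math.sqrt(p_o * (1.0 - p_o)) / ((1.0 - p_e) * math.sqrt(n))
    z = norm.ppf(0.5 + level / 2)
    return KappaWithCI(
        estimate=kappa,
        n=n,
        lower=max(-1.0, kappa - z * se),
        upper=min(1.0, kappa + z * se),
        level=level,
    )


# Verbal scales for agreement/reliability magnitudes. Upper bounds inclusive;
# values are rounded to 2 decimals before classification so the unprinted
# gaps between ranges (e.g. 0.805) resolve deterministically.
_ALTMAN_PA = ((0.20, "poor"), (0.40, "fair"), (0.60, "moderate"), (0.80, "good"), (1.00, "very_good"))
_LANDIS_KOCH = ((0.20, "slight"), (0.40, "fair"), (0.60, "moderate"), (0.80, "substantial"), (1.00, "almost_perfect"))


def classify_agreement(value: float, scale: str) -> str:
    """Verbal category for a PA (``altman_pa``) or kappa (``landis_koch_kappa``)."""
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"value {value} outside [-1, 1]")
    table = {"altman_pa": _ALTMAN_PA, "landis_koch_kappa": _LANDIS_KOCH}.get(scale)
    if table is None:
        raise ValueError(f"unknown scale {scale!r}")
    r = math.floor(value * 100 + 0.5) / 100  # round half up to 2 dp
    for upper, label in table:
        if r <= upper:
            return label
    return table[-1][1]


@dataclass(frozen=True)
class PairwiseAgreement:
    """PA and kappa between two professions' consensus vectors."""

    pair: tuple[str, str]
    n_overlap: int
    pa: ProportionWithCI
    kappa: KappaWithCI
    pa_class: str
    kappa_class: str
    pa_significant: bool


def pairwise_agreements(
    study: Study,
    professions: tuple[str, ...] = PROFESSIONS,
    tie_policy: str = "exclude",
    level: float = 0.95,
) -> tuple[list[PairwiseAgreement], dict[str, ConsensusVector]]:
    """All profession-pair agreements, plus the consensus vectors used.

    Pairs with no overlapping consensus cases are dropped (they cannot enter
    the weighted overall either).
    """
    vectors = {
        p: consensus_by_profession(study, p, tie_policy=tie_policy) for p in professions
    }
    out = []
    for p1, p2 in itertools.combinations(professions, 2):
        try:
            pa = proportion_agreement(vectors[p1], vectors[p2], level=level)
            kap = cohen_kappa(vectors[p1], vectors[p2], level=level)
        except UndefinedAgreement:
            continue
        out.append(
            PairwiseAgreement(
                pair=(p1, p2),
                n_overlap=pa.n,
                pa=pa,
                kappa=kap,
                pa_class=classify_agreement(pa.estimate, "altman_pa"),
                kappa_class=classify_agreement(kap.estimate, "landis_koch_kappa"),
                pa_significant=pa.lower >= 0.50,
            )
        )
    return out, vectors


@dataclass(frozen=True)
class OverallAgreement:
    """Overlap-weighted overall PA and kappa across profession pairs."""

    pa: float
    kappa: float
    weights: dict[tuple[str, str], int]
    pa_ci: tuple[float, float] | None = None
    kappa_ci: tuple[float, float] | None = None
    level: float = 0.95
    n_bootstrap: int = 0


def overall_agreement(
    pairwise: list[PairwiseAgreement],
    consensus: dict[str, ConsensusVector] | None = None,
    n_bootstrap: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> OverallAgreement:
    """Weighted mean of pairwise PA and kappa, weights = overlap sizes.

    When the consensus vectors are supplied, confidence intervals come from a
    case-level bootstrap: cases are resampled with replacement from the union
    of consensus cases, all pairwise statistics and the weighted overall are
    recomputed per replicate, and percentile bounds are taken. The resampling
    stream is keyed by ``seed`` so results are reproducible.
    """
    if not pairwise:
        raise UndefinedAgreement("no profession pair has a defined agreement")
    weights = {p.pair: p.n_overlap for p in pairwise}
    total = sum(weights.values())
    pa = sum(p.pa.estimate * p.n_overlap for p in pairwise) / total
    kappa = sum(p.kappa.estimate * p.n_overlap for p in pairwise) / total
    pa_ci = kappa_ci = None
    if consensus is not None and n_bootstrap > 0:
        pa_ci, kappa_ci = _bootstrap_overall(
            consensus, [p.pair for p in pairwise], n_bootstrap, seed, level
        )
    return OverallAgreement(
        pa=pa,
        kappa=kappa,
        weights=weights,
        pa_ci=pa_ci,
        kappa_ci=kappa_ci,
        level=level,
        n_bootstrap=n_bootstrap if consensus is not None else 0,
    )


def _bootstrap_overall(
    consensus: dict[str, ConsensusVector],
    pairs: list[tuple[str, str]],
    n_bootstrap: int,
    seed: int,
    level: float,
) -> tuple[tuple[float, float], tuple[float, float]]:
    universe = sorted(set().union(*(set(v.labels) for v in consensus.values())))
    idx_of = {c: i for i, c in enumerate(universe)}
    m = len(universe)
    # Aligned +1/-1/0 encodings over the case universe (0 = no consensus).
    enc = {}
    for prof, v in consensus.items():
        e = np.zeros(m, dtype=np.int8)
        for cid, lab in v.labels.items():
            e[idx_of[cid]] = 1 if lab == HYPOXIA else -1
        enc[prof] = e
    rng = keyed_rng(seed, "overall-bootstrap")
    pa_stats, k_stats = [], []
    for _ in range(n_bootstrap):
        take = rng.integers(0, m, size=m)
        pa_num = pa_den = 0.0
        k_num = k_den = 0.0
        for p1, p2 in pairs:
            x, y = enc[p1][take], enc[p2][take]
            mask = (x != 0) & (y != 0)
            n = int(mask.sum())
            if n == 0:
                continue
            xb, yb = x[mask] > 0, y[mask] > 0
            p_o = float((xb == yb).mean())
            pa_num += p_o * n
            pa_den += n
            p1h, p2h = float(xb.mean()), float(yb.mean())
            p_e = p1h * p2h + (1 - p1h) * (1 - p2h)
            if p_e < 1.0:
                k_num += (p_o - p_e) / (1.0 - p_e) * n
                k_den += n
        if pa_den:
            pa_stats.append(pa_num / pa_den)
        if k_den:
            k_stats.append(k_num / k_den)
    lo, hi = (1 - level) / 2 * 100, (1 + level) / 2 * 100
    pa_ci = tuple(np.percentile(pa_stats, [lo, hi]))
    kappa_ci = tuple(np.percentile(k_stats, [lo, hi]))
    return pa_ci, kappa_ci
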