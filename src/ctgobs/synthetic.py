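"""Synthetic annotator-cohort generator.

Emulates the statistical structure of a multi-reader CTG interpretation
study so that every pipeline stage can be exercised without access to the
original annotation data:

* 100 cases with a 50/50 hypoxia/normal split at pH threshold 7.15, cord pH
  drawn from a truncated normal on each side of the threshold;
* 120 participants across three professions (39 residents, 23 midwives,
  58 obstetrician-gynecologists by default);
* heavy-tailed participation — a point mass of completers who annotate all
  cases plus a truncated log-normal for everyone else;
* a two-parameter logistic response per rater: the probability of calling
  ``hypoxia`` is sigma(a + b*(tau - pH)), with bias ``a`` and discrimination
  ``b`` (log-odds per pH unit). This is the minimal model that makes success
  dip toward chance for pH near the threshold and rise at the extremes.

All draws come from streams keyed by (seed, entity ids), so a given
participant's data never changes when other participants are added.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from ._rng import keyed_rng
from .assignment import build_batch_plan, presentation_sequence
from .datamodel import (
    DEFAULT_PH_THRESHOLD,
    EXPERIENCE_BANDS,
    HYPOXIA,
    NORMAL,
    Study,
)
from .performance import ProportionWithCI, wilson_interval

__all__ = [
    "RaterModel",
    "GeneratorConfig",
    "generate_cases",
    "generate_raters",
    "simulate_annotations",
    "generate_study",
    "recover_rater_parameters",
    "write_truth",
    "read_truth",
]


@dataclass(frozen=True)
class RaterModel:
    """Latent response parameters of one simulated annotator.

    ``bias`` shifts the rater toward predicting hypoxia (log-odds offset);
    ``discrimination`` (>= 0) is the log-odds gained per pH unit below the
    threshold; ``planned_annotations`` is how many cases the rater labels.
    """

    participant_id: str
    bias: float
    discrimination: float
    planned_annotations: int

    def __post_init__(self):
        if self.discrimination < 0:
            raise ValueError("discrimination must be non-negative")
        if not 1 <= self.planned_annotations:
            raise ValueError("planned_annotations must be >= 1")

    def p_hypoxia(self, ph: float, threshold: float = DEFAULT_PH_THRESHOLD) -> float:
        """Probability of predicting hypoxia for a case with this cord pH."""
        x = self.bias + self.discrimination * (threshold - ph)
        return float(expit(x))


@dataclass
class GeneratorConfig:
    """Study-generating parameters; defaults emulate the reference cohort."""

    seed: int = 0
    n_cases: int = 100
    threshold: float = DEFAULT_PH_THRESHOLD
    #: Cord-pH distribution: normal truncated to ph_bounds, sampled separately
    #: below/above the threshold to force the 50/50 outcome split.
    ph_mean: float = 7.20
    ph_sd: float = 0.12
    ph_bounds: tuple[float, float] = (6.85, 7.47)
    n_participants: int = 120
    profession_counts: dict[str, int] = field(
        default_factory=lambda: {
            "resident": 39,
            "midwife": 23,
            "obstetrician_gynecologist": 58,
        }
    )
    #: Mixture over the four experience bands (0-2, 2-4, 4-8, >8 years).
    experience_probs: tuple[float, float, float, float] = (0.25, 0.20, 0.20, 0.35)
    p_university: float = 0.84
    p_france: float = 94 / 120
    bias_mean: float = 0.0
    bias_sd: float = 0.4
    discrimination_median: float = 8.0
    discrimination_sigma_log: float = 0.5
    #: Participation: with this probability a rater annotates every case,
    #: otherwise a truncated log-normal count.
    participation_full_prob: float = 0.10
    participation_median: float = 9.0
    participation_sigma_log: float = 1.1
    participation_bounds: tuple[int, int] = (1, 99)

    def __post_init__(self):
        if self.n_cases % 2 != 0:
            raise ValueError("n_cases must be even (balanced outcome split)")
        if sum(self.profession_counts.values()) != self.n_participants:
            raise ValueError("profession_counts must sum to n_participants")
        lo, hi = self.ph_bounds
        if not (lo < self.threshold < hi):
            raise ValueError("threshold must lie strictly inside ph_bounds")


_BAND_RANGES = {"0-2": (0.0, 2.0), "2-4": (2.0, 4.0), "4-8": (4.0, 8.0), ">8": (8.0, 25.0)}
_OTHER_COUNTRIES = ("Belgium", "Switzerland", "Italy", "Spain", "Finland")


def _trunc_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cases(config: GeneratorConfig) -> pd.DataFrame:
    """Balanced case set: n/2 cases strictly below the threshold, n/2 at or above.

    pH values are truncated-normal draws on each side of the threshold,
    rounded to 4 decimals (kept clear of the threshold so rounding never
    flips an outcome).
    """
    n_half = config.n_cases // 2
    lo, hi = config.ph_bounds
    eps = 1e-4
    rng = keyed_rng(config.seed, "cases")
    ph_hyp = _trunc_normal(rng, config.ph_mean, config.ph_sd, lo, config.threshold - eps, n_half)
    ph_norm = _trunc_normal(rng, config.ph_mean, config.ph_sd, config.threshold, hi, n_half)
    ph = np.round(np.concatenate([ph_hyp, ph_norm]), 4)
    ph = np.clip(ph, lo, hi)
    ph[:n_half] = np.minimum(ph[:n_half], config.threshold - eps)
    ph[n_half:] = np.maximum(ph[n_half:], config.threshold)
    return pd.DataFrame(
        {
            "case_id": [f"c{i:03d}" for i in range(config.n_cases)],
            "ph": ph,
            "true_outcome": [HYPOXIA] * n_half + [NORMAL] * n_half,
        }
    )


def generate_raters(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, dict[str, RaterModel]]:
    """Participant table plus the latent rater models keyed by participant id.

    Counts per profession match ``profession_counts`` exactly; bias is normal,
    discrimination log-normal, and the planned annotation count comes from the
    completer/log-normal participation mixture.
    """
    rows = []
    models: dict[str, RaterModel] = {}
    i = 0
    for profession in sorted(config.profession_counts):
        for _ in range(config.profession_counts[profession]):
            pid = f"p{i:03d}"
            rng = keyed_rng(config.seed, "rater", pid)
            band = EXPERIENCE_BANDS[
                rng.choice(len(config.experience_probs), p=config.experience_probs)
            ]
            b_lo, b_hi = _BAND_RANGES[band]
            years = round(float(rng.uniform(b_lo, b_hi)), 1)
            if years >= b_hi:  # keep the draw inside its band after rounding
                years = b_lo
            setting = (
                "university_hospital"
                if rng.random() < config.p_university
                else "general_hospital"
            )
            country = (
                "France"
                if rng.random() < config.p_france
                else _OTHER_COUNTRIES[int(rng.integers(len(_OTHER_COUNTRIES)))]
            )
            bias = float(rng.normal(config.bias_mean, config.bias_sd)) if config.bias_sd > 0 else config.bias_mean
            if config.discrimination_sigma_log > 0:
                disc = float(
                    np.exp(rng.normal(np.log(config.discrimination_median), config.discrimination_sigma_log))
                )
            else:
                disc = config.discrimination_median
            if rng.random() < config.participation_full_prob:
                k = config.n_cases
            else:
                k_lo, k_hi = config.participation_bounds
                x = _trunc_normal(
                    rng,
                    np.log(config.participation_median),
                    config.participation_sigma_log,
                    np.log(k_lo),
                    np.log(k_hi),
                    1,
                )[0]
                k = int(np.clip(round(np.exp(x)), k_lo, min(k_hi, config.n_cases)))
            rows.append(
                {
                    "participant_id": pid,
                    "profession": profession,
                    "years_experience": years,
                    "setting": setting,
                    "country": country,
                    "is_student": False,
                }
            )
            models[pid] = RaterModel(
                participant_id=pid,
                bias=bias,
                discrimination=disc,
                planned_annotations=k,
            )
            i += 1
    return pd.DataFrame(rows), models


def simulate_annotations(
    cases: pd.DataFrame,
    raters: dict[str, RaterModel],
    seed: int,
    threshold: float = DEFAULT_PH_THRESHOLD,
) -> pd.DataFrame:
    """Annotation table produced by the rater models over the batch plan.

    Each rater walks their presentation sequence (truncated to their planned
    count) and predicts hypoxia with probability sigma(a + b*(tau - pH));
    the Bernoulli draw for a (participant, case) pair is keyed by
    (seed, participant, case) so any subset of the cohort is reproducible.
    """
    plan = build_batch_plan(cases, seed)
    ph_of = dict(zip(cases["case_id"], cases["ph"]))
    rows = []
    for pid in sorted(raters):
        model = raters[pid]
        k = min(model.planned_annotations, plan.n_cases)
        for idx, cid in enumerate(presentation_sequence(plan, pid, k, seed), start=1):
            p = model.p_hypoxia(ph_of[cid], threshold)
            u = keyed_rng(seed, "annotation", pid, cid).random()
            rows.append(
                {
                    "participant_id": pid,
                    "case_id": cid,
                    "predicted_outcome": HYPOXIA if u < p else NORMAL,
                    "presentation_index": idx,
                }
            )
    return pd.DataFrame(rows)


def generate_study(config: GeneratorConfig) -> tuple[Study, dict[str, RaterModel]]:
    """Generate a complete validated study and its latent truth."""
    cases = generate_cases(config)
    participants, models = generate_raters(config)
    annotations = simulate_annotations(cases, models, config.seed, config.threshold)
    study = Study(cases, participants, annotations, threshold=config.threshold)
    return study, models


def write_truth(models: dict[str, RaterModel], path: str | Path) -> None:
    """Persist latent rater parameters as JSON for recovery experiments."""
    payload = {pid: asdict(m) for pid, m in sorted(models.items())}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> dict[str, RaterModel]:
    payload = json.loads(Path(path).read_text())
    return {pid: RaterModel(**kw) for pid, kw in payload.items()}


def recover_rater_parameters(
    study: Study,
    truth: dict[str, RaterModel] | None = None,
    min_annotations_fit: int = 30,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-rater empirical accuracy and maximum-likelihood response fits.

    For every rater: empirical sensitivity/specificity with Wilson intervals.
    For raters with at least ``min_annotations_fit`` annotations, the logistic
    response P(predict hypoxia) = sigma(a + b*(tau - pH)) is fitted by maximum
    likelihood; raters whose fit fails (e.g. perfect separation) carry NaN
    estimates. When ``truth`` is given, the true (a, b) are merged in for a
    recovery report.
    """
    import statsmodels.api as sm

    df = study.merged()
    tau = study.threshold
    rows = []
    for pid, grp in df.groupby("participant_id", sort=True):
        row: dict[str, object] = {"participant_id": pid, "n_annotations": len(grp)}
        for metric, outcome in (("se", HYPOXIA), ("sp", NORMAL)):
            sub = grp[grp["true_outcome"] == outcome]
            ci: ProportionWithCI | None = (
                wilson_interval(int(sub["correct"].sum()), len(sub), level=level)
                if len(sub)
                else None
            )
            row[metric] = ci.estimate if ci else np.nan
            row[f"{metric}_lower"] = ci.lower if ci else np.nan
            row[f"{metric}_upper"] = ci.upper if ci else np.nan
        a_hat = b_hat = np.nan
        if len(grp) >= min_annotations_fit:
            y = (grp["predicted_outcome"] == HYPOXIA).to_numpy(dtype=float)
            x = sm.add_constant((tau - grp["ph"]).to_numpy())
            try:
                res = sm.Logit(y, x).fit(disp=0, maxiter=200)
                if res.mle_retvals.get("converged", False) and np.all(
                    np.isfinite(res.params)
                ):
                    a_hat, b_hat = float(res.params[0]), float(res.params[1])
            except Exception:
                pass
        row["a_hat"], row["b_hat"] = a_hat, b_hat
        rows.append(row)
    out = pd.DataFrame(rows)
    if truth is not None:
        truth_df = pd.DataFrame(
            [
                {
                    "participant_id": pid,
                    "a_true": m.bias,
                    "b_true": m.discrimination,
                }
                for pid, m in truth.items()
            ]
        )
        out = out.merge(truth_df, on="participant_id", how="left")
    return out
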