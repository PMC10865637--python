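"""One-command orchestration: study -> report bundle.

``run_pipeline`` takes a declarative config, loads (or simulates) a study,
and writes the full set of report products:

* ``table1.csv`` — cohort description per profession (assessor counts,
  annotation counts, median and quartiles of annotations per assessor);
* ``table2.csv`` — success rate / sensitivity / specificity with Wilson CIs
  per profession plus the pooled total, and the interval-overlap flags;
* ``table3.csv`` — pairwise and overall proportion of agreement and kappa;
* ``fig1_data.csv`` — per-participant TPR/FPR operating points;
* ``fig2_data.csv`` — success rate per cord-pH range;
* ``run_manifest.json`` — config hash, seeds, row counts and output digests.

Every CSV is mirrored as JSON (full precision; the CSVs round metrics to two
decimals and percentages to integers for display). Reruns from the same
config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import overall_agreement, pairwise_agreements
from .datamodel import PROFESSIONS, Study, read_study_dir, write_study
from .performance import (
    DEFAULT_PH_BIN_THRESHOLDS,
    participant_points,
    significant_differences,
    success_by_ph_bin,
    summarize_performance,
)
from .synthetic import GeneratorConfig, generate_study, write_truth

__all__ = ["PipelineConfig", "run_pipeline", "tukey_hinges", "table1"]


@dataclass
class PipelineConfig:
    """Declarative pipeline settings; every tunable defaults to the study's value."""

    out_dir: str = "pipeline_out"
    study_dir: str | None = None  # when None, a study is simulated into out_dir/study
    seed: int = 0
    threshold: float = 7.15
    ph_thresholds: tuple[float, ...] = DEFAULT_PH_BIN_THRESHOLDS
    min_annotations: int = 10
    tie_policy: str = "exclude"
    bootstrap_resamples: int = 2000
    ci_level: float = 0.95
    quartile_method: str = "tukey"  # or "linear"
    generator: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        if "ph_thresholds" in raw:
            raw["ph_thresholds"] = tuple(raw["ph_thresholds"])
        return cls(**raw)

    def canonical(self) -> dict:
        d = dataclasses.asdict(self)
        d["ph_thresholds"] = list(self.ph_thresholds)
        return d


def tukey_hinges(values) -> tuple[float, float, float]:
    """(q1, median, q3) by the median-of-halves (Tukey hinge) rule.

    With an odd count the median belongs to both halves; ``linear``
    interpolation is available through the pipeline config instead.
    """
    x = np.sort(np.asarray(list(values), dtype=float))
    n = len(x)
    if n == 0:
        return (math.nan, math.nan, math.nan)
    med = float(np.median(x))
    half = (n + 1) // 2
    return float(np.median(x[:half])), med, float(np.median(x[n - half:]))


def _quartiles(values, method: str) -> tuple[float, float, float]:
    if method == "tukey":
        return tukey_hinges(values)
    if method == "linear":
        q1, med, q3 = np.percentile(np.asarray(list(values), dtype=float), [25, 50, 75])
        return float(q1), float(med), float(q3)
    raise ValueError(f"unknown quartile method {method!r}")


def table1(study: Study, quartile_method: str = "tukey") -> pd.DataFrame:
    """Cohort description per profession plus a total row.

    Counts and percentages of assessors and annotations, and the median
    (q1, q3) number of annotations per assessor.
    """
    parts = study.participants
    per_rater = (
        study.annotations.groupby("participant_id").size()
        if len(study.annotations)
        else pd.Series(dtype=int)
    )
    counts = per_rater.reindex(parts["participant_id"], fill_value=0)
    total_ann = int(counts.sum())
    rows = []
    for prof in list(PROFESSIONS) + ["total"]:
        mask = np.ones(len(parts), bool) if prof == "total" else (parts["profession"] == prof).to_numpy()
        sub = counts.iloc[np.nonzero(mask)[0]] if len(parts) else counts
        n_assessors = int(mask.sum())
        n_ann = int(sub.sum())
        q1, med, q3 = _quartiles(sub, quartile_method) if n_assessors else (math.nan,) * 3
        rows.append(
            {
                "profession": prof,
                "n_assessors": n_assessors,
                "pct_assessors": round(100 * n_assessors / max(len(parts), 1)),
                "n_annotations": n_ann,
                "pct_annotations": round(100 * n_ann / max(total_ann, 1)),
                "median_annotations": med,
                "q1_annotations": q1,
                "q3_annotations": q3,
            }
        )
    return pd.DataFrame(rows)


def _ci_cols(prefix: str, ci) -> dict:
    if ci is None:
        return {prefix: math.nan, f"{prefix}_lower": math.nan, f"{prefix}_upper": math.nan,
                f"{prefix}_n": 0}
    return {prefix: ci.estimate, f"{prefix}_lower": ci.lower, f"{prefix}_upper": ci.upper,
            f"{prefix}_n": ci.n}


def _table2(study: Study, level: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    by_prof = summarize_performance(study, "profession", level=level)
    for s in by_prof + summarize_performance(study, "none", level=level):
        row = {"group": s.group_label}
        row.update(_ci_cols("success_rate", s.success_rate))
        row.update(_ci_cols("sensitivity", s.sensitivity))
        row.update(_ci_cols("specificity", s.specificity))
        rows.append(row)
    return pd.DataFrame(rows), significant_differences(by_prof)


def _table3(study: Study, cfg: PipelineConfig) -> pd.DataFrame:
    pairwise, vectors = pairwise_agreements(
        study, tie_policy=cfg.tie_policy, level=cfg.ci_level
    )
    rows = []
    for p in pairwise:
        rows.append(
            {
                "pair": f"{p.pair[0]}|{p.pair[1]}",
                "n_overlap": p.n_overlap,
                "pa": p.pa.estimate,
                "pa_lower": p.pa.lower,
                "pa_upper": p.pa.upper,
                "pa_class": p.pa_class,
                "pa_significant": p.pa_significant,
                "kappa": p.kappa.estimate,
                "kappa_lower": p.kappa.lower,
                "kappa_upper": p.kappa.upper,
                "kappa_class": p.kappa_class,
            }
        )
    overall = overall_agreement(
        pairwise,
        consensus=vectors,
        n_bootstrap=cfg.bootstrap_resamples,
        seed=cfg.seed,
        level=cfg.ci_level,
    )
    from .agreement import classify_agreement

    rows.append(
        {
            "pair": "overall",
            "n_overlap": sum(overall.weights.values()),
            "pa": overall.pa,
            "pa_lower": overall.pa_ci[0] if overall.pa_ci else math.nan,
            "pa_upper": overall.pa_ci[1] if overall.pa_ci else math.nan,
            "pa_class": classify_agreement(overall.pa, "altman_pa"),
            "pa_significant": (overall.pa_ci[0] if overall.pa_ci else 1.0) >= 0.50,
            "kappa": overall.kappa,
            "kappa_lower": overall.kappa_ci[0] if overall.kappa_ci else math.nan,
            "kappa_upper": overall.kappa_ci[1] if overall.kappa_ci else math.nan,
            "kappa_class": classify_agreement(overall.kappa, "landis_koch_kappa"),
        }
    )
    return pd.DataFrame(rows)


_DISPLAY_DECIMALS = 2


def _write_product(df: pd.DataFrame, out_dir: Path, name: str) -> dict[str, str]:
    """CSV (display rounding) + JSON mirror (full precision); returns digests."""
    csv_path, json_path = out_dir / f"{name}.csv", out_dir / f"{name}.json"
    disp = df.copy()
    for col in disp.columns:
        if pd.api.types.is_float_dtype(disp[col]):
            disp[col] = disp[col].round(_DISPLAY_DECIMALS)
    disp.to_csv(csv_path, index=False)
    json_path.write_text(
        json.dumps(json.loads(df.to_json(orient="records")), indent=1, sort_keys=True)
    )
    return {
        f"{name}.csv": _sha256(csv_path),
        f"{name}.json": _sha256(json_path),
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every analysis stage and write the report bundle.

    Returns a mapping of product name to path. Reruns with an identical
    config produce byte-identical outputs (the manifest records content
    digests so this can be audited).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.study_dir is not None:
        study = read_study_dir(config.study_dir, threshold=config.threshold)
    else:
        gen_kwargs = dict(config.generator)
        gen_kwargs.setdefault("seed", config.seed)
        gen_kwargs.setdefault("threshold", config.threshold)
        if "profession_counts" in gen_kwargs:
            gen_kwargs["profession_counts"] = dict(gen_kwargs["profession_counts"])
        gen = GeneratorConfig(**gen_kwargs)
        study, models = generate_study(gen)
        study_dir = out_dir / "study"
        write_study(study, study_dir)
        write_truth(models, study_dir / "truth.json")

    t2, flags = _table2(study, config.ci_level)
    points = participant_points(study, min_annotations=config.min_annotations)
    fig1 = pd.DataFrame(
        [
            {"participant_id": p.participant_id, "tpr": p.tpr, "fpr": p.fpr,
             "n_annotations": p.n_annotations}
            for p in points
        ],
        columns=["participant_id", "tpr", "fpr", "n_annotations"],
    )
    bins = success_by_ph_bin(study, tuple(config.ph_thresholds), level=config.ci_level)
    fig2 = pd.DataFrame(
        [
            {"bin_lower": b.bin_lower, "bin_upper": b.bin_upper,
             **_ci_cols("success_rate", b.success_rate)}
            for b in bins
        ]
    )

    digests: dict[str, str] = {}
    products = {
        "table1": table1(study, config.quartile_method),
        "table2": t2,
        "table2_differences": flags,
        "table3": _table3(study, config),
        "fig1_data": fig1,
        "fig2_data": fig2,
    }
    paths: dict[str, Path] = {}
    for name, df in products.items():
        digests.update(_write_product(df, out_dir, name))
        paths[name] = out_dir / f"{name}.csv"

    manifest = {
        "package": "ctgobs",
        "version": __version__,
        "config": config.canonical(),
        "config_hash": hashlib.sha256(
            json.dumps(config.canonical(), sort_keys=True).encode()
        ).hexdigest(),
        "counts": {
            "cases": study.n_cases,
            "participants": study.n_participants,
            "annotations": study.n_annotations,
            **{name: len(df) for name, df in products.items()},
        },
        "outputs": dict(sorted(digests.items())),
    }
    manifest_path = out_dir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths
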