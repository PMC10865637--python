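# ctgobs

Observer-performance and interobserver-agreement analysis for
cardiotocography (CTG) interpretation studies.

During labor, clinicians read the fetal heart rate and uterine contraction
traces of a CTG to judge whether the fetus is becoming hypoxic. How well they
do this — and how much they agree with each other — is the subject of
multi-reader annotation studies: many midwives, residents and
obstetrician-gynecologists each label a shared set of delivery cases as
*hypoxia* or *normal*, and the ground truth is the umbilical cord blood pH
measured at birth (pH < 7.15 defines moderate fetal hypoxia). `ctgobs`
implements the complete statistical pipeline for such a study, for the
biostatisticians and clinical researchers who run them:

* **Case assignment** — the pseudorandom presentation scheme: fixed balanced
  batches of 10 cases (5 hypoxic, 5 normal) shared by all participants,
  independently shuffled within each batch per participant, so that any
  prefix of 10k annotations contains exactly 5k hypoxic cases.
* **Diagnostic accuracy** — success rate, sensitivity Se and specificity Sp,
  pooled over annotations and stratified by profession or experience band,
  each with a Wilson score interval
  (p̂ + z²/2n ± z√(p̂(1−p̂)/n + z²/4n²)) / (1 + z²/n);
  per-participant TPR/FPR operating points; and the success-rate profile
  across cord-pH ranges.
* **Agreement and reliability** — per-profession majority-consensus labels,
  pairwise proportion of agreement PA (Altman scale) and Cohen's kappa
  κ = (p_o − p_e)/(1 − p_e) (Landis–Koch scale) on overlapping cases, and an
  overlap-weighted overall figure with a seeded case-level bootstrap CI.
* **Design** — Buderer's sample-size formulas
  n = z²·Se(1−Se)/(d²·prev) (and the Sp analogue) for sizing a
  sensitivity/specificity study to a target CI half-width d.
* **Simulation** — a synthetic annotator-cohort generator in which each rater
  predicts hypoxia with probability σ(a + b·(τ − pH)) (bias a, discrimination
  b, threshold τ = 7.15), with heavy-tailed participation and realistic
  cohort structure, for end-to-end testing and parameter-recovery
  experiments.

## Worked example

```python
from ctgobs import (GeneratorConfig, generate_study, summarize_performance,
                    pairwise_agreements, overall_agreement, sample_size_sens_spec,
                    classify_agreement)

# How many cases does a study need to pin Se and Sp to ±0.14 at 95% confidence,
# given pilot values Se=0.45, Sp=0.67 and 50% hypoxia prevalence?
n = sample_size_sens_spec(0.45, 0.67, precision=0.14, prevalence=0.5)
print(f"cases needed: {n}")

# Simulate a 120-reader cohort and analyse it end to end.
study, _ = generate_study(GeneratorConfig(seed=0))
print(f"{study.n_participants} participants, {study.n_annotations} annotations")
(total,) = summarize_performance(study, "none")
sr = total.success_rate
print(f"success rate {sr.estimate:.2f} (95% CI {sr.lower:.2f}-{sr.upper:.2f})")
pairwise, vectors = pairwise_agreements(study)
overall = overall_agreement(pairwise, consensus=vectors, n_bootstrap=2000, seed=0)
print(f"overall PA {overall.pa:.2f} ({classify_agreement(overall.pa, 'altman_pa')}), "
      f"kappa {overall.kappa:.2f} ({classify_agreement(overall.kappa, 'landis_koch_kappa')})")
```

prints

```
cases needed: 97
120 participants, 2639 annotations
success rate 0.65 (95% CI 0.64-0.67)
overall PA 0.72 (good), kappa 0.44 (moderate)
```

97 is the minimum balanced case count at which a 95% Wilson-style interval on
both Se and Sp stays within ±0.14. The simulated cohort's pooled success rate
(fraction of annotations matching the pH-derived truth) carries a Wilson
interval over its 2,639 annotations; the overall PA is the overlap-weighted
mean of the three profession-pair agreement proportions on consensus labels,
and κ is the corresponding chance-corrected figure with its verbal category.

## Command line

The same stages are available as a CLI; each subcommand is a thin wrapper
over one library function:

```sh
ctgobs simulate --seed 0 --out study/          # synthetic study + truth.json
ctgobs metrics --study-dir study --group profession --out table2.csv
ctgobs ph-curve --study-dir study --out fig2_data.csv
ctgobs points --study-dir study --out fig1_data.csv
ctgobs agreement --study-dir study --seed 0 --out table3.csv
ctgobs samplesize --se 0.45 --sp 0.67 --precision 0.14 --prevalence 0.5
ctgobs run --config pipeline.yaml              # everything, plus a manifest
```

`ctgobs run` writes the full report bundle (cohort description, stratified
accuracy, agreement tables, plot-ready TPR/FPR and pH-profile data) as CSV
with JSON mirrors, and a manifest with content digests — reruns from the same
config are byte-identical.

Real studies are read from three CSVs (`cases.csv`: case_id, ph;
`participants.csv`: participant_id, profession, years_experience, setting,
country; `annotations.csv`: participant_id, case_id, predicted_outcome,
presentation_index); validation recomputes outcomes from pH and checks
referential integrity with row-level error messages.

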