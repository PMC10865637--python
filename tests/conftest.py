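import numpy as np
import pandas as pd
import pytest

from ctgobs import GeneratorConfig, Study, generate_study


def make_study(case_specs, participant_specs, annotation_specs):
    """Build a validated Study from terse tuples.

    case_specs: (case_id, ph); participant_specs: (pid, profession, years);
    annotation_specs: (pid, case_id, predicted_outcome) — presentation indices
    are assigned in listing order per participant.
    """
    cases = pd.DataFrame(case_specs, columns=["case_id", "ph"])
    participants = pd.DataFrame(
        [
            {
                "participant_id": pid,
                "profession": prof,
                "years_experience": years,
                "setting": "university_hospital",
                "country": "France",
            }
            for pid, prof, years in participant_specs
        ]
    )
    rows = []
    counter = {}
    for pid, cid, label in annotation_specs:
        counter[pid] = counter.get(pid, 0) + 1
        rows.append(
            {
                "participant_id": pid,
                "case_id": cid,
                "predicted_outcome": label,
                "presentation_index": counter[pid],
            }
        )
    annotations = pd.DataFrame(
        rows, columns=["participant_id", "case_id", "predicted_outcome", "presentation_index"]
    )
    return Study(cases, participants, annotations)


@pytest.fixture(scope="session")
def default_study():
    """A full synthetic cohort at the generator defaults (fixed seed)."""
    study, models = generate_study(GeneratorConfig(seed=7))
    return study, models


@pytest.fixture(scope="session")
def recovery_study():
    """200 identical raters (a=0, b=8) annotating all 100 cases."""
    cfg = GeneratorConfig(
        seed=11,
        n_participants=200,
        profession_counts={"resident": 200},
        bias_mean=0.0,
        bias_sd=0.0,
        discrimination_median=8.0,
        discrimination_sigma_log=0.0,
        participation_full_prob=1.0,
    )
    study, models = generate_study(cfg)
    return study, models


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))
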