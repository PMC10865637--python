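"""Pseudorandom case-presentation scheme.

Cases are grouped once into fixed, outcome-balanced batches of 10 (5 hypoxia,
5 normal). Every participant walks the batches in the same order, but the
order of cases *within* each batch is an independent permutation per
participant. Balanced batches guarantee that any participant's first 10k
annotations cover exactly 5k hypoxic and 5k normal cases, which keeps the case
sets of light annotators close to each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._rng import keyed_rng
from .datamodel import HYPOXIA, Study

__all__ = ["BatchPlan", "build_batch_plan", "presentation_sequence", "assignment_table"]

BATCH_SIZE = 10
_PER_OUTCOME = BATCH_SIZE // 2


@dataclass(frozen=True)
class BatchPlan:
    """An ordered partition of the case set into balanced batches of 10."""

    batches: tuple[tuple[str, ...], ...]
    seed: int

    @property
    def n_cases(self) -> int:
        return sum(len(b) for b in self.batches)

    def case_ids(self) -> list[str]:
        return [c for b in self.batches for c in b]


def build_batch_plan(cases: pd.DataFrame, seed: int) -> BatchPlan:
    """Compose balanced batches of 10 from a cases table.

    The hypoxia and normal pools are shuffled separately (stream keyed by
    ``seed``) and consumed 5 + 5 per batch; the resulting batch sequence is
    fixed and shared by all participants. Requires an equal number of hypoxia
    and normal cases and a total divisible by 10.
    """
    hyp = list(cases.loc[cases["true_outcome"] == HYPOXIA, "case_id"])
    norm = list(cases.loc[cases["true_outcome"] != HYPOXIA, "case_id"])
    if len(hyp) != len(norm):
        raise ValueError(
            f"unbalanced case set: {len(hyp)} hypoxia vs {len(norm)} normal cases"
        )
    if (len(hyp) + len(norm)) % BATCH_SIZE != 0:
        raise ValueError(
            f"case count {len(hyp) + len(norm)} is not divisible by {BATCH_SIZE}"
        )
    rng = keyed_rng(seed, "batch-plan")
    hyp = [hyp[i] for i in rng.permutation(len(hyp))]
    norm = [norm[i] for i in rng.permutation(len(norm))]
    batches = []
    for b in range(len(hyp) // _PER_OUTCOME):
        lo, hi = b * _PER_OUTCOME, (b + 1) * _PER_OUTCOME
        batches.append(tuple(hyp[lo:hi] + norm[lo:hi]))
    return BatchPlan(batches=tuple(batches), seed=seed)


def presentation_sequence(
    plan: BatchPlan, participant_id: str, k: int, seed: int
) -> list[str]:
    """The first ``k`` case ids shown to a participant.

    Batches are visited in plan order; within batch ``i`` the order is a
    permutation drawn from a stream keyed by ``(seed, participant_id, i)``,
    so the sequence is reproducible regardless of call order. A participant
    never sees a case from batch ``i+1`` before finishing batch ``i``.
    """
    if not 0 <= k <= plan.n_cases:
        raise ValueError(f"k={k} exceeds the {plan.n_cases} cases in the plan")
    seq: list[str] = []
    for i, batch in enumerate(plan.batches):
        if len(seq) >= k:
            break
        rng = keyed_rng(seed, "within-batch", participant_id, i)
        order = rng.permutation(len(batch))
        seq.extend(batch[j] for j in order)
    return seq[:k]


def assignment_table(study: Study, seed: int) -> pd.DataFrame:
    """Full presentation sequences for every participant of a study.

    Returns a tidy frame (participant_id, presentation_index, case_id) with
    each participant's complete ordering over all cases.
    """
    plan = build_batch_plan(study.cases, seed)
    rows = []
    for pid in study.participants["participant_id"]:
        for idx, cid in enumerate(
            presentation_sequence(plan, pid, plan.n_cases, seed), start=1
        ):
            rows.append((pid, idx, cid))
    return pd.DataFrame(rows, columns=["participant_id", "presentation_index", "case_id"])
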