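"""One subject's session: the trial sequence plus the realized choices.

Bridges the task structures and the models: validates that choices are
consistent with what was offered, exposes the session as flat numpy arrays
for fast likelihood evaluation, and replays it under fixed parameters to
recover per-trial values and prediction errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import models, task

__all__ = ["Session", "MACHINE_INDEX", "replay"]

MACHINE_ORDER = ("D20", "D40", "D80", "P40", "P80")
MACHINE_INDEX = {m: i for i, m in enumerate(MACHINE_ORDER)}


@dataclass(frozen=True)
class Session:
    """A trial sequence and its choice records, in task order."""

    sequence: task.TrialSequence
    records: tuple[task.ChoiceRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) != len(self.sequence):
            raise ValueError(
                f"{len(self.records)} records for {len(self.sequence)} trials"
            )
        for spec, rec in zip(self.sequence, self.records):
            if rec.trial != spec.index:
                raise ValueError(f"record order mismatch at trial {spec.index}")
            if rec.missed:
                if rec.outcome_points is not None or rec.image_id is not None:
                    raise ValueError(f"missed trial {spec.index} carries an outcome")
                continue
            if rec.chosen not in spec.offered:
                raise ValueError(
                    f"trial {spec.index}: chose {rec.chosen!r}, offered {spec.offered}"
                )

    @property
    def n_modeled_choices(self) -> int:
        """Non-missed free choices: the trials that enter the likelihood."""
        return sum(
            1
            for spec, rec in zip(self.sequence, self.records)
            if spec.is_free_choice and not rec.missed
        )

    def to_arrays(self) -> dict[str, np.ndarray]:
        """Flat encoding for the likelihood kernel.

        chosen/other are machine indices (other = -1 on forced trials),
        reward is rescaled points (NaN when missed), is_free marks trials
        contributing to the choice likelihood.
        """
        n = len(self.sequence)
        chosen = np.full(n, -1, dtype=np.int64)
        other = np.full(n, -1, dtype=np.int64)
        reward = np.full(n, np.nan)
        is_free = np.zeros(n, dtype=np.bool_)
        for i, (spec, rec) in enumerate(zip(self.sequence, self.records)):
            is_free[i] = spec.is_free_choice
            if rec.missed:
                continue
            chosen[i] = MACHINE_INDEX[rec.chosen]
            reward[i] = rec.reward
            if spec.is_free_choice:
                unchosen = [m for m in spec.offered if m != rec.chosen]
                other[i] = MACHINE_INDEX[unchosen[0]]
        return {"chosen": chosen, "other": other, "reward": reward, "is_free": is_free}


def replay(params: models.ModelParams, session: Session) -> models.LearningTrace:
    """Replay the session under fixed parameters.

    Reference implementation of the learning dynamics: every non-missed
    outcome updates the chosen machine's value; missed trials are skipped.
    """
    state = models.initialize_values(task.build_machines())
    trace = models.LearningTrace()
    for spec, rec in zip(session.sequence, session.records):
        if rec.missed:
            continue
        agency = "free" if spec.is_free_choice else "forced"
        q_pre = state.q[rec.chosen]
        state, delta = models.update_value(params, state, rec.chosen, rec.reward, agency)
        trace.steps.append(
            models.TraceStep(spec.index, agency, rec.chosen, q_pre, delta, state.q[rec.chosen])
        )
    return trace
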