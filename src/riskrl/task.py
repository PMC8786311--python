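"""The five point-machine bandit task.

Five slot-machine-like options pay points: three deterministic machines
(always 20, 40, or 80 points) and two probabilistic machines (50/50 chance
of 0 or 40, and 0 or 80). The two equal-expected-value pairs (D20 vs P40,
D40 vs P80) make risk preference observable without making any learning
asymmetry optimal.

A session is 183 trials: 42 equal-EV risky choices, 24 unequal-EV risky
choices (P80 vs D20), 75 forced single-option trials (15 per machine), and
42 test trials where one option dominates the other. Trial types are
balanced in thirds across three blocks and shuffled within block.
Probabilistic outcomes are scheduled in bags of eight (four wins, four
zeros) drawn without replacement, so realized win frequency is exactly 1/2
over every run of eight draws from one machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MAX_POINTS = 80  # rescaling denominator: reward = points / 80

__all__ = [
    "MachineSpec",
    "TrialSpec",
    "TrialSequence",
    "OutcomeSchedule",
    "ChoiceRecord",
    "build_machines",
    "machine_map",
    "generate_trial_sequence",
    "next_outcome",
    "dominates",
    "EQUAL_EV_PAIRS",
    "UNEQUAL_EV_PAIR",
    "TEST_PAIRS",
    "N_TRIALS",
    "N_FREE_CHOICES",
]


@dataclass(frozen=True)
class MachineSpec:
    """One point machine: its outcome distribution over points."""

    machine_id: str
    outcomes: tuple[int, ...]
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.outcomes) != len(self.probabilities):
            raise ValueError("outcomes and probabilities differ in length")
        if abs(sum(self.probabilities) - 1.0) > 1e-12:
            raise ValueError(f"probabilities of {self.machine_id} do not sum to 1")

    @property
    def deterministic(self) -> bool:
        return len(self.outcomes) == 1

    @property
    def expected_value(self) -> float:
        return float(sum(o * p for o, p in zip(self.outcomes, self.probabilities)))

    def quantile_outcomes(self) -> tuple[int, int]:
        """Outcomes at the lose/win quantiles; deterministic machines repeat."""
        if self.deterministic:
            return (self.outcomes[0], self.outcomes[0])
        lo, hi = sorted(self.outcomes)
        return (lo, hi)


# canonical five machines: D = deterministic, P = 50/50 probabilistic
def build_machines() -> list[MachineSpec]:
    """The canonical five machines with EVs 20, 40, 80, 20, 40."""
    return [
        MachineSpec("D20", (20,), (1.0,)),
        MachineSpec("D40", (40,), (1.0,)),
        MachineSpec("D80", (80,), (1.0,)),
        MachineSpec("P40", (0, 40), (0.5, 0.5)),
        MachineSpec("P80", (0, 80), (0.5, 0.5)),
    ]


def machine_map(machines: list[MachineSpec] | None = None) -> dict[str, MachineSpec]:
    return {m.machine_id: m for m in (machines or build_machines())}


# (probabilistic, deterministic) pairings
EQUAL_EV_PAIRS = (("P40", "D20"), ("P80", "D40"))
UNEQUAL_EV_PAIR = ("P80", "D20")

# (dominant, dominated); every dominance pair among the five machines
TEST_PAIRS = (
    ("D40", "P40"),
    ("D80", "P80"),
    ("D80", "P40"),
    ("D40", "D20"),
    ("D80", "D20"),
    ("D80", "D40"),
    ("P80", "P40"),
)

N_TRIALS = 183
N_FREE_CHOICES = 108  # 42 equal-EV + 24 unequal-EV + 42 test

_COUNTS_PER_BLOCK = {"risky_equal": 14, "risky_unequal": 8, "forced": 25, "test": 14}


def dominates(a: MachineSpec, b: MachineSpec) -> bool:
    """True if `a` dominates `b`: outcome-by-outcome (at matched win/lose
    quantiles) a pays at least as much, strictly more at least once."""
    qa, qb = a.quantile_outcomes(), b.quantile_outcomes()
    return all(x >= y for x, y in zip(qa, qb)) and any(x > y for x, y in zip(qa, qb))


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial: what is offered and how."""

    index: int  # 1-based
    block: int  # 1..3
    trial_type: str  # risky_equal | risky_unequal | forced | test
    offered: tuple[str, ...]  # one machine (forced) or two
    forced_position: str | None = None  # left | right for forced trials

    @property
    def is_free_choice(self) -> bool:
        return self.trial_type != "forced"


@dataclass(frozen=True)
class TrialSequence:
    trials: tuple[TrialSpec, ...]
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)


def _block_slate(rng: np.random.Generator) -> list[tuple[str, tuple[str, ...]]]:
    """One block's worth of (trial_type, offered-pair) entries, unshuffled."""
    slate: list[tuple[str, tuple[str, ...]]] = []
    for pair in EQUAL_EV_PAIRS:  # 7 trials per pair per block -> 14
        slate += [("risky_equal", pair)] * 7
    slate += [("risky_unequal", UNEQUAL_EV_PAIR)] * 8
    for m in ("D20", "D40", "D80", "P40", "P80"):  # 5 forced per machine -> 25
        slate += [("forced", (m,))] * 5
    for pair in TEST_PAIRS:  # 2 per dominance pair -> 14
        slate += [("test", pair)] * 2
    return slate


def generate_trial_sequence(seed: int) -> TrialSequence:
    """Pseudo-randomized 183-trial sequence: a third of each trial type per
    block, order shuffled within block, left/right placement uniform."""
    rng = np.random.default_rng(seed)
    trials: list[TrialSpec] = []
    index = 1
    for block in (1, 2, 3):
        slate = _block_slate(rng)
        order = rng.permutation(len(slate))
        for i in order:
            trial_type, offered = slate[i]
            forced_position = None
            if trial_type == "forced":
                forced_position = "left" if rng.random() < 0.5 else "right"
            elif rng.random() < 0.5:  # randomize on-screen order
                offered = (offered[1], offered[0])
            trials.append(TrialSpec(index, block, trial_type, tuple(offered), forced_position))
            index += 1
    return TrialSequence(tuple(trials), seed)


@dataclass
class OutcomeSchedule:
    """Bag-of-eight outcome scheduler for the probabilistic machines.

    Each probabilistic machine owns a bag refilled with four win outcomes and
    four zeros; draws are without replacement, so every consecutive run of
    eight draws from one machine pays exactly four wins.
    """

    machines: dict[str, MachineSpec] = field(default_factory=machine_map)
    bags: dict[str, list[int]] = field(default_factory=dict)
    draw_log: list[tuple[str, int]] = field(default_factory=list)

    def _refill(self, machine: MachineSpec, rng: np.random.Generator) -> list[int]:
        lo, hi = machine.quantile_outcomes()
        bag = [lo] * 4 + [hi] * 4
        rng.shuffle(bag)
        return bag


def next_outcome(schedule: OutcomeSchedule, machine_id: str, rng: np.random.Generator) -> int:
    """Realize one outcome (in points) from a machine under the schedule."""
    machine = schedule.machines.get(machine_id)
    if machine is None:
        raise KeyError(f"unknown machine {machine_id!r}")
    if machine.deterministic:
        outcome = machine.outcomes[0]
    else:
        bag = schedule.bags.get(machine_id)
        if not bag:
            bag = schedule._refill(machine, rng)
            schedule.bags[machine_id] = bag
        outcome = bag.pop()
    schedule.draw_log.append((machine_id, outcome))
    return outcome


@dataclass(frozen=True)
class ChoiceRecord:
    """One realized trial: what was chosen and what it paid."""

    trial: int
    chosen: str | None
    outcome_points: int | None
    missed: bool = False
    image_id: str | None = None

    @property
    def reward(self) -> float | None:
        """Outcome rescaled to [0, 1] (points / 80)."""
        if self.outcome_points is None:
            return None
        return self.outcome_points / MAX_POINTS
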