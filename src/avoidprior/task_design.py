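"""Generative task schedules for the robber and factory avoidance tasks.

Both tasks present, on every trial, a points offer and an action cost and
ask the agent to choose between an active attempt (``go``) whose success is
Bernoulli with a stimulus-specific probability, and a passive default
(``ng``).  The two tasks share offer magnitudes; they differ in framing
(gain to keep vs. loss to prevent) and in their cost regimes.

A 60-trial block crosses 20 offers with 3 cost regimes (each combination
exactly once), and presents 12 stimuli in consecutive runs of 4-8
encounters, each stimulus carrying one value of a 12-point equidistant
success-probability grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Task",
    "CostRegime",
    "TrialSpec",
    "DesignMatrix",
    "ROBBER_REGIMES",
    "FACTORY_REGIMES",
    "OFFER_DIVISORS",
    "RUN_LENGTH_LIST_A",
    "RUN_LENGTH_LIST_B",
    "generate_offers",
    "compute_cost",
    "generate_success_probabilities",
    "build_block_design",
    "build_practice_design",
]


class Task(str, Enum):
    """The two avoidance framings."""

    ROBBER = "robber"
    FACTORY = "factory"


def _as_task(task: "Task | str") -> Task:
    return Task(task)


@dataclass(frozen=True)
class CostRegime:
    """Action-cost rule: a fixed component plus a fraction of the offer."""

    set_cost: int
    pct_of_offer: float

    def __post_init__(self) -> None:
        if self.set_cost < 0:
            raise ValueError("set_cost must be >= 0")
        if not 0.0 <= self.pct_of_offer <= 1.0:
            raise ValueError("pct_of_offer must be in [0, 1]")


#: Robber task: set costs 10/40/75 points with 15/5/0 % of the offer.
ROBBER_REGIMES: tuple[CostRegime, ...] = (
    CostRegime(10, 0.15),
    CostRegime(40, 0.05),
    CostRegime(75, 0.00),
)

#: Factory task: set costs 0/50/100 points with 10/5/0 % of the offer.
FACTORY_REGIMES: tuple[CostRegime, ...] = (
    CostRegime(0, 0.10),
    CostRegime(50, 0.05),
    CostRegime(100, 0.00),
)

#: Offers are 50 divided by these values (0.10 to 0.95 in steps of 0.05,
#: then 1 and 2), rounded half-up to whole points.
OFFER_DIVISORS: tuple[float, ...] = tuple(
    round(0.10 + 0.05 * i, 2) for i in range(18)
) + (1.0, 2.0)

# Run-length counterbalancing: the encounter multiset
# {4,4,4,4,4,4,5,5,5,6,7,8} split into two lists of six runs, each
# summing to 30, shuffled within list and concatenated.
RUN_LENGTH_LIST_A: tuple[int, ...] = (4, 4, 4, 5, 5, 8)
RUN_LENGTH_LIST_B: tuple[int, ...] = (4, 4, 4, 5, 6, 7)

N_STIMULI = 12
BLOCK_TRIALS = 60


def _round_half_up(x: "float | np.ndarray") -> "int | np.ndarray":
    # np.round rounds halves to even; the task uses conventional half-up.
    out = np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)
    return out if out.ndim else int(out)


def regimes_for(task: "Task | str") -> tuple[CostRegime, ...]:
    """Cost regimes of a task."""
    return ROBBER_REGIMES if _as_task(task) is Task.ROBBER else FACTORY_REGIMES


def generate_offers(task: "Task | str") -> list[int]:
    """The 20 offer magnitudes, identical for both tasks.

    The factory task interprets them as potential losses; the sign is
    applied by the utility functions, not here.
    """
    _as_task(task)  # validate
    return [_round_half_up(50.0 / d) for d in OFFER_DIVISORS]


def compute_cost(offer: int, regime: CostRegime) -> int:
    """Action cost in points: round-half-up(set_cost + pct_of_offer*offer)."""
    if offer <= 0:
        raise ValueError(f"offer must be positive, got {offer}")
    return _round_half_up(regime.set_cost + regime.pct_of_offer * offer)


def generate_success_probabilities() -> list[float]:
    """The 12-point equidistant success-probability grid k/13, k=1..12.

    This is the unique 12-point equidistant grid symmetric about 0.5 whose
    endpoints print as 7.69 % and 92.31 %.
    """
    return [k / 13.0 for k in range(1, 13)]


@dataclass(frozen=True)
class TrialSpec:
    """One trial of an avoidance block."""

    task: Task
    trial_index: int  # 1-based within the block
    stimulus_id: int
    offer: int  # positive magnitude; utilities apply the task's sign
    cost: int
    success_prob: float

    def __post_init__(self) -> None:
        if not 0.0 < self.success_prob < 1.0:
            raise ValueError("success_prob must be in (0, 1)")


@dataclass(frozen=True)
class DesignMatrix:
    """An ordered trial schedule for one block."""

    trials: tuple[TrialSpec, ...]
    task: Task
    block_id: int = 1
    seed: int | None = None
    practice: bool = False
    _frame: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self, subject: int = 1) -> pd.DataFrame:
        """Flat table: subject, task, block, trial, stimulus, offer, cost, success_prob."""
        return pd.DataFrame(
            {
                "subject": subject,
                "task": [t.task.value for t in self.trials],
                "block": self.block_id,
                "trial": [t.trial_index for t in self.trials],
                "stimulus": [t.stimulus_id for t in self.trials],
                "offer": [t.offer for t in self.trials],
                "cost": [t.cost for t in self.trials],
                "success_prob": [t.success_prob for t in self.trials],
            }
        )


def _balanced_run_lengths(rng: np.random.Generator) -> list[int]:
    a = list(RUN_LENGTH_LIST_A)
    b = list(RUN_LENGTH_LIST_B)
    rng.shuffle(a)
    rng.shuffle(b)
    return a + b


def build_block_design(
    task: "Task | str", seed: int, block_id: int = 1
) -> DesignMatrix:
    """Build one seeded 60-trial block.

    Draw order of the single seeded generator (so designs are
    bit-reproducible): (1) success-probability-to-stimulus permutation,
    (2) shuffle of run-length list A then list B, (3) shuffle of the 60
    offer-cost pairs.  The stimulus sequence and the offer-cost sequence
    are therefore randomised independently of each other.
    """
    task = _as_task(task)
    rng = np.random.default_rng(seed)

    probs = np.array(generate_success_probabilities())
    prob_of_stim = probs[rng.permutation(N_STIMULI)]  # stimulus s -> its p

    run_lengths = _balanced_run_lengths(rng)
    stim_seq: list[int] = []
    for stim, n_enc in enumerate(run_lengths, start=1):
        stim_seq.extend([stim] * n_enc)
    assert len(stim_seq) == BLOCK_TRIALS

    pairs = [
        (offer, compute_cost(offer, regime))
        for regime in regimes_for(task)
        for offer in generate_offers(task)
    ]
    order = rng.permutation(len(pairs))

    trials = tuple(
        TrialSpec(
            task=task,
            trial_index=t + 1,
            stimulus_id=stim_seq[t],
            offer=pairs[order[t]][0],
            cost=pairs[order[t]][1],
            success_prob=float(prob_of_stim[stim_seq[t] - 1]),
        )
        for t in range(BLOCK_TRIALS)
    )
    return DesignMatrix(trials=trials, task=task, block_id=block_id, seed=seed)


# Practice: 4 stimuli, encounter counts 4/4/4/6, success probabilities
# 0.8, 0.2, 0.5 and 0.5 respectively.  Practice stimulus ids start at 101
# so they can never collide with the 1..12 ids of main blocks.
PRACTICE_STIMULUS_OFFSET = 100
_PRACTICE_RUNS: tuple[tuple[int, float], ...] = (
    (4, 0.8),
    (4, 0.2),
    (4, 0.5),
    (6, 0.5),
)


def build_practice_design(
    task: "Task | str", seed: int, block_id: int = 0
) -> DesignMatrix:
    """An 18-trial practice block with 4 stimuli and 3 distinct probabilities."""
    task = _as_task(task)
    rng = np.random.default_rng(seed)

    runs = list(_PRACTICE_RUNS)
    rng.shuffle(runs)

    offers = generate_offers(task)
    regimes = regimes_for(task)

    trials = []
    t = 0
    for stim_i, (n_enc, p) in enumerate(runs):
        for _ in range(n_enc):
            offer = offers[rng.integers(len(offers))]
            regime = regimes[rng.integers(len(regimes))]
            t += 1
            trials.append(
                TrialSpec(
                    task=task,
                    trial_index=t,
                    stimulus_id=PRACTICE_STIMULUS_OFFSET + stim_i + 1,
                    offer=offer,
                    cost=compute_cost(offer, regime),
                    success_prob=p,
                )
            )
    return DesignMatrix(
        trials=tuple(trials), task=task, block_id=block_id, seed=seed, practice=True
    )
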