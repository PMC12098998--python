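"""Synthetic choice data: simulate single agents and cohorts under any model.

Simulation walks trials sequentially: each trial's P(go) is computed from
the agent's current belief/history state, the action is sampled, an
outcome is sampled (Bernoulli in the stimulus's true success probability)
only when the agent acts, and the state is updated.  The exact rectified
lapse rule is used generatively; the SoftPlus surrogate exists only to
make fitting differentiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models as M
from .task_design import DesignMatrix, Task, build_block_design

__all__ = [
    "ChoiceData",
    "CohortConfig",
    "DEFAULT_BLOCK_PLAN",
    "default_group_params",
    "simulate_subject",
    "simulate_cohort",
]

#: Default session: two blocks of each task, 240 trials in total.
DEFAULT_BLOCK_PLAN: tuple[tuple[str, int], ...] = (
    (Task.ROBBER.value, 1),
    (Task.ROBBER.value, 2),
    (Task.FACTORY.value, 1),
    (Task.FACTORY.value, 2),
)

# Generative group means on the unconstrained scale.  Temperatures use
# log(10 / 0.01): a median tau of 10 points against typical go/no-go value
# differences of a few tens of points yields value-driven but clearly
# stochastic choices; the remaining parameters are centred (mu0 = p = 0.5,
# sigma0_sq = 0.5, phi = 0) with unit spread.
_TAU_LOG_MEAN = float(np.log(10.0 / 0.01))
_GROUP_MEAN_BY_KIND = {"tau": _TAU_LOG_MEAN, "pos": 0.0, "unit": 0.0, "signed_unit": 0.0}


def default_group_params(model: "str | M.ModelSpec") -> tuple[np.ndarray, np.ndarray]:
    """Default generative (mean, sd) of the unconstrained group Gaussian."""
    spec = M.get_model(model)
    mean = np.array([_GROUP_MEAN_BY_KIND[kind] for _, kind in spec.params])
    return mean, np.ones(spec.n_params)


@dataclass
class ChoiceData:
    """Simulated or observed choices and outcomes for one subject.

    ``frame`` holds one row per trial with columns subject, task, block,
    trial, stimulus, offer, cost, success_prob, choice (0=ng, 1=go) and
    outcome (1=success, 0=loss, NaN on passive trials).  For simulated
    agents the generating model, its true parameters, and the per-trial
    generative P(go) are attached.
    """

    frame: pd.DataFrame
    subject: int = 1
    model: str | None = None
    true_params: M.ParameterSet | None = None
    p_go: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_trials(self) -> int:
        return len(self.frame)


def _iter_designs(designs) -> list[DesignMatrix]:
    if isinstance(designs, DesignMatrix):
        return [designs]
    return list(designs)


def simulate_subject(
    spec: "str | M.ModelSpec",
    params: "M.ParameterSet | np.ndarray",
    designs,
    seed: int,
    subject: int = 1,
    smoothing: str = "rectifier",
) -> ChoiceData:
    """Simulate one agent over one or more block designs.

    Joint models require designs from both tasks.  State (beliefs,
    win-stay/lose-shift flags) is reset at every (task, block) boundary.
    """
    spec = M.get_model(spec)
    if not isinstance(params, M.ParameterSet):
        params = M.transform_parameters(spec, np.asarray(params, dtype=float))
    design_list = _iter_designs(designs)
    tasks = {d.task for d in design_list}
    if spec.joint and tasks != {Task.ROBBER, Task.FACTORY}:
        raise ValueError("joint models need designs for both tasks")
    if not spec.joint and len(tasks) > 1:
        pass  # single-task models may still be evaluated across tasks

    c = params.constrained
    rng = np.random.default_rng(seed)

    rows = []
    p_go_trace = []
    for design in design_list:
        is_fac = design.task is Task.FACTORY
        if spec.joint:
            tau = c["tau_F"] if is_fac else c["tau_R"]
        else:
            tau = c["tau"]

        if spec.family == "bayes":
            if spec.joint and not spec.shared_prior:
                suffix = "_F" if is_fac else "_R"
                a0, b0 = M.beta_prior_from_moments(
                    c["mu0" + suffix], c["sigma0_sq" + suffix]
                )
            else:
                a0, b0 = M.beta_prior_from_moments(c["mu0"], c["sigma0_sq"])
            belief = M.BeliefState(alpha0=a0, beta0=b0)
        else:
            belief = None

        prev_success = prev_loss = False
        for t in design.trials:
            if spec.family in ("softmax_only", "wsls"):
                p_succ = 1.0
            elif spec.family == "static":
                p_succ = c["p"]
            else:
                key = "all" if spec.between_stim else t.stimulus_id
                p_succ = belief.posterior_mean(key)

            q_go, q_ng = M.trial_utilities(
                spec,
                design.task,
                t.offer,
                t.cost,
                params,
                p_success=None if spec.family in ("softmax_only", "wsls") else p_succ,
                prev_success=prev_success,
                prev_loss=prev_loss,
            )
            p_go = float(M.softmax_p_go(q_go, q_ng, tau))
            if spec.bias == "all":
                p_go = float(M.biased_choice_prob(c["phi"], p_go, smoothing=smoothing))
            elif spec.bias == "factory" and is_fac:
                p_go = float(M.biased_choice_prob(c["phi_F"], p_go, smoothing=smoothing))
            p_go = float(np.clip(p_go, M.PROB_FLOOR, 1 - M.PROB_FLOOR))

            go = rng.random() < p_go
            if go:
                success = rng.random() < t.success_prob
                outcome = 1.0 if success else 0.0
                prev_success, prev_loss = success, not success
                if belief is not None:
                    key = "all" if spec.between_stim else t.stimulus_id
                    belief = M.update_belief(
                        belief, key, "go", "success" if success else "loss"
                    )
            else:
                outcome = np.nan
                prev_success = prev_loss = False

            p_go_trace.append(p_go)
            rows.append(
                {
                    "subject": subject,
                    "task": design.task.value,
                    "block": design.block_id,
                    "trial": t.trial_index,
                    "stimulus": t.stimulus_id,
                    "offer": t.offer,
                    "cost": t.cost,
                    "success_prob": t.success_prob,
                    "choice": 1 if go else 0,
                    "outcome": outcome,
                }
            )

    return ChoiceData(
        frame=pd.DataFrame(rows),
        subject=subject,
        model=spec.name,
        true_params=params,
        p_go=np.array(p_go_trace),
    )


@dataclass
class CohortConfig:
    """Generative settings for a simulated cohort.

    ``group_params`` maps model name to (mean, sd) of the unconstrained
    group Gaussian; models missing from it fall back to
    :func:`default_group_params`.  ``mixture`` gives each model's
    population frequency (must sum to 1).
    """

    n_subjects: int
    mixture: dict[str, float]
    group_params: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    block_plan: tuple[tuple[str, int], ...] = DEFAULT_BLOCK_PLAN
    seed: int | None = None

    def __post_init__(self):
        if not self.mixture:
            raise ValueError("mixture must name at least one model")
        total = sum(self.mixture.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"mixture frequencies must sum to 1, got {total}")
        for name, (mean, sd) in self.group_params.items():
            if np.any(np.asarray(sd) < 0):
                raise ValueError(f"negative group SD for {name}")


def simulate_cohort(config: CohortConfig, seed: int | None = None) -> list[ChoiceData]:
    """Simulate a cohort; each subject gets fresh seeded designs.

    One child random stream per subject is spawned from the master seed,
    so results do not depend on iteration order.  Ground truth (model and
    parameters) rides on each returned :class:`ChoiceData`.
    """
    master = seed if seed is not None else config.seed
    if master is None:
        raise ValueError("a master seed is required")
    names = sorted(config.mixture)
    freqs = np.array([config.mixture[n] for n in names])

    ss = np.random.SeedSequence(master)
    children = ss.spawn(config.n_subjects)
    assign_rng = np.random.default_rng(ss.spawn(1)[0])

    cohort = []
    for i, child in enumerate(children, start=1):
        sub_rng = np.random.default_rng(child)
        model = names[assign_rng.choice(len(names), p=freqs)]
        spec = M.get_model(model)
        mean, sd = config.group_params.get(model, default_group_params(model))
        theta = np.asarray(mean, float) + np.asarray(sd, float) * sub_rng.standard_normal(
            spec.n_params
        )
        designs = [
            build_block_design(task, seed=int(sub_rng.integers(2**31)), block_id=block)
            for task, block in config.block_plan
        ]
        data = simulate_subject(
            spec, theta, designs, seed=int(sub_rng.integers(2**31)), subject=i
        )
        cohort.append(data)
    return cohort
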