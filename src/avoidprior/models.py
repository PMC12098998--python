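"""Cognitive choice models for the avoidance tasks, as pure likelihood evaluators.

Four base models share one softmax choice rule over the go/no-go value
difference and differ in how they value the active option:

* ``softmax_only`` - assumes success is certain (one parameter, the
  temperature tau).
* ``wsls`` - win-stay/lose-shift: certain success plus a bonus/malus on
  the active value driven by the outcome of the immediately preceding
  trial (stimulus-independent).
* ``static_prob`` - a single subjective success probability p applied to
  every stimulus, never updated.
* ``bayes`` - a beta-distributed prior over each stimulus's success
  probability, conjugately updated on every active outcome; passive
  trials leave beliefs untouched.

Augmentations: ``bayes_between_stim`` carries one posterior across
stimulus changes; ``*_bias`` adds a lapse parameter phi in (-1, 1) that
mixes a fixed action (phi > 0) or passivity (phi < 0) tendency into the
softmax probability; the joint two-task models (``joint_1prior``,
``joint_2prior``) fit both tasks at once with task-specific temperatures,
a factory-only bias, and either a shared or task-specific prior.

All parameters live in an unconstrained real space (where a Gaussian
prior applies during fitting) and are mapped to their native supports by
fixed bijections; see :func:`transform_parameters`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .task_design import Task

__all__ = [
    "ModelSpec",
    "ParameterSet",
    "BeliefState",
    "MODELS",
    "get_model",
    "transform_parameters",
    "inverse_transform_parameters",
    "softmax_p_go",
    "trial_utilities",
    "beta_prior_from_moments",
    "update_belief",
    "biased_choice_prob",
    "negative_log_likelihood",
    "TrialArrays",
    "prepare_trial_arrays",
    "predict_p_go",
    "SOFTPLUS_ALPHA",
    "PROB_FLOOR",
]

#: Sharpness of the SoftPlus surrogate for the rectified-linear lapse term.
SOFTPLUS_ALPHA = 100.0

#: Choice probabilities are clipped to [PROB_FLOOR, 1 - PROB_FLOOR] before
#: taking logs, so the likelihood stays finite under extreme parameters.
PROB_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# parameter transforms


def _logistic(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def _logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


# Saturation guard: in float arithmetic logistic(x) hits exactly 0 or 1
# around |x| > 37 and exp underflows/overflows for |x| > 700, values an
# optimiser's line search can legitimately probe.  Constrained values are
# kept strictly inside their open supports.
_UNIT_EPS = 1e-12


def _unit(x):
    return np.clip(_logistic(x), _UNIT_EPS, 1.0 - _UNIT_EPS)


def _pos(x):
    return np.clip(np.exp(np.minimum(np.asarray(x, float), 700.0)), 1e-300, None)


# unconstrained -> constrained and back; tau carries the 0.01 scaling that
# improves sampling of small temperatures.
_TRANSFORMS: dict[str, tuple[Callable, Callable]] = {
    "tau": (lambda x: 0.01 * _pos(x), lambda y: np.log(y / 0.01)),
    "pos": (_pos, np.log),
    "unit": (_unit, _logit),
    "signed_unit": (lambda x: 2.0 * _unit(x) - 1.0,
                    lambda y: _logit((y + 1.0) / 2.0)),
}


@dataclass(frozen=True)
class ModelSpec:
    """Structural description of one choice model.

    ``params`` maps parameter names to transform kinds (keys of the
    transform table); order is the order of the unconstrained vector.
    """

    name: str
    params: tuple[tuple[str, str], ...]
    family: str  # softmax_only | wsls | static | bayes
    between_stim: bool = False
    bias: str = "none"  # none | all | factory
    joint: bool = False
    shared_prior: bool = True

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.params)


MODELS: dict[str, ModelSpec] = {
    m.name: m
    for m in (
        ModelSpec("softmax_only", (("tau", "tau"),), "softmax_only"),
        ModelSpec(
            "wsls",
            (("tau", "tau"), ("gamma_plus", "pos"), ("gamma_minus", "pos")),
            "wsls",
        ),
        ModelSpec("static_prob", (("tau", "tau"), ("p", "unit")), "static"),
        ModelSpec(
            "bayes",
            (("tau", "tau"), ("mu0", "unit"), ("sigma0_sq", "unit")),
            "bayes",
        ),
        ModelSpec(
            "bayes_between_stim",
            (("tau", "tau"), ("mu0", "unit"), ("sigma0_sq", "unit")),
            "bayes",
            between_stim=True,
        ),
        ModelSpec(
            "static_prob_bias",
            (("tau", "tau"), ("p", "unit"), ("phi", "signed_unit")),
            "static",
            bias="all",
        ),
        ModelSpec(
            "bayes_bias",
            (
                ("tau", "tau"),
                ("mu0", "unit"),
                ("sigma0_sq", "unit"),
                ("phi", "signed_unit"),
            ),
            "bayes",
            bias="all",
        ),
        ModelSpec(
            "joint_1prior",
            (
                ("tau_R", "tau"),
                ("tau_F", "tau"),
                ("phi_F", "signed_unit"),
                ("mu0", "unit"),
                ("sigma0_sq", "unit"),
            ),
            "bayes",
            bias="factory",
            joint=True,
            shared_prior=True,
        ),
        ModelSpec(
            "joint_2prior",
            (
                ("tau_R", "tau"),
                ("tau_F", "tau"),
                ("phi_F", "signed_unit"),
                ("mu0_R", "unit"),
                ("sigma0_sq_R", "unit"),
                ("mu0_F", "unit"),
                ("sigma0_sq_F", "unit"),
            ),
            "bayes",
            bias="factory",
            joint=True,
            shared_prior=False,
        ),
    )
}


def get_model(name: "str | ModelSpec") -> ModelSpec:
    if isinstance(name, ModelSpec):
        return name
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(MODELS)}"
        ) from None


@dataclass(frozen=True)
class ParameterSet:
    """A point in parameter space, in both coordinate systems."""

    spec: ModelSpec
    unconstrained: np.ndarray
    constrained: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.constrained[name]


def transform_parameters(
    spec: "str | ModelSpec", unconstrained: np.ndarray
) -> ParameterSet:
    """Map an unconstrained vector to the model's native parameters.

    tau = 0.01*exp(theta); gamma = exp(theta); unit-interval parameters
    (p, mu0, sigma0_sq) = logistic(theta); phi = 2*logistic(theta) - 1.
    """
    spec = get_model(spec)
    theta = np.asarray(unconstrained, dtype=float)
    if theta.shape != (spec.n_params,):
        raise ValueError(
            f"{spec.name} expects {spec.n_params} parameters, got shape {theta.shape}"
        )
    constrained = {
        name: float(_TRANSFORMS[kind][0](theta[i]))
        for i, (name, kind) in enumerate(spec.params)
    }
    return ParameterSet(spec=spec, unconstrained=theta.copy(), constrained=constrained)


def inverse_transform_parameters(
    spec: "str | ModelSpec", constrained: Mapping[str, float]
) -> np.ndarray:
    """Inverse of :func:`transform_parameters`; round-trips to machine precision."""
    spec = get_model(spec)
    return np.array(
        [_TRANSFORMS[kind][1](constrained[name]) for name, kind in spec.params]
    )


# ---------------------------------------------------------------------------
# choice and utility primitives


def softmax_p_go(q_go, q_ng, tau):
    """P(go) = logistic((Q(go) - Q(ng)) / tau)."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    return _logistic((np.asarray(q_go, float) - np.asarray(q_ng, float)) / tau)


def trial_utilities(
    spec: "str | ModelSpec",
    task: "Task | str",
    offer: float,
    cost: float,
    params: "ParameterSet | Mapping[str, float]",
    p_success: float | None = None,
    prev_success: bool = False,
    prev_loss: bool = False,
) -> tuple[float, float]:
    """(Q(go), Q(ng)) for one trial.

    Robber frames the offer as a gain to keep (passive value 0); factory
    frames it as a loss to prevent (passive value -offer).  ``p_success``
    is the model's subjective success probability: ignored (treated as 1)
    by softmax_only and wsls, the static p for static models, and the
    current posterior mean for Bayesian models.
    """
    spec = get_model(spec)
    task = Task(task)
    if isinstance(params, ParameterSet):
        params = params.constrained

    if spec.family in ("softmax_only", "wsls"):
        bonus = 0.0
        if spec.family == "wsls":
            bonus = prev_success * params["gamma_plus"] - prev_loss * params["gamma_minus"]
        if task is Task.ROBBER:
            return (offer - cost) + bonus, 0.0
        return -cost + bonus, -offer

    if p_success is None:
        p_success = params.get("p", params.get("mu0"))
    if task is Task.ROBBER:
        return -cost + p_success * offer, 0.0
    return -cost - (1.0 - p_success) * offer, -offer


def beta_prior_from_moments(mu0: float, sigma0_sq: float) -> tuple[float, float]:
    """Beta(alpha0, beta0) from a mean and a *relative* variance.

    The relative variance is the beta variance divided by its upper bound
    mu0*(1 - mu0) at that mean, so both moments live in (0, 1):
    alpha0 = mu0*(1/sigma0_sq - 1), beta0 = (1 - mu0)*(1/sigma0_sq - 1).
    """
    if not 0.0 < mu0 < 1.0:
        raise ValueError("mu0 must be in (0, 1)")
    if not 0.0 < sigma0_sq < 1.0:
        raise ValueError("sigma0_sq must be in (0, 1)")
    nu = 1.0 / sigma0_sq - 1.0  # total pseudo-count alpha0 + beta0
    return mu0 * nu, (1.0 - mu0) * nu


@dataclass(frozen=True)
class BeliefState:
    """Per-stimulus beta posteriors over success probability."""

    alpha0: float
    beta0: float
    counts: Mapping[tuple, tuple[int, int]] = None  # key -> (successes, losses)

    def __post_init__(self):
        if self.counts is None:
            object.__setattr__(self, "counts", {})

    def posterior(self, key) -> tuple[float, float]:
        s, f = self.counts.get(key, (0, 0))
        return self.alpha0 + s, self.beta0 + f

    def posterior_mean(self, key) -> float:
        a, b = self.posterior(key)
        return a / (a + b)


def update_belief(
    state: BeliefState, stimulus, action: str, outcome: str | None
) -> BeliefState:
    """Conjugate update: go+success -> alpha+1, go+loss -> beta+1, ng -> unchanged."""
    if action == "ng":
        if outcome not in (None, "none"):
            raise ValueError("passive trials carry no outcome")
        return state
    if action != "go":
        raise ValueError(f"action must be 'go' or 'ng', got {action!r}")
    if outcome not in ("success", "loss"):
        raise ValueError("active trials must have outcome 'success' or 'loss'")
    s, f = state.counts.get(stimulus, (0, 0))
    if outcome == "success":
        s += 1
    else:
        f += 1
    counts = dict(state.counts)
    counts[stimulus] = (s, f)
    return BeliefState(alpha0=state.alpha0, beta0=state.beta0, counts=counts)


def _softplus(x, alpha):
    # log(1 + e^(alpha x)) / alpha, overflow-safe
    x = np.asarray(x, dtype=float)
    return (np.logaddexp(0.0, alpha * x)) / alpha


def biased_choice_prob(
    phi, p_softmax, smoothing: str = "rectifier", alpha: float = SOFTPLUS_ALPHA
):
    """Lapse-mixed choice probability [phi]_+ + (1 - |phi|) * p_softmax.

    ``smoothing='softplus'`` replaces the rectifier by
    log(1 + e^(alpha*phi))/alpha and |phi| by softplus(phi) +
    softplus(-phi), a differentiable surrogate within log(2)/alpha of the
    exact rule; the result is clipped into (0, 1).
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(np.abs(phi) > 1.0):
        raise ValueError("phi must lie in [-1, 1]")
    p = np.asarray(p_softmax, dtype=float)
    if smoothing == "rectifier":
        pos = np.maximum(phi, 0.0)
        absval = np.abs(phi)
    elif smoothing == "softplus":
        pos = _softplus(phi, alpha)
        absval = _softplus(phi, alpha) + _softplus(-phi, alpha)
    else:
        raise ValueError("smoothing must be 'rectifier' or 'softplus'")
    return np.clip(pos + (1.0 - absval) * p, PROB_FLOOR, 1.0 - PROB_FLOOR)


# ---------------------------------------------------------------------------
# vectorised likelihood over a full dataset


@dataclass(frozen=True)
class TrialArrays:
    """Trial history pre-compiled into flat arrays for fast likelihood loops.

    Belief trajectories under conjugate updating depend on the data only
    through the per-trial counts of earlier successes/failures, so those
    counts are computed once; the likelihood is then a pure vectorised
    function of the parameters.
    """

    offer: np.ndarray
    cost: np.ndarray
    go: np.ndarray  # 1 active, 0 passive
    is_factory: np.ndarray  # bool
    prev_success: np.ndarray  # previous trial in block was an active success
    prev_loss: np.ndarray
    succ_within: np.ndarray  # successes so far, same (task, block, stimulus)
    fail_within: np.ndarray
    succ_between: np.ndarray  # successes so far, same (task, block), any stimulus
    fail_between: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.offer.size


def _coerce_frame(data) -> pd.DataFrame:
    frame = getattr(data, "frame", data)
    if not isinstance(frame, pd.DataFrame):
        raise TypeError("data must be a ChoiceData or a DataFrame")
    return frame


def prepare_trial_arrays(data) -> TrialArrays:
    """Compile a trial table (subject-level) into :class:`TrialArrays`.

    Expects columns task, block, trial, stimulus, offer, cost, choice
    (0=ng, 1=go) and outcome (1=success, 0=loss, NaN on passive trials).
    Trials are ordered by (task, block, trial); state never crosses a
    (task, block) boundary.
    """
    df = _coerce_frame(data)
    if df.empty:
        raise ValueError("empty choice data")
    df = df.sort_values(["task", "block", "trial"], kind="stable")
    go = df["choice"].to_numpy(dtype=float)
    if not np.isin(go, [0.0, 1.0]).all():
        raise ValueError("choice must be coded 0 (passive) or 1 (active)")
    out = df["outcome"].to_numpy(dtype=float)
    if np.isnan(out[go == 1]).any() or (~np.isnan(out[go == 0])).any():
        raise ValueError("outcome must be present exactly on active trials")

    succ = ((go == 1) & (out == 1.0)).astype(float)
    fail = ((go == 1) & (out == 0.0)).astype(float)
    work = df[["task", "block", "stimulus"]].copy()
    work["succ"] = succ
    work["fail"] = fail

    def _hist(keys: list[str]) -> tuple[np.ndarray, np.ndarray]:
        g = work.groupby(keys, sort=False)
        s = (g["succ"].cumsum() - work["succ"]).to_numpy()
        f = (g["fail"].cumsum() - work["fail"]).to_numpy()
        return s, f

    s_w, f_w = _hist(["task", "block", "stimulus"])
    s_b, f_b = _hist(["task", "block"])

    blk = work.groupby(["task", "block"], sort=False)
    prev_s = blk["succ"].shift(1, fill_value=0.0).to_numpy()
    prev_f = blk["fail"].shift(1, fill_value=0.0).to_numpy()

    return TrialArrays(
        offer=df["offer"].to_numpy(dtype=float),
        cost=df["cost"].to_numpy(dtype=float),
        go=go,
        is_factory=(df["task"].astype(str).to_numpy() == Task.FACTORY.value),
        prev_success=prev_s,
        prev_loss=prev_f,
        succ_within=s_w,
        fail_within=f_w,
        succ_between=s_b,
        fail_between=f_b,
    )


def predict_p_go(
    spec: "str | ModelSpec",
    arrays: TrialArrays,
    params: ParameterSet,
    smoothing: str = "softplus",
) -> np.ndarray:
    """Per-trial P(go) conditional on the recorded history."""
    spec = get_model(spec)
    c = params.constrained
    fac = arrays.is_factory

    if spec.joint:
        if not fac.any() or fac.all():
            raise ValueError("joint models need trials from both tasks")
        tau = np.where(fac, c["tau_F"], c["tau_R"])
    else:
        tau = c["tau"]

    # subjective success probability entering the value of acting
    if spec.family in ("softmax_only", "wsls"):
        p_succ = 1.0
    elif spec.family == "static":
        p_succ = c["p"]
    else:
        s = arrays.succ_between if spec.between_stim else arrays.succ_within
        f = arrays.fail_between if spec.between_stim else arrays.fail_within
        if spec.joint and not spec.shared_prior:
            a0_r, b0_r = beta_prior_from_moments(c["mu0_R"], c["sigma0_sq_R"])
            a0_f, b0_f = beta_prior_from_moments(c["mu0_F"], c["sigma0_sq_F"])
            a0 = np.where(fac, a0_f, a0_r)
            b0 = np.where(fac, b0_f, b0_r)
        else:
            a0, b0 = beta_prior_from_moments(c["mu0"], c["sigma0_sq"])
        p_succ = (a0 + s) / (a0 + b0 + s + f)

    # the go-minus-ng value difference is p*offer - cost in both framings
    dq = p_succ * arrays.offer - arrays.cost
    if spec.family == "wsls":
        dq = dq + arrays.prev_success * c["gamma_plus"] - arrays.prev_loss * c["gamma_minus"]

    p_go = _logistic(dq / tau)

    if spec.bias == "all":
        p_go = biased_choice_prob(c["phi"], p_go, smoothing=smoothing)
    elif spec.bias == "factory":
        p_go = np.where(
            fac, biased_choice_prob(c["phi_F"], p_go, smoothing=smoothing), p_go
        )
    return np.clip(p_go, PROB_FLOOR, 1.0 - PROB_FLOOR)


def negative_log_likelihood(
    spec: "str | ModelSpec",
    data,
    unconstrained: np.ndarray,
    smoothing: str = "softplus",
) -> float:
    """-sum_t log P_t(chosen action) over a subject's trials."""
    spec = get_model(spec)
    theta = np.asarray(unconstrained, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("parameters must be finite")
    arrays = data if isinstance(data, TrialArrays) else prepare_trial_arrays(data)
    params = transform_parameters(spec, theta)
    p_go = predict_p_go(spec, arrays, params, smoothing=smoothing)
    ll = np.sum(np.where(arrays.go == 1, np.log(p_go), np.log1p(-p_go)))
    return float(-ll)
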