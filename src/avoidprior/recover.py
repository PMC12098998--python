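"""Model-recovery, parameter-recovery and power-simulation harnesses.

These close the loop on the modelling pipeline: simulate agents with
known ground truth, fit the candidate models, run random-effects model
selection, and summarise how reliably the generating model and its
parameters are identified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models as M
from .compare import rfx_bms
from .fit import fit_subject_map
from .simulate import (
    DEFAULT_BLOCK_PLAN,
    ChoiceData,
    CohortConfig,
    default_group_params,
    simulate_cohort,
)

__all__ = [
    "ModelRecoveryResult",
    "model_recovery",
    "parameter_recovery",
    "power_simulation",
    "evidence_matrix",
]


def evidence_matrix(
    cohort: "list[ChoiceData]",
    candidate_models,
    seed: int = 0,
    n_restarts: int = 10,
) -> np.ndarray:
    """Laplace log evidences, one row per subject and one column per model."""
    names = [M.get_model(m).name for m in candidate_models]
    out = np.empty((len(cohort), len(names)))
    for i, data in enumerate(cohort):
        arrays = M.prepare_trial_arrays(data)
        for k, name in enumerate(names):
            out[i, k] = fit_subject_map(
                name, arrays, seed=seed + i, n_restarts=n_restarts
            ).log_evidence
    return out


@dataclass
class ModelRecoveryResult:
    """Confusion matrices over generating and selected models."""

    candidate_models: tuple[str, ...]
    generating_models: tuple[str, ...]
    confusion_pxp: pd.DataFrame  # winners by protected exceedance probability
    confusion_freq: pd.DataFrame  # winners by estimated model frequency
    mean_pxp: pd.DataFrame  # mean PXP of each candidate per generating model
    n_repeats: int
    failures: int = 0


def model_recovery(
    candidate_models,
    n_repeats: int = 20,
    n_subjects: int = 50,
    generating_models=None,
    group_params: "dict | None" = None,
    block_plan=DEFAULT_BLOCK_PLAN,
    seed: int = 0,
    n_restarts: int = 4,
) -> ModelRecoveryResult:
    """Simulate cohorts from each generating model and record which
    candidate wins random-effects model selection.

    For every repeat and generating model, a cohort of ``n_subjects`` is
    simulated with group parameters drawn from that model's generative
    Gaussian, all candidates are fitted to every subject, and the winner
    by PXP (and by M.freq) is tallied.
    """
    candidates = tuple(M.get_model(m).name for m in candidate_models)
    if len(candidates) < 2:
        raise ValueError("need at least two candidate models")
    gens = (
        candidates
        if generating_models is None
        else tuple(M.get_model(m).name for m in generating_models)
    )

    conf_pxp = pd.DataFrame(0, index=list(gens), columns=list(candidates))
    conf_freq = conf_pxp.copy()
    pxp_sum = pd.DataFrame(0.0, index=list(gens), columns=list(candidates))
    failures = 0

    ss = np.random.SeedSequence(seed)
    for rep in range(n_repeats):
        for g in gens:
            child = ss.spawn(1)[0]
            s1, s2 = (int(x % 2**31) for x in child.generate_state(2))
            config = CohortConfig(
                n_subjects=n_subjects,
                mixture={g: 1.0},
                group_params=group_params or {},
                block_plan=tuple(block_plan),
            )
            try:
                cohort = simulate_cohort(config, seed=s1)
                L = evidence_matrix(cohort, candidates, seed=s2, n_restarts=n_restarts)
                res = rfx_bms(L, models=candidates, seed=s2)
            except Exception:  # propagated fit failure
                failures += 1
                continue
            conf_pxp.loc[g, res.models[int(np.argmax(res.protected_exceedance_prob))]] += 1
            conf_freq.loc[g, res.models[int(np.argmax(res.model_frequency))]] += 1
            pxp_sum.loc[g] += res.protected_exceedance_prob

    return ModelRecoveryResult(
        candidate_models=candidates,
        generating_models=gens,
        confusion_pxp=conf_pxp,
        confusion_freq=conf_freq,
        mean_pxp=pxp_sum / max(n_repeats, 1),
        n_repeats=n_repeats,
        failures=failures,
    )


def parameter_recovery(
    model,
    n_subjects: int = 100,
    block_plan=DEFAULT_BLOCK_PLAN,
    group_params: "tuple[np.ndarray, np.ndarray] | None" = None,
    seed: int = 0,
    n_restarts: int = 4,
) -> pd.DataFrame:
    """Simulate-and-refit recovery report for one model.

    Returns a table indexed by constrained parameter name with Pearson
    and Spearman correlations between true and recovered values, plus
    bias (recovered minus true) and RMSE.
    """
    from scipy import stats

    spec = M.get_model(model)
    mean, sd = group_params if group_params is not None else default_group_params(spec)
    config = CohortConfig(
        n_subjects=n_subjects,
        mixture={spec.name: 1.0},
        group_params={spec.name: (mean, sd)},
        block_plan=tuple(block_plan),
    )
    cohort = simulate_cohort(config, seed=seed)

    true = np.array([c.true_params.unconstrained for c in cohort])
    rec = np.empty_like(true)
    for i, data in enumerate(cohort):
        rec[i] = fit_subject_map(
            spec, data, seed=seed + i, n_restarts=n_restarts
        ).theta

    rows = []
    for j, name in enumerate(spec.param_names):
        kind = spec.params[j][1]
        fwd = {"tau": lambda x: 0.01 * np.exp(x), "pos": np.exp}.get(kind)
        if fwd is None:
            t = np.array(
                [M.transform_parameters(spec, v).constrained[name] for v in true]
            )
            r = np.array(
                [M.transform_parameters(spec, v).constrained[name] for v in rec]
            )
        else:
            t, r = fwd(true[:, j]), fwd(rec[:, j])
        rows.append(
            {
                "parameter": name,
                "pearson_r": float(stats.pearsonr(t, r)[0]),
                "spearman_r": float(stats.spearmanr(t, r)[0]),
                "bias": float(np.mean(r - t)),
                "rmse": float(np.sqrt(np.mean((r - t) ** 2))),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def power_simulation(
    model_frequencies: "dict[str, float]",
    candidate_models=None,
    n_grid=(20, 50),
    n_repeats: int = 10,
    group_params: "dict | None" = None,
    block_plan=DEFAULT_BLOCK_PLAN,
    seed: int = 0,
    pxp_threshold: float = 0.95,
    target_model: "str | None" = None,
    n_restarts: int = 4,
) -> pd.DataFrame:
    """Probability of a conclusive model selection as a function of sample size.

    Replicates, at configurable scale, the design of an a-priori power
    simulation: cohorts are drawn from the stated model mixture, the
    candidates are fitted and compared, and the fraction of repeats in
    which the target model's PXP exceeds ``pxp_threshold`` is reported
    per sample size.
    """
    if not model_frequencies:
        raise ValueError("empty model mixture")
    target = target_model or max(model_frequencies, key=model_frequencies.get)
    target = M.get_model(target).name
    candidates = tuple(
        M.get_model(m).name
        for m in (candidate_models if candidate_models is not None else model_frequencies)
    )

    ss = np.random.SeedSequence(seed)
    rows = []
    for n in n_grid:
        hits = []
        for rep in range(n_repeats):
            child = ss.spawn(1)[0]
            s1, s2 = (int(x % 2**31) for x in child.generate_state(2))
            config = CohortConfig(
                n_subjects=int(n),
                mixture=dict(model_frequencies),
                group_params=group_params or {},
                block_plan=tuple(block_plan),
            )
            cohort = simulate_cohort(config, seed=s1)
            L = evidence_matrix(cohort, candidates, seed=s2, n_restarts=n_restarts)
            res = rfx_bms(L, models=candidates, seed=s2)
            k = res.models.index(target)
            hits.append(float(res.protected_exceedance_prob[k] > pxp_threshold))
        rows.append(
            {"n_subjects": int(n), "power": float(np.mean(hits)), "n_repeats": n_repeats}
        )
    return pd.DataFrame(rows)
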