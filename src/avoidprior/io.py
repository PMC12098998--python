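"""CSV/JSON plumbing: designs, choice data, and fit results on disk.

One flat CSV dialect is used throughout: comma-separated, UTF-8, ``NA``
for missing values, with a leading ``#`` provenance comment carrying the
package version and the seed that produced the file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fit import SubjectFit
from .simulate import ChoiceData
from .task_design import DesignMatrix

__all__ = [
    "write_design",
    "write_choice_data",
    "read_choice_data",
    "write_fits",
    "read_fits",
]

CHOICE_COLUMNS = [
    "subject",
    "task",
    "block",
    "trial",
    "stimulus",
    "offer",
    "cost",
    "success_prob",
    "choice",
    "outcome",
]


def _provenance(seed) -> str:
    return f"# avoidprior v{__version__} seed={seed}\n"


def write_design(design: DesignMatrix, path, subject: int = 1) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance(design.seed))
        design.to_frame(subject=subject).to_csv(fh, index=False, na_rep="NA")


def write_choice_data(cohort, path, seed=None) -> None:
    """Write one or many subjects' trials to a single CSV."""
    if isinstance(cohort, ChoiceData):
        cohort = [cohort]
    frame = pd.concat([c.frame for c in cohort], ignore_index=True)
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance(seed))
        frame[CHOICE_COLUMNS].to_csv(fh, index=False, na_rep="NA")


def write_truth(cohort: "list[ChoiceData]", path, seed=None) -> None:
    """Ground-truth sidecar for a simulated cohort (model + parameters)."""
    rows = []
    for c in cohort:
        row = {"subject": c.subject, "model": c.model}
        if c.true_params is not None:
            for name, val in c.true_params.constrained.items():
                row[name] = val
            for i, th in enumerate(c.true_params.unconstrained):
                row[f"theta_{i}"] = th
        rows.append(row)
    with open(Path(path), "w", encoding="utf-8") as fh:
        fh.write(_provenance(seed))
        pd.DataFrame(rows).to_csv(fh, index=False, na_rep="NA")


def read_choice_data(path) -> list[ChoiceData]:
    """Read a choice-data CSV back into per-subject :class:`ChoiceData`.

    Validates the coding conventions row by row: choices are 0/1,
    success probabilities lie in (0, 1), and an outcome is present
    exactly when the choice was active.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", na_values=["NA"])
    if df.empty:
        import warnings

        warnings.warn(f"{path} contains no trials", stacklevel=2)
        return []
    missing = [c for c in CHOICE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    # row numbers as the user sees them: header is line 2 after the comment
    rownum = df.index + 3

    bad = ~df["choice"].isin([0, 1])
    if bad.any():
        raise ValueError(
            f"{path}: choice must be 0 or 1 (rows {list(rownum[bad][:5])})"
        )
    bad = (df["success_prob"] <= 0) | (df["success_prob"] >= 1)
    if bad.any():
        raise ValueError(
            f"{path}: success_prob outside (0, 1) (rows {list(rownum[bad][:5])})"
        )
    passive_with_outcome = (df["choice"] == 0) & df["outcome"].notna()
    if passive_with_outcome.any():
        raise ValueError(
            f"{path}: outcome recorded on passive trials "
            f"(rows {list(rownum[passive_with_outcome][:5])})"
        )
    active_without = (df["choice"] == 1) & df["outcome"].isna()
    if active_without.any():
        raise ValueError(
            f"{path}: active trials lack an outcome "
            f"(rows {list(rownum[active_without][:5])})"
        )

    return [
        ChoiceData(frame=g.reset_index(drop=True), subject=int(subj))
        for subj, g in df.groupby("subject", sort=True)
    ]


def _fit_to_dict(f: SubjectFit) -> dict:
    return {
        "model": f.model,
        "theta": list(map(float, f.theta)),
        "params": {k: float(v) for k, v in f.params.items()},
        "hessian": np.asarray(f.hessian).tolist(),
        "log_evidence": f.log_evidence,
        "log_lik": f.log_lik,
        "pseudo_r2": f.pseudo_r2,
        "n_trials": f.n_trials,
        "grad_norm": f.grad_norm,
        "restarts_used": f.restarts_used,
        "converged": f.converged,
    }


def write_fits(fits: "dict[str, list[SubjectFit]]", path, seed=None) -> None:
    """JSON dump of per-model, per-subject fits."""
    payload = {
        "package": f"avoidprior v{__version__}",
        "seed": seed,
        "fits": {name: [_fit_to_dict(f) for f in fs] for name, fs in fits.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_fits(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
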