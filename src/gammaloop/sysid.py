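"""Least-squares identification of the ARX gamma-power plant.

The one-step linear-prediction problem is assembled as an overdetermined
system C v ~ d whose rows hold p lagged power samples plus the two exogenous
regressors (the constant u_DC and the step u_s), and solved by orthogonal
decomposition.  Quality metrics are the mean-squared one-step prediction
error eps_pred = ||Cv*-d||^2 / N and the normalized fit percentage
100 (1 - ||Cv*-d|| / ||d - mean(d)||).  The module also provides the order
sweep, leave-one-trial-out cross-validation, per-trial model averaging, and
the persistency-of-excitation limit matrices for step inputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from .arx import ARXModel, GammaPowerSeries, StepStimulus
from .errors import (
    InsufficientDataError,
    InvalidInputError,
    NonUniqueSolutionError,
    UnstableCompositeError,
)

CONDITION_WARN_THRESHOLD = 1e8


@dataclass
class DesignSystem:
    """Regression system C v ~ d for one gamma-power record.

    Column layout: [x(t-1) ... x(t-p), u_DC, u_s(t)], one row per target
    sample d_t = x(t), t = p .. N-1 (0-based).  ``n_total`` is the record
    length N used to normalize eps_pred.
    """

    C: np.ndarray
    d: np.ndarray
    p: int
    n_total: int

    @property
    def column_labels(self) -> list:
        return [f"x(t-{k})" for k in range(1, self.p + 1)] + ["u_dc", "u_s"]


@dataclass
class IdentificationReport:
    model: ARXModel
    eps_pred: float
    fit_perc: float
    condition_number: float
    n_samples_used: int

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "model": json.loads(self.model.to_json()),
            "eps_pred": self.eps_pred,
            "fit_perc": self.fit_perc,
            "condition_number": self.condition_number,
            "n_samples_used": self.n_samples_used,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _series_values(x) -> np.ndarray:
    return x.values if isinstance(x, GammaPowerSeries) else np.asarray(x, float)


def build_design_system(
    x: GammaPowerSeries | np.ndarray,
    p: int,
    u_dc: float,
    stim: StepStimulus | np.ndarray,
) -> DesignSystem:
    """Assemble the linear-prediction design matrix and target vector."""
    xv = _series_values(x)
    n = xv.size
    if p < 1:
        raise InvalidInputError("model order p must be >= 1")
    if n <= p + 2:
        raise InsufficientDataError(
            f"need more than p+2 = {p + 2} samples, got {n}"
        )
    u_s = stim.values if isinstance(stim, StepStimulus) else np.asarray(stim, float)
    if u_s.size != n:
        raise InvalidInputError("stimulus length must match series length")
    lags = [xv[p - 1 - k: n - 1 - k] for k in range(p)]
    C = np.column_stack(lags + [np.full(n - p, float(u_dc)), u_s[p:]])
    d = xv[p:]
    return DesignSystem(C=C, d=d, p=p, n_total=n)


def _rank_deficient_columns(C: np.ndarray, rank: int) -> np.ndarray:
    """Pivoted-QR heuristic: the columns whose pivots fall past the rank."""
    _, _, piv = linalg.qr(C, mode="economic", pivoting=True)
    return np.sort(piv[rank:])


def fit_arx(design: DesignSystem) -> IdentificationReport:
    """Solve the least-squares prediction problem by orthogonal decomposition.

    The regression coefficients on the lagged outputs are the negated AR
    coefficients of A(z), so the returned model is in the package's
    x(t) = -sum a_k x(t-k) + ... convention.  The residual mean square is
    used as the model's driving-noise variance estimate.
    """
    C, d = design.C, design.d
    ncols = design.p + 2
    s = np.linalg.svd(C, compute_uv=False)
    tol = np.finfo(float).eps * max(C.shape) * s[0]
    rank = int(np.sum(s > tol))
    if rank < ncols:
        bad = _rank_deficient_columns(C, rank)
        labels = [design.column_labels[i] for i in bad]
        raise NonUniqueSolutionError(
            f"design matrix is rank deficient (rank {rank} < {ncols}); "
            f"offending columns: {labels}"
        )
    cond = float(s[0] / s[-1])
    if cond > CONDITION_WARN_THRESHOLD:
        warnings.warn(
            f"design matrix condition number {cond:.3e} exceeds "
            f"{CONDITION_WARN_THRESHOLD:.0e}; estimates may be inaccurate",
            RuntimeWarning,
            stacklevel=2,
        )
    v, _, _, _ = linalg.lstsq(C, d, lapack_driver="gelsy")
    e = C @ v - d
    eps_pred = float(e @ e) / design.n_total
    denom = float(np.linalg.norm(d - d.mean()))
    fit_perc = 100.0 * (1.0 - float(np.linalg.norm(e)) / denom) if denom > 0 else (
        100.0 if np.allclose(e, 0) else -np.inf
    )
    model = ARXModel(
        a=tuple(-v[: design.p]),
        b_dc=float(v[design.p]),
        b_s=float(v[design.p + 1]),
        noise_variance=eps_pred,
    )
    return IdentificationReport(
        model=model,
        eps_pred=eps_pred,
        fit_perc=fit_perc,
        condition_number=cond,
        n_samples_used=design.n_total,
    )


def evaluate_fit(model: ARXModel, design: DesignSystem) -> tuple:
    """(eps_pred, fit_perc) of an already-fitted model on a (held-out)
    design system."""
    v = np.concatenate([-np.asarray(model.a), [model.b_dc, model.b_s]])
    e = design.C @ v - design.d
    eps = float(e @ e) / design.n_total
    denom = float(np.linalg.norm(design.d - design.d.mean()))
    fit = 100.0 * (1.0 - float(np.linalg.norm(e)) / denom)
    return eps, fit


def order_sweep(
    x: GammaPowerSeries | np.ndarray,
    p_range,
    u_dc: float,
    stim: StepStimulus | np.ndarray,
) -> pd.DataFrame:
    """Fit every order in ``p_range`` and tabulate the quality metrics."""
    rows = []
    for p in p_range:
        rep = fit_arx(build_design_system(x, int(p), u_dc, stim))
        rows.append({"p": int(p), "eps_pred": rep.eps_pred,
                     "fit_perc": rep.fit_perc})
    return pd.DataFrame(rows)


def fit_trials(
    trials: np.ndarray,
    p: int,
    u_dc: float,
    stim: StepStimulus | np.ndarray,
) -> list:
    """Per-trial fits (one IdentificationReport per row of ``trials``)."""
    return [fit_arx(build_design_system(tr, p, u_dc, stim)) for tr in trials]


def kfold_cv(
    trials: np.ndarray,
    p: int,
    u_dc: float,
    stim: StepStimulus | np.ndarray,
) -> tuple:
    """Leave-one-trial-out cross-validation.

    For each held-out trial the model is fitted on the remaining trials'
    stacked design systems (folds never split a trial) and its fit
    percentage evaluated on the held-out trial.  Returns the averaged
    (train_fit_perc, test_fit_perc).
    """
    trials = np.atleast_2d(np.asarray(trials, float))
    k = trials.shape[0]
    if k < 2:
        raise InvalidInputError("cross-validation needs at least 2 trials")
    designs = [build_design_system(tr, p, u_dc, stim) for tr in trials]
    train_scores, test_scores = [], []
    for hold in range(k):
        keep = [i for i in range(k) if i != hold]
        C = np.vstack([designs[i].C for i in keep])
        d = np.concatenate([designs[i].d for i in keep])
        pooled = DesignSystem(C=C, d=d, p=p,
                              n_total=sum(designs[i].n_total for i in keep))
        rep = fit_arx(pooled)
        train_scores.append(rep.fit_perc)
        _, test_fit = evaluate_fit(rep.model, designs[hold])
        test_scores.append(test_fit)
    return float(np.mean(train_scores)), float(np.mean(test_scores))


def average_models(models, stability_tol: float = 1e-6) -> ARXModel:
    """Element-wise mean of per-trial ARX fits (the composite model).

    Averaging stable polynomials does not guarantee a stable mean; the
    composite's spectral radius is re-checked and an error raised rather
    than silently returning an unusable plant.
    """
    models = list(models)
    if not models:
        raise InvalidInputError("no models to average")
    p = models[0].order
    dt = models[0].sampling_interval
    if any(m.order != p or m.sampling_interval != dt for m in models):
        raise InvalidInputError("models must share order and sampling interval")
    mean = ARXModel(
        a=tuple(np.mean([m.a for m in models], axis=0)),
        b_dc=float(np.mean([m.b_dc for m in models])),
        b_s=float(np.mean([m.b_s for m in models])),
        noise_variance=float(np.mean([m.noise_variance for m in models])),
        sampling_interval=dt,
    )
    if mean.spectral_radius > 1.0 + stability_tol:
        raise UnstableCompositeError(
            f"averaged polynomial is unstable (spectral radius "
            f"{mean.spectral_radius:.6f})"
        )
    return mean


@dataclass
class ExcitationDiagnostics:
    """Persistency-of-excitation check for the exogenous regressor block."""

    finite_matrix: np.ndarray
    limit_matrix: np.ndarray
    consistent: bool


def excitation_diagnostics(
    u_dc: float,
    stim: StepStimulus,
    q: int,
    n: int,
) -> ExcitationDiagnostics:
    """(1/N) C_exo^T C_exo for the [u_DC, u_s(t), ..., u_s(t-q+1)] block and
    its N -> infinity limit for a midpoint-onset step.

    A step is persistently exciting of order 1: the limit is nonsingular
    only for q = 1, so ARX models with more than one stimulus lag cannot be
    identified consistently from step experiments.
    """
    if q < 1:
        raise InvalidInputError("q must be >= 1")
    if n < q + 1:
        raise InvalidInputError("n must be at least q+1")
    u = stim.values[:n] if stim.n_samples >= n else np.concatenate(
        [stim.values, np.full(n - stim.n_samples, stim.amplitude)]
    )
    rows = n - q
    cols = [np.full(rows, float(u_dc))]
    for lag in range(q):
        cols.append(u[q - lag: n - lag])
    C = np.column_stack(cols)
    finite = (C.T @ C) / n
    amp = stim.amplitude
    limit = np.empty((q + 1, q + 1))
    limit[0, 0] = u_dc**2
    limit[0, 1:] = limit[1:, 0] = u_dc * amp / 2.0
    limit[1:, 1:] = amp**2 / 2.0
    s = np.linalg.svd(limit, compute_uv=False)
    tol = np.finfo(float).eps * (q + 1) * (s[0] if s[0] > 0 else 1.0)
    consistent = bool(np.sum(s > tol) == q + 1)
    return ExcitationDiagnostics(finite_matrix=finite, limit_matrix=limit,
                                 consistent=consistent)
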