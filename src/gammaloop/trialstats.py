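"""Ensemble statistics on gamma-power trials.

Covers the pre/post stimulation comparison (one-sided t-tests per trial and
on the ensemble average, plus the normalized power increase delta-gamma%),
and averaged-periodogram spectral estimation for comparison against the
plant's theoretical PSD.

Caveat reproduced deliberately: samples within a window are serially
correlated (the plant is autoregressive), which inflates the nominal t
statistics.  The procedure mirrors the standard per-trial window test as
practiced; interpret per-trial p-values accordingly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal, stats

from .arx import GammaPowerSeries
from .errors import DegenerateTestError, InvalidInputError


@dataclass
class TrialEnsemble:
    """k x N matrix of RMS gamma-power trials on a shared time base with
    stimulation onset at t = 0."""

    t: np.ndarray
    trials: np.ndarray
    onset_time: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=float))
        if self.trials.shape[1] != self.t.size:
            raise InvalidInputError("trials and time base disagree in length")
        if self.trials.shape[0] < 1:
            raise InvalidInputError("need at least one trial")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])

    def pre_mask(self) -> np.ndarray:
        return self.t < self.onset_time

    def post_mask(self) -> np.ndarray:
        return self.t >= self.onset_time


@dataclass
class StimComparison:
    per_trial_p: np.ndarray
    pct_trials_significant: float
    ensemble_p: float
    delta_gamma_pct: float
    alpha: float

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "per_trial_p": list(map(float, self.per_trial_p)),
            "pct_trials_significant": self.pct_trials_significant,
            "ensemble_p": self.ensemble_p,
            "delta_gamma_pct": self.delta_gamma_pct,
            "alpha": self.alpha,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def ensemble_average(ens: TrialEnsemble) -> GammaPowerSeries:
    """Pointwise mean trace over trials."""
    return GammaPowerSeries(t=ens.t, values=ens.trials.mean(axis=0))


def delta_gamma_pct(pre_mean: float, post_mean: float) -> float:
    """Normalized mean power increase (x_s - x_ns)/x_ns * 100."""
    if pre_mean == 0:
        raise InvalidInputError("pre-stimulation mean is zero")
    return 100.0 * (post_mean - pre_mean) / pre_mean


def pre_post_comparison(
    ens: TrialEnsemble,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> StimComparison:
    """One-sided two-sample t-tests of post- vs pre-onset window means.

    Per trial, tests H1: post mean > pre mean (Welch by default); the same
    test is applied to the ensemble-average trace, and delta-gamma% is the
    normalized increase of the ensemble-average window means.
    """
    pre = ens.trials[:, ens.pre_mask()]
    post = ens.trials[:, ens.post_mask()]
    if pre.shape[1] == 0 or post.shape[1] == 0:
        raise InvalidInputError("both pre- and post-onset windows must be nonempty")
    if np.all(pre.std(axis=1) == 0) and np.all(post.std(axis=1) == 0):
        raise DegenerateTestError("zero-variance windows in every trial")
    res = stats.ttest_ind(post, pre, axis=1, equal_var=equal_var,
                          alternative="greater")
    per_trial_p = np.asarray(res.pvalue)
    avg = ensemble_average(ens)
    pre_avg = avg.values[ens.pre_mask()]
    post_avg = avg.values[ens.post_mask()]
    ens_res = stats.ttest_ind(post_avg, pre_avg, equal_var=equal_var,
                              alternative="greater")
    return StimComparison(
        per_trial_p=per_trial_p,
        pct_trials_significant=100.0 * float(np.mean(per_trial_p < alpha)),
        ensemble_p=float(ens_res.pvalue),
        delta_gamma_pct=delta_gamma_pct(float(pre_avg.mean()),
                                        float(post_avg.mean())),
        alpha=alpha,
    )


def averaged_periodogram(
    ens: TrialEnsemble,
    window_len: int = 2000,
) -> tuple:
    """Hann-tapered periodogram per trial, averaged across trials.

    Normalization: white noise of variance sigma^2 yields a flat estimate at
    sigma^2 (the two-sided per-sample density multiplied by the sampling
    rate), matching the plant's theoretical-PSD convention.  One
    non-overlapping window per trial segment; per-segment mean removed
    before tapering.  Returns (freqs_hz, psd_estimate) for f > 0.
    """
    k, n = ens.trials.shape
    if n < window_len:
        raise InvalidInputError(
            f"trials of length {n} are shorter than the {window_len}-sample window"
        )
    fs = ens.sampling_rate
    psds = []
    for row in ens.trials:
        for start in range(0, n - window_len + 1, window_len):
            seg = row[start:start + window_len]
            f, pxx = signal.periodogram(seg, fs=fs, window="hann",
                                        detrend="constant",
                                        return_onesided=False)
            keep = f > 0
            psds.append(pxx[keep] * fs)
    f = f[keep]
    order = np.argsort(f)
    return f[order], np.mean(psds, axis=0)[order]
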