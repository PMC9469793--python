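"""ARX plant model of instantaneous RMS gamma power.

The plant is the scalar autoregressive-with-exogenous-input recursion

    x(t) = -sum_k a_k x(t-k) + b_DC * u_DC + b_s * u_s(t) + w(t)

where ``x`` is instantaneous RMS gamma power (uV), ``u_DC`` a constant
current (mA) setting the no-stimulation mean, ``u_s`` the stimulation
amplitude (mA) and ``w`` zero-mean Gaussian driving noise.  The module
provides simulation, the Final-Value-Theorem steady state, the model's
theoretical power spectral density, the companion-form state-space
realization and its controllability diagnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal

from .errors import (
    InvalidInputError,
    SingularFrequencyError,
    SingularModelError,
    StabilityError,
)

#: Spectral radii up to 1 + MARGINAL_TOL are treated as simulable.  Empirical
#: gamma-power plants sit extremely close to the unit circle (integrated
#: power drifts), and coefficient rounding can push a pole onto it exactly.
MARGINAL_TOL = 1e-9

#: |1 + sum(a)| below this is treated as a singular DC denominator.
DC_SINGULAR_TOL = 1e-9


@dataclass(frozen=True)
class StepStimulus:
    """Stimulation amplitude as a step: zero, then ``amplitude`` mA.

    With 0-based sample indexing the amplitude turns on at
    ``onset_index`` (default N/2), mirroring a midpoint-onset protocol.
    """

    n_samples: int
    amplitude: float = 2.0
    onset_index: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise InvalidInputError("n_samples must be positive")
        if self.amplitude < 0:
            raise InvalidInputError("stimulus amplitude must be nonnegative")
        if self.onset_index is None:
            if self.n_samples % 2:
                raise InvalidInputError(
                    "n_samples must be even for a midpoint-onset step"
                )
            object.__setattr__(self, "onset_index", self.n_samples // 2)

    @property
    def values(self) -> np.ndarray:
        u = np.zeros(self.n_samples)
        u[self.onset_index:] = self.amplitude
        return u


@dataclass
class GammaPowerSeries:
    """Uniformly sampled instantaneous RMS gamma power (uV)."""

    t: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape:
            raise InvalidInputError("t and values must have identical shape")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.ptp(dt) > 1e-9:
                raise InvalidInputError("time stamps must be uniformly spaced")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size >= 2 else float("nan")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ARXModel:
    """ARX gamma-power plant (see module docstring for the sign convention).

    ``a`` holds a_1..a_p of the polynomial A(z) = 1 + sum a_k z^-k; the
    recursion multiplies past outputs by -a_k.  ``b_dc`` and ``b_s`` are
    uV/mA input gains, ``noise_variance`` is in uV^2.
    """

    a: tuple
    b_dc: float
    b_s: float
    noise_variance: float
    sampling_interval: float = 0.002

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", tuple(float(v) for v in np.atleast_1d(self.a)))
        if self.noise_variance < 0:
            raise InvalidInputError("noise_variance must be nonnegative")
        if self.sampling_interval <= 0:
            raise InvalidInputError("sampling_interval must be positive")

    @property
    def order(self) -> int:
        return len(self.a)

    @property
    def a_poly(self) -> np.ndarray:
        """Coefficients [1, a_1, ..., a_p] of A(z) in descending powers of z."""
        return np.concatenate(([1.0], self.a))

    @property
    def poles(self) -> np.ndarray:
        return np.roots(self.a_poly)

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(self.poles))) if self.order else 0.0

    @property
    def is_stable(self) -> bool:
        """Strict stability: every pole inside the unit circle."""
        return self.spectral_radius < 1.0

    @property
    def is_marginally_stable(self) -> bool:
        """Simulable: no pole more than MARGINAL_TOL outside the unit circle."""
        return self.spectral_radius <= 1.0 + MARGINAL_TOL

    @property
    def dc_denominator(self) -> float:
        return float(1.0 + np.sum(self.a))

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.sampling_interval

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "order": self.order,
            "a": list(self.a),
            "b_dc": self.b_dc,
            "b_s": self.b_s,
            "noise_variance": self.noise_variance,
            "sampling_interval": self.sampling_interval,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ARXModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        doc = json.loads(text)
        model = cls(
            a=doc["a"],
            b_dc=doc["b_dc"],
            b_s=doc["b_s"],
            noise_variance=doc["noise_variance"],
            sampling_interval=doc.get("sampling_interval", 0.002),
        )
        if model.order != doc.get("order", model.order):
            raise InvalidInputError("JSON 'order' disagrees with len(a)")
        return model

    def with_noise(self, noise_variance: float) -> "ARXModel":
        return replace(self, noise_variance=noise_variance)


@dataclass(frozen=True)
class StateSpaceModel:
    """Companion-form realization of an ARXModel.

    x_{t+1} = A x_t + B [u_DC, u_s]^T + G w(t),   y = C x_t + v(t)
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: float
    G: np.ndarray
    noise_variance: float

    @property
    def order(self) -> int:
        return self.A.shape[0]

    @property
    def b_s_column(self) -> np.ndarray:
        return self.B[:, [1]]

    @property
    def b_dc_column(self) -> np.ndarray:
        return self.B[:, [0]]


def _drive(model: ARXModel, u_dc: float, stim: StepStimulus | np.ndarray,
           n_samples: int) -> np.ndarray:
    u_s = stim.values if isinstance(stim, StepStimulus) else np.asarray(stim, float)
    if u_s.size != n_samples:
        raise InvalidInputError(
            f"stimulus length {u_s.size} != n_samples {n_samples}"
        )
    return model.b_dc * u_dc + model.b_s * u_s


def initial_state_level(model: ARXModel, u_dc: float) -> float:
    """Pre-stimulation start level: the deterministic no-stimulation steady
    state when the DC gain is well defined, zero for (near-)unit-root plants
    where no finite steady state exists."""
    denom = model.dc_denominator
    if model.is_stable and abs(denom) > DC_SINGULAR_TOL:
        return model.b_dc * u_dc / denom
    return 0.0


def simulate_arx(
    model: ARXModel,
    u_dc: float,
    stim: StepStimulus | np.ndarray,
    seed: int | np.random.SeedSequence | np.random.Generator,
    n_samples: int | None = None,
) -> GammaPowerSeries:
    """Simulate the ARX recursion driven by a step stimulus plus white noise.

    Time stamps place t = 0 at the stimulus onset.  Equivalent to filtering
    the total drive b_DC*u_DC + b_s*u_s(t) + w(t) through 1/A(z); implemented
    with a direct-form IIR filter for speed and initialized at the
    no-stimulation steady state (zero for marginal plants).
    """
    if isinstance(stim, StepStimulus):
        if n_samples is None:
            n_samples = stim.n_samples
        onset = stim.onset_index
    else:
        stim = np.asarray(stim, float)
        if n_samples is None:
            n_samples = stim.size
        nz = np.nonzero(stim)[0]
        onset = int(nz[0]) if nz.size else n_samples // 2
    if n_samples < model.order:
        raise InvalidInputError("n_samples must be at least the model order")
    if not model.is_marginally_stable:
        raise StabilityError(
            f"plant spectral radius {model.spectral_radius:.6f} > 1; refusing to simulate"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = rng.normal(0.0, np.sqrt(model.noise_variance), n_samples)
    return simulate_arx_given_noise(model, u_dc, stim, w, onset=onset)


def simulate_arx_given_noise(
    model: ARXModel,
    u_dc: float,
    stim: StepStimulus | np.ndarray,
    w: np.ndarray,
    onset: int | None = None,
) -> GammaPowerSeries:
    """Deterministic core of :func:`simulate_arx` for a given noise sequence."""
    w = np.asarray(w, dtype=float)
    n_samples = w.size
    if isinstance(stim, StepStimulus) and onset is None:
        onset = stim.onset_index
    if onset is None:
        onset = n_samples // 2
    if not model.is_marginally_stable:
        raise StabilityError(
            f"plant spectral radius {model.spectral_radius:.6f} > 1; refusing to simulate"
        )
    drive = _drive(model, u_dc, stim, n_samples) + w
    x0 = initial_state_level(model, u_dc)
    zi = signal.lfiltic([1.0], model.a_poly, np.full(model.order, x0))
    x, _ = signal.lfilter([1.0], model.a_poly, drive, zi=zi)
    t = (np.arange(n_samples) - onset) * model.sampling_interval
    return GammaPowerSeries(t=t, values=x, meta={"u_dc": u_dc, "onset_index": onset})


def steady_state_gamma(model: ARXModel, u_dc: float, u_s: float) -> float:
    """Final-Value-Theorem mean gamma power for constant inputs:
    (b_DC u_DC + b_s u_s) / (1 + sum a_k)."""
    denom = model.dc_denominator
    if abs(denom) <= DC_SINGULAR_TOL:
        raise SingularModelError(
            "1 + sum(a) is numerically zero; no finite steady state"
        )
    return (model.b_dc * u_dc + model.b_s * u_s) / denom


def theoretical_psd(model: ARXModel, freqs_hz: np.ndarray) -> np.ndarray:
    """Model PSD  P(f) = (sigma_w^2 + 4 b_s^2/omega^2) / |A(e^{j omega})|^2
    with omega = 2 pi f / Fs, in the convention where unit-variance white
    noise has a flat PSD of 1 (two-sided density times Fs)."""
    f = np.asarray(freqs_hz, dtype=float)
    fs = model.sampling_rate
    if np.any(f <= 0):
        raise SingularFrequencyError("frequencies must be positive (step term diverges at DC)")
    if np.any(f > fs / 2 + 1e-12):
        raise InvalidInputError("frequencies must not exceed Nyquist")
    omega = 2.0 * np.pi * f / fs
    k = np.arange(1, model.order + 1)
    A = 1.0 + np.exp(-1j * np.outer(omega, k)) @ np.asarray(model.a)
    num = model.noise_variance + 4.0 * model.b_s**2 / omega**2
    return num / np.abs(A) ** 2


def to_state_space(model: ARXModel) -> StateSpaceModel:
    """Companion-form state-space realization.

    First row of A is -a; B routes [u_DC, u_s] through [b_dc, b_s] into the
    first state; C reads the first state; G injects w(t) there."""
    p = model.order
    A = np.zeros((p, p))
    A[0, :] = -np.asarray(model.a)
    if p > 1:
        A[1:, :-1] = np.eye(p - 1)
    B = np.zeros((p, 2))
    B[0, 0] = model.b_dc
    B[0, 1] = model.b_s
    C = np.zeros((1, p))
    C[0, 0] = 1.0
    G = np.zeros((p, 1))
    G[0, 0] = 1.0
    return StateSpaceModel(A=A, B=B, C=C, D=0.0, G=G,
                           noise_variance=model.noise_variance)


def simulate_state_space(
    ss: StateSpaceModel,
    u_dc: float,
    u_s: np.ndarray,
    w: np.ndarray,
    x0: float = 0.0,
) -> np.ndarray:
    """Run the state-space recursion sample-for-sample (oracle for the
    equivalence of the companion realization with the scalar recursion).

    Returns y(t) = x(t) for t = 0..N-1, starting from the constant state
    level ``x0``, with the convention that inputs indexed t produce the
    output at t (matching the scalar recursion's same-index drive)."""
    p = ss.order
    n = len(u_s)
    x = np.full(p, float(x0))
    y = np.empty(n)
    for t in range(n):
        u = np.array([u_dc, u_s[t]])
        x = ss.A @ x + ss.B @ u + ss.G[:, 0] * w[t]
        y[t] = (ss.C @ x)[0]
    return y


def controllability_matrix(ss: StateSpaceModel) -> np.ndarray:
    """[B_s, A B_s, ..., A^{p-1} B_s] for the stimulation input column."""
    p = ss.order
    cols = []
    v = ss.b_s_column
    for _ in range(p):
        cols.append(v)
        v = ss.A @ v
    return np.hstack(cols)

def controllability_rank(ss: StateSpaceModel) -> int:
    """Numerical rank of the stimulation-input controllability matrix.

    Full rank p means gamma power is controllable through stimulation alone.
    Threshold: machine epsilon x largest dimension x largest singular value.
    """
    M = controllability_matrix(ss)
    s = np.linalg.svd(M, compute_uv=False)
    if s.size == 0 or s[0] == 0.0:
        return 0
    tol = np.finfo(float).eps * max(M.shape) * s[0]
    return int(np.sum(s > tol))
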