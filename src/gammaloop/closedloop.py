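"""Closed-loop simulation of the controlled gamma-power plant.

Protocol: 4 s records at 500 Hz spanning t = -2 .. +1.998 s.  The plant
runs open loop (u_s = 0) before t = 0; from t = 0 the LQI law reads the
last p plant outputs plus the error integral and commands the saturated
stimulation amplitude.  Monte-Carlo ensembles use one independent noise
stream per trial, each reproducible in isolation from the base seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .arx import ARXModel, initial_state_level, steady_state_gamma
from .errors import ConfigError, InvalidInputError
from .lqi import LQIController


@dataclass
class SimulationResult:
    t: np.ndarray
    gamma: np.ndarray
    u_s: np.ndarray
    setpoint: float
    saturation_fraction: float
    seed: object

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.t, "gamma_uv": self.gamma,
                             "u_s_ma": self.u_s})


@dataclass
class MonteCarloSummary:
    t: np.ndarray
    mean_trace: np.ndarray
    std_trace: np.ndarray
    mean_u: np.ndarray
    n_trials: int
    metrics: pd.DataFrame
    setpoint: float


@dataclass
class ClosedLoopMetrics:
    """Window summaries of one closed-loop run.

    ``setpoint_error_pct`` uses the post-settling window (last
    ``settle_s`` seconds) so transients do not bias the steady-state error;
    ``setpoint_error_full_pct`` reports the full post-onset window mean.
    """

    delta_gamma_pct: float
    setpoint_error_pct: float
    setpoint_error_full_pct: float
    max_u: float
    saturation_fraction: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_closed_loop(
    plant: ARXModel,
    controller: LQIController,
    seed: int | np.random.SeedSequence | np.random.Generator,
    u_dc: float = 1.0,
    duration_s: float = 4.0,
) -> SimulationResult:
    """Simulate the 4-second protocol: open loop for t < 0, LQI control after.

    The controller's augmented state is the buffered last p outputs plus the
    error integral (initialized to 0 at t = 0); u_s(t) enters the plant
    recursion at the same sample index it is computed for.
    """
    p = plant.order
    if controller.order != p:
        raise ConfigError(
            f"controller gain is for order {controller.order}, plant has order {p}"
        )
    dt = plant.sampling_interval
    n = int(round(duration_s / dt))
    onset = n // 2
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = rng.normal(0.0, np.sqrt(plant.noise_variance), n)
    a = np.asarray(plant.a)
    x0 = initial_state_level(plant, u_dc)
    hist = np.full(p, x0)  # newest first
    ei = 0.0
    r = controller.setpoint
    gamma = np.empty(n)
    u_tr = np.zeros(n)
    n_sat = 0
    for i in range(n):
        saturated = False
        if i >= onset:
            z = np.concatenate([hist, [ei]])
            action = controller.control_step(z)
            u = action.u_s
            saturated = action.saturated
            if saturated:
                n_sat += 1
            u_tr[i] = u
        else:
            u = 0.0
        x = -float(a @ hist) + plant.b_dc * u_dc + plant.b_s * u + w[i]
        if i >= onset and not (controller.anti_windup and saturated):
            ei += controller.Ts * (r - x)  # conditional integration if anti_windup
        hist = np.roll(hist, 1)
        hist[0] = x
        gamma[i] = x
    t = (np.arange(n) - onset) * dt
    controlled = n - onset
    return SimulationResult(
        t=t, gamma=gamma, u_s=u_tr, setpoint=r,
        saturation_fraction=n_sat / controlled if controlled else 0.0,
        seed=seed if not isinstance(seed, np.random.Generator) else None,
    )


def monte_carlo(
    plant: ARXModel,
    controller: LQIController,
    n_trials: int,
    base_seed: int,
    u_dc: float = 1.0,
) -> MonteCarloSummary:
    """Independent closed-loop trials with per-trial counter-derived seeds."""
    if n_trials < 2:
        raise InvalidInputError("n_trials must be >= 2")
    runs = []
    for k in range(n_trials):
        ss = np.random.SeedSequence([int(base_seed), k])
        runs.append(run_closed_loop(plant, controller,
                                    np.random.default_rng(ss), u_dc=u_dc))
    G = np.vstack([r.gamma for r in runs])
    U = np.vstack([r.u_s for r in runs])
    metrics = pd.DataFrame([closed_loop_metrics(r).__dict__ for r in runs])
    metrics.insert(0, "trial", np.arange(n_trials))
    return MonteCarloSummary(
        t=runs[0].t, mean_trace=G.mean(axis=0), std_trace=G.std(axis=0),
        mean_u=U.mean(axis=0), n_trials=n_trials, metrics=metrics,
        setpoint=controller.setpoint,
    )


def closed_loop_metrics(result: SimulationResult,
                        settle_s: float = 1.0) -> ClosedLoopMetrics:
    """Pre/post window means, steady-state error and saturation summary."""
    pre = result.gamma[result.t < 0]
    post = result.gamma[result.t >= 0]
    if pre.size == 0 or post.size == 0:
        raise InvalidInputError("result must span both pre- and post-onset windows")
    pre_mean = float(pre.mean())
    if pre_mean == 0.0:
        raise InvalidInputError("pre-onset mean is zero; delta-gamma undefined")
    dt = float(result.t[1] - result.t[0])
    n_settle = max(1, int(round(settle_s / dt)))
    settled = result.gamma[-n_settle:]
    r = result.setpoint
    return ClosedLoopMetrics(
        delta_gamma_pct=100.0 * (float(post.mean()) - pre_mean) / pre_mean,
        setpoint_error_pct=100.0 * (float(settled.mean()) - r) / r if r else np.nan,
        setpoint_error_full_pct=100.0 * (float(post.mean()) - r) / r if r else np.nan,
        max_u=float(result.u_s.max()),
        saturation_fraction=result.saturation_fraction,
    )


def max_reachable_setpoint(plant: ARXModel, u_max: float = 9.0,
                           u_dc: float = 1.0) -> float:
    """Largest sustainable mean gamma power under the safety limit:
    the steady state at the full allowed stimulation amplitude."""
    return steady_state_gamma(plant, u_dc, u_max)
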