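"""End-to-end pipeline: trials -> composite ARX model -> LQI controller ->
Monte-Carlo closed-loop evaluation -> report artifacts.

Configuration is a flat document (YAML on disk) validated against the
documented ranges before any computation runs; every artifact embeds the
config hash and seed for byte-identical reruns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import yaml

from . import closedloop, lqi, sysid
from .arx import StepStimulus, to_state_space
from .errors import ConfigError
from .io import config_hash, read_trials_csv, write_artifact_json

log = logging.getLogger("gammaloop")


@dataclass
class RunConfig:
    input_trials: str
    out_dir: str = "runs"
    order: int = 6
    u_dc: float = 1.0
    step_amplitude: float = 2.0
    q_state: float = 0.005
    q_integrator: float = 100.0
    r_weight: float = 1.0
    setpoint: float | None = None  # default: steady state at the step amplitude
    u_max: float = 9.0
    n_trials: int = 100
    base_seed: int = 42
    settle_s: float = 1.0
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not (1 <= self.order <= 50):
            raise ConfigError(f"order must be in [1, 50], got {self.order}")
        if not (0 < self.u_max <= 9.0):
            raise ConfigError(
                f"u_max must be in (0, 9] mA (safety guardrail), got {self.u_max}"
            )
        if self.n_trials < 2:
            raise ConfigError("n_trials must be >= 2")
        if self.r_weight <= 0:
            raise ConfigError("r_weight must be positive")
        if not Path(self.input_trials).exists():
            raise ConfigError(f"input file not found: {self.input_trials}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in doc.items() if k in known}
        kwargs["extra"] = {k: v for k, v in doc.items() if k not in known}
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)

    def to_doc(self) -> dict:
        return asdict(self)


def run_pipeline(config: RunConfig) -> dict:
    """Identify -> design -> simulate -> report.  Returns artifact paths."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # hash only the scientifically relevant fields so reruns into a
    # different output directory remain byte-identical
    doc = {k: v for k, v in config.to_doc().items()
           if k not in ("out_dir", "log_level")}
    chash = config_hash(doc)

    t, trials = read_trials_csv(config.input_trials)
    log.info("stage=identify input shape=%s", trials.shape)
    n = trials.shape[1]
    stim = StepStimulus(n_samples=n, amplitude=config.step_amplitude,
                        onset_index=int(np.searchsorted(t, 0.0)))
    reports = sysid.fit_trials(trials, config.order, config.u_dc, stim)
    for rep in reports:
        if rep.condition_number > sysid.CONDITION_WARN_THRESHOLD:
            log.warning("condition number %.3e", rep.condition_number)
    composite = sysid.average_models([r.model for r in reports])
    model_path = out / "model.json"
    composite.to_json(model_path)
    report_path = out / "report.json"
    write_artifact_json(
        report_path,
        {
            "per_trial": [json.loads(r.to_json()) for r in reports],
            "composite": json.loads(composite.to_json()),
            "train_fit_perc": float(np.mean([r.fit_perc for r in reports])),
        },
        doc, config.base_seed,
    )

    ss = to_state_space(composite)
    setpoint = config.setpoint
    if setpoint is None:
        from .arx import steady_state_gamma
        setpoint = steady_state_gamma(composite, config.u_dc,
                                      config.step_amplitude)
    reachable = closedloop.max_reachable_setpoint(composite, config.u_max,
                                                  config.u_dc)
    if setpoint > reachable:
        log.warning("setpoint %.4g exceeds max reachable %.4g; clamping",
                    setpoint, reachable)
        setpoint = reachable
    weights = lqi.LQIWeights.from_scalars(
        config.order, config.q_state, config.q_integrator, config.r_weight
    )
    controller = lqi.design_controller(
        ss, setpoint=setpoint, weights=weights,
        Ts=composite.sampling_interval, u_max=config.u_max,
    )
    controller_path = out / "controller.json"
    controller.to_json(controller_path)

    log.info("stage=simulate n_trials=%d", config.n_trials)
    summary = closedloop.monte_carlo(composite, controller, config.n_trials,
                                     config.base_seed, u_dc=config.u_dc)
    traces_path = out / "closed_loop_traces.csv"
    import pandas as pd
    pd.DataFrame({
        "time_s": summary.t,
        "gamma_mean_uv": summary.mean_trace,
        "gamma_std_uv": summary.std_trace,
        "u_s_mean_ma": summary.mean_u,
    }).to_csv(traces_path, index=False, float_format="%.10g")
    metrics_path = out / "metrics.json"
    med = summary.metrics.drop(columns="trial").median()
    log.info("saturation_fraction=%.3f", float(med["saturation_fraction"]))
    write_artifact_json(
        metrics_path,
        {
            "setpoint": setpoint,
            "median": {k: float(v) for k, v in med.items()},
            "per_trial": summary.metrics.to_dict(orient="records"),
        },
        doc, config.base_seed,
    )
    return {
        "config_hash": chash,
        "model": str(model_path),
        "report": str(report_path),
        "controller": str(controller_path),
        "traces": str(traces_path),
        "metrics": str(metrics_path),
    }
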