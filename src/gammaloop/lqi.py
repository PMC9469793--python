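"""Linear quadratic integral (LQI) servo-controller synthesis.

The plant state (the last p gamma-power samples -- directly measurable, so
no state estimator is needed) is augmented with the discrete-time integral
of the setpoint error, e_i(t+1) = e_i(t) + Ts (r - y(t)).  Minimizing

    J = sum_t  z_t^T Q z_t + R u_s(t)^2,      z = [x; e_i]

over the stimulation amplitude u_s yields the state-feedback law
u_s = -K z with K from the discrete algebraic Riccati equation.  The
integrator guarantees zero steady-state tracking error for any reachable
constant setpoint; a hard saturation (default 0..9 mA) enforces the
charge-density safety guardrail.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy import linalg

from .arx import StateSpaceModel
from .errors import InvalidInputError, UnstabilizableError

RICCATI_TOL = 1e-12
RICCATI_MAX_ITER = 2_000_000


@dataclass(frozen=True)
class LQIWeights:
    """Cost weights: Q on the augmented state [x; e_i], scalar R on u_s."""

    Q: np.ndarray
    R: float

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        object.__setattr__(self, "Q", Q)
        if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
            raise InvalidInputError("Q must be square")
        if not np.allclose(Q, Q.T, atol=1e-12):
            raise InvalidInputError("Q must be symmetric")
        if np.min(np.linalg.eigvalsh(Q)) < -1e-12:
            raise InvalidInputError("Q must be positive semidefinite")
        if self.R <= 0:
            raise InvalidInputError("R must be positive")

    @classmethod
    def from_scalars(cls, p: int, q_state: float = 0.005,
                     q_integrator: float = 100.0, r: float = 1.0) -> "LQIWeights":
        """Block-diagonal default: q_state * I_p on the plant state and
        q_integrator on the integrated error."""
        return cls(Q=np.diag([q_state] * p + [q_integrator]), R=r)


@dataclass(frozen=True)
class AugmentedSystem:
    """Plant augmented with the setpoint-error integrator.

    z_{t+1} = A_aug z_t + B_aug u_s + reference_injection * r
              + dc_injection * (b_DC u_DC)  [the u_DC channel is a known
              constant disturbance, not a control input]
    """

    A_aug: np.ndarray
    B_aug: np.ndarray
    reference_injection: np.ndarray
    dc_injection: np.ndarray
    Ts: float


def augment_with_integrator(ss: StateSpaceModel, Ts: float = 0.002) -> AugmentedSystem:
    if Ts <= 0:
        raise InvalidInputError("Ts must be positive")
    p = ss.order
    A_aug = np.zeros((p + 1, p + 1))
    A_aug[:p, :p] = ss.A
    A_aug[p, :p] = -Ts * ss.C[0]
    A_aug[p, p] = 1.0
    B_aug = np.vstack([ss.b_s_column, [[0.0]]])
    r_inj = np.zeros((p + 1, 1))
    r_inj[p, 0] = Ts
    dc_inj = np.zeros((p + 1, 1))
    dc_inj[0, 0] = 1.0
    return AugmentedSystem(A_aug=A_aug, B_aug=B_aug, reference_injection=r_inj,
                           dc_injection=dc_inj, Ts=Ts)


def _riccati_value_iteration(A, B, Q, R):
    """Fixed-point iteration on the Riccati recursion; fallback solver."""
    P = Q.copy()
    for _ in range(RICCATI_MAX_ITER):
        BtPB = R + B.T @ P @ B
        K = np.linalg.solve(BtPB, B.T @ P @ A)
        Pn = Q + A.T @ P @ (A - B @ K)
        Pn = 0.5 * (Pn + Pn.T)
        if np.max(np.abs(Pn - P)) <= RICCATI_TOL * max(1.0, np.max(np.abs(P))):
            return Pn
        P = Pn
    raise UnstabilizableError("Riccati value iteration failed to converge")


def solve_lqi_gain(aug: AugmentedSystem, weights: LQIWeights) -> np.ndarray:
    """Infinite-horizon LQR gain K (row vector) for the augmented pair.

    Uses the structured discrete-algebraic-Riccati solver, falling back to
    value iteration if it fails; verifies the closed loop is stable.
    """
    A, B = aug.A_aug, aug.B_aug
    n = A.shape[0]
    if weights.Q.shape[0] != n:
        raise InvalidInputError(
            f"Q dimension {weights.Q.shape[0]} != augmented order {n}"
        )
    if np.max(np.abs(B)) == 0.0:
        raise UnstabilizableError("b_s = 0: no control authority over gamma power")
    R = np.atleast_2d(weights.R)
    try:
        P = linalg.solve_discrete_are(A, B, weights.Q, R)
    except (np.linalg.LinAlgError, linalg.LinAlgError, ValueError):
        P = _riccati_value_iteration(A, B, weights.Q, R)
    K = np.linalg.solve(R + B.T @ P @ B, B.T @ P @ A)
    sr = np.max(np.abs(np.linalg.eigvals(A - B @ K)))
    if sr >= 1.0:
        raise UnstabilizableError(
            f"closed loop not asymptotically stable (spectral radius {sr:.6f})"
        )
    return K[0]


def riccati_residual(aug: AugmentedSystem, weights: LQIWeights,
                     P: np.ndarray) -> float:
    """Relative norm of the DARE residual for a candidate P."""
    A, B = aug.A_aug, aug.B_aug
    R = np.atleast_2d(weights.R)
    res = A.T @ P @ A - P - A.T @ P @ B @ np.linalg.solve(
        R + B.T @ P @ B, B.T @ P @ A
    ) + weights.Q
    return float(np.linalg.norm(res) / np.linalg.norm(P))


class ControlAction(NamedTuple):
    u_s: float
    saturated: bool


@dataclass
class LQIController:
    """Saturated LQI control law u_s = clamp(-K z, u_min, u_max)."""

    K: np.ndarray
    Ts: float = 0.002
    setpoint: float = 0.0
    u_max: float = 9.0
    u_min: float = 0.0
    anti_windup: bool = False  # freeze integrator while saturated (off: plain clamp)
    weights: LQIWeights | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float).ravel()
        if self.u_min >= self.u_max:
            raise InvalidInputError("u_min must be below u_max")
        if self.setpoint < 0:
            raise InvalidInputError("setpoint must be nonnegative")

    @property
    def order(self) -> int:
        """Plant order p implied by the gain length p+1."""
        return self.K.size - 1

    def control_step(self, z: np.ndarray) -> ControlAction:
        z = np.asarray(z, dtype=float).ravel()
        if z.size != self.K.size:
            raise InvalidInputError(
                f"augmented state length {z.size} != gain length {self.K.size}"
            )
        raw = float(-(self.K @ z))
        u = min(max(raw, self.u_min), self.u_max)
        return ControlAction(u_s=u, saturated=(u != raw))

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "K": self.K.tolist(),
            "Ts": self.Ts,
            "setpoint": self.setpoint,
            "u_max": self.u_max,
            "u_min": self.u_min,
            "anti_windup": self.anti_windup,
        }
        if self.weights is not None:
            doc["Q"] = self.weights.Q.tolist()
            doc["R"] = self.weights.R
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LQIController":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        doc = json.loads(text)
        weights = None
        if "Q" in doc:
            weights = LQIWeights(Q=np.asarray(doc["Q"]), R=doc["R"])
        return cls(K=np.asarray(doc["K"]), Ts=doc["Ts"], setpoint=doc["setpoint"],
                   u_max=doc["u_max"], u_min=doc["u_min"],
                   anti_windup=doc.get("anti_windup", False), weights=weights)


def control_step(controller: LQIController, z: np.ndarray) -> ControlAction:
    """Functional alias for :meth:`LQIController.control_step`."""
    return controller.control_step(z)


def design_controller(
    ss: StateSpaceModel,
    setpoint: float,
    weights: LQIWeights | None = None,
    Ts: float = 0.002,
    u_max: float = 9.0,
    u_min: float = 0.0,
    anti_windup: bool = False,
) -> LQIController:
    """One-call design: augment, solve the Riccati problem, wrap the gain."""
    if weights is None:
        weights = LQIWeights.from_scalars(ss.order)
    aug = augment_with_integrator(ss, Ts)
    K = solve_lqi_gain(aug, weights)
    return LQIController(K=K, Ts=Ts, setpoint=setpoint, u_max=u_max,
                         u_min=u_min, anti_windup=anti_windup, weights=weights)
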