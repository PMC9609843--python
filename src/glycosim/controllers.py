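"""Controller synthesis: PID, LQR, and sliding-mode control.

Three control laws for the glucose-insulin loop:

* **PID** ``u = kp e + ki int(e) + kd de/dt`` on the glucose error
  ``e = G_ref - G``, realized discretely with a trapezoidal integral and a
  backward-difference derivative.
* **LQR** state feedback ``u = -K x`` with ``K = R^{-1} B^T P`` from the
  algebraic Riccati equation (continuous or discrete, matching the plant's
  domain tag).
* **SMC** ``u = ueq + udisc`` on the sliding surface
  ``s = c1 x1 + c2 x2 + c3 x3``: the equivalent control cancels the surface
  drift (``sdot = a.x + b u``), and the switching term
  ``udisc = -k1 s - k2 sign(s)`` enforces the Lyapunov reaching condition
  ``Vdot = -k1 s^2 - k2 |s| <= 0`` for ``V = s^2 / 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg as sla

from .glucose_plant import StateSpaceModel, ValidationError

__all__ = [
    "PIDGains",
    "PIDState",
    "LQRProblem",
    "LQRSolution",
    "SurfaceDynamics",
    "SMCParams",
    "SMCDiagnostics",
    "pid_step",
    "pid_transfer_function",
    "lqr_design",
    "smc_surface",
    "smc_equivalent_control",
    "smc_discontinuous_control",
    "smc_control",
    "smc_params_for_plant",
    "reaching_time_bound",
    "TUNED_PID",
    "PRINTED_LQR_Q",
    "PRINTED_LQR_K",
    "REFERENCE_SMC",
    "PRINTED_SURFACE_DYNAMICS",
]


# -- PID ----------------------------------------------------------------------

@dataclass(frozen=True)
class PIDGains:
    """Proportional (dimensionless), integral (1/s) and derivative (s) gains.

    Signs are unconstrained: the glucose loop uses negative gains because
    the plant gain is negative.
    """

    kp: float
    ki: float
    kd: float

    def __post_init__(self) -> None:
        for name in ("kp", "ki", "kd"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")


#: Tuned gains of the reference PID design.
TUNED_PID = PIDGains(kp=-0.000151, ki=-2.75e-8, kd=-0.207)


@dataclass(frozen=True)
class PIDState:
    """Integrator memory of the discrete PID realization."""

    integral: float = 0.0
    prev_error: float | None = None

    @property
    def initialized(self) -> bool:
        return self.prev_error is not None


def pid_step(
    gains: PIDGains, state: PIDState, error: float, dt: float
) -> tuple[float, PIDState]:
    """One sampled PID update; returns the control value and the new state.

    Trapezoidal integral (previous error taken as 0 on the first call),
    backward-difference derivative (0 on the first call), derivative on
    error, no anti-windup and no derivative filtering.
    """
    if dt <= 0:
        raise ValidationError(f"dt must be positive, got {dt}")
    if not math.isfinite(error):
        raise ValidationError(f"error must be finite, got {error}")
    prev = state.prev_error
    deriv = 0.0 if prev is None else (error - prev) / dt
    integral = state.integral + dt * (error + (prev if prev is not None else 0.0)) / 2.0
    u = gains.kp * error + gains.ki * integral + gains.kd * deriv
    return u, PIDState(integral=integral, prev_error=error)


def pid_transfer_function(gains: PIDGains):
    """s-domain PID transfer function (kd s^2 + kp s + ki) / s."""
    from .glucose_plant import ContinuousTransferFunction

    return ContinuousTransferFunction(
        num=np.array([gains.kd, gains.kp, gains.ki]), den=np.array([1.0, 0.0])
    )


# -- LQR ----------------------------------------------------------------------

@dataclass(frozen=True)
class LQRProblem:
    """Quadratic-cost regulator problem min int(x'Qx + u'Ru) dt."""

    model: StateSpaceModel
    Q: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        n = self.model.order
        Q = np.asarray(self.Q, dtype=float).reshape(n, n)
        R = np.atleast_2d(np.asarray(self.R, dtype=float))
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "R", R)


@dataclass(frozen=True)
class LQRSolution:
    """Optimal gain K, Riccati solution P, and the relative ARE residual."""

    K: np.ndarray
    P: np.ndarray
    residual: float
    domain: str

    def closed_loop_matrix(self, model: StateSpaceModel) -> np.ndarray:
        return model.A - np.outer(model.B, self.K)


#: Printed state-weight matrix of the reference LQR design (R = I).
PRINTED_LQR_Q = np.diag([0.001, 0.2341, 0.22])

#: Printed gain vector, kept as a comparison fixture only: it does not
#: stabilize the printed state matrix under either domain reading, so the
#: toolkit always recomputes K from (Q, R).
PRINTED_LQR_K = np.array([0.231, 0.4947, 0.4687])


def _check_symmetric_psd(M: np.ndarray, name: str, strict: bool) -> None:
    if not np.allclose(M, M.T, rtol=1e-10, atol=1e-12):
        raise ValidationError(f"{name} must be symmetric")
    eig = np.linalg.eigvalsh((M + M.T) / 2)
    if strict and eig.min() <= 0:
        raise ValidationError(f"{name} must be positive definite (min eig {eig.min():.3g})")
    if not strict and eig.min() < -1e-12 * max(1.0, eig.max()):
        raise ValidationError(f"{name} must be positive semidefinite (min eig {eig.min():.3g})")


def _check_stabilizable(A: np.ndarray, B: np.ndarray, domain: str) -> None:
    """PBH test on every non-stable eigenvalue."""
    n = A.shape[0]
    for lam in np.linalg.eigvals(A):
        unstable = abs(lam) >= 1.0 if domain == "discrete" else lam.real >= 0.0
        if unstable:
            M = np.hstack([lam * np.eye(n) - A, B.reshape(n, 1)])
            if np.linalg.matrix_rank(M, tol=1e-10 * max(1.0, abs(lam))) < n:
                raise ValidationError(
                    f"(A, B) is not stabilizable: uncontrollable eigenvalue {lam:.6g} "
                    f"is not {'inside the unit circle' if domain == 'discrete' else 'in the open left half-plane'}"
                )


def lqr_design(problem: LQRProblem) -> LQRSolution:
    """Solve the LQR problem for the model's domain (continuous or discrete).

    Continuous: ``A'P + PA - PBR^{-1}B'P + Q = 0``, ``K = R^{-1} B' P``.
    Discrete:  ``P = A'PA - A'PB (R + B'PB)^{-1} B'PA + Q``,
    ``K = (R + B'PB)^{-1} B'PA``.
    """
    model, Q, R = problem.model, problem.Q, problem.R
    _check_symmetric_psd(Q, "Q", strict=False)
    _check_symmetric_psd(R, "R", strict=True)
    A = model.A
    B = model.B.reshape(-1, 1)
    _check_stabilizable(A, model.B, model.domain)
    if model.domain == "continuous":
        P = sla.solve_continuous_are(A, B, Q, R)
        K = (np.linalg.solve(R, B.T @ P)).ravel()
        res = A.T @ P + P @ A - P @ B @ np.linalg.solve(R, B.T @ P) + Q
    else:
        P = sla.solve_discrete_are(A, B, Q, R)
        K = np.linalg.solve(R + B.T @ P @ B, B.T @ P @ A).ravel()
        res = A.T @ P @ A - P - A.T @ P @ B @ np.linalg.solve(R + B.T @ P @ B, B.T @ P @ A) + Q
    residual = float(np.linalg.norm(res) / max(np.linalg.norm(P), 1e-300))
    sol = LQRSolution(K=K, P=P, residual=residual, domain=model.domain)
    lam = np.linalg.eigvals(sol.closed_loop_matrix(model))
    stable = np.all(np.abs(lam) < 1.0) if model.domain == "discrete" else np.all(lam.real < 0.0)
    if not stable:
        raise ValidationError(f"Riccati solution is not stabilizing (closed-loop eigs {lam})")
    return sol


# -- sliding-mode control -----------------------------------------------------

@dataclass(frozen=True)
class SurfaceDynamics:
    """Coefficients of the sliding-variable dynamics sdot = a.x + b u."""

    a1: float
    a2: float
    a3: float
    b: float

    def __post_init__(self) -> None:
        if self.b == 0.0:
            raise ValidationError("b must be nonzero (control must act on the surface)")

    @property
    def a(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3])


#: Printed surface-dynamics coefficients used for reproduction runs.  These
#: differ from c'A, c'B computed on the printed state matrix; both presets
#: are available.
PRINTED_SURFACE_DYNAMICS = SurfaceDynamics(2.416e-4, 5.7105e-4, -9.105e-5, 0.25)


@dataclass(frozen=True)
class SMCParams:
    """Sliding-surface coefficients, switching gains, and surface dynamics.

    ``sign_zero`` fixes the value of sign(0): 0 by default so the control is
    bounded on the surface (configurable to +/-1 for experimentation).
    """

    c1: float = 1.0
    c2: float = 2.5
    c3: float = 1.0
    k1: float = 6.0
    k2: float = 9.0
    surface_dynamics: SurfaceDynamics = PRINTED_SURFACE_DYNAMICS
    sign_zero: float = 0.0

    def __post_init__(self) -> None:
        if self.k1 < 0:
            raise ValidationError(f"k1 must be >= 0, got {self.k1}")
        if self.k2 <= 0:
            raise ValidationError(f"k2 must be > 0, got {self.k2}")
        # sliding polynomial c3 lam^2 + c2 lam + c1 must be Hurwitz
        if np.any(np.roots([self.c3, self.c2, self.c1]).real >= 0):
            raise ValidationError(
                f"sliding surface c=({self.c1}, {self.c2}, {self.c3}) is not Hurwitz"
            )

    @property
    def c(self) -> np.ndarray:
        return np.array([self.c1, self.c2, self.c3])


#: Printed SMC tuning with the printed surface-dynamics preset.
REFERENCE_SMC = SMCParams()


@dataclass(frozen=True)
class SMCDiagnostics:
    """Per-evaluation sliding diagnostics: V = s^2/2, Vdot = -k1 s^2 - k2 |s|."""

    s: float
    V: float
    Vdot: float
    ueq: float
    udisc: float


def smc_params_for_plant(
    plant: StateSpaceModel,
    c1: float = 1.0,
    c2: float = 2.5,
    c3: float = 1.0,
    k1: float = 6.0,
    k2: float = 9.0,
) -> SMCParams:
    """SMC parameters with surface dynamics computed symbolically as c'A, c'B."""
    c = np.array([c1, c2, c3])
    a = c @ plant.A
    b = float(c @ plant.B)
    return SMCParams(c1, c2, c3, k1, k2, SurfaceDynamics(a[0], a[1], a[2], b))


def smc_surface(params: SMCParams, x: np.ndarray) -> float:
    """Sliding variable s = c1 x1 + c2 x2 + c3 x3."""
    x = np.asarray(x, dtype=float)
    if x.shape != (3,):
        raise ValidationError(f"state must have 3 components, got shape {x.shape}")
    return float(params.c @ x)


def smc_equivalent_control(params: SMCParams, x: np.ndarray) -> float:
    """Equivalent control ueq = -(a.x)/b, the unique u with sdot = 0."""
    dyn = params.surface_dynamics
    return float(-(dyn.a @ np.asarray(x, dtype=float)) / dyn.b)


def _sign(s: float, sign_zero: float) -> float:
    if s > 0:
        return 1.0
    if s < 0:
        return -1.0
    return sign_zero


def smc_discontinuous_control(params: SMCParams, s: float) -> float:
    """Switching term udisc = -k1 s - k2 sign(s)."""
    return -params.k1 * s - params.k2 * _sign(s, params.sign_zero)


def smc_control(params: SMCParams, x: np.ndarray) -> tuple[float, SMCDiagnostics]:
    """Full sliding-mode law u = ueq + udisc with Lyapunov diagnostics."""
    s = smc_surface(params, x)
    ueq = smc_equivalent_control(params, x)
    udisc = smc_discontinuous_control(params, s)
    diag = SMCDiagnostics(
        s=s,
        V=0.5 * s * s,
        Vdot=-params.k1 * s * s - params.k2 * abs(s),
        ueq=ueq,
        udisc=udisc,
    )
    return ueq + udisc, diag


def reaching_time_bound(params: SMCParams, s0: float) -> float:
    """Upper bound on the time for the ideal sliding dynamics to reach s = 0.

    For sdot = -k1 s - k2 sign(s) the surface is reached in at most
    (1/k1) ln(1 + k1 |s0| / k2), degenerating to |s0|/k2 when k1 = 0.
    """
    if params.k2 <= 0:
        raise ValidationError(f"k2 must be > 0, got {params.k2}")
    s0 = abs(s0)
    if s0 == 0.0:
        return 0.0
    if params.k1 == 0.0:
        return s0 / params.k2
    return math.log1p(params.k1 * s0 / params.k2) / params.k1


def with_sign_convention(params: SMCParams, sign_zero: float) -> SMCParams:
    """Copy of the parameters with a different sign(0) convention."""
    return replace(params, sign_zero=sign_zero)
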