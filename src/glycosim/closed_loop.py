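"""Closed-loop simulation of the glucose plant and time-response metrics.

The plant is simulated in deviation coordinates ``y = G - G_ref`` under

    xdot = A x + B (u + d(t)),   y = C x,

with the whole initial deviation placed on the output-coupled third state,
``x0 = (0, 0, (G0 - G_ref)/C3)`` so that ``y(0) = G0 - G_ref``.  Reported
glucose is ``G = y + G_ref``.  The PID consumes the error
``e = G_ref - G`` sampled at dt and held over the step; LQR applies
``u = -K x`` and SMC applies ``u = ueq + udisc`` continuously (evaluated at
every integrator substage, so sliding-mode switching is resolved at the dt
scale and chattering is measured, not suppressed).

Fixed-step RK4 is the default integrator (forward Euler available).
Discrete plants are stepped at their own sampling period.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .glucose_plant import StateSpaceModel, ValidationError
from .controllers import (
    LQRProblem,
    LQRSolution,
    PIDGains,
    PIDState,
    SMCParams,
    lqr_design,
    pid_step,
    smc_control,
)

__all__ = [
    "SimulationConfig",
    "Disturbance",
    "Trajectory",
    "PerformanceMetrics",
    "ComparisonReport",
    "SimulationDivergence",
    "simulate_closed_loop",
    "settling_time",
    "rise_time",
    "overshoot",
    "steady_state_error",
    "chattering_index",
    "low_pass_filter",
    "compute_metrics",
    "compare_controllers",
]


class SimulationDivergence(RuntimeError):
    """The closed-loop state became non-finite; carries the blow-up time."""

    def __init__(self, time_s: float):
        self.time_s = time_s
        super().__init__(f"simulation diverged (non-finite state) at t = {time_s:g} s")


@dataclass(frozen=True)
class Disturbance:
    """Input-additive (matched) sinusoid d(t) = amplitude sin(omega t + phase)."""

    amplitude: float = 1.0
    omega: float = 2.0 * math.pi / 300.0
    phase: float = 0.0

    def __call__(self, t: float) -> float:
        return self.amplitude * math.sin(self.omega * t + self.phase)


@dataclass(frozen=True)
class SimulationConfig:
    """Closed-loop run definition.

    G_ref and G0 in mg/dL; dt and horizon in seconds; settling_band as a
    fraction of the initial deviation.
    """

    G_ref: float = 70.0
    G0: float = 200.0
    dt: float = 0.1
    horizon: float = 1000.0
    settling_band: float = 0.02
    disturbance: Disturbance | None = None
    integrator: str = "rk4"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")
        if self.horizon < 10 * self.dt:
            raise ValidationError(
                f"horizon must be at least 10*dt, got horizon={self.horizon}, dt={self.dt}"
            )
        if not (0.0 < self.settling_band < 1.0):
            raise ValidationError(f"settling_band must lie in (0, 1), got {self.settling_band}")
        if self.G_ref <= 0 or self.G0 <= 0:
            raise ValidationError("G_ref and G0 must be physiologically positive")
        if self.integrator not in ("rk4", "euler"):
            raise ValidationError(f"integrator must be 'rk4' or 'euler', got {self.integrator!r}")

    def fingerprint(self) -> str:
        """Stable hash of the configuration for reproducibility reports."""
        payload = repr(
            (
                self.G_ref, self.G0, self.dt, self.horizon, self.settling_band,
                None if self.disturbance is None
                else (self.disturbance.amplitude, self.disturbance.omega, self.disturbance.phase),
                self.integrator, self.seed,
            )
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class Trajectory:
    """Sampled closed-loop record (uniform time grid)."""

    t: np.ndarray
    glucose: np.ndarray
    u: np.ndarray
    s: np.ndarray | None = None
    disturbance: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.t.size
        for name in ("glucose", "u"):
            if getattr(self, name).size != n:
                raise ValidationError(f"{name} length must match the time grid")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError("time grid must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_csv(self, path: str | Path) -> None:
        """Write time_s,glucose_mg_dl,control_u,sliding_s,disturbance rows."""
        def f(x: float) -> str:
            return format(x, ".10g")

        lines = ["time_s,glucose_mg_dl,control_u,sliding_s,disturbance"]
        s = self.s
        d = self.disturbance
        for i in range(self.t.size):
            lines.append(
                ",".join(
                    [
                        f(self.t[i]),
                        f(self.glucose[i]),
                        f(self.u[i]),
                        "" if s is None else f(s[i]),
                        f(0.0 if d is None else d[i]),
                    ]
                )
            )
        Path(path).write_text("\n".join(lines) + "\n")


def _rk4_matrices(A: np.ndarray, B: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """One-step RK4 propagator for xdot = Ax + Bu with u held over the step.

    Phi = sum_{j=0..4} (dt A)^j / j!,  Gamma = sum_{j=1..4} dt^j A^{j-1}/j! B —
    identical to running classical RK4 on the linear system.
    """
    n = A.shape[0]
    phi = np.eye(n)
    term = np.eye(n)
    for j in range(1, 5):
        term = term @ (dt * A) / j
        phi = phi + term
    gamma = dt * np.eye(n)
    power = np.eye(n)
    fact = 1.0
    for j in range(2, 5):
        power = power @ A
        fact *= j
        gamma = gamma + (dt**j / fact) * power
    return phi, gamma @ B


def _euler_matrices(A: np.ndarray, B: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    return np.eye(A.shape[0]) + dt * A, dt * B


def simulate_closed_loop(
    plant: StateSpaceModel,
    controller: PIDGains | LQRProblem | LQRSolution | SMCParams | None,
    config: SimulationConfig,
) -> Trajectory:
    """Simulate one controller on one plant; deterministic for a fixed config.

    ``controller=None`` runs the open loop (u = 0).  An LQRProblem is
    designed on the fly; an LQRSolution is applied as-is.
    """
    C3 = plant.C[2]
    if C3 == 0.0:
        raise ValidationError("plant C[3] must be nonzero to place the initial deviation")
    if isinstance(controller, LQRProblem):
        controller = lqr_design(controller)
    if plant.domain == "discrete":
        return _simulate_discrete(plant, controller, config)
    if isinstance(controller, (PIDGains, type(None))):
        return _simulate_sampled_input(plant, controller, config)
    if isinstance(controller, LQRSolution):
        if controller.domain != "continuous":
            raise ValidationError("discrete LQR solution applied to a continuous plant")
        return _simulate_state_feedback(plant, controller, config)
    if isinstance(controller, SMCParams):
        return _simulate_smc(plant, controller, config)
    raise ValidationError(f"unsupported controller spec {type(controller).__name__}")


def _init_state(plant: StateSpaceModel, config: SimulationConfig) -> np.ndarray:
    x = np.zeros(plant.order)
    x[2] = (config.G0 - config.G_ref) / plant.C[2]
    return x


def _check_finite(value: float, t: float) -> None:
    if not math.isfinite(value):
        raise SimulationDivergence(t)


def _quiet_overflow(fn):
    """Divergence is detected explicitly; silence the intermediate overflow."""
    import functools

    @functools.wraps(fn)
    def wrapped(*args, **kwargs):
        with np.errstate(over="ignore", invalid="ignore"):
            return fn(*args, **kwargs)

    return wrapped


@_quiet_overflow
def _simulate_sampled_input(
    plant: StateSpaceModel,
    gains: PIDGains | None,
    config: SimulationConfig,
) -> Trajectory:
    """PID (or open-loop) run: control sampled at dt, held over each step."""
    dt = config.dt
    n = int(round(config.horizon / dt))
    mats = _rk4_matrices if config.integrator == "rk4" else _euler_matrices
    phi, gamma = mats(plant.A, plant.B, dt)
    x = _init_state(plant, config)
    C = plant.C
    G = np.empty(n + 1)
    u_rec = np.zeros(n + 1)
    d_rec = np.zeros(n + 1)
    G[0] = C @ x + config.G_ref
    pid_state = PIDState()
    dist = config.disturbance
    if dist is not None:
        # disturbance varies inside the step: fall back to substage evaluation
        return _simulate_generic(
            plant, config,
            control=_pid_sampled_law(gains),
            record_s=None,
        )
    for k in range(n):
        if gains is not None:
            e = config.G_ref - G[k]
            u, pid_state = pid_step(gains, pid_state, e, dt)
        else:
            u = 0.0
        u_rec[k] = u
        x = phi @ x + gamma * u
        G[k + 1] = C @ x + config.G_ref
        _check_finite(G[k + 1], (k + 1) * dt)
    u_rec[n] = u_rec[n - 1] if n else 0.0
    return Trajectory(np.arange(n + 1) * dt, G, u_rec, None, d_rec)


def _pid_sampled_law(gains: PIDGains | None):
    """Sampled PID wrapped for the generic integrator (u updated once per step)."""
    state = {"pid": PIDState(), "u": 0.0}

    def law(plant, config, x, t, substage):
        if substage == 0:
            if gains is None:
                state["u"] = 0.0
            else:
                e = config.G_ref - (plant.C @ x + config.G_ref)
                state["u"], state["pid"] = pid_step(gains, state["pid"], e, config.dt)
        return state["u"], None

    return law


@_quiet_overflow
def _simulate_state_feedback(
    plant: StateSpaceModel, sol: LQRSolution, config: SimulationConfig
) -> Trajectory:
    """LQR run u = -Kx; the closed loop is linear so RK4 reduces to a matrix."""
    dt = config.dt
    n = int(round(config.horizon / dt))
    K = sol.K
    if config.disturbance is not None:
        def law(plant_, config_, x, t, substage):
            return float(-K @ x), None
        return _simulate_generic(plant, config, law, record_s=None)
    Acl = plant.A - np.outer(plant.B, K)
    mats = _rk4_matrices if config.integrator == "rk4" else _euler_matrices
    phi, _ = mats(Acl, plant.B, dt)
    x = _init_state(plant, config)
    C = plant.C
    G = np.empty(n + 1)
    u_rec = np.empty(n + 1)
    G[0] = C @ x + config.G_ref
    u_rec[0] = -K @ x
    for k in range(n):
        x = phi @ x
        G[k + 1] = C @ x + config.G_ref
        u_rec[k + 1] = -K @ x
        _check_finite(G[k + 1], (k + 1) * dt)
    return Trajectory(np.arange(n + 1) * dt, G, u_rec, None, np.zeros(n + 1))


def _simulate_smc(
    plant: StateSpaceModel, params: SMCParams, config: SimulationConfig
) -> Trajectory:
    def law(plant_, config_, x, t, substage):
        u, diag = smc_control(params, x)
        return u, diag.s

    return _simulate_generic(plant, config, law, record_s=True)


@_quiet_overflow
def _simulate_generic(
    plant: StateSpaceModel,
    config: SimulationConfig,
    control,
    record_s,
) -> Trajectory:
    """Fixed-step RK4/Euler with the control law evaluated at every substage."""
    dt = config.dt
    n = int(round(config.horizon / dt))
    A, B, C = plant.A, plant.B, plant.C
    dist = config.disturbance
    x = _init_state(plant, config)
    G = np.empty(n + 1)
    u_rec = np.empty(n + 1)
    s_rec = np.empty(n + 1) if record_s else None
    d_rec = np.zeros(n + 1)
    G[0] = C @ x + config.G_ref

    def deriv(x_, t_, substage):
        u, s = control(plant, config, x_, t_, substage)
        d = dist(t_) if dist is not None else 0.0
        return A @ x_ + B * (u + d), u, s, d

    for k in range(n):
        t = k * dt
        f1, u0, s0, d0 = deriv(x, t, 0)
        u_rec[k] = u0
        d_rec[k] = d0
        if s_rec is not None:
            s_rec[k] = s0
        if config.integrator == "euler":
            x = x + dt * f1
        else:
            f2, *_ = deriv(x + 0.5 * dt * f1, t + 0.5 * dt, 1)
            f3, *_ = deriv(x + 0.5 * dt * f2, t + 0.5 * dt, 2)
            f4, *_ = deriv(x + dt * f3, t + dt, 3)
            x = x + dt / 6.0 * (f1 + 2 * f2 + 2 * f3 + f4)
        G[k + 1] = C @ x + config.G_ref
        _check_finite(G[k + 1], (k + 1) * dt)
    _, u_end, s_end, d_end = deriv(x, n * dt, 0)
    u_rec[n] = u_end
    d_rec[n] = d_end
    if s_rec is not None:
        s_rec[n] = s_end
    return Trajectory(np.arange(n + 1) * dt, G, u_rec, s_rec, d_rec)


@_quiet_overflow
def _simulate_discrete(
    plant: StateSpaceModel,
    controller,
    config: SimulationConfig,
) -> Trajectory:
    """Step a discrete plant at its own sampling period."""
    Ts = plant.Ts
    n = max(int(round(config.horizon / Ts)), 1)
    x = _init_state(plant, config)
    A, B, C = plant.A, plant.B, plant.C
    G = np.empty(n + 1)
    u_rec = np.zeros(n + 1)
    s_rec = np.empty(n + 1) if isinstance(controller, SMCParams) else None
    G[0] = C @ x + config.G_ref
    pid_state = PIDState()
    for k in range(n):
        if controller is None:
            u = 0.0
        elif isinstance(controller, PIDGains):
            u, pid_state = pid_step(controller, pid_state, config.G_ref - G[k], Ts)
        elif isinstance(controller, LQRSolution):
            if controller.domain != "discrete":
                raise ValidationError("continuous LQR solution applied to a discrete plant")
            u = float(-controller.K @ x)
        elif isinstance(controller, SMCParams):
            u, diag = smc_control(controller, x)
            s_rec[k] = diag.s
        else:
            raise ValidationError(f"unsupported controller spec {type(controller).__name__}")
        u_rec[k] = u
        x = A @ x + B * u
        G[k + 1] = C @ x + config.G_ref
        _check_finite(G[k + 1], (k + 1) * Ts)
    if s_rec is not None:
        s_rec[n] = smc_control(controller, x)[1].s
    u_rec[n] = u_rec[n - 1]
    return Trajectory(np.arange(n + 1) * Ts, G, u_rec, s_rec, np.zeros(n + 1))


# -- metrics ------------------------------------------------------------------

def _as_t_g(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    return traj.t, traj.glucose


def settling_time(
    traj: Trajectory, G_ref: float, band: float = 0.02
) -> float | None:
    """Earliest time after which glucose stays within band*|G(0)-G_ref| of G_ref.

    Returns 0.0 when the initial deviation is zero and None when the
    trajectory never enters (or leaves again) the band within the horizon.
    """
    t, G = _as_t_g(traj)
    dev0 = abs(G[0] - G_ref)
    if dev0 == 0.0:
        return 0.0
    outside = np.abs(G - G_ref) > band * dev0
    idx = np.flatnonzero(outside)
    if idx.size == 0:
        return 0.0
    if idx[-1] == G.size - 1:
        return None
    return float(t[idx[-1] + 1])


def rise_time(traj: Trajectory, G_ref: float) -> float | None:
    """Time for the deviation to recover from 10% to 90% of its initial value."""
    t, G = _as_t_g(traj)
    dev = np.abs(G - G_ref)
    dev0 = dev[0]
    if dev0 == 0.0:
        return 0.0
    below90 = np.flatnonzero(dev <= 0.9 * dev0)
    below10 = np.flatnonzero(dev <= 0.1 * dev0)
    if below90.size == 0 or below10.size == 0:
        return None
    return float(t[below10[0]] - t[below90[0]])


def overshoot(traj: Trajectory, G_ref: float, G0: float) -> float:
    """Maximum excursion past G_ref opposite to G0, in % of |G0 - G_ref|."""
    if G0 == G_ref:
        raise ValidationError("overshoot undefined when G0 equals G_ref")
    _, G = _as_t_g(traj)
    span = abs(G0 - G_ref)
    if G0 > G_ref:
        exc = G_ref - G.min()
    else:
        exc = G.max() - G_ref
    return max(0.0, 100.0 * exc / span)


def steady_state_error(traj: Trajectory, G_ref: float, tail_fraction: float = 0.05) -> float:
    """Mean absolute glucose error over the final tail_fraction of the horizon."""
    t, G = _as_t_g(traj)
    start = t[-1] - tail_fraction * (t[-1] - t[0])
    mask = t >= start
    return float(np.mean(np.abs(G[mask] - G_ref)))


def low_pass_filter(u: np.ndarray, dt: float, cutoff: float) -> np.ndarray:
    """First-order low-pass ydot = cutoff (u - y), discretized exactly.

    Exponential smoothing with factor exp(-cutoff dt); unit DC gain; zero
    initial state.
    """
    if cutoff <= 0:
        raise ValidationError(f"cutoff must be positive, got {cutoff}")
    alpha = math.exp(-cutoff * dt)
    y = np.empty_like(np.asarray(u, dtype=float))
    prev = 0.0
    for i, ui in enumerate(u):
        prev = alpha * prev + (1.0 - alpha) * ui
        y[i] = prev
    return y


def chattering_index(
    traj: Trajectory, window_fraction: float = 0.2
) -> tuple[float, float]:
    """Sign-change rate (1/s) and peak-to-peak amplitude of the detrended
    control over the final window_fraction of the horizon.

    The trend is a centered moving average of half-width 50 samples
    (i.e. +/- 50*dt seconds); a window shorter than 10 samples is rejected.
    """
    t, u = traj.t, traj.u
    n = t.size
    start = int(math.floor((1.0 - window_fraction) * (n - 1)))
    uw = u[start:]
    tw = t[start:]
    if uw.size < 10:
        raise ValidationError(f"chattering window has {uw.size} samples; need >= 10")
    width = min(101, uw.size)
    kernel = np.ones(width) / width
    if uw.size > width:
        # centered moving average; the half-window edges where the trend
        # estimate is biased are excluded from the statistics
        trend = np.convolve(uw, kernel, mode="valid")
        half = width // 2
        detr = uw[half:half + trend.size] - trend
        tw = tw[half:half + trend.size]
    else:
        detr = uw - uw.mean()
    signs = np.sign(detr)
    nz = signs != 0
    changes = int(np.sum(signs[nz][:-1] * signs[nz][1:] < 0))
    duration = tw[-1] - tw[0]
    rate = changes / duration if duration > 0 else 0.0
    p2p = float(detr.max() - detr.min())
    return float(rate), p2p


@dataclass(frozen=True)
class PerformanceMetrics:
    """Time-response summary of one closed-loop run."""

    settling_time_s: float | None
    rise_time_s: float | None
    overshoot_pct: float
    steady_state_error_mg_dl: float
    chattering_rate_hz: float
    chattering_amplitude: float
    settled: bool


def compute_metrics(traj: Trajectory, config: SimulationConfig) -> PerformanceMetrics:
    st = settling_time(traj, config.G_ref, config.settling_band)
    return PerformanceMetrics(
        settling_time_s=st,
        rise_time_s=rise_time(traj, config.G_ref),
        overshoot_pct=overshoot(traj, config.G_ref, config.G0),
        steady_state_error_mg_dl=steady_state_error(traj, config.G_ref),
        chattering_rate_hz=chattering_index(traj)[0],
        chattering_amplitude=chattering_index(traj)[1],
        settled=st is not None,
    )


@dataclass
class ComparisonReport:
    """Per-controller metrics on one plant/config, plus a config fingerprint."""

    rows: list[tuple[str, PerformanceMetrics | None, str | None]]
    fingerprint: str

    def to_csv(self, path: str | Path) -> None:
        header = (
            "controller,settling_time_s,rise_time_s,overshoot_pct,"
            "steady_state_error_mg_dl,chattering_rate_hz,chattering_amplitude,"
            "settled,error,config_fingerprint"
        )
        def f(x):
            if x is None:
                return "not_settled"
            return format(x, ".10g")

        lines = [header]
        for name, m, err in self.rows:
            if m is None:
                lines.append(f'{name},,,,,,,,"{err}",{self.fingerprint}')
            else:
                lines.append(
                    ",".join(
                        [
                            name,
                            f(m.settling_time_s),
                            f(m.rise_time_s),
                            f(m.overshoot_pct),
                            f(m.steady_state_error_mg_dl),
                            f(m.chattering_rate_hz),
                            f(m.chattering_amplitude),
                            str(m.settled),
                            "",
                            self.fingerprint,
                        ]
                    )
                )
        Path(path).write_text("\n".join(lines) + "\n")


def compare_controllers(
    plant: StateSpaceModel,
    controllers: list[tuple[str, object]],
    config: SimulationConfig,
    dt_overrides: dict[str, float] | None = None,
) -> ComparisonReport:
    """Run every controller on the identical plant/config, one metrics row each.

    Individual simulation failures are recorded per row (error message) and
    do not abort the report.  ``dt_overrides`` maps controller names to
    per-controller integration steps (sliding-mode runs typically need a
    finer step to resolve switching).
    """
    if not controllers:
        raise ValidationError("at least one controller is required")
    rows = []
    for name, spec in controllers:
        cfg = config
        if dt_overrides and name in dt_overrides:
            cfg = replace(config, dt=dt_overrides[name])
        try:
            traj = simulate_closed_loop(plant, spec, cfg)
            rows.append((name, compute_metrics(traj, cfg), None))
        except Exception as exc:  # recorded, not fatal
            rows.append((name, None, f"{type(exc).__name__}: {exc}"))
    return ComparisonReport(rows=rows, fingerprint=config.fingerprint())
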