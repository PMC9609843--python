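"""Identified glucose-insulin plant model: construction, conversion, analysis.

The plant is a third-order discrete transfer function relating insulin input
to blood-glucose deviation,

    G(z) = -C0 / ((z - p1)(z - p2)(z - p3)),

identified from insulin-sweep experiments on virtual patients at a basal
operating point.  The gain is negative: insulin lowers glucose.  The poles
``p1, p2, p3`` lie in (0, 1) and vary from patient to patient; the nominal
patient has C0 = 0.132 and p = (0.965, 0.95, 0.93).

This module builds the discrete model, converts it to continuous time by
exact inverse zero-order hold, realizes it in state space, and analyzes its
structural properties (controllability, observability, unity-feedback
stability, frequency response).  A small virtual-patient cohort generator
perturbs the nominal parameters for robustness studies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg as sla
import scipy.signal as ssig

logger = logging.getLogger(__name__)

__all__ = [
    "PatientTFParams",
    "DiscreteTransferFunction",
    "ContinuousTransferFunction",
    "StateSpaceModel",
    "StructuralAnalysis",
    "ValidationError",
    "build_discrete_tf",
    "discrete_to_continuous",
    "printed_continuous_tf",
    "printed_state_space",
    "tf_to_state_space",
    "structural_analysis",
    "unity_feedback_poles",
    "frequency_response",
    "sample_patient_cohort",
    "save_model",
    "load_model",
    "NOMINAL_PATIENT",
]


class ValidationError(ValueError):
    """A model parameter violates its invariant; the message names the field."""


@dataclass(frozen=True)
class PatientTFParams:
    """Identified discrete model parameters for one virtual patient.

    C0 is the (positive) gain magnitude; the plant applies it with an
    explicit negative sign.  p1..p3 are discrete poles in (0, 1).  Ts is the
    sampling period in seconds (600 s by default; the printed continuous
    model is recovered from the discrete one at exactly this rate).
    """

    C0: float = 0.132
    p1: float = 0.965
    p2: float = 0.95
    p3: float = 0.93
    Ts: float = 600.0

    def __post_init__(self) -> None:
        if not (self.C0 > 0 and math.isfinite(self.C0)):
            raise ValidationError(f"C0 must be positive and finite, got {self.C0}")
        for name in ("p1", "p2", "p3"):
            p = getattr(self, name)
            if not (0.0 < p < 1.0):
                raise ValidationError(f"{name} must lie strictly in (0, 1), got {p}")
        if not self.Ts > 0:
            raise ValidationError(f"Ts must be positive, got {self.Ts}")

    @property
    def poles(self) -> tuple[float, float, float]:
        return (self.p1, self.p2, self.p3)


NOMINAL_PATIENT = PatientTFParams()


@dataclass(frozen=True)
class DiscreteTransferFunction:
    """Discrete transfer function, coefficients in descending powers of z."""

    num: np.ndarray
    den: np.ndarray
    Ts: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "num", np.atleast_1d(np.asarray(self.num, dtype=float)))
        object.__setattr__(self, "den", np.atleast_1d(np.asarray(self.den, dtype=float)))
        if self.den[0] != 1.0:
            raise ValidationError("denominator must be monic")
        if self.Ts <= 0:
            raise ValidationError(f"Ts must be positive, got {self.Ts}")

    @property
    def poles(self) -> np.ndarray:
        return np.roots(self.den)

    def dc_gain(self) -> float:
        """Gain at z = 1."""
        return float(np.polyval(self.num, 1.0) / np.polyval(self.den, 1.0))

    def is_stable(self) -> bool:
        return bool(np.all(np.abs(self.poles) < 1.0))


@dataclass(frozen=True)
class ContinuousTransferFunction:
    """Continuous transfer function with a monic denominator."""

    num: np.ndarray
    den: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "num", np.atleast_1d(np.asarray(self.num, dtype=float)))
        object.__setattr__(self, "den", np.atleast_1d(np.asarray(self.den, dtype=float)))
        if self.den[0] != 1.0:
            raise ValidationError("denominator must be monic")

    @property
    def poles(self) -> np.ndarray:
        return np.roots(self.den)

    @property
    def zeros(self) -> np.ndarray:
        return np.roots(self.num)

    def dc_gain(self) -> float:
        return float(self.num[-1] / self.den[-1])

    def is_hurwitz(self) -> bool:
        return bool(np.all(self.poles.real < 0.0))

    def __call__(self, s: complex | np.ndarray) -> complex | np.ndarray:
        return np.polyval(self.num, s) / np.polyval(self.den, s)


@dataclass(frozen=True)
class StateSpaceModel:
    """(A, B, C, D) realization with an explicit continuous/discrete tag."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: float = 0.0
    domain: str = "continuous"
    Ts: float | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        n = A.shape[0]
        if A.shape != (n, n):
            raise ValidationError(f"A must be square, got shape {A.shape}")
        B = np.asarray(self.B, dtype=float).reshape(n)
        C = np.asarray(self.C, dtype=float).reshape(n)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "D", float(self.D))
        if self.domain not in ("continuous", "discrete"):
            raise ValidationError(f"domain must be 'continuous' or 'discrete', got {self.domain!r}")
        if self.domain == "discrete" and (self.Ts is None or self.Ts <= 0):
            raise ValidationError("discrete models require a positive Ts")

    @property
    def order(self) -> int:
        return self.A.shape[0]

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(self.A)

    def is_stable(self) -> bool:
        lam = self.eigenvalues()
        if self.domain == "discrete":
            return bool(np.all(np.abs(lam) < 1.0))
        return bool(np.all(lam.real < 0.0))

    def transfer_function(self) -> ContinuousTransferFunction:
        num, den = ssig.ss2tf(
            self.A, self.B.reshape(-1, 1), self.C.reshape(1, -1), [[self.D]]
        )
        num = np.trim_zeros(num[0], "f")
        if num.size == 0:
            num = np.zeros(1)
        return ContinuousTransferFunction(num, den)


@dataclass(frozen=True)
class StructuralAnalysis:
    """Controllability/observability matrices, their ranks, and verdicts."""

    controllability: np.ndarray
    observability: np.ndarray
    rank_controllability: int
    rank_observability: int
    controllable: bool
    observable: bool


def build_discrete_tf(params: PatientTFParams) -> DiscreteTransferFunction:
    """Assemble G(z) = -C0 / ((z-p1)(z-p2)(z-p3)) for one patient."""
    den = np.poly(params.poles)  # monic by construction
    return DiscreteTransferFunction(num=np.array([-params.C0]), den=den, Ts=params.Ts)


def discrete_to_continuous(dtf: DiscreteTransferFunction) -> ContinuousTransferFunction:
    """Exact inverse zero-order-hold conversion of a stable discrete model.

    The discrete system is realized in controllable canonical form and the
    continuous matrices recovered through the matrix logarithm:

        A_c = log(A_d) / Ts,   B_c = A_c (A_d - I)^{-1} B_d.

    Continuous poles equal ln(p_i)/Ts and the DC gain is preserved exactly.
    With the nominal patient and Ts = 600 s this reproduces every printed
    coefficient of the reference continuous plant to 3 significant figures.
    """
    poles = dtf.poles
    if np.any(poles.real <= 0) or np.any(np.abs(poles.imag) > 1e-12):
        raise ValidationError(
            "inverse zero-order hold requires real positive discrete poles, "
            f"got {poles}"
        )
    if not dtf.is_stable():
        raise ValidationError(f"discrete poles must lie inside the unit circle, got {poles}")
    n = dtf.den.size - 1
    num = np.zeros(n)
    num[n - dtf.num.size:] = dtf.num  # pad to strictly proper
    Ad = np.zeros((n, n))
    Ad[0, :] = -dtf.den[1:]
    Ad[1:, :-1] = np.eye(n - 1)
    Bd = np.zeros(n)
    Bd[0] = 1.0
    Ac = sla.logm(Ad) / dtf.Ts
    Bc = Ac @ np.linalg.solve(Ad - np.eye(n), Bd)
    numc, denc = ssig.ss2tf(Ac.real, Bc.real.reshape(-1, 1), num.reshape(1, -1), [[0.0]])
    numc = numc[0][1:]  # strictly proper: drop the zero s^n coefficient
    return ContinuousTransferFunction(numc, denc)


#: Printed coefficients of the reference continuous plant (numerator and
#: monic cubic denominator).  This is the canonical plant used by every
#: reproduction simulation.
_PRINTED_NUM = np.array([-8.263e-5, 4.022e-7, -6.61e-10])
_PRINTED_DEN = np.array([1.0, 2.658e-4, 2.26e-8, 6.14e-13])


def printed_continuous_tf() -> ContinuousTransferFunction:
    """The verbatim printed continuous plant G(s)."""
    return ContinuousTransferFunction(_PRINTED_NUM.copy(), _PRINTED_DEN.copy())


def printed_state_space() -> StateSpaceModel:
    """The verbatim printed (A, B, C, D) fixture.

    The fixture is tagged ``discrete``: its characteristic invariants
    (trace 2.805, second invariant 2.6228, determinant 0.8172) are those of
    a zero-order-hold discretization of the identified plant, not of the
    printed continuous transfer function.  Note that the printed 4-figure
    rounding of A moves a tightly clustered eigenvalue slightly outside the
    unit circle (real root approx. 1.017), so the fixture as printed is not
    stable under either domain reading; it is kept for structural analysis
    and as a comparison fixture, while closed-loop simulations use the
    canonical realization of the printed continuous transfer function.
    """
    A = np.array([[2.805, -1.311, 0.8172], [2.0, 0.0, 0.0], [0.0, 0.5, 0.0]])
    B = np.array([0.5, 0.0, 0.0])
    C = np.array([0.0, 0.0, -0.264])
    return StateSpaceModel(A, B, C, 0.0, domain="discrete", Ts=600.0)


def tf_to_state_space(ctf: ContinuousTransferFunction) -> StateSpaceModel:
    """Controllable-canonical realization of a strictly proper cubic."""
    if ctf.den.size != 4:
        raise ValidationError(
            f"expected a degree-3 monic denominator, got degree {ctf.den.size - 1}"
        )
    if ctf.num.size > 3:
        raise ValidationError("numerator degree must be < 3 (strictly proper)")
    b = np.zeros(3)
    b[3 - ctf.num.size:] = ctf.num
    A = np.array([
        [-ctf.den[1], -ctf.den[2], -ctf.den[3]],
        [1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
    ])
    B = np.array([1.0, 0.0, 0.0])
    return StateSpaceModel(A, B, b, 0.0, domain="continuous")


def structural_analysis(ss: StateSpaceModel) -> StructuralAnalysis:
    """Kalman rank tests: Phi = [B, AB, A^2 B, ...], Psi = [C; CA; CA^2; ...]."""
    n = ss.order
    cols = [ss.B]
    rows = [ss.C]
    for _ in range(n - 1):
        cols.append(ss.A @ cols[-1])
        rows.append(rows[-1] @ ss.A)
    phi = np.column_stack(cols)
    psi = np.vstack(rows)
    rc = int(np.linalg.matrix_rank(phi))
    ro = int(np.linalg.matrix_rank(psi))
    return StructuralAnalysis(phi, psi, rc, ro, rc == n, ro == n)


def unity_feedback_poles(plant: ContinuousTransferFunction) -> np.ndarray:
    """Closed-loop poles of the unity negative-feedback loop 1 + G(s) = 0.

    For the printed plant at least one returned pole has positive real
    part: the raw loop is unstable and a controller is required.
    """
    char = np.polyadd(plant.den, plant.num)
    return np.roots(char)


def frequency_response(
    model: ContinuousTransferFunction, frequencies: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise |G(jw)| in dB and arg G(jw) in degrees; w must be > 0."""
    w = np.asarray(frequencies, dtype=float)
    if np.any(w <= 0):
        raise ValidationError("frequencies must be strictly positive rad/s")
    resp = model(1j * w)
    mag_db = 20.0 * np.log10(np.abs(resp))
    phase_deg = np.degrees(np.angle(resp))
    return mag_db, phase_deg


def sample_patient_cohort(
    n: int,
    seed: int,
    spread: float = 0.01,
    nominal: PatientTFParams = NOMINAL_PATIENT,
) -> list[PatientTFParams]:
    """Draw a deterministic virtual-patient cohort around the nominal model.

    Element 0 is always the nominal patient.  Each remaining patient
    perturbs (C0, p1, p2, p3) multiplicatively by N(0, spread); any pole
    pushed outside (0, 1) is clipped back with a logged warning.  The spread
    is capped below 5% to stay within the identified small-signal regime.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if not (0.0 <= spread < 0.05):
        raise ValidationError(f"spread must lie in [0, 0.05), got {spread}")
    rng = np.random.default_rng(seed)
    eps = 1e-6
    cohort = [nominal]
    for i in range(1, n):
        factors = 1.0 + spread * rng.standard_normal(4)
        c0 = max(nominal.C0 * factors[0], eps)
        ps = []
        for j, p0 in enumerate(nominal.poles):
            p = p0 * factors[j + 1]
            if not (0.0 < p < 1.0):
                clipped = min(max(p, eps), 1.0 - eps)
                logger.warning(
                    "patient %d: pole p%d=%.6g clipped to %.6g", i, j + 1, p, clipped
                )
                p = clipped
            ps.append(p)
        cohort.append(PatientTFParams(c0, *ps, Ts=nominal.Ts))
    return cohort


# -- flat TOML-style model import/export -------------------------------------

def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def save_model(
    path: str | Path,
    params: PatientTFParams,
    state_space: StateSpaceModel | None = None,
) -> None:
    """Write a patient model (and optional explicit realization) as flat TOML."""
    lines = [
        f"C0 = {_fmt(params.C0)}",
        f"p1 = {_fmt(params.p1)}",
        f"p2 = {_fmt(params.p2)}",
        f"p3 = {_fmt(params.p3)}",
        f"Ts = {_fmt(params.Ts)}",
    ]
    if state_space is not None:
        lines.append("")
        for key, mat in (("A", state_space.A), ("B", state_space.B), ("C", state_space.C)):
            flat = ", ".join(_fmt(v) for v in np.asarray(mat).ravel())
            lines.append(f"[{key}]")
            lines.append(f"values = [{flat}]")
        lines.append("[D]")
        lines.append(f"values = [{_fmt(state_space.D)}]")
        lines.append(f'domain = "{state_space.domain}"')
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: str | Path) -> tuple[PatientTFParams, StateSpaceModel | None]:
    """Read a model file written by :func:`save_model` (bit-exact round trip)."""
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    params = PatientTFParams(
        C0=data["C0"], p1=data["p1"], p2=data["p2"], p3=data["p3"], Ts=data["Ts"]
    )
    ss = None
    if "A" in data:
        A = np.array(data["A"]["values"], dtype=float).reshape(3, 3)
        B = np.array(data["B"]["values"], dtype=float)
        C = np.array(data["C"]["values"], dtype=float)
        D = float(data["D"]["values"][0])
        domain = data["D"].get("domain", "continuous")
        ss = StateSpaceModel(A, B, C, D, domain=domain,
                             Ts=params.Ts if domain == "discrete" else None)
    return params, ss
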