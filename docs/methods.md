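# Methods

## Plant model

The plant is a third-order linear deviation model of the glucose–insulin
response of a virtual T1DM patient, identified at a basal operating point:
insulin input (abstract "insulin units"; the source material never fixes
pmol/min vs U/h) maps to blood-glucose deviation (mg/dL) through

    G(z) = -C0 / ((z - p1)(z - p2)(z - p3)),

with nominal C0 = 0.132 and poles (0.965, 0.95, 0.93).  The DC gain is
-1077.55 mg/dL per insulin unit.  Being a deviation model, all signals are
excursions about the operating point; the simulator adds the reference
level back for reporting (G = y + G_ref).

**Sampling period.**  The identification sampling period is not part of the
printed record.  The default Ts = 600 s is adopted because exact inverse
zero-order-hold conversion of the discrete model at exactly this rate
reproduces every printed coefficient of the continuous reference plant to
3 significant figures (numerator and denominator); no other Ts does.  Ts is
exposed as a configuration parameter of the `derived` plant source.

**Discrete-to-continuous conversion.**  `discrete_to_continuous` implements
the exact inverse of zero-order-hold discretization through the matrix
logarithm, A_c = log(A_d)/Ts, B_c = A_c (A_d - I)^{-1} B_d.  Continuous
poles are ln(p_i)/Ts and the DC gain is preserved exactly.  This is both
the conversion named in the source material and the one that best matches
the printed coefficients, so no separate numerator-fitting step is needed.

**Realizations.**  Two state-space descriptions are exposed:

* `printed_tf` (default simulation plant): the controllable-canonical
  realization of the printed continuous transfer function.
* `printed_ss`: the verbatim printed (A, B, C, D) fixture.  Its
  characteristic invariants (trace 2.805, second invariant 2.6228,
  determinant 0.8172) identify it as a zero-order-hold discretization of
  the identified model — not a realization of the printed continuous
  transfer function (whose discrete invariants would be 2.845, 2.6977,
  0.85258) — so it carries a `discrete` domain tag.  Note a genuine
  numerical pathology: the three eigenvalues of the underlying exact matrix
  cluster near 1, and the printed 4-significant-figure rounding moves the
  real eigenvalue to about 1.0167, outside the unit circle.  The printed
  fixture as printed is therefore stable under *neither* domain reading.
  It is retained for structural analysis (controllability/observability,
  where it is exact and full-rank) and as a comparison fixture, while all
  closed-loop simulations default to `printed_tf`.

## Controllers

**PID.**  Continuous law u = kp e + ki ∫e + kd ė, realized discretely with
a trapezoidal integral (previous error taken as zero on the first sample)
and a backward-difference derivative (zero on the first sample), derivative
on error, no anti-windup, no derivative filter.  These are deliberate
minimal choices — the tuned design specifies none of these refinements —
and each is an extension point.  The tuned gains are
(kp, ki, kd) = (-1.51e-4, -2.75e-8, -0.207); negative because the plant
gain is negative.

**LQR.**  `lqr_design` dispatches on the plant's domain tag: continuous
algebraic Riccati equation with K = R⁻¹BᵀP, or discrete ARE with
K = (R + BᵀPB)⁻¹BᵀPA.  Stabilizability is checked by a PBH rank test
before solving, and every returned solution is verified stabilizing with a
relative ARE residual below 1e-8.  The published gain vector
K = (0.231, 0.4947, 0.4687) is shipped as a comparison fixture only: it
stabilizes the printed state matrix under neither the continuous reading
(max Re eig = +1.23) nor the discrete one (spectral radius 1.60).  A
dedicated test pins this negative result so it cannot be silently "fixed".
The toolkit always recomputes K from (Q, R) on the configured plant; with
Q = diag(0.001, 0.2341, 0.22) and R = 1 on the default plant this gives
K = (1.6297, 1.3278, 0.4690) — the third component agrees with the
published value, the others do not.

**Sliding-mode control.**  Surface s = c·x with c = (1, 2.5, 1); the
induced sliding polynomial λ² + 2.5λ + 1 is Hurwitz (poles -2, -0.5), as
required for stable order-reduced motion.  The control is u = u_eq +
u_disc with u_eq = -(a·x)/b cancelling the surface drift ṡ = a·x + b·u,
and u_disc = -k1 s - k2 sign(s) (k1 = 6, k2 = 9) enforcing the reaching
condition V̇ = -k1 s² - k2|s| ≤ 0.  sign(0) is defined as 0 so the control
stays bounded on the surface (configurable to ±1).  Two surface-dynamics
presets exist because the published coefficients
(2.416e-4, 5.7105e-4, -9.105e-5, b = 0.25) do not equal cᵀA, cᵀB for any
exposed realization (cᵀB = 0.5 on the printed fixture, 1.0 on the default
plant): the `printed` preset injects the literal published coefficients
(used for reproduction runs) and the `symbolic` preset computes cᵀA, cᵀB
from the configured plant.  `reaching_time_bound` gives the closed-form
bound (1/k1) ln(1 + k1|s0|/k2) (|s0|/k2 when k1 = 0) on the time to reach
the surface under ideal sliding dynamics.

## Closed-loop simulation

Deviation dynamics ẋ = Ax + B(u + d(t)), y = Cx, with the entire initial
deviation placed on the output-coupled third state:
x0 = (0, 0, (G0 - G_ref)/C3), the minimal assumption consistent with
y(0) = G0 - G_ref.  Defaults: G_ref = 70 mg/dL, G0 = 200 mg/dL, 2% settling
band (5% preset available), fixed-step classical RK4, dt = 0.1 s for the
linear loops and 0.01 s for sliding-mode runs (to resolve switching),
forward Euler available for comparison.  The PID is a sampled controller:
its output is held over each integration step.  LQR and SMC are evaluated
at every RK4 substage.  For linear laws without disturbance the RK4 step
reduces to a precomputed one-step propagator (identical arithmetic, much
faster), which is how multi-day PID horizons stay tractable.  Matched
disturbances enter through the input channel as a sinusoid (default
amplitude 1 unit, period 300 s) — small relative to k2, hence rejectable
by the switching term.

One caveat of the canonical-coordinates default: the output matrix of the
`printed_tf` realization has entries of order 1e-4..1e-10, so the initial
deviation maps to internal states of order 1e11 and the simulated glucose
passes through large non-physiological excursions before converging.
These trajectories are faithful to the configured linear model; they are
not physiological predictions.  The `printed_ss` realization keeps glucose
excursions monotone and physiological but is unstable as printed (above),
so it is not the default.

**Metrics.**  Settling time: earliest time after which |G - G_ref| stays
within band·|G(0) - G_ref| (0 for zero initial deviation; "not settled" if
the trajectory is outside the band at the horizon).  Rise time: 10–90%
deviation recovery.  Overshoot: excursion past the reference opposite to
the initial deviation, % of the commanded change.  Steady-state error:
mean |G - G_ref| over the final 5% of the horizon.  Chattering: on the
final 20% of the horizon, the control is detrended by a centered moving
average of half-width 50 samples (the half-window edges, where the trend
estimate is biased, are excluded) and summarized by the zero-crossing rate
(1/s) and the peak-to-peak amplitude.  The first-order low-pass
`low_pass_filter` (exact exponential-smoothing discretization, unit DC
gain) is the provided chattering mitigation.

**Chattering phenomenology (numerical observation).**  With sign(s)
evaluated at every RK4 substage, the four-stage average acts as a smoothed
sign and the closed loop converges to a spurious fixed point with s frozen
a few dt·k2 from the surface — no persistent switching.  Under forward
Euler the classic limit cycle appears: switching at the Nyquist rate
1/(2 dt) with amplitude ≈ 2(k1|s| + k2).  Chattering studies therefore use
the Euler integrator with the symbolic surface dynamics; a linear low-pass
preserves the crossing rate of the residual ripple but reduces its
amplitude by orders of magnitude, so chattering reduction is asserted on
the amplitude.

## Reproduction scope and known limitations

* The published settling-time trio (PID ≈ 430 s, LQR ≈ 113 s, SMC ≈ 15 s)
  is not reproducible from the printed model and gains: under the
  documented defaults the package obtains ≈ 3.06e5 s, 30.6 s and 29.7 s
  respectively.  The PID discrepancy is structural, not numerical — the
  tuned gains produce a control effort of order 0.02 units on a plant that
  needs order 3.6e3 units to move glucose 130 mg/dL in 430 s.  The
  qualitative claims *are* reproduced and asserted: strict ordering
  SMC < LQR < PID at both settling bands, sliding-mode steady state at
  70 mg/dL (mean 70.000 over the final 20 s), open-loop stability,
  unity-feedback instability, and the full Lyapunov/reaching/Riccati
  property suite.  One acceptance test states the published magnitudes
  verbatim and is expected to fail; it is kept red deliberately.
* The virtual-patient cohort generator perturbs (C0, p1, p2, p3)
  multiplicatively with Gaussian relative spread (< 5%, clipped to keep
  poles in (0,1)).  It emulates inter-patient parameter variation only; it
  does not model meals, exercise, CGM sensor noise, insulin-pump
  quantization, or intra-patient time variation, so passing cohort tests
  says nothing about those effects.
* No observer is designed: state-feedback laws assume full state access.
* Basal insulin appears only in the identification narrative and has no
  role in the deviation model; it is out of scope by design.
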