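# Methods

## Circuit model

The bipolar stimulation path is modelled as working interface + medium +
counter interface.  Each electrode–electrolyte interface is a non-ideal
double-layer capacitor — a constant-phase element (CPE) with impedance
Z = 1/(q·(j2πf)^n), phase −n·90° — in parallel with a Faradaic branch: a
charge-transfer resistance R_CT in series with an optional Faradaic
pseudo-capacitance CPE (q_f, n_f).  Whether that pseudo-capacitance sits in
series or parallel with R_CT is not experimentally resolved at this level
of description; series is adopted, and with q_f = 0 the branch reduces to
R_CT alone.  The medium is a lead resistance, a spreading resistance from
current crowding at the contact edge, and a bulk branch: extracellular
resistance R_EX in parallel with an intracellular path R_IN + C_IN
(C_IN = 0 — saline — opens the intracellular path).

Wiring configurations compose these blocks: a 4-contact measurement sees
the medium only, 3-contact adds the working interface, 2-contact adds both
interfaces.  The composition identities (2c = 3c + working interface;
3c − 4c = working interface) hold exactly by construction and are what the
delineation step in `eis` relies on.

### Time-domain CPE realisation

For transients, each CPE is realised as a series chain of parallel-RC rungs
with pole frequencies log-spaced over [1/(10·t_pw), 10/dt] (8 rungs per
decade by default), extended one decade below and half above the band so
the edges stay clean.  Rung resistances are solved by non-negative least
squares against the analytic CPE, weighted by 1/|Z| (relative fit);
positivity keeps the ladder passive.  Worst-case magnitude error across
n ∈ [0.3, 0.95] is ~3.4% over the band (asserted at 5% in the tests).
n ≥ 0.9995 and n ≤ 1e−6 are realised as an ideal capacitor and a resistor
respectively — a band-limited ladder cannot represent a true integrator or
a flat resistor outside its band, and the degenerate cases are exactly
solvable.

With all nonlinearities off the assembled state-space system is linear and
time-invariant; it is stepped exactly per sample with matrix exponentials
(one propagator per distinct segment current), so square-pulse responses of
RC networks match closed forms to machine precision.  The optional
Faradaic bias dependence g(V) = exp(γ|V|)/R_CT (one-branch,
Butler–Volmer-like; γ = 0 by default) makes the system stiffly nonlinear,
and the simulator switches to an implicit BDF integrator.

Sample-at-boundary convention: a sample falling exactly on a phase boundary
reads the *earlier* segment (left-continuous), so the sample at t = t_pw is
the end-of-cathodal-phase voltage — the read-out instant for the cathodal
excitation, chosen as the maximum polarization of a monotone charging phase.

## EIS analysis

* Delineation: pointwise complex subtraction of the 4-contact spectrum from
  the 3-contact spectrum; non-identical grids are resampled onto their
  intersection, linear in log f per real/imaginary part.
* Reactance extraction: |Im Z| interpolated log–log (exact for power laws,
  the natural local model for these spectra); no extrapolation.  The
  model-facing frequency defaults to 10 kHz — the principal frequency of a
  100 μs pulse — and is configurable (1 kHz is the conventional choice when
  parametrising impedance against diameter for charge-density comparisons);
  both uses are exposed through the same function.
* Diameter scaling: |Z_imag| = α·D^d1 fit as a line in log–log space.
* Circuit fitting: complex nonlinear least squares, residuals weighted by
  1/|Z|.  The bulk one-pole response carries only three identifiable
  degrees of freedom while the raw element list has four, so the
  intracellular branch is fit in the canonical form r_in = r_ex (and the
  generator emits media in the same form).  In saline (no intracellular
  branch) only the total series resistance is identifiable and is reported
  in the series element.  Elements the spectrum carries no information
  about (pinned at a bound or with a vanishing Jacobian column) are listed
  in `insensitive_`.

## CV window detection

The electrolysis onset is "sudden, unrestricted current growth".  The
detector estimates a baseline envelope from the central 40% of the
potential range (folding forward/reverse arms by potential-binning the
absolute current, which cancels capacitive hysteresis), then marks the
lowest potential on each arm where |i| exceeds 3× that envelope **and**
keeps growing for the remainder of the arm.  The ratio criterion makes the
detector invariant to uniform current scaling; the sustained-growth
condition rejects isolated noise spikes, which is why a derivative-only
criterion was not used.  An arm with no onset returns a NaN open-window
sentinel.  Both thresholds are exposed as settings and recorded in the
result.  The window used for safety limits is taken from the same wiring
configuration as the transient data, and that choice travels in the
window's metadata.

## Transient analysis

The access voltage is the intercept at t = 0⁺ of a line fit to |v| over
(0, t_pw/10] — back-extrapolation is robust to one-sample onset smearing,
where a single-sample step read is not.  The cathodal excitation is the
end-of-phase magnitude minus that intercept; negative estimates (possible
under noise) clamp to zero with a flag.  In 2-contact records this is the
total polarization (both interfaces) minus the access step; no attempt is
made to split working from counter polarization.

`find_imax` bisects any monotone excitation provider (measured library,
circuit simulator, or the fitted law) against |E_mc| to a 1 mV default
tolerance, verifying monotonicity on the bracket first; ≤ 60 iterations
always suffice at that tolerance.

## Excitation surface and safety limits

Cathodal potentials are negative; all fitting is done on magnitudes with
a > 0 and the sign restored at reporting.  Because the units of b depend on
the fitted exponents, inputs are scaled to (μA, μs, kΩ) before fitting and
the convention is recorded inside `SafetyParams`; helpers re-express
predictions for SI inputs transparently.

Fitting choices:

* Exponents are initialised from one-factor fits |V| = ln(k·x^m + 1) on the
  largest available subset where the other two factors are constant
  (log-linearised start), b from a decade grid 10⁻⁶…10² (multi-start — the
  ln(1+x) law has a flat region single starts stall in), a from
  max(V)/ln 10.  Exponents are box-bounded to (0, 3]; best sum of squares
  wins, ties broken by smaller parameter norm.
* Residuals are relative (log-excitation misfit) by default: the
  measurement noise is multiplicative, and the small-excitation records are
  what anchor b.  Under 1% noise on a 5×5×3 grid this recovers all five
  constants within 5%, where absolute residuals leave b uncertain at the
  ~30% level.  Plain volt residuals are available for data containing
  zero excitations.
* Adjusted R² = 1 − (1−R²)(N−1)/(N−p−1) with p the number of free
  parameters, computed on the linear (volt) scale.
* A design with a constant factor is rank-deficient for that factor's
  exponent; the fit refuses with the factor's name unless the exponent is
  frozen (`fix_k6=1.0` is the standard move for single-reactance data — the
  frozen factor's contribution is absorbed into b).

The current limit is the closed-form inverse of the law at |E_mc|; the
diameter-resolved limit substitutes |Z_imag| = α·D^d1 into it literally, so
the two forms are consistent by construction (note that this substitution
raises α to the power k6 together with the rest of the reactance).  The
Shannon comparison solves log₁₀(Q/A) = k − log₁₀ Q exactly:
Q = √(A·10^k) μC with A in cm², I = Q/t_pw.

Benchtop-to-in-vivo transfer refits only k6 (1-D bounded minimisation, log
misfit when all excitations are positive), keeping a, b, k2, k4; it reports
R² of predicted vs observed excitations and a paired t-test p-value.
Differences at numerical-precision scale are reported as p = 1 — a t-test
on them carries no evidence.

## Synthetic data generator

Every dataset is a deterministic function of (electrode spec, preset,
seed), and generator truth (circuit elements, reactance, window, excitation
constants, access resistance) is exported alongside, so each analysis stage
has an exact recovery target.

What the presets encode (trends with point anchors): reactance–diameter
exponents d1 = −1.67 (PtNR) / −1.61 (planar Pt) / −1.65 (PEDOT);
pulse-width exponents k4 = 0.9 / 1.1 / 0.8 respectively; in-vivo impedance
above benchtop (multipliers 1.5–2); electrolysis windows wider in vivo and
wider in the 2-contact configuration (+0.3 V per edge — both interfaces
share the applied potential); impedance exponent shifting to 1.08 for
insertion-type electrodes in vivo and 1.04 for surface strips.  The rate
constants b of the low-impedance materials are set so their modeled limits
exceed the Shannon boundary at microelectrode diameters — the behaviour
that distinguishes high-surface-area coatings from planar platinum, whose
preset stays below it.  The spreading resistance follows ρ·G/(4π) with an
empirical G(D, S) = (2π/D)(1 + 0.8/S): growing as contacts shrink, falling
as separation grows; the disc-spreading scale 2π/D anchors magnitude, and
the separation law is a trend-faithful free choice of the generator.
Medium resistivities: 0.7 Ω·m (phosphate-buffered saline), 3 Ω·m (cortical
tissue).  Device-to-device spread enters as seeded ~5% log-normal jitter on
the target reactance.

Noise defaults are 1% multiplicative on |Z| and transient samples and 1°
additive on phase — chosen to keep recovery well-posed at desk scale; no
instrument artifacts (drift, mains pickup, quantisation) are emulated.
Generated transients embed the excitation law directly: an instantaneous
access step r_access·I plus a polarization ramp reaching exactly the truth
V_elec at end of phase.  The default ramp is linear, which makes the
extractor's back-extrapolation split exact; a curvature knob bends it
sublinearly at the cost of a small, documented intercept bias.  CV sweeps
are a capacitive baseline C_eff·(scan rate) plus exponential onset branches
(steepness 100 V⁻¹) scaled to the baseline, so detection lands within a few
mV of the embedded window.

What passing tests therefore show: the analysis chain inverts data whose
generating process matches its assumptions (CPE + lumped elements,
multiplicative noise, abrupt electrolysis onsets).  They do not show that
real tissue obeys the lumped model, that real windows are abrupt, or that
the preset constants equal any particular electrode's.

## Problem sizes

Recovery suites use 5×5×3 excitation grids (50 seeds), 100-seed scaling and
geometric-factor series, 20-seed window detection, and 40-frequency spectra
over five decades — sizes at which every statistical assertion is stable
while the full suite stays interactive (a few seconds).

## Known limitations

* Electrolysis is treated as the damage criterion; chronic, neurobiological
  and mechanical damage modes are out of scope, so the computed limits are
  upper bounds on electrochemical safety only.
* The model is calibrated for cathodal-first biphasic square pulses; the
  anodal window E_ma is extracted but no anodal-first limit model is fit.
* Chronic impedance drift and electrode aging are not modelled; parameters
  describe an acute snapshot.
* Geometry enters only through lumped parameters and the empirical G —
  there is no spatially resolved field computation.
* The single-exponential Faradaic bias term is a one-branch approximation;
  fits of heavily Faradaic interfaces should treat γ as effective, not
  mechanistic.
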