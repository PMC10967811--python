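# Methods

## The duct model

The nasal passage is idealised as a straight, rigid, horizontal duct of
constant cross-section carrying unsteady, incompressible, fully
developed flow. Its two geometric parameters are the hydraulic diameter
`Dh = 4A/O` (area over wetted perimeter, metres) and an effective
channel length `L` (metres); the wall may carry a relative roughness
`eps_r` (dimensionless, 0 for the smooth nasal surrogate). The pressure
drop is the sum of a Darcy–Weisbach friction term and a plug-flow
inertial term,

    dP = L * [ 8 rho fD Q|Q| / (pi^2 Dh^5) + 4 rho/(pi Dh^2) dQ/dt ].

The friction term is written `fD * Q|Q|` rather than `fD * Q^2` so that
friction opposes the flow in both breathing directions; for positive
flow the two forms coincide. With laminar friction (`fD = 64/Re`) and
`dQ/dt = 0` the model reduces exactly to the Hagen–Poiseuille line
`dP = R_HP * Q`, `R_HP = 128 L mu/(pi Dh^4)` — this identity is a
property test at relative 1e-12.

Assumptions inherited from the idealisation: rigid walls (no
compliance, so `Dh` does not depend on pressure), no minor losses from
bends or area changes, fully developed flow (no entrance effects), and
constant air properties. Two fluid presets are shipped: standard-
condition air (rho = 1.225 kg/m^3, mu = 1.7894e-5 Pa s, the values used
by the simulation protocol) and a rounded-viscosity variant with
nu = 1.5e-5 m^2/s used for order-of-magnitude estimates such as the
Womersley number.

## Friction-factor policy

Three regimes are selectable. `laminar` uses 64/Re; `turbulent` uses
the explicit Haaland correlation

    1/sqrt(fD) = -1.8 log10[ (eps_r/3.7)^1.11 + 6.9/Re ];

`blended` (the default) takes `wt*f_lam + (1-wt)*f_turb` with a cosine
taper `wt(Re)` equal to 1 at Re <= 2000 and 0 at Re >= 4000. Only the
smoothness of the transitional weight is physically meaningful — the
true transitional friction factor is not well characterised — so the
taper was chosen for continuity and monotonicity with no extra
parameters; the band edges are configurable. Because `64/Re * Q|Q|` is
linear in Q, the laminar contribution is implemented in that analytic
form, which removes the apparent 0/0 at zero flow: the friction term
vanishes smoothly at Q = 0 under every policy and no special-casing of
the breathing-cycle turning points is needed.

The Haaland correlation is cross-checked in the tests against the
implicit Colebrook equation solved by bisection — an independent
smooth-pipe oracle, never the implementation path.

## Hysteresis

For sinusoidal flow `Q = Qmax sin(omega t)` the inertial term evaluated
at the zero-flow instants (|dQ/dt| = omega*Qmax) gives the loop width

    W = 8 rho L omega Qmax / (pi Dh^2),

and normalising by the peak laminar drop `R_HP * Qmax` gives

    W_rel = omega Dh^2 / (16 nu),

independent of both L and Qmax. The identity
`W_rel * R_HP * Qmax = W` is exact and is asserted at relative 1e-10.
The measured width is obtained by linearly interpolating the pressure
at each sign change of Q and averaging the absolute differences of
consecutive crossings, which for multi-cycle series is the per-cycle
mean. On generated loops the measurement converges to the closed form
with order >= 1 in the sample spacing; at the default 1000 samples per
cycle the error is far below the 1% test tolerance.

The direction of traversal of the loop follows directly from the model
(pressure leads flow through the inertial term); the package plots and
labels what the equations produce and takes no position on the
conflicting loop-direction conventions reported for clinical charts.

## Breathing waveforms and the synthetic generator

Two waveform kinds: `sine`, `Q = Qmax sin(omega t)`, with inspiration
taken as positive flow; and `negative_cosine`,
`Q = -Qmax cos(2 pi (t - t0)/tau)`, the transient-simulation boundary
condition that starts at peak inspiration after an initialisation
offset `t0` and counts inspiration as negative flow. Protocol presets:
Qmax = 600 mL/s with tau = 5 s (reference sine), and the same plus
t0 = 1 s over three cycles (negative cosine). Both integrate to an
inspired volume of `Qmax*tau/pi` per cycle — 955 mL at the preset
values, deliberately above quiet-breathing tidal volumes.

The generator evaluates the duct model at the analytic `(Q, dQ/dt)` —
finite differences are used only for imported CSV series, where the
truth is unknown — at a default 1000 samples per cycle (minimum
enforced: 50). Two noise channels emulate in vivo scatter:

* additive Gaussian pressure noise, per sample, standard deviation in
  Pa — instrument/turbulence scatter;
* breath-to-breath jitter of `Dh`, resampled once per cycle with a
  given coefficient of variation — a crude surrogate for the nasal
  cycle and posture effects.

Both are driven by one integer seed; identical (seed, parameters)
reproduce the series bitwise. The generator does **not** emulate
asymmetric inspiration/expiration shapes, pressure-dependent collapse
(compliance), intra-breath drift, or correlated noise; passing tests
therefore demonstrate correctness of the model and pipeline mechanics,
not fidelity to any particular patient's data.

Clinical four-quadrant charts are produced by signing the magnitudes:
`x = phase_sign * |dP|` (inspiration positive) and
`y = side_sign * phase_sign * |Q|` (right side positive), which places
right/left inspiration in the upper/lower right quadrant and right/left
expiration in the lower/upper left. This axis assignment is a
documented display convention reconstructed from the quadrant
placement; the underlying magnitudes are preserved exactly, and the
clinical literature's own sign conventions are internally inconsistent
enough that only the quadrant placement is treated as normative.

## Fitting

Both fits are single-parameter least-squares problems in `Dh`, solved
by bounded scalar minimisation (Brent-style, derivative-free) on
Dh in [1, 30] mm with absolute tolerance 1e-7 m — deterministic by
construction, no starting point or randomness. Residuals are unweighted
in dP (an optional |Q| weighting flag exists); inspiration and
expiration can be fitted separately or jointly, joint fits simply
concatenating the samples.

* **Fixed-length fit**: the steady model (`dQ/dt` dropped) at an
  assumed L, the convention used to compare passages at L = 0.1 m.
* **Hysteresis-constrained fit**: substituting
  `L = W pi Dh^2/(8 rho omega Qmax)` into the unsteady model gives
  `dP = (W/(omega Qmax)) * (fD Q|Q|/(pi Dh^3) + dQ/dt/2)`, with the
  measured W as a constraint; L is recovered afterwards from the same
  relation. The published variant of this fit applies the Haaland
  friction factor at all flowrates; that policy is selectable, and on
  loops generated in the laminar regime it measurably increases the
  residual relative to the blended policy — quantifying the model
  mismatch that variant accepts.

Noise-free round-trips on synthetic curves recover Dh to well within
0.5% (fixed-length) and Dh/L within 1%/3% (constrained); under 2%
additive pressure noise the median Dh error over 20 seeds stays below
5%. These figures are recomputed by `scripts/acceptance.py` on a
12-point randomized parameter grid (Dh 4–15 mm, L 0.05–0.15 m,
Qmax 200–800 mL/s, tau 3–8 s) — sizes chosen to cover the
physiological range while keeping the full run under a minute.

`resistance_at` reads dP off a chosen phase/sub-phase branch by linear
interpolation in Q and divides by the reference flowrate; zero flow and
out-of-range queries are errors, not extrapolations.

## CFD resolution diagnostics

Computed from per-cell tabular summaries only; the package never
touches solver fields. `y+ = sqrt(tau_w/rho) * y / nu`; the law of the
wall uses `u+ = y+` for y+ <= 5 and `u+ = ln(y+)/0.41 + 5` for
y+ >= 35. The buffer layer between is linearly interpolated in ln(y+)
between the two laws' endpoint values and always flagged `buffer`: no
universal profile exists there, and the flag marks the value as a
bracketed estimate. CFL = u dt/dx. Kolmogorov scales
`eta = (nu^3/eps)^(1/4)`, `tau_eta = (nu/eps)^(1/2)` (identity
`tau_eta = eta^2/nu` asserted at 1e-10); the WALE mixing length is
`l_LES = min(kappa y, 0.325 Delta)` with kappa = 0.4187 and Delta the
cube root of the cell volume.

The resolution report histograms `l_LES/eta` and `dt/tau_eta` (default
bin width 0.1, with 0.01 selectable — both conventions appear in
practice) and reports the fraction of cells with ratio > 1, the
under-resolution metric. Cells with eps <= 0 (laminar regions) are
excluded from the ratios and counted separately — treating them as
ratio 0 would silently dilute the exceedance fraction. Fractions are
invariant to cell ordering and bin width, and to consistent rescaling
of lengths and times.

Large-eddy-simulation datasets at realistic mesh sizes (tens of
millions of cells) are outside desk scale; the diagnostics pathway is
validated on constructed populations with known exceedance fractions
(e.g. exactly 3 of 100 cells built to exceed ratio 1) rather than on
archived CFD output.

## Numerical and interface choices

* Strict SI inside the library; mL/s and other display units exist only
  at the CSV/CLI boundary (the flow column name declares its unit).
* Floats are serialised in shortest round-trip representation and CSVs
  read with round-trip float parsing, so identical configs produce
  byte-identical files.
* Configs are flat YAML mappings hashed with SHA-256; every CLI stage
  logs one structured line with the config hash and seed.
* An occluded side in the bilateral-resistance combination is an
  explicit `None`, never 0 or infinity.
* Degenerate inputs fail loudly with typed errors (distinct CLI exit
  codes): zero-width constraint, all-zero flow, unidirectional series,
  zero-flow resistance queries, eps <= 0 microscales.

## Known limitations

The model omits minor losses, compliance, entrance effects, and any
transitional-flow physics beyond a smooth friction blend, so fitted
`Dh` and `L` are effective parameters of a surrogate, not anatomical
measurements — effective channel lengths recovered from real loops are
known to come out far shorter than the anatomical passage. The noise
model is uncorrelated and symmetric, unlike real RMM scatter. The
buffer-layer law-of-the-wall value is an interpolation convention, not
physics. Hysteresis here is purely inertial: a real loop also carries
compliance and start-up contributions the model cannot represent.
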