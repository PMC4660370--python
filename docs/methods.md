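# Methods

This note records the models implemented in `allokin`, the assumptions
behind them, the defaults that matter, and what the synthetic-data tests
do and do not demonstrate.

## Enzyme kinetics

**Rate laws.** Velocities are modelled at fixed co-substrate (NAD⁺ held at
0.5 mM in the emulated design, so no bi-substrate terms) by one of three
nested laws: Michaelis–Menten, competitive inhibition, and the hyperbolic
(partial) mixed-inhibition law

    v = Vmax (1 + βI/(αKi)) S / ( Km (1 + I/Ki) + S (1 + I/(αKi)) ).

This is the canonical partial mixed-type family: the inhibitor binds free
enzyme with dissociation constant Ki and the ES complex with αKi, and the
ternary ESI complex turns over at fraction β of the ES rate. All stated
limits hold algebraically: I = 0 recovers Michaelis–Menten; α → ∞
recovers competition; α = β = 1 removes the inhibitor's effect; I → ∞
gives v → βVmax·S/(αKm + S). At fixed I the law is exactly
Michaelis–Menten with Vmax_app = Vmax(1+βI/(αKi))/(1+I/(αKi)) and
Km_app = Km(1+I/Ki)/(1+I/(αKi)); the property suite checks this
consistency to machine precision.

**Fitting.** One weighted least-squares regression per candidate law over
the full (S, I) grid (lmfit/Levenberg–Marquardt), unweighted by default
with optional 1/v² weighting. Initial guesses: Vmax = 1.1·max v; Km = the
substrate level nearest half-maximal velocity; Ki = median nonzero I;
α = 2; β = 0.5. Bounds: all parameters positive, α ∈ (10⁻², 10⁶],
β ∈ [0, 10]; fits pinned at the α upper bound or the β zero bound are
flagged, not silently accepted. Per-level Michaelis–Menten fits are kept
for apparent-parameter diagnostics, and Hanes–Woolf linearizations
([S]/v vs [S]; slope 1/Vmax_app) include a common-slope vs
separate-slopes F-test, since parallel lines are the classical signature
of competition.

**Mechanism selection.** Corrected Akaike criterion (AICc, Gaussian
least-squares form with the noise variance counted as a parameter).
The lowest-AICc law wins, except that a simpler law within ΔAICc < 2 of
the winner is preferred and the result flagged ambiguous. This
indifference rule is what keeps a competitive dataset from being
over-fitted by the mixed law: two extra parameters must buy a decisive
likelihood gain.

**Initial velocities.** A340 progress curves are converted through
Beer–Lambert with ε₃₄₀(NADH) = 6220 M⁻¹cm⁻¹ and path length 1 cm. The
estimator fits a quadratic over the longest initial prefix it describes
cleanly (R² ≥ 0.999, ≥ 5 points) and reports the extrapolated slope at
t = 0. A straight-line prefix with an R² gate was considered and
rejected: R² is insensitive to the smooth curvature of a saturating
trace, so a linear prefix systematically underestimates v₀ (10–25% at
realistic designs in our simulations), while the quadratic's t = 0 slope
stays within a few percent.

## Titration calorimetry

**Model.** n identical independent sites. After injection i the total
concentrations in the V₀ = 200 μL cell follow the overfilled-cell
bookkeeping M_t = M₀(1 − ΔV/2V₀)/(1 + ΔV/2V₀),
X_t = X₀(ΔV/V₀)/(1 + ΔV/2V₀); the bound concentration is the smaller
root of the mass-balance quadratic; the cell heat content is
Q = V₀·ΔH·[MX]; and the injection heat carries the perfusion correction
ΔQᵢ = Qᵢ − Qᵢ₋₁ + (dVᵢ/V₀)(Qᵢ + Qᵢ₋₁)/2. The implementation is verified
against an independent brute-force equilibrium solver (per-injection
Brent root finding) to 10⁻⁸ relative on randomized protocols.

**Fitting.** Free parameters are n (optionally fixed), log₁₀Kd, ΔH and a
constant per-injection baseline absorbing dilution heats; the first
injection can be discarded. The Wiseman parameter c = n·M_t/Kd governs
identifiability: for c ≲ 1 the isotherm is nearly featureless and the
baseline becomes collinear with (Kd, ΔH), so the recovery analyses fix
n = 1 and omit the baseline (the generator adds no dilution heats);
both switches are explicit API flags, and c outside [0.01, 10⁶] is
flagged low-information. Thermodynamics: ΔG = RT ln Kd (Kd in molar,
R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹), −TΔS = ΔG − ΔH, an identity that holds
exactly by construction.

## SAXS

**Concentration series.** Curves are divided by concentration and, per q,
I/c is regressed linearly on c; the intercept is the infinite-dilution
curve with propagated uncertainty. A single concentration is returned
normalized with a warning.

**Guinier.** Weighted straight-line fit in (q², ln I). The window grows
from the lowest q until q·Rg = 1.3 (iterated to self-consistency,
≥ 8 points) and then shrinks from the high-q side until a Wald–Wolfowitz
runs test on the residuals shows no systematic trend (p ≥ 0.01; skipped
when residuals are at rounding level).

**P(r) and Dmax.** The pair-distance distribution is obtained by
penalized non-negative least squares: p on 101 uniform points of
[0, Dmax], endpoints pinned to zero, kernel 4π·sin(qr)/(qr), σ-weighted
residuals plus λ‖p″‖² smoothness, solved by NNLS; λ = 0 is refused as
ill-conditioned and "auto" selects the L-curve corner over a 7-point λ
grid. Rg and I(0) follow from the moments of p. Dmax is estimated by
scanning 14 candidates on [1.5, 4.5]·Rg (geometric spacing) and taking
the smallest whose p(r) decays to ≤ 1% of its peak over the terminal 5%
of [0, Dmax], refined by four bisection steps between the last failing
and first passing candidate; if none passes, the best-scoring candidate
is returned flagged.

**Porod volume and mass.** Q = ∫q²I dq is assembled from an analytic
Guinier extension on [0, q_min], the data trapezoid up to
q_cut = 0.25 Å⁻¹, and an A·q⁻⁴ tail with A = ⟨I·q⁴⟩ over the 0.05 Å⁻¹
below the cutoff (skipped with a warning if the tail estimate is
negative). Vp = 2π²I(0)/Q, and the mass estimate is Vp × 0.6 Da·Å⁻³
rounded to integer kDa — the convention that reproduces the published
volume→mass pairs; a particle is called a tetramer for
mw/(4·monomer) ∈ [0.8, 1.3), an octamer for [1.6, 2.4], and "other" in
the gap (no forced call).

**Debye profiles.** I(q) = Σᵢⱼ fᵢfⱼ·sin(qdᵢⱼ)/(qdᵢⱼ) over beads with
sphere-amplitude form factors (series expansion below x = 0.05 to avoid
cancellation) and volume-proportional weights. Cross terms are
histogrammed per radius-class pair with 0.5 Å bins, each bin represented
by its weighted mean distance; this matches the brute-force double sum
to better than 0.1% on the tested q range. No hydration shell or
excluded-volume contrast is modelled — profiles are vacuum bead sums,
sufficient for shape and size comparisons, not for absolute-scale
comparison with experimental contrast.

## Synthetic data

Generators are pure functions of (truth, design, seed) using
`numpy.random.default_rng`; identical seeds give identical datasets and
byte-identical files.

* **Kinetics**: IMP 2-fold dilution series 19.5–5000 μM, inhibitor 0 plus
  five log-spaced levels 20–5000 μM, 3 replicates;
  v_obs = v(1 + N(0, 2%)) + N(0, 0.002·Vmax) by default. The additive
  floor keeps low-velocity points from having unrealistically perfect
  relative precision.
* **ITC**: 19 × 2 μL injections of 300 μM ligand into 20 μM protein at
  25 °C; Gaussian heat noise with SD 2% of the isotherm's largest
  |injection heat| — the thermogram's own scale. (Scaling the noise to a
  hypothetical fully-bound injection instead would inflate it several-fold
  for weak binders and make Kd recovery at the stated precision impossible
  for any estimator.)
* **SAXS**: q ∈ [0.005, 0.35] Å⁻¹, 400 points; I(q,c) = c·I_Debye·
  (1 − k_sf·c·e^{−(q/q_sf)²}) with the interparticle term off by default;
  Poisson-like σ = 1%·√(I·I_max) plus a small floor. Bead geometries were
  calibrated once, before any test was written, to the measured
  hydrodynamics: each monomer is a core sphere (R 23 Å at radius 34.58 Å
  from the 4-fold axis) plus a finger sphere (R 14 Å at 65 Å); the
  octamer stacks two tetramers 42 Å apart with a 45° twist. This gives
  exact Rg 45.1/49.7 Å and geometric Dmax 158/158 Å for
  tetramer/octamer.

**What passing tests show — and don't.** Parameter recovery on these
generators demonstrates that the estimators are unbiased and correctly
calibrated *under the stated noise model*: independent Gaussian errors,
no baseline drift, no inter-injection correlation, no radiation damage,
no buffer-subtraction artefacts, and bead-level (not atomic) scattering
contrast. Real datasets violate all of these to some degree, so recovery
percentages here are upper bounds on real-data performance; the
structural conclusions (mechanism class, entropic penalty, volume
doubling) are robust qualitative signatures and transfer more reliably
than the error bars.

## Reporting conventions

Inhibition constants are reported to 2 significant figures in mM,
thermodynamic quantities to 1 decimal in kcal/mol, masses as integer kDa
— the precisions of the corresponding published tables. Velocity units
are canonical μM·min⁻¹ internally; since the reference tables carry no
velocity units, recovery assertions are unit-free on Km, Ki, α and β.
Pipeline reports are deterministic for a fixed config and seed (config
hash and seed recorded in provenance); exit codes are 0/2/3 for
success/validation/computation errors.

## Problem sizes

Recovery analyses use 20 seeds per kinetic condition (162-point grids),
5 titrations per ITC condition (19 injections each) and 10 seeds per
oligomeric state (3-concentration series, 400-point curves) — sizes at
which the medians are stable to well under the published uncertainties
while the whole acceptance run completes in seconds.

## Known limitations

* No substrate-inhibition, Hill or bi-substrate rate laws; no kcat
  normalization (enzyme mass varies across the emulated assays).
* Single-site ITC only; no multi-site, sequential or displacement
  models, and no raw-thermogram peak integration.
* The indirect Fourier transform uses a second-difference smoothness
  prior with L-curve λ selection, not a perceptual-criteria search; very
  anisotropic particles may need a manual λ or Dmax override.
* The Porod q_cut and tail conventions are one defensible choice among
  several; absolute volumes carry ~10% method uncertainty even on ideal
  curves (mass *ratios*, which drive classification, are much tighter).
* Oligomer calls outside the tetramer/octamer bands return "other"
  rather than guessing.
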