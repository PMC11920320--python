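# Methods

## Models

**Power-law growth (in vivo).** Tumor volume V (mm³) over time t (days)
follows `dV/dt = α V^β`, `V(t₀) = V₀`. For β ≠ 1 the closed form is
`V(t) = [V₀^(1−β) + α(1−β)(t−t₀)]^(1/(1−β))`. Fits use t₀ = 0, V₀ = 0:
the tumor is assumed present but unmeasurably small at injection, which
with β < 1 gives the well-defined `V(t) = [α(1−β)t]^(1/(1−β))`. A
consequence worth keeping in mind is that α carries units
mm^{3(1−β)}/day — α values are comparable across lines only as fitted
under this common convention (mm³, days, V₀ = 0). β = 1 is excluded: the
singularity in the closed form is removable (the exponential limit), but
the model family is defined by its non-exponential scaling. β > 1
produces finite-time blow-up at `T* = V₀^(1−β)/(α(β−1))`; the solver
reports T* when evaluated past it, and the synthetic generator only
produces β > 1 under an explicit opt-in flag.

**Logistic proliferation (in vitro).** Confluence N (% of dish area)
follows `dN/dt = ρN(1 − N/k)` with k fixed at 100 % (a full dish). The
solution is evaluated in the overflow-safe form
`N(t) = k / (1 + (k/N₀ − 1)e^{−ρt})`. Confluence is recorded hourly but
converted to days at ingest, so ρ is in 1/day, the same time base as the
in vivo models.

**Point-source diffusion.** Density obeys `u_t = DΔu + ρu` with
`u(x,0) = C₀δ(x)` in ℝ³; the solution is
`u(r,t) = C₀/(8(πDt)^{3/2}) · exp(ρt − r²/(4Dt))`. The detectable radius
(where u = u*) satisfies
`r*² = 4Dρt² − 4Dt·ln(8u*/C₀·(πDt)^{3/2})`; the log term is o(t²), so
asymptotically `r* ≈ 2√(Dρ)t` — the Fisher–KPP front speed. Since u* and
C₀ are unknown for real data, the estimator inverts only the asymptote:
`D_i = r_i²/(4ρt_i²)` per observation. The ratio u*/C₀ appears only in
exact-mode synthesis and in the closed-form error analysis (the relative
error of D_i is exactly `|ln(8u*/C₀·(πDt)^{3/2})|/(ρt)`, decaying in t);
its default 1e−3 is a synthesis setting, never an estimator input.

## Estimation

* Growth fits: unconstrained Levenberg–Marquardt on the summed squared
  volume residuals, seeds (α, β) = (0.9, 0.9). Iterates entering
  |β − 1| < 1e−6 are perturbed off the removable singularity, and a
  negative bracket (possible while iterates wander above β = 1) is
  floored so residuals stay finite. Optima with α ≤ 0 or β ∉ (0, 1.5)
  are reported with `converged=False` rather than silently accepted;
  non-convergence likewise never raises.
* R² is `1 − SS_res/SS_tot` with SS_tot about the observed mean (the
  standard definition).
* Logistic fits pool all replicate points of a (line, condition) group
  into one residual vector — this uses every observation, is invariant
  to replicate order, and matches reporting a single rate with a
  replicate count n. N₀ is pinned to the nominal seeding density (5 or
  10 %) by default; `n0_mode="first"` (mean of first observations) and
  `"fit"` (joint estimation) cover the alternative readings.
* The weighted rate `(ρ₅n₅ + ρ₁₀n₁₀)/(n₅+n₁₀)` is reported at 2 decimals
  in report tables; internal computation keeps full precision.
* Diffusion: D̄ is the mean of per-timepoint estimates, not the
  slope-derived value — an sd/CV summary only makes sense for a
  per-timepoint collection. The OLS radius fit (slope = front speed v,
  `D = v²/4ρ`) is retained as a cross-check. Sample (n−1) sd. The time
  origin is the injection day; t = 0 points are excluded (the estimator
  divides by t²), and appearance-time offsets are not applied — absolute
  time is used.
* Tier thresholds: α ≥ 0.80 High, ≥ 0.30 Medium high, ≥ 0.15 Medium,
  else Low; ρ_w at (1.70, 1.49, 1.20); D̄ at (8e−3, 1e−3, 3e−4) mm²/day.
  Lower bounds inclusive. These breakpoints are the midpoint separators
  of the reference panel's printed tier groupings (no boundary values are
  published); all are configurable. CV validity cutoff 0.5.
* β-clusters: nearest of {2/3, 3/4, 5/6} in absolute distance, ties to
  the smaller cluster. Applied to the reference panel's 17 exponents this
  reproduces the published three-group membership exactly.
* Correlations: Pearson on raw values by default (phenotype scores are
  treated as printed numeric levels, no rank transform); Spearman
  available. Panel assembly is an inner join — listwise deletion of any
  line missing a source table, each drop logged once.

## Synthetic data

The generator emulates the study conditions of the reference panel:
power-law volume trajectories with β ∈ (0.5, 0.9) and α spanning
0.08–2.18, sigmoid confluence saturating at 100 % from 5 %/10 % seeding,
linear-in-time radii, appearance days of 3–36 with windows clipped to the
3–172-day range (fast lines get short windows: the volume grid runs from
the appearance day until the trajectory reaches ~1000 mm³), and 3-hourly
confluence sampling over 0–120 h.

Noise defaults are volume_sigma = 0.05 (lognormal multiplicative — the
minimal positive-valued model for data spanning three orders of
magnitude) and confluence_sigma = 2.0 percentage points (additive
Gaussian clipped to [0.1, 100]). No observation-noise magnitudes are
published for these assays; these values produce the R² range seen in
the published fits (≳ 0.92) and are exposed in `NoiseSpec`.

Phenotype levels are constructed monotone in the kinetic parameters so
correlation tests carry signal: TL/CL/IL/ML track α and PL tracks the
weighted ρ. Scores use equal-width binning of the parameter range into
integer levels (1–4, PL 1–3) rather than rank quartiles — with a skewed
α spread, rank-quartile coding caps the Pearson correlation near 0.84,
whereas equal-width binning keeps the score approximately linear in the
parameter (ρ ≈ 0.95 on the reference α vector). TL/PL jitter is bounded
at ±0.2 level-units so quantization plus jitter cannot erase the designed
signal; the secondary assay scores get ±0.75 deliberately.

What passing tests on synthetic data do **not** show: the generator
draws from the same model families the pipeline fits, so recovery tests
certify the estimation machinery, not the adequacy of power-law/logistic
kinetics for real tumors; real digitized curves have serially correlated
digitization error, irregular sampling, and inter-animal variability
that the iid noise models omit.

## Numerical choices

* Fits run at ftol = xtol = 1e−12 with a 5000-evaluation budget; the
  problems are 1–2 parameter and converge in tens of iterations.
* The logistic solution's saturated tail underflows finite-difference
  resolution; ODE-consistency checks mask N > 99.5 %.
* ODE-consistency checks for the power law use a geometric time grid so
  the relative step (hence the O(h²) error) is uniform even for steep
  exponents 1/(1−β).
* Degenerate inputs raise typed errors: < 3 points for a 2-parameter
  fit, all-constant confluence, t = 0 in the diffusion estimator,
  negative volumes, duplicate (line, time) CSV keys (with row numbers),
  a still-undetectable tumor in exact-mode radius synthesis (with the
  offending time).
* Pipeline runs are deterministic under a fixed seed; the serialized run
  log drops timestamps so fixed-seed output trees are byte-identical.

## Problem sizes

Recovery suites use 200 replicates at 12 volume points or 41 confluence
points × 4 replicates; the PDE cross-check integrates a Crank–Nicolson
scheme on a 1000-node radial grid for 2000 steps; the full-panel runs use
the 17-line reference-scale panel. At these sizes the whole test suite
runs in a few seconds.

## Known limitations

* α is unit-coupled to β (see above); cross-study comparison of α values
  requires identical conventions.
* The diffusion estimator inherits the asymptotic approximation; for
  small ρt its bias is the log-term ratio, e.g. ~44 % at ρt = 15 and
  ~4 % at ρt = 90 under the default detection ratio.
* Constant D and ρ are assumed throughout; angiogenesis, necrotic cores,
  immune interaction and mechanical effects are out of scope.
* The CV < 50 % rule validates constancy of D over the window, not the
  reaction–diffusion model itself.
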