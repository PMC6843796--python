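# Methods

## Feature extraction

Daily weather and PM2.5 series are reduced to annual (or monthly) counts
of six events per city:

| counter | condition | convention |
|---|---|---|
| calm wind | wind speed < 1.5 m/s | strict |
| no precipitation | precipitation ≤ 0 mm | threshold configurable (`wet_threshold`, e.g. 0.1 mm for "no effective precipitation") |
| warming | T_d − T_{d−1} > 0 | strict; first day of each period contributes nothing |
| pressure drop | P_d − P_{d−1} < 0 | strict; same first-day rule |
| humid dry day | 60 % ≤ RH ≤ 90 % and precipitation-free | band inclusive at both ends |
| pollution day | 24-h mean PM2.5 > 75 μg/m³ | strict ("exceeds"); optional joint AQI-category criterion |

A 24-h mean above 75 μg/m³ already places the PM2.5 sub-index above the
"good" band, so the concentration-only rule is the default and the AQI
column, when present, enforces the joint criterion.  Change-day counters
never chain across period boundaries (no cross-year or cross-month
leakage).  Missing days are skipped, not imputed; `n_observed_days`
records actual coverage and a warning is logged below 90 %.  When monthly
counts are aggregated to a year, the two change-day counters can
undercount the annual computation by at most 11 boundary days.

## Panel assembly and the SD question

The frontier model needs a standard deviation for every cell, but annual
evaluation of yearbook indicators provides a single number per cell.
Rather than hide one guess, three strategies are implemented and
config-selected:

* **monthly** (default): day counters are summarised over the 12 monthly
  sub-counts; the annual mean is the monthly mean ×12 and the annual SD
  the monthly SD ×√12, treating months as independent.  Yearbook
  indicators have no sub-annual replication, so their SD defaults to a
  coefficient of variation of 5 % of the mean (`activity_cv`).
* **across-years**: mean and SD of each city–variable cell over a 4-year
  window (both sources must cover it).
* **zero-sd**: all SDs zero — the deterministic BCC mode, useful as a
  reduction check.

Variables enter untransformed; units live in the metadata sidecar and are
never rescaled silently.  (The radial model is invariant to rescaling a
variable together with its SD, which is also what makes the solver's
internal normalisation below legitimate.)

## Solving the chance-constrained program

The probabilistic constraints are made deterministic through the standard
normal quantile Φ⁻¹(α) and the per-cell SDs, exactly as stated in the
model (independent cells; the evaluated unit's own terms carry
(λ_o−1)² on the input side and (λ_o−θ)² on the output side; no
covariance terms).  The identity point (λ = e_o, θ = 1) is feasible for
every α, so θ\* ≥ 1 and the efficiency 1/θ\* lies in (0, 1].

Solution strategy, scipy only:

* **Internal scaling.** Every input/output column is divided by its
  largest mean, so all magnitudes are ≈ 1 and the absolute feasibility
  tolerance (10⁻⁷ certificates) is meaningful regardless of raw units.
  λ and θ are unchanged by this scaling.
* **Exact reductions.** α = 0.5 or all SDs zero ⇒ the program *is* the
  output-oriented BCC LP; solved with HiGHS.
* **α < 0.5 (Φ⁻¹ < 0).** The constraints are second-order-cone shaped and
  the program is convex: any local optimum is global.  Two shortcuts are
  exact: the α < 0.5 feasible set is contained in the BCC set, so if the
  BCC optimum is θ = 1 then θ\* = 1 with no NLP at all (this covers most
  units on realistic panels); otherwise SLSQP runs from the identity and
  BCC starts.
* **α > 0.5 (Φ⁻¹ > 0).** Nonconvex.  Multistart SLSQP from the identity
  point, the BCC solution, an optional warm start, and up to K = 20
  Dirichlet-random simplex points; the loop stops early after 6
  consecutive random starts fail to improve the incumbent by more than
  10⁻⁹ (`n_starts_used` reports the effort).  Best-of-starts is a
  documented approximation of the global optimum; on every instance small
  enough for exhaustive lattice search it matches the grid oracle to
  better than 10⁻² (tested).
* **Polish and certificates.** Every candidate λ (from any start) is
  projected onto the simplex and its exactly largest feasible θ is
  recomputed by bisection: input constraints do not involve θ, and per
  output the slack is convex in θ for Φ⁻¹ > 0 and non-increasing for
  Φ⁻¹ ≤ 0 (θ ≥ 1 ≥ λ_o), so the feasible θ-set within [1, θ_max] is an
  interval whose right endpoint bisection finds.  The returned solution
  therefore satisfies the constraints *as printed* (the tiny smoothing
  term used inside SLSQP for differentiability never reaches the result)
  and is re-checked to 10⁻⁷ before being emitted.  Ties among equally
  optimal candidates break toward minimal ‖λ‖₂.
* **Monotonicity by construction.** `efficiency_profile` sweeps an
  ascending α grid and warm-starts each level with the previous level's
  weights; since a fixed λ's polished θ is monotone in the quantile, the
  θ path is non-decreasing up to bisection precision (≪ 10⁻⁶).
* **Degenerate regime.** When Φ⁻¹(α)·σᴼᵣₒ exceeds ȳᵣₒ the output
  constraint cannot bind and θ is unbounded; θ is capped at 10⁶ and the
  result flagged `at-theta-bound`.

Numerical defaults: feasibility tolerance 10⁻⁸ inside SLSQP
(`ftol` 10⁻¹²), certificate tolerance 10⁻⁷, efficiency comparisons 10⁻⁶,
θ ∈ [1, 10⁶], "efficiency = 1" reporting tolerance 10⁻⁴.

## Influence attribution

Deleting a variable means removing its column — hence its constraint —
and re-solving; it never means zeroing.  Deletion relaxes the program, so
`eff_deleted ≤ eff_baseline` up to tolerance, which every scan checks.  A
(city, target, α) record is flagged `changed` when the efficiency moves
by more than `change_tol = 10⁻⁴` (efficiencies are conventionally read to
4 decimals and no tighter tolerance is defensible).  Group targets follow
the fixed variable system: MF {WS, NPD, PTC, NPC, RH}, ID {GOVIE},
SP {UR, PD, BCA}, T {CCO, NPTVO}, EU {EC, TCC}, EP {GCRBA}.  The two
regional schemes (Southern/Central/Northern 5+3+5 and coastal/inland
3+10) are hard-coded with a config override.  The procedure is
deliberately flag-based — it reports *whether* a factor matters per city
and risk level, not a marginal-effect magnitude.

## Grey relational screen

Deng's formulation with distinguishing coefficient ρ = 0.5 and
initial-value normalisation by default (mean-value and raw modes are
options): after normalisation, ξ(k) = (Δmin + ρΔmax)/(Δ(k) + ρΔmax) with
Δ(k) = |ref(k) − cmp(k)|, and the grade is the mean of ξ.  Identical
normalised series grade exactly 1; the grade is symmetric and every ξ(k)
is non-decreasing in ρ.  Grades can be computed across years within a
city or across cities within a year — both axes are supported because
either reading is defensible.

## Synthetic data: what it emulates, and what it does not

The weather generator produces AR(1) temperature (mean 16 °C, φ = 0.85,
innovation SD 2.5 °C) and pressure (1016 hPa, φ = 0.8, SD 3 hPa), Weibull
wind (shape 2, scale 2.5 m/s ⇒ ≈ 110 calm days/year), Bernoulli–gamma
precipitation (wet probability 0.35; gamma shape 0.7, scale 12 mm), and
two-regime normal RH (85 % wet / 68 % dry, SD 12, clipped to [0, 100]).
Daily PM2.5 is log-normal with log-level raised by each active disaster
condition, so the exceedance probability grows with the number of active
conditions; with null coupling the exceedance rate has the closed form
Φ̄(log(75/baseline)/σ).  Defaults put the disaster counters in plausible
annual ranges for a humid subtropical climate; they are documentation
values, not estimates for any real region.  One RNG substream per
variable is split off the seed with `SeedSequence.spawn`, so every
sub-series is independently reproducible.

Planted DEA panels provide ground truth: unit 0 dominates all non-planted
units (small inputs, strictly largest output); each further frontier unit
holds the strict minimum of a dedicated input column, which forces
λ = e_o in its own evaluation and guarantees efficiency 1 at zero noise;
the planted influencer holds the strict global minimum of one input and
slack-large values of all others, so exactly that input's deletion moves
its efficiency.  Cell SDs are `noise_cv` × mean (default 5 %).

What passing these tests shows: the solver, the reductions, the
monotonicity mechanism, the deletion logic and the counters are correct
on data with the *assumed* statistical structure.  What they do not show:
anything about real panels — real weather has seasonality, spatial
correlation between cities and measurement gaps; real socioeconomic
indicators are strongly collinear; and with 14 inputs and 13 units the
deterministic frontier saturates (most units efficient at α ≤ 0.5), so
real-world discrimination rests entirely on the high-α stochastic regime
and on the quality of the SD estimates, which observational sources
rarely pin down.

## Problem sizes used in verification

Reduction/monotonicity/certificate checks: 50 random panels of 13 units ×
14 inputs × 1 output at CV 0.1 across the nine-level α grid.  Oracle
agreement: 20 instances with n ≤ 3, m ≤ 2 at α = 0.95 against an
exhaustive simplex lattice (step 0.01).  Planted-factor recovery: 50
seeded panels (8 units, 5 inputs, influencer at the last unit/input),
single-variable scans at α ∈ {0.8, 0.9, 0.95}.  Counter exactness: 100
synthetic years against one-line predicate filters.  These sizes were
chosen as the smallest that exercise the full study geometry.
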