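# Methods

## Problem

Repeated behavioral assays (here: daily open-field trials of laboratory
mice) mix several sources of variation: novelty-driven exploration that
decays as the animal habituates, stable between-individual differences
("animal personality"), strain and batch effects, and residual noise.  A
measurement protocol is only reliable once between-individual differences
are stable, which is a stronger requirement than a falling group mean.  The
package quantifies this with repeatability — the intraclass correlation of
a grouping factor under a variance-component model — and turns its
trajectory over the habituation series into a concrete recommendation for
how many habituation days a comparable experiment needs.

## Model

For a response measure `y` (one value per animal × day) the package fits the
Gaussian random-intercept model

    y = X β + Σ_g Z_g u_g + ε,
    u_g ~ N(0, σ²_g I),   ε ~ N(0, σ²_ε I),

where each grouping factor g (animal, strain, experiment/batch) contributes
an independent random intercept per level; crossed factors simply enter as
separate terms.  The fixed part is an intercept plus optional categorical
covariates (treatment coding, reference = lexicographically smallest
level).  Agreement repeatability of factor g is

    R_g = σ²_g / (Σ_h σ²_h + σ²_ε),

with fixed-effect variance excluded from the denominator throughout;
adjusted repeatability conditions on covariates (e.g. strain) by moving
them into the fixed part, so their variance leaves numerator and
denominator alike.  "Enhanced" repeatability (fixed-effect variance in the
denominator) is deliberately not offered.

### Estimation

Variance components are estimated by REML (ML is available for sensitivity
analysis).  Writing V = σ²_ε·W with W = I + Z Λ Z′, the fixed effects and
σ²_ε are profiled out analytically and the search runs over
θ_g = log(σ²_g/σ²_ε), bounded to [−20, 20].  All likelihood pieces are
reduced to q-dimensional quantities (q = total number of group levels) via
the Woodbury identity; for a single grouping factor Z′Z is diagonal and an
objective evaluation is O(q) vector arithmetic.  This is what makes
resampling-based inference (≈10⁵ refits in the coverage study) affordable.

Numerical choices:

* single factor: bounded scalar minimization (xatol 1e-9);
* several factors: L-BFGS-B from three deterministic starts (equal shares,
  residual-dominant θ = −3, group-dominant θ = +2), followed by a
  Nelder–Mead polish (fatol 1e-10).  The polish matters: near a boundary
  the profiled surface is almost flat along ridges and finite-difference
  quasi-Newton steps stall a few 1e-5 log-likelihood units short of the
  optimum.  After polishing, fits agree with lme4 to ~1e-8 in
  log-likelihood on study-sized three-factor data;
* components whose share of total variance falls below 1e-8 at the optimum
  are clamped to exactly 0 and flagged as boundary estimates;
* optimization is deterministic — identical input gives identical output.

The reported restricted log-likelihood follows the lme4 convention
(−2ℓ = (n−p)·log σ̂²_ε + log|S| + log|X′W⁻¹X| + (n−p)(1 + log 2π)), so
restricted likelihoods of models with identical fixed effects are directly
comparable.

### Inference

* **Bootstrap CI** — parametric: simulate responses from the fitted model
  (fresh intercepts per level, fresh residuals), refit, recompute R;
  percentile interval (linear interpolation) at [2.5%, 97.5%], 500
  replicates by default.  One set of refits serves every factor of a
  multi-factor model.  Non-convergent replicates are dropped and counted; a
  warning is attached when more than 10% fail.
* **Permutation test** — residuals of the reduced model (the model without
  the focal factor; remaining random effects enter the fitted values via
  their BLUPs) are permuted, the full model refit, and R recomputed; 100
  permutations by default with the observed statistic counted as one, so
  the smallest achievable p is 1/n_permut.  When n! ≤ n_permut (tiny
  tables) all permutations are enumerated and the p-value is exact.
  Refits reproduce the observed statistic only to optimizer precision, so
  tail counts use a 1e-6 tolerance on the [0, 1] R scale.
* **Likelihood-ratio test** — 2(ℓ_full − ℓ_reduced) on restricted
  log-likelihoods, floored at 0.  Because σ² = 0 lies on the boundary of
  the parameter space, the null distribution is the equal mixture
  ½χ²₀ + ½χ²₁ and the χ²₁ tail probability is halved (p = 0.5 at
  statistic 0).  Empirical size at α = 0.05 is 0.03–0.07 in the
  acceptance simulation.
* p-values are never reported as exactly 0.

### Day-effect statistics

Complete-case Friedman test (animals missing any day are dropped and
counted) with mid-ranks within animal and the tie-corrected rank-sum
statistic, referred to χ² on k−1 df; the statistic matches
`scipy.stats.friedmanchisquare` exactly and the χ² p sits inside the exact
permutation bracket on desk-scale tables.  Dunn's many-to-one comparisons
against day 1 use z = |R̄_ctrl − R̄_d| / sqrt(k(k+1)/(6n)) with Bonferroni
correction over the k−1 comparisons (the convention of common graphing
software for this design).  Per-day summaries are means with two-sided
t-based 95% CIs — the interval construction for such tables is not
standardized across tools, so these are diagnostics, not an inferential
surface.  Normal Q-Q diagnostics pair order statistics with standard-normal
quantiles at plotting positions (i − ½)/n and report the quantile-pair
correlation.

## Sliding windows and the habituation recommendation

Repeatability is re-estimated on every window of `width` (default 3)
consecutive observed days — days 1..7 give the five windows 1–3 … 5–7 —
with a **single** random factor per series (the multi-factor model is
reserved for the full-period analysis).  Windows spanning gaps in the day
set are excluded and logged.  Per-window resampling seeds are
`base_seed + window_index`, making windows independently reproducible.

The plateau rule converts a trajectory into a recommendation.  Window w is
*stable* when

1. R_w ≥ ρ_min (default 0.4),
2. its bootstrap CI excludes zero (toggleable), and
3. |R_w − R_v| ≤ δ (default 0.15) for every later window v.

For the earliest stable window starting at day s with width k:
first_repeatable_day = s, minimum_habituation_days = s − 1, and
recommended_habituation_days = s + k − 2 (measuring from the window's last
day onward keeps the whole observation period inside the stable regime).
The overall recommendation is the maximum across measures; if any measure
has no stable window the report flags that habituation should be extended.
The rule is a deliberate formalization of informal "the series has
plateaued" reasoning; defaults were fixed once so that the canonical
habituation shape (one unstable novelty window, then a ~0.5–0.6 plateau)
yields a three-day recommendation, and all three knobs are exposed on the
CLI.  Raising ρ_min can only delay the recommendation (tested property).
No changepoint model or sequential test is attempted.

## Synthetic data

The generator produces the structure the analysis assumes, with known
ground truth:

    y_{i,d} = μ + ν·exp(−(d−1)/τ) + w_d·a_i + s_strain(i) + b_batch(i) + e_{i,d}

with a_i ~ N(0, σ²_a), s ~ N(0, σ²_s), b ~ N(0, σ²_b),
e_{i,1} ~ N(0, (κσ_ε)²) and e_{i,d>1} ~ N(0, σ²_ε).  Day 1 deviates by two
independent mechanisms: attenuated personality expression (w₁ = 0.3 < 1)
and inflated residual noise (κ = 2) — the data cannot distinguish "the
animal does not yet express its personality" from "day-1 behavior is noise
from stress or anxiety", so both knobs exist and either can be switched off.
κ's default is a plausible setting, not an estimate.

The study-sized scenario has 68 animals (38 C57BL/6J, 15 BALB/cJ,
15 129S1/SvImJ), 7 daily trials and 2 experimental batches.
Distance-travelled-like defaults (cm): μ = 350, ν = 590, τ = 0.6 days,
σ_a = 110, σ_s = 60, σ_b = 20, σ_ε = 120, giving a day-1 population mean of
940 cm decaying to ≈351 cm, and a steady-state single-factor animal share
of ≈0.53 once strain and batch are conflated into the between-animal term.
The activity scenario rescales the same structure to percent units
(μ = 30.5, ν = 31, σ_a = 10, σ_s = 5.5, σ_b = 1.5, σ_ε = 8.5); both
calibrations place the expected day-1 and day-5 means inside the published
per-day dispersion bands that anchor them.

What the generator does **not** emulate: within-animal autocorrelation of
residuals, within-trial time series, correlation between measures of the
same animal (distance and activity are drawn independently), non-Gaussian
responses, and sex or age structure.  Passing recovery tests therefore
demonstrate correctness of the estimators under the model's own
assumptions, not robustness to real-data violations of them.

### Problem sizes used in tests and the acceptance script

Monte-Carlo studies run at sizes chosen to give decisive checks at desk
scale: recovery and CI coverage use 200 replicates of 50 animals × 5 days
with 500 bootstrap draws each; LRT size uses 1000 null replicates; the
recommendation study uses 100 study-sized draws with 100 bootstrap draws
per window; exact enumerations use 4-observation and 3×3 tables.  Strain
and batch draws (3 and 2 levels) cannot yield convergent empirical variance
estimates, so the large-n decomposition check (10⁴ animals) targets the
animal and residual components.

## Known limitations

* Independent random intercepts only: no random slopes, correlated effects,
  heteroscedastic residuals (beyond the generator's day-1 κ), or
  non-Gaussian families.
* Percentile bootstrap intervals at a variance boundary pile up at 0 and
  are known to under-cover slightly in small samples.
* The permutation scheme (residual permutation under the reduced model) is
  one of several defensible conventions; with multiple random factors the
  reduced model retains the non-focal factors.
* With three strains the strain component rests on three draws; its CI is
  wide and its point estimate unstable — a design limitation of such data,
  not of the estimator.
* The plateau rule's δ compares point estimates and ignores their sampling
  covariance; at n ≈ 68 animals the recommendation can shift by a day
  between draws (the modal recommendation across seeds is stable).
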