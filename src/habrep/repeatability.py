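"""Agreement and adjusted repeatability with resampling-based inference.

Repeatability (intraclass correlation) of a grouping factor g is the share
of total random variation attributable to that factor,

    R_g = sigma2_g / (sum_h sigma2_h + sigma2_e),

the sum running over every random factor in the fit (agreement
repeatability: fixed-effect variance is excluded from the denominator).
Inference:

* percentile confidence intervals from a parametric bootstrap (simulate from
  the fitted model, refit, recompute R),
* permutation p-values from residual permutation under the reduced model
  (the model without the focal factor),
* likelihood-ratio tests of sigma2_g = 0 with the boundary-corrected null
  distribution 0.5 * chi2_0 + 0.5 * chi2_1 (the tail probability is halved).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace
from itertools import permutations as _all_permutations

import numpy as np
from scipy import stats

from .behavior_io import BehaviorTable
from .errors import SettingsError
from .vc_lmm import (
    LMMFit,
    ModelSpec,
    build_design,
    fit_design,
    fit_vc_lmm,
    fitted_values,
    ols_restricted_loglik,
    simulate_from_fit,
)

# observed-statistic comparison tolerance: a refit of the unpermuted data
# reproduces R-hat only to optimizer precision (and y-hat + residuals only to
# float rounding), so counts use R* >= R-hat - EPS on the [0, 1] R scale
_PERM_EPS = 1e-6

_P_FLOOR = 1e-300  # p-values are never reported as exactly 0


@dataclass(frozen=True)
class ResamplingSettings:
    """Bootstrap/permutation sizes, seed and CI quantiles."""

    n_boot: int = 500
    n_permut: int = 100
    seed: int = 0
    ci_quantiles: tuple[float, float] = (2.5, 97.5)

    def __post_init__(self):
        if self.n_boot < 1 or self.n_permut < 1:
            raise SettingsError("n_boot and n_permut must be >= 1")
        lo, hi = self.ci_quantiles
        if not (0.0 < lo < hi < 100.0):
            raise SettingsError("ci_quantiles must be strictly increasing within (0, 100)")


@dataclass
class LMMFitSummary:
    """Serializable summary of the underlying fit."""

    response: str
    random_factors: tuple[str, ...]
    fixed_factors: tuple[str, ...]
    variances: dict[str, float]
    residual: float
    boundary: dict[str, bool]
    fixed_effects: dict[str, float]
    loglik: float
    n_obs: int
    group_counts: dict[str, int]


def summarize_fit(fit: LMMFit) -> LMMFitSummary:
    return LMMFitSummary(
        response=fit.spec.response,
        random_factors=fit.spec.random_factors,
        fixed_factors=fit.spec.fixed_factors,
        variances=dict(fit.vc.variances),
        residual=fit.vc.residual,
        boundary=dict(fit.vc.boundary),
        fixed_effects=dict(fit.fixed_effects),
        loglik=fit.loglik,
        n_obs=fit.n_obs,
        group_counts=dict(fit.group_counts),
    )


@dataclass
class RepeatabilityResult:
    """Point estimate plus bootstrap CI, permutation p and boundary-corrected LRT p."""

    factor: str
    R: float
    ci: tuple[float, float]
    p_lrt: float
    p_permut: float
    lrt_statistic: float
    fit: LMMFitSummary
    settings: ResamplingSettings
    n_boot_used: int = 0
    n_boot_failed: int = 0
    warnings: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Point estimate
# ---------------------------------------------------------------------------

def point_repeatability(fit: LMMFit, factor: str) -> float:
    """R_g = sigma2_g / (sum of all random variances + residual variance)."""
    if factor not in fit.vc.variances:
        raise KeyError(f"{factor!r} is not a random factor of this fit "
                       f"(have {list(fit.vc.variances)})")
    return fit.vc.variances[factor] / fit.vc.total


def _seed_for(settings: ResamplingSettings, label: str) -> np.random.SeedSequence:
    # stage/factor-specific deterministic streams; keyed by name so results
    # do not depend on the order factors are listed
    return np.random.SeedSequence([settings.seed % (2 ** 31), zlib.crc32(label.encode())])


# ---------------------------------------------------------------------------
# Parametric bootstrap
# ---------------------------------------------------------------------------

def bootstrap_samples(fit: LMMFit, settings: ResamplingSettings,
                      factors: tuple[str, ...] | None = None):
    """Bootstrap replicates of R for each requested factor.

    Simulates ``n_boot`` responses from the fitted model, refits the same
    model to each, and recomputes every factor's repeatability from the
    refit, so one set of refits serves all factors of a multi-factor model.
    Returns (samples dict factor -> array, n_failed).
    """
    factors = factors or fit.spec.random_factors
    rng = np.random.default_rng(_seed_for(settings, "__bootstrap__"))
    rep_seeds = rng.integers(0, 2 ** 31 - 1, size=settings.n_boot)
    design = fit._design
    out = {f: [] for f in factors}
    n_failed = 0
    for b in range(settings.n_boot):
        y_star = simulate_from_fit(fit, int(rep_seeds[b]))
        try:
            refit = fit_design(design.with_new_y(y_star), fit.spec)
        except Exception:
            n_failed += 1
            continue
        for f in factors:
            out[f].append(point_repeatability(refit, f))
    return {f: np.asarray(v) for f, v in out.items()}, n_failed


def _percentile_ci(samples: np.ndarray, quantiles: tuple[float, float]) -> tuple[float, float]:
    lo, hi = np.percentile(samples, quantiles, method="linear")
    return float(lo), float(hi)


def bootstrap_ci(table: BehaviorTable, spec: ModelSpec, factor: str,
                 settings: ResamplingSettings) -> tuple[float, float]:
    """Percentile bootstrap CI for R of one factor (seeded, reproducible)."""
    fit = fit_vc_lmm(table, spec)
    samples, n_failed = bootstrap_samples(fit, settings, (factor,))
    return _percentile_ci(samples[factor], settings.ci_quantiles)


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def _reduced_fit_and_residuals(table: BehaviorTable, spec: ModelSpec, factor: str):
    """Fitted values and residuals of the model without the focal factor.

    When other random factors remain, their BLUPs are part of the fitted
    values (so only the putative factor-g signal is destroyed by permuting);
    with none remaining the reduced model is the fixed-effects OLS fit.
    """
    reduced = spec.without(factor)
    full_design = build_design(table, spec)
    y = full_design.y
    if reduced is None:
        X = full_design.X
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        yhat = X @ beta
    else:
        rfit = fit_vc_lmm(table, reduced)
        yhat = fitted_values(rfit, include_random=True)
    return full_design, yhat, y - yhat


def permutation_test(table: BehaviorTable, spec: ModelSpec, factor: str,
                     settings: ResamplingSettings) -> float:
    """Permutation p-value for the repeatability of ``factor``.

    The null ensemble is built by permuting the reduced-model residuals,
    adding back the reduced-model fitted values, refitting the full model
    and recomputing R.  For tiny tables (n! <= n_permut) all permutations
    are enumerated and p = #{R* >= R-hat} / n! exactly; otherwise
    n_permut - 1 random permutations are drawn and the observed value counts
    as one permutation, p = (1 + #{R* >= R-hat}) / n_permut (so the smallest
    achievable p is 1 / n_permut).
    """
    if settings.n_permut < 2:
        raise SettingsError("n_permut must be >= 2 for a permutation test")
    full_fit = fit_vc_lmm(table, spec)
    r_obs = point_repeatability(full_fit, factor)
    design, yhat, resid = _reduced_fit_and_residuals(table, spec, factor)
    n = len(resid)

    def r_star(perm: np.ndarray) -> float:
        refit = fit_design(design.with_new_y(yhat + resid[perm]), spec)
        return point_repeatability(refit, factor)

    if math.factorial(n) <= settings.n_permut:
        count = sum(r_star(np.asarray(p)) >= r_obs - _PERM_EPS
                    for p in _all_permutations(range(n)))
        return count / math.factorial(n)

    rng = np.random.default_rng(_seed_for(settings, f"__permute__{factor}"))
    count = 0
    for _ in range(settings.n_permut - 1):
        if r_star(rng.permutation(n)) >= r_obs - _PERM_EPS:
            count += 1
    return (1 + count) / settings.n_permut


# ---------------------------------------------------------------------------
# Likelihood-ratio test
# ---------------------------------------------------------------------------

def lrt(table: BehaviorTable, spec: ModelSpec, factor: str) -> tuple[float, float]:
    """Boundary-corrected LRT of sigma2_factor = 0.

    statistic = 2 (l_full - l_reduced) on restricted log-likelihoods with
    identical fixed effects, floored at 0; the null is the equal mixture of a
    point mass at 0 and chi2_1, so p = 0.5 * P(chi2_1 >= statistic)
    (p = 0.5 when the statistic is 0).
    """
    full = fit_vc_lmm(table, spec)
    reduced = spec.without(factor)
    if reduced is None:
        ll_reduced = ols_restricted_loglik(build_design(table, spec), reml=spec.reml)
    else:
        ll_reduced = fit_vc_lmm(table, reduced).loglik
    statistic = max(0.0, 2.0 * (full.loglik - ll_reduced))
    p = max(0.5 * float(stats.chi2.sf(statistic, df=1)), _P_FLOOR)
    return statistic, p


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _assemble(table, spec, factor, fit, samples, n_failed, settings) -> RepeatabilityResult:
    warnings: list[str] = []
    used = len(samples)
    if n_failed > 0.10 * settings.n_boot:
        warnings.append(f"{n_failed}/{settings.n_boot} bootstrap replicates "
                        "failed to converge; CI may be unreliable")
    ci = _percentile_ci(samples, settings.ci_quantiles)
    statistic, p_lrt = lrt(table, spec, factor)
    p_permut = permutation_test(table, spec, factor, settings)
    return RepeatabilityResult(
        factor=factor,
        R=point_repeatability(fit, factor),
        ci=ci,
        p_lrt=p_lrt,
        p_permut=p_permut,
        lrt_statistic=statistic,
        fit=summarize_fit(fit),
        settings=settings,
        n_boot_used=used,
        n_boot_failed=n_failed,
        warnings=tuple(warnings),
    )


def rpt(table: BehaviorTable, response: str, random_factors, fixed_factors=(),
        settings: ResamplingSettings = ResamplingSettings()) -> dict[str, RepeatabilityResult]:
    """Multi-factor repeatability analysis: one result per random factor.

    A single multi-factor fit provides all point estimates and one shared
    set of bootstrap refits; permutation tests and LRTs are run per factor.
    Results are keyed by factor name and invariant to factor order.
    """
    spec = ModelSpec(response=response, random_factors=tuple(random_factors),
                     fixed_factors=tuple(fixed_factors))
    fit = fit_vc_lmm(table, spec)
    samples, n_failed = bootstrap_samples(fit, settings)
    return {
        f: _assemble(table, spec, f, fit, samples[f], n_failed, settings)
        for f in spec.random_factors
    }


def adjusted_repeatability(table: BehaviorTable, response: str, factor: str,
                           covariates, settings: ResamplingSettings = ResamplingSettings()
                           ) -> RepeatabilityResult:
    """Repeatability of ``factor`` adjusted for fixed covariates.

    Fits ``value ~ covariates + (1 | factor)``; the covariates' variance is
    absorbed by the fixed effects and leaves both numerator and denominator,
    so R = sigma2_factor / (sigma2_factor + sigma2_e).
    """
    covariates = tuple(covariates)
    spec = ModelSpec(response=response, random_factors=(factor,),
                     fixed_factors=covariates)
    fit = fit_vc_lmm(table, spec)
    samples, n_failed = bootstrap_samples(fit, settings, (factor,))
    result = _assemble(table, spec, factor, fit, samples[factor], n_failed, settings)
    warn = _confounding_warning(table, response, factor, covariates)
    if warn:
        result = replace(result, warnings=result.warnings + (warn,))
    return result


def _confounding_warning(table, response, factor, covariates) -> str | None:
    """Warn when a covariate is completely confounded with the grouping factor."""
    df = table.subset(response).data
    for cov in covariates:
        nunique_within = df.groupby(factor)[cov].nunique()
        groups_per_level = df.groupby(cov)[factor].nunique()
        if (nunique_within <= 1).all() and (groups_per_level <= 1).all():
            return (f"covariate {cov!r} is completely confounded with {factor!r}; "
                    "adjusted repeatability is not identified")
    return None
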