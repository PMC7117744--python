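"""Gaussian linear mixed models with independent random intercepts, by REML.

The model is

    y = X beta + sum_g Z_g u_g + eps,   u_g ~ N(0, sigma2_g I),  eps ~ N(0, sigma2_e I)

with one indicator matrix ``Z_g`` per grouping factor (crossed factors enter
as independent intercept terms).  Estimation maximizes the restricted
likelihood (ML is available for sensitivity checks) over the log
variance ratios ``theta_g = log(sigma2_g / sigma2_e)`` with the residual
variance and the fixed effects profiled out analytically.

Writing V = sigma2_e * W with W = I + Z Lambda Z', all likelihood pieces are
reduced to q-dimensional quantities (q = total number of group levels) via
the Woodbury identity, so a single objective evaluation costs O(q^3) rather
than O(n^3); for a single grouping factor Z'Z is diagonal and the evaluation
collapses to O(q) vector arithmetic.  This is what makes the parametric
bootstrap (hundreds of thousands of refits) tractable.

With S = I_q + Lambda^{1/2} Z'Z Lambda^{1/2}:

    -2 l_REML(theta) = (n-p) log s2 + log|S| + log|X' W^-1 X| + (n-p)(1 + log 2 pi)

where s2 = r' W^-1 r / (n-p) at the GLS coefficients, matching the REML
criterion used by lme4 (restricted log-likelihoods are therefore directly
comparable across nested random structures with identical fixed effects).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import linalg, optimize

from .behavior_io import BehaviorTable
from .errors import (
    ConvergenceError,
    DegenerateDataError,
    IdentifiabilityError,
)

# Numerical policy (fitting)
THETA_BOUNDS = (-20.0, 20.0)       # bounds on log variance ratios
SHARE_CLAMP = 1e-8                 # variance share below which a component is set to 0
FTOL = 1e-12                       # objective tolerance, quasi-Newton search
XTOL = 1e-9                        # parameter tolerance
MULTISTARTS = (0.0, -3.0, 2.0)     # equal-shares / residual-dominant / group-dominant

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Model specification and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Specification of a variance-component LMM on a behavioral table.

    ``response`` names the measure; ``fixed_factors`` are categorical
    covariates (intercept always included; empty list = intercept only);
    ``random_factors`` name the grouping columns receiving random intercepts.
    """

    response: str
    random_factors: tuple[str, ...]
    fixed_factors: tuple[str, ...] = ()
    reml: bool = True

    def __post_init__(self):
        object.__setattr__(self, "random_factors", tuple(self.random_factors))
        object.__setattr__(self, "fixed_factors", tuple(self.fixed_factors))
        if not self.random_factors:
            raise IdentifiabilityError("at least one random factor is required")
        overlap = set(self.random_factors) & set(self.fixed_factors)
        if overlap:
            raise IdentifiabilityError(f"factor(s) {sorted(overlap)} appear as both fixed and random")

    def without(self, factor: str) -> "ModelSpec | None":
        """Reduced spec with one random factor removed (None if none remain)."""
        remaining = tuple(f for f in self.random_factors if f != factor)
        if factor not in self.random_factors:
            raise KeyError(f"{factor!r} is not a random factor of this spec")
        if not remaining:
            return None
        return replace(self, random_factors=remaining)


@dataclass
class VarianceComponents:
    """Per-factor and residual variances (squared response units)."""

    variances: dict[str, float]
    residual: float
    boundary: dict[str, bool]

    @property
    def total(self) -> float:
        return sum(self.variances.values()) + self.residual

    def share(self, factor: str) -> float:
        return self.variances[factor] / self.total


@dataclass
class LMMFit:
    """A fitted variance-component LMM."""

    spec: ModelSpec
    fixed_effects: dict[str, float]
    vc: VarianceComponents
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    n_obs: int
    group_counts: dict[str, int]
    _design: "_Design" = field(repr=False, compare=False, default=None)


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

class _Design:
    """Precomputed sufficient statistics for fast repeated likelihood evaluation."""

    __slots__ = ("y", "X", "fixed_names", "factor_names", "codes", "levels",
                 "col_factor", "C", "cdiag", "ZtX", "Zty", "XtX", "Xty", "yty",
                 "n", "p", "q_per_factor")

    def __init__(self, y: np.ndarray, X: np.ndarray, fixed_names: list[str],
                 factor_names: list[str], codes: list[np.ndarray], levels: list[list[str]]):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.fixed_names = fixed_names
        self.factor_names = factor_names
        self.codes = codes
        self.levels = levels
        self.n, self.p = self.X.shape
        self.q_per_factor = [len(lv) for lv in levels]
        q = sum(self.q_per_factor)
        self.col_factor = np.concatenate([
            np.full(qg, g, dtype=int) for g, qg in enumerate(self.q_per_factor)
        ]) if q else np.zeros(0, dtype=int)

        # Z'Z: diagonal when a single factor (disjoint indicator columns)
        if len(factor_names) == 1:
            self.cdiag = np.bincount(codes[0], minlength=q).astype(float)
            self.C = None
        else:
            self.cdiag = None
            C = np.zeros((q, q))
            offs = np.cumsum([0] + self.q_per_factor)
            for g in range(len(factor_names)):
                for h in range(len(factor_names)):
                    block = np.zeros((self.q_per_factor[g], self.q_per_factor[h]))
                    np.add.at(block, (codes[g], codes[h]), 1.0)
                    C[offs[g]:offs[g + 1], offs[h]:offs[h + 1]] = block
            self.C = C

        self.ZtX = np.vstack([
            np.column_stack([np.bincount(c, weights=self.X[:, j], minlength=qg)
                             for j in range(self.p)])
            for c, qg in zip(codes, self.q_per_factor)
        ]) if q else np.zeros((0, self.p))
        self.XtX = self.X.T @ self.X
        self._set_y(self.y)

    def _set_y(self, y: np.ndarray) -> None:
        self.y = y
        self.Zty = np.concatenate([
            np.bincount(c, weights=y, minlength=qg)
            for c, qg in zip(self.codes, self.q_per_factor)
        ]) if len(self.codes) else np.zeros(0)
        self.Xty = self.X.T @ y
        self.yty = float(y @ y)

    def with_new_y(self, y: np.ndarray) -> "_Design":
        """Shallow copy sharing X/Z statistics, with response replaced."""
        new = object.__new__(_Design)
        for s in self.__slots__:
            setattr(new, s, getattr(self, s))
        new._set_y(np.asarray(y, dtype=float))
        return new

    def lam_to_columns(self, lam: np.ndarray) -> np.ndarray:
        return np.asarray(lam, dtype=float)[self.col_factor]


def build_design(table: BehaviorTable, spec: ModelSpec) -> _Design:
    """Assemble response, fixed-effect design and grouping codes for a spec."""
    df = table.subset(spec.response).data
    if len(df) < 2:
        raise DegenerateDataError("need at least 2 observations")
    y = df["value"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateDataError(f"response {spec.response!r} is constant")

    for name in spec.random_factors + spec.fixed_factors:
        if name not in df.columns:
            raise IdentifiabilityError(f"factor {name!r} is not a column of the table")

    # fixed part: intercept + treatment coding, reference = lexicographically smallest
    cols = [np.ones(len(df))]
    fixed_names = ["(Intercept)"]
    for f in spec.fixed_factors:
        lv = sorted(df[f].astype(str).unique())
        for level in lv[1:]:
            cols.append((df[f].astype(str) == level).to_numpy(dtype=float))
            fixed_names.append(f"{f}[{level}]")
    X = np.column_stack(cols)

    codes, levels = [], []
    for f in spec.random_factors:
        lv, code = np.unique(df[f].astype(str).to_numpy(), return_inverse=True)
        if len(lv) < 2:
            raise IdentifiabilityError(f"random factor {f!r} has a single level")
        codes.append(code.astype(int))
        levels.append([str(v) for v in lv])

    return _Design(y, X, fixed_names, list(spec.random_factors), codes, levels)


# ---------------------------------------------------------------------------
# Likelihood evaluation
# ---------------------------------------------------------------------------

def _whitened_pieces(design: _Design, lam: np.ndarray):
    """log|S|, X'W^-1 X, X'W^-1 y, y'W^-1 y for W = I + Z Lambda Z'."""
    lam_col = design.lam_to_columns(lam)
    if design.cdiag is not None:
        s = 1.0 + lam_col * design.cdiag
        logdetS = float(np.sum(np.log(s)))
        wl = lam_col / s
        XtWiX = design.XtX - design.ZtX.T @ (design.ZtX * wl[:, None])
        XtWiy = design.Xty - design.ZtX.T @ (wl * design.Zty)
        ytWiy = design.yty - float(np.sum(wl * design.Zty ** 2))
        return logdetS, XtWiX, XtWiy, ytWiy
    d = np.sqrt(lam_col)
    S = np.eye(len(d)) + (d[:, None] * design.C) * d[None, :]
    cho = linalg.cho_factor(S, lower=True, check_finite=False)
    logdetS = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    A = d[:, None] * design.ZtX
    b = d * design.Zty
    SiA = linalg.cho_solve(cho, A, check_finite=False)
    Sib = linalg.cho_solve(cho, b, check_finite=False)
    XtWiX = design.XtX - A.T @ SiA
    XtWiy = design.Xty - A.T @ Sib
    ytWiy = design.yty - float(b @ Sib)
    return logdetS, XtWiX, XtWiy, ytWiy


def _gls(XtWiX, XtWiy, ytWiy):
    try:
        beta = linalg.solve(XtWiX, XtWiy, assume_a="pos")
    except linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise IdentifiabilityError("singular fixed-effects design") from exc
    qform = max(ytWiy - float(XtWiy @ beta), 1e-300)
    sign, logdet_XtWiX = np.linalg.slogdet(XtWiX)
    if sign <= 0:
        raise IdentifiabilityError("fixed-effects design is rank deficient")
    return beta, qform, logdet_XtWiX


def _profiled_m2ll(design: _Design, lam: np.ndarray, reml: bool):
    """-2 log-likelihood profiled over beta and sigma2_e; returns pieces."""
    logdetS, XtWiX, XtWiy, ytWiy = _whitened_pieces(design, lam)
    beta, qform, logdet_XtWiX = _gls(XtWiX, XtWiy, ytWiy)
    dof = design.n - design.p if reml else design.n
    sig2 = qform / dof
    if reml:
        m2ll = dof * math.log(sig2) + logdetS + logdet_XtWiX + dof * (1.0 + _LOG2PI)
    else:
        m2ll = dof * math.log(sig2) + logdetS + dof * (1.0 + _LOG2PI)
    return m2ll, sig2, beta


def loglik_at(design: _Design, lam: Sequence[float], sigma2_e: float, reml: bool = True) -> float:
    """Log-likelihood at given variance ratios and residual variance (beta profiled)."""
    lam = np.asarray(lam, dtype=float)
    logdetS, XtWiX, XtWiy, ytWiy = _whitened_pieces(design, lam)
    beta, qform, logdet_XtWiX = _gls(XtWiX, XtWiy, ytWiy)
    if reml:
        dof = design.n - design.p
        m2ll = (dof * math.log(sigma2_e) + logdetS + logdet_XtWiX
                + qform / sigma2_e + dof * _LOG2PI)
    else:
        m2ll = (design.n * math.log(sigma2_e) + logdetS
                + qform / sigma2_e + design.n * _LOG2PI)
    return -0.5 * m2ll


def restricted_loglik(table: BehaviorTable, spec: ModelSpec,
                      variances: VarianceComponents) -> float:
    """REML (or ML, per spec.reml) log-likelihood at the given variances.

    Fixed effects are profiled out; exact to linear-algebra precision.
    """
    if variances.residual <= 0:
        raise DegenerateDataError("residual variance must be positive")
    design = build_design(table, spec)
    lam = np.array([variances.variances[f] / variances.residual
                    for f in spec.random_factors])
    if np.any(lam < 0):
        raise DegenerateDataError("variances must be non-negative")
    return loglik_at(design, lam, variances.residual, reml=spec.reml)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _fit_design(design: _Design, reml: bool = True):
    """Optimize the profiled objective; returns (lam_hat, diagnostics)."""
    G = len(design.factor_names)
    lo, hi = THETA_BOUNDS

    def nll(theta):
        return _profiled_m2ll(design, np.exp(np.asarray(theta, dtype=float)), reml)[0]

    if G == 1:
        res = optimize.minimize_scalar(lambda t: nll([t]), bounds=(lo, hi),
                                       method="bounded",
                                       options={"xatol": XTOL})
        theta_hat = np.array([res.x])
        n_iter = int(res.nfev)
        success = bool(res.success)
        fun = float(res.fun)
    else:
        best = None
        n_iter = 0
        success = False
        for start in MULTISTARTS:
            r = optimize.minimize(nll, np.full(G, start), method="L-BFGS-B",
                                  bounds=[(lo, hi)] * G,
                                  options={"ftol": FTOL, "gtol": 1e-9, "maxiter": 500})
            n_iter += int(r.nit)
            if np.isfinite(r.fun) and (best is None or r.fun < best.fun - 0.0):
                best = r
            success = success or bool(r.success)
        if best is None:
            raise ConvergenceError("all optimizer starts failed",
                                   {"n_starts": len(MULTISTARTS)})
        # derivative-free polish: the profiled surface is nearly flat along
        # ridges when a component sits at the boundary, where quasi-Newton
        # steps based on finite-difference gradients stall early
        polish = optimize.minimize(nll, best.x, method="Nelder-Mead",
                                   options={"fatol": 1e-10, "xatol": 1e-8,
                                            "maxiter": 2000})
        n_iter += int(polish.nit)
        if np.isfinite(polish.fun) and polish.fun <= best.fun:
            theta_hat = np.clip(np.asarray(polish.x, dtype=float), lo, hi)
            fun = float(polish.fun)
        else:
            theta_hat = np.asarray(best.x, dtype=float)
            fun = float(best.fun)

    # final-gradient diagnostic (central differences on the objective)
    h = 1e-5
    grad = np.zeros(G)
    for g in range(G):
        tp = theta_hat.copy(); tp[g] = min(tp[g] + h, hi)
        tm = theta_hat.copy(); tm[g] = max(tm[g] - h, lo)
        grad[g] = (nll(tp) - nll(tm)) / (tp[g] - tm[g])
    diagnostics = {"n_iter": n_iter, "grad_norm": float(np.linalg.norm(grad)),
                   "objective": fun, "converged": success}
    if not np.isfinite(fun):
        raise ConvergenceError("objective not finite at optimum", diagnostics)
    return np.exp(theta_hat), diagnostics


def fit_design(design: _Design, spec: ModelSpec) -> LMMFit:
    """Fit a prepared design (used directly by resampling loops)."""
    lam_hat, diag = _fit_design(design, reml=spec.reml)
    m2ll, sig2, beta = _profiled_m2ll(design, lam_hat, spec.reml)

    # clamp components whose share of total variance is numerically zero
    sig2_g = lam_hat * sig2
    total = float(np.sum(sig2_g) + sig2)
    clamp = sig2_g / total < SHARE_CLAMP
    if np.any(clamp):
        lam_hat = np.where(clamp, 0.0, lam_hat)
        m2ll, sig2, beta = _profiled_m2ll(design, lam_hat, spec.reml)
        sig2_g = lam_hat * sig2

    vc = VarianceComponents(
        variances={f: float(v) for f, v in zip(design.factor_names, sig2_g)},
        residual=float(sig2),
        boundary={f: bool(c) for f, c in zip(design.factor_names, clamp)},
    )
    return LMMFit(
        spec=spec,
        fixed_effects={n: float(b) for n, b in zip(design.fixed_names, beta)},
        vc=vc,
        loglik=-0.5 * m2ll,
        converged=bool(diag["converged"]),
        n_iter=int(diag["n_iter"]),
        grad_norm=float(diag["grad_norm"]),
        n_obs=design.n,
        group_counts={f: q for f, q in zip(design.factor_names, design.q_per_factor)},
        _design=design,
    )


def fit_vc_lmm(table: BehaviorTable, spec: ModelSpec) -> LMMFit:
    """REML (default) fit of the variance-component LMM defined by ``spec``.

    Deterministic for fixed input: optimization uses fixed multi-starts and
    no random initialization.
    """
    return fit_design(build_design(table, spec), spec)


def ols_restricted_loglik(design: _Design, reml: bool = True) -> float:
    """Restricted log-likelihood of the fixed-effects-only model (all lam = 0)."""
    m2ll, _, _ = _profiled_m2ll(design, np.zeros(len(design.factor_names)), reml)
    return -0.5 * m2ll


# ---------------------------------------------------------------------------
# Simulation and BLUPs
# ---------------------------------------------------------------------------

def _factor_rng(seed: int, name: str) -> np.random.Generator:
    # per-factor streams keyed by the factor name, so that draws do not
    # depend on the order factors are listed in the spec
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2 ** 31), zlib.crc32(name.encode())])
    )


def simulate_from_fit(fit: LMMFit, seed: int) -> np.ndarray:
    """Parametric draw of a response vector aligned to the fit's input rows.

    Fresh random intercepts are drawn per group level from the fitted
    variances and fresh residuals from the fitted residual variance; the
    fixed-effect predictions are added.  Identical seeds give identical
    vectors.
    """
    design = fit._design
    if design is None:
        raise ValueError("fit carries no design; refit before simulating")
    if fit.vc.residual <= 0:
        raise DegenerateDataError("cannot simulate with zero residual variance")
    beta = np.array([fit.fixed_effects[n] for n in design.fixed_names])
    y = design.X @ beta
    for g, name in enumerate(design.factor_names):
        sd = math.sqrt(fit.vc.variances[name])
        u = _factor_rng(seed, name).normal(0.0, sd, size=design.q_per_factor[g])
        y = y + u[design.codes[g]]
    y = y + _factor_rng(seed, "__residual__").normal(
        0.0, math.sqrt(fit.vc.residual), size=design.n)
    return y


def fitted_values(fit: LMMFit, include_random: bool = True) -> np.ndarray:
    """X beta-hat, plus the BLUPs of every random intercept when requested."""
    design = fit._design
    beta = np.array([fit.fixed_effects[n] for n in design.fixed_names])
    yhat = design.X @ beta
    if not include_random:
        return yhat
    lam = np.array([fit.vc.variances[f] / fit.vc.residual
                    for f in design.factor_names])
    lam_col = design.lam_to_columns(lam)
    c_r = design.Zty - design.ZtX @ beta
    if design.cdiag is not None:
        u = lam_col * c_r / (1.0 + lam_col * design.cdiag)
    else:
        d = np.sqrt(lam_col)
        S = np.eye(len(d)) + (d[:, None] * design.C) * d[None, :]
        cho = linalg.cho_factor(S, lower=True, check_finite=False)
        u = lam_col * (c_r - design.C @ (d * linalg.cho_solve(cho, d * c_r, check_finite=False)))
    offs = np.cumsum([0] + design.q_per_factor)
    for g in range(len(design.factor_names)):
        yhat = yhat + u[offs[g]:offs[g + 1]][design.codes[g]]
    return yhat
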