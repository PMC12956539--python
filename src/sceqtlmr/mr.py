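"""Two-sample Mendelian randomization estimators and directionality filters.

All estimators consume a :class:`~sceqtlmr.sumstats.HarmonizedSet` and
return an :class:`MRResult`. The causal parameter is the effect of a one-SD
change in gene expression (in one immune cell type) on the outcome:

- Wald ratio (k = 1):      beta_out / beta_exp
- IVW (k >= 2):            weighted regression of beta_out on beta_exp
                           through the origin, weights 1 / se_out^2
- correlated IVW:          generalized least squares through the origin
                           with Sigma = diag(se_out) . R . diag(se_out)
- MR-Egger (k >= 3):       weighted regression with a free intercept;
                           the intercept tests directional pleiotropy
- weighted median (k >= 3): weight-interpolated median of per-variant
                           ratio estimates, bootstrap SE

Dispersion handling for IVW (the ``dispersion`` argument):

``"wls"`` (default)
    Multiplicative dispersion estimated from Cochran's Q without a floor,
    inference against t with k-1 degrees of freedom. This is exact
    weighted-least-squares inference: under the null with normal errors
    the test has exactly nominal size, and confidence intervals attain
    nominal coverage even when instrument-level noise over-disperses the
    residuals.
``"mre"``
    The convention of widely used MR tooling: standard error inflated by
    sqrt(Q/df) only when Q/df > 1, normal reference. Slightly
    conservative at small instrument counts.
``"fixed"``
    No inflation, normal reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .sumstats import HarmonizedSet

__all__ = [
    "MRResult",
    "TierConfig",
    "InsufficientInstrumentsError",
    "DegenerateInstrumentError",
    "IllConditionedLDError",
    "wald_ratio",
    "ivw",
    "ivw_correlated",
    "mr_egger",
    "weighted_median",
    "steiger_filter",
    "assign_tier",
    "bh_adjust",
]


class InsufficientInstrumentsError(ValueError):
    pass


class DegenerateInstrumentError(ValueError):
    pass


class IllConditionedLDError(np.linalg.LinAlgError):
    pass


@dataclass(frozen=True)
class TierConfig:
    """Two-level significance tiering: ``global`` below the across-genes
    threshold (0.05/150), ``potential`` below the per-cell-type threshold
    (0.05/14), ``nonsignificant`` otherwise."""

    global_threshold: float = 0.0003
    potential_threshold: float = 0.003

    def __post_init__(self):
        if not (0 < self.global_threshold < self.potential_threshold < 1):
            raise ValueError("need 0 < global < potential < 1")


@dataclass(frozen=True)
class MRResult:
    gene: str
    cell_type: str
    method: str  # wald | ivw | ivw_correlated | egger | weighted_median
    beta: float
    se: float
    pvalue: float
    n_snps: int
    egger_intercept: Optional[tuple[float, float, float]] = None  # (value, se, p)
    q_stat: Optional[tuple[float, int, float]] = None  # (Q, df, p)
    steiger_pass: bool = True
    tier: Optional[str] = None
    df: Optional[int] = None  # t reference when set, normal otherwise

    def __post_init__(self):
        if not (self.se > 0):
            raise ValueError("se must be positive")

    def with_tier(self, config: TierConfig = TierConfig()) -> "MRResult":
        return replace(self, tier=assign_tier(self.pvalue, config))

    @property
    def ci95(self) -> tuple[float, float]:
        # quantile matches the reference distribution of the p-value
        q = (1.959963984540054 if self.df is None
             else float(stats.t.ppf(0.975, self.df)))
        return (self.beta - q * self.se, self.beta + q * self.se)


def _clip_p(p: float) -> float:
    # keep p in (0,1]: extreme z-scores underflow the survival function
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def _norm_p(z: float) -> float:
    return _clip_p(2.0 * stats.norm.sf(abs(z)))


def wald_ratio(h: HarmonizedSet, second_order: bool = False) -> MRResult:
    """Single-instrument causal estimate beta_out / beta_exp.

    The default SE is the first-order delta approximation se_out/|beta_exp|;
    ``second_order=True`` adds the exposure-uncertainty term
    sqrt(se_out^2/beta_exp^2 + beta_out^2 se_exp^2 / beta_exp^4).
    """
    if h.k != 1:
        raise InsufficientInstrumentsError(f"wald_ratio needs k=1, got k={h.k}")
    bx, by = float(h.beta_exp[0]), float(h.beta_out[0])
    sx, sy = float(h.se_exp[0]), float(h.se_out[0])
    if bx == 0:
        raise DegenerateInstrumentError("exposure beta is zero")
    beta = by / bx
    if second_order:
        se = math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = sy / abs(bx)
    return MRResult(gene=h.gene, cell_type=h.cell_type, method="wald",
                    beta=beta, se=se, pvalue=_norm_p(beta / se), n_snps=1)


def _dispersed(beta: float, se_fe: float, Q: float, df: int,
               dispersion: str) -> tuple[float, float, Optional[int]]:
    """Apply the dispersion convention; returns (se, pvalue, t_df)
    where t_df is None for a normal reference."""
    if dispersion == "fixed":
        return se_fe, _norm_p(beta / se_fe), None
    s2 = Q / df if df > 0 else 1.0
    if dispersion == "mre":
        se = se_fe * math.sqrt(max(1.0, s2))
        return se, _norm_p(beta / se), None
    if dispersion == "wls":
        if s2 <= np.finfo(float).tiny:  # exact fit; fall back to fixed
            return se_fe, _norm_p(beta / se_fe), None
        se = se_fe * math.sqrt(s2)
        return se, _clip_p(2.0 * stats.t.sf(abs(beta / se), df)), df
    raise ValueError("dispersion must be 'wls', 'mre' or 'fixed'")


def ivw(h: HarmonizedSet, dispersion: str = "wls") -> MRResult:
    """Inverse-variance-weighted estimate (independent instruments).

    Weighted regression of beta_out on beta_exp through the origin with
    weights 1/se_out^2; k = 1 delegates to the Wald ratio. Cochran's Q and
    its chi-square p (df = k-1) are always reported.
    """
    if h.k == 1:
        return wald_ratio(h)
    x, y, sy = h.beta_exp, h.beta_out, h.se_out
    w = 1.0 / sy**2
    sxx = float(np.sum(w * x * x))
    if sxx <= 0:
        raise DegenerateInstrumentError("all exposure betas are zero")
    beta = float(np.sum(w * x * y)) / sxx
    se_fe = math.sqrt(1.0 / sxx)
    resid = y - beta * x
    Q = float(np.sum(w * resid**2))
    df = h.k - 1
    q_p = float(stats.chi2.sf(Q, df))
    se, p, t_df = _dispersed(beta, se_fe, Q, df, dispersion)
    return MRResult(gene=h.gene, cell_type=h.cell_type, method="ivw",
                    beta=beta, se=se, pvalue=p, n_snps=h.k,
                    q_stat=(Q, df, q_p), df=t_df)


def ivw_correlated(h: HarmonizedSet, dispersion: str = "wls",
                   ridge: float = 1e-6, ridge_max: float = 1e-3,
                   cond_cap: float = 1e12) -> MRResult:
    """IVW for correlated instruments: GLS through the origin.

    Sigma = D R D with D = diag(se_out) and R the LD correlation matrix;
    beta = (x' Sigma^-1 x)^-1 x' Sigma^-1 y. Near-singular R is ridged by
    adding ``ridge`` to the diagonal, escalating tenfold up to
    ``ridge_max``; if the condition number still exceeds ``cond_cap`` an
    :class:`IllConditionedLDError` is raised.
    """
    if h.ld is None:
        raise ValueError("harmonized set has no LD matrix")
    if h.k == 1:
        return wald_ratio(h)
    x, y, sy = h.beta_exp, h.beta_out, h.se_out
    R = np.asarray(h.ld, dtype=float)

    lam = ridge
    factor = None
    Sigma = None
    while True:
        Rl = R + lam * np.eye(h.k)
        Sigma = Rl * np.outer(sy, sy)
        try:
            if np.linalg.cond(Rl) <= cond_cap:
                factor = cho_factor(Sigma)
                break
        except np.linalg.LinAlgError:
            pass
        lam *= 10.0
        if lam > ridge_max:
            raise IllConditionedLDError(
                f"LD matrix remains ill-conditioned at ridge {ridge_max}")

    Sinv_x = cho_solve(factor, x)
    Sinv_y = cho_solve(factor, y)
    A = float(x @ Sinv_x)
    if A <= 0:
        raise DegenerateInstrumentError("all exposure betas are zero")
    beta = float(x @ Sinv_y) / A
    se_fe = math.sqrt(1.0 / A)
    resid = y - beta * x
    Q = float(resid @ cho_solve(factor, resid))
    df = h.k - 1
    q_p = float(stats.chi2.sf(Q, df))
    se, p, t_df = _dispersed(beta, se_fe, Q, df, dispersion)
    return MRResult(gene=h.gene, cell_type=h.cell_type, method="ivw_correlated",
                    beta=beta, se=se, pvalue=p, n_snps=h.k,
                    q_stat=(Q, df, q_p), df=t_df)


def mr_egger(h: HarmonizedSet) -> MRResult:
    """MR-Egger regression: slope is the causal estimate, the intercept
    (with its SE and p) tests directional pleiotropy.

    Instruments are oriented so every exposure beta is non-negative (the
    InSIDE orientation) before the weighted fit (weights 1/se_out^2). The
    residual scale is floored at 1 so the SE is never deflated below the
    fixed-effect level; p-values use t with k-2 degrees of freedom.
    """
    if h.k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs k>=3, got k={h.k}")
    flip = np.where(h.beta_exp < 0, -1.0, 1.0)
    x = h.beta_exp * flip
    y = h.beta_out * flip
    w = 1.0 / h.se_out**2
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    df = h.k - 2
    sigma = math.sqrt(float(res.scale))
    infl = 1.0 / min(1.0, sigma)  # floor residual scale at 1
    icpt, slope = float(res.params[0]), float(res.params[1])
    se_icpt = float(res.bse[0]) * infl
    se_slope = float(res.bse[1]) * infl
    if se_slope <= 0 or not np.isfinite(se_slope):
        raise DegenerateInstrumentError("Egger fit is degenerate")
    p_slope = _clip_p(2.0 * stats.t.sf(abs(slope / se_slope), df))
    p_icpt = _clip_p(2.0 * stats.t.sf(abs(icpt / se_icpt), df)) if se_icpt > 0 else 1.0
    return MRResult(gene=h.gene, cell_type=h.cell_type, method="egger",
                    beta=slope, se=se_slope, pvalue=p_slope, n_snps=h.k,
                    egger_intercept=(icpt, se_icpt, p_icpt))


def _interp_weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with linear interpolation at cumulative weight 0.5."""
    order = np.argsort(values, kind="stable")
    b = values[order]
    w = weights[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if 0.5 <= p[0]:
        return float(b[0])
    if 0.5 >= p[-1]:
        return float(b[-1])
    return float(np.interp(0.5, p, b))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000,
                    seed: Optional[int] = None) -> MRResult:
    """Weighted-median estimator (valid if >= 50% of weight is on valid
    instruments). Per-variant ratios beta_out_j/beta_exp_j are weighted by
    the inverse variance of the first-order ratio SE; the SE of the median
    comes from a parametric bootstrap with ``n_boot`` resamples.

    ``seed`` is required: the bootstrap is the only stochastic step in the
    estimator suite and must be reproducible.
    """
    if h.k < 3:
        raise InsufficientInstrumentsError(f"weighted median needs k>=3, got k={h.k}")
    if seed is None:
        raise ValueError("weighted_median requires an explicit bootstrap seed")
    if np.any(h.beta_exp == 0):
        raise DegenerateInstrumentError("zero exposure beta gives an undefined ratio")
    ratios = h.beta_out / h.beta_exp
    se_ratio = h.se_out / np.abs(h.beta_exp)
    w = 1.0 / se_ratio**2
    est = _interp_weighted_median(ratios, w)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx = h.beta_exp + h.se_exp * rng.standard_normal(h.k)
        by = h.beta_out + h.se_out * rng.standard_normal(h.k)
        bx = np.where(bx == 0, np.finfo(float).tiny, bx)
        r = by / bx
        boots[b] = _interp_weighted_median(r, w)
    se = float(np.std(boots, ddof=1))
    if se <= 0:
        raise DegenerateInstrumentError("bootstrap SE collapsed to zero")
    return MRResult(gene=h.gene, cell_type=h.cell_type, method="weighted_median",
                    beta=est, se=se, pvalue=_norm_p(est / se), n_snps=h.k)


# ---------------------------------------------------------------------------
# Steiger directionality


def steiger_filter(h: HarmonizedSet, n_exp: Optional[int] = None,
                   n_out: Optional[int] = None
                   ) -> tuple[Optional[HarmonizedSet], pd.DataFrame]:
    """Remove instruments that explain more outcome than exposure variance.

    Per variant, the variance explained is r^2 = z^2 / (z^2 + n - 2) with
    z = beta/se; a variant passes iff r2_exp > r2_out (strict, so a tie
    fails). Returns the filtered set (None when every variant fails) and a
    per-variant report with both r^2 values.
    """
    n_exp = h.n_exp if n_exp is None else n_exp
    n_out = h.n_out if n_out is None else n_out
    if n_exp < 10 or n_out < 10:
        raise ValueError("Steiger filtering needs sample sizes >= 10")
    z_exp = h.beta_exp / h.se_exp
    z_out = h.beta_out / h.se_out
    r2_exp = z_exp**2 / (z_exp**2 + n_exp - 2)
    r2_out = z_out**2 / (z_out**2 + n_out - 2)
    passed = r2_exp > r2_out
    report = pd.DataFrame({
        "variant_id": list(h.variant_ids),
        "r2_exp": r2_exp, "r2_out": r2_out, "steiger_pass": passed,
    })
    if not passed.any():
        return None, report
    if passed.all():
        return h, report
    keep = np.flatnonzero(passed)
    return h.subset(keep, reason="steiger fail"), report


# ---------------------------------------------------------------------------
# Multiplicity


def assign_tier(pvalue: float, config: TierConfig = TierConfig()) -> str:
    """Map a p-value to the two-level significance tier."""
    if not (0 < pvalue <= 1):
        raise ValueError("pvalue must lie in (0,1]")
    if pvalue < config.global_threshold:
        return "global"
    if pvalue < config.potential_threshold:
        return "potential"
    return "nonsignificant"


def bh_adjust(pvalues: Sequence[float], grouping: str = "global",
              groups: Optional[Sequence] = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``grouping="global"`` adjusts across all tests; ``"per_cell_type"``
    adjusts within each level of ``groups`` (required, same length).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0,1]")
    from statsmodels.stats.multitest import multipletests

    if grouping == "global":
        return multipletests(p, method="fdr_bh")[1]
    if grouping == "per_cell_type":
        if groups is None or len(groups) != p.size:
            raise ValueError("per_cell_type grouping needs a groups vector")
        adj = np.empty_like(p)
        groups = np.asarray(groups)
        for g in pd.unique(groups):
            mask = groups == g
            adj[mask] = multipletests(p[mask], method="fdr_bh")[1]
        return adj
    raise ValueError("grouping must be 'global' or 'per_cell_type'")
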