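"""Method-agreement and inference layer.

Everything needed to compare PAF estimators and EEG-age models with each
other and with chronological age: Pearson and partial correlations, the
Hotelling-Williams test for two dependent correlations sharing a variable,
Bland-Altman agreement, OLS with in-sample RMSE, paired t tests, MINQUE
variance components for a two-way crossed random-effects layout (with
missing cells), and Jeffreys-Zellner-Siow Bayes factors for nested linear
regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats as sp_stats
from scipy.special import gammaln


def _finite_pairs(*arrays):
    arrays = [np.asarray(a, dtype=float).ravel() for a in arrays]
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("arrays must have equal length")
    keep = np.all(np.isfinite(np.vstack(arrays)), axis=0)
    return [a[keep] for a in arrays]


def pearson(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided t-based p value."""
    x, y = _finite_pairs(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r, p = sp_stats.pearsonr(x, y)
    return float(r), float(p)


def partial_correlation(x, y, controls=None) -> tuple[float, float]:
    """Correlation of x and y after regressing both on the controls.

    Degrees of freedom are reduced by the number of controls; with no
    controls this is the plain Pearson correlation.
    """
    if controls is None or (hasattr(controls, "size") and np.size(controls) == 0):
        return pearson(x, y)
    controls = np.atleast_2d(np.asarray(controls, dtype=float))
    if controls.shape[0] != np.size(x):
        controls = controls.T
    cols = [np.asarray(x, float).ravel(), np.asarray(y, float).ravel()] + [
        controls[:, j] for j in range(controls.shape[1])
    ]
    cleaned = _finite_pairs(*cols)
    x, y = cleaned[0], cleaned[1]
    z = np.column_stack(cleaned[2:])
    n, k = z.shape
    if n <= k + 3:
        raise ValueError(f"need more than {k + 3} observations for {k} controls")
    design = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear controls")
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    # a variable fully explained by the controls carries no partial association
    if float(rx @ rx) <= 1e-12 * (float(x @ x) + 1.0) or \
            float(ry @ ry) <= 1e-12 * (float(y @ y) + 1.0):
        return 0.0, 1.0
    denom = np.sqrt(float(rx @ rx) * float(ry @ ry))
    r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return r, float(2.0 * sp_stats.t.sf(abs(t), df))


@dataclass
class CorrelationComparison:
    r13: float
    r23: float
    r12: float
    n: int
    t_stat: float
    df: int
    p: float


def compare_dependent_correlations(r13, r23, r12, n) -> CorrelationComparison:
    """Hotelling-Williams test for r13 vs r23 sharing variable 3, df = n - 3."""
    for r in (r13, r23, r12):
        if abs(r) > 1:
            raise ValueError("correlations must lie in [-1, 1]")
    if n < 4:
        raise ValueError("need n >= 4")
    det = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    if det <= 0:
        raise ValueError(f"degenerate correlation matrix (|R| = {det:.3g})")
    rbar = 0.5 * (r13 + r23)
    denom = 2 * ((n - 1) / (n - 3)) * det + rbar**2 * (1 - r12) ** 3
    t = (r13 - r23) * np.sqrt((n - 1) * (1 + r12) / denom)
    df = n - 3
    return CorrelationComparison(
        r13=r13, r23=r23, r12=r12, n=n,
        t_stat=float(t), df=df, p=float(2.0 * sp_stats.t.sf(abs(t), df)),
    )


@dataclass
class BlandAltmanResult:
    bias: float  # mean of a - b
    sd_diff: float
    loa_low: float
    loa_high: float
    proportional_slope: float  # slope of (a - b) on (a + b)/2
    n: int


def bland_altman(a, b) -> BlandAltmanResult:
    """Agreement between paired estimates; differences are a - b."""
    a, b = _finite_pairs(a, b)
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    mean_pair = 0.5 * (a + b)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.std(mean_pair) > 0:
        slope = float(np.polyfit(mean_pair, d, 1)[0])
    else:
        slope = 0.0
    return BlandAltmanResult(
        bias=bias, sd_diff=sd,
        loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        proportional_slope=slope, n=a.size,
    )


@dataclass
class RegressionFit:
    coefficients: np.ndarray  # slopes, in predictor order
    intercept: float
    r: float  # multiple correlation (signed for a single predictor)
    rmse: float
    n: int
    fitted: np.ndarray


def linreg_rmse(x, y, rmse_divisor: str = "n") -> RegressionFit:
    """OLS fit with in-sample RMSE.

    RMSE uses divisor n by default (the in-sample convention used alongside
    regression scatter plots); pass ``rmse_divisor="residual_df"`` for the
    n - p - 1 variant.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n, k = x.shape
    if n <= k + 1:
        raise ValueError("need n > number of predictors + 1")
    design = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular design matrix")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    resid = y - fitted
    divisor = n if rmse_divisor == "n" else n - k - 1
    rmse = float(np.sqrt(np.sum(resid**2) / divisor))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 0.0
    r = np.sqrt(max(r2, 0.0))
    if k == 1:
        r *= np.sign(coef[1]) if coef[1] != 0 else 1.0
    return RegressionFit(
        coefficients=coef[1:], intercept=float(coef[0]),
        r=float(r), rmse=rmse, n=n, fitted=fitted,
    )


def paired_t(a, b) -> tuple[float, int, float]:
    """One-sample t test of the paired differences a - b against zero.

    Zero-variance differences with a nonzero mean are reported as signed
    infinite t with p = 0; all-zero differences give t = 0, p = 1.
    """
    a, b = _finite_pairs(a, b)
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    df = d.size - 1
    sd = d.std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(d.mean())):
        if d.mean() == 0:
            return 0.0, df, 1.0
        return float(np.sign(d.mean()) * np.inf), df, 0.0
    t = d.mean() / (sd / np.sqrt(d.size))
    return float(t), df, float(2.0 * sp_stats.t.sf(abs(t), df))


@dataclass
class VarianceComponents:
    between_subject: float  # raw estimates (may be negative)
    within_subject: float
    error: float
    proportions: dict  # after truncating negatives to zero

    def as_dict(self):
        return {
            "between_subject": self.between_subject,
            "within_subject": self.within_subject,
            "error": self.error,
            "proportions": self.proportions,
        }


def minque_components(values: np.ndarray) -> VarianceComponents:
    """MINQUE (uniform prior weights, scheme 1) for a two-way crossed layout.

    Model: y_pc = mu + a_p + b_c + e_pc with participants p (between-subject),
    channels c (within-subject) and error, all random.  Missing cells (NaN)
    are allowed.  Negative raw estimates are truncated to zero for the
    reported proportions only.
    """
    grid = np.asarray(values, dtype=float)
    if grid.ndim != 2 or grid.shape[0] < 2 or grid.shape[1] < 2:
        raise ValueError("need at least a 2 x 2 participants-by-channels grid")
    rows, cols = np.nonzero(np.isfinite(grid))
    y = grid[rows, cols]
    n = y.size
    n_p, n_c = grid.shape
    if n < n_p + n_c:
        raise ValueError("too few non-missing cells for variance estimation")
    za = np.zeros((n, n_p))
    za[np.arange(n), rows] = 1.0
    zb = np.zeros((n, n_c))
    zb[np.arange(n), cols] = 1.0
    z = np.hstack([za, zb])
    gram = z.T @ z
    m = np.linalg.inv(np.eye(gram.shape[0]) + gram)

    def w_apply(v):  # V^{-1} v with V = I + Z Z'
        return v - z @ (m @ (z.T @ v))

    ones = np.ones(n)
    u = w_apply(ones)
    s_scalar = float(ones @ u)

    def r_apply(v):
        return w_apply(v) - np.outer(u, u @ v).reshape(v.shape) / s_scalar if v.ndim > 1 \
            else w_apply(v) - u * float(u @ v) / s_scalar

    r_za = r_apply(za)
    r_zb = r_apply(zb)
    r_y = r_apply(y)
    s11 = np.sum((za.T @ r_za) ** 2)
    s12 = np.sum((za.T @ r_zb) ** 2)
    s22 = np.sum((zb.T @ r_zb) ** 2)
    s13 = np.sum(r_za**2)
    s23 = np.sum(r_zb**2)
    # tr(R^2) with R = W - u u'/s, W = I - Z M Z'
    tr_w2 = n - 2.0 * np.trace(m @ gram) + np.trace(m @ gram @ m @ gram)
    w_u = w_apply(u)
    s33 = tr_w2 - 2.0 * float(u @ w_u) / s_scalar + float(u @ u) ** 2 / s_scalar**2
    s_mat = np.array([[s11, s12, s13], [s12, s22, s23], [s13, s23, s33]])
    q = np.array([np.sum((za.T @ r_y) ** 2), np.sum((zb.T @ r_y) ** 2), float(r_y @ r_y)])
    theta = np.linalg.solve(s_mat, q)
    trunc = np.maximum(theta, 0.0)
    total = trunc.sum()
    props = trunc / total if total > 0 else np.zeros(3)
    return VarianceComponents(
        between_subject=float(theta[0]),
        within_subject=float(theta[1]),
        error=float(theta[2]),
        proportions={
            "between_subject": float(props[0]),
            "within_subject": float(props[1]),
            "error": float(props[2]),
        },
    )


@dataclass
class BayesFactorResult:
    bf01: float  # evidence for the smaller (null) model over the larger
    bf_null_vs_intercept: float
    bf_alt_vs_intercept: float
    r_scale: float
    method: str = "adaptive quadrature on log g (JZS mixture-of-g prior)"


def _jzs_log_bf10(y: np.ndarray, x: np.ndarray | None, r_scale: float) -> float:
    """log BF of a linear model (with intercept) against intercept-only.

    Integrates (1+g)^((n-1-p)/2) (1+g(1-R^2))^(-(n-1)/2) against the
    inverse-gamma(1/2, n r^2/2) prior on g, on the log-g scale.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if x is None or x.size == 0:
        return 0.0
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != n:
        x = x.T
    p = x.shape[1]
    if n <= p + 2:
        raise ValueError("need n > number of covariates + 2")
    design = np.column_stack([np.ones(n), x])
    resid = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    scale = n * r_scale**2 / 2.0

    def log_integrand(u):  # u = log g
        g = np.exp(u)
        return (
            0.5 * (n - 1 - p) * np.log1p(g)
            - 0.5 * (n - 1) * np.log1p(g * (1.0 - r2))
            + 0.5 * np.log(scale) - gammaln(0.5)
            - 1.5 * u - scale / g
            + u  # Jacobian dg = g du
        )

    grid = np.linspace(-35.0, 35.0, 400)
    shift = float(np.max(log_integrand(grid)))
    val, _ = integrate.quad(lambda u: np.exp(log_integrand(u) - shift), -35.0, 35.0,
                            limit=200)
    return shift + float(np.log(val))


def jzs_regression_bf01(y, covariates_null, covariates_alt, r_scale=0.354) -> BayesFactorResult:
    """BF01 for a null regression nested in an alternative, via the JZS prior.

    Both models are scored against the intercept-only model; bf01 is their
    ratio.  The null's covariates must span a subspace of the alternative's.
    """
    y = np.asarray(y, dtype=float).ravel()

    def as_matrix(c):
        if c is None:
            return np.empty((y.size, 0))
        c = np.atleast_2d(np.asarray(c, dtype=float))
        return c if c.shape[0] == y.size else c.T

    x0, x1 = as_matrix(covariates_null), as_matrix(covariates_alt)
    if x0.shape[1] > 0:
        if x1.shape[1] == 0:
            raise ValueError("null covariates are not nested in the alternative's")
        proj = x1 @ np.linalg.lstsq(x1, x0, rcond=None)[0]
        if not np.allclose(proj, x0, atol=1e-8 * max(1.0, np.abs(x0).max())):
            raise ValueError("null covariates are not nested in the alternative's")
    log_bf0 = _jzs_log_bf10(y, x0 if x0.shape[1] else None, r_scale)
    log_bf1 = _jzs_log_bf10(y, x1 if x1.shape[1] else None, r_scale)
    return BayesFactorResult(
        bf01=float(np.exp(log_bf0 - log_bf1)),
        bf_null_vs_intercept=float(np.exp(log_bf0)),
        bf_alt_vs_intercept=float(np.exp(log_bf1)),
        r_scale=r_scale,
    )


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk W and p (delegated to the standard routine)."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    w, p = sp_stats.shapiro(x)
    return float(w), float(p)
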