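"""Estimating chronological age from broad-spectrum EEG features.

The univariate route regresses age on the SVD-summarised log2-amplitude
spectrum (participants x frequencies) with PLS1; the number of latent
factors is chosen by permutation testing of each factor's incremental
explained age variance, frequency importance is scored by VIP, and a
recursive weighted PLS (R-PLS) reduces the spectrum to a minimal set of
critical frequencies.  The multichannel route works on the
participants x channels x frequencies tensor: PARAFAC-ALS diagnostics
(SSE, core consistency, iterations over replicated random starts) guide the
factor count, and trilinear PLS1 (tri-PLS / M-PLS) regresses age on tensor
scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# PLS1 (NIPALS)
# ---------------------------------------------------------------------------


@dataclass
class PlsModel:
    n_factors: int
    x_mean: np.ndarray
    y_mean: float
    x_weights: np.ndarray  # p x A, unit-norm columns
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # A
    scores: np.ndarray  # n x A
    beta: np.ndarray  # p
    intercept: float
    explained_y_variance: np.ndarray  # per-factor proportion of var(y)
    perm_pvalues: np.ndarray | None = None

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
        if x_new.shape[1] != self.beta.size:
            raise ValueError(
                f"predictor grid mismatch: model has {self.beta.size} columns, "
                f"input has {x_new.shape[1]}"
            )
        return x_new @ self.beta + self.intercept


def fit_pls(x: np.ndarray, y: np.ndarray, n_factors: int) -> PlsModel:
    """PLS1 by NIPALS with internal centring of X columns and y.

    Factors stop early (with zero contribution) if the X-y covariance
    vanishes, e.g. for constant y, in which case beta = 0 and predictions
    equal the mean age.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if n != y.size:
        raise ValueError("row count of X must match length of y")
    if n_factors < 1 or n_factors > min(n - 1, p):
        raise ValueError(f"n_factors={n_factors} exceeds the data rank bound")
    x_mean, y_mean = x.mean(axis=0), float(y.mean())
    xc, yc = x - x_mean, y - y_mean
    tss = float(yc @ yc)
    w_list, p_list, q_list, t_list, ssy = [], [], [], [], []
    xd, yd = xc.copy(), yc.copy()
    for _ in range(n_factors):
        cov = xd.T @ yd
        norm = np.linalg.norm(cov)
        if norm < 1e-12 * max(1.0, np.abs(xd).max(), np.abs(yd).max()) or norm == 0.0:
            break
        w = cov / norm
        t = xd @ w
        tt = float(t @ t)
        if tt <= 0:
            break
        p_vec = xd.T @ t / tt
        q = float(yd @ t / tt)
        xd = xd - np.outer(t, p_vec)
        yd = yd - q * t
        w_list.append(w)
        p_list.append(p_vec)
        q_list.append(q)
        t_list.append(t)
        ssy.append(q * q * tt)
    a = len(w_list)
    if a == 0:
        return PlsModel(
            n_factors=0, x_mean=x_mean, y_mean=y_mean,
            x_weights=np.zeros((p, 0)), x_loadings=np.zeros((p, 0)),
            y_loadings=np.zeros(0), scores=np.zeros((n, 0)),
            beta=np.zeros(p), intercept=y_mean,
            explained_y_variance=np.zeros(0),
        )
    w_mat = np.column_stack(w_list)
    p_mat = np.column_stack(p_list)
    q_vec = np.asarray(q_list)
    t_mat = np.column_stack(t_list)
    beta = w_mat @ np.linalg.solve(p_mat.T @ w_mat, q_vec)
    return PlsModel(
        n_factors=a,
        x_mean=x_mean,
        y_mean=y_mean,
        x_weights=w_mat,
        x_loadings=p_mat,
        y_loadings=q_vec,
        scores=t_mat,
        beta=beta,
        intercept=y_mean - float(x_mean @ beta),
        explained_y_variance=np.asarray(ssy) / tss if tss > 0 else np.zeros(a),
    )


def predict_age(model: PlsModel, x_new: np.ndarray) -> np.ndarray:
    """EEG-age: apply the fitted beta (plus intercept) to new spectra."""
    return model.predict(x_new)


def _incremental_variance(x, y, max_factors) -> np.ndarray:
    model = fit_pls(x, y, max_factors)
    inc = np.zeros(max_factors)
    inc[: model.n_factors] = model.explained_y_variance
    return inc


def select_factors_by_permutation(
    x: np.ndarray,
    y: np.ndarray,
    max_factors: int = 5,
    n_perm: int = 1000,
    level: float = 0.05,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Number of significant PLS factors by permutation of the response.

    Factor k is significant when its incremental explained age variance
    exceeds all but a fraction ``level`` of the same quantity from fits with
    y permuted (the full sequential fit is re-run per permutation),
    i.e. when its permutation p-value (1 + #{null >= observed})/(n_perm + 1)
    is at most ``level`` -- the order-statistic form of the (1 - level)
    quantile rule, exactly sized when (n_perm + 1) * level is an integer.
    Selection stops at the first non-significant factor.  Returns (count,
    per-factor permutation p-values).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float).ravel()
    observed = _incremental_variance(x, y, max_factors)
    null = np.empty((n_perm, max_factors))
    for b in range(n_perm):
        null[b] = _incremental_variance(x, rng.permutation(y), max_factors)
    pvals = (1.0 + np.sum(null >= observed[None, :], axis=0)) / (n_perm + 1.0)
    count = 0
    for k in range(max_factors):
        if pvals[k] <= level:
            count += 1
        else:
            break
    return count, pvals


def vip_scores(model: PlsModel) -> np.ndarray:
    """Variable Importance in Projection per frequency.

    VIP_j = sqrt(p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a); the mean
    of squared VIP over the p predictors is exactly 1.
    """
    w = model.x_weights
    ssy = model.explained_y_variance
    p = w.shape[0]
    if w.shape[1] == 0 or ssy.sum() <= 0:
        return np.zeros(p)
    wn2 = (w / np.linalg.norm(w, axis=0, keepdims=True)) ** 2
    return np.sqrt(p * (wn2 @ ssy) / ssy.sum())


@dataclass
class RplsResult:
    selected: np.ndarray  # boolean support over columns
    selected_frequencies: np.ndarray
    iterations: int
    final_model: PlsModel
    weight_history: list[np.ndarray]


def rpls_select(
    x: np.ndarray,
    y: np.ndarray,
    freqs: np.ndarray | None = None,
    n_factors: int = 2,
    max_iter: int = 50,
    survival_tol: float = 1e-3,
    seed: int = 0,
) -> RplsResult:
    """Recursive weighted PLS frequency selection.

    Each iteration multiplies the cumulative column weights by
    |beta| / max|beta| from a PLS fit on the weighted predictors and refits;
    columns whose weight stays above ``survival_tol`` of the maximum form
    the support.  Iteration stops when the support stabilises or at
    ``max_iter``; the final model is refitted on the surviving columns only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    freqs = np.arange(p, dtype=float) if freqs is None else np.asarray(freqs, dtype=float)
    weights = np.ones(p)
    history = [weights.copy()]
    support = weights >= survival_tol
    iterations = 0
    for iterations in range(1, max_iter + 1):
        k = min(n_factors, max(1, int(support.sum())), n - 1)
        model = fit_pls(x * weights, y, k)
        beta_mag = np.abs(model.beta)
        if beta_mag.max() <= 0:
            break
        weights = weights * beta_mag / beta_mag.max()
        history.append(weights.copy())
        new_support = weights >= survival_tol * weights.max()
        if np.array_equal(new_support, support) and iterations > 1:
            support = new_support
            break
        support = new_support
    k = min(n_factors, max(1, int(support.sum())), n - 1)
    final = fit_pls(x[:, support], y, k)
    return RplsResult(
        selected=support,
        selected_frequencies=freqs[support],
        iterations=iterations,
        final_model=final,
        weight_history=history,
    )


# ---------------------------------------------------------------------------
# PARAFAC and trilinear PLS
# ---------------------------------------------------------------------------


def _khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a[:, None, :] * b[None, :, :]).reshape(-1, a.shape[1])


def _unfold(t: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(t, mode, 0).reshape(t.shape[mode], -1)


@dataclass
class ParafacFit:
    factors: list[np.ndarray]  # [A (I x F), B (J x F), C (K x F)]
    sse: float
    corcondia: float
    iterations: int
    converged: bool
    replicate: int = 0


def _parafac_als(x, n_factors, rng, max_iter, tol):
    dims = x.shape
    factors = [rng.standard_normal((d, n_factors)) for d in dims]
    unfolds = [_unfold(x, m) for m in range(3)]
    total = float(np.sum(x**2))
    prev_sse = np.inf
    sse = total
    for it in range(1, max_iter + 1):
        for mode in range(3):
            others = [factors[m] for m in range(3) if m != mode]
            kr = _khatri_rao(others[0], others[1])
            gram = (others[0].T @ others[0]) * (others[1].T @ others[1])
            factors[mode] = unfolds[mode] @ kr @ np.linalg.pinv(gram)
        a, b, c = factors
        gram_full = (a.T @ a) * (b.T @ b) * (c.T @ c)
        # ||X - Xhat||^2 = ||X||^2 - 2 <X, Xhat> + ||Xhat||^2
        inner = float(np.sum((unfolds[0] @ _khatri_rao(b, c)) * a))
        sse = max(total - 2.0 * inner + float(np.sum(gram_full)), 0.0)
        if np.isfinite(prev_sse) and prev_sse - sse <= tol * max(prev_sse, 1e-300):
            return factors, sse, it, True
        prev_sse = sse
    return factors, sse, max_iter, False


def _normalize_factors(factors):
    a, b, c = factors
    for mat in (b, c):
        norms = np.linalg.norm(mat, axis=0)
        norms[norms == 0] = 1.0
        mat /= norms
        a *= norms
    return [a, b, c]


def corcondia(x: np.ndarray, factors: list[np.ndarray]) -> float:
    """Core consistency: 100 * (1 - ||G - T||^2 / ||T||^2).

    G is the least-squares Tucker core given the PARAFAC loadings and T the
    superdiagonal identity core.
    """
    core = x
    for mode, mat in enumerate(factors):
        pinv = np.linalg.pinv(mat)
        core = np.moveaxis(np.tensordot(pinv, core, axes=(1, mode)), 0, mode)
    f = factors[0].shape[1]
    target = np.zeros((f, f, f))
    target[np.arange(f), np.arange(f), np.arange(f)] = 1.0
    return float(100.0 * (1.0 - np.sum((core - target) ** 2) / f))


def fit_parafac(
    tensor: np.ndarray,
    n_factors: int,
    n_replications: int = 25,
    seed: int = 0,
    max_iter: int = 2500,
    tol: float = 1e-8,
    compress_rank: int | None = None,
) -> ParafacFit:
    """Best-of-replications PARAFAC by alternating least squares.

    ``n_replications`` random starts are run; the lowest-SSE replicate is
    kept and its core consistency computed.  ``compress_rank`` optionally
    truncates each mode to that many HOSVD components before ALS (lossless
    up to the discarded singular energy, which is added back to the SSE) --
    the usual trick for large smooth tensors.
    """
    x = np.asarray(tensor, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected a 3-mode tensor")
    if not np.all(np.isfinite(x)):
        raise ValueError("tensor must be finite")
    bases = None
    x_work, sse_offset = x, 0.0
    if compress_rank is not None:
        bases = []
        x_work = x
        for mode in range(3):
            r = min(compress_rank, x.shape[mode])
            u, _, _ = np.linalg.svd(_unfold(x_work, mode), full_matrices=False)
            u = u[:, :r]
            bases.append(u)
            x_work = np.moveaxis(np.tensordot(u.T, x_work, axes=(1, mode)), 0, mode)
        sse_offset = float(np.sum(x**2) - np.sum(x_work**2))
    ss = np.random.SeedSequence(seed)
    best, iteration_log = None, []
    for rep, child in enumerate(ss.spawn(n_replications)):
        rng = np.random.default_rng(child)
        factors, sse, iters, conv = _parafac_als(x_work, n_factors, rng, max_iter, tol)
        sse += sse_offset
        iteration_log.append((rep, iters, conv))
        if not np.isfinite(sse):
            continue
        if best is None or sse < best.sse:
            best = ParafacFit(factors=factors, sse=sse, corcondia=np.nan,
                              iterations=iters, converged=conv, replicate=rep)
    if best is None:
        raise RuntimeError(
            f"PARAFAC diverged in all {n_replications} replications; "
            f"(replicate, iterations, converged) log: {iteration_log}"
        )
    if bases is not None:
        best.factors = [u @ f for u, f in zip(bases, best.factors)]
    best.factors = _normalize_factors(best.factors)
    best.corcondia = corcondia(x, best.factors)
    return best


def diagnose_parafac(
    tensor: np.ndarray,
    max_factors: int = 10,
    n_replications: int = 25,
    seed: int = 0,
    max_iter: int = 2500,
    tol: float = 1e-8,
    compress_rank: int | None = None,
):
    """SSE / CORCONDIA / iteration diagnostics for factor counts 1..max_factors."""
    import pandas as pd

    rows = []
    fits = {}
    for f in range(1, max_factors + 1):
        fit = fit_parafac(tensor, f, n_replications=n_replications, seed=seed + f,
                          max_iter=max_iter, tol=tol, compress_rank=compress_rank)
        fits[f] = fit
        rows.append({
            "n_factors": f, "sse": fit.sse, "corcondia": fit.corcondia,
            "iterations": fit.iterations, "n_replications": n_replications,
            "best_replicate_id": fit.replicate,
        })
    return pd.DataFrame(rows), fits


@dataclass
class TriPlsModel:
    n_factors: int
    x_mean: np.ndarray  # J x K
    y_mean: float
    channel_weights: np.ndarray  # J x F, unit norm
    frequency_weights: np.ndarray  # K x F, unit norm
    scores: np.ndarray  # n x F
    score_age_corr: np.ndarray  # F
    coef: np.ndarray  # F (regression of y on scores)
    intercept: float
    fitted: np.ndarray = field(default=None)

    def predict(self, tensor_new: np.ndarray) -> np.ndarray:
        x = np.asarray(tensor_new, dtype=float) - self.x_mean[None]
        n = x.shape[0]
        t_mat = np.empty((n, self.n_factors))
        for a in range(self.n_factors):
            wj = self.channel_weights[:, a]
            wk = self.frequency_weights[:, a]
            t = np.einsum("ijk,j,k->i", x, wj, wk)
            t_mat[:, a] = t
            x = x - t[:, None, None] * np.outer(wj, wk)[None]
        return t_mat @ self.coef + self.intercept


def fit_tripls(tensor: np.ndarray, y: np.ndarray, n_factors: int) -> TriPlsModel:
    """Trilinear PLS1 for a participants x channels x frequencies tensor.

    Each factor takes the dominant singular pair of the y-covariance matrix
    Z_jk = sum_i y_i X_ijk as (channel, frequency) weights, scores the
    participants, and deflates; age is finally regressed on all scores
    jointly.
    """
    x = np.asarray(tensor, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if x.ndim != 3 or x.shape[0] != y.size:
        raise ValueError("tensor first mode must match length of y")
    if n_factors < 1 or n_factors > min(x.shape):
        raise ValueError(f"n_factors={n_factors} exceeds the smallest mode")
    x_mean = x.mean(axis=0)
    y_mean = float(y.mean())
    xd = x - x_mean[None]
    yd = y - y_mean
    wj_list, wk_list, t_list = [], [], []
    for _ in range(n_factors):
        z = np.einsum("i,ijk->jk", yd, xd)
        if np.linalg.norm(z) < 1e-12:
            break
        u, _, vt = np.linalg.svd(z, full_matrices=False)
        wj, wk = u[:, 0], vt[0]
        t = np.einsum("ijk,j,k->i", xd, wj, wk)
        if t @ (y - y_mean) < 0:  # orient factors positively with age
            wj, wk, t = -wj, wk, -t
        tt = float(t @ t)
        if tt <= 0:
            break
        xd = xd - t[:, None, None] * np.outer(wj, wk)[None]
        yd = yd - t * float(yd @ t / tt)
        wj_list.append(wj)
        wk_list.append(wk)
        t_list.append(t)
    a = len(t_list)
    if a == 0:
        zeros = np.zeros((x.shape[0], 0))
        return TriPlsModel(
            n_factors=0, x_mean=x_mean, y_mean=y_mean,
            channel_weights=np.zeros((x.shape[1], 0)),
            frequency_weights=np.zeros((x.shape[2], 0)),
            scores=zeros, score_age_corr=np.zeros(0), coef=np.zeros(0),
            intercept=y_mean, fitted=np.full(x.shape[0], y_mean),
        )
    t_mat = np.column_stack(t_list)
    yc = y - y_mean
    coef, *_ = np.linalg.lstsq(t_mat, yc, rcond=None)
    fitted = t_mat @ coef + y_mean
    with np.errstate(invalid="ignore"):
        corr = np.array([
            np.corrcoef(t_mat[:, j], y)[0, 1] if np.std(t_mat[:, j]) > 0 else 0.0
            for j in range(a)
        ])
    return TriPlsModel(
        n_factors=a, x_mean=x_mean, y_mean=y_mean,
        channel_weights=np.column_stack(wj_list),
        frequency_weights=np.column_stack(wk_list),
        scores=t_mat, score_age_corr=corr, coef=coef,
        intercept=y_mean, fitted=fitted,
    )
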