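"""Shared constrained-ordination arithmetic and the forward-selection engine.

Both spatial-eigenvector selection (:mod:`seagea.seaspace`) and environmental
variable selection (:mod:`seagea.envsel`) select predictors of a multivariate
genotype response with the same procedure:

1. at each step, the candidate with the largest additional explained variance
   is considered; its permutation p-value uses a max-statistic null (the
   maximum gain over all remaining candidates is recomputed for every
   permutation of the residuals of the current model), which accounts for the
   selection of the best candidate and calibrates the probability of a first
   false selection to alpha;
2. the candidate enters if p <= alpha;
3. selection stops when the cumulative adjusted R^2 would exceed the
   adjusted R^2 of the global model with all candidates (double stopping
   rule); the global model's permutation p is also computed and reported.

Permutation p-values are (exceedances + 1) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["center", "total_ss", "fitted_ss", "adjusted_r2", "ForwardSelection", "forward_select"]


def center(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    return M - M.mean(axis=0, keepdims=True)


def total_ss(Y: np.ndarray) -> float:
    Yc = center(Y)
    return float(np.sum(Yc * Yc))


def _basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of centered X (rank-trimmed)."""
    Xc = center(X)
    if Xc.size == 0:
        return np.empty((X.shape[0], 0))
    Q, Rm = np.linalg.qr(Xc)
    keep = np.abs(np.diag(Rm)) > 1e-10 * max(1.0, np.abs(np.diag(Rm)).max())
    return Q[:, keep]


def fitted_ss(Yc: np.ndarray, Q: np.ndarray) -> float:
    """Sum of squares of the projection of Yc onto the orthonormal basis Q."""
    if Q.shape[1] == 0:
        return 0.0
    B = Q.T @ Yc
    return float(np.sum(B * B))


def adjusted_r2(r2: float, n: int, q: int) -> float:
    if n - q - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - q - 1)


def _global_test(Yc: np.ndarray, Q: np.ndarray, n_perm: int, rng) -> tuple[float, float]:
    """Permutation test of the model with predictor basis Q; returns (F, p)."""
    n = Yc.shape[0]
    q = Q.shape[1]
    tot = float(np.sum(Yc * Yc))
    if q == 0 or tot <= 0 or n - q - 1 <= 0:
        return np.nan, 1.0
    ss = fitted_ss(Yc, Q)
    f_obs = (ss / q) / ((tot - ss) / (n - q - 1))
    f_perm = np.empty(n_perm)
    for b in range(n_perm):
        Yp = Yc[rng.permutation(n)]
        ssb = fitted_ss(Yp, Q)
        f_perm[b] = (ssb / q) / ((tot - ssb) / (n - q - 1))
    return f_obs, float((np.sum(f_perm >= f_obs - 1e-12) + 1) / (n_perm + 1))


@dataclass
class ForwardSelection:
    """Result of forward selection over candidate predictor columns."""

    selected: list[int]
    pvalues: list[float]
    gains: list[float]
    adj_r2_path: list[float]
    global_p: float
    global_adj_r2: float
    names: list[str] = field(default_factory=list)


def _step_gains(Yres: np.ndarray, Qcand: np.ndarray) -> np.ndarray:
    """Per-candidate additional SS explained: columns of Qcand are unit
    vectors orthogonal to the current model."""
    B = Qcand.T @ Yres
    return np.sum(B * B, axis=1)


def forward_select(
    Y: np.ndarray,
    W: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 100,
    seed: int | None = 0,
    names: list[str] | None = None,
) -> ForwardSelection:
    """Forward selection of columns of W as predictors of multivariate Y.

    Y is the (individuals x loci) response; W the (individuals x k) candidate
    matrix.  Returns the selected column indices in order of entry, per-step
    max-statistic permutation p-values and variance-gain fractions.
    ``alpha >= 1`` is a diagnostic mode: all candidates are ranked by gain
    with the stopping rules disabled.
    """
    rng = np.random.default_rng(seed)
    Yc = center(np.asarray(Y, dtype=float))
    W = np.asarray(W, dtype=float)
    n, k = W.shape
    tot = float(np.sum(Yc * Yc))
    if tot <= 0 or k == 0:
        return ForwardSelection([], [], [], [], 1.0, 0.0, [])

    Q_all = _basis(W)
    r2_all = fitted_ss(Yc, Q_all) / tot
    g_adj = adjusted_r2(r2_all, n, Q_all.shape[1])
    _, g_p = _global_test(Yc, Q_all, n_perm, rng)

    sel: list[int] = []
    pvals: list[float] = []
    gains: list[float] = []
    adj_path: list[float] = []
    remaining = list(range(k))
    Qs = np.empty((n, 0))
    ss_cur = 0.0
    while remaining:
        if n - (Qs.shape[1] + 1) - 1 <= 0:
            break
        # unit residuals of each remaining candidate w.r.t. current model
        Wr = W[:, remaining] - W[:, remaining].mean(axis=0, keepdims=True)
        if Qs.shape[1]:
            Wr = Wr - Qs @ (Qs.T @ Wr)
        norms = np.linalg.norm(Wr, axis=0)
        ok = norms > 1e-10
        if not ok.any():
            break
        cand_idx = [remaining[i] for i in np.flatnonzero(ok)]
        Qcand = Wr[:, ok] / norms[ok]
        Yres = Yc - Qs @ (Qs.T @ Yc) if Qs.shape[1] else Yc
        g = _step_gains(Yres, Qcand)
        best_pos = int(np.argmax(g))
        best_j = cand_idx[best_pos]
        gain_obs = float(g[best_pos])
        # max-statistic permutation null: the best candidate's gain is
        # compared with the best gain over ALL remaining candidates under
        # permutation, so selecting the maximum does not inflate alpha
        exceed = 0
        for _ in range(n_perm):
            Yp = Yres[rng.permutation(n)]
            if float(_step_gains(Yp, Qcand).max()) >= gain_obs - 1e-12:
                exceed += 1
        p = (exceed + 1) / (n_perm + 1)
        if alpha < 1 and p > alpha:
            break
        r2_new = (ss_cur + gain_obs) / tot
        adj_new = adjusted_r2(r2_new, n, Qs.shape[1] + 1)
        # adjusted-R^2 scope rule from the second step onward: a single
        # strong predictor legitimately exceeds the global adjusted R^2
        # whenever the candidate set contains uninformative variables, and
        # the first selection is already exactly controlled by the
        # max-statistic test.  alpha >= 1 disables both stopping rules
        # (diagnostic ranking mode).
        if alpha < 1 and sel and np.isfinite(g_adj) and adj_new > g_adj + 1e-12:
            break
        sel.append(best_j)
        pvals.append(p)
        gains.append(gain_obs / tot)
        adj_path.append(adj_new)
        remaining.remove(best_j)
        Qs = _basis(W[:, sel])
        ss_cur = fitted_ss(Yc, Qs)
    return ForwardSelection(
        sel, pvals, gains, adj_path, g_p, g_adj,
        [names[i] for i in sel] if names else [],
    )
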