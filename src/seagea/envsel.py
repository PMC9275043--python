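"""Environmental variable standardization and reduction.

Variables are z-scored, pruned by pairwise correlation (|r| > r_max) and
variance inflation factor (VIF >= vif_max), then forward-selected against
the multivariate genotype response with the shared permutation engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._forward import ForwardSelection, forward_select

logger = logging.getLogger(__name__)

__all__ = [
    "EnvMatrix",
    "standardize_env",
    "vif",
    "collinearity_prune",
    "forward_select_env",
    "broadcast_to_individuals",
]


@dataclass
class EnvMatrix:
    """Rows (individuals or sites) x environmental variables."""

    values: np.ndarray
    names: list[str]
    standardized: bool = False
    row_ids: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values shape does not match variable names")
        if not np.isfinite(self.values).all():
            raise ValueError("environmental values must be finite")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        if self.row_ids is not None:
            df.insert(0, "id", self.row_ids)
        return df

    def select(self, names: list[str]) -> "EnvMatrix":
        idx = [self.names.index(n) for n in names]
        return EnvMatrix(self.values[:, idx], list(names), self.standardized, self.row_ids)


def broadcast_to_individuals(env: pd.DataFrame, sample_sites, site_col: str = "site") -> EnvMatrix:
    """Expand a per-site environmental table to one row per individual."""
    names = [c for c in env.columns if c != site_col]
    lookup = env.set_index(site_col)
    missing = sorted(set(sample_sites) - set(lookup.index))
    if missing:
        raise ValueError(f"sites without environmental rows: {missing}")
    values = lookup.loc[list(sample_sites), names].to_numpy(dtype=float)
    return EnvMatrix(values=values, names=names, row_ids=list(sample_sites))


def standardize_env(E: EnvMatrix) -> EnvMatrix:
    """Column-wise z-scores (sample SD, n-1 denominator)."""
    sd = E.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if len(zero):
        raise ValueError(f"zero-variance environmental variable: {E.names[zero[0]]!r}")
    Z = (E.values - E.values.mean(axis=0)) / sd
    return EnvMatrix(values=Z, names=list(E.names), standardized=True, row_ids=E.row_ids)


def vif(values: np.ndarray) -> np.ndarray:
    """VIF_j = 1 / (1 - R^2_j) of each column regressed on the others."""
    X = np.asarray(values, dtype=float)
    X = X - X.mean(axis=0)
    k = X.shape[1]
    if k < 2:
        return np.ones(k)
    out = np.empty(k)
    for j in range(k):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = float(y @ y)
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
        out[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out


def collinearity_prune(
    E: EnvMatrix, r_max: float = 0.7, vif_max: float = 3.0
) -> tuple[list[str], list[dict]]:
    """Two-stage multicollinearity pruning; returns (kept names, drop log).

    Stage 1: while any pair has |Pearson r| > r_max, drop the member of the
    worst pair with the larger mean |r| to all other remaining variables
    (tie: the later column).  Stage 2: while any VIF >= vif_max, drop the
    largest-VIF variable.
    """
    if not E.standardized:
        raise ValueError("collinearity_prune expects standardized variables")
    names = list(E.names)
    if len(names) < 2:
        return names, []
    X = E.values.copy()
    log: list[dict] = []

    def corr(M):
        return np.corrcoef(M, rowvar=False)

    while X.shape[1] >= 2:
        R = np.abs(corr(X))
        np.fill_diagonal(R, 0.0)
        i, j = np.unravel_index(np.argmax(R), R.shape)
        if R[i, j] <= r_max:
            break
        mean_i = R[i].sum() / (X.shape[1] - 1)
        mean_j = R[j].sum() / (X.shape[1] - 1)
        drop = (j if mean_j >= mean_i else i) if not np.isclose(mean_i, mean_j) else max(i, j)
        log.append(
            {"stage": "correlation", "dropped": names[drop], "r": float(R[i, j]),
             "partner": names[i if drop == j else j]}
        )
        X = np.delete(X, drop, axis=1)
        del names[drop]

    while X.shape[1] >= 2:
        v = vif(X)
        worst = int(np.argmax(v))
        if v[worst] < vif_max:
            break
        log.append({"stage": "vif", "dropped": names[worst], "vif": float(v[worst])})
        X = np.delete(X, worst, axis=1)
        del names[worst]
    if log:
        logger.info("collinearity_prune: dropped %s", [d["dropped"] for d in log])
    return names, log


def forward_select_env(
    Y: np.ndarray,
    E: EnvMatrix,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> ForwardSelection:
    """Forward-select environmental variables against the genotype response
    (same engine and stopping rules as MEM selection)."""
    if E.values.shape[0] != np.asarray(Y).shape[0]:
        raise ValueError("environmental rows do not align with individuals")
    return forward_select(Y, E.values, alpha=alpha, n_perm=n_perm, seed=seed, names=list(E.names))
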