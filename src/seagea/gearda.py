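"""Genotype-environment association by partial redundancy analysis.

The core of the pipeline: an individuals x loci dosage matrix (mean-imputed,
centered) is regressed on retained environmental predictors while spatial
eigenvectors are partialled out; constrained axes are the PCA of the fitted
values.  Locus loadings on permutation-significant axes are z-scored and
loci beyond +-3 SD are candidate adaptive markers, each assigned its best
environmental predictor by Spearman rank correlation of the raw (observed,
un-imputed) dosages.

Variance partition: conditioned (spatial), constrained (environmental) and
residual fractions of the total centered genotype variance; pseudo-F
follows the constrained-ordination convention
F = (constrained/q) / (residual/(n - q - r - 1)) and permutation tests
permute residuals of the reduced (conditioning-only) model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genoqc import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RDAModel",
    "PermTestResult",
    "CandidateSet",
    "impute_dosage",
    "partial_rda",
    "permutation_significance",
    "detect_candidates",
    "assign_predictors",
]


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_dosage(G: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages per locus, then center columns."""
    X = G.dosage if isinstance(G, GenotypeMatrix) else np.asarray(G, dtype=float)
    X = X.copy()
    n_obs = np.sum(~np.isnan(X), axis=0)
    if np.any(n_obs == 0):
        j = int(np.argmax(n_obs == 0))
        raise ValueError(f"locus column {j} has no observed genotypes")
    means = np.nansum(X, axis=0) / n_obs
    idx = np.where(np.isnan(X))
    X[idx] = means[idx[1]]
    return X - means[None, :]


# ---------------------------------------------------------------------------
# Partial RDA
# ---------------------------------------------------------------------------

def _orthobasis(M: np.ndarray, names=None, what: str = "matrix") -> np.ndarray:
    """Orthonormal basis of centered M; raises naming collinear columns."""
    Mc = M - M.mean(axis=0, keepdims=True)
    if Mc.shape[1] == 0:
        return np.empty((M.shape[0], 0))
    Q, R = np.linalg.qr(Mc)
    diag = np.abs(np.diag(R))
    bad = diag <= 1e-10 * max(1.0, diag.max())
    if bad.any():
        which = (
            [names[i] for i in np.flatnonzero(bad)] if names else np.flatnonzero(bad).tolist()
        )
        raise ValueError(f"rank-deficient {what}: collinear columns {which}")
    return Q


@dataclass
class RDAModel:
    """Fitted partial RDA: constrained axes, loadings, variance partition."""

    eigenvalues: np.ndarray  # descending, constrained axes
    eigenvectors: np.ndarray  # loci x axes, unit norm
    loadings: np.ndarray  # species scores: eigenvector * sqrt(eigenvalue)
    individual_scores: np.ndarray  # residual Y projected on eigenvectors
    biplot_scores: np.ndarray  # predictors x axes correlations
    variance_partition: dict
    env_names: list[str] = field(default_factory=list)
    mem_indices: list[int] = field(default_factory=list)
    locus_ids: list[str] = field(default_factory=list)
    # retained inputs for permutation tests
    _Yres: np.ndarray | None = None
    _Xres: np.ndarray | None = None
    _Qz: np.ndarray | None = None
    _fitted_scores: np.ndarray | None = None
    n: int = 0
    q: int = 0
    r: int = 0


def partial_rda(
    Y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray | None = None,
    env_names: list[str] | None = None,
    mem_indices: list[int] | None = None,
    locus_ids: list[str] | None = None,
) -> RDAModel:
    """Partial RDA of response Y on predictors X given conditioners Z.

    Y: imputed individuals x loci matrix; X: environmental predictors;
    Z: spatial conditioners (may be None/empty for plain RDA).
    """
    Y = np.asarray(Y, dtype=float)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    n, L = Yc.shape
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Z = np.empty((n, 0)) if Z is None else np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if X.shape[0] != n or Z.shape[0] != n:
        raise ValueError("rows of Y, X and Z must align")
    env_names = list(env_names) if env_names else [f"x{i + 1}" for i in range(X.shape[1])]

    ss_total = float(np.sum(Yc * Yc))
    if ss_total <= 0:
        raise ValueError("response matrix has zero variance")

    # collinearity within X itself is an error; columns aliased by the
    # conditioners and earlier predictors are dropped sequentially
    # (vegan-style), so Z = X gives a null fit and site-level designs whose
    # joint [Z, X] rank is exhausted degrade gracefully
    _orthobasis(X, names=env_names, what="predictor matrix (X)")
    Qz = _orthobasis(Z, what="conditioning matrix (Z)") if Z.shape[1] else np.empty((n, 0))
    r = Qz.shape[1]
    Yres = Yc - Qz @ (Qz.T @ Yc) if r else Yc
    Xc_full = X - X.mean(axis=0, keepdims=True)
    norm0 = np.linalg.norm(Xc_full, axis=0)
    Xres_full = Xc_full - Qz @ (Qz.T @ Xc_full) if r else Xc_full
    kept, basis_cols = [], []
    for j in range(Xres_full.shape[1]):
        x = Xres_full[:, [j]].copy()
        for b in basis_cols:
            x -= b @ (b.T @ x)
        nr = float(np.linalg.norm(x))
        if nr <= 1e-8 * max(norm0[j], 1.0):
            continue
        kept.append(j)
        basis_cols.append(x / nr)
    if len(kept) < X.shape[1]:
        dropped = [env_names[j] for j in range(X.shape[1]) if j not in kept]
        logger.warning("partial_rda: predictors aliased by conditioners: %s", dropped)
        env_names = [env_names[j] for j in kept]
    Xres = Xres_full[:, kept]
    Qx = np.hstack(basis_cols) if basis_cols else np.empty((n, 0))
    q = Qx.shape[1]
    Yhat = Qx @ (Qx.T @ Yres) if q else np.zeros_like(Yres)

    ss_res_after_z = float(np.sum(Yres * Yres))
    ss_constrained = float(np.sum(Yhat * Yhat))
    conditioned = (ss_total - ss_res_after_z) / ss_total
    constrained = ss_constrained / ss_total
    residual = 1.0 - conditioned - constrained

    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    keep = (s**2) > 1e-12 * max((s**2).max(), 1.0)
    keep &= np.arange(len(s)) < q  # at most q constrained axes
    U, s, V = U[:, keep], s[keep], Vt[keep].T
    # deterministic sign convention
    for j in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
            U[:, j] = -U[:, j]
    eigenvalues = s**2 / (n - 1)
    loadings = V * np.sqrt(eigenvalues)[None, :]
    scores = Yres @ V
    fitted_scores = U * s[None, :]
    if scores.shape[1] and Xres.shape[1]:
        sd_x = Xres.std(axis=0, ddof=1)
        sd_s = fitted_scores.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            biplot = (Xres.T @ fitted_scores) / (n - 1) / np.outer(sd_x, sd_s)
        biplot = np.nan_to_num(biplot)
    else:
        biplot = np.empty((Xres.shape[1], scores.shape[1]))

    return RDAModel(
        eigenvalues=eigenvalues,
        eigenvectors=V,
        loadings=loadings,
        individual_scores=scores,
        biplot_scores=biplot,
        variance_partition={
            "conditioned": conditioned,
            "constrained": constrained,
            "residual": residual,
        },
        env_names=env_names,
        mem_indices=list(mem_indices) if mem_indices else [],
        locus_ids=list(locus_ids) if locus_ids else [f"locus{i + 1}" for i in range(L)],
        _Yres=Yres,
        _Xres=Xres,
        _Qz=Qz,
        _fitted_scores=fitted_scores,
        n=n,
        q=q,
        r=r,
    )


# ---------------------------------------------------------------------------
# Permutation significance (ANOVA-like)
# ---------------------------------------------------------------------------

@dataclass
class PermTestResult:
    scope: str
    label: str
    statistic: float
    pvalue: float
    n_perm: int


def _pseudo_f(ss_model: float, ss_resid: float, q: int, dof_resid: int) -> float:
    return (ss_model / q) / (ss_resid / dof_resid)


def _residual_perm_test(Yres, Qcond, Qpred, q, r, n_perm, rng):
    """Permute residuals of the reduced (conditioning-only) model.

    Yres: response already residualized on the conditioners; Qcond:
    conditioning basis (re-applied after each permutation); Qpred:
    predictor basis orthogonal to Qcond.
    """
    n = Yres.shape[0]
    dof = n - q - r - 1
    if dof <= 0:
        raise ValueError("not enough residual degrees of freedom")

    def f_of(Ym):
        if Qcond.shape[1]:
            Ym = Ym - Qcond @ (Qcond.T @ Ym)
        ssm = float(np.sum((Qpred.T @ Ym) ** 2))
        ssr = float(np.sum(Ym * Ym)) - ssm
        return _pseudo_f(ssm, ssr, q, dof)

    f_obs = f_of(Yres)
    f_perm = np.empty(n_perm)
    for b in range(n_perm):
        f_perm[b] = f_of(Yres[rng.permutation(n)])
    p = (np.sum(f_perm >= f_obs - 1e-12) + 1) / (n_perm + 1)
    return f_obs, p


def permutation_significance(
    model: RDAModel, scope: str = "overall", n_perm: int = 1000, seed: int | None = 0
) -> list[PermTestResult]:
    """Permutation ANOVA of the fitted model.

    scope="overall": one test of all predictors; scope="term": marginal test
    per environmental variable (all other variables join the conditioners);
    scope="axis": sequential axis tests (earlier constrained axes join the
    conditioners).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if model._Yres is None:
        raise ValueError("model does not retain its inputs")
    rng = np.random.default_rng(seed)
    Yres, Xres, Qz = model._Yres, model._Xres, model._Qz
    n, q, r = model.n, model.q, model.r
    results: list[PermTestResult] = []
    if scope == "overall":
        if q == 0:
            results.append(PermTestResult("overall", "model", np.nan, 1.0, n_perm))
            return results
        Qx = _orthobasis(Xres)
        f, p = _residual_perm_test(Yres, Qz, Qx, q, r, n_perm, rng)
        results.append(PermTestResult("overall", "model", f, p, n_perm))
    elif scope == "term":
        for j, name in enumerate(model.env_names):
            others = np.delete(Xres, j, axis=1)
            cond = np.hstack([Qz, _orthobasis(others)]) if others.shape[1] else Qz
            Qc = _orthobasis(cond) if cond.shape[1] else cond
            xj = Xres[:, [j]]
            xj = xj - Qc @ (Qc.T @ xj) if Qc.shape[1] else xj
            Qj = _orthobasis(xj, names=[name], what=f"marginal predictor {name}")
            Yr = Yres - Qc @ (Qc.T @ Yres) if Qc.shape[1] else Yres
            f, p = _residual_perm_test(Yr, Qc, Qj, 1, q - 1 + r, n_perm, rng)
            results.append(PermTestResult("term", name, f, p, n_perm))
    elif scope == "axis":
        F = model._fitted_scores
        for a in range(len(model.eigenvalues)):
            cond = np.hstack([Qz, F[:, :a]]) if (Qz.shape[1] or a) else np.empty((n, 0))
            Qc = _orthobasis(cond) if cond.shape[1] else cond
            Xr = Xres - Qc @ (Qc.T @ Xres) if Qc.shape[1] else Xres
            # after removing earlier axes the predictor space loses one rank
            Qxr, Rr = np.linalg.qr(Xr - Xr.mean(axis=0))
            dj = np.abs(np.diag(Rr))
            Qxr = Qxr[:, dj > 1e-9 * max(1.0, dj.max())]
            Yr = Yres - Qc @ (Qc.T @ Yres) if Qc.shape[1] else Yres
            dof = n - q - r - 1

            def f_axis(Ym, _Qc=Qc, _Qxr=Qxr, _dof=dof):
                if _Qc.shape[1]:
                    Ym = Ym - _Qc @ (_Qc.T @ Ym)
                if not _Qxr.shape[1]:
                    return 0.0
                B = _Qxr.T @ Ym
                lam = np.linalg.svd(B, compute_uv=False)
                lam1 = float(lam[0] ** 2) if len(lam) else 0.0
                ssr = float(np.sum(Ym * Ym)) - float(np.sum(B * B))
                return lam1 / (ssr / _dof)

            f_obs = f_axis(Yr)
            f_perm = np.empty(n_perm)
            for b in range(n_perm):
                f_perm[b] = f_axis(Yr[rng.permutation(n)])
            p = (np.sum(f_perm >= f_obs - 1e-12) + 1) / (n_perm + 1)
            results.append(PermTestResult("axis", f"RDA{a + 1}", f_obs, p, n_perm))
    else:
        raise ValueError("scope must be 'overall', 'term' or 'axis'")
    return results


# ---------------------------------------------------------------------------
# Candidate detection and predictor assignment
# ---------------------------------------------------------------------------

@dataclass
class CandidateSet:
    table: pd.DataFrame  # locus_id, axis, loading, z, best_predictor, rho, p
    sd_mult: float

    def __len__(self) -> int:
        return len(self.table)

    @property
    def locus_ids(self) -> list[str]:
        return self.table["locus_id"].tolist()


def detect_candidates(
    model: RDAModel, significant_axes: list[int], sd_mult: float = 3.0
) -> CandidateSet:
    """Flag loci whose loading z-score exceeds +-``sd_mult`` on any
    significant axis; duplicates resolved to the axis of largest |z|."""
    if not len(significant_axes):
        raise ValueError("significant_axes must be a nonempty list of axis indices")
    rows = {}
    for a in significant_axes:
        load = model.loadings[:, a]
        sd = load.std(ddof=1) if len(load) > 1 else 0.0
        if not np.isfinite(sd) or sd == 0:
            logger.warning("detect_candidates: axis %d has zero loading SD; skipped", a)
            continue
        z = (load - load.mean()) / sd
        for i in np.flatnonzero(np.abs(z) >= sd_mult):
            lid = model.locus_ids[i]
            if lid not in rows or abs(z[i]) > abs(rows[lid]["z"]):
                rows[lid] = {
                    "locus_id": lid,
                    "axis": a + 1,
                    "loading": float(load[i]),
                    "z": float(z[i]),
                    "best_predictor": "",
                    "rho": np.nan,
                    "p": np.nan,
                }
    table = pd.DataFrame(
        list(rows.values()),
        columns=["locus_id", "axis", "loading", "z", "best_predictor", "rho", "p"],
    )
    return CandidateSet(table=table.reset_index(drop=True), sd_mult=sd_mult)


def assign_predictors(
    candidates: CandidateSet, G: GenotypeMatrix, E_values: np.ndarray, env_names: list[str]
) -> CandidateSet:
    """Assign each candidate its best predictor by |Spearman rho|.

    Uses the raw observed dosages (not the imputed matrix) over
    pairwise-complete individuals; ties in ranks use average ranks.
    """
    E_values = np.asarray(E_values, dtype=float)
    idx = {lid: i for i, lid in enumerate(G.locus_ids)}
    tab = candidates.table.copy()
    for row_i, lid in enumerate(tab["locus_id"]):
        dos = G.dosage[:, idx[lid]]
        obs = ~np.isnan(dos)
        best = ("", 0.0, np.nan)
        if obs.sum() >= 3 and np.nanstd(dos[obs]) > 0:
            for j, name in enumerate(env_names):
                rho, p = stats.spearmanr(dos[obs], E_values[obs, j])
                if np.isnan(rho):
                    continue
                if abs(rho) > abs(best[1]) or best[0] == "":
                    best = (name, float(rho), float(p))
        else:
            logger.warning("assign_predictors: constant/near-empty dosage at %s", lid)
            best = ("none", np.nan, np.nan)
        tab.loc[row_i, ["best_predictor", "rho", "p"]] = best
    return CandidateSet(table=tab, sd_mult=candidates.sd_mult)
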