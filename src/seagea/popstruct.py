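"""Population diversity and structure.

Per-site observed/expected heterozygosity, pairwise Weir & Cockerham (1984)
F_ST with label-permutation significance and Benjamini-Yekutieli control,
genotype PCA, and a maximum-likelihood finite-mixture ("snapclust-style")
ancestry model fitted by EM with AIC / cross-validation choice of K.

Multilocus theta is the ratio of summed variance components over loci
(ratio of sums, not mean of ratios).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .genoqc import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FstResult",
    "ClusterResult",
    "diversity_by_site",
    "wc_theta",
    "pairwise_fst",
    "fdr_adjust",
    "genotype_pca",
    "em_cluster",
    "choose_k",
]


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) variance components
# ---------------------------------------------------------------------------

def _group_counts(dosage: np.ndarray, labels: np.ndarray):
    """Per-group, per-locus: genotyped count N, allele-copy sum S, het count H."""
    groups, inv = np.unique(labels, return_inverse=True)
    r = len(groups)
    n = dosage.shape[0]
    ind = np.zeros((r, n))
    ind[inv, np.arange(n)] = 1.0
    obs = (~np.isnan(dosage)).astype(float)
    A = np.nan_to_num(dosage)
    het = (dosage == 1).astype(float)
    return groups, ind @ obs, ind @ A, ind @ het


def _wc_sums(N: np.ndarray, S: np.ndarray, H: np.ndarray):
    """Summed W&C components (sum_a, sum_abc) from per-group count arrays.

    N, S, H have shape (..., r, L): genotyped diploids, allele-copy sums and
    heterozygote counts per group.  Loci (slices) with fewer than two
    populated groups, or nbar <= 1, contribute nothing.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        present = N >= 1
        r_l = present.sum(axis=-2)
        n_tot = N.sum(axis=-2)
        nbar = n_tot / np.maximum(r_l, 1)
        nc = (n_tot - (N * N).sum(axis=-2) / np.where(n_tot > 0, n_tot, 1.0)) / np.maximum(
            r_l - 1, 1
        )
        p = np.where(present, S / np.maximum(2.0 * N, 1e-300), 0.0)
        pbar = S.sum(axis=-2) / np.maximum(2.0 * n_tot, 1e-300)
        s2 = (N * (p - pbar[..., None, :]) ** 2).sum(axis=-2) / np.maximum(
            (r_l - 1) * nbar, 1e-300
        )
        hbar = H.sum(axis=-2) / np.maximum(n_tot, 1e-300)
        pq = pbar * (1.0 - pbar)
        frac = (r_l - 1.0) / np.maximum(r_l, 1)
        a = (nbar / np.maximum(nc, 1e-300)) * (
            s2 - (pq - frac * s2 - hbar / 4.0) / np.maximum(nbar - 1.0, 1e-300)
        )
        b = (nbar / np.maximum(nbar - 1.0, 1e-300)) * (
            pq - frac * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    valid = (r_l >= 2) & (nbar > 1.0) & (nc > 0)
    a = np.where(valid, a, 0.0)
    b = np.where(valid, b, 0.0)
    c = np.where(valid, c, 0.0)
    return a.sum(axis=-1), (a + b + c).sum(axis=-1)


def wc_theta(dosage: np.ndarray, labels) -> float:
    """Multilocus Weir-Cockerham theta over all groups in ``labels``."""
    labels = np.asarray(labels)
    _, N, S, H = _group_counts(np.asarray(dosage, dtype=float), labels)
    sa, sabc = _wc_sums(N, S, H)
    if sabc == 0:
        return np.nan
    return float(sa / sabc)


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def diversity_by_site(G: GenotypeMatrix, site_labels) -> pd.DataFrame:
    """Per-site observed (Ho) and unbiased expected (He) heterozygosity.

    He per locus is 2 p (1-p) * 2n/(2n-1) with n genotyped diploids at the
    site; loci with fewer than 2 genotyped individuals at a site are skipped
    there.  Site values are means over retained loci.
    """
    site_labels = np.asarray(site_labels)
    if len(site_labels) != G.n_individuals:
        raise ValueError("site labels do not match individuals")
    rows = []
    for site in pd.unique(site_labels):
        sub = G.dosage[site_labels == site]
        n = np.sum(~np.isnan(sub), axis=0)
        keep = n >= 2
        if not keep.any():
            raise ValueError(f"site {site!r} has no locus with >= 2 genotyped individuals")
        n = n[keep].astype(float)
        sub = sub[:, keep]
        ho = np.nansum(sub == 1, axis=0) / n
        p = np.nansum(sub, axis=0) / (2.0 * n)
        he = 2.0 * p * (1.0 - p) * (2.0 * n) / (2.0 * n - 1.0)
        rows.append({"site": site, "N": int(sub.shape[0]), "Ho": float(ho.mean()), "He": float(he.mean())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pairwise F_ST with permutation tests
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    sites: list
    theta: np.ndarray
    pvalues: np.ndarray
    adjusted: np.ndarray
    significant: np.ndarray
    q: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.sites)):
            for j in range(i + 1, len(self.sites)):
                rows.append(
                    {
                        "site_a": self.sites[i],
                        "site_b": self.sites[j],
                        "theta": self.theta[i, j],
                        "p": self.pvalues[i, j],
                        "p_adjusted": self.adjusted[i, j],
                        "significant": bool(self.significant[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def _pair_theta_perm(dos: np.ndarray, n1: int, n_perm: int, rng, chunk: int = 2000):
    """Observed two-group theta and permuted thetas for one site pair.

    ``dos`` holds the pooled individuals (first ``n1`` rows = group 1)."""
    n = dos.shape[0]
    obs = (~np.isnan(dos)).astype(float)
    A = np.nan_to_num(dos)
    het = (dos == 1).astype(float)
    Nt, St, Ht = obs.sum(0), A.sum(0), het.sum(0)

    def theta_from_g1(ind1):
        # ind1: (B, n) 0/1 indicator of group-1 membership
        N1 = ind1 @ obs
        S1 = ind1 @ A
        H1 = ind1 @ het
        N = np.stack([N1, Nt - N1], axis=-2)
        S = np.stack([S1, St - S1], axis=-2)
        H = np.stack([H1, Ht - H1], axis=-2)
        sa, sabc = _wc_sums(N, S, H)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sabc != 0, sa / sabc, np.nan)

    ind_obs = np.zeros((1, n))
    ind_obs[0, :n1] = 1.0
    theta_obs = float(theta_from_g1(ind_obs)[0])
    perm = np.empty(n_perm)
    done = 0
    while done < n_perm:
        B = min(chunk, n_perm - done)
        keys = rng.random((B, n))
        order = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
        ind1 = np.zeros((B, n))
        np.put_along_axis(ind1, order, 1.0, axis=1)
        perm[done : done + B] = theta_from_g1(ind1)
        done += B
    return theta_obs, perm


def pairwise_fst(
    G: GenotypeMatrix,
    site_labels,
    n_perm: int = 10_000,
    q: float = 0.10,
    seed: int | None = 0,
    method: str = "BY",
) -> FstResult:
    """Pairwise multilocus Weir-Cockerham theta with permutation p-values
    ((exceedances+1)/(n_perm+1)) and step-up FDR flags across all pairs."""
    site_labels = np.asarray(site_labels)
    sites = [s for s in pd.unique(site_labels)]
    sizes = {s: int(np.sum(site_labels == s)) for s in sites}
    small = [s for s in sites if sizes[s] < 2]
    if small:
        logger.warning("pairwise_fst: excluding sites with < 2 individuals: %s", small)
        sites = [s for s in sites if sizes[s] >= 2]
    if len(sites) < 2:
        raise ValueError("pairwise_fst needs at least two sites with >= 2 individuals")
    rng = np.random.default_rng(seed)
    m = len(sites)
    theta = np.zeros((m, m))
    pmat = np.full((m, m), np.nan)
    pairs, pvals = [], []
    for i in range(m):
        for j in range(i + 1, m):
            dos = np.vstack(
                [G.dosage[site_labels == sites[i]], G.dosage[site_labels == sites[j]]]
            )
            t_obs, t_perm = _pair_theta_perm(dos, sizes[sites[i]], n_perm, rng)
            p = (np.sum(t_perm >= t_obs - 1e-12) + 1) / (n_perm + 1)
            theta[i, j] = theta[j, i] = t_obs
            pmat[i, j] = pmat[j, i] = p
            pairs.append((i, j))
            pvals.append(p)
    adjusted, flags = fdr_adjust(np.asarray(pvals), method=method, q=q)
    adj = np.full((m, m), np.nan)
    sig = np.zeros((m, m), dtype=bool)
    for (i, j), a, f in zip(pairs, adjusted, flags):
        adj[i, j] = adj[j, i] = a
        sig[i, j] = sig[j, i] = f
    return FstResult(sites=sites, theta=theta, pvalues=pmat, adjusted=adj, significant=sig, q=q)


def fdr_adjust(pvalues, method: str = "BY", q: float = 0.05):
    """Step-up FDR adjustment (BH or BY); returns (adjusted, flags at <= q)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"BY": "fdr_by", "BH": "fdr_bh"}.get(method.upper())
    if key is None:
        raise ValueError(f"unknown FDR method {method!r}")
    _, adjusted, _, _ = multipletests(p, alpha=q, method=key)
    return adjusted, adjusted <= q


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def genotype_pca(Y: np.ndarray):
    """PCA of a centered individuals x loci matrix.

    Returns (scores, explained_fractions): scores are individual coordinates
    (U * s), fractions are eigenvalue shares of total variance.
    """
    Y = np.asarray(Y, dtype=float)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Yc, full_matrices=False)
    tot = float(np.sum(Yc * Yc))
    frac = (s**2) / tot if tot > 0 else np.zeros_like(s)
    return U * s, frac


# ---------------------------------------------------------------------------
# ML mixture clustering (EM)
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    K: int
    membership: np.ndarray  # individuals x K, rows sum to 1
    frequencies: np.ndarray  # K x loci
    log_likelihood: float
    aic: float
    loglik_path: list[float]
    cv_error: float | None = None


def _binom_const(dosage: np.ndarray) -> float:
    # sum over observed genotypes of log C(2, g); only hets contribute log 2
    return float(np.sum(dosage == 1) * np.log(2.0))


def _em_once(A, M, K, rng, max_iter, tol):
    n, L = A.shape
    resp = rng.dirichlet(np.ones(K), size=n)
    pi = np.full(K, 1.0 / K)
    ll_prev = -np.inf
    path = []
    F = None
    for _ in range(max_iter):
        # M-step from responsibilities
        denom = 2.0 * (resp.T @ M)
        F = (resp.T @ A) / np.maximum(denom, 1e-300)
        F = np.clip(F, 1e-9, 1.0 - 1e-9)
        pi = resp.mean(axis=0)
        pi = np.clip(pi, 1e-12, None)
        pi = pi / pi.sum()
        # E-step
        logF = np.log(F)
        log1F = np.log1p(-F)
        ll_ik = A @ logF.T + (2.0 * M - A) @ log1F.T + np.log(pi)[None, :]
        ll = float(np.sum(logsumexp(ll_ik, axis=1)))
        resp = np.exp(ll_ik - logsumexp(ll_ik, axis=1, keepdims=True))
        path.append(ll)
        if ll - ll_prev < tol * max(1.0, abs(ll)) and ll >= ll_prev - 1e-9:
            ll_prev = ll
            break
        ll_prev = ll
    return ll_prev, resp, F, path


def em_cluster(
    dosage: np.ndarray,
    K: int,
    seed: int | None = 0,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> ClusterResult:
    """Fit a K-component binomial mixture (Hardy-Weinberg within cluster)
    by EM; best of ``n_restarts`` seeded random starts.

    AIC = -2 logL + 2 * K * L, counting only the K x L cluster allele
    frequencies as parameters (snapclust convention).
    """
    X = np.asarray(dosage, dtype=float)
    n, L = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of individuals ({n})")
    M = (~np.isnan(X)).astype(float)
    A = np.nan_to_num(X)
    const = _binom_const(X)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts if K > 1 else 1)):
        ll, resp, F, path = _em_once(A, M, K, rng, max_iter, tol)
        if best is None or ll > best[0]:
            best = (ll, resp, F, path)
    ll, resp, F, path = best
    ll_total = ll + const
    aic = -2.0 * ll_total + 2.0 * K * L
    return ClusterResult(
        K=K,
        membership=resp,
        frequencies=F,
        log_likelihood=ll_total,
        aic=aic,
        loglik_path=[p + const for p in path],
    )


def choose_k(
    dosage: np.ndarray,
    k_range=range(1, 10),
    method: str = "AIC",
    cv_replicates: int = 10,
    cv_mask_frac: float = 0.10,
    seed: int | None = 0,
    n_restarts: int = 10,
) -> tuple[pd.DataFrame, int]:
    """Score K over ``k_range`` by AIC or masked-entry cross-validation.

    CV mode masks ``cv_mask_frac`` of the observed genotype entries per
    replicate, refits, and scores mean squared prediction error of the
    masked dosages from membership-weighted expected dosages.
    """
    X = np.asarray(dosage, dtype=float)
    rng = np.random.default_rng(seed)
    method = method.upper()
    if method not in {"AIC", "CV"}:
        raise ValueError("method must be 'AIC' or 'CV'")
    rows = []
    for K in k_range:
        fit_seed = int(rng.integers(2**31 - 1))
        res = em_cluster(X, K, seed=fit_seed, n_restarts=n_restarts)
        row = {"K": K, "logL": res.log_likelihood, "AIC": res.aic, "cv_error": np.nan}
        if method == "CV":
            obs_idx = np.argwhere(~np.isnan(X))
            errs = []
            for _ in range(cv_replicates):
                pick = rng.choice(
                    len(obs_idx), size=max(1, int(cv_mask_frac * len(obs_idx))), replace=False
                )
                mask_idx = obs_idx[pick]
                Xm = X.copy()
                Xm[mask_idx[:, 0], mask_idx[:, 1]] = np.nan
                sub_seed = int(rng.integers(2**31 - 1))
                fit = em_cluster(Xm, K, seed=sub_seed, n_restarts=n_restarts)
                pred = fit.membership @ (2.0 * fit.frequencies)
                truth = X[mask_idx[:, 0], mask_idx[:, 1]]
                errs.append(float(np.mean((pred[mask_idx[:, 0], mask_idx[:, 1]] - truth) ** 2)))
            row["cv_error"] = float(np.mean(errs))
        rows.append(row)
    table = pd.DataFrame(rows)
    crit = "AIC" if method == "AIC" else "cv_error"
    best_k = int(table.loc[table[crit].idxmin(), "K"])
    return table, best_k
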