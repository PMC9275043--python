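"""Partial RDA, permutation ANOVA, outlier detection, predictor assignment."""

import numpy as np
import pytest
from scipy import stats

from seagea.gearda import (
    RDAModel,
    assign_predictors,
    detect_candidates,
    impute_dosage,
    partial_rda,
    permutation_significance,
)
from seagea.genoqc import GenotypeMatrix


def brute_force_rda(Y, X, Z=None):
    """Independent oracle: explicit projection matrices + dense eigensolver."""
    def c(M):
        return M - M.mean(axis=0, keepdims=True)

    Yc, Xc = c(np.asarray(Y, float)), c(np.asarray(X, float))
    n = Yc.shape[0]
    if Z is not None and np.asarray(Z).size:
        Zc = c(np.asarray(Z, float))
        Pz = Zc @ np.linalg.pinv(Zc.T @ Zc) @ Zc.T
        Yr, Xr = Yc - Pz @ Yc, Xc - Pz @ Xc
    else:
        Yr, Xr = Yc, Xc
    Px = Xr @ np.linalg.pinv(Xr.T @ Xr) @ Xr.T
    Yh = Px @ Yr
    w, v = np.linalg.eigh(Yh.T @ Yh / (n - 1))
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    keep = w > 1e-12 * max(w.max(), 1.0)
    ss_tot = np.sum(Yc**2)
    parts = {
        "conditioned": (ss_tot - np.sum(Yr**2)) / ss_tot,
        "constrained": np.sum(Yh**2) / ss_tot,
    }
    parts["residual"] = 1 - parts["conditioned"] - parts["constrained"]
    return w[keep], v[:, keep], parts, Yr


class TestImpute:
    def test_no_missing_centering_only(self, rng):
        X = rng.integers(0, 3, size=(8, 5)).astype(float)
        out = impute_dosage(X)
        assert np.abs(out.sum(axis=0)).max() < 1e-10
        assert np.allclose(out, X - X.mean(axis=0))

    def test_closed_form_missing(self):
        X = np.array([[0.0], [2.0], [np.nan]])
        out = impute_dosage(X)
        assert np.allclose(out[:, 0], [-1, 1, 0])

    def test_mean_preserved(self, rng):
        X = rng.integers(0, 3, size=(30, 10)).astype(float)
        X[rng.random(X.shape) < 0.2] = np.nan
        means = np.nanmean(X, axis=0)
        out = impute_dosage(X)
        filled = out + means[None, :]
        assert np.allclose(filled.mean(axis=0), means)

    def test_all_missing_locus_raises(self):
        X = np.array([[np.nan], [np.nan]])
        with pytest.raises(ValueError, match="no observed"):
            impute_dosage(X)


class TestPartialRDA:
    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(8):
            n = int(rng.integers(8, 20))
            L = int(rng.integers(4, 30))
            q = int(rng.integers(1, 4))
            r = int(rng.integers(0, 3))
            Y = rng.standard_normal((n, L))
            X = rng.standard_normal((n, q))
            Z = rng.standard_normal((n, r)) if r else None
            m = partial_rda(Y, X, Z)
            w, v, parts, Yr = brute_force_rda(Y, X, Z)
            k = len(m.eigenvalues)
            assert np.allclose(m.eigenvalues, w[:k], atol=1e-8)
            for j in range(k):  # eigenvectors defined up to sign
                dot = abs(m.eigenvectors[:, j] @ v[:, j])
                assert dot == pytest.approx(1.0, abs=1e-8)
            for key in parts:
                assert m.variance_partition[key] == pytest.approx(parts[key], abs=1e-8)

    def test_null_constrained_fraction_small(self, rng):
        n, q = 200, 2
        Y = rng.standard_normal((n, 300))
        X = rng.standard_normal((n, q))
        m = partial_rda(Y, X)
        assert m.variance_partition["constrained"] < 2 * q / n

    def test_perfect_fit(self, rng):
        X = rng.standard_normal((15, 2))
        B = rng.standard_normal((2, 6))
        m = partial_rda(X @ B, X)
        assert m.variance_partition["constrained"] == pytest.approx(1.0, abs=1e-10)
        assert m.variance_partition["residual"] == pytest.approx(0.0, abs=1e-10)

    def test_conditioning_on_x_removes_everything(self, rng):
        Y = rng.standard_normal((40, 30))
        X = rng.standard_normal((40, 3))
        m = partial_rda(Y, X, Z=X)
        assert m.variance_partition["constrained"] < 1e-8
        assert len(m.eigenvalues) == 0

    def test_rotation_consistency(self, rng):
        Y = rng.standard_normal((25, 40))
        X = rng.standard_normal((25, 3))
        Z = rng.standard_normal((25, 2))
        m = partial_rda(Y, X, Z)
        _, _, _, Yr = brute_force_rda(Y, X, Z)
        recon = Yr @ m.eigenvectors
        assert np.abs(m.individual_scores - recon).max() < 1e-8

    def test_axis_count_bounded_by_predictors(self, rng):
        m = partial_rda(rng.standard_normal((20, 50)), rng.standard_normal((20, 2)))
        assert len(m.eigenvalues) <= 2
        assert np.all(m.eigenvalues >= 0)
        assert np.all(np.diff(m.eigenvalues) <= 1e-12)

    def test_collinear_predictors_named(self, rng):
        x = rng.standard_normal(12)
        with pytest.raises(ValueError, match="dup"):
            partial_rda(
                rng.standard_normal((12, 5)),
                np.column_stack([x, x]),
                env_names=["orig", "dup"],
            )


class TestPermutationSignificance:
    def test_same_seed_identical_p(self, rng):
        Y = rng.standard_normal((30, 40))
        X = rng.standard_normal((30, 2))
        m = partial_rda(Y, X)
        p1 = permutation_significance(m, "overall", 99, seed=7)[0].pvalue
        p2 = permutation_significance(m, "overall", 99, seed=7)[0].pvalue
        assert p1 == p2

    def test_planted_signal_smallest_p(self, rng):
        n = 100
        X = rng.standard_normal((n, 2))
        Y = X @ rng.standard_normal((2, 50)) + 0.5 * rng.standard_normal((n, 50))
        m = partial_rda(Y, X)
        assert m.variance_partition["constrained"] > 0.2
        res = permutation_significance(m, "overall", 199, seed=0)[0]
        assert res.pvalue == pytest.approx(1 / 200)

    def test_term_and_axis_scopes_return_per_item_results(self, rng):
        Y = rng.standard_normal((40, 30))
        X = rng.standard_normal((40, 3))
        m = partial_rda(Y, X, env_names=["a", "b", "c"])
        terms = permutation_significance(m, "term", 49, seed=1)
        assert [t.label for t in terms] == ["a", "b", "c"]
        axes = permutation_significance(m, "axis", 49, seed=1)
        assert len(axes) == len(m.eigenvalues)
        for t in terms + axes:
            assert 0 < t.pvalue <= 1

    def test_invalid_n_perm(self, rng):
        m = partial_rda(rng.standard_normal((10, 5)), rng.standard_normal((10, 1)))
        with pytest.raises(ValueError, match="n_perm"):
            permutation_significance(m, "overall", 0)


def model_with_loadings(load):
    load = np.asarray(load, dtype=float)
    if load.ndim == 1:
        load = load[:, None]
    return RDAModel(
        eigenvalues=np.ones(load.shape[1]),
        eigenvectors=load,
        loadings=load,
        individual_scores=np.empty((0, load.shape[1])),
        biplot_scores=np.empty((0, load.shape[1])),
        variance_partition={},
        locus_ids=[f"l{i}" for i in range(load.shape[0])],
    )


class TestDetectCandidates:
    def test_planted_outlier_is_the_only_flag(self, rng):
        # normal draws truncated inside +-2.5 SD, plus one value at 5 SD
        load = rng.standard_normal(999)
        load = load[np.abs(load) < 2.5][:900]
        load = np.append(load, 5.0 * load.std())
        cs = detect_candidates(model_with_loadings(load), [0], 3.0)
        assert cs.locus_ids == [f"l{len(load) - 1}"]

    def test_sd_mult_zero_flags_everything(self, rng):
        load = rng.standard_normal(50)
        cs = detect_candidates(model_with_loadings(load), [0], 0.0)
        assert len(cs) == 50

    def test_duplicate_across_axes_keeps_largest_z(self, rng):
        load = rng.standard_normal((200, 2)) * 0.1
        load[0] = [5.0, -8.0]
        cs = detect_candidates(model_with_loadings(load), [0, 1], 3.0)
        row = cs.table[cs.table["locus_id"] == "l0"]
        assert len(row) == 1 and int(row["axis"].iloc[0]) == 2

    def test_zero_sd_axis_yields_no_candidates(self):
        cs = detect_candidates(model_with_loadings(np.ones(10)), [0], 3.0)
        assert len(cs) == 0

    def test_empty_axis_list_raises(self):
        with pytest.raises(ValueError, match="nonempty"):
            detect_candidates(model_with_loadings(np.arange(5.0)), [])


def tiny_G(dosage):
    dosage = np.asarray(dosage, dtype=float)
    n, L = dosage.shape
    return GenotypeMatrix(
        dosage=dosage,
        sample_ids=[f"i{k}" for k in range(n)],
        locus_ids=[f"l{j}" for j in range(L)],
        contigs=np.asarray(["chr1"] * L, dtype=object),
        positions=np.arange(1, L + 1),
        ref=np.asarray(["A"] * L, dtype=object),
        alt=np.asarray(["T"] * L, dtype=object),
    )


def all_flagged(n_loci):
    """CandidateSet covering every locus of an n_loci two-axis toy model."""
    load = np.column_stack([np.linspace(-1, 1, n_loci), np.linspace(1, -1, n_loci)])
    return detect_candidates(model_with_loadings(load), [0, 1], 0.0)


class TestAssignPredictors:
    def test_monotone_gives_rho_one(self):
        # strictly increasing dosage vs a monotone variable
        G = tiny_G(np.array([[0, 0], [1, 1], [2, 0]], dtype=float))
        cs = all_flagged(2)
        E = np.array([[2.0], [6.0], [10.0]])
        out = assign_predictors(cs, G, E, ["v"])
        row = out.table.set_index("locus_id").loc["l0"]
        assert row["rho"] == pytest.approx(1.0)
        assert row["best_predictor"] == "v"

    def test_invariant_under_monotone_transform(self, rng):
        dos = rng.integers(0, 3, size=(30, 2)).astype(float)
        G = tiny_G(dos)
        cs = all_flagged(2)
        x = rng.standard_normal(30)
        r1 = assign_predictors(cs, G, x[:, None], ["v"]).table.set_index("locus_id")
        r2 = assign_predictors(cs, G, np.exp(3 * x)[:, None], ["v"]).table.set_index("locus_id")
        assert r1.loc["l0", "rho"] == pytest.approx(r2.loc["l0", "rho"])

    def test_tied_ranks_match_average_rank_formula(self):
        dos = np.array([[0, 1], [0, 0], [1, 2], [1, 1], [2, 0], [2, 2]], dtype=float)
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        G = tiny_G(dos)
        out = assign_predictors(all_flagged(2), G, x[:, None], ["v"])
        # hand oracle: Pearson correlation of average ranks
        rd = stats.rankdata(dos[:, 0])
        rx = stats.rankdata(x)
        expected = np.corrcoef(rd, rx)[0, 1]
        assert out.table.set_index("locus_id").loc["l0", "rho"] == pytest.approx(
            expected, abs=1e-12
        )

    def test_constant_dosage_gets_none(self):
        G = tiny_G(np.column_stack([np.ones(6), [0, 1, 2, 0, 1, 2]]))
        out = assign_predictors(all_flagged(2), G, np.arange(6.0)[:, None], ["v"])
        assert out.table.set_index("locus_id").loc["l0", "best_predictor"] == "none"
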