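"""Heterozygosity, Weir-Cockerham F_ST, FDR, PCA and EM clustering."""

import numpy as np
import pytest
from scipy import stats

from seagea.gearda import impute_dosage
from seagea.genoqc import GenotypeMatrix
from seagea.popstruct import (
    choose_k,
    diversity_by_site,
    em_cluster,
    fdr_adjust,
    genotype_pca,
    pairwise_fst,
    wc_theta,
)
from seagea.simgen import site_labels


def make_G(dosage):
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


def hand_wc_two_pops(d1, d2):
    """Scalar hand-computation of W&C (1984) a, b, c for one biallelic locus."""
    n1, n2 = len(d1), len(d2)
    p1, p2 = sum(d1) / (2 * n1), sum(d2) / (2 * n2)
    h1, h2 = sum(1 for g in d1 if g == 1) / n1, sum(1 for g in d2 if g == 1) / n2
    r = 2
    nbar = (n1 + n2) / 2
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


class TestDiversity:
    def test_all_heterozygote_closed_form(self):
        G = make_G(np.ones((4, 1)))
        out = diversity_by_site(G, ["A"] * 4)
        assert out["Ho"].iloc[0] == pytest.approx(1.0)
        assert out["He"].iloc[0] == pytest.approx((8 / 7) * 0.5)

    def test_monomorphic_zero(self):
        G = make_G(np.zeros((5, 1)))
        out = diversity_by_site(G, ["A"] * 5)
        assert out["Ho"].iloc[0] == 0.0 and out["He"].iloc[0] == 0.0

    def test_hardy_weinberg_simulation(self, rng):
        p = 0.3
        g = rng.binomial(2, p, size=(500, 200)).astype(float)
        out = diversity_by_site(make_G(g), ["A"] * 500)
        expected = 2 * p * (1 - p)
        assert out["Ho"].iloc[0] == pytest.approx(expected, abs=0.02)
        assert out["He"].iloc[0] == pytest.approx(expected, abs=0.02)

    def test_unknown_labels_length_raises(self):
        with pytest.raises(ValueError):
            diversity_by_site(make_G(np.ones((4, 1))), ["A"] * 3)


class TestWeirCockerham:
    def test_fixed_difference_theta_one(self):
        dos = np.array([[0.0]] * 10 + [[2.0]] * 10)
        assert wc_theta(dos, ["A"] * 10 + ["B"] * 10) == pytest.approx(1.0)

    def test_toy_counts_match_hand_components(self):
        d1 = [0] * 10
        d2 = [0] * 5 + [1] * 5
        a, b, c = hand_wc_two_pops(d1, d2)
        expected = a / (a + b + c)
        dos = np.asarray(d1 + d2, dtype=float)[:, None]
        theta = wc_theta(dos, ["A"] * 10 + ["B"] * 10)
        assert theta == pytest.approx(expected, abs=1e-10)
        assert theta == pytest.approx(2 / 9, abs=1e-10)

    def test_multilocus_is_ratio_of_sums(self, rng):
        dos = rng.binomial(2, 0.4, size=(30, 5)).astype(float)
        labels = ["A"] * 15 + ["B"] * 15
        per_locus = []
        for j in range(5):
            a, b, c = hand_wc_two_pops(dos[:15, j].tolist(), dos[15:, j].tolist())
            per_locus.append((a, a + b + c))
        expected = sum(x for x, _ in per_locus) / sum(y for _, y in per_locus)
        assert wc_theta(dos, labels) == pytest.approx(expected, abs=1e-10)

    def test_identical_frequency_pops_near_zero(self, rng):
        p = rng.uniform(0.1, 0.9, 1000)
        dos = rng.binomial(2, p, size=(100, 1000)).astype(float)
        labels = ["A"] * 50 + ["B"] * 50
        res = pairwise_fst(make_G(dos), labels, n_perm=99, seed=0)
        assert abs(res.theta[0, 1]) < 0.01
        assert res.pvalues[0, 1] > 0.05

    def test_null_permutation_p_uniform(self, rng):
        pvals = []
        for _ in range(200):
            p = rng.uniform(0.2, 0.8, 60)
            dos = rng.binomial(2, p, size=(30, 60)).astype(float)
            labels = ["A"] * 15 + ["B"] * 15
            res = pairwise_fst(make_G(dos), labels, n_perm=99, seed=int(rng.integers(2**31 - 1)))
            pvals.append(res.pvalues[0, 1])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_site_below_two_individuals_excluded(self, rng):
        dos = rng.binomial(2, 0.5, size=(11, 50)).astype(float)
        labels = ["A"] * 5 + ["B"] * 5 + ["C"]
        res = pairwise_fst(make_G(dos), labels, n_perm=19, seed=0)
        assert res.sites == ["A", "B"]


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        adj, _ = fdr_adjust([0.04], "BH", 0.05)
        assert adj[0] == pytest.approx(0.04)

    def test_bh_step_up_closed_form(self):
        adj, _ = fdr_adjust([0.01, 0.02, 0.03, 0.04], "BH", 0.05)
        assert np.allclose(adj, 0.04)

    def test_by_closed_form(self):
        p = [0.001, 0.01, 0.02, 0.04, 0.05]
        cm = sum(1 / i for i in range(1, 6))  # 137/60
        adj, flags = fdr_adjust(p, "BY", 0.10)
        assert adj.min() == pytest.approx(0.001 * 5 * cm, abs=1e-12)
        assert adj.min() == pytest.approx(0.01141666667, abs=1e-9)

    def test_by_flags_subset_of_bh(self, rng):
        p = rng.uniform(0, 0.3, 40)
        _, by = fdr_adjust(p, "BY", 0.1)
        _, bh = fdr_adjust(p, "BH", 0.1)
        assert np.all(bh[by])  # every BY discovery is a BH discovery

    def test_empty_input(self):
        adj, flags = fdr_adjust([], "BH", 0.05)
        assert adj.size == 0 and flags.size == 0

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            fdr_adjust([1.2], "BH", 0.05)


class TestPCA:
    def test_separates_two_populations(self, rng):
        f = np.vstack([rng.uniform(0.05, 0.3, 200), rng.uniform(0.7, 0.95, 200)])
        dos = np.vstack(
            [rng.binomial(2, f[0], size=(40, 200)), rng.binomial(2, f[1], size=(40, 200))]
        ).astype(float)
        scores, frac = genotype_pca(impute_dosage(dos))
        labels = np.array([0] * 40 + [1] * 40)
        r = np.corrcoef(scores[:, 0], labels)[0, 1]
        assert abs(r) > 0.9
        assert frac[0] > frac[1]

    def test_scores_preserve_distances(self, rng):
        Y = rng.standard_normal((15, 20))
        Yc = Y - Y.mean(axis=0)
        scores, frac = genotype_pca(Y)
        d1 = np.linalg.norm(Yc[:, None] - Yc[None], axis=2)
        d2 = np.linalg.norm(scores[:, None] - scores[None], axis=2)
        assert np.abs(d1 - d2).max() < 1e-8
        assert frac.sum() <= 1 + 1e-12

    def test_duplicated_individual_coincident(self, rng):
        Y = rng.standard_normal((10, 12))
        Y[3] = Y[7]
        scores, _ = genotype_pca(Y)
        assert np.allclose(scores[3], scores[7], atol=1e-10)


class TestEMCluster:
    def test_k1_matches_closed_form_likelihood(self, rng):
        dos = rng.binomial(2, rng.uniform(0.2, 0.8, 40), size=(25, 40)).astype(float)
        dos[rng.random(dos.shape) < 0.05] = np.nan
        res = em_cluster(dos, 1, seed=0)
        assert np.allclose(res.membership, 1.0)
        obs = ~np.isnan(dos)
        p = np.nansum(dos, axis=0) / (2 * obs.sum(axis=0))
        ll = 0.0
        for i in range(25):
            for j in range(40):
                if obs[i, j]:
                    g = dos[i, j]
                    ll += (
                        np.log([1, 2, 1][int(g)])
                        + g * np.log(p[j])
                        + (2 - g) * np.log(1 - p[j])
                    )
        assert res.log_likelihood == pytest.approx(ll, rel=1e-6)
        assert res.aic == pytest.approx(-2 * ll + 2 * 40, rel=1e-6)

    def test_two_populations_high_assignment_accuracy(self, rng):
        p0 = rng.uniform(0.2, 0.8, 100)
        a = 9.0  # Beta concentration for divergence F = 1/(a+1) = 0.1
        f = rng.beta(p0 * a, (1 - p0) * a, size=(2, 100))
        dos = np.vstack(
            [rng.binomial(2, f[0], size=(50, 100)), rng.binomial(2, f[1], size=(50, 100))]
        ).astype(float)
        res = em_cluster(dos, 2, seed=0)
        hard = res.membership.argmax(axis=1)
        acc = max(np.mean(hard == [0] * 50 + [1] * 50), np.mean(hard == [1] * 50 + [0] * 50))
        assert acc >= 0.95

    def test_loglik_nondecreasing(self, rng):
        dos = rng.binomial(2, 0.5, size=(30, 50)).astype(float)
        res = em_cluster(dos, 3, seed=1, n_restarts=1)
        path = np.asarray(res.loglik_path)
        assert np.all(np.diff(path) >= -1e-6)

    def test_k_exceeding_individuals_raises(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            em_cluster(rng.binomial(2, 0.5, size=(3, 10)).astype(float), 4)


class TestChooseK:
    def test_aic_recomputable_from_loglik(self, rng):
        dos = rng.binomial(2, rng.uniform(0.2, 0.8, 60), size=(30, 60)).astype(float)
        table, _ = choose_k(dos, range(1, 4), "AIC", seed=0, n_restarts=3)
        L = 60
        for _, row in table.iterrows():
            assert row["AIC"] == pytest.approx(-2 * row["logL"] + 2 * row["K"] * L, rel=1e-12)

    def test_three_planted_populations_recovered(self, rng):
        p0 = rng.uniform(0.2, 0.8, 150)
        a = 9.0
        f = rng.beta(p0 * a, (1 - p0) * a, size=(3, 150))
        dos = np.vstack(
            [rng.binomial(2, f[k], size=(30, 150)) for k in range(3)]
        ).astype(float)
        _, best_aic = choose_k(dos, range(1, 6), "AIC", seed=0)
        _, best_cv = choose_k(dos, range(1, 6), "CV", cv_replicates=5, seed=0)
        assert best_aic == 3 and best_cv == 3


def test_adaptive_fst_exceeds_neutral_on_fixture(small_fixture):
    G = small_fixture.genotypes
    truth = small_fixture.truth
    labels = site_labels(G)
    adaptive = set(truth.loc[truth["is_adaptive"], "locus_id"])
    idx_a = [i for i, l in enumerate(G.locus_ids) if l in adaptive]
    idx_n = [i for i, l in enumerate(G.locus_ids) if l not in adaptive]
    # contrast between the environmentally extreme ends of the coast
    ends = np.isin(labels, ["S01", small_fixture.config.site_names[-1]])
    theta_a = wc_theta(G.dosage[np.ix_(ends, idx_a)], labels[ends])
    theta_n = wc_theta(G.dosage[np.ix_(ends, idx_n)], labels[ends])
    assert theta_a > theta_n
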