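"""Statistical machinery vs independent oracles: rmANOVA, FDR, contrasts,
ensembles, similarity profiles, network correlations and the spin test."""

import numpy as np
import pytest
from scipy import stats

from fcmanifold import inference as inf
from fcmanifold.inference import (
    InferenceError,
    fdr_bh,
    generate_spins,
    kmeans_ensembles,
    network_correlation,
    paired_contrast,
    reinstatement_test,
    rm_anova_1way,
    rm_anova_2way,
    rsa_profile,
    spin_test,
)


def pingouin_rm_anova_2way(y):
    """Independent two-way rmANOVA oracle (single outcome)."""
    import pandas as pd
    import pingouin as pg

    n, a, b = y.shape
    rows = [
        {"subject": s, "day": d, "epoch": e, "y": y[s, d, e]}
        for s in range(n) for d in range(a) for e in range(b)
    ]
    res = pg.rm_anova(data=pd.DataFrame(rows), dv="y", within=["day", "epoch"],
                      subject="subject", detailed=True)
    return res.set_index("Source")


class TestRmAnova2Way:
    def test_matches_pingouin(self, rng):
        y = rng.standard_normal((8, 2, 5))
        y[:, :, 1] += 0.8                      # plant an epoch effect
        ours = rm_anova_2way(y[..., None])
        oracle = pingouin_rm_anova_2way(y)
        assert ours.f_day[0] == pytest.approx(oracle.loc["day", "F"], abs=1e-8)
        assert ours.f_epoch[0] == pytest.approx(oracle.loc["epoch", "F"], abs=1e-8)
        assert ours.f_inter[0] == pytest.approx(oracle.loc["day * epoch", "F"], abs=1e-8)
        assert ours.p_epoch[0] == pytest.approx(oracle.loc["epoch", "p_unc"], abs=1e-10)

    def test_degrees_of_freedom_convention(self, rng):
        y = rng.standard_normal((32, 2, 5, 3))
        res = rm_anova_2way(y)
        assert res.df_epoch == (4, 124)
        assert res.df_day == (1, 31)
        assert res.df_inter == (4, 124)

    def test_type1_rate_under_null(self, rng):
        y = rng.standard_normal((10, 2, 5, 500))
        res = rm_anova_2way(y)
        rate = (res.p_epoch < 0.05).mean()
        lo, hi = stats.binom.interval(0.95, 500, 0.05)
        assert lo / 500 <= rate <= hi / 500

    def test_planted_effect_detected(self, rng):
        y = rng.standard_normal((12, 2, 5, 1))
        y[:, :, 2, 0] += 5.0
        res = rm_anova_2way(y)
        assert res.p_epoch[0] < 1e-6

    def test_missing_cells_rejected(self, rng):
        y = rng.standard_normal((5, 2, 5))
        y[0, 0, 0] = np.nan
        with pytest.raises(InferenceError):
            rm_anova_2way(y[..., None])


class TestRmAnova1Way:
    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        y = rng.standard_normal((9, 7))
        y[:, 3] += 0.5
        f, p, df = rm_anova_1way(y)
        rows = [{"s": s, "cond": c, "y": y[s, c]} for s in range(9) for c in range(7)]
        res = pg.rm_anova(data=pd.DataFrame(rows), dv="y", within="cond", subject="s")
        assert f == pytest.approx(res.loc[0, "F"], abs=1e-8)
        assert p == pytest.approx(res.loc[0, "p_unc"], abs=1e-10)
        assert df == (6, 48)

    def test_seven_epoch_df_convention(self, rng):
        # 32 subjects x 7 epochs -> F(6, 186)
        _, _, df = rm_anova_1way(rng.standard_normal((32, 7)))
        assert df == (6, 186)


class TestFdrBH:
    def test_stepup_hand_example(self):
        reject, _ = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        assert reject.all()

    def test_all_ones_rejected_nothing(self):
        reject, adj = fdr_bh(np.ones(10), q=0.05)
        assert not reject.any() and np.all(adj == 1)

    def test_matches_bruteforce_threshold_search(self, rng):
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            reject, _ = fdr_bh(p, q=0.05)
            m = p.size
            order = np.argsort(p)
            ps = p[order]
            passing = np.flatnonzero(ps <= 0.05 * (np.arange(1, m + 1)) / m)
            expected = np.zeros(m, dtype=bool)
            if passing.size:
                expected[order[: passing[-1] + 1]] = True
            np.testing.assert_array_equal(reject, expected)

    def test_realized_fdr_under_null(self, rng):
        # fully-null simulations: false-discovery proportion averages <= q
        fdps = []
        for _ in range(300):
            reject, _ = fdr_bh(rng.random(50), q=0.05)
            fdps.append(reject.any())
        assert np.mean(fdps) <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / 300)

    def test_empty_rejected(self):
        with pytest.raises(InferenceError):
            fdr_bh(np.array([]))


class TestPairedContrast:
    def test_identical_arrays_give_zero(self, rng):
        a = rng.standard_normal((6, 4))
        t, p = paired_contrast(a, a.copy())
        assert np.all(t == 0) and np.all(p == 1)

    def test_antisymmetry(self, rng):
        a, b = rng.standard_normal((8, 3)), rng.standard_normal((8, 3))
        t1, _ = paired_contrast(a, b)
        t2, _ = paired_contrast(b, a)
        np.testing.assert_allclose(t1, -t2, atol=1e-12)

    def test_matches_textbook_formula(self, rng):
        a, b = rng.standard_normal(10), rng.standard_normal(10)
        d = a - b
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        t, p = paired_contrast(a, b)
        assert t == pytest.approx(expected_t, abs=1e-10)
        assert p == pytest.approx(2 * stats.t.sf(abs(expected_t), 9), abs=1e-10)

    def test_one_tailed_is_half_two_tailed_for_positive_t(self, rng):
        a = rng.standard_normal(12) + 1.0
        b = rng.standard_normal(12)
        t2, p2 = paired_contrast(a, b)
        t1, p1 = paired_contrast(a, b, alternative="greater")
        if t2 > 0:
            assert p1 == pytest.approx(p2 / 2, abs=1e-12)

    def test_minimum_sample_size(self, rng):
        with pytest.raises(InferenceError):
            paired_contrast(rng.standard_normal(2), rng.standard_normal(2))


class TestKmeansEnsembles:
    def test_recovers_separated_blobs(self, rng):
        from sklearn.metrics import adjusted_rand_score

        centers = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10.0]])
        truth = np.repeat(np.arange(4), 12)
        coords = centers[truth] + 0.2 * rng.standard_normal((48, 3))
        ens = kmeans_ensembles(coords, np.arange(48), ["N"] * 48, k=4, seed=0)
        assert adjusted_rand_score(truth, ens.labels) == 1.0

    def test_k_one_single_cluster(self, rng):
        ens = kmeans_ensembles(rng.standard_normal((10, 3)), np.arange(10),
                               ["N"] * 10, k=1, seed=0)
        assert np.all(ens.labels == 0)

    def test_same_seed_identical_and_deterministic_relabel(self, rng):
        coords = rng.standard_normal((30, 3))
        e1 = kmeans_ensembles(coords, np.arange(30), ["N"] * 30, k=4, seed=3)
        e2 = kmeans_ensembles(coords, np.arange(30), ["N"] * 30, k=4, seed=3)
        np.testing.assert_array_equal(e1.labels, e2.labels)
        sizes = [(e1.labels == c).sum() for c in range(4)]
        assert sizes == sorted(sizes, reverse=True)

    def test_modal_network_annotation(self, rng):
        coords = np.vstack([np.zeros((5, 3)), 10 + np.zeros((5, 3))])
        coords += 0.1 * rng.standard_normal((10, 3))
        nets = ["A"] * 4 + ["B"] + ["B"] * 5
        ens = kmeans_ensembles(coords, np.arange(10), nets, k=2, seed=0)
        assert set(ens.modal_network) == {"A", "B"}

    def test_too_few_regions(self, rng):
        with pytest.raises(InferenceError):
            kmeans_ensembles(rng.standard_normal((3, 3)), np.arange(3), ["N"] * 3, k=4)


class TestRsaProfile:
    EPOCHS = ("Baseline", "EarlyLearning", "LateLearning", "EarlyWashout", "LateWashout")

    def _ecc(self, rng, n_subj=4, n_regions=12):
        return rng.standard_normal((n_subj, 2, 5, n_regions))

    def test_identical_patterns_give_one(self, rng):
        ecc = self._ecc(rng)
        pattern = rng.standard_normal(12)
        ecc[:, :, :, :] = pattern                    # every epoch identical
        prof = rsa_profile(ecc, self.EPOCHS, np.arange(12))
        np.testing.assert_allclose(prof, 1.0, atol=1e-12)

    def test_negated_pattern_gives_minus_one(self, rng):
        ecc = self._ecc(rng)
        pattern = rng.standard_normal(12)
        ecc[:, :, :, :] = pattern
        ecc[:, 1, 1, :] = -pattern                   # day-2 early learning negated
        prof = rsa_profile(ecc, self.EPOCHS, np.arange(12))
        assert np.allclose(prof[:, inf.RSA_REINSTATEMENT_INDEX], -1.0)

    def test_spearman_equals_pearson_on_ranks(self, rng):
        ecc = self._ecc(rng)
        sp = rsa_profile(ecc, self.EPOCHS, np.arange(12), metric="spearman")
        ranked = np.empty_like(ecc)
        for s in range(ecc.shape[0]):
            for d in range(2):
                for e in range(5):
                    ranked[s, d, e] = stats.rankdata(ecc[s, d, e])
        pe = rsa_profile(ranked, self.EPOCHS, np.arange(12), metric="pearson")
        np.testing.assert_allclose(sp, pe, atol=1e-12)

    def test_constant_pattern_rejected(self, rng):
        ecc = self._ecc(rng)
        ecc[0, 0, 1, :] = 2.0
        with pytest.raises(InferenceError):
            rsa_profile(ecc, self.EPOCHS, np.arange(12))

    def test_small_ensemble_rejected(self, rng):
        with pytest.raises(InferenceError):
            rsa_profile(self._ecc(rng), self.EPOCHS, [0, 1])


class TestReinstatementTest:
    def test_type1_on_exchangeable_profiles(self, rng):
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            profiles = rng.standard_normal((10, 7)) + rng.standard_normal((10, 1))
            res = reinstatement_test(profiles)
            rejections += res.p_omnibus < 0.05
        lo, hi = stats.binom.interval(0.95, n_sim, 0.05)
        assert lo <= rejections <= hi

    def test_planted_peak_all_contrasts_significant(self, rng):
        profiles = 0.1 * rng.standard_normal((20, 7))
        profiles[:, inf.RSA_REINSTATEMENT_INDEX] += 1.0
        res = reinstatement_test(profiles)
        assert res.p_omnibus < 1e-6
        assert np.all(res.contrast_p < 0.05)
        assert len(res.contrast_epochs) == 6

    def test_one_tailed_definition(self, rng):
        profiles = rng.standard_normal((9, 7))
        res = reinstatement_test(profiles)
        j = 0
        other = [k for k in range(7) if k != inf.RSA_REINSTATEMENT_INDEX][j]
        t2, p2 = paired_contrast(profiles[:, inf.RSA_REINSTATEMENT_INDEX],
                                 profiles[:, other])
        if t2 > 0:
            assert res.contrast_p[j] == pytest.approx(p2 / 2, abs=1e-12)


class TestNetworkCorrelation:
    def test_perfect_and_singleton(self, rng):
        delta = rng.standard_normal((8, 6))
        nets = ["A", "A", "A", "B", "B", "C"]
        means_a = delta[:, :3].mean(axis=1)
        r, names = network_correlation(delta, means_a, nets)
        assert r[names.index("A")] == pytest.approx(1.0)
        # singleton network equals that region's correlation
        rc = stats.pearsonr(delta[:, 5], means_a).statistic
        assert r[names.index("C")] == pytest.approx(rc, abs=1e-12)

    def test_independent_noise_centred_on_zero(self, rng):
        rs = []
        for _ in range(200):
            delta = rng.standard_normal((10, 4))
            scores = rng.standard_normal(10)
            r, _ = network_correlation(delta, scores, ["A", "A", "B", "B"])
            rs.append(r)
        assert abs(np.mean(rs)) < 0.05

    def test_constant_scores_rejected(self, rng):
        with pytest.raises(InferenceError):
            network_correlation(rng.standard_normal((6, 4)), np.ones(6),
                                ["A", "A", "B", "B"])


class TestSpins:
    def _parcellation(self, rng, n=40):
        pts = rng.standard_normal((n, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        hemi = np.where(pts[:, 0] < 0, "L", "R")
        return pts, hemi

    def test_spins_are_permutations_within_hemisphere(self, rng):
        pts, hemi = self._parcellation(rng)
        spins = generate_spins(pts, hemi, n_perm=20, seed=0)
        for p in spins:
            assert sorted(p) == list(range(40))
            for h in ("L", "R"):
                ix = np.flatnonzero(hemi == h)
                assert set(p[ix]) == set(ix)

    def test_same_seed_same_spins(self, rng):
        pts, hemi = self._parcellation(rng)
        s1 = generate_spins(pts, hemi, n_perm=5, seed=9)
        s2 = generate_spins(pts, hemi, n_perm=5, seed=9)
        np.testing.assert_array_equal(s1, s2)

    def test_missing_coordinates_rejected(self, rng):
        pts, hemi = self._parcellation(rng)
        pts[0, 0] = np.nan
        with pytest.raises(InferenceError):
            generate_spins(pts, hemi, n_perm=2, seed=0)

    def test_spin_p_near_one_for_null_observation(self, rng):
        pts, hemi = self._parcellation(rng)
        nets = np.array(["A", "B", "C", "D"] * 10)
        delta = rng.standard_normal((12, 40))
        scores = rng.standard_normal(12)
        res = spin_test(delta, scores, nets, coords=pts, hemisphere=hemi,
                        n_perm=200, seed=1)
        assert np.all(res.p > 0.001)
        assert res.null_r.shape == (200, 4)
        assert not res.fallback_label_permutation

    def test_fallback_label_permutation_flagged(self, rng):
        nets = np.array(["A", "B"] * 10)
        res = spin_test(rng.standard_normal((8, 20)), rng.standard_normal(8), nets,
                        n_perm=50, seed=2)
        assert res.fallback_label_permutation

    def test_addone_pvalue_never_zero(self, rng):
        pts, hemi = self._parcellation(rng)
        nets = np.array(["A", "B", "C", "D"] * 10)
        delta = np.tile(rng.standard_normal(40), (10, 1)) * rng.standard_normal((10, 1))
        scores = delta[:, nets == "A"].mean(axis=1)
        res = spin_test(delta, scores, nets, coords=pts, hemisphere=hemi,
                        n_perm=100, seed=3)
        assert np.all(res.p >= 1.0 / 101)
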