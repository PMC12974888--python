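"""Tests for time-series standardization, epoch splicing, covariance
estimation, nuisance regression and seed contrasts."""

import numpy as np
import pytest

from fcmanifold import connectivity as conn
from fcmanifold.connectivity import (
    EpochDefinition,
    RegionTimeSeries,
    TimeSeriesError,
    default_epoch_definitions,
    epoch_mean_activation,
    ledoit_wolf_covariance,
    nuisance_regress_components,
    seed_contrast,
    splice_epochs,
    trial_window_to_volumes,
    zscore_timeseries,
)


def make_ts(values, scan="task", subject="sub-01", day=1):
    ids = [f"R{i}" for i in range(values.shape[0])]
    return RegionTimeSeries(values=values, subject=subject, day=day, scan=scan,
                            region_ids=ids)


class TestZscore:
    def test_mean_zero_population_sd_one(self, rng):
        ts = make_ts(5 + 3 * rng.standard_normal((4, 200)))
        z = zscore_timeseries(ts)
        np.testing.assert_allclose(z.values.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.values.std(axis=1, ddof=0), 1, atol=1e-12)

    def test_already_standardized_unchanged(self):
        row = np.array([1.0, 2.0, 3.0])
        expect = np.array([-1.22474487, 0.0, 1.22474487])
        z = zscore_timeseries(make_ts(row[None, :]))
        np.testing.assert_allclose(z.values[0], expect, atol=1e-8)
        z2 = zscore_timeseries(make_ts(z.values))
        np.testing.assert_allclose(z2.values, z.values, atol=1e-12)

    def test_zero_variance_region_named(self):
        vals = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.raises(TimeSeriesError, match="R0"):
            zscore_timeseries(make_ts(vals))


class TestSplice:
    def test_default_layout_five_epochs(self, rng):
        defs = default_epoch_definitions()
        task = make_ts(rng.standard_normal((3, 6 + 3 * 96)), scan="task")
        wash = make_ts(rng.standard_normal((3, 6 + 2 * 96)), scan="washout")
        blocks = {**splice_epochs(task, defs), **splice_epochs(wash, defs)}
        assert sorted(blocks) == sorted(conn.EPOCH_NAMES)
        assert all(b.shape == (3, 96) for b in blocks.values())

    def test_discard_zero_takes_first_volumes(self, rng):
        vals = rng.standard_normal((2, 120))
        ts = make_ts(vals)
        blocks = splice_epochs(ts, [EpochDefinition("Baseline", "task", 0)],
                               discard_initial=0)
        np.testing.assert_array_equal(blocks["Baseline"], vals[:, :96])

    def test_discard_offsets_window(self, rng):
        vals = rng.standard_normal((2, 120))
        blocks = splice_epochs(make_ts(vals), [EpochDefinition("Baseline", "task", 0)],
                               discard_initial=6)
        np.testing.assert_array_equal(blocks["Baseline"], vals[:, 6:102])

    def test_out_of_range_window(self, rng):
        ts = make_ts(rng.standard_normal((2, 100)))
        with pytest.raises(TimeSeriesError, match="Baseline"):
            splice_epochs(ts, [EpochDefinition("Baseline", "task", 10)])

    def test_trial_volume_bookkeeping(self):
        # trials 1-48 at 2 volumes/trial span exactly one 96-volume block
        assert trial_window_to_volumes(1, 48) == slice(0, 96)
        assert trial_window_to_volumes(17, 8) == slice(32, 48)


class TestLedoitWolf:
    def test_iid_noise_approaches_identity(self, rng):
        block = rng.standard_normal((5, 20000))
        cov, shrink = ledoit_wolf_covariance(block)
        assert 0.0 <= shrink <= 1.0
        np.testing.assert_allclose(cov, np.eye(5), atol=0.05)

    def test_spd_when_rank_deficient(self, rng):
        # more regions than volumes: sample covariance is singular, LW is not
        block = rng.standard_normal((120, 96))
        cov, shrink = ledoit_wolf_covariance(block)
        assert 0.0 < shrink <= 1.0
        assert np.linalg.eigvalsh(cov)[0] > 0

    def test_too_few_volumes(self):
        with pytest.raises(TimeSeriesError):
            ledoit_wolf_covariance(np.ones((3, 1)))


class TestMeanActivation:
    def test_zero_mean_and_constant_blocks(self, rng):
        block = rng.standard_normal((3, 96))
        block -= block.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(epoch_mean_activation(block), 0, atol=1e-12)
        np.testing.assert_allclose(epoch_mean_activation(np.full((2, 96), 3.5)), 3.5)

    def test_planted_offset_recovered(self, rng):
        offsets = np.array([0.5, -1.0, 2.0])
        block = rng.standard_normal((3, 96))
        block -= block.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(epoch_mean_activation(block + offsets[:, None]),
                                   offsets, atol=1e-12)


class TestNuisanceRegression:
    def test_nuisance_pc_removed(self, rng):
        nuis = rng.standard_normal((6, 200))
        X = nuis.T - nuis.T.mean(axis=0)
        pc1 = np.linalg.svd(X, full_matrices=False)[0][:, 0]
        cleaned = nuisance_regress_components(pc1[None, :], nuis, n_components=3)
        assert np.abs(cleaned).max() < 1e-10

    def test_orthogonal_target_unchanged(self, rng):
        nuis = np.vstack([np.sin(np.linspace(0, 8 * np.pi, 256)),
                          np.cos(np.linspace(0, 8 * np.pi, 256)),
                          np.sin(np.linspace(0, 16 * np.pi, 256))])
        target = rng.standard_normal((1, 256))
        # orthogonalize target against nuisance subspace and intercept
        design = np.column_stack([np.ones(256), nuis.T])
        beta, *_ = np.linalg.lstsq(design, target.T, rcond=None)
        target = (target.T - design @ beta).T
        cleaned = nuisance_regress_components(target, nuis, n_components=3)
        np.testing.assert_allclose(cleaned, target, atol=1e-10)

    def test_planted_mixture_recovery(self, rng):
        nuis = rng.standard_normal((8, 400))
        X = nuis.T - nuis.T.mean(axis=0)
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        pc2 = U[:, 1] * s[1]
        signal = rng.standard_normal(400)
        target = (signal + 0.5 * pc2)[None, :]
        cleaned = nuisance_regress_components(target, nuis, n_components=3)
        r = np.corrcoef(cleaned[0], signal)[0, 1]
        assert r > 0.99

    def test_rank_deficient_nuisance(self, rng):
        row = rng.standard_normal(100)
        nuis = np.vstack([row, row, row])
        with pytest.raises(TimeSeriesError, match="rank"):
            nuisance_regress_components(rng.standard_normal((2, 100)), nuis, 3)


class TestSeedContrast:
    def _covs(self, rng, n_subj=6, n_regions=8, boost=0.0):
        region_ids = [f"R{i}" for i in range(n_regions)]
        networks = {r: ("NetA" if i < 4 else "NetB") for i, r in enumerate(region_ids)}
        covs = {}
        for s in range(n_subj):
            base = rng.standard_normal((n_regions, n_regions))
            base = base @ base.T / n_regions + np.eye(n_regions)
            for day in (1, 2):
                for epoch in ("Baseline", "EarlyLearning"):
                    M = base.copy()
                    if epoch == "EarlyLearning" and boost:
                        b = boost * (1.0 + 0.2 * s)     # subject-varying change
                        M[0, 1:] += b
                        M[1:, 0] += b
                    covs[(f"s{s}", day, epoch)] = M
        return covs, region_ids, networks

    def test_identical_epoch_sets_give_zero_t(self, rng):
        covs, ids, nets = self._covs(rng)
        res = seed_contrast(covs, "R0", ids, [(1, "Baseline")], [(1, "Baseline")], nets)
        assert np.all(res.t[~np.isnan(res.t)] == 0)
        assert np.all(res.network_t == 0)

    def test_planted_uniform_increase_positive_t(self, rng):
        covs, ids, nets = self._covs(rng, boost=0.4)
        res = seed_contrast(covs, "R0", ids,
                            [(1, "EarlyLearning"), (2, "EarlyLearning")],
                            [(1, "Baseline"), (2, "Baseline")], nets)
        assert np.all(res.t[~np.isnan(res.t)] > 0)
        assert np.isnan(res.t[0])          # seed self-entry excluded

    def test_network_summary_matches_bruteforce(self, rng):
        from scipy import stats

        covs, ids, nets = self._covs(rng, boost=0.2)
        A = [(1, "EarlyLearning")]
        B = [(1, "Baseline")]
        res = seed_contrast(covs, "R2", ids, A, B, nets)
        subjects = sorted({k[0] for k in covs})
        seed_ix = ids.index("R2")
        for k, net in enumerate(res.network_names):
            members = [i for i, r in enumerate(ids) if nets[r] == net and i != seed_ix]
            a = np.array([np.mean([covs[(s, d, e)][seed_ix, members] for d, e in A])
                          for s in subjects])
            b = np.array([np.mean([covs[(s, d, e)][seed_ix, members] for d, e in B])
                          for s in subjects])
            if np.allclose(a - b, 0):          # untouched network: exact zero contrast
                assert res.network_t[k] == 0.0
            else:
                t, _ = stats.ttest_rel(a, b)
                assert abs(res.network_t[k] - t) < 1e-10

    def test_subject_order_invariance(self, rng):
        covs, ids, nets = self._covs(rng, boost=0.1)
        res1 = seed_contrast(covs, "R0", ids, [(1, "EarlyLearning")], [(1, "Baseline")], nets)
        shuffled = dict(reversed(list(covs.items())))
        res2 = seed_contrast(shuffled, "R0", ids, [(1, "EarlyLearning")], [(1, "Baseline")], nets)
        np.testing.assert_allclose(res1.t[1:], res2.t[1:], atol=1e-12)

    def test_unknown_seed(self, rng):
        covs, ids, nets = self._covs(rng)
        with pytest.raises(KeyError):
            seed_contrast(covs, "nope", ids, [(1, "Baseline")], [(1, "EarlyLearning")], nets)
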