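"""Site selection: correlation/MAE screens, residual clustering, merging."""

import logging

import numpy as np
import pytest

from epimod.selection import (SiteScreenResult, ClusterReport,
                              cluster_residuals, evaluate_clusters,
                              mae_screen, merge_clusters, pcc_filter,
                              variance_filter)
from epimod.simulate import MethylationMatrix

from conftest import make_linear_dataset


def matrix_from(values):
    values = np.asarray(values, dtype=float)
    return MethylationMatrix(values,
                             [f"s{i}" for i in range(values.shape[0])],
                             [f"c{j}" for j in range(values.shape[1])])


def site_with_correlation(ages, target_pcc, rng, scale=0.1, center=0.5):
    """Construct a vector whose sample PCC with age is exactly target_pcc."""
    u = ages - ages.mean()
    u = u / np.linalg.norm(u)
    z = rng.normal(size=len(ages))
    z = z - z.mean()
    z = z - (z @ u) * u
    z = z / np.linalg.norm(z)
    v = target_pcc * u + np.sqrt(1 - target_pcc ** 2) * z
    return center + scale * v


class TestPccFilter:
    def test_constructed_pcc_values_filtered_exactly(self):
        rng = np.random.default_rng(0)
        ages = np.linspace(0, 100, 50)
        rows = [site_with_correlation(ages, p, rng) for p in (0.9, 0.41, 0.1)]
        kept = pcc_filter(matrix_from(rows), ages, threshold=0.4)
        assert kept == ["s0", "s1"]

    def test_perfectly_linear_site_always_retained(self):
        ages = np.linspace(0, 100, 30)
        kept = pcc_filter(matrix_from([0.1 + 0.005 * ages]), ages,
                          threshold=0.99)
        assert kept == ["s0"]

    def test_pure_noise_excluded_at_default_threshold(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(0, 100, 500)
        kept = pcc_filter(matrix_from([rng.uniform(0.4, 0.6, 500)]), ages,
                          threshold=0.4)
        assert kept == []

    def test_zero_variance_site_excluded_with_warning(self, caplog):
        ages = np.linspace(0, 100, 20)
        with caplog.at_level(logging.WARNING, logger="epimod.selection"):
            kept = pcc_filter(matrix_from([np.full(20, 0.5)]), ages, 0.4)
        assert kept == []
        assert any("zero-variance" in r.message for r in caplog.records)


class TestMaeScreen:
    def test_noiseless_linear_site_retained_with_zero_mae(self):
        ages = np.linspace(0, 100, 40)
        screens = mae_screen(matrix_from([0.2 + 0.004 * ages]), ages, 0.025)
        assert len(screens) == 1
        assert screens[0].mae == pytest.approx(0.0, abs=1e-12)

    def test_noisy_site_rejected_by_folded_normal_mean(self):
        # residual sd 0.05 -> expected MAE 0.05*sqrt(2/pi) ~ 0.040 > 0.025
        rng = np.random.default_rng(2)
        ages = rng.uniform(0, 100, 1000)
        vals = np.clip(0.5 + rng.normal(0, 0.05, 1000), 0, 1)
        screens = mae_screen(matrix_from([vals]), ages, 0.025)
        assert screens == []

    def test_hand_built_residuals(self):
        # ages chosen so the residuals are orthogonal to (1, age):
        # sum r = 0 and sum r*age = 0 -> OLS residuals equal them exactly
        ages = np.array([10.0, 40.0, 40.0, 30.0])
        resid = np.array([0.01, -0.01, 0.03, -0.03])
        assert abs(resid.sum()) < 1e-12 and abs(resid @ ages) < 1e-12
        vals = 0.3 + 0.002 * ages + resid
        screens = mae_screen(matrix_from([vals]), ages, 0.025)
        assert len(screens) == 1
        assert screens[0].mae == pytest.approx(0.02, abs=1e-12)
        np.testing.assert_allclose(screens[0].residuals, resid, atol=1e-10)


def reference_affinity_propagation(S, damping=0.9, max_iter=1000, tol_iters=50):
    """Independent message-passing affinity propagation (Frey & Dueck)."""
    n = S.shape[0]
    A = np.zeros((n, n))
    R = np.zeros((n, n))
    last = None
    stable = 0
    for _ in range(max_iter):
        AS = A + S
        idx = np.argmax(AS, axis=1)
        first = AS[np.arange(n), idx]
        AS[np.arange(n), idx] = -np.inf
        second = AS.max(axis=1)
        Rnew = S - first[:, None]
        Rnew[np.arange(n), idx] = S[np.arange(n), idx] - second
        R = damping * R + (1 - damping) * Rnew
        Rp = np.maximum(R, 0)
        np.fill_diagonal(Rp, R.diagonal())
        Anew = np.minimum(0, Rp.sum(axis=0)[None, :] - Rp)
        np.fill_diagonal(Anew, Rp.sum(axis=0) - Rp.diagonal())
        A = damping * A + (1 - damping) * Anew
        exemplars = np.where(np.diag(A + R) > 0)[0]
        key = tuple(exemplars)
        if key == last:
            stable += 1
            if stable >= tol_iters and len(exemplars) > 0:
                break
        else:
            stable = 0
            last = key
    if len(exemplars) == 0:
        return np.arange(n)
    labels = np.argmax(S[:, exemplars], axis=1)
    labels[exemplars] = np.arange(len(exemplars))
    return labels


class TestClusterResiduals:
    @staticmethod
    def screens_from(residual_rows):
        return [SiteScreenResult(f"s{i}", 0.9, 0.0, 0.0, 0.0, np.asarray(r))
                for i, r in enumerate(residual_rows)]

    def test_antipodal_groups_split_into_two_clusters(self):
        v = np.array([1.0, -1.0, 0.5, -0.5, 0.2])
        rows = [v, v * 1.01, v * 0.99, -v, -v * 1.01, -v * 0.99]
        labels = cluster_residuals(self.screens_from(rows), preference=-2.5,
                                   seed=1)
        assert len(set(labels)) == 2
        assert len({labels[0], labels[1], labels[2]}) == 1
        assert len({labels[3], labels[4], labels[5]}) == 1
        assert labels[0] != labels[3]

    def test_duplicate_residuals_share_a_cluster(self):
        rng = np.random.default_rng(3)
        rows = [rng.normal(size=6) for _ in range(4)]
        rows.append(rows[0].copy())
        labels = cluster_residuals(self.screens_from(rows), seed=1)
        assert labels[0] == labels[-1]

    def test_matches_independent_message_passing_on_blobs(self):
        rng = np.random.default_rng(4)
        centers = [np.array([3.0, 0.0]), np.array([-3.0, 0.0]),
                   np.array([0.0, 3.0])]
        rows = [c + rng.normal(0, 0.1, 2) for c in centers for _ in range(6)]
        screens = self.screens_from(rows)
        labels = cluster_residuals(screens, preference=-2.5, seed=1)
        X = np.stack(rows)
        S = -((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(S, -2.5)
        ref = reference_affinity_propagation(S)
        # identical partitions (up to label names)
        assert len(set(labels)) == len(set(ref)) == 3
        pairing = {}
        for a, b in zip(labels, ref):
            assert pairing.setdefault(a, b) == b


class TestEvaluateClusters:
    def test_noiseless_linear_cluster_has_near_zero_mae(self):
        cohort, _, matrix = make_linear_dataset(n_samples=80, n_sites=12,
                                                noise_sd=0.0, seed=1)
        labels = np.zeros(matrix.n_sites, dtype=int)
        reports = evaluate_clusters(matrix, cohort.ages, labels,
                                    site_ids=matrix.site_ids, min_size=10,
                                    folds=5, seed=0)
        assert len(reports) == 1
        assert reports[0].epm_cv_mae < 0.1
        assert reports[0].trend_r2 > 0.99

    def test_min_size_filtering(self):
        cohort, _, matrix = make_linear_dataset(n_samples=40, n_sites=51,
                                                noise_sd=0.002, seed=2)
        labels = np.array([0] * 12 + [1] * 9 + [2] * 30)
        reports = evaluate_clusters(matrix, cohort.ages, labels,
                                    site_ids=matrix.site_ids, min_size=10,
                                    folds=4, seed=0)
        assert sorted(r.cluster_id for r in reports) == [0, 2]

    def test_epm_cv_mae_close_to_fold_level_oracle(self):
        from sklearn.model_selection import KFold
        from epimod.pacemaker import StateAgeMap
        cohort, _, matrix = make_linear_dataset(n_samples=60, n_sites=12,
                                                noise_sd=0.01, seed=3)
        labels = np.zeros(matrix.n_sites, dtype=int)
        reports = evaluate_clusters(matrix, cohort.ages, labels,
                                    site_ids=matrix.site_ids, min_size=10,
                                    folds=5, seed=7)
        # oracle: a from-scratch EM over the same folds
        errs = []
        kf = KFold(n_splits=5, shuffle=True, random_state=7)
        for tr, te in kf.split(np.arange(matrix.n_samples)):
            M = matrix.values[:, tr]
            s = cohort.ages[tr].astype(float)
            for _ in range(100):
                sc = s - s.mean()
                rates = (M @ sc) / (sc @ sc)
                m0 = M.mean(1) - rates * s.mean()
                s_new = rates @ (M - m0[:, None]) / (rates @ rates)
                if np.max(np.abs(s_new - s)) < 1e-10:
                    s = s_new
                    break
                s = s_new
            trend = StateAgeMap.fit(s, cohort.ages[tr])
            s_te = rates @ (matrix.values[:, te] - m0[:, None]) / (rates @ rates)
            errs.append(np.abs(trend.to_age(s_te) - cohort.ages[te]))
        oracle = float(np.mean(np.concatenate(errs)))
        assert reports[0].epm_cv_mae <= 2 * max(oracle, 0.05)
        assert oracle <= 2 * max(reports[0].epm_cv_mae, 0.05)


class TestMergeClusters:
    @staticmethod
    def report(cid, sites, epm, enet):
        return ClusterReport(cid, sites, epm, enet, 0.9)

    def test_merges_clusters_below_cutoff(self):
        reports = [self.report(0, ["a", "b"], 3, 4),
                   self.report(1, ["c"], 7, 2),
                   self.report(2, ["d", "e"], 5, 5)]
        assert merge_clusters(reports, 6.0) == ["a", "b", "d", "e"]

    def test_cutoff_below_all_raises(self):
        with pytest.raises(ValueError, match="relax"):
            merge_clusters([self.report(0, ["a"], 8, 9)], 6.0)

    def test_idempotent(self):
        merged = merge_clusters([self.report(0, ["a", "b"], 1, 2)], 6.0)
        again = merge_clusters([self.report(0, merged, 1, 2)], 6.0)
        assert merged == again


class TestVarianceFilter:
    def test_constant_site_removed(self):
        kept = variance_filter(matrix_from([np.full(10, 0.5)]), 0.001)
        assert kept == []

    def test_alternating_site_retained(self):
        vals = np.tile([0.0, 1.0], 5)
        kept = variance_filter(matrix_from([vals]), 0.001)
        assert kept == ["s0"]  # variance 0.25

    def test_planted_variances_straddling_threshold(self):
        rng = np.random.default_rng(5)
        n = 400
        rows, expected = [], 0
        for i, sd in enumerate([0.01, 0.02, 0.05, 0.08]):
            z = rng.normal(size=n)
            z = (z - z.mean()) / z.std()      # exact sample sd 1
            rows.append(0.5 + sd * z)
            if sd ** 2 >= 0.001:
                expected += 1
        kept = variance_filter(matrix_from(rows), 0.001)
        assert len(kept) == expected


class TestPipelineInvariances:
    def test_screen_order_invariance(self):
        cohort, _, matrix = make_linear_dataset(n_samples=50, n_sites=10,
                                                noise_sd=0.01, seed=6)
        perm = np.random.default_rng(0).permutation(matrix.n_sites)
        shuffled = MethylationMatrix(matrix.values[perm],
                                     [matrix.site_ids[i] for i in perm],
                                     matrix.sample_ids)
        kept_a = set(pcc_filter(matrix, cohort.ages, 0.4))
        kept_b = set(pcc_filter(shuffled, cohort.ages, 0.4))
        assert kept_a == kept_b
        mae_a = {s.site_id for s in mae_screen(matrix, cohort.ages, 0.025)}
        mae_b = {s.site_id for s in mae_screen(shuffled, cohort.ages, 0.025)}
        assert mae_a == mae_b

    def test_age_coupled_sites_survive_pcc_more_than_flat_sites(self):
        from epimod.simulate import (TraitSpec, SiteSpec, simulate_cohort,
                                     simulate_methylation)
        traits = [TraitSpec("aged", gamma_mean=1.0),
                  TraitSpec("flat", gamma_mean=0.0, q_mean=1.0, q_sd=0.3)]
        cohort = simulate_cohort(200, (0, 100), 0.0, traits, seed=0)
        sites = []
        for i in range(20):
            sites.append(SiteSpec(f"aged{i}", m0=0.2, rate=0.003,
                                  noise_sd=0.01, trait_weights={"aged": 1.0}))
            sites.append(SiteSpec(f"flat{i}", m0=0.5, rate=0.1,
                                  noise_sd=0.01, trait_weights={"flat": 1.0}))
        matrix = simulate_methylation(cohort, sites, seed=1)
        kept = pcc_filter(matrix, cohort.ages, 0.4)
        aged_rate = sum(1 for s in kept if s.startswith("aged")) / 20
        flat_rate = sum(1 for s in kept if s.startswith("flat")) / 20
        assert aged_rate > flat_rate
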