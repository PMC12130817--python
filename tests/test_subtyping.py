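"""Subtype discovery, feature association, and survival stratification.

The log-rank results are cross-checked against a brute-force oracle that
enumerates the observed-vs-expected event table directly.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, kstest

from contextnets import (
    SampleNetworks,
    SurvivalTable,
    cluster_networks,
    feature_association,
    flatten_networks,
    logrank_tests,
    select_k_silhouette,
    subtype_pipeline,
)


def brute_force_logrank_p(time_a, event_a, time_b, event_b):
    """Two-group log-rank via explicit enumeration of the risk table."""
    times = np.concatenate([time_a, time_b])
    events = np.concatenate([event_a, event_b])
    groups = np.concatenate([np.zeros(len(time_a)), np.ones(len(time_b))])
    O_a = E_a = V = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & (groups == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & (groups == 0)).sum()
        O_a += d_a
        E_a += d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    stat = (O_a - E_a) ** 2 / V
    return float(chi2.sf(stat, df=1))


def _blob_networks(rng, centers, n_each=20, p=3, spread=0.01):
    """Symmetric p x p networks clustered around given off-diagonal levels."""
    mats, labels = [], []
    for gi, c in enumerate(centers):
        for _ in range(n_each):
            m = np.zeros((p, p))
            iu = np.triu_indices(p, 1)
            m[iu] = c + spread * rng.standard_normal(len(iu[0]))
            mats.append(m + m.T)
            labels.append(gi)
    return SampleNetworks(np.stack(mats), "markov"), np.array(labels)


class TestClusterNetworks:
    def test_planted_two_group_recovery(self):
        rng = np.random.default_rng(0)
        nets, labels = _blob_networks(rng, [0.0, 1.0])
        report = cluster_networks(nets, k=2)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels, report.labels) == 1.0

    def test_identical_networks_flagged_degenerate(self):
        nets = SampleNetworks(np.zeros((10, 3, 3)), "markov")
        with pytest.warns(UserWarning):
            cluster_networks(nets, k=2)

    def test_labels_invariant_to_sample_permutation(self):
        rng = np.random.default_rng(3)
        nets, _ = _blob_networks(rng, [0.0, 1.0, -1.0], n_each=10)
        perm = rng.permutation(nets.n)
        permuted = SampleNetworks(nets.values[perm], "markov")
        lab = cluster_networks(nets, k=3).labels
        lab_perm = cluster_networks(permuted, k=3).labels
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(lab[perm], lab_perm) == 1.0

    def test_k_exceeding_n_rejected(self):
        nets = SampleNetworks(np.zeros((3, 2, 2)), "markov")
        with pytest.raises(ValueError):
            cluster_networks(nets, k=4)

    def test_flattening_conventions(self):
        vals = np.arange(9.0).reshape(1, 3, 3)
        asym = SampleNetworks(vals * (1 - np.eye(3)), "neighborhood")
        assert flatten_networks(asym).shape == (1, 6)
        sym = SampleNetworks(vals, "correlation")
        assert flatten_networks(sym).shape == (1, 3)


class TestSelectK:
    def test_two_well_separated_blobs(self):
        flat = np.array([[0.0], [0.1], [10.0], [10.1]])
        k, scores = select_k_silhouette(flat, k_range=range(2, 4))
        assert k == 2
        assert scores[2] > 0.97
        assert scores[3] < scores[2]

    def test_three_equidistant_tight_blobs(self):
        rng = np.random.default_rng(1)
        flat = np.concatenate(
            [c + 0.01 * rng.standard_normal((30, 2)) for c in (0.0, 5.0, 10.0)]
        )
        k, _ = select_k_silhouette(flat)
        assert k == 3

    def test_identical_points_fall_back_with_warning(self):
        flat = np.zeros((12, 2))
        with pytest.warns(UserWarning, match="identical"):
            k, _ = select_k_silhouette(flat)
        assert k == 2

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            select_k_silhouette(np.zeros((2, 2)))


class TestFeatureAssociation:
    def test_textbook_t_statistic_oracle(self):
        """[5,6,7] vs [0,1,2]: t = 6.124, df = 4, two-sided p ~ 0.0036."""
        from scipy.stats import t as tdist

        x = np.array([5.0, 6.0, 7.0, 0.0, 1.0, 2.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        p = feature_association(pd.DataFrame({"f": x}), labels)["f"]
        # independent brute-force: pooled-variance t (equal here by symmetry)
        diff = 5.0
        s2 = 1.0  # both group variances
        t_stat = diff / np.sqrt(s2 / 3 + s2 / 3)
        assert t_stat == pytest.approx(6.123724, abs=1e-6)
        p_oracle = 2 * tdist.sf(t_stat, df=4)
        assert p == pytest.approx(p_oracle, abs=1e-6)
        assert p == pytest.approx(0.003633, abs=1e-4)

    def test_constant_feature_gets_p_one(self):
        labels = np.array([0, 0, 1, 1])
        p = feature_association(pd.DataFrame({"f": [3.0] * 4}), labels)["f"]
        assert p == 1.0

    def test_null_pvalues_uniform_under_label_permutation(self):
        """Calibration: permuted 2-group labels give ~Unif[0,1] p-values.

        With two balanced subtypes, subtype-vs-rest is the same comparison
        from either side, so the per-feature minimum equals the single Welch
        p-value and should be uniform under the null (KS test at 0.01).
        """
        rng = np.random.default_rng(5)
        x = rng.standard_normal(60)
        labels = np.repeat([0, 1], 30)
        ps = [
            float(feature_association(pd.DataFrame({"f": x}),
                                      rng.permutation(labels))["f"])
            for _ in range(200)
        ]
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_ranking_puts_informative_feature_first(self, planted_cohort):
        cohort = planted_cohort
        ranked = feature_association(cohort.contexts, cohort.labels)
        assert ranked.index[0] in cohort.informative_features


class TestLogrank:
    def test_identical_groups_give_p_one(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.ones(6, dtype=int)
        labels = np.repeat([0, 1], 3)
        mv_p, pairwise, min_p = logrank_tests(labels, SurvivalTable(t, e))
        assert mv_p == pytest.approx(1.0)
        assert min_p == pytest.approx(1.0)

    def test_pairwise_matches_brute_force_oracle(self):
        time_a = np.array([1.0, 2.0, 3.0])
        time_b = np.array([10.0, 20.0, 30.0])
        e = np.ones(3, dtype=int)
        labels = np.repeat(["a", "b"], 3)
        surv = SurvivalTable(np.concatenate([time_a, time_b]), np.ones(6, dtype=int))
        _, pairwise, min_p = logrank_tests(labels, surv)
        oracle = brute_force_logrank_p(time_a, e, time_b, e)
        assert min_p == pytest.approx(oracle, abs=1e-6)

    def test_three_groups_two_identical(self):
        rng = np.random.default_rng(7)
        t_short = rng.exponential(1.0, 30)
        t_long = rng.exponential(10.0, 30)
        times = np.concatenate([t_short, t_short, t_long])
        events = np.ones(90, dtype=int)
        labels = np.repeat([0, 1, 2], 30)
        _, pairwise, min_p = logrank_tests(labels, SurvivalTable(times, events))
        df = pd.DataFrame(pairwise)
        # the distinct pairs (0,2) and (1,2) attain the minimum, not (0,1)
        assert min(df.iloc[0, 2], df.iloc[1, 2]) == pytest.approx(min_p)
        assert df.iloc[0, 1] > min_p

    def test_type_one_error_controlled_under_shuffling(self, planted_cohort):
        """Empirical type-I <= 0.07 at nominal 0.05 over 400 label shuffles."""
        cohort = planted_cohort
        rng = np.random.default_rng(11)
        rejections = 0
        n_shuffles = 400
        from lifelines.statistics import multivariate_logrank_test

        for _ in range(n_shuffles):
            lab = rng.permutation(cohort.labels)
            p = multivariate_logrank_test(
                cohort.survival.time, lab, cohort.survival.event
            ).p_value
            rejections += p < 0.05
        assert rejections / n_shuffles <= 0.07

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_tests(np.array([0, 1]), SurvivalTable(np.ones(2), np.zeros(2)))


class TestPipeline:
    def test_reference_labels_force_k(self):
        rng = np.random.default_rng(2)
        nets, _ = _blob_networks(rng, [0.0, 1.0, 2.0, 3.0], n_each=10)
        report = subtype_pipeline(nets, reference_labels=np.repeat([0, 1], 20))
        assert report.k == 2

    def test_full_pipeline_outputs_populated(self, planted_cohort):
        cohort = planted_cohort
        # cluster the true precisions directly: the protocol, independent of fitting
        nets = SampleNetworks(cohort.true_precisions, "markov")
        report = subtype_pipeline(
            nets, context_features=cohort.contexts, survival=cohort.survival
        )
        assert report.k == 3
        assert report.feature_pvalues is not None
        assert report.logrank_multivariate_p < 1e-4
        assert report.min_pairwise_p <= 1.0
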