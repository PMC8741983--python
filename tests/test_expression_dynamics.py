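"""Normalization, correlations, fuzzy c-means and composition tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirwave import expression_dynamics as dyn
from mirwave import synthetic_data as sim


def sample_sheet(n_tp, n_rep):
    rows = [(f"S{t}_r{r}", t, r)
            for t in range(1, n_tp + 1) for r in range(1, n_rep + 1)]
    return pd.DataFrame(rows, columns=["sample_id", "time_point", "replicate"])


class TestNormalization:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        _, sf = dyn.normalize_median_of_ratios(counts)
        assert np.allclose(sf, 1.0)

    def test_doubled_sample_closed_form(self):
        counts = pd.DataFrame({"a": [10, 20, 400], "b": [20, 40, 800]})
        norm, sf = dyn.normalize_median_of_ratios(counts)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2))
        assert sf["b"] == pytest.approx(np.sqrt(2))
        assert np.allclose(norm["a"], norm["b"])

    def test_scaling_one_sample_scales_its_factor(self):
        counts = pd.DataFrame({"a": [11, 23, 307, 54], "b": [13, 19, 290, 61],
                               "c": [9, 25, 310, 50]})
        _, sf1 = dyn.normalize_median_of_ratios(counts)
        scaled = counts.copy()
        scaled["b"] = scaled["b"] * 5
        norm1, _ = dyn.normalize_median_of_ratios(counts)
        norm2, sf2 = dyn.normalize_median_of_ratios(scaled)
        assert sf2["b"] / sf1["b"] == pytest.approx(5 ** (2 / 3))  # geo-mean shift
        assert np.allclose(norm2["a"] / norm1["a"], norm2["a"] / norm1["a"])

    def test_no_common_nonzero_feature_rejected(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="nonzero"):
            dyn.normalize_median_of_ratios(counts)

    def test_planted_multipliers_recovered(self):
        # depth differences only; Poisson sampling noise
        cfg = sim.SimulationConfig(rng_seed=21, nb_dispersion=0.0,
                                   archetype_fractions={"flat": 1.0})
        data, truth = sim.gen_count_matrix(cfg, "mirna", n_features=50,
                                           base_mean=500)
        _, sf = dyn.normalize_median_of_ratios(data.counts)
        sf_rel = sf / np.exp(np.log(sf).mean())
        planted = truth.library_multipliers
        planted_rel = planted / np.exp(np.log(planted).mean())
        assert np.abs(sf_rel / planted_rel - 1).max() < 0.05


class TestExpressedFilter:
    def test_boundary_inclusive(self):
        samples = sample_sheet(2, 1)
        norm = pd.DataFrame({"S1_r1": [9.9, 10.0], "S2_r1": [9.9, 3.0]},
                            index=["low", "edge"])
        kept = dyn.expressed_filter(norm, samples)
        assert list(kept) == ["edge"]

    def test_matches_bruteforce_scan(self):
        cfg = sim.SimulationConfig(rng_seed=4)
        data, _ = sim.gen_count_matrix(cfg, "mirna", n_features=300)
        norm, _ = dyn.normalize_median_of_ratios(data.counts)
        kept = set(dyn.expressed_filter(norm, data.samples))
        means = dyn.timepoint_means(norm, data.samples)
        expected = {f for f, row in means.iterrows() if (row >= 10).any()}
        assert kept == expected


class TestSpearman:
    def test_monotone_transform_gives_unit_correlation(self):
        samples = sample_sheet(2, 1)
        x = np.arange(1.0, 31.0)
        norm = pd.DataFrame({"S1_r1": x, "S2_r1": np.exp(x / 10)})
        corr = dyn.timepoint_correlation(norm, samples)
        assert corr.loc[1, 2] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        samples = sample_sheet(2, 1)
        x = np.arange(1.0, 31.0)
        norm = pd.DataFrame({"S1_r1": x, "S2_r1": x[::-1]})
        assert dyn.timepoint_correlation(norm, samples).loc[1, 2] == pytest.approx(-1.0)

    def test_matches_rank_formula_with_ties(self, rng):
        samples = sample_sheet(2, 1)
        a = rng.integers(0, 20, 50).astype(float)  # ties likely
        b = rng.integers(0, 20, 50).astype(float)
        norm = pd.DataFrame({"S1_r1": a, "S2_r1": b})
        corr = dyn.timepoint_correlation(norm, samples)
        ra, rb = stats.rankdata(a), stats.rankdata(b)
        expected = np.corrcoef(ra, rb)[0, 1]
        assert corr.loc[1, 2] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_unit_diagonal(self):
        cfg = sim.SimulationConfig(rng_seed=2)
        data, _ = sim.gen_count_matrix(cfg, "mirna", n_features=100)
        norm, _ = dyn.normalize_median_of_ratios(data.counts)
        corr = dyn.timepoint_correlation(norm, data.samples)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)


class TestFuzzyCmeans:
    def two_groups(self):
        rng = np.random.default_rng(0)
        a = rng.normal(-1, 0.05, (50, 5))
        b = rng.normal(+1, 0.05, (50, 5))
        return pd.DataFrame(np.vstack([a, b]))

    def test_two_tight_groups_recovered(self):
        asg = dyn.fuzzy_cmeans(self.two_groups(), 2, rng_seed=1)
        labels = asg.hard_labels.to_numpy()
        assert len(set(labels[:50])) == 1 and len(set(labels[50:])) == 1
        assert labels[0] != labels[-1]
        assert (asg.memberships.max(axis=1) > 0.9).all()

    def test_equidistant_point_gets_half_memberships(self):
        X = pd.DataFrame(np.array([[-1.0], [-1.0], [1.0], [1.0], [0.0]]))
        asg = dyn.fuzzy_cmeans(X, 2, rng_seed=0)
        assert np.allclose(asg.memberships.iloc[-1], [0.5, 0.5], atol=1e-3)

    def test_memberships_row_stochastic(self):
        asg = dyn.fuzzy_cmeans(self.two_groups(), 3, rng_seed=2)
        assert np.allclose(asg.memberships.sum(axis=1), 1.0, atol=1e-9)
        assert (asg.memberships.to_numpy() >= 0).all()

    def test_objective_non_increasing(self):
        asg = dyn.fuzzy_cmeans(self.two_groups(), 2, rng_seed=3, n_init=1)
        assert (np.diff(asg.objective_path) <= 1e-9).all()

    def test_near_hard_fuzzifier_matches_kmeans(self):
        from scipy.cluster.vq import kmeans2
        X = self.two_groups()
        asg = dyn.fuzzy_cmeans(X, 2, fuzzifier=1.05, rng_seed=4)
        _, km_labels = kmeans2(X.to_numpy(), 2, seed=4, minit="++")
        ours = asg.hard_labels.factorize()[0]
        agreement = max((ours == km_labels).mean(), (ours != km_labels).mean())
        assert agreement == 1.0

    def test_invalid_parameters_rejected(self):
        X = self.two_groups()
        with pytest.raises(ValueError):
            dyn.fuzzy_cmeans(X, 1)
        with pytest.raises(ValueError):
            dyn.fuzzy_cmeans(X, 2, fuzzifier=1.0)


class TestElbow:
    def test_four_archetypes_select_four(self, config):
        profiles, _ = sim.gen_archetype_profiles(config, n_features=600)
        result = dyn.elbow_select_k(profiles, rng_seed=0)
        assert result.k == 4 and not result.flagged

    def test_objective_non_increasing_in_k(self, config):
        profiles, _ = sim.gen_archetype_profiles(config, n_features=300)
        result = dyn.elbow_select_k(profiles, rng_seed=1)
        assert (np.diff(result.objectives) <= 1e-6).all()

    def test_flat_curve_flagged(self):
        k, flagged = dyn.select_elbow_from_curve([2, 3, 4, 5],
                                                 np.array([10.0, 10.0, 10.0, 10.0]))
        assert flagged and k == 2


class TestCompositionTest:
    def assignment(self, labels):
        idx = [f"f{i}" for i in range(len(labels))]
        member = pd.DataFrame({"cluster1": 1.0}, index=idx)
        return dyn.ClusterAssignment(
            memberships=member,
            hard_labels=pd.Series(labels, index=idx),
            high_confidence=pd.Series(True, index=idx),
            centers=pd.DataFrame(),
            objective_path=np.array([0.0]),
            n_iter=1,
        )

    def test_closed_form_statistic(self):
        labels = ["c1"] * 61
        cons = pd.Series(["novel"] * 42 + ["conserved"] * 19,
                         index=[f"f{i}" for i in range(61)])
        out = dyn.composition_test(self.assignment(labels), cons, 0.5)
        assert out["chi2"].iloc[0] == pytest.approx(2 * 11.5 ** 2 / 30.5)
        assert out["pvalue"].iloc[0] == pytest.approx(
            stats.chi2.sf(2 * 11.5 ** 2 / 30.5, 1))

    def test_matching_proportions_give_zero(self):
        labels = ["c1"] * 10
        cons = pd.Series(["novel"] * 4 + ["conserved"] * 6,
                         index=[f"f{i}" for i in range(10)])
        out = dyn.composition_test(self.assignment(labels), cons, 0.4)
        assert out["chi2"].iloc[0] == 0.0

    def test_statistic_matches_enumeration_for_small_n(self):
        # exhaustive binomial enumeration of the null distribution (N = 10)
        N, p = 10, 0.5
        labels = ["c1"] * N
        for k in range(N + 1):
            cons = pd.Series(["novel"] * k + ["conserved"] * (N - k),
                             index=[f"f{i}" for i in range(N)])
            out = dyn.composition_test(self.assignment(labels), cons, p)
            expected_stat = (k - N * p) ** 2 / (N * p) + \
                ((N - k) - N * (1 - p)) ** 2 / (N * (1 - p))
            assert out["chi2"].iloc[0] == pytest.approx(expected_stat)

    def test_low_expected_cell_warns(self):
        labels = ["c1"] * 5
        cons = pd.Series(["novel"] * 5, index=[f"f{i}" for i in range(5)])
        out = dyn.composition_test(self.assignment(labels), cons, 0.1)
        assert bool(out["low_expected_warning"].iloc[0])
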