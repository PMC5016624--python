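"""Centrality profiles, Gaussian-mixture grouping, and outcome comparison."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

from ohcnet import (
    CHANNELS,
    MultirelationalNetwork,
    PROFILE_COLUMNS,
    extract_profiles,
    fit_mixture,
    group_abstinence,
    pairwise_anova,
    select_k,
    select_k_from_loglik,
)
from ohcnet.netbuild import FIRST_TS
from ohcnet.profiler import COVARIANCE_RIDGE


def empty_multinet():
    return MultirelationalNetwork(layers={c: nx.DiGraph(channel=c) for c in CHANNELS})


class TestExtractProfiles:
    def test_inactive_user_gets_zero_vector(self):
        profiles = extract_profiles(empty_multinet(), ["ghost"])
        assert profiles.loc["ghost"].tolist() == [0] * 8

    def test_pm_only_user(self):
        layers = {c: nx.DiGraph(channel=c) for c in CHANNELS}
        layers["PM"].add_edge("a", "b", **{FIRST_TS: 1})
        profiles = extract_profiles(MultirelationalNetwork(layers=layers), ["a", "b"])
        assert profiles.loc["a", "PM_out"] == 1 and profiles.loc["a", "PM_in"] == 0
        assert profiles.loc["b", "PM_in"] == 1
        assert profiles.loc[:, [c for c in PROFILE_COLUMNS if not c.startswith("PM")]].to_numpy().sum() == 0

    def test_profiles_equal_per_layer_degree_recount(self, default_multinet):
        cohort = sorted(default_multinet.aggregated.nodes)[:50]
        profiles = extract_profiles(default_multinet, cohort)
        for user in cohort[:10]:
            for column in PROFILE_COLUMNS:
                channel, side = column.split("_")
                layer = default_multinet.layer(channel)
                expected = 0
                if user in layer:
                    edges = layer.in_edges(user) if side == "in" else layer.out_edges(user)
                    expected = len(list(edges))
                assert profiles.loc[user, column] == expected

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            extract_profiles(empty_multinet(), [])


def gaussian_blobs(means, n_per, seed, scale=1.0):
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for i, mu in enumerate(means):
        blocks.append(rng.normal(loc=mu, scale=scale, size=(n_per, len(mu))))
        labels += [i] * n_per
    X = np.vstack(blocks)
    frame = pd.DataFrame(X, columns=list(PROFILE_COLUMNS))
    return frame, np.array(labels)


class TestFitMixture:
    def test_single_component_matches_closed_form(self):
        frame, _ = gaussian_blobs([np.zeros(8)], 200, seed=0)
        _, loglik = fit_mixture(frame, k=1, restarts=1, seed=0)
        X = frame.to_numpy()
        mu = X.mean(axis=0)
        cov = np.cov(X, rowvar=False, bias=True) + COVARIANCE_RIDGE * np.eye(8)
        expected = stats.multivariate_normal(mean=mu, cov=cov).logpdf(X).sum()
        assert loglik == pytest.approx(expected, rel=1e-6)

    def test_k_must_be_below_sample_size(self):
        frame, _ = gaussian_blobs([np.zeros(8)], 5, seed=0)
        with pytest.raises(ValueError):
            fit_mixture(frame, k=5)
        with pytest.raises(ValueError):
            fit_mixture(frame, k=0)

    def test_two_separated_clouds_recovered_exactly(self):
        frame, labels = gaussian_blobs([np.zeros(8), np.full(8, 25.0)], 100, seed=1)
        model, _ = fit_mixture(frame, k=2, restarts=3, seed=0)
        pred = model.predict(frame.to_numpy())
        assert adjusted_rand_score(labels, pred) == 1.0

    def test_three_component_means_recovered(self):
        means = [np.zeros(8), np.full(8, 12.0), np.r_[np.full(4, 24.0), np.zeros(4)]]
        frame, labels = gaussian_blobs(means, 500, seed=2)
        model, _ = fit_mixture(frame, k=3, restarts=5, seed=0)
        fitted = model.means_
        for mu in means:
            distances = np.linalg.norm(fitted - mu, axis=1)
            best = fitted[np.argmin(distances)]
            # component-mean SE is roughly scale/sqrt(n_k) per coordinate
            assert np.all(np.abs(best - mu) < 3.0 / np.sqrt(500))

    def test_em_loglik_monotone_within_restart(self):
        frame, _ = gaussian_blobs([np.zeros(8), np.full(8, 6.0)], 150, seed=3)
        X = frame.to_numpy()
        model = GaussianMixture(
            n_components=2, covariance_type="full", reg_covar=COVARIANCE_RIDGE,
            max_iter=1, warm_start=True, random_state=0, n_init=1,
        )
        scores = []
        for _ in range(25):
            model.fit(X)
            scores.append(model.score(X))
        assert all(b >= a - 1e-9 for a, b in zip(scores, scores[1:]))


class TestSelectK:
    def test_flat_trace_selects_smallest(self):
        loglik = {2: -1000.0, 3: -990.0, 4: -989.0, 5: -988.5}
        k, warning = select_k_from_loglik(loglik, plateau_threshold=0.05)
        assert (k, warning) == (2, False)

    def test_plateau_after_growth(self):
        loglik = {2: -2000.0, 3: -1200.0, 4: -1190.0, 5: -1185.0}
        k, warning = select_k_from_loglik(loglik, plateau_threshold=0.05)
        assert (k, warning) == (3, False)

    def test_persistent_gains_fall_back_to_max_with_warning(self):
        loglik = {2: -4000.0, 3: -2000.0, 4: -1000.0, 5: -500.0}
        k, warning = select_k_from_loglik(loglik, plateau_threshold=0.05)
        assert (k, warning) == (5, True)

    def test_noncontiguous_range_rejected(self):
        frame, _ = gaussian_blobs([np.zeros(8)], 50, seed=0)
        with pytest.raises(ValueError):
            select_k(frame, k_range=[2, 4, 6])

    def test_group_means_equal_member_averages(self):
        frame, _ = gaussian_blobs([np.zeros(8), np.full(8, 20.0)], 80, seed=4)
        result = select_k(frame, k_range=range(2, 4), restarts=2, seed=0)
        for group, members in result.assignments.groupby(result.assignments):
            expected = frame.loc[members.index].mean()
            assert np.allclose(result.group_means.loc[group], expected)
        assert sum(result.group_sizes.values()) == len(frame)


def outcome_frame(spec):
    """spec: list of (user_id, responded, abstinent)"""
    return pd.DataFrame(spec, columns=["user_id", "responded", "abstinent"])


def grouping_with(assignments):
    from ohcnet import GroupingResult

    labels = pd.Series(assignments, name="group")
    labels.index.name = "user_id"
    frame = pd.DataFrame(
        0, index=labels.index, columns=list(PROFILE_COLUMNS)
    )
    return GroupingResult(
        selected_k=len(set(assignments.values())),
        loglik={},
        plateau_threshold=0.05,
        warning=False,
        assignments=labels,
        group_sizes=pd.Series(assignments).value_counts().to_dict(),
        group_means=frame.groupby(labels).mean(),
    )


class TestGroupAbstinence:
    def test_itt_and_responder_rates(self):
        users = [f"u{i}" for i in range(18)]
        rows = []
        for i, u in enumerate(users):
            responded = i < 14
            abstinent = i < 10  # all abstinent users responded
            rows.append((u, responded, abstinent and responded))
        outcomes = outcome_frame(rows)
        result = grouping_with({u: 1 for u in users})
        itt = group_abstinence(result, outcomes, mode="ITT")
        resp = group_abstinence(result, outcomes, mode="responders")
        assert itt.loc[1, "rate"] == pytest.approx(10 / 18)
        assert resp.loc[1, "rate"] == pytest.approx(10 / 14)
        assert itt.loc[1, "rate"] <= resp.loc[1, "rate"]

    def test_zero_abstinent_group(self):
        outcomes = outcome_frame([(f"u{i}", True, False) for i in range(5)])
        result = grouping_with({f"u{i}": 1 for i in range(5)})
        assert group_abstinence(result, outcomes, "ITT").loc[1, "rate"] == 0.0
        assert group_abstinence(result, outcomes, "responders").loc[1, "rate"] == 0.0

    def test_missing_outcome_row_named(self):
        outcomes = outcome_frame([("u0", True, False)])
        result = grouping_with({"u0": 1, "u1": 1})
        with pytest.raises(KeyError, match="u1"):
            group_abstinence(result, outcomes, "ITT")

    def test_itt_never_exceeds_responder_rate(self, default_multinet, default_config, default_log):
        from ohcnet import generate_outcomes

        outcomes = generate_outcomes(default_log, default_config)
        cohort = list(outcomes.table["user_id"])
        profiles = extract_profiles(default_multinet, cohort)
        result = select_k(profiles, k_range=range(2, 5), restarts=2, seed=0)
        itt = group_abstinence(result, outcomes.table, "ITT")
        resp = group_abstinence(result, outcomes.table, "responders")
        for group in itt.index:
            if not math.isnan(resp.loc[group, "rate"]):
                assert itt.loc[group, "rate"] <= resp.loc[group, "rate"] + 1e-12


class TestPairwiseAnova:
    def test_equal_proportions_give_zero(self):
        a = [1] * 5 + [0] * 5
        b = [1] * 5 + [0] * 5
        assert pairwise_anova(a, b).F == 0.0

    def test_constant_groups_with_different_means_flagged(self):
        res = pairwise_anova([1, 1, 1], [0, 0, 0])
        assert res.infinite and math.isinf(res.F) and res.p == 0.0

    def test_constant_groups_with_equal_means(self):
        res = pairwise_anova([1, 1], [1, 1])
        assert res.F == 0.0 and res.p == 1.0

    def test_degrees_of_freedom(self):
        res = pairwise_anova([0, 1, 1], [0, 0, 1, 1])
        assert res.df == (1, 5)

    @pytest.mark.parametrize("seed", range(100))
    def test_f_equals_t_squared(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, size=rng.integers(3, 30))
        b = rng.integers(0, 2, size=rng.integers(3, 30))
        if a.std() == 0 and b.std() == 0:
            return
        res = pairwise_anova(a, b)
        t, p_t = stats.ttest_ind(a, b, equal_var=True)
        assert res.F == pytest.approx(t**2, abs=1e-9)
        assert res.p == pytest.approx(p_t, abs=1e-12)
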