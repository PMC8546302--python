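import math

import numpy as np
import pytest

from conftest import random_observations, separated_instance
from oracle_utils import best_partition_loglik

from mqtlkit.errors import InvalidInputError
from mqtlkit.meta_analysis import (
    QtlMixtureModel,
    QtlObservation,
    ci_to_sd,
    run_meta_analysis,
    select_model,
    summarize_mqtl,
)
from mqtlkit.map_projection import ProjectedQtl, ProjectionStatus


def obs(y, s=1.0, qtl_id="", trait=""):
    return QtlObservation(y=y, s=s, qtl_id=qtl_id or f"q{y}", trait=trait)


class TestCiToSd:
    @pytest.mark.parametrize(
        "width,expected",
        [(3.92, 1.0), (0.0, 0.05), (13.73, 13.73 / 3.92), (0.01, 0.05)],
    )
    def test_conversion_and_floor(self, width, expected):
        assert ci_to_sd(0.0, width) == pytest.approx(expected)

    def test_mean_published_width(self):
        assert ci_to_sd(0.0, 13.73) == pytest.approx(3.5026, abs=5e-5)

    def test_inverted_interval_raises(self):
        with pytest.raises(InvalidInputError):
            ci_to_sd(5.0, 4.0)


class TestMixtureFit:
    def test_single_observation_k1(self):
        model = QtlMixtureModel([12.5], [2.0])
        res = model.fit(1, seed=0)
        assert res.means[0] == pytest.approx(12.5)
        expected_ll = -0.5 * math.log(2 * math.pi) - math.log(2.0)
        assert res.loglike == pytest.approx(expected_ll, abs=1e-9)

    def test_two_well_separated_pairs(self):
        model = QtlMixtureModel([10, 10, 50, 50], [1, 1, 1, 1])
        res = model.fit(2, seed=0)
        assert res.means == pytest.approx([10.0, 50.0], abs=1e-6)
        assert res.weights == pytest.approx([0.5, 0.5], abs=1e-6)
        assert sorted(res.assignments.tolist()) == [0, 0, 1, 1]

    def test_loglik_non_decreasing_in_k(self):
        rng = np.random.default_rng(3)
        y, s = random_observations(rng, 9, n_clusters=3)
        model = QtlMixtureModel(y, s)
        lls = [model.fit(k, seed=0).loglike for k in range(1, 7)]
        for a, b in zip(lls, lls[1:]):
            assert b >= a - 1e-6

    def test_k_out_of_range(self):
        model = QtlMixtureModel([1.0, 2.0], [1.0, 1.0])
        with pytest.raises(InvalidInputError):
            model.fit(3)
        with pytest.raises(InvalidInputError):
            model.fit(0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        y, s = random_observations(rng, 12, n_clusters=3)
        a = QtlMixtureModel(y, s).fit(3, seed=42)
        b = QtlMixtureModel(y, s).fit(3, seed=42)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.assignments, b.assignments)

    @pytest.mark.parametrize("seed", range(12))
    def test_hard_clustering_matches_exhaustive_partition_search(self, seed):
        """On cluster-separated instances fitted at the true K, EM's hard
        clustering attains the exhaustive-partition optimum of the
        classification likelihood."""
        rng = np.random.default_rng(500 + seed)
        y, s, k_true = separated_instance(rng)
        res = QtlMixtureModel(y, s).fit(k_true, seed=seed)
        k_hard = len(set(res.assignments.tolist()))
        oracle = best_partition_loglik(y, s, k_hard)
        assert res.classification_loglike() >= oracle - 1e-6

    @pytest.mark.parametrize("seed", range(6))
    def test_loglik_attains_exhaustive_multistart_optimum(self, seed):
        """fit() reaches the global mixture-likelihood optimum found by an
        independent EM run from every set partition."""
        from oracle_utils import best_mixture_loglik

        rng = np.random.default_rng(300 + seed)
        y, s = random_observations(rng, int(rng.integers(4, 8)), n_clusters=2)
        model = QtlMixtureModel(y, s)
        for k in (1, 2, 3):
            fit_ll = model.fit(k, seed=seed).loglike
            assert fit_ll >= best_mixture_loglik(y, s, k) - 1e-6


class TestModelSelection:
    def test_two_coincident_observations_prefer_one_component(self):
        sel = select_model([obs(10.0, 1.0, "a"), obs(10.0, 1.0, "b")], seed=0)
        assert sel.final_k == 1

    def test_two_clear_clusters(self):
        # two clusters five SDs apart, five observations each
        y = [0.0, 0.1, -0.1, 0.05, -0.05, 5.0, 5.1, 4.9, 5.05, 4.95]
        sel = select_model([obs(v, 1.0, f"q{i}") for i, v in enumerate(y)], seed=0)
        assert sel.final_k == 2

    def test_single_observation(self):
        sel = select_model([obs(3.0, 1.0)], seed=0)
        assert sel.final_k == 1
        assert sel.table["K"].tolist() == [1]

    def test_aicc_abstains_when_undefined_anywhere(self):
        # n = 4, Kmax = 4 -> p = 7 at K = 4 and AICc undefined there
        sel = select_model([obs(v, 1.0, f"q{v}") for v in (0.0, 1.0, 10.0, 11.0)], seed=0)
        assert sel.chosen_k_per_criterion["AICc"] is None
        assert sel.final_k >= 1

    def test_empty_input_raises(self):
        with pytest.raises(InvalidInputError):
            select_model([])

    def test_vote_tie_breaks_to_smaller_k(self):
        # verify the tie rule directly on the recorded votes
        y = [0.0, 0.2, 8.0, 8.2, 30.0, 30.2]
        sel = select_model([obs(v, 1.0, f"q{i}") for i, v in enumerate(y)], seed=0)
        votes = [v for v in sel.chosen_k_per_criterion.values() if v is not None]
        from collections import Counter

        counts = Counter(votes)
        top = max(counts.values())
        assert sel.final_k == min(k for k, c in counts.items() if c == top)


class TestSummarize:
    def test_single_member(self):
        m = summarize_mqtl([obs(10.0, 2.0, "a")], "1A")
        assert m.position == pytest.approx(10.0)
        assert m.ci_width == pytest.approx(3.92 * 2.0)

    def test_two_equal_sd_members(self):
        m = summarize_mqtl([obs(10.0, 1.0, "a"), obs(14.0, 1.0, "b")], "1A")
        assert m.position == pytest.approx(12.0)
        assert m.ci_width == pytest.approx(3.92 / math.sqrt(2.0), abs=1e-9)

    def test_heteroscedastic_pooling(self):
        members = [obs(0.0, 1.0, "a"), obs(0.0, 1.0, "b"), obs(0.0, 2.0, "c")]
        m = summarize_mqtl(members, "1A")
        assert m.position == pytest.approx(0.0)
        assert m.ci_width == pytest.approx(3.92 / math.sqrt(2.25), abs=1e-9)

    def test_position_within_member_range_and_ci_shrinks(self):
        rng = np.random.default_rng(5)
        members = [obs(float(y), float(s), f"q{i}")
                   for i, (y, s) in enumerate(zip(rng.normal(50, 3, 6), rng.uniform(0.5, 4, 6)))]
        m = summarize_mqtl(members, "1A")
        ys = [o.y for o in members]
        assert min(ys) <= m.position <= max(ys)
        assert m.ci_width < min(3.92 * o.s for o in members)

    def test_flanking_markers_clamp_at_chromosome_ends(self, dense_map):
        # CI [-116.6, 118.6] exceeds the 0-100 cM map on both sides
        m = summarize_mqtl([obs(1.0, 60.0, "a")], "2B", consensus=dense_map)
        assert m.left_marker == "M00" and m.right_marker == "M10"

    def test_empty_cluster_raises(self):
        with pytest.raises(InvalidInputError):
            summarize_mqtl([], "1A")


def _projected(qtl_id, chrom, peak, half_width, make_qtl):
    q = make_qtl(qtl_id, chrom=chrom, peak=peak, ci=(peak - half_width, peak + half_width))
    return ProjectedQtl(
        source=q, status=ProjectionStatus.PROJECTED, consensus_peak=peak,
        consensus_ci_lo=peak - half_width, consensus_ci_hi=peak + half_width,
    )


class TestRunMetaAnalysis:
    def test_single_qtl_single_chromosome(self, make_qtl):
        mqtls, traces = run_meta_analysis([_projected("Q1", "3B", 40.0, 4.0, make_qtl)], seed=0)
        assert len(mqtls) == 1
        assert mqtls[0].name == "MQTL_3B_1"
        assert mqtls[0].members == ("Q1",)

    def test_names_ordered_by_position(self, make_qtl):
        projected = [
            _projected(f"Q{i}", "5A", pos, 2.0, make_qtl)
            for i, pos in enumerate([80.0, 81.0, 20.0, 21.0, 19.5, 79.5])
        ]
        mqtls, _ = run_meta_analysis(projected, seed=0)
        names = [m.name for m in mqtls]
        positions = [m.position for m in mqtls]
        assert names == [f"MQTL_5A_{i}" for i in range(1, len(mqtls) + 1)]
        assert positions == sorted(positions)

    def test_deterministic_end_to_end(self, make_qtl):
        projected = [
            _projected(f"Q{i}", "2D", float(p), 3.0, make_qtl)
            for i, p in enumerate([10, 11, 12, 60, 62, 61, 100, 99])
        ]
        a, _ = run_meta_analysis(projected, seed=9)
        b, _ = run_meta_analysis(projected, seed=9)
        assert [(m.name, m.position, m.members) for m in a] == [
            (m.name, m.position, m.members) for m in b
        ]

    def test_mean_mqtl_ci_below_mean_member_ci(self, make_qtl):
        projected = [
            _projected(f"Q{i}", "2D", float(p), 3.0, make_qtl)
            for i, p in enumerate([10, 11, 12, 60, 62, 61])
        ]
        mqtls, _ = run_meta_analysis(projected, seed=0)
        member_mean = np.mean([6.0] * len(projected))
        assert np.mean([m.ci_width for m in mqtls]) < member_mean
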