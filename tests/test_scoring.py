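"""Partial scores, class scores, and the decision rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netquant.errors import ConfigError
from netquant.features import FeatureVector
from netquant.scoring import (
    AmbiguityReason,
    ClassDefinition,
    ClassifierConfig,
    FeatureRange,
    UNKNOWN_INTRACELLULAR,
    class_score,
    classify,
    margins,
    partial_score,
)


def fv(**kw) -> FeatureVector:
    base = dict(area=100, mean_total=0.0, mean_extra=0.0, std_extra=0.0,
                mean_log=0.0, circ_perimeter=0.05, circ_diameter=0.5)
    base.update(kw)
    return FeatureVector(**base)


R = lambda l, u: FeatureRange("mean_total", l, u)


class TestPartialScore:
    def test_inside_interval_scores_one(self):
        assert partial_score(15, R(10, 20), s=1) == 1.0
        assert partial_score(10, R(10, 20), s=1) == 1.0
        assert partial_score(20, R(10, 20), s=1) == 1.0

    def test_zero_at_margin_edges(self):
        # dl = 1*10*10/30 = 10/3; du = 1*20*10/30 = 20/3
        rng = R(10, 20)
        assert partial_score(10 - 10 / 3, rng, s=1) == pytest.approx(0.0, abs=1e-12)
        assert partial_score(20 + 20 / 3, rng, s=1) == pytest.approx(0.0, abs=1e-12)
        assert partial_score(1.0, rng, s=1) == 0.0

    def test_half_at_margin_midpoints(self):
        rng = R(10, 20)
        assert partial_score(10 - 10 / 6, rng, s=1) == pytest.approx(0.5)
        assert partial_score(20 + 20 / 6, rng, s=1) == pytest.approx(0.5)

    def test_zero_margin_is_hard_interval_test(self):
        rng = R(10, 20)
        assert partial_score(20.0001, rng, s=0) == 0.0
        assert partial_score(9.9999, rng, s=0) == 0.0
        assert partial_score(20, rng, s=0) == 1.0

    def test_invalid_interval_rejected(self):
        with pytest.raises(ConfigError):
            FeatureRange("mean_total", 20, 10)
        with pytest.raises(ConfigError):
            FeatureRange("mean_total", -math.inf, math.inf)
        with pytest.raises(ConfigError):
            FeatureRange("not_a_feature", 0, 1)

    def test_infinite_upper_bound_keeps_soft_lower_edge(self):
        rng = R(10, math.inf)
        assert partial_score(1e12, rng, s=1) == 1.0
        # dl falls back to s*l = 10
        assert partial_score(0.0, rng, s=1) == pytest.approx(0.0, abs=1e-12)
        assert partial_score(5.0, rng, s=1) == pytest.approx(0.5)

    def test_infinite_lower_bound_symmetric(self):
        rng = R(-math.inf, 20)
        assert partial_score(-1e12, rng, s=1) == 1.0
        assert partial_score(30.0, rng, s=1) == pytest.approx(0.5)
        assert partial_score(40.0, rng, s=1) == pytest.approx(0.0, abs=1e-12)

    def test_point_interval_is_equality_test(self):
        rng = R(7, 7)
        assert partial_score(7, rng, s=2) == 1.0
        assert partial_score(7.001, rng, s=2) == 0.0

    def test_zero_lower_bound_gives_hard_lower_edge(self):
        rng = R(0, 10)
        assert margins(rng, 1.0)[0] == 0.0
        assert partial_score(-0.001, rng, s=1) == 0.0

    def test_negative_feature_margins_nonnegative(self):
        rng = FeatureRange("mean_log", -8, 8)
        dl, du = margins(rng, 0.5)
        assert dl >= 0 and du >= 0
        assert partial_score(-8 - dl / 2, rng, s=0.5) == pytest.approx(0.5)

    def test_continuity_by_dense_sampling(self):
        rng_np = np.random.default_rng(19)
        for _ in range(25):
            l = rng_np.uniform(0.5, 50)
            u = l + rng_np.uniform(0.5, 50)
            s = rng_np.uniform(0.05, 2.0)
            rng = R(l, u)
            dl, du = margins(rng, s)
            xs = np.linspace(l - dl - 1, u + du + 1, 4001)
            ys = np.array([partial_score(x, rng, s) for x in xs])
            step = xs[1] - xs[0]
            max_jump = np.abs(np.diff(ys)).max()
            # |S'| <= pi/(2*min(dl,du)); jump bounded accordingly
            bound = step * math.pi / (2 * min(dl, du)) * 1.5 + 1e-12
            assert max_jump <= bound
            # monotone up to the interval, monotone down after it
            left = ys[xs <= l]
            right = ys[xs >= u]
            assert np.all(np.diff(left) >= -1e-12)
            assert np.all(np.diff(right) <= 1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(
        l=st.floats(0.1, 100), width=st.floats(0.1, 100),
        s=st.floats(0, 3), x=st.floats(-200, 400), k=st.floats(0.01, 50),
    )
    def test_scale_coherence(self, l, width, s, x, k):
        """Margins are relative: scaling l, u, x together preserves S."""
        a = partial_score(x, R(l, l + width), s)
        b = partial_score(k * x, R(k * l, k * (l + width)), s)
        assert a == pytest.approx(b, abs=1e-9)


class TestClassScore:
    def test_product_of_partial_scores(self):
        cd = ClassDefinition("PMN", (
            FeatureRange("area", 50, 200),
            FeatureRange("mean_total", 10, 20),
        ))
        # area in range (1), mean_total at lower-margin midpoint (0.5)
        v = fv(area=100, mean_total=10 - 10 / 6)
        assert class_score(v, cd, s=1.0) == pytest.approx(0.5)

    def test_all_in_range_scores_one(self):
        cd = ClassDefinition("PMN", (FeatureRange("area", 50, 200),))
        assert class_score(fv(area=120), cd, s=0.3) == 1.0

    def test_any_zero_partial_annihilates(self):
        cd = ClassDefinition("PMN", (
            FeatureRange("area", 50, 200),
            FeatureRange("mean_total", 10, 20),
        ))
        assert class_score(fv(area=120, mean_total=500), cd, s=0.3) == 0.0

    def test_score_bounded_by_smallest_partial(self):
        rng_np = np.random.default_rng(4)
        cd = ClassDefinition("PMN", (
            FeatureRange("area", 80, 120),
            FeatureRange("mean_total", 10, 20),
            FeatureRange("mean_extra", 0, 5),
        ))
        for _ in range(50):
            v = fv(area=int(rng_np.uniform(60, 140)),
                   mean_total=rng_np.uniform(0, 40),
                   mean_extra=rng_np.uniform(0, 10))
            total = class_score(v, cd, s=0.8)
            partials = [partial_score(v[r.feature_name], r, 0.8) for r in cd.ranges]
            assert 0.0 <= total <= min(partials) + 1e-12

    def test_duplicate_feature_ranges_rejected(self):
        with pytest.raises(ConfigError):
            ClassDefinition("PMN", (
                FeatureRange("area", 0, 1), FeatureRange("area", 2, 3),
            ))


def two_class_config(s=1.0):
    return ClassifierConfig(
        classes={
            "PMN": ClassDefinition("PMN", (FeatureRange("mean_total", 10, 20),)),
            "RND": ClassDefinition("RND", (FeatureRange("mean_total", 40, 60),)),
        },
        s=s,
    )


class TestClassify:
    def test_unique_high_scorer_wins(self):
        out = classify(fv(mean_total=15), two_class_config(), ["PMN", "RND"])
        assert out.label == "PMN"
        assert out.ambiguity_reason is AmbiguityReason.NONE
        assert out.scores["PMN"] == 1.0 and out.scores["RND"] == 0.0

    def test_competitor_above_reject_threshold_blocks(self):
        # RND's lower margin: dl = 1*40*20/100 = 8; x=56 -> inside RND,
        # and also choose overlapping PMN interval via wide s
        config = ClassifierConfig(
            classes={
                "PMN": ClassDefinition("PMN", (FeatureRange("mean_total", 10, 50),)),
                "RND": ClassDefinition("RND", (FeatureRange("mean_total", 40, 60),)),
            },
            s=1.0,
        )
        # x=45 sits inside both intervals: two scores of 1.0
        out = classify(fv(mean_total=45), config, ["PMN", "RND"])
        assert out.label == UNKNOWN_INTRACELLULAR
        assert out.ambiguity_reason is AmbiguityReason.MULTIPLE_HIGH_SCORES

    def test_no_high_score_flags_unknown(self):
        # margin midpoint scores 0.5 < 0.8
        out = classify(fv(mean_total=10 - 10 / 6), two_class_config(), ["PMN", "RND"])
        assert out.label == UNKNOWN_INTRACELLULAR
        assert out.ambiguity_reason is AmbiguityReason.NO_HIGH_SCORE
        assert out.scores["PMN"] == pytest.approx(0.5)

    def test_competitor_exactly_at_reject_threshold_tolerated(self):
        config = ClassifierConfig(
            classes={
                "PMN": ClassDefinition("PMN", (FeatureRange("mean_total", 10, 20),)),
                "RND": ClassDefinition("RND", (FeatureRange("area", 100, 100),)),
            },
            s=0.0,
            reject_threshold=1.0,
            assign_threshold=1.0,
        )
        # RND scores exactly 1.0 == reject_threshold -> closed comparison passes
        out = classify(fv(mean_total=15, area=100), config, ["PMN"])
        assert out.label == "PMN"

    def test_hard_threshold_limit_matches_interval_membership(self):
        config = two_class_config(s=0.0)
        for x, expect in [(10, "PMN"), (20, "PMN"), (9.999, UNKNOWN_INTRACELLULAR),
                          (41, "RND"), (30, UNKNOWN_INTRACELLULAR)]:
            assert classify(fv(mean_total=x), config, ["PMN", "RND"]).label == expect

    def test_never_assigns_below_assign_threshold(self):
        rng_np = np.random.default_rng(23)
        for _ in range(200):
            l1 = rng_np.uniform(0, 50)
            config = ClassifierConfig(
                classes={
                    "PMN": ClassDefinition("PMN", (
                        FeatureRange("mean_total", l1, l1 + rng_np.uniform(1, 30)),)),
                    "RND": ClassDefinition("RND", (
                        FeatureRange("mean_total", rng_np.uniform(0, 60),
                                     rng_np.uniform(60, 120)),)),
                },
                s=rng_np.uniform(0, 2),
            )
            out = classify(fv(mean_total=rng_np.uniform(-20, 150)), config, ["PMN", "RND"])
            if out.label != UNKNOWN_INTRACELLULAR:
                assert out.scores[out.label] >= config.assign_threshold

    def test_candidate_classes_must_be_defined(self):
        with pytest.raises(ConfigError):
            classify(fv(), two_class_config(), ["PMN", "NET"])
        with pytest.raises(ConfigError):
            classify(fv(), two_class_config(), [])

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ConfigError):
            ClassifierConfig(classes={}, assign_threshold=0.3, reject_threshold=0.5)
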