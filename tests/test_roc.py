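import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from midpass import (
    DegenerateIntervalWarning,
    EstimationError,
    auc,
    auc_ci_delong,
    bootstrap_ci,
    optimal_cutpoint,
    roc_curve,
)


def brute_force_cutpoint(labels, scores, orientation="higher_score_positive"):
    """Independent exhaustive search over every midpoint candidate threshold.

    Positive call: score beyond the threshold in the positive direction.
    Ties on the corner distance break toward higher sensitivity, then
    toward the smaller absolute threshold.
    """
    y = np.asarray(labels, bool)
    x = np.asarray(scores, float)
    s = x if orientation == "higher_score_positive" else -x
    d = np.unique(s)
    half_gap = np.min(np.diff(d)) / 2 if d.size > 1 else 0.5
    cands = (
        [d[0] - half_gap]
        + [(a + b) / 2 for a, b in zip(d[:-1], d[1:])]
        + [d[-1] + half_gap]
    )
    best = None
    for t in cands:
        sens = np.mean(s[y] > t)
        spec = np.mean(s[~y] <= t)
        dist = np.hypot(1 - sens, 1 - spec)
        t_orig = t if orientation == "higher_score_positive" else -t
        key = (round(dist, 12), -round(sens, 12), abs(t_orig))
        if best is None or key < best[0]:
            best = (key, t_orig, sens, spec)
    return best[1], best[2], best[3]


def random_instance(rng, half_integers=True):
    n = rng.integers(4, 51)
    y = np.zeros(n, bool)
    y[: rng.integers(1, n)] = True
    rng.shuffle(y)
    if not y.any() or y.all():
        y[0], y[-1] = True, False
    vals = rng.integers(0, 11, n).astype(float)
    if half_integers and rng.random() < 0.5:
        vals += rng.integers(0, 2, n) * 0.5
    return y, vals


class TestRocCurve:
    def test_perfect_separation_has_perfect_point(self):
        y = [True, True, False, False]
        x = [3, 4, 0, 1]
        curve = roc_curve(y, x)
        perfect = (curve.sensitivity == 1) & (curve.specificity == 1)
        assert perfect.any()
        cp = optimal_cutpoint(curve)
        assert cp.threshold == 2.0 and cp.distance_to_corner == 0.0

    def test_overlapping_classes_have_no_perfect_point(self):
        # positives {2,1}, negatives {2,0}: the shared score 2 forces a trade-off
        curve = roc_curve([True, True, False, False], [2, 1, 2, 0])
        assert not ((curve.sensitivity == 1) & (curve.specificity == 1)).any()

    def test_single_class_rejected(self):
        with pytest.raises(EstimationError, match="ROC undefined"):
            roc_curve([True, True], [1, 2])

    def test_degenerate_endpoints_present(self):
        curve = roc_curve([True, False, True, False], [3, 1, 2, 2])
        pts = set(zip(curve.sensitivity, curve.specificity))
        assert (1.0, 0.0) in pts and (0.0, 1.0) in pts

    def test_monotone_operating_points(self, nrs_pairs):
        grc = nrs_pairs.df["grc"]
        labels = grc.isin([1, 2])[grc.isin([1, 2, 3])]
        scores = nrs_pairs.df.loc[grc.isin([1, 2, 3]), "change"]
        curve = roc_curve(labels.to_numpy(), scores.to_numpy())
        assert np.all(np.diff(curve.sensitivity) <= 0)
        assert np.all(np.diff(curve.specificity) >= 0)
        assert np.all(np.diff(curve.thresholds) > 0)


class TestOptimalCutpoint:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            y, x = random_instance(rng)
            orient = "lower_score_positive" if rng.random() < 0.5 else "higher_score_positive"
            cp = optimal_cutpoint(roc_curve(y, x, orient))
            t, sens, spec = brute_force_cutpoint(y, x, orient)
            assert cp.threshold == pytest.approx(t)
            assert cp.sensitivity == pytest.approx(sens)
            assert cp.specificity == pytest.approx(spec)

    def test_tie_breaks_toward_sensitivity(self):
        # symmetric tie: threshold 0.5 gives (sens .9, spec .8), threshold
        # 1.5 gives (sens .8, spec .9); the sensitivity rule picks the former
        y = np.array([True] * 10 + [False] * 10)
        x = np.concatenate([[0, 1], np.full(8, 2), np.zeros(8), [1, 2]])
        cp = optimal_cutpoint(roc_curve(y, x))
        assert cp.threshold == pytest.approx(0.5)
        assert cp.sensitivity == pytest.approx(0.9)
        assert cp.specificity == pytest.approx(0.8)


class TestAuc:
    @pytest.mark.parametrize(
        "labels, scores, expected",
        [
            ([True, True, False, False], [4, 3, 2, 1], 1.0),
            ([True, True, False, False], [2, 1, 2, 0], 0.625),
        ],
    )
    def test_pair_counting_examples(self, labels, scores, expected):
        assert auc(labels, scores) == pytest.approx(expected)

    def test_equals_trapezoidal_area_and_sklearn(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            y, x = random_instance(rng)
            a = auc(y, x)
            assert a == pytest.approx(roc_curve(y, x).trapezoidal_auc(), abs=1e-12)
            assert a == pytest.approx(roc_auc_score(y, x), abs=1e-12)

    def test_relabeling_flips_auc(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            y, x = random_instance(rng)
            assert auc(~y, x) == pytest.approx(1 - auc(y, x), abs=1e-12)
            assert auc(y, x, "lower_score_positive") == pytest.approx(
                1 - auc(y, x), abs=1e-12
            )

    def test_independent_labels_near_half(self):
        rng = np.random.default_rng(3)
        y = rng.random(10000) < 0.5
        x = rng.integers(0, 11, 10000).astype(float)
        assert auc(y, x) == pytest.approx(0.5, abs=0.02)


class TestDelong:
    def test_interval_brackets_auc_and_orders_with_alpha(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(1, 1, 200), rng.normal(0, 1, 200)])
        y = np.array([True] * 200 + [False] * 200)
        r95 = auc_ci_delong(y, x, alpha=0.05)
        r90 = auc_ci_delong(y, x, alpha=0.10)
        assert 0 <= r95.ci_low <= r95.auc <= r95.ci_high <= 1
        assert r95.ci_low < r90.ci_low and r90.ci_high < r95.ci_high

    def test_perfect_separation_degenerate_with_warning(self):
        y = np.array([True] * 20 + [False] * 20)
        x = np.concatenate([np.arange(20) + 100.0, np.arange(20.0)])
        with pytest.warns(DegenerateIntervalWarning):
            r = auc_ci_delong(y, x)
        assert r.auc == 1.0 and r.ci_low == r.ci_high == 1.0 and r.degenerate

    def test_requires_two_per_class(self):
        with pytest.raises(EstimationError):
            auc_ci_delong([True, False, False], [3, 1, 2])

    def test_discrimination_labels(self):
        from midpass import AucResult

        assert AucResult(0.65, 0, 1, 0).discrimination_label == "poor"
        assert AucResult(0.75, 0, 1, 0).discrimination_label == "acceptable"
        assert AucResult(0.80, 0, 1, 0).discrimination_label == "acceptable"
        assert AucResult(0.85, 0, 1, 0).discrimination_label == "excellent"


class TestBootstrapCI:
    def test_constant_statistic_gives_point_interval(self):
        with pytest.warns(DegenerateIntervalWarning):
            ci = bootstrap_ci(lambda d: 3.25, np.arange(50.0), n_reps=100, seed=0)
        assert (ci.low, ci.high) == (3.25, 3.25) and ci.degenerate

    def test_same_seed_reproduces_interval(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=100)
        a = bootstrap_ci(np.mean, data, n_reps=200, seed=11)
        b = bootstrap_ci(np.mean, data, n_reps=200, seed=11)
        c = bootstrap_ci(np.mean, data, n_reps=200, seed=12)
        assert (a.low, a.high) == (b.low, b.high)
        assert (a.low, a.high) != (c.low, c.high)

    def test_width_matches_closed_form_for_mean(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal(250)
        ci = bootstrap_ci(np.mean, data, n_reps=2000, seed=7)
        expected = 2 * 1.96 / np.sqrt(250)
        assert abs((ci.high - ci.low) - expected) / expected < 0.2

    def test_nested_alphas_on_same_seed(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal(100)
        wide = bootstrap_ci(np.mean, data, n_reps=500, alpha=0.05, seed=3)
        narrow = bootstrap_ci(np.mean, data, n_reps=500, alpha=0.10, seed=3)
        assert wide.low <= narrow.low and narrow.high <= wide.high

    def test_undefined_rate_cap_enforced(self):
        def bad(d):
            raise EstimationError("always undefined")

        with pytest.raises(EstimationError, match="undefined"):
            bootstrap_ci(bad, np.arange(10.0), n_reps=100, seed=0)

    def test_cluster_bootstrap_respects_units(self):
        # two clusters with very different means: the cluster bootstrap
        # interval must be far wider than the pair-level interval
        data = np.concatenate([np.zeros(50), np.ones(50) * 10])
        units = np.repeat(["a", "b"], 50)
        pair = bootstrap_ci(np.mean, data, n_reps=300, seed=1)
        clust = bootstrap_ci(np.mean, data, n_reps=300, seed=1, units=units)
        assert (clust.high - clust.low) > 3 * (pair.high - pair.low)


@given(st.data())
@settings(max_examples=60, deadline=None, derandomize=True)
def test_cutpoint_oracle_property(data):
    """optimal_cutpoint equals exhaustive search on arbitrary tied instances."""
    n = data.draw(st.integers(4, 30))
    y = np.array(data.draw(st.lists(st.booleans(), min_size=n, max_size=n)))
    if y.all() or not y.any():
        y[0] = ~y[0]
    x = np.array(
        data.draw(
            st.lists(
                st.sampled_from([0.0, 0.5, 1, 2, 3, 3.5, 4, 7, 10]),
                min_size=n,
                max_size=n,
            )
        )
    )
    if np.unique(x[y]).size == 0 or np.unique(x).size < 1:
        return
    cp = optimal_cutpoint(roc_curve(y, x))
    t, sens, spec = brute_force_cutpoint(y, x)
    assert (cp.sensitivity, cp.specificity) == pytest.approx((sens, spec))
    assert cp.threshold == pytest.approx(t)
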