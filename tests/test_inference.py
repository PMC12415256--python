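"""Trend tests, epoch contrasts, mixed model, surrogates, locked curves."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from insightews import (
    ContextConfig,
    EpochLabels,
    binned_trend,
    epoch_contrast,
    hierarchical_regression,
    insight_locked_curve,
    kendall_trend,
    label_epochs,
    permute_session,
    surprisal_series,
    surrogate_null,
)
from insightews.ews import SurprisalSeries

from conftest import make_series


def brute_kendall_tau(x, y):
    """O(n^2) pair-counting oracle, tau-b with tie corrections."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[j] - x[i], y[j] - y[i]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom if denom else np.nan, conc


def make_surprisal(session_id, times, values, is_new=None):
    frame = pd.DataFrame(
        {
            "time": times,
            "inscription": ["x"] * len(times),
            "surprisal_bits": values,
            "cond_prob": [0.5] * len(times),
            "context_n": [5] * len(times),
            "is_new": is_new if is_new is not None else [False] * len(times),
        }
    )
    return SurprisalSeries(session_id=session_id, frame=frame, config=ContextConfig(delta=10))


class TestKendallTrend:
    def test_perfect_concordance(self):
        res = kendall_trend([1, 2, 3], [1, 2, 3])
        assert res.tau == 1.0 and res.concordant_pairs == 3

    def test_perfect_discordance(self):
        res = kendall_trend([1, 2, 3], [3, 2, 1])
        assert res.tau == -1.0 and res.concordant_pairs == 0

    def test_pair_count_identity_at_n15(self):
        """With n=15 (105 pairs), 102 concordant and 3 discordant pairs give
        tau = 99/105 ~ 0.943 — the printed statistic's arithmetic."""
        y = list(range(15))
        y[13], y[14] = y[14], y[13]
        y[0], y[1] = y[1], y[0]
        res = kendall_trend(list(range(15)), y)
        assert res.concordant_pairs + res.discordant_pairs == 105
        assert res.tau == pytest.approx(
            (res.concordant_pairs - res.discordant_pairs) / 105
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(-5, 5), min_size=3, max_size=12),
        st.data(),
    )
    def test_agrees_with_pair_counting_oracle(self, x, data):
        y = data.draw(st.lists(st.integers(-5, 5), min_size=len(x), max_size=len(x)))
        tau_o, conc_o = brute_kendall_tau(x, y)
        if np.isnan(tau_o):
            return
        res = kendall_trend(x, y)
        assert res.tau == pytest.approx(tau_o, abs=1e-12)
        assert res.concordant_pairs == conc_o

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            kendall_trend([1, 2, 3], [1, 2])


class TestLabelEpochs:
    def test_window_arithmetic(self):
        s = make_series("s", [50.0, 100.0, 250.0], list("abc"))
        lab = label_epochs(s, [100.0], w_pre=120, w_post=120)
        assert lab.pre.tolist() == [True, False, False]
        assert lab.post.tolist() == [False, True, False]
        assert lab.other.tolist() == [False, False, True]

    def test_no_insights_all_other(self):
        s = make_series("s", [1.0, 2.0], ["a", "b"])
        lab = label_epochs(s, [], 100, 100)
        assert lab.other.all()

    def test_close_insights_overlap_flags(self):
        s = make_series("s", [130.0], ["a"])
        lab = label_epochs(s, [100.0, 160.0], w_pre=120, w_post=120)
        assert lab.pre[0] and lab.post[0]

    def test_negative_width_rejected(self):
        s = make_series("s", [1.0], ["a"])
        with pytest.raises(ValueError):
            label_epochs(s, [1.0], -1, 0)


class TestEpochContrast:
    def test_constant_surprisal_equal_means(self):
        sup = make_surprisal("s", np.arange(10.0), np.full(10, 1.5))
        lab = label_epochs(make_series("s", np.arange(10.0), ["a"] + ["b"] * 9),
                          [5.0], 2, 2)
        table = epoch_contrast([sup], [lab])
        assert table.loc["pre", "mean"] == table.loc["other", "mean"] == 1.5

    def test_injected_contrast_recovered(self, rng):
        sups, labs = [], []
        for si in range(8):
            times = np.arange(200.0)
            base = rng.normal(1.0, 0.3, size=200)
            lab = label_epochs(make_series(f"s{si}", times, ["a"] * 1 + ["b"] * 199),
                              [100.0], w_pre=30, w_post=30)
            vals = base + 0.3 * lab.pre
            sups.append(make_surprisal(f"s{si}", times, vals))
            labs.append(lab)
        table = epoch_contrast(sups, labs)
        contrast = table.loc["pre", "mean"] - table.loc["other", "mean"]
        assert contrast == pytest.approx(0.3, abs=0.1)

    def test_empty_stratum_reported_missing(self):
        sup = make_surprisal("s", np.arange(5.0), np.ones(5))
        lab = label_epochs(make_series("s", np.arange(5.0), list("abcde")), [], 1, 1)
        table = epoch_contrast([sup], [lab])
        assert table.loc["pre", "n"] == 0
        assert np.isnan(table.loc["pre", "mean"])


class TestHierarchicalRegression:
    def _synthetic(self, rng, n_sessions=12, n_events=500, b_pre=0.10, b_post=0.10,
                   b_time=0.0, b_new=0.05, sd_intercept=0.2, sd_noise=0.5):
        sups, labs = [], []
        for si in range(n_sessions):
            times = np.arange(float(n_events))
            series = make_series(f"s{si}", times,
                                 [str(rng.integers(0, 8)) for _ in range(n_events)])
            lab = label_epochs(series, [n_events * 0.7], w_pre=n_events * 0.1,
                              w_post=n_events * 0.1)
            is_new = np.array([e.is_new for e in series.events])
            y = (1.0 + rng.normal(0, sd_intercept)
                 + b_time * times / 60.0
                 + b_pre * lab.pre + b_post * lab.post + b_new * is_new
                 + rng.normal(0, sd_noise, size=n_events))
            sups.append(make_surprisal(f"s{si}", times, y, is_new=is_new.tolist()))
            labs.append(lab)
        return sups, labs

    def test_parameter_recovery_within_two_se(self, rng):
        sups, labs = self._synthetic(rng)
        table = hierarchical_regression(sups, labs)
        for term, true in [("pre", 0.10), ("post", 0.10), ("time_scaled", 0.0),
                           ("is_new", 0.05)]:
            est, se = table.loc[term, "coef"], table.loc[term, "se"]
            assert abs(est - true) < 2 * se + 1e-9, term

    def test_single_session_degrades_to_ols_with_warning(self, rng):
        sups, labs = self._synthetic(rng, n_sessions=1)
        with pytest.warns(UserWarning, match="single session"):
            table = hierarchical_regression(sups, labs)
        assert {"pre", "post"} <= set(table.index)

    def test_rank_deficiency_reported(self):
        mask = (np.arange(20) % 2).astype(bool)
        sup0 = make_surprisal("s0", np.arange(20.0), np.ones(20))
        sup1 = make_surprisal("s1", np.arange(20.0), np.ones(20))
        # pre == post everywhere (non-constant) -> collinear design
        lab0 = EpochLabels("s0", pre=mask, post=mask.copy())
        lab1 = EpochLabels("s1", pre=mask, post=mask.copy())
        with pytest.raises(ValueError, match="rank deficient"):
            hierarchical_regression([sup0, sup1], [lab0, lab1])

    def test_constant_covariate_dropped_with_warning(self, rng):
        sups, labs = self._synthetic(rng, n_sessions=3, n_events=200)
        # force is_new constant by marking nothing new
        for s in sups:
            s.frame["is_new"] = False
        with pytest.warns(UserWarning, match="constant covariates"):
            table = hierarchical_regression(sups, labs)
        assert "is_new" not in table.index


class TestPermuteSession:
    def test_conservation_laws(self, rng):
        s = make_series("s", np.sort(rng.uniform(0, 100, 40)),
                        [str(x) for x in rng.integers(0, 5, 40)])
        p = permute_session(s, seed=3)
        assert [e.time for e in p.events] == [e.time for e in s.events]
        assert sorted(p.labels) == sorted(s.labels)
        seen = set()
        for e in p.events:
            assert e.is_new == (e.inscription not in seen)
            seen.add(e.inscription)

    def test_singleton_unchanged(self):
        s = make_series("s", [1.0], ["a"])
        assert permute_session(s, seed=1) == s

    def test_all_arrangements_equally_likely(self):
        """Distribution check over 10^4 permutations of a 4-event series:
        each distinct ordering appears at its exchangeable frequency."""
        s = make_series("s", [0.0, 1.0, 2.0, 3.0], ["a", "a", "b", "c"])
        rng = np.random.default_rng(0)
        counts = {}
        n = 10_000
        for _ in range(n):
            p = permute_session(s, rng)
            counts[tuple(p.labels)] = counts.get(tuple(p.labels), 0) + 1
        # 4!/2! = 12 distinct arrangements, each with probability 1/12
        assert len(counts) == 12
        for c in counts.values():
            assert c / n == pytest.approx(1 / 12, abs=0.012)


class TestSurrogateNull:
    def test_single_permutation_p_values(self):
        s = make_series("s", np.arange(30.0), [str(i % 3) for i in range(30)])
        res = surrogate_null([s], {"s": [20.0]}, ContextConfig(delta=10, smoothing_k=0.5),
                             w_pre=5, w_post=5, n_permutations=1, seed=0)
        assert res.p_pre in (0.5, 1.0)
        assert res.p_post in (0.5, 1.0)

    def test_injected_signal_detected(self, rng):
        """Sessions repetitive except for scrambled pre-insight stretches:
        the pre contrast must beat nearly every surrogate."""
        series, insights = [], {}
        for si in range(5):
            labels = [str(i % 4) for i in range(240)]
            for i in range(160, 200):
                labels[i] = str(int(rng.integers(0, 4)))
            sid = f"s{si}"
            series.append(make_series(sid, np.arange(240.0), labels))
            insights[sid] = [200.0]
        res = surrogate_null(series, insights, ContextConfig(delta=30, smoothing_k=0.5),
                             w_pre=40, w_post=40, n_permutations=99, seed=1)
        assert res.observed_contrast_pre > 0
        assert res.p_pre <= 0.05

    def test_exchangeable_null_contrasts_centered_on_zero(self, rng):
        """Label-shuffled data: the null contrast distribution has mean ~0."""
        series, insights = [], {}
        for si in range(4):
            sid = f"s{si}"
            series.append(make_series(sid, np.arange(80.0),
                                      [str(x) for x in rng.integers(0, 5, 80)]))
            insights[sid] = [float(rng.integers(20, 60))]
        res = surrogate_null(series, insights, ContextConfig(delta=15, smoothing_k=0.5),
                             w_pre=10, w_post=10, n_permutations=200, seed=2)
        se = res.null_pre.std(ddof=1) / np.sqrt(len(res.null_pre))
        assert abs(res.null_pre.mean()) < 4 * se + 0.01


class TestInsightLockedCurve:
    def test_constant_surprisal_flat_curve(self):
        sup = make_surprisal("s", np.arange(100.0), np.full(100, 2.0))
        curve = insight_locked_curve([sup], {"s": [50.0]}, window_width=10, step=10)
        vals = curve["mean"].dropna()
        assert (vals == 2.0).all()

    def test_needs_an_insight(self):
        sup = make_surprisal("s", np.arange(10.0), np.ones(10))
        with pytest.raises(ValueError):
            insight_locked_curve([sup], {"s": []}, 5, 5)

    def test_single_event_sessions_give_singleton_windows(self):
        sups = [make_surprisal(f"s{i}", [10.0], [1.0 + i]) for i in range(3)]
        ins = {f"s{i}": [10.0] for i in range(3)}
        curve = insight_locked_curve(sups, ins, window_width=4, step=4)
        at_zero = curve[curve["rel_time"] == 0.0]
        assert int(at_zero["n"].iloc[0]) == 3

    def test_rises_into_insight_on_synthetic_corpus(self, small_corpus):
        cfg = ContextConfig(delta=40, smoothing_k=0.0)
        sups = [surprisal_series(r.series, cfg) for r in small_corpus.sessions]
        curve = insight_locked_curve(sups, small_corpus.insights(),
                                     window_width=40, step=40, span=200)
        m = curve.set_index("rel_time")["mean"]
        near = m.loc[-40:0].mean()
        far = m.loc[-200:-160].mean()
        late = m.loc[120:200].mean()
        assert near > far       # ramps up toward the insight
        assert near > late      # falls off after settling


class TestBinnedTrend:
    def test_sd_u_trend_positive_on_small_corpus(self, small_corpus):
        res = binned_trend(small_corpus, "sd_u", n_bins=10)
        assert res.tau > 0.5

    def test_n_bins_validation(self, small_corpus):
        with pytest.raises(ValueError):
            binned_trend(small_corpus, "sd_u", n_bins=2)
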