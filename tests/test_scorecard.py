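"""ChiMerge binning, WOE, score scaling, KS threshold, KDE risk bands."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mascard.scorecard import (BinStats, RiskFunction, ScoreBands, assemble_points,
                               band_thresholds, build_scorecard, chimerge_bin,
                               fit_woe_lr, kde_risk, ks_threshold, scaling_coeffs,
                               score_patient, woe_table)
from mascard.synth import CohortTable


# --------------------------------------------------------------------------
# independent oracles

def _chi2_pair(table):
    """2x2 chi-square without continuity correction; zero-expectation cells
    contribute nothing."""
    obs = np.asarray(table, float)
    exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    stat = float(np.sum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0)))
    return stat, float(stats.chi2.sf(stat, df=1))


def _chimerge_oracle(values, labels, edges, alpha, min_bins, max_bins):
    """Plain re-simulation of the merge sequence, recomputed from scratch at
    every step: repeatedly fuse the most similar adjacent pair while it is
    not significant (or too many bins remain)."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, int)
    edges = list(edges)
    while True:
        idx = np.searchsorted(edges, values, side="left")
        k = len(edges) + 1
        counts = [(np.sum((idx == i) & (labels == 0)),
                   np.sum((idx == i) & (labels == 1))) for i in range(k)]
        if k <= min_bins:
            return edges
        pairs = [_chi2_pair([counts[i], counts[i + 1]]) for i in range(k - 1)]
        i_best = int(np.argmin([c for c, _ in pairs]))
        _, p = pairs[i_best]
        if p >= alpha or k > max_bins:
            del edges[i_best]
        else:
            return edges


def _ks_oracle(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    best = (-1.0, None)
    for c in sorted(set(scores)):
        d = abs(np.mean(scores[labels == 1] <= c) - np.mean(scores[labels == 0] <= c))
        if d > best[0] + 1e-15:
            best = (d, c)
    return best


# --------------------------------------------------------------------------

class TestChimerge:
    def test_uninformative_feature_collapses_to_min_bins(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=400)
        y = rng.integers(0, 2, 400)
        b = chimerge_bin(x, y, min_bins=3)
        assert b.n_bins == 3

    def test_step_change_yields_a_cut_near_the_step(self):
        # class ratio flips at x = 0.5: a surviving edge must sit close by
        x = np.concatenate([np.linspace(0, 0.5, 20, endpoint=False),
                            np.linspace(0.5, 1.0, 20)])
        y = np.array([0] * 20 + [1] * 20)
        b = chimerge_bin(x, y, n_prebins=10, min_bins=2)
        assert any(0.4 <= e <= 0.6 for e in b.edges)

    @pytest.mark.parametrize("seed", range(25))
    def test_final_edges_match_merge_sequence_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 41))
        x = rng.normal(size=n) + np.arange(n) * 1e-6  # distinct values
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        b = chimerge_bin(x, y, n_prebins=8, min_bins=2, max_bins=6)
        # oracle starts from the same quantile pre-bin edge set
        qs = np.quantile(x, np.linspace(0, 1, 9)[1:-1])
        pre = sorted(set(float(v) for v in qs if x.min() <= v < x.max()))
        expect = _chimerge_oracle(x, y, pre, 0.05, 2, 6)
        assert b.edges == pytest.approx(expect)

    def test_few_distinct_values_become_their_own_bins(self):
        x = np.array([0.0, 1.0, 2.0] * 10)
        y = np.tile([0, 1], 15)
        b = chimerge_bin(x, y, min_bins=3)
        assert b.n_bins == 3
        assert b.edges == [0.0, 1.0]

    def test_literal_rule_merges_most_different_pair(self):
        # the inverted rule fuses significant pairs; with one sharp step it
        # therefore destroys the informative cut standard ChiMerge keeps
        x = np.concatenate([np.linspace(0, 1, 30, endpoint=False),
                            np.linspace(1, 2, 30)])
        y = np.array([0] * 30 + [1] * 30)
        std = chimerge_bin(x, y, n_prebins=6, min_bins=2)
        lit = chimerge_bin(x, y, n_prebins=6, min_bins=2, rule="literal")
        assert any(0.9 <= e <= 1.1 for e in std.edges)
        assert not any(0.9 <= e <= 1.1 for e in lit.edges)


class TestWoe:
    def test_balanced_bin_has_zero_woe(self):
        x = np.array([0.0] * 20 + [1.0] * 20)
        y = np.tile([0, 1], 20)
        t = woe_table([0.5], x, y)
        assert t.woe == pytest.approx([0.0, 0.0])

    def test_forty_percent_versus_ten_percent_gives_ln_four(self):
        # one bin holding 40% of SLE and 10% of MAS samples
        x = np.concatenate([np.zeros(40), np.ones(60), np.zeros(10), np.ones(90)])
        y = np.array([0] * 100 + [1] * 100)
        t = woe_table([0.5], x, y)
        assert t.woe[0] == pytest.approx(np.log(4.0))

    def test_zero_count_bin_is_finite_and_positive_under_smoothing(self):
        x = np.concatenate([np.zeros(30), np.ones(70), np.ones(100)])
        y = np.array([0] * 100 + [1] * 100)  # bin 0 has zero MAS members
        t = woe_table([0.5], x, y)
        assert np.isfinite(t.woe[0]) and t.woe[0] > 0

    def test_class_shares_sum_to_one_after_smoothing(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=120)
        y = rng.integers(0, 2, 120)
        t = woe_table([-1.0, 0.0, 1.0], x, y)
        assert sum(t.pct_neg) == pytest.approx(1.0, abs=1e-9)
        assert sum(t.pct_pos) == pytest.approx(1.0, abs=1e-9)

    def test_doubly_empty_bin_merged_with_warning(self):
        x = np.array([0.0] * 10 + [10.0] * 10)
        y = np.tile([0, 1], 10)
        with pytest.warns(UserWarning, match="empty"):
            t = woe_table([2.0, 5.0], x, y)  # (2, 5] holds nobody
        assert t.n_bins == 2


class TestWoeLogistic:
    def test_null_features_recover_class_ratio_intercept(self):
        rng = np.random.default_rng(2)
        y = np.array([0] * 300 + [1] * 100)
        woe = pd.DataFrame({"a": rng.normal(size=400), "b": rng.normal(size=400)})
        intercept, coefs = fit_woe_lr(woe, y, C=10.0)
        assert intercept == pytest.approx(np.log(100 / 300), abs=0.2)
        assert all(abs(b) < 0.2 for b in coefs.values())

    def test_informative_woe_feature_gets_negative_weight(self):
        # high WOE = SLE-typical, so the MAS log-odds must fall with WOE
        rng = np.random.default_rng(3)
        y = np.tile([0, 1], 200)
        woe = pd.DataFrame({"a": (1 - y) * 1.0 + rng.normal(scale=0.4, size=400)})
        _, coefs = fit_woe_lr(woe, y)
        assert coefs["a"] < 0

    def test_duplicated_feature_splits_its_weight(self):
        rng = np.random.default_rng(4)
        y = np.tile([0, 1], 150)
        a = (1 - y) + rng.normal(scale=0.5, size=300)
        single, s_coef = fit_woe_lr(pd.DataFrame({"a": a}), y, C=5.0)
        _, d_coef = fit_woe_lr(pd.DataFrame({"a": a, "b": a.copy()}), y, C=5.0)
        assert d_coef["a"] == pytest.approx(d_coef["b"], abs=1e-6)
        assert d_coef["a"] + d_coef["b"] == pytest.approx(s_coef["a"], rel=0.15)


class TestScaling:
    def test_published_parameterization(self):
        s = scaling_coeffs(1.0 / 19.0, 70.0, 4.14)
        assert round(s.B, 2) == 5.97
        assert round(s.A, 2) == 52.41

    @given(st.floats(0.01, 10.0), st.floats(10.0, 100.0), st.floats(0.5, 10.0))
    @settings(max_examples=100, derandomize=True)
    def test_scaling_identities_hold_exactly(self, odds0, P0, PD0):
        s = scaling_coeffs(odds0, P0, PD0)
        assert s.B * np.log(2.0) == pytest.approx(PD0, rel=1e-12)
        assert s.A - s.B * np.log(odds0) == pytest.approx(P0, rel=1e-9, abs=1e-9)

    def test_unit_odds_maps_baseline_to_P0(self):
        assert scaling_coeffs(1.0, 55.0, 4.0).A == pytest.approx(55.0)

    def test_pdo_of_ln2_gives_unit_slope(self):
        assert scaling_coeffs(0.5, 55.0, np.log(2.0)).B == pytest.approx(1.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            scaling_coeffs(0.0, 70.0, 4.14)
        with pytest.raises(ValueError):
            scaling_coeffs(0.5, 70.0, -1.0)

    def test_doubling_the_odds_drops_the_score_by_pdo(self):
        s = scaling_coeffs(1.0 / 19.0, 70.0, 4.14)
        for odds in (0.05, 0.5, 3.0):
            drop = (s.A - s.B * np.log(odds)) - (s.A - s.B * np.log(2 * odds))
            assert drop == pytest.approx(s.PD0, rel=1e-12)


class TestKsThreshold:
    def test_perfect_separation(self):
        ks, thr = ks_threshold([10, 20, 30, 80, 90, 95], [1, 1, 1, 0, 0, 0])
        assert ks == 1.0 and thr == 30

    def test_identical_distributions_give_zero(self):
        s = [1, 2, 3, 4] * 2
        y = [0] * 4 + [1] * 4
        ks, _ = ks_threshold(s, y)
        assert ks == pytest.approx(0.0)

    def test_eight_point_example_matches_enumeration(self):
        s = [3, 5, 5, 6, 7, 8, 9, 9]
        y = [1, 1, 0, 1, 0, 0, 1, 0]
        ks, thr = ks_threshold(s, y)
        eks, ethr = _ks_oracle(s, y)
        assert ks == pytest.approx(eks) and thr == ethr

    @pytest.mark.parametrize("seed", range(50))
    def test_random_instances_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 51))
        s = rng.integers(0, 100, n).astype(float)
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        ks, thr = ks_threshold(s, y)
        eks, ethr = _ks_oracle(s, y)
        assert ks == pytest.approx(eks, abs=1e-12)
        assert thr == ethr

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ks_threshold([1, 2, 3], [1, 1, 1])


class TestKdeRisk:
    def test_identical_distributions_risk_half(self):
        rng = np.random.default_rng(5)
        s = rng.normal(50, 10, size=200)
        risk = kde_risk(s, s.copy(), prior_pos=0.5)
        for v in (30, 50, 70):
            assert risk(v) == pytest.approx(0.5, abs=1e-9)

    def test_separated_classes_polarize_the_risk(self):
        rng = np.random.default_rng(6)
        pos = rng.normal(25, 6, 150)
        neg = rng.normal(75, 6, 150)
        risk = kde_risk(pos, neg)
        assert risk(20) > 0.99
        assert risk(80) < 0.01

    def test_fitted_densities_integrate_to_one(self):
        rng = np.random.default_rng(7)
        risk = kde_risk(rng.normal(30, 5, 100), rng.normal(70, 5, 100))
        for kde in (risk.kde_pos, risk.kde_neg):
            assert kde.integrate_box_1d(-np.inf, np.inf) == pytest.approx(1.0, abs=0.01)

    def test_degenerate_scores_suggest_bandwidth(self):
        with pytest.raises(ValueError, match="bandwidth"):
            kde_risk(np.full(10, 5.0), np.arange(10.0))

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            kde_risk([1, 2, 3], np.arange(10.0))


class TestBands:
    @staticmethod
    def _monotone_risk():
        rng = np.random.default_rng(8)
        return kde_risk(rng.normal(30, 8, 200), rng.normal(70, 8, 200))

    def test_monotone_risk_yields_ordered_thresholds(self):
        bands = band_thresholds(self._monotone_risk())
        t = [bands.thresholds[lv] for lv in (0.95, 0.75, 0.25, 0.05)]
        assert t == sorted(t)
        assert all(a < b for a, b in zip(t, t[1:]))

    def test_bands_partition_the_score_range(self):
        bands = band_thresholds(self._monotone_risk())
        intervals = bands.intervals()
        covered = sorted(s for lo, hi in intervals.values()
                         for s in range(lo, hi + 1))
        assert covered == list(range(0, 101))
        for s in (0, 25, 50, 75, 100):
            assert sum(lo <= s <= hi for lo, hi in intervals.values()) == 1

    def test_unattainable_level_is_an_error(self):
        rng = np.random.default_rng(9)
        s = rng.normal(50, 10, 200)
        flat = kde_risk(s, s.copy(), prior_pos=0.5)  # risk stuck at 0.5
        with pytest.raises(ValueError, match="never attained"):
            band_thresholds(flat)

    def test_band_lookup_is_consistent_with_intervals(self):
        bands = band_thresholds(self._monotone_risk())
        for s in range(0, 101, 5):
            lab = bands.band_of(s)
            lo, hi = bands.intervals()[lab]
            assert lo <= s <= hi


class TestAssembledCard:
    @staticmethod
    def _fit(seed=0, n=400):
        rng = np.random.default_rng(seed)
        y = np.tile([0, 1], n // 2)
        frame = pd.DataFrame({
            "ferritin": np.exp(rng.normal(6.5 + 1.6 * y, 0.7)),
            "FIB": rng.normal(3.4 - 1.2 * y, 0.8),
            "pancytopenia": rng.binomial(1, 0.05 + 0.6 * y).astype(float),
        })
        cohort = CohortTable(frame, y)
        # a wide explicit bandwidth keeps the coarse 3-feature score
        # distribution smooth enough for well-ordered bands
        return build_scorecard(cohort, bandwidth=0.6), cohort

    def test_unrounded_score_reconstructs_the_log_odds(self):
        (card, _), cohort = self._fit()
        for _, row in cohort.frame.head(40).iterrows():
            rec = dict(row)
            expect = card.scaling.A - card.scaling.B * card.linear_predictor(rec)
            assert card.score_unrounded(rec) == pytest.approx(expect, abs=1e-9)

    def test_rounding_error_bounded_by_half_point_per_feature(self):
        (card, _), cohort = self._fit()
        p = len(card.features)
        for _, row in cohort.frame.iterrows():
            rec = dict(row)
            assert abs(card.score(rec) - card.score_unrounded(rec)) <= p / 2 + 1e-9

    def test_zero_woe_patient_scores_near_A_when_intercept_vanishes(self):
        scaling = scaling_coeffs(1.0 / 19.0, 70.0, 4.14)
        bins = {"f": BinStats("f", [0.0], woe=[0.0, 0.0], n_neg=[1, 1], n_pos=[1, 1],
                              pct_neg=[0.5, 0.5], pct_pos=[0.5, 0.5])}
        card = assemble_points(0.0, {"f": 1.0}, bins, scaling)
        assert card.score({"f": 1.0}) == round(scaling.A)

    def test_ferritin_points_fall_in_mas_enriched_bins(self):
        (card, _), _ = self._fit()
        pts = card.points["ferritin"]
        woe = card.bins["ferritin"].woe
        # WOE decreases toward MAS-enriched (high ferritin) bins; points follow
        order = np.argsort(woe)
        assert [pts[i] for i in order] == sorted(pts)

    def test_feature_missing_from_bins_is_an_error(self):
        scaling = scaling_coeffs(1.0 / 19.0, 70.0, 4.14)
        with pytest.raises(ValueError, match="ghost"):
            assemble_points(0.0, {"ghost": 1.0}, {}, scaling)

    def test_serialization_round_trip_rescores_identically(self, tmp_path):
        (card, risk), cohort = self._fit(seed=1)
        card.to_json(tmp_path / "card.json")
        from mascard.scorecard import ScorecardModel
        back = ScorecardModel.from_json(tmp_path / "card.json")
        a = card.score_cohort(cohort)
        b = back.score_cohort(cohort)
        assert np.array_equal(a, b)
        assert back.threshold == card.threshold
        assert back.bands.thresholds == card.bands.thresholds

    def test_score_patient_contract(self):
        (card, risk), cohort = self._fit(seed=2)
        rec = dict(cohort.frame.iloc[0])
        out = score_patient(card, rec, risk)
        assert out["band"] == card.bands.band_of(out["score_clamped"])
        assert out["predicted"] in ("MAS", "SLE")
        # same-bin perturbation leaves the score unchanged
        b = card.bins["FIB"]
        rec2 = dict(rec)
        rec2["FIB"] = rec["FIB"] + 1e-9
        if int(b.assign([rec2["FIB"]])[0]) == int(b.assign([rec["FIB"]])[0]):
            assert score_patient(card, rec2, risk)["score"] == out["score"]
        with pytest.raises(ValueError, match="ferritin"):
            score_patient(card, {"FIB": 3.0, "pancytopenia": 0.0})
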