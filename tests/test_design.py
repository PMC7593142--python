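"""Rarefaction engine: scenario enumeration, thinning/subsetting algebra,
scenario scoring and the metric correlations."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from scrdesign import (ScenarioSpec, correlate_metrics, enumerate_scenarios,
                       evaluate_scenario, fit, make_mask,
                       run_design_evaluation, subset_occasions,
                       thin_transects)
from scrdesign.survey import SurveyDesign, generate_survey_dataset

from _oracles import pearson_r


@pytest.fixture(scope="module")
def survey():
    """A well-populated synthetic survey reused across scenario tests."""
    design = SurveyDesign((0, 0, 30000, 30000))
    truth = dict(D=200.0, g0=0.3, sigma=1400.0)
    ds = generate_survey_dataset(design, truth, seed=123)
    mask = make_mask(ds.detectors, buffer_m=8000.0, spacing_m=1500.0)
    ref = fit(ds.histories, ds.detectors, mask, label="reference")
    assert ref.converged
    return ds, mask, ref


class TestEnumeration:
    def test_three_occasion_full_grid(self):
        specs = enumerate_scenarios(3, (1, 2, 3), ("both", "F", "M"))
        assert len(specs) == 36  # (1 full + 3 pairs) x 3 spacings x 3 sexes

    @pytest.mark.parametrize("S", [2, 3, 4, 5])
    def test_count_formula_by_exhaustion(self, S):
        specs = enumerate_scenarios(S, (1, 2), ("both",))
        n_pairs = len(list(combinations(range(S), 2)))
        expected_sets = 1 + n_pairs - (1 if S == 2 else 0)  # dedup at S=2
        assert len(specs) == expected_sets * 2
        assert len(set(specs)) == len(specs)

    def test_two_occasions_deduplicates_full_set(self):
        specs = enumerate_scenarios(2, (1,), ("both",))
        assert len(specs) == 1
        assert specs[0].occasion_set == (1, 2)

    def test_deterministic_ordering(self):
        a = enumerate_scenarios(3, (1, 2, 3), ("both", "F", "M"))
        b = enumerate_scenarios(3, (1, 2, 3), ("both", "F", "M"))
        assert a == b
        # occasions vary slowest, sex fastest
        assert [s.sex_group for s in a[:3]] == ["both", "F", "M"]

    def test_empty_factor_lists_rejected(self):
        with pytest.raises(ValueError):
            enumerate_scenarios(3, (), ("both",))


class TestThinning:
    def test_keep_every_one_is_identity(self, survey):
        ds, _, _ = survey
        det, hist = thin_transects(ds.detectors, ds.histories, 1)
        assert len(det) == len(ds.detectors)
        assert hist.n_detections == ds.histories.n_detections

    def test_alternate_transects_removed(self, survey):
        ds, _, _ = survey
        tids = pd.unique(ds.detectors.transect_id)
        det, hist = thin_transects(ds.detectors, ds.histories, 2)
        kept = set(pd.unique(det.transect_id))
        assert kept == set(tids[::2])
        # no detection references a dropped detector
        assert set(hist.detections["detector_id"]) <= set(det.detector_id)

    def test_offset_selects_other_lines(self, survey):
        ds, _, _ = survey
        tids = pd.unique(ds.detectors.transect_id)
        det, _ = thin_transects(ds.detectors, ds.histories, 2, offset=1)
        assert set(pd.unique(det.transect_id)) == set(tids[1::2])

    def test_individual_only_on_dropped_lines_vanishes(self):
        from scrdesign.detectors import DetectorArray
        from scrdesign.histories import from_records

        dets = DetectorArray(["A", "B"], [0.0, 3000.0], [0.0, 0.0],
                             ["t1", "t2"])
        hist = from_records([("a", 1, "A"), ("b", 1, "B"), ("b", 2, "B")], 2)
        det2, hist2 = thin_transects(dets, hist, 2)  # keeps t1 only
        assert list(hist2.individuals) == ["a"]

    def test_thinning_composition_commutes_with_subsetting(self, survey):
        ds, _, _ = survey
        d1, h1 = thin_transects(ds.detectors, ds.histories, 2)
        d1, h1 = subset_occasions(d1, h1, (1, 3))
        d2, h2 = subset_occasions(ds.detectors, ds.histories, (1, 3))
        d2, h2 = thin_transects(d2, h2, 2)
        assert set(d1.detector_id) == set(d2.detector_id)
        a = h1.detections.sort_values(
            ["individual_id", "occasion", "detector_id"]).reset_index(drop=True)
        b = h2.detections.sort_values(
            ["individual_id", "occasion", "detector_id"]).reset_index(drop=True)
        assert a.equals(b)


class TestOccasionSubsetting:
    def test_full_set_is_identity(self, survey):
        ds, _, _ = survey
        _, hist = subset_occasions(ds.detectors, ds.histories, (1, 2, 3))
        assert hist.n_detections == ds.histories.n_detections

    def test_renumbering_is_consecutive(self, survey):
        ds, _, _ = survey
        _, hist = subset_occasions(ds.detectors, ds.histories, (1, 3))
        assert hist.n_occasions == 2
        assert set(hist.detections["occasion"]) <= {1, 2}
        # occasion-3 detections became occasion 2, counts preserved
        before = (ds.histories.detections["occasion"] == 3).sum()
        after = (hist.detections["occasion"] == 2).sum()
        assert before == after

    def test_empty_set_rejected(self, survey):
        ds, _, _ = survey
        with pytest.raises(ValueError):
            subset_occasions(ds.detectors, ds.histories, ())


class TestScenarioScoring:
    def test_full_data_scenario_has_zero_bias(self, survey):
        ds, mask, ref = survey
        spec = ScenarioSpec((1, 2, 3), 1, "both")
        res = evaluate_scenario(spec, ds.detectors, ds.histories, mask, ref)
        assert res.converged
        assert res.abs_RB == pytest.approx(0.0, abs=1e-8)

    def test_relative_bias_hand_arithmetic(self):
        # |RB| = |(D_hat - D)/D| with D_ref = 16.1, D_hat = 18.0
        assert abs((18.0 - 16.1) / 16.1) == pytest.approx(0.118, abs=5e-4)

    def test_zero_recapture_scenario_recorded_not_raised(self, survey):
        from scrdesign.detectors import DetectorArray
        from scrdesign.histories import from_records

        ds, mask, ref = survey
        dets = DetectorArray(["A", "B"], [0.0, 3000.0], [0.0, 0.0],
                             ["t1", "t1"])
        hist = from_records([("a", 1, "A"), ("b", 2, "B")], 3)
        spec = ScenarioSpec((1, 2), 1, "both")
        res = evaluate_scenario(spec, dets, hist, mask, ref)
        assert not res.converged
        assert res.D_hat is None
        assert not any(res.favorable.values())

    def test_favorable_flags_follow_thresholds(self):
        from scrdesign.design import ScenarioResult

        r = ScenarioResult(ScenarioSpec((1, 2), 1), CV=0.25, abs_RB=0.1,
                           converged=True)
        assert r.favorable == {"CV<0.20": False, "CV<0.30": True,
                               "RB<0.15": True, "RB<0.20": True}

    def test_run_design_evaluation_shape(self, survey):
        ds, mask, _ = survey
        tab = run_design_evaluation(ds.detectors, ds.histories, mask,
                                    spacing_factors=(1, 2),
                                    sex_groups=("both",))
        assert len(tab) == 4 * 2  # (full + three 2-subsets) x 2 spacings
        full = tab[(tab["occasions"] == "1+2+3") & (tab["spacing_factor"] == 1)]
        assert full["abs_RB"].iloc[0] == pytest.approx(0.0, abs=1e-8)


class TestCorrelations:
    @staticmethod
    def _frame(cv, rb, n):
        return pd.DataFrame({
            "CV": cv, "abs_RB": rb, "n_individuals": n,
            "n_recaptures": n, "n_spatial_recaptures": n,
            "converged": [True] * len(cv)})

    def test_perfect_linear_association(self):
        tab = correlate_metrics(self._frame([1, 2, 3, 4], [2, 4, 6, 8],
                                            [1, 2, 3, 4]))
        row = tab[(tab.metric == "CV") & (tab.against == "abs_RB")].iloc[0]
        assert row.r == pytest.approx(1.0)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(3)
        cv = rng.random(12)
        n = rng.integers(5, 50, 12).astype(float)
        tab = correlate_metrics(self._frame(cv, rng.random(12), n))
        row = tab[(tab.metric == "CV") & (tab.against == "n_individuals")].iloc[0]
        assert row.r == pytest.approx(pearson_r(list(cv), list(n)), rel=1e-10)

    def test_zero_variance_reported_missing(self):
        tab = correlate_metrics(self._frame([0.2] * 4, [1, 2, 3, 4],
                                            [1, 2, 3, 4]))
        row = tab[(tab.metric == "CV") & (tab.against == "abs_RB")].iloc[0]
        assert np.isnan(row.r) and np.isnan(row.p)

    def test_too_few_points_reported_missing(self):
        tab = correlate_metrics(self._frame([1, 2], [1, 2], [1, 2]))
        assert tab["r"].isna().all()
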