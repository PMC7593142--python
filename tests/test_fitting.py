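"""Fitting behaviour: the census limit, derived-density identities, AICc
arithmetic, and the non-identifiability guard."""

import numpy as np
import pytest

from scrdesign import (DetectionModel, aicc_rank, fit, make_mask,
                       simulate_detections, simulate_homogeneous)
from scrdesign.fitting import FitResult, _data_key
from scrdesign.histories import from_records
from scrdesign.survey import SurveyDesign, generate_survey_dataset


@pytest.fixture(scope="module")
def fitted_survey():
    """One moderate synthetic survey and its constant-model fit."""
    design = SurveyDesign((0, 0, 30000, 30000))
    truth = dict(D=150.0, g0=0.25, sigma=1400.0)
    ds = generate_survey_dataset(design, truth, seed=77)
    mask = make_mask(ds.detectors, buffer_m=8000.0, spacing_m=1500.0)
    res = fit(ds.histories, ds.detectors, mask, region_area_km2=900.0)
    return ds, mask, res, truth


class TestDerivedDensity:
    def test_converges_and_recovers_truth_loosely(self, fitted_survey):
        ds, mask, res, truth = fitted_survey
        assert res.converged
        assert res.D_hat == pytest.approx(truth["D"], rel=0.35)
        assert res.model.g0[0] == pytest.approx(truth["g0"], abs=0.15)
        assert res.model.sigma[0] == pytest.approx(truth["sigma"], rel=0.35)

    def test_cv_identity_and_ci_brackets(self, fitted_survey):
        _, _, res, _ = fitted_survey
        assert res.CV_D == pytest.approx(res.SE_D / res.D_hat, rel=1e-12)
        lo, hi = res.CI_D
        assert 0 < lo < res.D_hat < hi

    def test_abundance_scales_with_region_area(self, fitted_survey):
        _, _, res, _ = fitted_survey
        assert res.N_hat == pytest.approx(res.D_hat * 900.0 / 1000.0, rel=1e-12)

    def test_census_limit(self):
        """With detection saturated everywhere the estimator returns the
        realized population count divided by the area."""
        rng_region = (0.0, 0.0, 12000.0, 12000.0)
        pop = simulate_homogeneous(400.0, rng_region, seed=5)
        # dense grid of strong detectors covering the whole square
        from scrdesign.detectors import DetectorArray

        g = np.arange(500.0, 12000.0, 1000.0)
        gx, gy = np.meshgrid(g, g)
        dets = DetectorArray([f"d{i}" for i in range(gx.size)], gx.ravel(),
                             gy.ravel(), ["t"] * gx.size)
        model = DetectionModel(0.95, 3000.0)
        hist = simulate_detections(pop, dets, model, 3, seed=6)
        assert hist.n_individuals == pop.n  # saturation: everyone detected
        mask = make_mask(dets, buffer_m=6000.0, spacing_m=1000.0)
        res = fit(hist, dets, mask)
        a = res.esa_km2
        assert res.D_hat == pytest.approx(1000.0 * pop.n / a, rel=1e-10)
        # esa approaches the area over which animals could be detected, so
        # D_hat lands near the realized density of the buffered population
        realized = 1000.0 * pop.n / ((12.0 + 2 * 6.0) ** 2)
        assert res.D_hat == pytest.approx(realized, rel=0.35)

    def test_buffer_width_beyond_5_sigma_immaterial(self):
        """Widening an already-sufficient buffer barely moves the density.

        The hazard-exponential tail decays as e^(-d/sigma), slower than a
        half-normal, so sufficiency sets in around 5 sigma (a 4-sigma
        buffer still truncates over 1% of the effective sampling area).
        """
        design = SurveyDesign((0, 0, 24000, 24000))
        truth = dict(D=250.0, g0=0.3, sigma=1200.0)
        ds = generate_survey_dataset(design, truth, seed=21)
        fits = {}
        for nsig in (5, 7):
            mask = make_mask(ds.detectors, buffer_m=nsig * truth["sigma"],
                             spacing_m=1200.0)
            fits[nsig] = fit(ds.histories, ds.detectors, mask)
        assert fits[5].D_hat == pytest.approx(fits[7].D_hat, rel=0.01)

    def test_no_recaptures_flags_non_identifiable(self, line_detectors,
                                                  toy_mask):
        hist = from_records([("a", 1, "d0"), ("b", 1, "d3")], 2)
        res = fit(hist, line_detectors, toy_mask)
        assert not res.converged
        assert "non-identifiable" in res.status
        assert res.D_hat is None


class TestAICc:
    def test_formula_hand_evaluation(self):
        r = FitResult(None, None, None, loglik=-100.0, K=3, n=50,
                      n_detections=60)
        r.AICc = -2 * r.loglik + 2 * r.K + 2 * r.K * (r.K + 1) / (r.n - r.K - 1)
        assert r.AICc == pytest.approx(206.0 + 24.0 / 46.0, rel=1e-12)

    def test_single_model_delta_zero(self):
        r = FitResult(None, None, None, -10.0, 2, 20, 30, AICc=24.5,
                      data_key="k1", label="m0")
        tab = aicc_rank([r])
        assert tab["dAICc"].iloc[0] == 0.0

    def test_equal_loglik_fewer_params_ranks_first(self):
        shared = dict(vcov=None, loglik=-100.0, n=50, n_detections=70,
                      data_key="k1")
        r3 = FitResult(None, None, K=3, label="small", **shared)
        r5 = FitResult(None, None, K=5, label="big", **shared)
        for r in (r3, r5):
            r.AICc = -2 * r.loglik + 2 * r.K + 2 * r.K * (r.K + 1) / (r.n - r.K - 1)
        tab = aicc_rank([r5, r3])
        assert tab["label"].iloc[0] == "small"

    def test_mixed_datasets_rejected(self):
        a = FitResult(None, None, None, -1.0, 2, 5, 6, data_key="aaa")
        b = FitResult(None, None, None, -1.0, 2, 5, 6, data_key="bbb")
        with pytest.raises(ValueError):
            aicc_rank([a, b])

    def test_data_key_ignores_row_order(self):
        h1 = from_records([("a", 1, "d0"), ("b", 1, "d1")], 2)
        h2 = from_records([("b", 1, "d1"), ("a", 1, "d0")], 2)
        assert _data_key(h1) == _data_key(h2)


class TestModelStructures:
    def test_time_structure_fits_with_more_parameters(self, fitted_survey):
        ds, mask, base, _ = fitted_survey
        res_t = fit(ds.histories, ds.detectors, mask, g0_structure="time")
        assert res_t.K == 3 + 1
        assert res_t.loglik >= base.loglik - 1e-6  # nesting
        tab = aicc_rank([base, res_t])
        assert set(tab["K"]) == {2, 4}
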