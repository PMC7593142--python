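"""Conditional likelihood: equivalence with a brute-force direct-summation
oracle and the structural invariances the likelihood must satisfy."""

import numpy as np
import pytest
from scipy.special import logit

from scrdesign import DetectionModel, negloglik_conditional
from scrdesign.detectors import DetectorArray, HabitatMask
from scrdesign.histories import from_records
from scrdesign.likelihood import (ConditionalLikelihood, pack_theta,
                                  unpack_theta)

from _oracles import brute_force_nll
from conftest import random_toy_instance

STRUCTS = ["constant", "time", "behaviour"]


def _theta_for(form, g0_levels, sigma_levels):
    if form == "hazard-exponential":
        icpt = np.log(-np.log1p(-np.asarray(g0_levels)))
    else:
        icpt = logit(np.asarray(g0_levels))
    return np.concatenate([icpt, np.log(sigma_levels)])


def _nlev(structure, S):
    return {"constant": 1, "time": S, "behaviour": 2}[structure]


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(25))
    def test_matches_brute_force_on_random_toys(self, trial):
        """Engine and loop-based oracle agree to 1e-10 on tiny instances
        across forms and parameter structures."""
        rng = np.random.default_rng(1000 + trial)
        dets, hist, mask, usage = random_toy_instance(rng)
        S = hist.n_occasions
        form = "hazard-exponential" if trial % 3 else "halfnormal"
        g0s = STRUCTS[int(rng.integers(3))]
        sgs = STRUCTS[int(rng.integers(3))]
        g0l = rng.uniform(0.05, 0.6, _nlev(g0s, S))
        sgl = rng.uniform(500, 3000, _nlev(sgs, S))
        eng = ConditionalLikelihood(hist, dets, mask, form, g0s, sgs)
        theta = _theta_for(form, g0l, sgl)
        got = eng.nll(theta)
        want = brute_force_nll(hist.to_array(dets).tolist(),
                               dets.xy.tolist(), mask.xy.tolist(),
                               mask.cell_area_km2, usage.tolist(),
                               list(g0l), list(sgl), form, g0s, sgs)
        assert got == pytest.approx(want, abs=1e-10)

    def test_public_wrapper_uses_model_parameters(self, line_detectors,
                                                  toy_mask, toy_histories):
        m = DetectionModel(0.3, 1200.0)
        v1 = negloglik_conditional(toy_histories, line_detectors, toy_mask, m)
        v2 = negloglik_conditional(toy_histories, line_detectors, toy_mask, m,
                                   theta=pack_theta(m))
        assert v1 == pytest.approx(v2, rel=1e-14)

    def test_quadrature_refinement_consistency(self):
        """Doubling mask resolution changes the value only via quadrature
        error, small on a smooth toy surface."""
        dets = DetectorArray(["a", "b"], [0.0, 1500.0], [0.0, 0.0], ["t", "t"])
        hist = from_records([("i1", 1, "a"), ("i1", 2, "b")], 2)
        m = DetectionModel(0.3, 1200.0)
        vals = {}
        for spacing in (500.0, 250.0, 125.0):
            g = np.arange(-3000.0, 4500.0 + spacing, spacing)
            gx, gy = np.meshgrid(g, g)
            mask = HabitatMask(gx.ravel(), gy.ravel(),
                               cell_area_km2=(spacing / 1000.0) ** 2)
            vals[spacing] = negloglik_conditional(hist, dets, mask, m)
        coarse = abs(vals[500.0] - vals[250.0])
        fine = abs(vals[250.0] - vals[125.0])
        assert coarse < 2e-2
        assert fine < coarse  # error shrinks with refinement


class TestInvariances:
    def test_translation_invariance(self, line_detectors, toy_mask,
                                    toy_histories):
        m = DetectionModel(0.25, 1400.0)
        v0 = negloglik_conditional(toy_histories, line_detectors, toy_mask, m)
        v1 = negloglik_conditional(toy_histories,
                                   line_detectors.translated(12345.0, -6789.0),
                                   toy_mask.translated(12345.0, -6789.0), m)
        assert v1 == pytest.approx(v0, rel=1e-12)

    def test_individual_and_detector_order_invariance(self):
        rng = np.random.default_rng(5)
        dets, hist, mask, usage = random_toy_instance(rng, max_detectors=3,
                                                      max_occasions=2)
        m = DetectionModel(0.3, 1000.0)
        v0 = negloglik_conditional(hist, dets, mask, m)
        # permute detector order (with matching usage rows)
        perm = rng.permutation(len(dets))
        dets2 = DetectorArray(dets.detector_id[perm], dets.x[perm],
                              dets.y[perm], dets.transect_id[perm],
                              usage=dets.usage[perm])
        v1 = negloglik_conditional(hist, dets2, mask, m)
        # permute individual (row) order
        det_shuffled = hist.detections.sample(frac=1.0, random_state=3)
        hist2 = from_records(det_shuffled.to_numpy().tolist(), hist.n_occasions)
        v2 = negloglik_conditional(hist2, dets, mask, m)
        assert v1 == pytest.approx(v0, rel=1e-12)
        assert v2 == pytest.approx(v0, rel=1e-12)

    def test_duplicated_individual_adds_its_own_contribution(self):
        """Adding an individual with an identical history changes the nll
        by exactly that individual's contribution."""
        dets = DetectorArray(["a", "b"], [0.0, 1500.0], [0.0, 0.0], ["t", "t"])
        mask = HabitatMask([-1000.0, 750.0, 2500.0], [0.0, 0.0, 0.0],
                           cell_area_km2=4.0)
        m = DetectionModel(0.3, 1200.0)
        base = [("i1", 1, "a"), ("i1", 2, "b"), ("i2", 1, "b")]
        v2 = negloglik_conditional(from_records(base, 2), dets, mask, m)
        v3 = negloglik_conditional(
            from_records(base + [("i3", 1, "b")], 2), dets, mask, m)
        v_single = negloglik_conditional(
            from_records([("i2", 1, "b")], 2), dets, mask, m)
        assert v3 - v2 == pytest.approx(v_single, rel=1e-10)

    def test_zero_esa_returns_infinity_not_exception(self, toy_histories,
                                                     line_detectors):
        # a mask so far away that p.(x) underflows to zero everywhere
        far = HabitatMask([1e9], [1e9], cell_area_km2=1.0)
        eng = ConditionalLikelihood(toy_histories, line_detectors, far)
        theta = pack_theta(DetectionModel(0.1, 100.0))
        assert np.isinf(eng.nll(theta))


class TestLinkScale:
    def test_pack_unpack_roundtrip(self):
        m = DetectionModel([0.1, 0.3], [800.0, 2000.0], g0_structure="time",
                           sigma_structure="behaviour", n_occasions=2)
        g0, sigma = unpack_theta(pack_theta(m), m.form, 2, 2)
        np.testing.assert_allclose(g0, m.g0, rtol=1e-12)
        np.testing.assert_allclose(sigma, m.sigma, rtol=1e-12)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            unpack_theta(np.zeros(3), "hazard-exponential", 1, 1)
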