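"""Maximum-likelihood fitting and derived density.

Detection parameters are estimated by minimising the conditional negative
log-likelihood on the link scale with a quasi-Newton optimiser.  Density
is then derived by Horvitz-Thompson: D_hat = n / a(theta_hat), with the
variance combining the parameter uncertainty (delta method through the
effective sampling area) and the Poisson variation of n.  Confidence
intervals for D are lognormal, the convention for abundance-type
parameters.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .detection import DetectionModel, _n_levels
from .detectors import DetectorArray, HabitatMask
from .histories import CaptureHistories
from .likelihood import ConditionalLikelihood, pack_theta, unpack_theta

__all__ = ["FitResult", "fit", "aicc_rank", "starting_values"]

_Z95 = 1.959963984540054


@dataclass
class FitResult:
    """Fitted SCR model with derived density.

    Density units are animals per 1,000 km^2 (the reporting convention for
    low-density ungulates); ``esa_km2`` is the effective sampling area.
    """

    model: DetectionModel | None
    theta: np.ndarray | None
    vcov: np.ndarray | None
    loglik: float
    K: int
    n: int
    n_detections: int
    esa_km2: float | None = None
    D_hat: float | None = None
    SE_D: float | None = None
    CV_D: float | None = None
    CI_D: tuple | None = None
    N_hat: float | None = None
    CI_N: tuple | None = None
    region_area_km2: float | None = None
    AICc: float = np.inf
    converged: bool = False
    status: str = ""
    label: str = ""
    data_key: str = ""

    def summary_row(self) -> dict:
        """One-row summary in the usual density-table layout."""
        def ci(t):
            return "" if t is None else f"({t[0]:.1f}-{t[1]:.1f})"
        g0 = None if self.model is None else np.atleast_1d(self.model.g0)
        sg = None if self.model is None else np.atleast_1d(self.model.sigma)
        return {
            "label": self.label,
            "D": self.D_hat, "CI_D": ci(self.CI_D), "SE_D": self.SE_D,
            "CV_D": self.CV_D,
            "g0": None if g0 is None else float(g0[0]),
            "sigma": None if sg is None else float(sg[0]),
            "N": self.N_hat, "CI_N": ci(self.CI_N),
            "loglik": self.loglik, "K": self.K, "AICc": self.AICc,
            "n": self.n, "converged": self.converged,
        }


def _data_key(histories: CaptureHistories) -> str:
    rows = sorted(map(tuple, histories.detections.astype(str).to_numpy()))
    h = hashlib.sha1(repr((rows, histories.n_occasions)).encode())
    return h.hexdigest()[:12]


def starting_values(histories: CaptureHistories, detectors: DetectorArray,
                    g0_start: float = 0.05) -> tuple[float, float]:
    """Data-driven (g0, sigma) starting values.

    sigma starts from the pooled spatial spread of each individual's
    detections about its own centroid (an RPSV-style statistic); when no
    individual moved between detectors, it falls back to the median
    nearest-detector spacing.
    """
    xy = detectors.xy
    idx = detectors.index_of(histories.detections["detector_id"].to_numpy())
    pts = xy[idx]
    ind = histories.detections["individual_id"].to_numpy()
    ss, df = 0.0, 0
    for u in np.unique(ind):
        p = pts[ind == u]
        if len(p) >= 2:
            c = p.mean(axis=0)
            ss += ((p - c) ** 2).sum()
            df += len(p) - 1
    if df > 0 and ss > 0:
        sigma = float(np.sqrt(ss / (2.0 * df)))
    else:
        from scipy.spatial import cKDTree
        d, _ = cKDTree(xy).query(xy, k=min(2, len(xy)))
        sigma = float(np.median(d[:, -1])) if xy.shape[0] > 1 else 1000.0
    return g0_start, max(sigma, 1.0)


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; adequate for a smooth 2-6 parameter surface."""
    k = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * h[i] * h[j])
    return H


def _lognormal_ci(est: float, cv: float) -> tuple[float, float]:
    c = np.exp(_Z95 * np.sqrt(np.log1p(cv * cv)))
    return (est / c, est * c)


def fit(histories: CaptureHistories, detectors: DetectorArray, mask: HabitatMask,
        model_spec: DetectionModel | None = None, *,
        form: str = "hazard-exponential", g0_structure: str = "constant",
        sigma_structure: str = "constant", region_area_km2: float | None = None,
        start: tuple[float, float] | None = None, label: str = "",
        gtol: float = 1e-6, cutoff_sigmas: float | None = None) -> FitResult:
    """Fit an SCR detection model by conditional maximum likelihood.

    ``model_spec`` (if given) supplies the functional form and parameter
    structures; its parameter values, when meaningful, seed the optimiser.
    With zero recaptures the spatial scale is unidentifiable and the fit
    is abandoned with ``status='non-identifiable'`` rather than raised.
    """
    if model_spec is not None:
        form = model_spec.form
        g0_structure = model_spec.g0_structure
        sigma_structure = model_spec.sigma_structure
    S = histories.n_occasions
    n = histories.n_individuals
    n_det = histories.n_detections
    key = _data_key(histories)
    n_g0 = _n_levels(g0_structure, S)
    n_sigma = _n_levels(sigma_structure, S)
    K = n_g0 + n_sigma

    if n_det - n <= 0:
        return FitResult(None, None, None, np.nan, K, n, n_det,
                         converged=False, status="non-identifiable: no recaptures",
                         label=label, data_key=key)

    eng = ConditionalLikelihood(histories, detectors, mask, form,
                                g0_structure, sigma_structure,
                                cutoff_sigmas=cutoff_sigmas)
    if start is None:
        start = starting_values(histories, detectors)
    g0s, sgs = start
    tmpl = DetectionModel(np.full(n_g0, g0s), np.full(n_sigma, sgs), form=form,
                          g0_structure=g0_structure, sigma_structure=sigma_structure,
                          n_occasions=S)
    theta0 = pack_theta(tmpl)

    res = minimize(eng.nll, theta0, method="BFGS",
                   options={"gtol": gtol, "maxiter": 500})
    theta = res.x
    loglik = -float(res.fun)
    status = res.message
    # BFGS often reports precision loss when the numeric gradient bottoms
    # out below its tolerance; accept the optimum if the surface is locally
    # quadratic with a PD Hessian.
    ok = bool(res.success) or ("precision loss" in str(res.message).lower())

    vcov = None
    if ok and np.isfinite(res.fun):
        H = _numeric_hessian(eng.nll, theta)
        try:
            np.linalg.cholesky(H)
            vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            ok = False
            status = "Hessian not positive definite"
    converged = ok and vcov is not None

    g0_hat, sigma_hat = unpack_theta(theta, form, n_g0, n_sigma)
    model = None
    if np.isfinite(theta).all() and (g0_hat > 0).all() and (g0_hat < 1).all():
        model = DetectionModel(g0_hat, sigma_hat, form=form,
                               g0_structure=g0_structure,
                               sigma_structure=sigma_structure, n_occasions=S)

    out = FitResult(model, theta, vcov, loglik, K, n, n_det,
                    converged=converged, status=str(status), label=label,
                    data_key=key, region_area_km2=region_area_km2)
    penalty = np.inf if n - K - 1 <= 0 else 2.0 * K * (K + 1) / (n - K - 1)
    out.AICc = -2.0 * loglik + 2.0 * K + penalty

    a = eng.esa_km2(theta)
    if a > 0 and np.isfinite(a):
        out.esa_km2 = a
        out.D_hat = 1000.0 * n / a
        if converged:
            # delta method through a(theta), plus Poisson var(n)
            h = 1e-4 * (1.0 + np.abs(theta))
            grad_a = np.empty_like(theta)
            for j in range(len(theta)):
                e = np.zeros_like(theta); e[j] = h[j]
                grad_a[j] = (eng.esa_km2(theta + e) - eng.esa_km2(theta - e)) / (2 * h[j])
            dDdth = -1000.0 * n / a**2 * grad_a
            var_D = float(dDdth @ vcov @ dDdth) + (1000.0 / a) ** 2 * n
            if var_D >= 0:
                out.SE_D = float(np.sqrt(var_D))
                out.CV_D = out.SE_D / out.D_hat
                out.CI_D = _lognormal_ci(out.D_hat, out.CV_D)
        if region_area_km2 is not None:
            out.N_hat = out.D_hat * region_area_km2 / 1000.0
            if out.CV_D is not None:
                out.CI_N = _lognormal_ci(out.N_hat, out.CV_D)
    return out


def aicc_rank(fits: list[FitResult]) -> pd.DataFrame:
    """Rank candidate fits of the *same* data by AICc (ties favour fewer K).

    Raises when the fits do not share the underlying capture data.
    """
    if not fits:
        raise ValueError("no fits to rank")
    keys = {f.data_key for f in fits}
    if len(keys) != 1:
        raise ValueError("fits were not made on identical data")
    rows = []
    for f in fits:
        rows.append({"label": f.label, "K": f.K, "loglik": f.loglik,
                     "AICc": f.AICc, "converged": f.converged})
    tab = pd.DataFrame(rows).sort_values(["AICc", "K"], kind="mergesort")
    tab["dAICc"] = tab["AICc"] - tab["AICc"].iloc[0]
    return tab.reset_index(drop=True)
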