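"""Distance-dependent detection functions.

The primary form is the hazard exponential,

    p(d) = 1 - exp(-lambda0 * exp(-d / sigma)),

appropriate for area-search data where search effort accumulates a hazard
of detection.  It is parameterized here through g0 = p(0), the detection
probability at the activity centre, so lambda0 = -ln(1 - g0).  A
half-normal alternative p(d) = g0 * exp(-d^2 / (2 sigma^2)) is provided
for comparison fits.

g0 and sigma may each be constant, occasion-specific ("time"), or switch
permanently after an individual's first capture ("behaviour").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FORMS = ("hazard-exponential", "halfnormal")
STRUCTURES = ("constant", "time", "behaviour")


def _n_levels(structure: str, n_occasions: int) -> int:
    if structure == "constant":
        return 1
    if structure == "time":
        return n_occasions
    if structure == "behaviour":
        return 2  # pre / post first capture
    raise ValueError(f"unknown structure {structure!r}")


@dataclass
class DetectionModel:
    """Detection function with (possibly structured) g0 and sigma.

    ``g0`` and ``sigma`` are scalars for a constant structure, otherwise
    arrays with one value per level (per occasion for "time"; (naive,
    post-capture) for "behaviour").  sigma is in metres.
    """

    g0: float | np.ndarray
    sigma: float | np.ndarray
    form: str = "hazard-exponential"
    g0_structure: str = "constant"
    sigma_structure: str = "constant"
    n_occasions: int = 1

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"form must be one of {FORMS}")
        for s in (self.g0_structure, self.sigma_structure):
            if s not in STRUCTURES:
                raise ValueError(f"structure must be one of {STRUCTURES}")
        self.g0 = np.atleast_1d(np.asarray(self.g0, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if len(self.g0) != _n_levels(self.g0_structure, self.n_occasions):
            raise ValueError("g0 has wrong number of levels for its structure")
        if len(self.sigma) != _n_levels(self.sigma_structure, self.n_occasions):
            raise ValueError("sigma has wrong number of levels for its structure")
        if not ((self.g0 > 0) & (self.g0 < 1)).all():
            raise ValueError("g0 must lie strictly in (0, 1)")
        if not (self.sigma > 0).all():
            raise ValueError("sigma must be positive")

    @property
    def n_params(self) -> int:
        return len(self.g0) + len(self.sigma)

    def level(self, structure: str, occasion: int, prior_capture: bool) -> int:
        if structure == "constant":
            return 0
        if structure == "time":
            return occasion
        return int(bool(prior_capture))

    def params_for(self, occasion: int = 0, prior_capture: bool = False):
        """(g0, sigma) applying on ``occasion`` (0-based) for this capture state."""
        if occasion < 0:
            raise IndexError("occasion must be non-negative")
        if "time" in (self.g0_structure, self.sigma_structure) \
                and occasion >= self.n_occasions:
            raise IndexError(f"occasion {occasion} out of range")
        g0 = self.g0[self.level(self.g0_structure, occasion, prior_capture)]
        sigma = self.sigma[self.level(self.sigma_structure, occasion, prior_capture)]
        return float(g0), float(sigma)


def hazard_exponential(distance, g0: float, sigma: float):
    """p(d) = 1 - exp(-lambda0 e^(-d/sigma)) with lambda0 = -ln(1-g0)."""
    lam0 = -np.log1p(-g0)
    return -np.expm1(-lam0 * np.exp(-np.asarray(distance, dtype=float) / sigma))


def halfnormal(distance, g0: float, sigma: float):
    d = np.asarray(distance, dtype=float)
    return g0 * np.exp(-d * d / (2.0 * sigma * sigma))


def detection_probability(model: DetectionModel, distance, occasion: int = 0,
                          prior_capture: bool = False):
    """Per-occasion probability that an animal centred ``distance`` metres
    from a detector is recorded there.

    Raises on negative distances; vectorized over ``distance``.
    """
    d = np.asarray(distance, dtype=float)
    if (d < 0).any():
        raise ValueError("distance must be non-negative")
    g0, sigma = model.params_for(occasion, prior_capture)
    fn = hazard_exponential if model.form == "hazard-exponential" else halfnormal
    out = fn(d, g0, sigma)
    return float(out) if np.isscalar(distance) else out
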