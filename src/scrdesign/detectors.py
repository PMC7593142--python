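"""Detector arrays and habitat masks for spatial capture-recapture.

Coordinates are planar metres throughout.  A detector is a "proximity"
detector: it records the presence of an individual on an occasion without
restricting its movement, so one animal can show up at several detectors
within the same occasion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DetectorArray:
    """A set of proximity detectors (searched grid cells).

    Parameters
    ----------
    detector_id
        Unique identifier per detector.
    x, y
        Planar coordinates in metres.
    transect_id
        Identifier of the flight line (transect) each detector lies on.
    usage
        Optional (n_detectors, n_occasions) 0/1 array; a zero switches a
        detector off for that occasion.  ``None`` means always on.
    """

    detector_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    transect_id: np.ndarray
    usage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.detector_id = np.asarray(self.detector_id)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.transect_id = np.asarray(self.transect_id)
        if not (len(self.detector_id) == len(self.x) == len(self.y) == len(self.transect_id)):
            raise ValueError("detector_id, x, y, transect_id must have equal length")
        if len(self.detector_id) == 0:
            raise ValueError("detector array is empty")
        if len(np.unique(self.detector_id)) != len(self.detector_id):
            raise ValueError("detector_ids are not unique")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("detector coordinates must be finite")
        if self.usage is not None:
            self.usage = np.asarray(self.usage, dtype=float)
            if self.usage.ndim != 2 or self.usage.shape[0] != len(self.detector_id):
                raise ValueError("usage must be (n_detectors, n_occasions)")
            if not np.isin(self.usage, (0.0, 1.0)).all():
                raise ValueError("usage entries must be 0/1")

    def __len__(self) -> int:
        return len(self.detector_id)

    @property
    def xy(self) -> np.ndarray:
        """(n_detectors, 2) coordinate array."""
        return np.column_stack([self.x, self.y])

    def usage_matrix(self, n_occasions: int) -> np.ndarray:
        """Per-occasion on/off flags as a dense (n_detectors, S) array."""
        if self.usage is None:
            return np.ones((len(self), n_occasions))
        if self.usage.shape[1] < n_occasions:
            raise ValueError(
                f"usage covers {self.usage.shape[1]} occasions, {n_occasions} requested"
            )
        return self.usage[:, :n_occasions]

    def index_of(self, detector_ids) -> np.ndarray:
        """Positions of ``detector_ids`` within the array (error on unknowns)."""
        order = {d: i for i, d in enumerate(self.detector_id)}
        try:
            return np.array([order[d] for d in np.asarray(detector_ids)], dtype=int)
        except KeyError as err:
            raise KeyError(f"unknown detector_id {err.args[0]!r}") from None

    def subset(self, keep: np.ndarray) -> "DetectorArray":
        """New array containing only the detectors selected by ``keep``."""
        keep = np.asarray(keep)
        return DetectorArray(
            detector_id=self.detector_id[keep],
            x=self.x[keep],
            y=self.y[keep],
            transect_id=self.transect_id[keep],
            usage=None if self.usage is None else self.usage[keep],
        )

    def translated(self, dx: float, dy: float) -> "DetectorArray":
        return DetectorArray(
            self.detector_id.copy(), self.x + dx, self.y + dy,
            self.transect_id.copy(),
            None if self.usage is None else self.usage.copy(),
        )


@dataclass
class HabitatMask:
    """Discretized state space of candidate activity centres.

    The mask must extend far enough beyond the detectors that animals
    centred outside it have a negligible chance of detection; ``buffer_m``
    records the width used when the mask was built.
    """

    x: np.ndarray
    y: np.ndarray
    cell_area_km2: float
    buffer_m: float = 0.0
    spacing_m: float | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) != len(self.y) or len(self.x) == 0:
            raise ValueError("mask must contain at least one point")
        if not (self.cell_area_km2 > 0):
            raise ValueError("cell_area_km2 must be positive")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    @property
    def area_km2(self) -> float:
        """Total mask area (points x cell area)."""
        return len(self) * self.cell_area_km2

    def translated(self, dx: float, dy: float) -> "HabitatMask":
        return HabitatMask(self.x + dx, self.y + dy, self.cell_area_km2,
                           self.buffer_m, self.spacing_m)


def make_mask(detectors: DetectorArray, buffer_m: float = 15_000.0,
              spacing_m: float | None = None,
              sigma_hint_m: float | None = None) -> HabitatMask:
    """Build a rectangular-grid habitat mask around a detector array.

    The grid covers the detector bounding box extended by ``buffer_m`` on
    all sides.  Spacing defaults to half a spatial-scale hint (if given),
    capped at 1,500 m — the detector cell size used in the field design.
    """
    if spacing_m is None:
        spacing_m = 1500.0 if sigma_hint_m is None else min(sigma_hint_m / 2.0, 1500.0)
    if spacing_m <= 0:
        raise ValueError("spacing_m must be positive")
    x0, x1 = detectors.x.min() - buffer_m, detectors.x.max() + buffer_m
    y0, y1 = detectors.y.min() - buffer_m, detectors.y.max() + buffer_m
    # cell centres of a grid that fully covers the buffered box
    nx = max(int(np.ceil((x1 - x0) / spacing_m)), 1)
    ny = max(int(np.ceil((y1 - y0) / spacing_m)), 1)
    gx = x0 + (np.arange(nx) + 0.5) * spacing_m
    gy = y0 + (np.arange(ny) + 0.5) * spacing_m
    mx, my = np.meshgrid(gx, gy)
    cell_area_km2 = (spacing_m / 1000.0) ** 2
    return HabitatMask(mx.ravel(), my.ravel(), cell_area_km2, buffer_m, spacing_m)
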