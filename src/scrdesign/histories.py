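"""Capture histories: who was detected where and when.

Detections are stored tidily as unique (individual, occasion, detector)
triples, the natural unit for proximity detectors where an animal either
was or was not recorded at a detector on an occasion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detectors import DetectorArray

VALID_SEX = ("F", "M", "U")


@dataclass
class CaptureHistories:
    """Binary individual x occasion x detector detection records.

    Parameters
    ----------
    detections
        DataFrame with columns ``individual_id``, ``occasion`` (1-based),
        ``detector_id``; rows are unique triples.
    sex
        Series mapping individual_id -> 'F', 'M' or 'U' (unknown).
    n_occasions
        Number of sampling occasions in the session.
    """

    detections: pd.DataFrame
    sex: pd.Series
    n_occasions: int
    session_id: str = "session1"

    def __post_init__(self) -> None:
        req = ["individual_id", "occasion", "detector_id"]
        missing = [c for c in req if c not in self.detections.columns]
        if missing:
            raise ValueError(f"detections missing columns: {missing}")
        det = self.detections[req].reset_index(drop=True)
        if det.duplicated().any():
            dup = det[det.duplicated()].iloc[0]
            raise ValueError(
                "duplicate detection row "
                f"(individual={dup.individual_id!r}, occasion={dup.occasion}, "
                f"detector={dup.detector_id!r})"
            )
        if len(det) == 0:
            raise ValueError("no individuals: capture history is empty")
        occ = det["occasion"].to_numpy()
        if occ.min() < 1 or occ.max() > self.n_occasions:
            raise ValueError(f"occasions must lie in 1..{self.n_occasions}")
        self.detections = det
        ids = pd.Index(det["individual_id"].unique())
        self.sex = self.sex.reindex(ids).fillna("U").astype(str)
        bad = ~self.sex.isin(VALID_SEX)
        if bad.any():
            raise ValueError(f"invalid sex labels: {sorted(self.sex[bad].unique())}")

    # ------------------------------------------------------------------
    @property
    def individuals(self) -> pd.Index:
        return self.sex.index

    @property
    def n_individuals(self) -> int:
        return len(self.sex)

    @property
    def n_detections(self) -> int:
        return len(self.detections)

    def validate_against(self, detectors: DetectorArray) -> None:
        """Every referenced detector must exist in the array."""
        known = set(detectors.detector_id.tolist())
        unknown = set(self.detections["detector_id"]) - known
        if unknown:
            raise ValueError(f"detections reference unknown detector_ids: {sorted(map(str, unknown))[:5]}")

    def to_array(self, detectors: DetectorArray) -> np.ndarray:
        """Dense 0/1 array omega with shape (n_individuals, S, n_detectors)."""
        self.validate_against(detectors)
        n, S, K = self.n_individuals, self.n_occasions, len(detectors)
        omega = np.zeros((n, S, K), dtype=np.uint8)
        irow = {ind: i for i, ind in enumerate(self.individuals)}
        kcol = {d: k for k, d in enumerate(detectors.detector_id)}
        for ind, occ, det in self.detections.itertuples(index=False):
            omega[irow[ind], occ - 1, kcol[det]] = 1
        return omega

    def filter_sex(self, group: str) -> "CaptureHistories":
        """Subset by sex group: 'both' keeps everyone (incl. unknowns)."""
        if group == "both":
            return self
        if group not in ("F", "M"):
            raise ValueError("sex group must be 'both', 'F' or 'M'")
        keep = self.sex.index[self.sex == group]
        det = self.detections[self.detections["individual_id"].isin(keep)]
        if len(det) == 0:
            raise ValueError(f"no individuals of sex {group!r}")
        return CaptureHistories(det.reset_index(drop=True), self.sex.loc[keep],
                                self.n_occasions, self.session_id)

    def drop_detectors(self, detector_ids) -> "CaptureHistories":
        """Remove detections at the given detectors; drop emptied individuals."""
        drop = set(np.asarray(detector_ids).tolist())
        det = self.detections[~self.detections["detector_id"].isin(drop)]
        if len(det) == 0:
            raise ValueError("no detections remain after dropping detectors")
        kept = det["individual_id"].unique()
        return CaptureHistories(det.reset_index(drop=True),
                                self.sex.loc[pd.Index(kept)],
                                self.n_occasions, self.session_id)


def from_records(records, n_occasions: int, sex: dict | pd.Series | None = None,
                 session_id: str = "session1") -> CaptureHistories:
    """Build histories from an iterable of (individual_id, occasion, detector_id)."""
    det = pd.DataFrame(records, columns=["individual_id", "occasion", "detector_id"])
    if sex is None:
        sex = pd.Series("U", index=pd.Index(det["individual_id"].unique()))
    elif isinstance(sex, dict):
        sex = pd.Series(sex)
    return CaptureHistories(det, sex, n_occasions, session_id)
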