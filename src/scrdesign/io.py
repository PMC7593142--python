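"""Readers and writers for the plain-text exchange formats.

Detector layouts and capture histories travel as TSV, in the spirit of
the standard SCR "traps" and "captures" files:

  detectors.tsv : detector_id  x  y  transect_id  [u1 .. uS]
  captures.tsv  : session  individual_id  occasion  detector_id  sex

Validation reports offending line numbers so field data problems can be
fixed at the source.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .detectors import DetectorArray
from .fitting import FitResult
from .histories import VALID_SEX, CaptureHistories

__all__ = ["read_detectors", "write_detectors", "read_captures",
           "write_captures", "fit_result_to_json", "fit_result_to_csv"]


class ValidationError(ValueError):
    """Raised with row-level context when an input file is malformed."""


def read_detectors(path) -> DetectorArray:
    """Read a detector layout TSV (header: detector_id, x, y, transect_id,
    optional per-occasion usage columns u1..uS)."""
    df = pd.read_csv(path, sep="\t", dtype={"detector_id": str, "transect_id": str})
    req = ["detector_id", "x", "y", "transect_id"]
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    for col in ("x", "y"):
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]  # +2: header + 1-based
            raise ValidationError(f"{path}: malformed {col} at lines {lines}")
    dup = df.index[df["detector_id"].duplicated()]
    if len(dup):
        raise ValidationError(
            f"{path}: duplicate detector_id at lines {[int(i) + 2 for i in dup[:5]]}")
    ucols = sorted([c for c in df.columns if c.startswith("u") and c[1:].isdigit()],
                   key=lambda c: int(c[1:]))
    usage = df[ucols].to_numpy(dtype=float) if ucols else None
    return DetectorArray(df["detector_id"].to_numpy(), df["x"].to_numpy(float),
                         df["y"].to_numpy(float), df["transect_id"].to_numpy(),
                         usage=usage)


def write_detectors(detectors: DetectorArray, path) -> None:
    df = pd.DataFrame({
        "detector_id": detectors.detector_id, "x": detectors.x,
        "y": detectors.y, "transect_id": detectors.transect_id,
    })
    if detectors.usage is not None:
        for s in range(detectors.usage.shape[1]):
            df[f"u{s+1}"] = detectors.usage[:, s].astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_captures(path, detectors: DetectorArray | None = None,
                  n_occasions: int | None = None) -> CaptureHistories:
    """Read a capture-history TSV (header: session, individual_id, occasion,
    detector_id, sex).  If ``detectors`` is given, every referenced
    detector must exist in it."""
    df = pd.read_csv(path, sep="\t",
                     dtype={"session": str, "individual_id": str,
                            "detector_id": str, "sex": str})
    req = ["session", "individual_id", "occasion", "detector_id", "sex"]
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValidationError(f"{path}: no individuals (empty capture file)")
    occ = pd.to_numeric(df["occasion"], errors="coerce")
    bad = df.index[~np.isfinite(occ) | (occ < 1) | (occ != occ.round())]
    if len(bad):
        raise ValidationError(
            f"{path}: malformed occasion at lines {[int(i) + 2 for i in bad[:5]]}")
    df["occasion"] = occ.astype(int)
    dup = df.index[df[["individual_id", "occasion", "detector_id"]].duplicated()]
    if len(dup):
        raise ValidationError(
            f"{path}: duplicate (individual, occasion, detector) rows at lines "
            f"{[int(i) + 2 for i in dup[:5]]}")
    if detectors is not None:
        known = set(detectors.detector_id.tolist())
        bad = df.index[~df["detector_id"].isin(known)]
        if len(bad):
            ids = sorted(df.loc[bad, "detector_id"].unique()[:5])
            raise ValidationError(
                f"{path}: unknown detector_id(s) {ids} at lines "
                f"{[int(i) + 2 for i in bad[:5]]}")
    sessions = df["session"].unique()
    if len(sessions) != 1:
        raise ValidationError(f"{path}: expected a single session, found {len(sessions)}")
    df["sex"] = df["sex"].fillna("U").str.upper().str[0]
    df.loc[~df["sex"].isin(VALID_SEX), "sex"] = "U"
    sex = df.groupby("individual_id")["sex"].agg(
        lambda s: next((v for v in s if v != "U"), "U"))
    S = n_occasions if n_occasions is not None else int(df["occasion"].max())
    hist = CaptureHistories(df[["individual_id", "occasion", "detector_id"]],
                            sex, S, session_id=str(sessions[0]))
    if detectors is not None:
        hist.validate_against(detectors)
    return hist


def write_captures(histories: CaptureHistories, path) -> None:
    df = histories.detections.copy()
    df.insert(0, "session", histories.session_id)
    df["sex"] = histories.sex.loc[df["individual_id"]].to_numpy()
    df.to_csv(path, sep="\t", index=False)


# -------------------------------------------------------- fit serialization
def fit_result_to_json(result: FitResult, path=None) -> str:
    """FitResult as JSON with parameters on both link and natural scales."""
    d = {
        "converged": result.converged, "status": result.status,
        "label": result.label, "n": result.n, "n_detections": result.n_detections,
        "K": result.K, "loglik": result.loglik, "AICc": result.AICc,
        "esa_km2": result.esa_km2,
        "D_hat_per_1000km2": result.D_hat, "SE_D": result.SE_D,
        "CV_D": result.CV_D, "CI_D": result.CI_D,
        "N_hat": result.N_hat, "CI_N": result.CI_N,
        "theta_link": None if result.theta is None else list(result.theta),
        "g0": None if result.model is None else list(np.atleast_1d(result.model.g0)),
        "sigma_m": None if result.model is None else list(np.atleast_1d(result.model.sigma)),
        "vcov": None if result.vcov is None else result.vcov.tolist(),
    }
    text = json.dumps(d, indent=2, default=float)
    if path is not None:
        Path(path).write_text(text)
    return text


def fit_result_to_csv(result: FitResult, path) -> None:
    """One-row CSV in the conventional density-table layout."""
    pd.DataFrame([result.summary_row()]).to_csv(path, index=False)
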