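"""Capture-history summaries and genotyping tally arithmetic.

Noninvasive genetic surveys report, per population, the number of fecal
samples collected, the number successfully genotyped, the unique
individuals identified, and the spatial recaptures those individuals
provide.  These counts drive both data-quality reporting (genotyping
success) and the information content available to the SCR fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .histories import CaptureHistories

__all__ = ["GenotypingTally", "genotyping_success", "aggregate_tallies",
           "summarize_captures"]


@dataclass
class GenotypingTally:
    """Per-population genotyping bookkeeping."""

    population: str
    samples_collected: int
    samples_scored: int
    unique_genotypes: int
    spatial_recaptures: int

    def __post_init__(self) -> None:
        if self.samples_scored > self.samples_collected:
            raise ValueError("scored cannot exceed collected")
        if self.unique_genotypes > self.samples_scored:
            raise ValueError("unique genotypes cannot exceed scored samples")

    @property
    def success_pct(self) -> float:
        return genotyping_success(self)


def genotyping_success(tally: GenotypingTally) -> float:
    """Percent of collected samples successfully scored, to 1 decimal."""
    if tally.samples_collected <= 0:
        raise ValueError("samples_collected must be positive")
    return round(100.0 * tally.samples_scored / tally.samples_collected, 1)


def aggregate_tallies(tallies: list[GenotypingTally]) -> dict:
    """Column-wise totals plus the mean per-population genotyping success.

    The headline success rate is the unweighted mean of the per-population
    percentages (populations are the reporting unit), not the pooled
    scored/collected ratio.
    """
    if not tallies:
        raise ValueError("no tallies to aggregate")
    return {
        "samples_collected": sum(t.samples_collected for t in tallies),
        "samples_scored": sum(t.samples_scored for t in tallies),
        "unique_genotypes": sum(t.unique_genotypes for t in tallies),
        "spatial_recaptures": sum(t.spatial_recaptures for t in tallies),
        "mean_success_pct": round(
            float(np.mean([genotyping_success(t) for t in tallies])), 1),
    }


def summarize_captures(histories: CaptureHistories,
                       spatial_definition: str = "extra-detector") -> dict:
    """Capture, recapture and spatial-recapture counts, with a per-sex split.

    Definitions:
      n_detections          distinct (individual, occasion, detector) triples
      n_recaptures          n_detections - n_individuals
      n_spatial_recaptures  'extra-detector' (default): per individual, the
                            number of distinct detectors beyond the first;
                            'non-first-site': detections at any detector
                            other than the individual's first-capture site.
    """
    if spatial_definition not in ("extra-detector", "non-first-site"):
        raise ValueError("unknown spatial recapture definition")
    det = histories.detections
    n_ind = histories.n_individuals
    n_det = len(det)

    def _spatial(sub: pd.DataFrame) -> int:
        if spatial_definition == "extra-detector":
            return int((sub.groupby("individual_id")["detector_id"].nunique() - 1)
                       .clip(lower=0).sum())
        total = 0
        for _, g in sub.groupby("individual_id"):
            g = g.sort_values(["occasion", "detector_id"], kind="mergesort")
            first = g["detector_id"].iloc[0]
            total += int((g["detector_id"] != first).sum())
        return total

    out = {
        "n_individuals": n_ind,
        "n_detections": n_det,
        "n_recaptures": n_det - n_ind,
        "n_spatial_recaptures": _spatial(det),
        "by_sex": {},
    }
    for sx in sorted(histories.sex.unique()):
        ids = histories.sex.index[histories.sex == sx]
        sub = det[det["individual_id"].isin(ids)]
        out["by_sex"][sx] = {
            "n_individuals": int(len(ids)),
            "n_detections": int(len(sub)),
            "n_recaptures": int(len(sub) - len(ids)),
            "n_spatial_recaptures": _spatial(sub),
        }
    return out
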