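"""Diameter statistics, per-sample QC and batch consolidation.

Retained particle areas become equivalent circular diameters
(d = 2·√(A/π)); a sample is summarized by its mean and sample SD and
assigned a QC status from the retained cell count: at least 200 cells is
``ok``, 100–199 flags the slide for visual inspection (``inspect``,
results kept), and fewer than 100 cells is ``excluded`` — the slide's
summary statistics are withheld.  A manual re-threshold hook re-runs the
pipeline at a user-chosen level for slides where the automatic threshold
failed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import CalibratedImage
from .particles import Particle, ParticleFilter, analyze_particles
from .segmentation import SegmentationParams, segment

__all__ = [
    "QC_OK",
    "QC_INSPECT",
    "QC_EXCLUDED",
    "SampleMeasurement",
    "area_to_diameter",
    "qc_gate",
    "summarize_sample",
    "process_sample",
    "rethreshold_sample",
    "consolidate",
]

QC_OK = "ok"
QC_INSPECT = "inspect"
QC_EXCLUDED = "excluded"

#: Retained-count bounds of the QC rule: >= 200 cells passes outright,
#: 100-199 is kept but flagged for visual inspection, < 100 is omitted.
QC_OK_MIN = 200
QC_INSPECT_MIN = 100


@dataclass(frozen=True)
class SampleMeasurement:
    """Per-slide sizing result."""

    sample_id: str
    depot: str  # omental | subcutaneous | unspecified
    diameters: tuple[float, ...]  # µm, one per retained cell
    qc_status: str
    threshold_used: int
    rethresholded: bool = False

    @property
    def n_cells(self) -> int:
        return len(self.diameters)

    @property
    def mean_diameter(self) -> float:
        """Mean retained diameter in µm (NaN when no cells were retained)."""
        return float(np.mean(self.diameters)) if self.diameters else math.nan

    @property
    def sd_diameter(self) -> float:
        """Sample SD (n−1 denominator) of retained diameters in µm."""
        if len(self.diameters) < 2:
            return math.nan
        return float(np.std(self.diameters, ddof=1))


def area_to_diameter(area: float | np.ndarray) -> float | np.ndarray:
    """Equivalent circular diameter d = 2·√(A/π), µm from µm²."""
    arr = np.asarray(area, dtype=np.float64)
    if np.any(arr <= 0):
        raise ValueError("area must be strictly positive")
    d = 2.0 * np.sqrt(arr / np.pi)
    return float(d) if np.isscalar(area) or arr.ndim == 0 else d


def qc_gate(n_detected: int) -> str:
    """QC status from the retained cell count (monotone in n)."""
    if n_detected < 0:
        raise ValueError("n_detected must be >= 0")
    if n_detected >= QC_OK_MIN:
        return QC_OK
    if n_detected >= QC_INSPECT_MIN:
        return QC_INSPECT
    return QC_EXCLUDED


def summarize_sample(
    sample_id: str,
    depot: str,
    retained_particles: list[Particle],
    threshold_used: int = 0,
    rethresholded: bool = False,
) -> SampleMeasurement:
    """Convert retained areas to diameters and attach the QC verdict."""
    diameters = tuple(float(area_to_diameter(p.area)) for p in retained_particles)
    return SampleMeasurement(
        sample_id=sample_id,
        depot=depot,
        diameters=diameters,
        qc_status=qc_gate(len(diameters)),
        threshold_used=threshold_used,
        rethresholded=rethresholded,
    )


def process_sample(
    image: CalibratedImage,
    sample_id: str,
    depot: str = "unspecified",
    params: SegmentationParams | None = None,
    particle_filter: ParticleFilter | None = None,
    include_holes: bool = False,
) -> tuple[SampleMeasurement, list[Particle], list[Particle]]:
    """Full pipeline on one slide: segment, analyze particles, summarize.

    Returns the sample measurement plus the complete and retained
    particle lists (for the per-slide particle table).
    """
    params = params or SegmentationParams()
    mask = segment(image, params)
    particles, retained = analyze_particles(
        mask, particle_filter=particle_filter, include_holes=include_holes
    )
    meas = summarize_sample(
        sample_id,
        depot,
        retained,
        threshold_used=mask.threshold_used,
        rethresholded=params.manual_threshold_override is not None,
    )
    return meas, particles, retained


def rethreshold_sample(
    image: CalibratedImage,
    manual_level: int,
    sample_id: str,
    depot: str = "unspecified",
    params: SegmentationParams | None = None,
    particle_filter: ParticleFilter | None = None,
) -> tuple[SampleMeasurement, list[Particle], list[Particle]]:
    """Re-run one slide with a manually chosen threshold level.

    Used after visual inspection of a low-count slide; the result is
    marked ``rethresholded``.
    """
    if not 0 <= manual_level <= 255:
        raise ValueError(f"manual_level must be in [0, 255], got {manual_level}")
    base = params or SegmentationParams()
    forced = SegmentationParams(
        erode_iterations_per_pass=base.erode_iterations_per_pass,
        outlier_pass_radii=base.outlier_pass_radii,
        outlier_threshold=base.outlier_threshold,
        outlier_which=base.outlier_which,
        background=base.background,
        manual_threshold_override=int(manual_level),
    )
    return process_sample(
        image, sample_id, depot, params=forced, particle_filter=particle_filter
    )


_SUMMARY_COLUMNS = [
    "sample_id",
    "depot",
    "n_cells",
    "mean_diameter_um",
    "sd_diameter_um",
    "qc_status",
    "threshold_used",
    "rethresholded",
]


def consolidate(
    measurements: list[SampleMeasurement],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge per-slide results into one tidy summary plus a long table.

    The summary has one row per sample; excluded samples keep their row
    (qc_status = ``excluded``) but their mean/SD fields are blank.  The
    companion long-format table carries every retained diameter of the
    non-excluded samples.  Duplicate sample ids are an error.
    """
    ids = [m.sample_id for m in measurements]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"duplicate sample_id values: {dupes}")
    rows = []
    long_rows: list[tuple[str, str, float]] = []
    for m in measurements:
        excluded = m.qc_status == QC_EXCLUDED
        rows.append(
            {
                "sample_id": m.sample_id,
                "depot": m.depot,
                "n_cells": m.n_cells,
                "mean_diameter_um": math.nan if excluded else m.mean_diameter,
                "sd_diameter_um": math.nan if excluded else m.sd_diameter,
                "qc_status": m.qc_status,
                "threshold_used": m.threshold_used,
                "rethresholded": m.rethresholded,
            }
        )
        if not excluded:
            long_rows.extend((m.sample_id, m.depot, d) for d in m.diameters)
    summary = pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)
    long = pd.DataFrame(long_rows, columns=["sample_id", "depot", "diameter_um"])
    return summary, long
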