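"""Corneal densitometry and adaptive-threshold brightness-artefact metrics.

Corneal densitometry (CD) is operationalised as the mean pixel intensity
(MPI) of the segmented cornea in a grayscale Scheimpflug frame.  Reflections
off the iris and the corneoscleral periphery produce spurious bright pixels
that inflate apparent backscatter; they are quantified per frame with an
adaptive threshold

    T = MPI_cornea + 3 * SD_cornea

and reported as the percentage of pixels in each artefact-prone region
(iris band, lateral flanks, and their union) that exceed T.  Per-eye values
are unweighted means over the frame set (nominally 25 meridians).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateRegion, EmptyInput
from .segmentation import RegionMasks, ScheimpflugFrame

__all__ = [
    "FrameDensitometry",
    "EyeDensitometry",
    "region_intensity_stats",
    "artefact_threshold",
    "artefact_percentage",
    "analyze_frame",
    "aggregate_eye",
]


@dataclass(frozen=True)
class FrameDensitometry:
    """Densitometry readings for a single frame (all intensities in a.u.)."""

    eye_id: str
    meridian_index: int
    mpi_cornea: float
    sd_cornea: float
    threshold: float
    pct_iris: float
    pct_lateral: float
    pct_overall: float


@dataclass(frozen=True)
class EyeDensitometry:
    """Per-eye aggregates: CD and artefact percentages averaged over frames."""

    eye_id: str
    n_frames: int
    cd: float
    pct_iris: float
    pct_lateral: float
    pct_overall: float


def region_intensity_stats(
    frame: ScheimpflugFrame, mask: np.ndarray
) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1) of intensities under a mask.

    The SD is 0 for a single-pixel or constant region.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frame.pixels.shape:
        raise DegenerateRegion("mask shape does not match frame")
    values = frame.pixels[mask].astype(float)
    if values.size == 0:
        raise DegenerateRegion("empty mask")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return mean, sd


def artefact_threshold(mpi: float, sd: float) -> float:
    """Adaptive artefact threshold: corneal MPI plus three times its SD.

    Not clamped to 255 — a threshold above the intensity range legitimately
    yields 0% artefacts.
    """
    if mpi < 0 or sd < 0:
        raise ValueError("mpi and sd must be non-negative")
    return mpi + 3.0 * sd

def artefact_percentage(
    frame: ScheimpflugFrame, mask: np.ndarray, threshold: float
) -> float:
    """Percentage of mask pixels with intensity strictly above ``threshold``."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise DegenerateRegion("empty mask")
    above = int((frame.pixels[mask].astype(float) > threshold).sum())
    return 100.0 * above / n


def analyze_frame(frame: ScheimpflugFrame, masks: RegionMasks) -> FrameDensitometry:
    """Full single-frame analysis: corneal stats, threshold, artefact rates.

    ``pct_overall`` is computed over the pixel-wise union of the iris and
    lateral masks (pixel-weighted), not as the mean of the two percentages.
    """
    mpi, sd = region_intensity_stats(frame, masks.cornea)
    thr = artefact_threshold(mpi, sd)
    pct_iris = artefact_percentage(frame, masks.iris, thr)
    pct_lateral = artefact_percentage(frame, masks.lateral, thr)
    pct_overall = artefact_percentage(frame, masks.iris | masks.lateral, thr)
    return FrameDensitometry(
        eye_id=frame.eye_id,
        meridian_index=frame.meridian_index,
        mpi_cornea=mpi,
        sd_cornea=sd,
        threshold=thr,
        pct_iris=pct_iris,
        pct_lateral=pct_lateral,
        pct_overall=pct_overall,
    )


def aggregate_eye(
    results: Sequence[FrameDensitometry] | Iterable[FrameDensitometry],
    eye_id: str | None = None,
) -> EyeDensitometry:
    """Average per-frame results into one per-eye record.

    Unweighted arithmetic means across however many frames are available
    (nominally 25); ``n_frames`` records the count actually used.
    """
    results = list(results)
    if not results:
        raise EmptyInput("no frame results to aggregate")
    if eye_id is None:
        eye_id = results[0].eye_id
    return EyeDensitometry(
        eye_id=eye_id,
        n_frames=len(results),
        cd=float(np.mean([r.mpi_cornea for r in results])),
        pct_iris=float(np.mean([r.pct_iris for r in results])),
        pct_lateral=float(np.mean([r.pct_lateral for r in results])),
        pct_overall=float(np.mean([r.pct_overall for r in results])),
    )
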