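"""Region-of-interest delineation in Scheimpflug-style anterior-segment frames.

A raw Scheimpflug optical section shows a bright corneal arc in the upper
part of the frame, the iris below it, and two lateral corneoscleral flanks.
Densitometry needs three pixel sets: the cornea (for the mean-pixel-intensity
reading), the iris band and the lateral flanks (where reflection artefacts
are counted).  This module builds those masks automatically with a classic
median-filter + Canny pipeline, or validates masks supplied by any external
segmentation tool — all downstream math accepts either provenance.

Coordinate convention: row-major arrays, origin at the top-left, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import feature, filters

from .errors import DegenerateRegion, MaskMismatch, MaskOverlap, NoEdgesFound

__all__ = [
    "ScheimpflugFrame",
    "RegionMasks",
    "SegmentationParams",
    "segment_frame",
    "validate_masks",
    "masks_to_label_image",
    "label_image_to_masks",
]


@dataclass(frozen=True)
class ScheimpflugFrame:
    """One grayscale anterior-segment frame.

    Parameters
    ----------
    pixels : ndarray
        2-D 8-bit intensity grid, values in [0, 255] (arbitrary units).
    eye_id : str
        Opaque eye identifier.
    meridian_index : int
        Acquisition meridian, 1-25 (a Pentacam-style scan takes 25 frames).
    """

    pixels: np.ndarray
    eye_id: str = "eye"
    meridian_index: int = 1

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("frame pixels must be a 2-D array")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise ValueError("frame must be at least 64x64 pixels")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        if not 1 <= int(self.meridian_index) <= 25:
            raise ValueError("meridian_index must be in [1, 25]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class RegionMasks:
    """Cornea / iris / lateral binary masks for one frame.

    The three masks are pairwise disjoint and share the frame's shape.
    ``lateral`` is the union of the left and right corneoscleral flanks.
    ``provenance`` records whether the masks came from :func:`segment_frame`
    (``"automatic"``) or from an external file (``"external"``).
    """

    cornea: np.ndarray
    iris: np.ndarray
    lateral: np.ndarray
    provenance: str = "automatic"

    def __post_init__(self) -> None:
        for name in ("cornea", "iris", "lateral"):
            m = np.asarray(getattr(self, name), dtype=bool)
            object.__setattr__(self, name, m)
        if not (self.cornea.shape == self.iris.shape == self.lateral.shape):
            raise MaskMismatch("region masks differ in shape")
        overlap = (
            (self.cornea & self.iris)
            | (self.cornea & self.lateral)
            | (self.iris & self.lateral)
        )
        if overlap.any():
            raise MaskOverlap("region masks must be pairwise disjoint")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cornea.shape


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the automatic pipeline.

    median_kernel : odd edge length of the median pre-filter (pixels).
    canny_sigma : Gaussian smoothing inside the Canny detector (pixels).
    max_tilt_deg : contours whose principal axis deviates from horizontal
        by more than this are rejected as corneal-boundary candidates.
    upper_fraction : only edges in this top fraction of the frame compete
        as corneal boundaries.
    iris_depth_factor : iris-band height as a fraction of the local corneal
        thickness, measured downward from the posterior boundary.
    central_fraction : width fraction (centred) assigned to the iris band;
        the flanks take the same depth range outside it.
    """

    median_kernel: int = 5
    canny_sigma: float = 1.4
    max_tilt_deg: float = 30.0
    upper_fraction: float = 0.75
    iris_depth_factor: float = 0.5
    central_fraction: float = 1.0 / 3.0


def _contour_orientation_deg(rows: np.ndarray, cols: np.ndarray) -> float:
    """Angle (degrees, in [0, 90]) between a pixel cloud's principal axis
    and the horizontal, from the eigenvectors of the coordinate covariance."""
    pts = np.stack([cols.astype(float), rows.astype(float)])
    if pts.shape[1] < 2:
        return 90.0
    cov = np.cov(pts)
    evals, evecs = np.linalg.eigh(cov)
    vx, vy = evecs[:, np.argmax(evals)]
    if vx == 0 and vy == 0:
        return 90.0
    return float(np.degrees(np.arctan2(abs(vy), abs(vx))))


def _boundary_profile(rows: np.ndarray, cols: np.ndarray, width: int) -> np.ndarray:
    """Per-column boundary row (float), linearly interpolated across gaps."""
    order = np.argsort(cols)
    cols_s, rows_s = cols[order], rows[order]
    # average duplicate columns (a contour can be >1 px thick locally)
    uniq, inverse = np.unique(cols_s, return_inverse=True)
    sums = np.bincount(inverse, weights=rows_s.astype(float))
    counts = np.bincount(inverse)
    profile = np.interp(np.arange(width), uniq, sums / counts)
    return profile


def segment_frame(
    frame: ScheimpflugFrame, params: SegmentationParams | None = None
) -> RegionMasks:
    """Delineate cornea, iris band and lateral flanks in one frame.

    The frame is median-filtered, edges are found with a Canny detector
    whose hysteresis thresholds derive from the frame's Otsu level
    (high = Otsu, low = Otsu/2, applied to the gradient-magnitude scale
    after normalising intensities to [0, 1]).  The two longest near-
    horizontal edge contours in the upper part of the frame are taken as
    the anterior and posterior corneal boundaries; the cornea is the fill
    between them.  The iris band sits directly below the posterior
    boundary, ``iris_depth_factor`` of the local corneal thickness deep,
    in the central third of the width; the lateral flanks occupy the same
    depth range in the outer thirds.

    Raises
    ------
    NoEdgesFound
        Fewer than two candidate corneal contours (e.g. a blank frame).
    DegenerateRegion
        A constructed region is empty (e.g. the band falls off-frame).
    """
    if params is None:
        params = SegmentationParams()

    img = frame.pixels.astype(float)
    img = ndimage.median_filter(img, size=params.median_kernel)
    scaled = img / 255.0

    otsu = float(filters.threshold_otsu(scaled)) if scaled.max() > scaled.min() else 0.0
    if otsu <= 0:
        raise NoEdgesFound("frame has no intensity structure")
    edges = feature.canny(
        scaled,
        sigma=params.canny_sigma,
        low_threshold=0.5 * otsu,
        high_threshold=otsu,
    )

    h, w = frame.pixels.shape
    upper = np.zeros_like(edges)
    upper[: int(round(params.upper_fraction * h)), :] = True
    labels, n_lab = ndimage.label(edges & upper, structure=np.ones((3, 3), int))

    candidates: list[tuple[int, float, np.ndarray, np.ndarray]] = []
    for lab in range(1, n_lab + 1):
        rows, cols = np.nonzero(labels == lab)
        span = cols.max() - cols.min() + 1
        if span < w // 4:
            continue
        if _contour_orientation_deg(rows, cols) > params.max_tilt_deg:
            continue
        candidates.append((span, float(rows.mean()), rows, cols))
    if len(candidates) < 2:
        raise NoEdgesFound(
            f"found {len(candidates)} corneal boundary candidates, need 2"
        )

    # The anterior and posterior corneal boundaries are the two *topmost*
    # of the long near-horizontal contours: the lower edge of the iris
    # band can be just as long, but always lies deeper.
    max_span = max(c[0] for c in candidates)
    long_ones = [c for c in candidates if c[0] >= 0.6 * max_span]
    if len(long_ones) < 2:
        long_ones = sorted(candidates, key=lambda c: c[0], reverse=True)[:2]
    long_ones.sort(key=lambda c: c[1])
    (rows_a, cols_a), (rows_b, cols_b) = (
        (long_ones[0][2], long_ones[0][3]),
        (long_ones[1][2], long_ones[1][3]),
    )
    prof_a = _boundary_profile(rows_a, cols_a, w)
    prof_b = _boundary_profile(rows_b, cols_b, w)
    anterior = np.minimum(prof_a, prof_b)
    posterior = np.maximum(prof_a, prof_b)

    cols_grid = np.arange(w)
    rows_grid = np.arange(h)[:, None]

    cornea = (rows_grid >= np.ceil(anterior)) & (rows_grid <= np.floor(posterior))

    thickness = posterior - anterior
    band_top = posterior + 1.0
    band_bottom = posterior + np.maximum(params.iris_depth_factor * thickness, 1.0)
    band = (rows_grid >= np.ceil(band_top)) & (rows_grid <= np.floor(band_bottom))

    half_c = params.central_fraction / 2.0
    central = (cols_grid >= int(round(w * (0.5 - half_c)))) & (
        cols_grid < int(round(w * (0.5 + half_c)))
    )
    iris = band & central
    lateral = band & ~central

    masks = RegionMasks(cornea=cornea, iris=iris, lateral=lateral,
                        provenance="automatic")
    for name in ("cornea", "iris", "lateral"):
        if not getattr(masks, name).any():
            raise DegenerateRegion(f"{name} region is empty after construction")
    return masks


def validate_masks(frame: ScheimpflugFrame, masks: RegionMasks) -> RegionMasks:
    """Check externally supplied masks against a frame and re-tag them.

    Verifies dimension match, pairwise disjointness (enforced by the
    :class:`RegionMasks` constructor) and non-emptiness of every region,
    then returns the masks with ``provenance="external"``.
    """
    if masks.shape != frame.pixels.shape:
        raise MaskMismatch(
            f"mask shape {masks.shape} != frame shape {frame.pixels.shape}"
        )
    for name in ("cornea", "iris", "lateral"):
        if not getattr(masks, name).any():
            raise DegenerateRegion(f"{name} mask is empty")
    return replace(masks, provenance="external")


# Label codes used in 8-bit mask PNGs.
LABEL_BACKGROUND, LABEL_CORNEA, LABEL_IRIS, LABEL_LATERAL = 0, 1, 2, 3


def masks_to_label_image(masks: RegionMasks) -> np.ndarray:
    """Encode masks as one uint8 label image (0=bg, 1=cornea, 2=iris, 3=lateral)."""
    label = np.zeros(masks.shape, dtype=np.uint8)
    label[masks.cornea] = LABEL_CORNEA
    label[masks.iris] = LABEL_IRIS
    label[masks.lateral] = LABEL_LATERAL
    return label


def label_image_to_masks(label: np.ndarray, provenance: str = "external") -> RegionMasks:
    """Decode a uint8 label image back into :class:`RegionMasks`."""
    label = np.asarray(label)
    if label.ndim != 2:
        raise MaskMismatch("label image must be 2-D")
    return RegionMasks(
        cornea=label == LABEL_CORNEA,
        iris=label == LABEL_IRIS,
        lateral=label == LABEL_LATERAL,
        provenance=provenance,
    )
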