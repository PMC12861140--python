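"""Objective iris-pigmentation scoring from color slit-lamp photographs.

Iris color is summarised as a single cohort-relative scalar.  Each RGB
photograph is converted to CIELAB (sRGB transfer function, D65 white), the
iris region of interest is reduced to per-eye L*, a*, b* summaries, each
component is robustly normalised across the cohort,

    X_n = (X - median(X)) / IQR(X),        X in {L*, a*, b*},

and, because lightness runs opposite to the chromatic channels along the
blue-to-brown pigmentation axis, the normalised L* enters with a flipped
sign in the composite index

    IrisColor = -L_n + a_n + b_n.

Negative values indicate light irises, positive values dark irises, and
values near zero mixed or intermediate pigmentation.  The index is cohort
relative by construction: editing the cohort changes every normalised
value, so it must be recomputed, never cached across cohort edits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import draw

from .errors import CohortTooSmall, DegenerateRegion, NotColorImage, ZeroIQR

__all__ = [
    "IrisLabSummary",
    "CohortNormalization",
    "IrisColorRecord",
    "rgb_to_cielab",
    "summarize_iris_roi",
    "fit_cohort_normalization",
    "normalize_component",
    "iris_color_index",
    "classify_pigmentation",
    "score_cohort",
    "polygon_roi_mask",
]


@dataclass(frozen=True)
class IrisLabSummary:
    """Per-eye CIELAB summary over the iris ROI (L in [0, 100])."""

    eye_id: str
    L: float
    a: float
    b: float


@dataclass(frozen=True)
class CohortNormalization:
    """Cohort medians and interquartile ranges for each Lab component."""

    median_L: float
    median_a: float
    median_b: float
    iqr_L: float
    iqr_a: float
    iqr_b: float
    n_eyes: int


@dataclass(frozen=True)
class IrisColorRecord:
    """Normalised components, composite index and sign-rule class for one eye."""

    eye_id: str
    Ln: float
    an: float
    bn: float
    iris_color: float
    pigment_class: str


# sRGB -> XYZ linear transform (IEC 61966-2-1, D65 primaries).  The
# reference white is taken as this matrix's own image of (1, 1, 1): that
# keeps the conversion exactly self-consistent, so the sRGB white maps to
# precisely (100, 0, 0) and grays to the achromatic axis, instead of
# inheriting the ~0.005-unit chroma offset that a separately rounded
# tabulated white point introduces.
_SRGB_TO_XYZ = np.array(
    [
        [0.41239080, 0.35758434, 0.18048079],
        [0.21263901, 0.71516868, 0.07219232],
        [0.01933082, 0.11919478, 0.95053215],
    ]
)
_WHITE_XYZ = _SRGB_TO_XYZ.sum(axis=1)


def _srgb_linearize(s: np.ndarray) -> np.ndarray:
    return np.where(s <= 0.04045, s / 12.92, ((s + 0.055) / 1.055) ** 2.4)


def rgb_to_cielab(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to CIELAB (sRGB encoding, D65 white).

    Returns a float array of shape (H, W, 3) holding (L*, a*, b*) per
    pixel, with L* in [0, 100].  Float input is assumed already scaled to
    [0, 1].
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] < 3:
        raise NotColorImage("expected an RGB image with 3 channels")
    rgb = image[..., :3]
    if np.issubdtype(rgb.dtype, np.integer):
        rgb = rgb.astype(float) / 255.0
    xyz = _srgb_linearize(rgb) @ _SRGB_TO_XYZ.T
    t = xyz / _WHITE_XYZ
    delta = 6.0 / 29.0
    f = np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    return np.stack([116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)], axis=-1)


def summarize_iris_roi(
    lab: np.ndarray, roi: np.ndarray, eye_id: str, statistic: str = "mean"
) -> IrisLabSummary:
    """Reduce the Lab pixels inside the iris ROI to one (L, a, b) triple.

    ``statistic`` is ``"mean"`` (default) or ``"median"``; the ROI should
    exclude the pupil, specular highlights and any non-iris area.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != lab.shape[:2]:
        raise DegenerateRegion("ROI shape does not match image")
    if not roi.any():
        raise DegenerateRegion("empty iris ROI")
    reduce = {"mean": np.mean, "median": np.median}[statistic]
    vals = lab[roi]
    return IrisLabSummary(
        eye_id=eye_id,
        L=float(reduce(vals[:, 0])),
        a=float(reduce(vals[:, 1])),
        b=float(reduce(vals[:, 2])),
    )


def _iqr(values: np.ndarray) -> float:
    """Q3 - Q1 with linear interpolation between order statistics."""
    q1, q3 = np.percentile(values, [25, 75])
    return float(q3 - q1)


def fit_cohort_normalization(
    summaries: list[IrisLabSummary],
) -> CohortNormalization:
    """Median and IQR of each Lab component across the cohort.

    Requires at least 4 eyes and a strictly positive IQR per component
    (a zero IQR signals a degenerate cohort in that channel).
    """
    if len(summaries) < 4:
        raise CohortTooSmall(f"need >= 4 eyes, got {len(summaries)}")
    Ls = np.array([s.L for s in summaries], dtype=float)
    As = np.array([s.a for s in summaries], dtype=float)
    Bs = np.array([s.b for s in summaries], dtype=float)
    iqrs = {"L": _iqr(Ls), "a": _iqr(As), "b": _iqr(Bs)}
    for comp, v in iqrs.items():
        if v <= 0:
            raise ZeroIQR(f"component {comp}* has zero IQR across the cohort")
    return CohortNormalization(
        median_L=float(np.median(Ls)),
        median_a=float(np.median(As)),
        median_b=float(np.median(Bs)),
        iqr_L=iqrs["L"],
        iqr_a=iqrs["a"],
        iqr_b=iqrs["b"],
        n_eyes=len(summaries),
    )


def normalize_component(x: float, median: float, iqr: float) -> float:
    """Robust z-like score (x - median) / IQR."""
    if iqr <= 0:
        raise ZeroIQR("IQR must be strictly positive")
    return (x - median) / iqr


def iris_color_index(Ln: float, an: float, bn: float) -> float:
    """Composite pigmentation scalar -Ln + an + bn.

    The lightness term is sign-flipped so that all three components
    increase with darker pigmentation.
    """
    return -Ln + an + bn


def classify_pigmentation(iris_color: float) -> str:
    """Sign rule: negative -> ``light``, positive -> ``dark``, zero ->
    ``indeterminate`` (excluded from two-group comparisons)."""
    if iris_color < 0:
        return "light"
    if iris_color > 0:
        return "dark"
    return "indeterminate"


def score_cohort(
    summaries: list[IrisLabSummary],
    norm: CohortNormalization | None = None,
) -> tuple[list[IrisColorRecord], CohortNormalization]:
    """Normalise a cohort of Lab summaries and score every eye.

    Fits the cohort normalisation (unless one is passed explicitly, e.g.
    to score a new eye against frozen constants) and returns one
    :class:`IrisColorRecord` per summary plus the constants used.
    """
    if norm is None:
        norm = fit_cohort_normalization(summaries)
    records = []
    for s in summaries:
        Ln = normalize_component(s.L, norm.median_L, norm.iqr_L)
        an = normalize_component(s.a, norm.median_a, norm.iqr_a)
        bn = normalize_component(s.b, norm.median_b, norm.iqr_b)
        ic = iris_color_index(Ln, an, bn)
        records.append(
            IrisColorRecord(
                eye_id=s.eye_id,
                Ln=Ln,
                an=an,
                bn=bn,
                iris_color=ic,
                pigment_class=classify_pigmentation(ic),
            )
        )
    return records, norm


def polygon_roi_mask(
    shape: tuple[int, int], vertices: np.ndarray
) -> np.ndarray:
    """Rasterise polygon vertices (row, col) into a binary ROI mask.

    Convenience replacement for interactive ROI tools: any external
    segmentation can hand over either a mask file or a vertex list.
    """
    vertices = np.asarray(vertices, dtype=float)
    rr, cc = draw.polygon(vertices[:, 0], vertices[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask
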