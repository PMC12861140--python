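"""Seeded synthetic inputs with known ground truth for every pipeline stage.

Three generators close the validation loop without any clinical data:

* :func:`make_phantom` — a Scheimpflug-like grayscale frame: a bright
  corneal arc with controlled mean/SD, an iris band and lateral flanks at
  sub-threshold base intensity, and an exact planted count of
  super-threshold "reflection" pixels per region.  Ground-truth masks and
  planted counts are recorded, so segmentation Dice and artefact-percentage
  recovery are directly testable.
* :func:`make_iris_image` — an annular iris patch whose base color
  interpolates in CIELAB from a light blue-gray anchor to a dark brown
  anchor as the pigmentation level runs 0 -> 1, with seeded per-pixel
  noise and the pupil excluded from the ROI.
* :func:`make_cohort` — a study table of subjects contributing one or two
  eyes, with subject random intercepts, a planted light-minus-dark CD
  difference, and artefact percentages / Lab summaries coupled to the
  pigmentation level.  Optionally renders per-eye image bundles so the
  whole image -> statistics pipeline can run end to end.

Every generator is a pure function of its spec + seed (bit-reproducible).
Default phantom size is 300x155, a quarter linear scale of the nominal
1200x620 frame, to keep simulated batches fast; pass full dimensions for
full-scale frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import color as _skcolor

from .errors import SpecInvalid
from .iriscolor import IrisLabSummary, score_cohort
from .segmentation import RegionMasks, ScheimpflugFrame

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "IrisImageTruth",
    "CohortSpec",
    "make_phantom",
    "make_iris_image",
    "make_cohort",
    "make_eye_bundle",
    "phantom_batch_specs",
    "LIGHT_ANCHOR_LAB",
    "DARK_ANCHOR_LAB",
    "lab_at_level",
]


# ---------------------------------------------------------------------------
# Scheimpflug-like phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity recipe for one synthetic frame.

    Intensities are 8-bit arbitrary units.  The corneal arc is a parabolic
    band (apex at ``apex_row``, vertical sag ``sag`` toward the frame
    edges, constant ``thickness``).  The iris band occupies half the local
    corneal thickness below the posterior boundary in the central third of
    the width; the lateral flanks take the same rows in the outer thirds.
    Artefact pixels of value ``artefact_value`` are planted at seeded
    positions, exactly ``round(fraction * region size)`` of them per
    region.
    """

    width: int = 300
    height: int = 155
    apex_row: int = 30
    sag: float = 18.0
    thickness: int = 22
    cornea_mean: float = 48.0
    cornea_sd: float = 3.0
    iris_base: float = 25.0
    lateral_base: float = 30.0
    background: float = 5.0
    base_noise_sd: float = 1.0
    artefact_fraction_iris: float = 0.0
    artefact_fraction_lateral: float = 0.0
    artefact_fraction_cornea: float = 0.0
    artefact_value: float = 140.0
    seed: int = 0
    eye_id: str = "phantom"
    meridian_index: int = 1

    def validate(self) -> None:
        thr = self.cornea_mean + 3.0 * self.cornea_sd
        if self.artefact_value <= thr:
            raise SpecInvalid("artefact_value must exceed cornea_mean + 3*sd")
        if self.iris_base >= thr or self.lateral_base >= thr:
            raise SpecInvalid("base intensities must stay below the threshold")
        for f in (
            self.artefact_fraction_iris,
            self.artefact_fraction_lateral,
            self.artefact_fraction_cornea,
        ):
            if not 0.0 <= f < 1.0:
                raise SpecInvalid("artefact fractions must lie in [0, 1)")
        if self.width < 64 or self.height < 64:
            raise SpecInvalid("frame must be at least 64x64")
        if self.thickness < 4:
            raise SpecInvalid("corneal thickness must be >= 4 px")


@dataclass(frozen=True)
class PhantomTruth:
    """Generator bookkeeping for one phantom."""

    n_cornea: int
    n_iris: int
    n_lateral: int
    planted_iris: int
    planted_lateral: int
    planted_cornea: int
    fraction_iris: float
    fraction_lateral: float
    threshold_nominal: float

    @property
    def pct_iris(self) -> float:
        return 100.0 * self.planted_iris / self.n_iris if self.n_iris else 0.0

    @property
    def pct_lateral(self) -> float:
        return (
            100.0 * self.planted_lateral / self.n_lateral if self.n_lateral else 0.0
        )

    @property
    def pct_overall(self) -> float:
        n = self.n_iris + self.n_lateral
        return 100.0 * (self.planted_iris + self.planted_lateral) / n if n else 0.0


def _phantom_geometry(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ground-truth cornea/iris/lateral masks from the analytic arc."""
    h, w = spec.height, spec.width
    x = np.arange(w)
    u = (x - (w - 1) / 2.0) / (w / 2.0)
    anterior = spec.apex_row + spec.sag * u**2
    posterior = anterior + spec.thickness

    rows = np.arange(h)[:, None]
    cornea = (rows >= np.ceil(anterior)) & (rows <= np.floor(posterior))

    band_depth = max(round(spec.thickness / 2.0), 1)
    band = (rows >= np.floor(posterior) + 1) & (
        rows <= np.floor(posterior) + band_depth
    )
    cols = np.arange(w)
    central = (cols >= int(round(w / 3.0))) & (cols < int(round(2.0 * w / 3.0)))
    iris = band & central
    lateral = band & ~central
    return cornea, iris, lateral


def make_phantom(
    spec: PhantomSpec,
) -> tuple[ScheimpflugFrame, RegionMasks, PhantomTruth]:
    """Render one phantom frame with its ground-truth masks and bookkeeping.

    The corneal arc is sampled from N(cornea_mean, cornea_sd^2) clipped to
    [0, 255]; iris/lateral/background get their base intensity plus small
    Gaussian noise; exactly ``round(f * N_region)`` artefact pixels per
    region are set to ``artefact_value`` at seeded positions.  Bit
    reproducible per seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    cornea, iris, lateral = _phantom_geometry(spec)

    img = rng.normal(spec.background, spec.base_noise_sd, size=(h, w))
    img[cornea] = rng.normal(spec.cornea_mean, spec.cornea_sd, size=int(cornea.sum()))
    img[iris] = rng.normal(spec.iris_base, spec.base_noise_sd, size=int(iris.sum()))
    img[lateral] = rng.normal(
        spec.lateral_base, spec.base_noise_sd, size=int(lateral.sum())
    )

    planted = {}
    for name, mask, frac in (
        ("iris", iris, spec.artefact_fraction_iris),
        ("lateral", lateral, spec.artefact_fraction_lateral),
        ("cornea", cornea, spec.artefact_fraction_cornea),
    ):
        n_region = int(mask.sum())
        n_plant = int(round(frac * n_region))
        planted[name] = n_plant
        if n_plant:
            flat = np.flatnonzero(mask)
            chosen = rng.choice(flat, size=n_plant, replace=False)
            img.ravel()[chosen] = spec.artefact_value

    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    frame = ScheimpflugFrame(
        pixels=img, eye_id=spec.eye_id, meridian_index=spec.meridian_index
    )
    masks = RegionMasks(cornea=cornea, iris=iris, lateral=lateral,
                        provenance="external")
    truth = PhantomTruth(
        n_cornea=int(cornea.sum()),
        n_iris=int(iris.sum()),
        n_lateral=int(lateral.sum()),
        planted_iris=planted["iris"],
        planted_lateral=planted["lateral"],
        planted_cornea=planted["cornea"],
        fraction_iris=spec.artefact_fraction_iris,
        fraction_lateral=spec.artefact_fraction_lateral,
        threshold_nominal=spec.cornea_mean + 3.0 * spec.cornea_sd,
    )
    return frame, masks, truth


def phantom_batch_specs(n: int, seed: int = 0) -> list[PhantomSpec]:
    """A seeded batch of phantom specs spanning the generator's geometry
    and intensity ranges (apex 20-45 px, sag 8-25 px, thickness 18-28 px,
    corneal mean 42-55 a.u., SD 2-4 a.u., planted fractions 0-5 %)."""
    rng = np.random.default_rng(seed)
    specs = []
    for k in range(n):
        specs.append(
            PhantomSpec(
                apex_row=int(rng.integers(20, 45)),
                sag=float(rng.uniform(8, 25)),
                thickness=int(rng.integers(18, 28)),
                cornea_mean=float(rng.uniform(42, 55)),
                cornea_sd=float(rng.uniform(2, 4)),
                artefact_fraction_iris=float(rng.uniform(0, 0.05)),
                artefact_fraction_lateral=float(rng.uniform(0, 0.05)),
                seed=int(rng.integers(0, 2**31)),
                eye_id=f"phantom{k:02d}",
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Iris color images
# ---------------------------------------------------------------------------

# CIELAB anchors of the pigmentation gradient: a pale blue-gray iris at
# level 0, a dark brown iris at level 1.  All three components move
# monotonically with level, matching the directional design of the
# composite index (-Ln + an + bn increases with darkness).
LIGHT_ANCHOR_LAB = np.array([75.0, -5.0, -15.0])
DARK_ANCHOR_LAB = np.array([28.0, 14.0, 28.0])


def lab_at_level(level: float) -> np.ndarray:
    """Base CIELAB triple of the gradient at pigmentation ``level`` in [0,1]."""
    if not 0.0 <= level <= 1.0:
        raise SpecInvalid("pigmentation level must lie in [0, 1]")
    return LIGHT_ANCHOR_LAB + level * (DARK_ANCHOR_LAB - LIGHT_ANCHOR_LAB)


@dataclass(frozen=True)
class IrisImageTruth:
    """Ground truth for one synthetic iris image."""

    level: float
    lab_mean: tuple[float, float, float]
    n_roi: int


def make_iris_image(
    pigmentation: float,
    seed: int = 0,
    size: int = 96,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, IrisImageTruth]:
    """Render an annular iris patch at the given pigmentation level.

    Returns ``(rgb_uint8, roi_mask, truth)``.  The ROI is the annulus
    between the pupil (central disk, excluded) and the outer iris border;
    per-pixel Gaussian noise of ``noise_sd`` CIELAB units is added inside
    the iris before conversion to 8-bit sRGB.
    """
    base = lab_at_level(pigmentation)
    rng = np.random.default_rng(seed)

    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    r = np.hypot(yy - c, xx - c)
    outer, pupil = 0.45 * size, 0.16 * size
    roi = (r <= outer) & (r > pupil)

    lab = np.empty((size, size, 3))
    lab[...] = [70.0, 8.0, 14.0]        # skin-toned surround, outside ROI
    lab[r <= pupil] = [8.0, 0.0, 0.0]   # near-black pupil
    lab[roi] = base
    if noise_sd > 0:
        lab[roi] += rng.normal(0.0, noise_sd, size=(int(roi.sum()), 3))

    rgb = _skcolor.lab2rgb(lab)
    rgb8 = np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)
    truth = IrisImageTruth(
        level=float(pigmentation),
        lab_mean=tuple(float(v) for v in base),
        n_roi=int(roi.sum()),
    )
    return rgb8, roi, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic study cohort.

    Defaults emulate the target study structure: 47 subjects contributing
    91 eyes, a planted light-minus-dark CD difference of 3.1 a.u. on a
    dark-group mean of 47.2 a.u., residual SD 2.9 a.u. and between-subject
    intercept SD 1.0 a.u.  When ``n_light``/``n_dark`` are given the class
    sizes are fixed exactly (levels sampled clear of the gradient
    midpoint); otherwise levels are uniform over ``pigment_gradient`` and
    the class is the side of the midpoint.
    """

    n_subjects: int = 47
    p_both_eyes: float = 0.94
    n_light: int | None = 39
    n_dark: int | None = 52
    delta_cd: float = 3.1
    cd_dark_mean: float = 47.2
    cd_sd: float = 2.9
    subject_sd: float = 1.0
    pigment_gradient: tuple[float, float] = (0.0, 1.0)
    class_margin: float = 0.05
    lab_noise_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise SpecInvalid("need at least 4 subjects")
        if self.cd_sd <= 0:
            raise SpecInvalid("cd_sd must be positive")
        if not 0.0 <= self.p_both_eyes <= 1.0:
            raise SpecInvalid("p_both_eyes must lie in [0, 1]")
        if (self.n_light is None) != (self.n_dark is None):
            raise SpecInvalid("give both n_light and n_dark or neither")
        if self.n_light is not None:
            total = self.n_light + self.n_dark
            if not self.n_subjects <= total <= 2 * self.n_subjects:
                raise SpecInvalid(
                    "n_light + n_dark must fit the subject count (1-2 eyes each)"
                )


# Artefact-percentage coupling to the pigmentation level.  Linear in
# (1 - level) with mean-zero Gaussian noise, calibrated so the group means
# land near the reference values (iris 2.3/0.8 %, lateral 3.9/3.4 %,
# overall 6.5/4.3 % for light/dark).
_PCT_COUPLING = {
    "pct_iris": (0.186, 2.727, 0.5),
    "pct_lateral": (3.195, 0.909, 0.7),
    "pct_overall": (3.400, 4.000, 0.8),
}


def make_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Sample a study table with planted effects and full bookkeeping.

    Returns ``(table, truth)``.  The table has one row per eye with
    columns ``subject_id, eye_id, level, planted_light, cd, pct_iris,
    pct_lateral, pct_overall, L, a, b, Ln, an, bn, iris_color,
    pigment_class``.  ``pigment_class`` carries the planted class (level
    below/above the gradient midpoint); ``iris_color`` is computed by the
    scoring pipeline from the cohort's Lab summaries.  ``truth`` records
    every planted parameter.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # eyes per subject
    if spec.n_light is not None:
        total_eyes = spec.n_light + spec.n_dark
        n_both = total_eyes - spec.n_subjects
        both = np.zeros(spec.n_subjects, dtype=bool)
        both[rng.permutation(spec.n_subjects)[:n_both]] = True
    else:
        both = rng.random(spec.n_subjects) < spec.p_both_eyes

    subjects = [f"S{i:03d}" for i in range(spec.n_subjects)]
    intercepts = rng.normal(0.0, spec.subject_sd, size=spec.n_subjects)

    eye_subject: list[int] = []
    for i in range(spec.n_subjects):
        eye_subject.extend([i, i] if both[i] else [i])
    n_eyes = len(eye_subject)

    # pigmentation levels and planted class
    g0, g1 = spec.pigment_gradient
    mid = 0.5 * (g0 + g1)
    if spec.n_light is not None:
        is_light = np.zeros(n_eyes, dtype=bool)
        is_light[rng.permutation(n_eyes)[: spec.n_light]] = True
        levels = np.where(
            is_light,
            rng.uniform(g0, mid - spec.class_margin, size=n_eyes),
            rng.uniform(mid + spec.class_margin, g1, size=n_eyes),
        )
    else:
        levels = rng.uniform(g0, g1, size=n_eyes)
        is_light = levels < mid

    cd = (
        spec.cd_dark_mean
        + spec.delta_cd * is_light
        + intercepts[np.array(eye_subject)]
        + rng.normal(0.0, spec.cd_sd, size=n_eyes)
    )

    pcts = {}
    for name, (a0, a1, sd) in _PCT_COUPLING.items():
        pcts[name] = np.maximum(
            a0 + a1 * (1.0 - levels) + rng.normal(0.0, sd, size=n_eyes), 0.0
        )

    # per-eye Lab summaries along the anchor gradient, with between-eye noise
    lab = np.array([lab_at_level(lv) for lv in levels])
    lab += rng.normal(0.0, spec.lab_noise_sd, size=lab.shape)
    summaries = [
        IrisLabSummary(eye_id=f"E{k:03d}", L=lab[k, 0], a=lab[k, 1], b=lab[k, 2])
        for k in range(n_eyes)
    ]
    records, norm = score_cohort(summaries)

    table = pd.DataFrame(
        {
            "subject_id": [subjects[i] for i in eye_subject],
            "eye_id": [f"E{k:03d}" for k in range(n_eyes)],
            "level": levels,
            "planted_light": is_light,
            "cd": cd,
            "pct_iris": pcts["pct_iris"],
            "pct_lateral": pcts["pct_lateral"],
            "pct_overall": pcts["pct_overall"],
            "L": lab[:, 0],
            "a": lab[:, 1],
            "b": lab[:, 2],
            "Ln": [r.Ln for r in records],
            "an": [r.an for r in records],
            "bn": [r.bn for r in records],
            "iris_color": [r.iris_color for r in records],
            "pigment_class": np.where(is_light, "light", "dark"),
        }
    )
    truth = {
        "delta_cd": spec.delta_cd,
        "cd_dark_mean": spec.cd_dark_mean,
        "cd_sd": spec.cd_sd,
        "subject_sd": spec.subject_sd,
        "n_eyes": n_eyes,
        "n_light": int(is_light.sum()),
        "n_dark": int((~is_light).sum()),
        "subject_intercepts": dict(zip(subjects, intercepts.tolist())),
        "normalization": norm,
    }
    return table, truth


def make_eye_bundle(
    level: float,
    cd_target: float,
    seed: int,
    n_frames: int = 5,
    eye_id: str = "eye",
) -> dict:
    """Render the image bundle for one eye of a cohort.

    Produces ``n_frames`` phantom frames whose corneal mean equals the
    eye's target CD and whose planted artefact fractions increase with
    lightness (the reflection mechanism), plus one iris image at the eye's
    pigmentation level.  Returns a dict with ``frames``, ``masks``,
    ``truths``, ``iris_rgb``, ``iris_roi``, ``iris_truth``.
    """
    a0, a1, _ = _PCT_COUPLING["pct_iris"]
    f_iris = max(a0 + a1 * (1.0 - level), 0.0) / 100.0
    b0, b1, _ = _PCT_COUPLING["pct_lateral"]
    f_lat = max(b0 + b1 * (1.0 - level), 0.0) / 100.0

    frames, masks_list, truths = [], [], []
    for k in range(n_frames):
        fspec = PhantomSpec(
            cornea_mean=float(cd_target),
            artefact_fraction_iris=f_iris,
            artefact_fraction_lateral=f_lat,
            seed=seed * 1009 + k,
            eye_id=eye_id,
            meridian_index=k + 1,
        )
        frame, masks, truth = make_phantom(fspec)
        frames.append(frame)
        masks_list.append(masks)
        truths.append(truth)
    iris_rgb, iris_roi, iris_truth = make_iris_image(level, seed=seed * 2003 + 1)
    return {
        "frames": frames,
        "masks": masks_list,
        "truths": truths,
        "iris_rgb": iris_rgb,
        "iris_roi": iris_roi,
        "iris_truth": iris_truth,
    }
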