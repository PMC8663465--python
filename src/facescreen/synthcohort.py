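"""Synthetic two-group cohorts of expressive face sequences.

The clinical task this package addresses — screening Parkinson disease from
a short poker-face-then-smile video — cannot be exercised on public data,
so this module generates a controllable stand-in cohort: each subject has
latent facial traits (neutral mouth-corner angle, smile-amplitude angle
gain, corner asymmetry, texture contrast), an analytic 68-point landmark
trajectory through the smile, line-art face renders with fine-scale wrinkle
texture, and clinical covariates.  Hypomimia is emulated by three group
effects on patients:

* ``effect_angle`` — reduces the smile corner-angle gain by that many
  within-group standard deviations (smaller, stiffer smiles);
* ``effect_asym``  — inflates the dispersion of mouth-corner asymmetry
  (uncoordinated corner movement);
* ``effect_texture`` — multiplies facial texture contrast by
  ``1 - effect_texture`` (reduced fine expressive detail around eyes and
  mouth).

With all effects zero the two groups are drawn from identical
distributions.  Landmarks are exact ground truth: geometric features
recovered downstream match the generating parameters to small stated
tolerances, which is what makes the whole pipeline testable.

Clinical covariates (UPDRS, H-Y, MMSE, ...) are sampled from plausible
scale ranges and are, by default, statistically independent of the facial
traits; ``covariate_link=True`` instead couples UPDRS to smile severity
(population correlation 0.6) for power studies of the correlation analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import disk, line, polygon, polygon_perimeter

from .errors import ConfigurationError
from .facenorm import BoundingBox, LandmarkSet, save_landmarks_json

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

GROUPS = ("patient", "control")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs of the synthetic cohort.

    Defaults mirror the target screening study: 70 patients and 70 matched
    controls, a large hypomimia effect on smile amplitude (1.5 SD), halved
    facial texture contrast, and a moderate inflation of corner asymmetry.
    """

    n_patient: int = 70
    n_control: int = 70
    effect_angle: float = 1.5      # SD units of smile-angle-gain reduction
    effect_asym: float = 0.5       # relative inflation of asymmetry SD
    effect_texture: float = 0.5    # texture contrast multiplied by (1 - this)
    n_frames: int = 11
    image_size: int = 256
    rng_seed: int = 0
    covariate_link: bool = False
    # Latent population parameters (degrees / pixels).
    mu_gain: float = 12.0          # mean smile corner-angle gain
    sigma_gain: float = 3.0        # between-subject SD of the gain
    sigma_asym: float = 1.5        # SD of corner asymmetry (degrees)
    mu_neutral_angle: float = 70.0
    sigma_neutral_angle: float = 4.0
    mu_mouth_width: float = 60.0
    sigma_mouth_width: float = 4.0
    interocular: float = 100.0
    sigma_contrast: float = 0.33   # between-subject SD of texture contrast

    def __post_init__(self) -> None:
        if self.n_patient < 1 or self.n_control < 1:
            raise ConfigurationError("group sizes must be >= 1")
        if not 0.0 <= self.effect_texture <= 1.0:
            raise ConfigurationError("effect_texture must lie in [0, 1]")
        if self.n_frames < 1 or self.image_size < 32:
            raise ConfigurationError("invalid frame count or image size")
        if self.image_size < 2.2 * self.interocular:
            raise ConfigurationError(
                "image_size must be at least 2.2x the inter-ocular distance "
                "for the head to fit the canvas"
            )


@dataclass(frozen=True)
class SubjectParams:
    """Latent facial traits of one synthetic subject."""

    group: str
    neutral_corner_angle: float  # degrees
    smile_angle_gain: float      # degrees, corner-angle change at smile apex
    asymmetry: float             # degrees, left-minus-right corner elevation
    mouth_width: float           # pixels at neutral
    interocular: float           # pixels
    texture_contrast: float      # dimensionless, ~1 for healthy texture


@dataclass(frozen=True)
class ClinicalCovariates:
    age: float
    duration: float
    ledd: float
    updrs_total: float
    hy_stage: int
    mmse: float
    nmss: float
    pdq39: float
    ham_a: float
    rbd: float
    quip: float
    fog: float

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


# ---------------------------------------------------------------------------
# Subject parameter sampling
# ---------------------------------------------------------------------------

def sample_subject_params(config: CohortConfig, group: str,
                          rng: np.random.Generator) -> SubjectParams:
    """Draw one subject's latent traits.

    The group enters only through the configured effects, so with all
    effects zero an identical RNG stream yields identical parameters for
    either group label.  The smile gain is truncated at zero (a smile never
    reduces below no movement).
    """
    if group not in GROUPS:
        raise ConfigurationError(f"invalid group {group!r}; expected one of {GROUPS}")
    is_pd = group == "patient"
    neutral = rng.normal(config.mu_neutral_angle, config.sigma_neutral_angle)
    gain_mu = config.mu_gain - (config.effect_angle * config.sigma_gain if is_pd else 0.0)
    gain = max(0.0, rng.normal(gain_mu, config.sigma_gain))
    asym_sd = config.sigma_asym * (1.0 + (config.effect_asym if is_pd else 0.0))
    asym = rng.normal(0.0, asym_sd)
    width = max(30.0, rng.normal(config.mu_mouth_width, config.sigma_mouth_width))
    contrast = float(np.clip(rng.normal(1.0, config.sigma_contrast), 0.05, 2.0))
    if is_pd:
        contrast *= 1.0 - config.effect_texture
    return SubjectParams(group, neutral, gain, asym, width,
                         config.interocular, contrast)


# ---------------------------------------------------------------------------
# Analytic landmark model
# ---------------------------------------------------------------------------

#: Shared elevation (degrees) of both mouth corners at the smile apex.  Kept
#: small so the corner-triangle angle stays within 0.2 degrees of its
#: closed-form target in the presence of corner elevation.
SMILE_LIFT_DEG = 4.0
#: Relative mouth widening at the smile apex.
SMILE_WIDEN = 0.15

# Facial layout as fractions of the inter-ocular distance, centered on the
# canvas.  y grows downward.
_EYE_Y = -0.28           # eye row relative to canvas center
_MOUTH_Y = 0.45          # mouth center row
_EYE_HALF_W = 0.12
_EYE_HALF_H = 0.05
_BROW_Y = -0.46
_BROW_HALF_W = 0.18
_BROW_ARCH = 0.05
_JAW_A = 0.78            # jaw half-width
_JAW_B = 1.05            # jaw drop below the eye row
_HEAD_CY = -0.03         # head-ellipse center relative to canvas center
_HEAD_RX = 0.88
_HEAD_RY = 0.85


def default_canvas_size(params: SubjectParams) -> int:
    """Canvas side implied by the inter-ocular distance (100 px -> 256 px)."""
    return int(round(2.56 * params.interocular))


def landmarks_from_params(params: SubjectParams, phase: float,
                          image_size: int | None = None) -> LandmarkSet:
    """Ground-truth 68-point landmark set at a given expression phase.

    ``phase`` runs from 0 (poker face) to 1 (smile apex).  The mouth widens
    by ``SMILE_WIDEN * phase`` and its corner-triangle angle grows linearly
    from the neutral angle to neutral + gain: during the synthetic smile the
    lips part faster than the mouth widens, so the net corner angle
    increases by exactly the subject's ``smile_angle_gain``.  Corner
    elevations follow ``(SMILE_LIFT_DEG +/- asymmetry/2) * phase``.
    """
    if not 0.0 <= phase <= 1.0:
        raise ValueError(f"phase must lie in [0, 1], got {phase}")
    iod = params.interocular
    size = image_size if image_size is not None else default_canvas_size(params)
    cx = cy = size / 2.0

    pts = np.zeros((68, 2))
    eye_y = cy + _EYE_Y * iod
    # jaw 0-16: half-ellipse from image-left temple through the chin
    t = np.pi * np.arange(17) / 16.0
    pts[0:17, 0] = cx - _JAW_A * iod * np.cos(t)
    pts[0:17, 1] = eye_y + _JAW_B * iod * np.sin(t)
    # brows 17-26: arched arcs above each eye
    u = np.linspace(-1.0, 1.0, 5)
    for s, idx in ((-1, slice(17, 22)), (1, slice(22, 27))):
        ex = cx + s * 0.5 * iod
        pts[idx, 0] = ex + u * _BROW_HALF_W * iod
        pts[idx, 1] = cy + _BROW_Y * iod - _BROW_ARCH * iod * (1 - u ** 2)
    # nose 27-35
    pts[27:31, 0] = cx
    pts[27:31, 1] = eye_y + np.array([0.06, 0.16, 0.26, 0.36]) * iod
    pts[31:36, 0] = cx + np.array([-0.10, -0.05, 0.0, 0.05, 0.10]) * iod
    pts[31:36, 1] = eye_y + 0.42 * iod
    # eyes: hexagons whose vertex mean is exactly the eye center
    hexagon = np.array([
        [-_EYE_HALF_W, 0.0],
        [-_EYE_HALF_W / 2, -_EYE_HALF_H],
        [_EYE_HALF_W / 2, -_EYE_HALF_H],
        [_EYE_HALF_W, 0.0],
        [_EYE_HALF_W / 2, _EYE_HALF_H],
        [-_EYE_HALF_W / 2, _EYE_HALF_H],
    ]) * iod
    right_center = np.array([cx - iod / 2.0, eye_y])
    pts[36:42] = right_center + hexagon
    # left eye = mirror image about the facial midline, laid out with the
    # iBUG mirror correspondence 36<->45, 37<->44, 38<->43, 39<->42,
    # 40<->47, 41<->46
    for left_i, right_i in ((45, 36), (44, 37), (43, 38), (42, 39),
                            (47, 40), (46, 41)):
        pts[left_i] = [2 * cx - pts[right_i, 0], pts[right_i, 1]]

    # mouth: closed-form characteristic-triangle construction
    mouth_cy = cy + _MOUTH_Y * iod
    w = params.mouth_width * (1.0 + SMILE_WIDEN * phase)
    a = w / 2.0
    theta = params.neutral_corner_angle + params.smile_angle_gain * phase
    h = a * math.tan(math.radians(theta) / 2.0)
    dev_l = math.radians((SMILE_LIFT_DEG + params.asymmetry / 2.0) * phase)
    dev_r = math.radians((SMILE_LIFT_DEG - params.asymmetry / 2.0) * phase)
    y48 = mouth_cy - math.tan(dev_l) * a
    y54 = mouth_cy - math.tan(dev_r) * a
    top = mouth_cy - h
    bot = mouth_cy + h

    def _arc(y_left: float, y_mid: float, y_right: float, u: np.ndarray):
        # quadratic Lagrange arc through the two corners and the lip center
        return (y_left * u * (u - 1) / 2 + y_mid * (1 - u ** 2)
                + y_right * u * (u + 1) / 2)

    uu = np.linspace(-1.0, 1.0, 7)
    pts[48:55, 0] = cx + uu * a
    pts[48:55, 1] = _arc(y48, top, y54, uu)
    ul = np.array([2 / 3, 1 / 3, 0.0, -1 / 3, -2 / 3])
    pts[55:60, 0] = cx + ul * a
    pts[55:60, 1] = _arc(y48, bot, y54, ul)
    # inner lip: outer ring contracted toward the mouth center
    center = np.array([cx, mouth_cy])
    for inner, outer, f in ((60, 48, 0.75), (61, 50, 0.60), (62, 51, 0.60),
                            (63, 52, 0.60), (64, 54, 0.75), (65, 56, 0.60),
                            (66, 57, 0.60), (67, 58, 0.60)):
        pts[inner] = center + f * (pts[outer] - center)
    return LandmarkSet(pts)


def head_ellipse(params: SubjectParams, image_size: int):
    """(cx, cy, rx, ry) of the rendered head outline."""
    iod = params.interocular
    cx = cy = image_size / 2.0
    return cx, cy + _HEAD_CY * iod, _HEAD_RX * iod, _HEAD_RY * iod


def head_box(params: SubjectParams, image_size: int) -> BoundingBox:
    """Ground-truth bounding box: the pixel bounding box of the head mask."""
    mask = _head_mask(params, image_size)
    rows, cols = np.nonzero(mask)
    return BoundingBox(int(cols.min()), int(rows.min()),
                       int(cols.max() - cols.min() + 1),
                       int(rows.max() - rows.min() + 1))


def _head_mask(params: SubjectParams, image_size: int) -> np.ndarray:
    cx, cy, rx, ry = head_ellipse(params, image_size)
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

FACE_INTENSITY = 170.0
LIP_INTENSITY = 70.0
INNER_MOUTH_INTENSITY = 45.0
FEATURE_LINE_INTENSITY = 90.0
IRIS_INTENSITY = 50.0
#: Peak wrinkle-band amplitude per unit texture contrast, chosen to be of
#: the same order as the pixel noise so that texture contrast modulates the
#: local signal-to-noise ratio of fine detail rather than disappearing into
#: the descriptors' own contrast normalization.
WRINKLE_AMPLITUDE = 10.0
#: SD of the additive Gaussian pixel noise inside the head region.
NOISE_SD = 3.0


def _draw_polyline(canvas: np.ndarray, pts: np.ndarray, value: float) -> None:
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        rr, cc = line(int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1)))
        ok = (rr >= 0) & (rr < canvas.shape[0]) & (cc >= 0) & (cc < canvas.shape[1])
        canvas[rr[ok], cc[ok]] = value


def _wrinkle_band(canvas: np.ndarray, mask: np.ndarray, x0, x1, y0, y1,
                  amplitude: float, kx: float, ky: float) -> None:
    x0, x1 = int(round(x0)), int(round(x1))
    y0, y1 = int(round(y0)), int(round(y1))
    x0, x1 = max(x0, 0), min(x1, canvas.shape[1])
    y0, y1 = max(y0, 0), min(y1, canvas.shape[0])
    if x1 <= x0 or y1 <= y0:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    band = amplitude * np.sin(2 * np.pi * xx / kx) * np.sin(2 * np.pi * yy / ky)
    canvas[y0:y1, x0:x1] += band * mask[y0:y1, x0:x1]


def render_face(landmarks: LandmarkSet, params: SubjectParams,
                rng: np.random.Generator, image_size: int | None = None) -> np.ndarray:
    """Render one grayscale frame of the synthetic face.

    Line-art construction: a filled head ellipse on a black background, with
    brows, nose, eye outlines and irises, and lip contours drawn through the
    mouth landmarks; sinusoidal wrinkle bands (crow's feet beside the eyes,
    perioral/chin bands around the mouth) with amplitude proportional to
    ``texture_contrast``; additive Gaussian pixel noise (SD ``NOISE_SD``)
    inside the head.  Deterministic given the RNG state.
    """
    iod = params.interocular
    size = image_size if image_size is not None else default_canvas_size(params)
    pts = landmarks.points
    if pts.min() < 0 or pts.max() >= size:
        raise ValueError("landmarks extend outside the canvas")

    canvas = np.zeros((size, size))
    mask = _head_mask(params, size)
    canvas[mask] = FACE_INTENSITY

    # brows and nose
    _draw_polyline(canvas, pts[17:22], FEATURE_LINE_INTENSITY)
    _draw_polyline(canvas, pts[22:27], FEATURE_LINE_INTENSITY)
    _draw_polyline(canvas, pts[27:31], FEATURE_LINE_INTENSITY)
    _draw_polyline(canvas, pts[31:36], FEATURE_LINE_INTENSITY)
    # eye outlines and irises
    for sl, center in ((slice(36, 42), pts[36:42].mean(axis=0)),
                       (slice(42, 48), pts[42:48].mean(axis=0))):
        eye = pts[sl]
        rr, cc = polygon_perimeter(np.round(eye[:, 1]).astype(int),
                                   np.round(eye[:, 0]).astype(int), shape=canvas.shape)
        canvas[rr, cc] = FEATURE_LINE_INTENSITY
        rr, cc = disk((center[1], center[0]), 0.04 * iod, shape=canvas.shape)
        canvas[rr, cc] = IRIS_INTENSITY
    # lips: filled outer-lip polygon, darker inner mouth
    rr, cc = polygon(pts[48:60, 1], pts[48:60, 0], shape=canvas.shape)
    canvas[rr, cc] = LIP_INTENSITY
    rr, cc = polygon(pts[60:68, 1], pts[60:68, 0], shape=canvas.shape)
    canvas[rr, cc] = INNER_MOUTH_INTENSITY

    # fine texture: crow's feet lateral to each eye, perioral + chin bands
    amp = WRINKLE_AMPLITUDE * params.texture_contrast
    r_eye, l_eye = pts[36:42].mean(axis=0), pts[42:48].mean(axis=0)
    for ex, ey, side in ((r_eye[0], r_eye[1], -1), (l_eye[0], l_eye[1], 1)):
        xa = ex + side * 0.16 * iod
        xb = ex + side * 0.30 * iod
        _wrinkle_band(canvas, mask, min(xa, xb), max(xa, xb),
                      ey - 0.07 * iod, ey + 0.07 * iod, amp, kx=4.0, ky=7.0)
    mouth_c = 0.5 * (pts[51] + pts[57])
    for corner, side in ((pts[48], -1), (pts[54], 1)):
        xa = corner[0] + side * 0.02 * iod
        xb = corner[0] + side * 0.16 * iod
        _wrinkle_band(canvas, mask, min(xa, xb), max(xa, xb),
                      mouth_c[1] - 0.20 * iod, mouth_c[1] + 0.20 * iod,
                      amp, kx=5.0, ky=9.0)
    _wrinkle_band(canvas, mask, mouth_c[0] - 0.20 * iod, mouth_c[0] + 0.20 * iod,
                  pts[57][1] + 0.03 * iod, pts[57][1] + 0.14 * iod,
                  amp, kx=7.0, ky=5.0)

    canvas[mask] += rng.normal(0.0, NOISE_SD, size=int(mask.sum()))
    return np.clip(canvas, 0.0, 255.0)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def expression_phases(n_frames: int) -> np.ndarray:
    """Half-sine smile profile: poker face -> apex at mid-sequence -> relax."""
    if n_frames == 1:
        return np.zeros(1)
    return np.sin(np.pi * np.arange(n_frames) / (n_frames - 1))


@dataclass
class SyntheticSubject:
    """One generated subject: latent traits, ground-truth landmark sequence,
    lazily rendered frames and clinical covariates."""

    subject_id: str
    params: SubjectParams
    covariates: ClinicalCovariates
    phases: np.ndarray
    landmark_sequence: list[LandmarkSet]
    image_size: int
    _frame_seed: tuple[int, ...] = field(repr=False, default=())

    @property
    def group(self) -> str:
        return self.params.group

    def frame(self, index: int) -> np.ndarray:
        """Render frame ``index`` deterministically (per-frame RNG stream)."""
        rng = np.random.default_rng(self._frame_seed + (int(index),))
        return render_face(self.landmark_sequence[index], self.params, rng,
                           self.image_size)

    @property
    def frames(self) -> list[np.ndarray]:
        return [self.frame(i) for i in range(len(self.landmark_sequence))]

    def head_box(self) -> BoundingBox:
        return head_box(self.params, self.image_size)


@dataclass
class Cohort:
    config: CohortConfig
    subjects: list[SyntheticSubject]
    manifest: pd.DataFrame

    def patients(self) -> list[SyntheticSubject]:
        return [s for s in self.subjects if s.group == "patient"]

    def controls(self) -> list[SyntheticSubject]:
        return [s for s in self.subjects if s.group == "control"]


def _sample_covariates(config: CohortConfig, group: str, params: SubjectParams,
                       rng: np.random.Generator) -> ClinicalCovariates:
    def tn(mu, sd, lo, hi):
        return float(np.clip(rng.normal(mu, sd), lo, hi))

    if group == "patient":
        if config.covariate_link:
            # UPDRS coupled to smile severity with population correlation 0.6
            z = (config.mu_gain - params.smile_angle_gain) / config.sigma_gain
            noise = rng.normal()
            updrs = float(np.clip(40 + 15 * (0.6 * z + math.sqrt(1 - 0.36) * noise),
                                  10, 80))
        else:
            updrs = tn(40, 15, 10, 80)
        return ClinicalCovariates(
            age=tn(66, 8, 40, 85), duration=tn(6, 3, 0.5, 20),
            ledd=tn(600, 250, 0, 2000), updrs_total=updrs,
            hy_stage=int(np.clip(round(rng.normal(2.5, 0.8)), 1, 5)),
            mmse=tn(27, 2, 10, 30), nmss=tn(45, 25, 0, 160),
            pdq39=tn(35, 18, 0, 100), ham_a=tn(11, 6, 0, 40),
            rbd=tn(5, 3, 0, 13), quip=tn(1, 1.2, 0, 8), fog=tn(8, 5, 0, 24),
        )
    return ClinicalCovariates(
        age=tn(66, 8, 40, 85), duration=0.0, ledd=0.0,
        updrs_total=tn(2, 1.5, 0, 8), hy_stage=0,
        mmse=tn(28.5, 1.2, 24, 30), nmss=tn(8, 6, 0, 40),
        pdq39=tn(5, 4, 0, 20), ham_a=tn(5, 3, 0, 20),
        rbd=tn(2, 1.5, 0, 8), quip=0.0, fog=tn(1, 1, 0, 6),
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full synthetic cohort (patients first, then controls).

    Every random draw derives from ``config.rng_seed`` plus the subject
    index, so cohorts are fully reproducible and individual subjects can be
    re-rendered in isolation.  Frames are rendered lazily by
    :meth:`SyntheticSubject.frame`.
    """
    phases = expression_phases(config.n_frames)
    subjects: list[SyntheticSubject] = []
    rows = []
    groups = ["patient"] * config.n_patient + ["control"] * config.n_control
    for idx, group in enumerate(groups):
        rng = np.random.default_rng((config.rng_seed, idx))
        params = sample_subject_params(config, group, rng)
        cov_rng = np.random.default_rng((config.rng_seed, idx, 1))
        cov = _sample_covariates(config, group, params, cov_rng)
        lms = [landmarks_from_params(params, p, config.image_size) for p in phases]
        sid = f"{'pd' if group == 'patient' else 'hc'}{idx:03d}"
        subjects.append(SyntheticSubject(
            subject_id=sid, params=params, covariates=cov, phases=phases,
            landmark_sequence=lms, image_size=config.image_size,
            _frame_seed=(config.rng_seed, idx, 2),
        ))
        rows.append({"subject_id": sid, "group": group,
                     **{k: getattr(cov, k) for k in ClinicalCovariates.field_names()}})
    manifest = pd.DataFrame(rows)
    return Cohort(config, subjects, manifest)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write the cohort to disk: per-subject PNG frame directories
    (``<id>/frame_%04d.png``), ibug68-v1 landmark JSON, and ``manifest.csv``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        sdir = out / s.subject_id
        sdir.mkdir(exist_ok=True)
        for i in range(len(s.landmark_sequence)):
            iio.imwrite(sdir / f"frame_{i:04d}.png",
                        np.round(s.frame(i)).astype(np.uint8))
        save_landmarks_json(sdir / "landmarks.json", s.landmark_sequence)
    cohort.manifest.to_csv(out / "manifest.csv", index=False)
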