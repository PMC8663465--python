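"""Landmark schema, face/landmark detection interface and face normalization.

Coordinate conventions used throughout the package
--------------------------------------------------
Images are 2-D numpy arrays of grayscale intensities in [0, 255], indexed
``image[row, col]``; landmark coordinates are ``(x, y)`` pixel positions with
the origin at the top-left corner, x increasing rightward and y increasing
*downward*.  Landmarks follow the 68-point iBUG annotation scheme with
0-based indices: jaw 0-16, brows 17-26, nose 27-35, right eye 36-41 (the
subject's right, i.e. image left), left eye 42-47, outer lip 48-59, inner
lip 60-67.

Normalization maps every face into a canonical 256x256 frame in which the
two eye centers (the means of points 36-41 and 42-47) sit at fixed anchor
positions.  The mapping is a 4-degree-of-freedom similarity transform
(uniform scale, rotation, translation): shear is deliberately excluded
because it would distort the mouth angles measured downstream, and two-point
eye alignment determines the similarity exactly in closed form.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from skimage.transform import warp

from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    NoFaceError,
    SchemaError,
)

#: Canonical output frame: 256x256 pixels, inter-ocular distance 76.8 px,
#: eyes at 40% of the frame height.  These are fixed package constants,
#: not per-run settings.
CANONICAL_SIZE = 256
RIGHT_EYE_ANCHOR = (89.6, 102.4)
LEFT_EYE_ANCHOR = (166.4, 102.4)
CANONICAL_INTEROCULAR = LEFT_EYE_ANCHOR[0] - RIGHT_EYE_ANCHOR[0]

RIGHT_EYE_IDX = slice(36, 42)
LEFT_EYE_IDX = slice(42, 48)

LANDMARK_SCHEMA = "ibug68-v1"


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel rectangle: origin (x, y), extent (w, h)."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"bounding box must have positive extent, got {self}")

    def contains_point(self, x: float, y: float, margin: float = 0.0) -> bool:
        mx, my = margin * self.w, margin * self.h
        return (self.x - mx <= x <= self.x + self.w + mx) and (
            self.y - my <= y <= self.y + self.h + my
        )


class LandmarkSet:
    """An immutable set of 68 (x, y) facial landmarks in pixel units."""

    __slots__ = ("points",)

    def __init__(self, points) -> None:
        pts = np.asarray(points, dtype=float)
        if pts.shape != (68, 2):
            raise ValueError(f"expected 68 (x, y) points, got array of shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmark coordinates must be finite")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    def __setattr__(self, name, value):  # immutability guard
        raise AttributeError("LandmarkSet is immutable")

    def __getitem__(self, idx) -> np.ndarray:
        return self.points[idx]

    def __len__(self) -> int:
        return 68

    def __eq__(self, other) -> bool:
        return isinstance(other, LandmarkSet) and np.array_equal(self.points, other.points)

    def right_eye_center(self) -> np.ndarray:
        return self.points[RIGHT_EYE_IDX].mean(axis=0)

    def left_eye_center(self) -> np.ndarray:
        return self.points[LEFT_EYE_IDX].mean(axis=0)

    def interocular(self) -> float:
        return float(np.linalg.norm(self.left_eye_center() - self.right_eye_center()))

    def translated(self, dx: float, dy: float) -> "LandmarkSet":
        return LandmarkSet(self.points + np.array([dx, dy]))


@dataclass(frozen=True)
class SimilarityTransform:
    """p -> scale * R(rotation) @ p + translation, in image (y-down) coordinates.

    ``rotation`` is in degrees, measured in the image coordinate frame
    (positive angles rotate x toward y, i.e. clockwise on screen).
    """

    scale: float
    rotation: float
    translation: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on (x, y, 1) column vectors."""
        th = math.radians(self.rotation)
        c, s = self.scale * math.cos(th), self.scale * math.sin(th)
        tx, ty = self.translation
        return np.array([[c, -s, tx], [s, c, ty], [0.0, 0.0, 1.0]])

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(1.0, 0.0, (0.0, 0.0))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "SimilarityTransform":
        scale = float(np.hypot(m[0, 0], m[1, 0]))
        rot = math.degrees(math.atan2(m[1, 0], m[0, 0]))
        return cls(scale, rot, (float(m[0, 2]), float(m[1, 2])))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        m = self.matrix
        out = pts @ m[:2, :2].T + m[:2, 2]
        return out if np.asarray(points).ndim == 2 else out[0]

    def apply_landmarks(self, landmarks: LandmarkSet) -> LandmarkSet:
        return LandmarkSet(self.apply(landmarks.points))

    def inverse(self) -> "SimilarityTransform":
        return SimilarityTransform.from_matrix(np.linalg.inv(self.matrix))

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return SimilarityTransform.from_matrix(self.matrix @ other.matrix)


@dataclass(frozen=True)
class NormalizedFace:
    """A face resampled into the canonical frame, with mapped landmarks."""

    image: np.ndarray
    landmarks: LandmarkSet
    transform: SimilarityTransform


# ---------------------------------------------------------------------------
# Detection backends
# ---------------------------------------------------------------------------

class DetectorAdapter(Protocol):
    """Interface an external pretrained detector adapter must provide.

    No weights are bundled with this package; a user wrapping e.g. a dlib
    frontal-face detector plus shape predictor only needs to implement these
    two methods.
    """

    def detect_face_box(self, image: np.ndarray) -> BoundingBox: ...

    def locate_landmarks(self, image: np.ndarray, box: BoundingBox) -> LandmarkSet: ...


class ThresholdFaceDetector:
    """Face-box backend for synthetic renders: the face is the only bright
    region on a dark background, so its bounding box is the bounding box of
    pixels above an intensity threshold."""

    def __init__(self, threshold: float = 64.0) -> None:
        self.threshold = threshold

    def detect_face_box(self, image: np.ndarray) -> BoundingBox:
        img = np.asarray(image)
        if img.size == 0:
            raise NoFaceError("empty image")
        rows, cols = np.nonzero(img > self.threshold)
        if rows.size == 0:
            raise NoFaceError("no face found: no pixels above threshold")
        return BoundingBox(
            int(cols.min()), int(rows.min()),
            int(cols.max() - cols.min() + 1), int(rows.max() - rows.min() + 1),
        )

    def locate_landmarks(self, image: np.ndarray, box: BoundingBox) -> LandmarkSet:
        raise ConfigurationError(
            "ThresholdFaceDetector has no landmark model; use a "
            "GroundTruthDetector or an external DetectorAdapter"
        )


class GroundTruthDetector:
    """Backend that serves the synthetic generator's ground-truth annotation.

    Landmarks are stored relative to the ground-truth head box, so passing a
    shifted box returns correspondingly shifted points (translation
    equivariance, matching how a real detector tracks its input box).
    """

    def __init__(self, box: BoundingBox, landmarks: LandmarkSet) -> None:
        self._box = box
        self._landmarks = landmarks

    def detect_face_box(self, image: np.ndarray) -> BoundingBox:
        img = np.asarray(image)
        if img.size == 0 or not np.any(img > 0):
            raise NoFaceError("no face found in blank image")
        return self._box

    def locate_landmarks(self, image: np.ndarray, box: BoundingBox) -> LandmarkSet:
        dx, dy = box.x - self._box.x, box.y - self._box.y
        return self._landmarks.translated(dx, dy)


def detect_face_box(image: np.ndarray, backend=None) -> BoundingBox:
    """Find the face bounding box using the given backend (default: intensity
    threshold, appropriate for synthetic renders)."""
    backend = backend if backend is not None else ThresholdFaceDetector()
    box = backend.detect_face_box(image)
    h, w = np.asarray(image).shape[:2]
    if box.x < 0 or box.y < 0 or box.x + box.w > w or box.y + box.h > h:
        raise NoFaceError(f"detected box {box} extends outside the image")
    return box


def locate_landmarks(image: np.ndarray, box: BoundingBox, backend=None) -> LandmarkSet:
    """Locate the 68 landmarks inside ``box`` using the given backend."""
    if backend is None:
        raise ConfigurationError(
            "no landmark backend configured: pass a GroundTruthDetector or an "
            "external DetectorAdapter (no pretrained model is bundled)"
        )
    return backend.locate_landmarks(image, box)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def estimate_normalization_transform(
    landmarks: LandmarkSet,
    method: str = "two_point",
    reference: LandmarkSet | None = None,
) -> SimilarityTransform:
    """Estimate the similarity transform into the canonical frame.

    ``two_point`` (default) maps the two eye centers exactly onto the
    canonical anchors, in closed form via complex arithmetic.  ``lsq`` fits
    the similarity minimizing squared error over all 68 points against an
    explicit ``reference`` landmark set given in canonical coordinates.
    """
    if method == "two_point":
        a = complex(*landmarks.right_eye_center())
        b = complex(*landmarks.left_eye_center())
        if abs(b - a) < 1e-12:
            raise DegenerateGeometryError("coincident eye centers")
        va, vb = complex(*RIGHT_EYE_ANCHOR), complex(*LEFT_EYE_ANCHOR)
        r = (vb - va) / (b - a)
        t = va - r * a
        return SimilarityTransform(abs(r), math.degrees(math.atan2(r.imag, r.real)),
                                   (t.real, t.imag))
    if method == "lsq":
        if reference is None:
            raise ConfigurationError("lsq mode requires a reference LandmarkSet")
        # Umeyama closed form restricted to similarity (uniform scale).
        src, dst = landmarks.points, reference.points
        mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
        xs, xd = src - mu_s, dst - mu_d
        cov = xd.T @ xs / len(src)
        u, s, vt = np.linalg.svd(cov)
        d = np.sign(np.linalg.det(u @ vt))
        diag = np.diag([1.0, d])
        var_s = (xs ** 2).sum() / len(src)
        if var_s < 1e-12:
            raise DegenerateGeometryError("zero-variance landmark set")
        scale = float(np.trace(np.diag(s) @ diag) / var_s)
        rot = u @ diag @ vt
        t = mu_d - scale * rot @ mu_s
        m = np.eye(3)
        m[:2, :2] = scale * rot
        m[:2, 2] = t
        return SimilarityTransform.from_matrix(m)
    raise ConfigurationError(f"unknown normalization method {method!r}")


def normalize(image: np.ndarray | None, landmarks: LandmarkSet,
              transform: SimilarityTransform | None = None) -> NormalizedFace:
    """Resample a face into the canonical 256x256 frame.

    The image is warped by the eye-anchored similarity transform with
    bilinear interpolation; pixels mapping outside the source frame are 0.
    ``image`` may be None to normalize landmarks only (the output image is
    then an all-zero canvas).
    """
    t = transform if transform is not None else estimate_normalization_transform(landmarks)
    inv = t.inverse()
    if image is None:
        out = np.zeros((CANONICAL_SIZE, CANONICAL_SIZE))
    else:
        out = warp(
            np.asarray(image, dtype=float),
            inverse_map=inv.apply,
            output_shape=(CANONICAL_SIZE, CANONICAL_SIZE),
            order=1,
            cval=0.0,
            preserve_range=True,
        )
    return NormalizedFace(out, t.apply_landmarks(landmarks), t)


# ---------------------------------------------------------------------------
# Landmark file I/O (ibug68-v1 JSON schema)
# ---------------------------------------------------------------------------

def save_landmarks_json(path, frames: Sequence[LandmarkSet]) -> None:
    """Write a landmark sequence as ibug68-v1 JSON:
    ``{"schema": "ibug68-v1", "frames": [{"index": i, "points": [[x, y], ...]}]}``.
    """
    doc = {
        "schema": LANDMARK_SCHEMA,
        "frames": [
            {"index": i, "points": np.asarray(f.points).tolist()}
            for i, f in enumerate(frames)
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_landmarks_json(path) -> list[LandmarkSet]:
    """Read an ibug68-v1 landmark file, validating the schema.

    Violations raise :class:`SchemaError` naming the offending frame index.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or doc.get("schema") != LANDMARK_SCHEMA:
        raise SchemaError(
            f"{path}: unknown landmark schema tag {doc.get('schema')!r} "
            f"(expected {LANDMARK_SCHEMA!r})"
        )
    frames = doc.get("frames")
    if not isinstance(frames, list):
        raise SchemaError(f"{path}: 'frames' must be a list")
    out = []
    for slot, frame in enumerate(frames):
        idx = frame.get("index", slot)
        pts = np.asarray(frame.get("points", []), dtype=float)
        if pts.shape != (68, 2):
            raise SchemaError(
                f"{path}: frame {idx}: expected 68 [x, y] points, got shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise SchemaError(f"{path}: frame {idx}: non-finite coordinates")
        out.append(LandmarkSet(pts))
    return out
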