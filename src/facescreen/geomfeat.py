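"""Geometric mouth-angle features from neutral and smile-apex frames.

Hypomimia ("masked face") reduces the amplitude of a smile, and in some
patients makes the two mouth corners move asymmetrically.  These effects are
quantified with angles built on the outer-lip landmarks of the normalized
face:

* the *characteristic triangle* of each mouth corner — corner angle at p48
  (resp. p54) subtended by the upper-lip center p51 and lower-lip center
  p57.  The change of these corner angles between a neutral (poker-face)
  frame and the smile apex is the main feature: a stiff mouth changes less.
* the signed *overall deviation* of the mouth axis p48->p54 from horizontal,
  and the signed per-side *corner deviations* relative to the mouth center
  (midpoint of p51 and p57) — auxiliary asymmetry features.

All angles are reported in degrees.  Signed angles use the image convention
(y grows downward): ``delta_overall > 0`` means the p54 corner sits lower
than p48 on screen, and a *positive* side deviation means the corner is
elevated above the mouth center.  Because the inputs are landmarks in the
canonical frame, every feature is invariant to rotation, translation and
uniform scaling of the raw video frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError
from .facenorm import LandmarkSet

# Outer-lip landmark indices used by the characteristic triangle.
LEFT_CORNER = 48   # subject's right corner (image left)
RIGHT_CORNER = 54
UPPER_LIP = 51
LOWER_LIP = 57

#: Fraction of the sequence start within which the neutral frame is sought
#: (subjects are instructed to hold a poker face before smiling).
NEUTRAL_WINDOW = 0.4


@dataclass(frozen=True)
class KeyFramePair:
    """Neutral and smile-apex frames selected from a landmark sequence."""

    neutral_index: int
    apex_index: int
    neutral_landmarks: LandmarkSet
    apex_landmarks: LandmarkSet
    degenerate: bool = False  # set when the sequence shows no mouth motion


@dataclass(frozen=True)
class MouthAngles:
    theta_left: float
    theta_right: float
    delta_overall: float
    dev_left: float
    dev_right: float


@dataclass(frozen=True)
class GeometricFeatures:
    """Per-subject geometric feature vector (all degrees)."""

    d_theta_left: float
    d_theta_right: float
    delta_overall_apex: float
    dev_left_apex: float
    dev_right_apex: float
    asym_apex: float

    FIELDS = (
        "d_theta_left", "d_theta_right", "delta_overall_apex",
        "dev_left_apex", "dev_right_apex", "asym_apex",
    )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELDS])


def _vec_angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise DegenerateGeometryError("zero-length vector in angle computation")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def mouth_width_ratio(landmarks: LandmarkSet) -> float:
    """Mouth width ||p54 - p48|| relative to the inter-ocular distance.

    A dimensionless, similarity-invariant measure of smile excursion used
    only to select key frames, keeping selection decoupled from the angle
    features being measured.
    """
    iod = landmarks.interocular()
    if iod < 1e-12:
        raise DegenerateGeometryError("zero inter-ocular distance")
    width = np.linalg.norm(landmarks[RIGHT_CORNER] - landmarks[LEFT_CORNER])
    return float(width / iod)


def select_key_frames(landmark_sequence: Sequence[LandmarkSet]) -> KeyFramePair:
    """Pick the neutral and smile-apex frames of a sequence.

    Neutral is the minimum mouth-width ratio within the first 40% of frames
    (the poker-face period); apex is the global maximum.  Ties break toward
    the earlier frame.  A sequence with no measurable mouth motion returns
    (first, last) flagged as degenerate.
    """
    n = len(landmark_sequence)
    if n < 2:
        raise ValueError(f"need at least 2 frames, got {n}")
    ratios = np.array([mouth_width_ratio(l) for l in landmark_sequence])
    if np.ptp(ratios) < 1e-12:
        return KeyFramePair(0, n - 1, landmark_sequence[0], landmark_sequence[-1],
                            degenerate=True)
    k = max(1, int(np.ceil(NEUTRAL_WINDOW * n)))
    neutral = int(np.argmin(ratios[:k]))
    apex = int(np.argmax(ratios))
    return KeyFramePair(neutral, apex,
                        landmark_sequence[neutral], landmark_sequence[apex])


def corner_angles(landmarks: LandmarkSet) -> tuple[float, float]:
    """Corner angles (degrees) of the mouth's characteristic triangles.

    theta_left is the angle at p48 between p48->p51 and p48->p57;
    theta_right the angle at p54 between p54->p51 and p54->p57.
    """
    p48, p54 = landmarks[LEFT_CORNER], landmarks[RIGHT_CORNER]
    p51, p57 = landmarks[UPPER_LIP], landmarks[LOWER_LIP]
    theta_left = _vec_angle_deg(p51 - p48, p57 - p48)
    theta_right = _vec_angle_deg(p51 - p54, p57 - p54)
    return theta_left, theta_right


def overall_deviation(landmarks: LandmarkSet) -> float:
    """Signed angle (degrees) of the mouth axis p48->p54 from horizontal."""
    d = landmarks[RIGHT_CORNER] - landmarks[LEFT_CORNER]
    if np.linalg.norm(d) < 1e-12:
        raise DegenerateGeometryError("coincident mouth corners")
    return float(np.degrees(np.arctan2(d[1], d[0])))


def side_deviations(landmarks: LandmarkSet) -> tuple[float, float]:
    """Signed elevation angles (degrees) of each corner above the mouth center.

    The mouth center C is the midpoint of p51 and p57; a positive value
    means the corner is higher (smaller y) than C.
    """
    c = 0.5 * (landmarks[UPPER_LIP] + landmarks[LOWER_LIP])
    out = []
    for corner_idx in (LEFT_CORNER, RIGHT_CORNER):
        p = landmarks[corner_idx]
        dx = np.abs(p[0] - c[0])  # horizontal reach toward the corner
        if np.hypot(p[0] - c[0], p[1] - c[1]) < 1e-12:
            raise DegenerateGeometryError("mouth corner coincides with mouth center")
        out.append(float(np.degrees(np.arctan2(-(p[1] - c[1]), dx))))
    return out[0], out[1]


def mouth_angles(landmarks: LandmarkSet) -> MouthAngles:
    tl, tr = corner_angles(landmarks)
    dl, dr = side_deviations(landmarks)
    return MouthAngles(tl, tr, overall_deviation(landmarks), dl, dr)


def geometric_feature_vector(pair: KeyFramePair) -> GeometricFeatures:
    """Assemble the subject-level geometric features from a key-frame pair:
    apex-minus-neutral corner-angle changes (main feature) plus the apex
    deviation angles and the absolute corner-elevation asymmetry (auxiliary).
    """
    tl_n, tr_n = corner_angles(pair.neutral_landmarks)
    tl_a, tr_a = corner_angles(pair.apex_landmarks)
    dl, dr = side_deviations(pair.apex_landmarks)
    return GeometricFeatures(
        d_theta_left=tl_a - tl_n,
        d_theta_right=tr_a - tr_n,
        delta_overall_apex=overall_deviation(pair.apex_landmarks),
        dev_left_apex=dl,
        dev_right_apex=dr,
        asym_apex=abs(dl - dr),
    )
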