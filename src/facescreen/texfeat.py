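"""HOG and LBP texture descriptors over eye and mouth regions.

Reduced expressive detail around the eyes and mouth is a texture phenomenon,
so the normalized face is described by two classical local descriptors
computed on two landmark-anchored regions of interest:

* **HOG** — orientation histograms of image gradients, accumulated in square
  cells, normalized over sliding blocks (L2-Hys).  Captures the local
  distribution of edge orientations.
* **Uniform LBP** — per-pixel circular neighbor comparisons mapped to the
  non-rotation-invariant uniform code set (59 codes for 8 neighbors),
  histogrammed over a grid of cells.  Captures micro-pattern statistics and
  is invariant to any strictly monotone intensity transform.

The subject-level texture feature is the concatenation
``[HOG_mouth, HOG_eyes, LBP_mouth, LBP_eyes]`` with a named layout so the
mouth-only and eye-only subsets can be sliced back out for region
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import DegenerateGeometryError
from .facenorm import NormalizedFace

# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RoiSpec:
    """A landmark-anchored region of interest on the normalized face."""

    region: str
    landmark_indices: tuple[int, ...]
    margin: float              # box expansion, fraction of box extent per side
    target_size: tuple[int, int]  # (width, height) of the resampled patch

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be >= 0")


@dataclass(frozen=True)
class HogParams:
    cell: int = 8              # cell side, pixels
    block: int = 2             # block side, cells
    bins: int = 9              # orientation bins
    signed: bool = False       # False: orientations folded into [0, 180)
    block_norm: str = "l2hys"
    clip: float = 0.2

    def __post_init__(self) -> None:
        if self.bins < 2 or self.block < 1 or self.cell < 1:
            raise ValueError("invalid HOG parameters")


@dataclass(frozen=True)
class LbpParams:
    neighbors: int = 8
    radius: float = 1.0
    mapping: str = "uniform"
    cell_grid: tuple[int, int] = (4, 8)  # (rows, cols)

    def __post_init__(self) -> None:
        if self.neighbors < 4 or self.radius < 1:
            raise ValueError("invalid LBP parameters")
        if self.mapping != "uniform":
            raise ValueError(f"unsupported LBP mapping {self.mapping!r}")

    @property
    def n_codes(self) -> int:
        p = self.neighbors
        return p * (p - 1) + 3  # uniform patterns + one non-uniform bin


#: Default ROIs: outer+inner lips and both eyes, sized to preserve the
#: aspect ratio of the corresponding canonical-face regions.
MOUTH_ROI = RoiSpec("mouth", tuple(range(48, 68)), 0.2, (64, 32))
EYES_ROI = RoiSpec("eyes", tuple(range(36, 48)), 0.25, (128, 32))
MOUTH_LBP = LbpParams(cell_grid=(4, 8))
EYES_LBP = LbpParams(cell_grid=(4, 16))


@dataclass(frozen=True)
class TextureFeatures:
    """Concatenated texture descriptor with a named slice layout."""

    vector: np.ndarray
    layout: dict = field(default_factory=dict)  # name -> slice

    def subset(self, region: str) -> np.ndarray:
        """Extract the concatenated HOG+LBP features of one region."""
        parts = [self.vector[sl] for name, sl in self.layout.items()
                 if name.endswith(f"_{region}")]
        if not parts:
            raise KeyError(f"no layout entries for region {region!r}")
        return np.concatenate(parts)


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

def extract_roi(face: NormalizedFace, spec: RoiSpec) -> np.ndarray:
    """Cut the ROI out of the normalized face and resample it bilinearly to
    ``spec.target_size``.  The box is the bounding box of the spec's
    landmarks, expanded by ``margin`` times the box extent on each side and
    clipped to the frame."""
    pts = face.landmarks.points[list(spec.landmark_indices)]
    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    if x1 - x0 < 1e-9 or y1 - y0 < 1e-9:
        raise DegenerateGeometryError(f"empty ROI box for region {spec.region!r}")
    mx, my = spec.margin * (x1 - x0), spec.margin * (y1 - y0)
    h, w = face.image.shape
    x0, x1 = max(0.0, x0 - mx), min(w - 1.0, x1 + mx)
    y0, y1 = max(0.0, y0 - my), min(h - 1.0, y1 + my)
    tw, th = spec.target_size
    xs = np.linspace(x0, x1, tw)
    ys = np.linspace(y0, y1, th)
    grid_y, grid_x = np.meshgrid(ys, xs, indexing="ij")
    return map_coordinates(np.asarray(face.image, dtype=float),
                           [grid_y, grid_x], order=1, mode="nearest")


# ---------------------------------------------------------------------------
# HOG
# ---------------------------------------------------------------------------

def hog_descriptor(patch: np.ndarray, params: HogParams = HogParams()) -> np.ndarray:
    """Histogram-of-oriented-gradients descriptor of a single patch.

    Gradients are centered finite differences; each pixel's magnitude is
    split linearly between the two orientation bins bracketing its gradient
    direction (circularly over [0, 180) unsigned or [0, 360) signed); cell
    histograms are normalized over sliding blocks with L2-Hys (clip then
    renormalize).  Output order is blocks row-major, then cells within the
    block row-major, then bins.
    """
    img = np.asarray(patch, dtype=float)
    h, w = img.shape
    if h % params.cell or w % params.cell:
        raise ValueError(f"patch shape {img.shape} not divisible by cell {params.cell}")
    gy, gx = np.gradient(img)
    mag = np.hypot(gx, gy)
    span = 360.0 if params.signed else 180.0
    ang = np.degrees(np.arctan2(gy, gx)) % span
    binw = span / params.bins
    pos = ang / binw - 0.5
    lo = np.floor(pos).astype(int)
    frac = pos - lo
    lo %= params.bins
    hi = (lo + 1) % params.bins

    ncy, ncx = h // params.cell, w // params.cell
    cells = np.zeros((ncy, ncx, params.bins))
    cy = (np.arange(h) // params.cell)[:, None] * np.ones((1, w), dtype=int)
    cxx = (np.arange(w) // params.cell)[None, :] * np.ones((h, 1), dtype=int)
    np.add.at(cells, (cy, cxx, lo), mag * (1 - frac))
    np.add.at(cells, (cy, cxx, hi), mag * frac)

    b = params.block
    nby, nbx = ncy - b + 1, ncx - b + 1
    if nby < 1 or nbx < 1:
        raise ValueError("patch too small for the requested block size")
    out = np.empty((nby, nbx, b * b * params.bins))
    for by in range(nby):
        for bx in range(nbx):
            v = cells[by:by + b, bx:bx + b].ravel()
            n = np.sqrt((v ** 2).sum() + 1e-12)
            v = v / n
            if params.block_norm == "l2hys":
                v = np.minimum(v, params.clip)
                n2 = np.sqrt((v ** 2).sum())
                if n2 > 1e-12:
                    v = v / n2
            out[by, bx] = v
    return out.ravel()


def hog_length(patch_shape: tuple[int, int], params: HogParams) -> int:
    h, w = patch_shape
    ncy, ncx = h // params.cell, w // params.cell
    return (ncy - params.block + 1) * (ncx - params.block + 1) \
        * params.block ** 2 * params.bins


# ---------------------------------------------------------------------------
# LBP
# ---------------------------------------------------------------------------

def _uniform_lookup(p: int) -> np.ndarray:
    """Map each of the 2**p raw codes to a uniform-pattern bin index.

    Uniform patterns (at most 2 circular 0/1 transitions) get consecutive
    indices in ascending code order; all non-uniform codes share the final
    bin, giving p*(p-1)+3 bins in total.
    """
    lut = np.empty(2 ** p, dtype=int)
    nxt = 0
    for code in range(2 ** p):
        bits = [(code >> k) & 1 for k in range(p)]
        transitions = sum(bits[k] != bits[(k + 1) % p] for k in range(p))
        if transitions <= 2:
            lut[code] = nxt
            nxt += 1
        else:
            lut[code] = -1
    lut[lut == -1] = nxt
    return lut


def lbp_codes(patch: np.ndarray, params: LbpParams = LbpParams()) -> np.ndarray:
    """Uniform LBP code image over the patch interior.

    Neighbors are sampled bilinearly on a circle of the given radius
    (neighbor k at angle 2*pi*k/P from the +x axis, counterclockwise in
    image terms, i.e. upward on screen); a bit is set when the neighbor is
    >= the center (ties set the bit, so flat regions give the all-ones
    code).  Border pixels closer than ``radius`` to the edge are excluded.
    """
    img = np.asarray(patch, dtype=float)
    r = int(np.ceil(params.radius))
    h, w = img.shape
    if h <= 2 * r or w <= 2 * r:
        raise ValueError(f"patch {img.shape} too small for radius {params.radius}")
    rows = np.arange(r, h - r)
    cols = np.arange(r, w - r)
    grid_y, grid_x = np.meshgrid(rows, cols, indexing="ij")
    center = img[r:h - r, r:w - r]
    codes = np.zeros_like(center, dtype=int)
    for k in range(params.neighbors):
        ang = 2 * np.pi * k / params.neighbors
        dx, dy = params.radius * np.cos(ang), -params.radius * np.sin(ang)
        # snap near-integer offsets to avoid epsilon-level interpolation error
        if abs(dx - round(dx)) < 1e-9:
            dx = round(dx)
        if abs(dy - round(dy)) < 1e-9:
            dy = round(dy)
        sample = map_coordinates(img, [grid_y + dy, grid_x + dx], order=1)
        # ties set the bit; the relative tolerance absorbs interpolation
        # round-off so exactly flat regions give the all-ones code
        bit = (sample - center) >= -1e-9 * (1.0 + np.abs(center))
        codes |= bit.astype(int) << k
    return codes


def lbp_descriptor(patch: np.ndarray, params: LbpParams = LbpParams()) -> np.ndarray:
    """Per-cell L1-normalized uniform-LBP histograms, concatenated row-major
    over the ``cell_grid``."""
    codes = lbp_codes(patch, params)
    lut = _uniform_lookup(params.neighbors)
    mapped = lut[codes]
    n_rows, n_cols = params.cell_grid
    h, w = mapped.shape
    row_edges = np.linspace(0, h, n_rows + 1).astype(int)
    col_edges = np.linspace(0, w, n_cols + 1).astype(int)
    hists = []
    for i in range(n_rows):
        for j in range(n_cols):
            cell = mapped[row_edges[i]:row_edges[i + 1],
                          col_edges[j]:col_edges[j + 1]]
            hist = np.bincount(cell.ravel(), minlength=params.n_codes).astype(float)
            total = hist.sum()
            if total > 0:
                hist /= total
            hists.append(hist)
    return np.concatenate(hists)


def lbp_length(params: LbpParams) -> int:
    return params.cell_grid[0] * params.cell_grid[1] * params.n_codes


# ---------------------------------------------------------------------------
# Subject-level texture vector
# ---------------------------------------------------------------------------

def texture_feature_vector(
    face: NormalizedFace,
    hog_params: HogParams = HogParams(),
    mouth_lbp: LbpParams = MOUTH_LBP,
    eyes_lbp: LbpParams = EYES_LBP,
    mouth_roi: RoiSpec = MOUTH_ROI,
    eyes_roi: RoiSpec = EYES_ROI,
) -> TextureFeatures:
    """Extract the full texture descriptor of a normalized face, in the
    fixed order [HOG_mouth, HOG_eyes, LBP_mouth, LBP_eyes]."""
    mouth = extract_roi(face, mouth_roi)
    eyes = extract_roi(face, eyes_roi)
    parts = {
        "hog_mouth": hog_descriptor(mouth, hog_params),
        "hog_eyes": hog_descriptor(eyes, hog_params),
        "lbp_mouth": lbp_descriptor(mouth, mouth_lbp),
        "lbp_eyes": lbp_descriptor(eyes, eyes_lbp),
    }
    layout = {}
    offset = 0
    for name, vec in parts.items():
        layout[name] = slice(offset, offset + len(vec))
        offset += len(vec)
    return TextureFeatures(np.concatenate(list(parts.values())), layout)
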