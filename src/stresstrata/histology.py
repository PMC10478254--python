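"""TUNEL positivity quantification from RGB brightfield images.

The chain mirrors the classic ImageJ workflow for DAB-stained sections with
a methyl-green counterstain: per-pixel optical densities are unmixed into
stain concentrations through the inverse of a stain-vector matrix
(Beer–Lambert colour deconvolution), each concentration channel is binarized
with the iterative intermeans (isodata) threshold, connected components are
filtered by area and circularity, and the positivity rate is the DAB count
over the total nucleus count.

Coordinate convention: images are indexed (row, col), origin top-left,
0-based.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Published optical-density triplet for brightfield DAB (Ruifrok-style basis).
DAB_OD = (0.26814753, 0.57031375, 0.77642715)
#: Methyl green absorbs mainly red; this unit triplet was fixed once from a
#: pure-stain synthetic calibration field and ships as the default.
METHYL_GREEN_OD = (0.87834, 0.33527, 0.34038)


class StainError(ValueError):
    """Invalid stain model (collinear or non-normalizable vectors)."""


@dataclass(frozen=True)
class StainModel:
    """Two (or three) unit-length optical-density stain vectors.

    The first vector is the positive stain (DAB for TUNEL), the second the
    counterstain. When only two are given, the residual third basis vector is
    the normalized cross product of the first two.
    """

    vectors: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        arr = np.asarray(self.vectors, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] not in (2, 3):
            raise StainError("stain model needs 2 or 3 OD triplets")
        if (arr < -1e-12).any():
            raise StainError("stain OD vectors must be non-negative")
        norms = np.linalg.norm(arr, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise StainError("stain OD vectors must have unit L2 norm")
        if np.linalg.norm(np.cross(arr[0], arr[1])) < 1e-8:
            raise StainError("first two stain vectors are collinear")

    @property
    def n_stains(self) -> int:
        return len(self.vectors)

    def basis(self) -> np.ndarray:
        """Full 3×3 basis with rows = stain OD vectors (residual appended)."""
        arr = np.asarray(self.vectors, dtype=float)
        if arr.shape[0] == 3:
            return arr
        third = np.cross(arr[0], arr[1])
        third = np.abs(third)  # residual stays in the non-negative octant
        third /= np.linalg.norm(third)
        return np.vstack([arr, third])


def normalized(v: Sequence[float]) -> tuple[float, float, float]:
    a = np.asarray(v, dtype=float)
    n = np.linalg.norm(a)
    if n == 0:
        raise StainError("cannot normalize zero vector")
    return tuple(a / n)


def default_stain_model() -> StainModel:
    """DAB + methyl green stain basis used by TUNEL quantification."""
    return StainModel((normalized(DAB_OD), normalized(METHYL_GREEN_OD)))


# --------------------------------------------------------------------------
# colour deconvolution


def color_deconvolve(image: np.ndarray, stains: StainModel) -> np.ndarray:
    """Unmix an 8-bit RGB image into per-stain concentration channels.

    Per pixel and colour channel c, OD_c = -log10(max(I_c, 1)/255); the OD
    vector is projected through the inverse of the stain basis and negative
    concentrations are clipped to 0.

    Returns an (H, W, n_stains) float array holding the declared stains'
    concentrations (the residual channel is dropped).
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    od = -np.log10(np.maximum(img.astype(float), 1.0) / 255.0)
    inv = np.linalg.inv(stains.basis())
    conc = od @ inv  # (H, W, 3) per-stain amplitudes
    conc = np.clip(conc, 0.0, None)
    return conc[..., : stains.n_stains]


# --------------------------------------------------------------------------
# isodata threshold


def isodata_threshold_value(channel: np.ndarray) -> float:
    """Iterative intermeans fixed point t = (mean(v <= t) + mean(v > t)) / 2."""
    v = np.asarray(channel, dtype=float).ravel()
    vmin, vmax = v.min(), v.max()
    if vmin == vmax:
        raise ValueError("constant channel: isodata threshold undefined")
    t = v.mean()
    for _ in range(500):
        low = v[v <= t]
        high = v[v > t]
        if low.size == 0 or high.size == 0:
            break
        t_new = 0.5 * (low.mean() + high.mean())
        if abs(t_new - t) < 1e-10:
            t = t_new
            break
        t = t_new
    return float(t)


def isodata_threshold(channel: np.ndarray) -> np.ndarray:
    """Binarize a concentration channel at its isodata fixed point (v > t*)."""
    t = isodata_threshold_value(channel)
    return np.asarray(channel, dtype=float) > t


# --------------------------------------------------------------------------
# particle analysis


@dataclass
class Particle:
    """A connected component kept by the size/shape filter."""

    pixels: np.ndarray  # (N, 2) row/col indices
    area_px2: int
    perimeter_px: float
    circularity: float
    centroid: tuple[float, float]


_EIGHT = np.ones((3, 3), dtype=int)

# Moore neighbourhood in clockwise order starting east: E SE S SW W NW N NE.
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
_STEP_LEN = [1.0, np.sqrt(2.0), 1.0, np.sqrt(2.0), 1.0, np.sqrt(2.0), 1.0, np.sqrt(2.0)]
_DELTA_TO_DIR = {d: i for i, d in enumerate(_MOORE)}


def _boundary_perimeter(mask: np.ndarray) -> float:
    """Chain-code length of the outer boundary (diagonal steps weigh √2).

    Moore-neighbour tracing with Jacob's stopping criterion (terminate on
    re-entering the start pixel along the start direction). The scan origin
    at each step is the background cell examined immediately before the
    previous move, which keeps the walk on the outer boundary. Hole
    boundaries are not counted; an isolated pixel has perimeter 0.
    """
    m = np.pad(np.asarray(mask, dtype=bool), 1)
    rows, cols = np.nonzero(m)
    if rows.size <= 1:
        return 0.0
    b = (int(rows[0]), int(cols[0]))  # uppermost-leftmost pixel
    back = 4  # west of the start pixel is guaranteed background
    first_move: tuple[tuple[int, int], int] | None = None
    perim = 0.0
    for _ in range(8 * m.size):
        for k in range(1, 9):
            d = (back + k) % 8
            nb = (b[0] + _MOORE[d][0], b[1] + _MOORE[d][1])
            if m[nb]:
                break
        else:
            return 0.0  # isolated pixel (cannot happen for size >= 2 comps)
        move = (b, d)
        if first_move is None:
            first_move = move
        elif move == first_move:
            return perim
        perim += _STEP_LEN[d]
        # background cell examined just before the move: new scan origin
        pk = (back + k - 1) % 8
        c = (b[0] + _MOORE[pk][0], b[1] + _MOORE[pk][1])
        back = _DELTA_TO_DIR[(c[0] - nb[0], c[1] - nb[1])]
        b = nb
    raise RuntimeError("boundary tracing failed to terminate")


def particle_analysis(
    mask: np.ndarray,
    min_area: int = 2000,
    circularity_range: tuple[float, float] = (0.1, 1.0),
) -> list[Particle]:
    """Count 8-connected particles passing the area and circularity filters.

    Circularity = min(1, 4π·area / perimeter²) with the chain-code perimeter
    rule; components whose perimeter degenerates to 0 (single pixels) get
    circularity 1 and are in practice removed by the area filter.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_EIGHT)
    lo, hi = circularity_range
    kept: list[Particle] = []
    slices = ndimage.find_objects(labels)
    for i, sl in enumerate(slices, start=1):
        comp = labels[sl] == i
        area = int(comp.sum())
        if area < min_area:
            continue
        perim = _boundary_perimeter(comp)
        circ = 1.0 if perim == 0 else min(1.0, 4.0 * np.pi * area / perim**2)
        if not (lo <= circ <= hi):
            continue
        rr, cc = np.nonzero(comp)
        rr = rr + sl[0].start
        cc = cc + sl[1].start
        kept.append(
            Particle(
                pixels=np.column_stack([rr, cc]),
                area_px2=area,
                perimeter_px=perim,
                circularity=circ,
                centroid=(float(rr.mean()), float(cc.mean())),
            )
        )
    return kept


# --------------------------------------------------------------------------
# rates


def tunel_positivity(tunel_particles: int, counterstain_particles: int) -> float:
    """Positivity rate = TUNEL-positive / (TUNEL-positive + counterstained)."""
    if tunel_particles < 0 or counterstain_particles < 0:
        raise ValueError("particle counts must be non-negative")
    total = tunel_particles + counterstain_particles
    if total == 0:
        raise ValueError("no particles in either channel: rate undefined")
    return tunel_particles / total


@dataclass
class FieldQuant:
    n_tunel_pos: int
    n_counterstain: int

    @property
    def positivity_rate(self) -> float:
        return tunel_positivity(self.n_tunel_pos, self.n_counterstain)


@dataclass
class QuantResult:
    """Per-field counts plus the case-level pooled positivity rate."""

    fields: list[FieldQuant]
    n_tunel_pos: int
    n_counterstain: int
    positivity_rate: float


@dataclass(frozen=True)
class QuantConfig:
    stains: StainModel = field(default_factory=default_stain_model)
    min_area: int = 2000
    circularity_range: tuple[float, float] = (0.1, 1.0)


def quantify_field(image: np.ndarray, config: QuantConfig | None = None) -> FieldQuant:
    """Deconvolve → threshold → count particles for both stain channels."""
    config = config or QuantConfig()
    conc = color_deconvolve(image, config.stains)
    counts = []
    for ch in range(2):
        mask = isodata_threshold(conc[..., ch])
        particles = particle_analysis(
            mask, min_area=config.min_area, circularity_range=config.circularity_range
        )
        counts.append(len(particles))
    return FieldQuant(n_tunel_pos=counts[0], n_counterstain=counts[1])


def quantify_case(
    fields: Sequence[np.ndarray], config: QuantConfig | None = None
) -> QuantResult:
    """Quantify a case from its captured fields (the study design uses six).

    The case-level positivity rate pools particle counts across fields.
    Fields whose channels cannot be thresholded (e.g. blank images) are
    skipped with a warning; if every field fails, an error is raised.
    """
    if len(fields) == 0:
        raise ValueError("quantify_case needs at least one field")
    config = config or QuantConfig()
    per_field: list[FieldQuant] = []
    for i, img in enumerate(fields):
        try:
            per_field.append(quantify_field(img, config))
        except ValueError as exc:
            warnings.warn(f"field {i} skipped: {exc}", stacklevel=2)
            logger.warning("field %d skipped: %s", i, exc)
    if not per_field:
        raise ValueError("all fields failed thresholding")
    n_t = sum(f.n_tunel_pos for f in per_field)
    n_c = sum(f.n_counterstain for f in per_field)
    return QuantResult(
        fields=per_field,
        n_tunel_pos=n_t,
        n_counterstain=n_c,
        positivity_rate=tunel_positivity(n_t, n_c),
    )
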