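"""Frontal silhouettes of vehicles as scaled binary occupancy grids.

The collision-probability model treats the approaching vehicle's trajectory as
a 2-D plane (width x height) in which the vehicle's frontal surface occupies a
subset of pixels.  The probability that an animal at a given lateral position
is struck is the occupied fraction of a body-length-wide, full-height vertical
strip of that plane (the *collision window*), under the assumption that the
animal may sit at any altitude within the trajectory.

This module provides:

* :class:`FrontalSilhouette` -- the occupancy grid plus physical scale;
* :func:`load_silhouette` -- read a grayscale image or 0/1 text grid;
* :func:`generate_parametric_silhouette` -- a deterministic, parametric
  stand-in for a digitized narrow-body airliner schematic (fuselage disk, two
  engine nacelles, wing and stabilizer bands, fin root);
* :func:`window_probability` -- the collision-window occupancy integral.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence, Union

import numpy as np

__all__ = [
    "FrontalSilhouette",
    "SilhouetteSpec",
    "SilhouetteError",
    "load_silhouette",
    "save_silhouette",
    "generate_parametric_silhouette",
    "length_to_pixels",
    "window_probability",
]

#: Grayscale pixels strictly darker than this fraction of full intensity are
#: treated as vehicle surface when loading an image mask.
DEFAULT_BINARIZATION_THRESHOLD = 0.5

_IMAGE_SUFFIXES = {".png", ".pgm", ".pbm", ".bmp", ".tif", ".tiff", ".jpg", ".jpeg"}


class SilhouetteError(ValueError):
    """Raised for unusable silhouette inputs (empty, ragged, out of canvas)."""


@dataclasses.dataclass(frozen=True)
class FrontalSilhouette:
    """Binary frontal-projection grid of a vehicle with physical scale.

    Parameters
    ----------
    mask
        2-D array of 0/1 values; rows index height (row 0 = top of the
        vehicle), columns index width (column 0 = left edge).
    width_m
        Physical width spanned by the grid's columns, in meters.
    height_m
        Physical height spanned by the grid's rows, in meters.  If omitted it
        is inferred from the row count assuming square pixels.
    """

    mask: np.ndarray
    width_m: float
    height_m: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 2:
            raise SilhouetteError(f"mask must be 2-D, got shape {mask.shape}")
        if not np.isin(mask, (0, 1)).all():
            raise SilhouetteError("mask must contain only 0 and 1")
        mask = np.ascontiguousarray(mask, dtype=np.uint8)
        if mask.sum() == 0:
            raise SilhouetteError("mask has no occupied pixel")
        if not self.width_m > 0:
            raise SilhouetteError("width_m must be positive")
        object.__setattr__(self, "mask", mask)
        if self.height_m is None:
            object.__setattr__(self, "height_m", mask.shape[0] * self.scale)
        # prefix sum of per-column occupied counts; padded so that
        # _colsum_cum[j] = occupied pixels in columns [0, j)
        cum = np.zeros(mask.shape[1] + 1, dtype=np.int64)
        np.cumsum(mask.sum(axis=0, dtype=np.int64), out=cum[1:])
        object.__setattr__(self, "_colsum_cum", cum)
        self.mask.setflags(write=False)

    # -- geometry ---------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.mask.shape[0]

    @property
    def n_cols(self) -> int:
        return self.mask.shape[1]

    @property
    def scale(self) -> float:
        """Meters per pixel along the width axis."""
        return self.width_m / self.mask.shape[1]

    @property
    def frontal_area_m2(self) -> float:
        """Physical frontal surface area: occupied pixels x scale^2."""
        return float(self.mask.sum()) * self.scale**2

    def occupancy_profile(self) -> np.ndarray:
        """Occupied fraction of each pixel column (length ``n_cols``)."""
        return self.mask.mean(axis=0)

    def window_probability(self, d_collision, l: float):
        return window_probability(self, d_collision, l)


def length_to_pixels(l: float, s: FrontalSilhouette) -> int:
    """Animal body length in whole pixels on silhouette ``s`` (minimum 1)."""
    if not l > 0:
        raise ValueError("body length must be positive")
    return max(1, int(round(l / s.scale)))


def window_probability(
    s: FrontalSilhouette,
    d_collision: Union[float, np.ndarray],
    l: float,
):
    """Collision probability for an animal centered at ``d_collision``.

    The collision window spans ``[d_collision - l/2, d_collision + l/2]`` on
    the width axis and the full trajectory height.  The window is discretized
    to exactly ``length_to_pixels(l, s)`` columns centered on the column
    nearest ``d_collision`` (left-biased by one column for even widths), and
    the returned probability is the occupied fraction of those columns.
    Columns falling outside the grid contribute zero occupancy but stay in
    the denominator, so the probability decays smoothly to 0 as the window
    slides off either edge of the trajectory.

    Accepts a scalar or an array of positions; returns the matching shape.
    """
    if not l > 0:
        raise ValueError("body length must be positive")
    w = length_to_pixels(l, s)
    d = np.asarray(d_collision, dtype=float)
    # column whose center is nearest d (column j has center (j + 0.5) * scale)
    center = np.rint(d / s.scale - 0.5).astype(np.int64)
    start = center - w // 2
    stop = start + w
    cum = s._colsum_cum  # type: ignore[attr-defined]
    nc = s.n_cols
    occupied = cum[np.clip(stop, 0, nc)] - cum[np.clip(start, 0, nc)]
    p = occupied / (w * s.n_rows)
    if np.isscalar(d_collision) or np.ndim(d_collision) == 0:
        return float(p)
    return p


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_silhouette(
    path: Union[str, Path],
    width_m: float,
    height_m: float = None,
    threshold: float = DEFAULT_BINARIZATION_THRESHOLD,
) -> FrontalSilhouette:
    """Load a silhouette mask from an image or a plain-text 0/1 grid.

    Image files (by suffix: png/pgm/bmp/tif/jpg) are converted to grayscale
    and binarized: pixels strictly darker than ``threshold`` of full
    intensity count as vehicle surface.  Any other suffix is parsed as a
    text grid of whitespace-separated 0/1 values, one row per line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _IMAGE_SUFFIXES:
        from PIL import Image

        with Image.open(path) as img:
            gray = np.asarray(img.convert("L"), dtype=float) / 255.0
        mask = (gray < threshold).astype(np.uint8)
    else:
        rows = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if line:
                rows.append([int(tok) for tok in line.split()])
        if not rows:
            raise SilhouetteError(f"{path}: empty grid file")
        if len({len(r) for r in rows}) != 1:
            raise SilhouetteError(f"{path}: ragged (non-rectangular) grid")
        mask = np.array(rows, dtype=np.uint8)
    return FrontalSilhouette(mask=mask, width_m=width_m, height_m=height_m)


def save_silhouette(s: FrontalSilhouette, path: Union[str, Path]) -> None:
    """Write the mask to disk (PNG/PGM image or text 0/1 grid, by suffix)."""
    path = Path(path)
    if path.suffix.lower() in _IMAGE_SUFFIXES:
        from PIL import Image

        # occupied pixels black, background white
        img = Image.fromarray(((1 - s.mask) * 255).astype(np.uint8), mode="L")
        img.save(path)
    else:
        np.savetxt(path, s.mask, fmt="%d")


# ---------------------------------------------------------------------------
# Parametric generator
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SilhouetteSpec:
    """Shape parameters for a parametric narrow-body airliner frontal view.

    All dimensions are meters.  Heights are measured from the bottom edge of
    the canvas (y = 0) upward.  The default values describe a gear-up
    737-class airframe cropped to the core strike-relevant extent: the span
    between the horizontal-stabilizer tips (14.35 m) by the height from the
    engine-nacelle underside to the fuselage crown / fin root (4.3 m).
    Components with a zero size are omitted; disks and extra rectangles must
    fit inside the canvas, while the wing and stabilizer bands (structures
    that physically continue past the crop) are clipped at the canvas edges.
    """

    width_m: float = 14.35
    height_m: float = 4.3
    fuselage_diameter: float = 3.76
    fuselage_center_height: float = 2.38
    engine_diameter: float = 2.00
    engine_offset: float = 4.85  # nacelle center to fuselage centerline
    engine_center_height: float = 1.00
    wing_thickness: float = 0.40
    wing_root_height: float = 2.30
    wing_dihedral_deg: float = 6.0
    stabilizer_thickness: float = 0.30
    stabilizer_root_height: float = 3.40
    stabilizer_dihedral_deg: float = 7.0
    fin_width: float = 0.80
    fin_root_height: float = 3.90
    rectangles: Sequence[tuple] = ()  # extra (x0, x1, y0, y1) boxes, meters


def _require_inside(name: str, ok: bool) -> None:
    if not ok:
        raise SilhouetteError(f"{name} extends outside the canvas")


def generate_parametric_silhouette(
    spec: SilhouetteSpec = SilhouetteSpec(),
    resolution: int = 1031,
) -> FrontalSilhouette:
    """Rasterize ``spec`` into a deterministic binary silhouette.

    ``resolution`` is the pixel count across the canvas width; rows follow
    from square pixels.  The same spec and resolution always produce the
    bit-identical mask.  With fuselage and engines present and laterally
    disjoint, the column occupancy profile is trimodal (engine-fuselage-
    engine peaks), mirroring the multimodal strike-probability pattern of a
    real airliner front view.
    """
    if not (spec.width_m > 0 and spec.height_m > 0):
        raise SilhouetteError("canvas dimensions must be positive")
    if resolution < 2:
        raise SilhouetteError("resolution must be at least 2 pixels")
    scale = spec.width_m / resolution
    n_rows = max(1, int(round(spec.height_m / scale)))
    # pixel-center coordinates; row 0 is the top of the canvas
    x = (np.arange(resolution) + 0.5) * scale
    y = spec.height_m - (np.arange(n_rows) + 0.5) * scale
    X, Y = np.meshgrid(x, y)
    cx = spec.width_m / 2.0
    occ = np.zeros((n_rows, resolution), dtype=bool)

    def disk(name: str, cx_d: float, cy_d: float, diameter: float) -> None:
        r = diameter / 2.0
        _require_inside(
            name,
            cx_d - r >= 0 and cx_d + r <= spec.width_m
            and cy_d - r >= 0 and cy_d + r <= spec.height_m,
        )
        occ[:] |= (X - cx_d) ** 2 + (Y - cy_d) ** 2 <= r**2

    def band(root: float, thickness: float, dihedral_deg: float) -> None:
        # thin full-span band rising from the root at the centerline outward
        lower = root + math.tan(math.radians(dihedral_deg)) * np.abs(X - cx)
        occ[:] |= (Y >= lower) & (Y <= lower + thickness)

    if spec.fuselage_diameter > 0:
        disk("fuselage", cx, spec.fuselage_center_height, spec.fuselage_diameter)
    if spec.engine_diameter > 0:
        for side in (-1.0, 1.0):
            disk(
                "engine",
                cx + side * spec.engine_offset,
                spec.engine_center_height,
                spec.engine_diameter,
            )
    if spec.wing_thickness > 0:
        band(spec.wing_root_height, spec.wing_thickness, spec.wing_dihedral_deg)
    if spec.stabilizer_thickness > 0:
        band(
            spec.stabilizer_root_height,
            spec.stabilizer_thickness,
            spec.stabilizer_dihedral_deg,
        )
    if spec.fin_width > 0:
        occ[:] |= (np.abs(X - cx) <= spec.fin_width / 2.0) & (Y >= spec.fin_root_height)
    for i, (x0, x1, y0, y1) in enumerate(spec.rectangles):
        _require_inside(
            f"rectangle {i}",
            0 <= x0 < x1 <= spec.width_m and 0 <= y0 < y1 <= spec.height_m,
        )
        occ[:] |= (X >= x0) & (X <= x1) & (Y >= y0) & (Y <= y1)

    if not occ.any():
        raise SilhouetteError("spec produced an empty mask (all components absent)")
    return FrontalSilhouette(
        mask=occ.astype(np.uint8), width_m=spec.width_m, height_m=spec.height_m
    )
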