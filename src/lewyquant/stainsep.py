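"""Stain separation and region tiling for hematoxylin/DAB brightfield tiles.

Brightfield stains mix multiplicatively in transmitted intensity and hence
additively in optical density (Beer-Lambert): ``OD_c = -log10(I_c / I0_c)``
per RGB channel ``c``.  Each stain absorbs with a characteristic unit
direction in OD space, so a pixel's 3-vector of optical densities is a
non-negative combination of the hematoxylin direction, the DAB direction and
a residual direction.  Color deconvolution inverts that 3x3 mixing matrix to
recover per-stain OD maps; the DAB map carries the immunohistochemical
signal of interest.

Annotated regions are processed in square tiles (default 4096 px, i.e.
roughly 900x900 um^2 at 0.22 um/px) to bound memory; :func:`tile_annotation`
produces the half-open tile grid over an annotation polygon together with
exact in-annotation pixel counts so that covered-area denominators can use
true region areas even for partial edge tiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.geometry import box as _box

__all__ = [
    "StainVectorSet",
    "ODImage",
    "Tile",
    "TileGrid",
    "deconvolve",
    "to_grayscale",
    "tile_annotation",
    "DEFAULT_OD_SCALE",
]

# Fixed OD value mapped to 1.0 by to_grayscale. Global (not per-image) so
# classifier inputs are comparable across tiles.
DEFAULT_OD_SCALE = 2.0

#: Ruifrok-Johnston style unit absorbance directions for an H-DAB stain pair.
_HEMATOXYLIN = np.array([0.650, 0.704, 0.286])
_DAB = np.array([0.268, 0.570, 0.776])

_MAX_CONDITION_NUMBER = 1e3


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero stain vector")
    return v / n


@dataclass(frozen=True)
class StainVectorSet:
    """Unit OD direction vectors for hematoxylin, DAB and a residual channel.

    The residual channel defaults to the normalized cross product of the two
    stain vectors, which completes an invertible basis.  ``i0`` is the
    per-channel transmitted intensity of unstained background (255 for 8-bit
    scans).
    """

    hematoxylin: np.ndarray = field(default_factory=lambda: _HEMATOXYLIN.copy())
    dab: np.ndarray = field(default_factory=lambda: _DAB.copy())
    residual: np.ndarray | None = None
    i0: float = 255.0

    def __post_init__(self) -> None:
        h = _unit(self.hematoxylin)
        d = _unit(self.dab)
        r = self.residual
        if r is None:
            r = np.cross(h, d)
        r = _unit(r)
        object.__setattr__(self, "hematoxylin", h)
        object.__setattr__(self, "dab", d)
        object.__setattr__(self, "residual", r)
        cond = np.linalg.cond(self.matrix)
        if not np.isfinite(cond) or cond > _MAX_CONDITION_NUMBER:
            raise ValueError(
                f"stain matrix is ill-conditioned (cond={cond:.3g} > {_MAX_CONDITION_NUMBER:g})"
            )

    @property
    def matrix(self) -> np.ndarray:
        """3x3 mixing matrix with one stain direction per row (H, DAB, residual)."""
        return np.stack([self.hematoxylin, self.dab, self.residual])

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def stain_index(self, stain: str) -> int:
        order = {"hematoxylin": 0, "dab": 1, "residual": 2}
        if stain not in order:
            raise ValueError(f"unknown stain channel {stain!r}")
        return order[stain]


@dataclass(frozen=True)
class ODImage:
    """A per-pixel optical-density map for one stain channel."""

    values: np.ndarray  # H x W, >= 0, finite
    stain: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("ODImage expects a 2-D array")
        if not np.all(np.isfinite(v)):
            raise ValueError("ODImage values must be finite")
        if v.size and v.min() < 0:
            raise ValueError("ODImage values must be non-negative")
        object.__setattr__(self, "values", v)


def rgb_to_od(image: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Convert an 8-bit RGB image to per-channel optical densities.

    Intensities are floored at 1 before the log so fully opaque pixels map to
    a finite OD of ``log10(i0)`` instead of infinity.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    arr = np.maximum(arr.astype(float), 1.0)
    return -np.log10(arr / float(i0))


def od_to_rgb(od_stack: np.ndarray, vectors: StainVectorSet) -> np.ndarray:
    """Forward Beer-Lambert model: stain OD maps -> quantized 8-bit RGB.

    ``od_stack`` is H x W x 3 with per-stain OD in the order (hematoxylin,
    DAB, residual).  This is the synthesis counterpart of :func:`deconvolve`
    and is used by the synthetic tile generator.
    """
    od_rgb = np.asarray(od_stack, dtype=float) @ vectors.matrix
    transmitted = vectors.i0 * np.power(10.0, -od_rgb)
    return np.clip(np.round(transmitted), 0, 255).astype(np.uint8)


def deconvolve(
    image: np.ndarray,
    vectors: StainVectorSet | None = None,
    stain: str = "dab",
) -> ODImage:
    """Unmix an RGB tile into a single stain's optical-density map.

    Per-channel OD is computed with an intensity floor of 1, unmixed by the
    inverse stain matrix, and negative unmixed values (noise outside the
    stain simplex) are clipped to zero.
    """
    vectors = vectors or StainVectorSet()
    od = rgb_to_od(image, i0=vectors.i0)
    unmixed = od @ vectors.inverse
    values = np.clip(unmixed[..., vectors.stain_index(stain)], 0.0, None)
    return ODImage(values=values, stain=stain)


def to_grayscale(od: ODImage, scale: float = DEFAULT_OD_SCALE) -> np.ndarray:
    """Monotone rescaling of an OD map to [0, 1] by a fixed global constant.

    OD ``scale`` (default 2.0) and above saturate at 1.0.  The constant is
    deliberately not per-image so tiles remain comparable as classifier
    inputs.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    return np.clip(od.values / scale, 0.0, 1.0)


@dataclass(frozen=True)
class Tile:
    """One half-open tile window [x0, x0+width) x [y0, y0+height)."""

    x0: int
    y0: int
    width: int
    height: int
    annotation_pixels: int
    partial: bool

    @property
    def bounds(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.x0 + self.width, self.y0 + self.height)


@dataclass(frozen=True)
class TileGrid:
    tiles: tuple[Tile, ...]
    tile_size: int
    total_annotation_pixels: int

    def __len__(self) -> int:
        return len(self.tiles)


def _count_pixels(geometry: BaseGeometry, x0: int, y0: int, w: int, h: int) -> int:
    """Count pixels in the window whose centers lie inside the geometry."""
    window = _box(x0, y0, x0 + w, y0 + h)
    if not geometry.intersects(window):
        return 0
    if geometry.contains(window):
        return w * h
    xs = x0 + 0.5 + np.arange(w)
    ys = y0 + 0.5 + np.arange(h)
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(geometry, gx.ravel(), gy.ravel())
    return int(inside.sum())


def tile_annotation(geometry: BaseGeometry, tile_size: int = 4096) -> TileGrid:
    """Cover an annotation polygon with a half-open tile grid.

    The grid is anchored at the floor of the annotation bounding box and
    truncated at its ceiling, so edge tiles may be smaller than
    ``tile_size``; they are retained and flagged ``partial`` together with
    their true in-annotation pixel counts (pixel-center-in-polygon rule).
    Tiles containing no annotation pixel are dropped.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    if geometry is None or geometry.is_empty:
        raise ValueError("empty annotation geometry")
    minx, miny, maxx, maxy = geometry.bounds
    x_lo, y_lo = int(np.floor(minx)), int(np.floor(miny))
    x_hi, y_hi = int(np.ceil(maxx)), int(np.ceil(maxy))
    tiles: list[Tile] = []
    total = 0
    for y0 in range(y_lo, y_hi, tile_size):
        h = min(tile_size, y_hi - y0)
        for x0 in range(x_lo, x_hi, tile_size):
            w = min(tile_size, x_hi - x0)
            n_px = _count_pixels(geometry, x0, y0, w, h)
            if n_px == 0:
                continue
            partial = (w < tile_size) or (h < tile_size) or (n_px < w * h)
            tiles.append(Tile(x0, y0, w, h, n_px, partial))
            total += n_px
    if not tiles:
        raise ValueError("annotation contains no pixel centers")
    return TileGrid(tiles=tuple(tiles), tile_size=tile_size, total_annotation_pixels=total)
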