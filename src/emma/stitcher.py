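"""Pairwise tile registration and global mosaic layout (translation-only).

Adjacent tiles are registered by phase correlation on their nominal overlap
strips (mean-subtracted, Hann-windowed), with sub-pixel refinement by
quadratic peak interpolation.  Low-confidence pairs fall back to the nominal
grid offset.  Global positions come from a weighted linear least-squares
solve over all pairwise offsets, anchored at tile (0, 0).

Coordinate frame: x grows rightward (columns), y grows downward (rows),
origin at the top-left pixel, 0-based.  ``dx_px/dy_px`` of a :class:`PairOffset`
is the position of tile ``b`` relative to tile ``a`` in this frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, StitchError
from .flatfield import FlatfieldParams, apply_flatfield

log = logging.getLogger("emma.stitcher")

TileId = Tuple[int, int]

#: weight assigned to rejected (fallback-to-nominal) pairs in the global solve
REJECTED_WEIGHT = 1e-3


@dataclass
class Tile:
    """One grid-positioned raw image with acquisition metadata."""

    pixels: np.ndarray
    row: int
    col: int
    nominal_overlap: float = 0.3
    pixel_size_nm: float = 1.0

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ConfigurationError("tile pixels must be a 2-D grayscale array")
        if self.pixel_size_nm <= 0:
            raise ConfigurationError("pixel_size_nm must be positive")

    @property
    def id(self) -> TileId:
        return (self.row, self.col)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class PairOffset:
    """Measured translation between two adjacent tiles.

    ``status == "rejected"`` means the correlation was not trusted and
    ``dx_px/dy_px`` carry the nominal grid offset instead.
    """

    a: TileId
    b: TileId
    dx_px: float
    dy_px: float
    score: float
    status: str = "accepted"
    peak_ratio: float = float("inf")


@dataclass
class MosaicLayout:
    """Globally consistent absolute tile positions on a common canvas."""

    positions: Dict[TileId, Tuple[float, float]]
    canvas_width: int
    canvas_height: int

    def normalized(self) -> "MosaicLayout":
        """Translate positions so the minimum is exactly (0, 0)."""
        xs = [p[0] for p in self.positions.values()]
        ys = [p[1] for p in self.positions.values()]
        x0, y0 = min(xs), min(ys)
        pos = {k: (x - x0, y - y0) for k, (x, y) in self.positions.items()}
        return MosaicLayout(pos, self.canvas_width, self.canvas_height)


@dataclass
class StitchParams:
    search_px: int = 16
    score_threshold: float = 0.3
    min_peak_ratio: float = 1.5
    integer_offsets: bool = False
    flatfield: Optional[FlatfieldParams] = None


def nominal_step(tile_extent: int, overlap_fraction: float) -> int:
    """Grid step in pixels implied by the tile extent and overlap fraction."""
    if not 0 < overlap_fraction < 0.9:
        raise ConfigurationError("overlap_fraction must lie in (0, 0.9)")
    return int(round(tile_extent * (1.0 - overlap_fraction)))


def _hann2d(shape: Tuple[int, int]) -> np.ndarray:
    wy = np.hanning(shape[0]) if shape[0] > 1 else np.ones(1)
    wx = np.hanning(shape[1]) if shape[1] > 1 else np.ones(1)
    return np.outer(wy, wx)


def _phase_correlation_surface(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """fftshift-ed phase-correlation surface of two equally shaped strips.

    The peak sits at shift ``t`` such that ``b(p) ~= a(p + t)``, with ``t``
    measured from the surface centre after the shift.
    """
    a = a.astype(np.float64)
    b = b.astype(np.float64)
    a = (a - a.mean()) * _hann2d(a.shape)
    b = (b - b.mean()) * _hann2d(b.shape)
    fa = np.fft.fft2(a)
    fb = np.fft.fft2(b)
    cross = fa * np.conj(fb)
    denom = np.abs(cross)
    denom[denom < 1e-12] = 1e-12
    surface = np.real(np.fft.ifft2(cross / denom))
    return np.fft.fftshift(surface)


def _ncc_at_shift(a: np.ndarray, b: np.ndarray, ty: int, tx: int) -> float:
    """Pearson correlation of the overlap of ``a`` and ``b`` for ``b = a(p+t)``."""
    h, w = a.shape
    ay0, ay1 = max(ty, 0), min(h, h + ty)
    ax0, ax1 = max(tx, 0), min(w, w + tx)
    if ay1 - ay0 < 2 or ax1 - ax0 < 2:
        return -1.0
    pa = a[ay0:ay1, ax0:ax1].astype(np.float64)
    pb = b[ay0 - ty:ay1 - ty, ax0 - tx:ax1 - tx].astype(np.float64)
    pa = pa - pa.mean()
    pb = pb - pb.mean()
    denom = np.sqrt((pa * pa).sum() * (pb * pb).sum())
    if denom < 1e-12:
        return -1.0
    return float((pa * pb).sum() / denom)


def _quadratic_subpixel(c_minus: float, c0: float, c_plus: float) -> float:
    """1-D sub-pixel offset of a peak from three samples around it."""
    denom = c_minus - 2.0 * c0 + c_plus
    if abs(denom) < 1e-12:
        return 0.0
    delta = 0.5 * (c_minus - c_plus) / denom
    return float(np.clip(delta, -0.5, 0.5))


def _overlap_strips(a: Tile, b: Tile, relation: str) -> Tuple[np.ndarray, np.ndarray, int, int]:
    """Nominal overlap strips of the two tiles plus the nominal offset (dx, dy)."""
    if relation == "right":
        step = nominal_step(a.width, a.nominal_overlap)
        ov = a.width - step
        if ov < 1:
            raise ConfigurationError("nominal overlap strip is empty")
        return a.pixels[:, a.width - ov:], b.pixels[:, :ov], step, 0
    if relation == "below":
        step = nominal_step(a.height, a.nominal_overlap)
        ov = a.height - step
        if ov < 1:
            raise ConfigurationError("nominal overlap strip is empty")
        return a.pixels[a.height - ov:, :], b.pixels[:ov, :], 0, step
    raise ConfigurationError(f"unknown relation {relation!r} (expected 'right' or 'below')")


def estimate_pair_offset(
    a: Tile,
    b: Tile,
    relation: str,
    search_px: int = 16,
    score_threshold: float = 0.3,
    min_peak_ratio: float = 1.5,
    subpixel: bool = True,
) -> PairOffset:
    """Measure the translation of tile ``b`` relative to tile ``a``.

    The integer peak of the phase-correlation surface is searched within
    ``+-search_px`` of the nominal grid offset; ties are broken toward the
    smallest displacement from nominal.  The returned ``score`` is the
    normalized cross-correlation of the overlap at the integer peak, clipped
    to [0, 1].  Featureless strips or an untrusted peak yield a rejected
    offset carrying the nominal grid offset — never an exception.
    """
    strip_a, strip_b, nom_dx, nom_dy = _overlap_strips(a, b, relation)
    nominal = PairOffset(a.id, b.id, float(nom_dx), float(nom_dy), 0.0, "rejected", 0.0)

    if float(strip_a.std()) < 1e-9 or float(strip_b.std()) < 1e-9:
        return nominal

    surface = _phase_correlation_surface(strip_a, strip_b)
    cy, cx = surface.shape[0] // 2, surface.shape[1] // 2
    ry = min(search_px, cy)
    rx = min(search_px, cx)
    window = surface[cy - ry:cy + ry + 1, cx - rx:cx + rx + 1]

    # the phase peak is spread over a small lobe by windowing and sub-pixel
    # content; a light smoothing consolidates it for peak finding and the
    # peak-ratio confidence test
    smoothed = ndimage.gaussian_filter(window, sigma=1.0, mode="nearest")

    # argmax with ties broken toward the smallest displacement from nominal
    flat = smoothed.ravel()
    best = flat.max()
    ties = np.flatnonzero(flat >= best - 1e-12)
    tys, txs = np.unravel_index(ties, smoothed.shape)
    dist = (tys - ry) ** 2 + (txs - rx) ** 2
    pick = int(np.argmin(dist))
    py, px = int(tys[pick]), int(txs[pick])

    # peak ratio against the strongest competitor outside the main lobe
    masked = smoothed.copy()
    masked[max(py - 3, 0):py + 4, max(px - 3, 0):px + 4] = -np.inf
    second = float(masked.max()) if np.isfinite(masked).any() else -np.inf
    peak = float(smoothed[py, px])
    if second <= 1e-12:
        ratio = float("inf")
    else:
        ratio = peak / second

    # the final integer offset maximizes the normalized cross-correlation in
    # a small neighbourhood of the phase-correlation peak
    r_nb = 2
    ncc: Dict[Tuple[int, int], float] = {}
    for dy in range(-r_nb, r_nb + 1):
        for dx in range(-r_nb, r_nb + 1):
            ty, tx = py - ry + dy, px - rx + dx
            if abs(ty) <= ry and abs(tx) <= rx:
                ncc[(ty, tx)] = _ncc_at_shift(strip_a, strip_b, ty, tx)
    ty, tx = max(ncc, key=lambda k: (ncc[k], -(k[0] ** 2 + k[1] ** 2)))
    score = max(0.0, ncc[(ty, tx)])

    if score < score_threshold or ratio < min_peak_ratio:
        return replace(nominal, score=score, peak_ratio=ratio)

    sy, sx = float(ty), float(tx)
    if subpixel:
        c0 = ncc[(ty, tx)]
        up = ncc.get((ty - 1, tx), _ncc_at_shift(strip_a, strip_b, ty - 1, tx))
        down = ncc.get((ty + 1, tx), _ncc_at_shift(strip_a, strip_b, ty + 1, tx))
        left = ncc.get((ty, tx - 1), _ncc_at_shift(strip_a, strip_b, ty, tx - 1))
        right = ncc.get((ty, tx + 1), _ncc_at_shift(strip_a, strip_b, ty, tx + 1))
        sy += _quadratic_subpixel(up, c0, down)
        sx += _quadratic_subpixel(left, c0, right)

    return PairOffset(a.id, b.id, nom_dx + sx, nom_dy + sy, score, "accepted", ratio)


def solve_layout(
    offsets: List[PairOffset],
    rows: int,
    cols: int,
    tile_shape: Tuple[int, int],
) -> MosaicLayout:
    """Weighted least-squares tile positions from pairwise offsets.

    Weights are the pair scores (rejected pairs get a small epsilon so the
    graph stays connected through the nominal fallback).  Tile (0, 0) anchors
    the gauge; the result is then translated so the minimum position is (0, 0).
    """
    if rows < 1 or cols < 1:
        raise ConfigurationError("grid must have at least one row and column")
    ids = [(r, c) for r in range(rows) for c in range(cols)]
    index = {tid: i for i, tid in enumerate(ids)}
    n = len(ids)
    th, tw = tile_shape

    if n == 1:
        return MosaicLayout({ids[0]: (0.0, 0.0)}, tw, th)

    for off in offsets:
        if off.a not in index or off.b not in index:
            raise ConfigurationError(f"offset references unknown tile {off.a} or {off.b}")

    # connectivity check (rejected pairs still connect via their fallback offset)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for off in offsets:
        ia, ib = find(index[off.a]), find(index[off.b])
        parent[ia] = ib
    if len({find(i) for i in range(n)}) != 1:
        raise ConfigurationError("tile adjacency graph is disconnected")

    m = len(offsets)
    rows_a = np.zeros((m + 1, n))
    bx = np.zeros(m + 1)
    by = np.zeros(m + 1)
    w = np.zeros(m + 1)
    for k, off in enumerate(offsets):
        rows_a[k, index[off.b]] = 1.0
        rows_a[k, index[off.a]] = -1.0
        bx[k] = off.dx_px
        by[k] = off.dy_px
        w[k] = max(off.score, REJECTED_WEIGHT) if off.status == "accepted" else REJECTED_WEIGHT
    # gauge: anchor tile (0,0) at the origin with a dominant weight
    rows_a[m, index[(0, 0)]] = 1.0
    w[m] = 1e6

    sw = np.sqrt(w)[:, None]
    aw = rows_a * sw
    px = np.linalg.lstsq(aw, bx * sw[:, 0], rcond=None)[0]
    py = np.linalg.lstsq(aw, by * sw[:, 0], rcond=None)[0]

    positions = {tid: (float(px[i]), float(py[i])) for tid, i in index.items()}
    layout = MosaicLayout(positions, 0, 0).normalized()
    xs = [p[0] for p in layout.positions.values()]
    ys = [p[1] for p in layout.positions.values()]
    layout.canvas_width = int(np.ceil(max(xs) + tw))
    layout.canvas_height = int(np.ceil(max(ys) + th))
    return layout


def grid_adjacencies(rows: int, cols: int) -> List[Tuple[TileId, TileId, str]]:
    """Every horizontal ('right') and vertical ('below') tile adjacency."""
    pairs: List[Tuple[TileId, TileId, str]] = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                pairs.append(((r, c), (r, c + 1), "right"))
            if r + 1 < rows:
                pairs.append(((r, c), (r + 1, c), "below"))
    return pairs


def stitch(
    tiles: List[Tile],
    rows: int,
    cols: int,
    params: Optional[StitchParams] = None,
) -> Tuple[MosaicLayout, List[PairOffset]]:
    """Full stitching pass: optional flat-field, pairwise offsets, global solve."""
    params = params or StitchParams()
    by_id = {t.id: t for t in tiles}
    if len(by_id) != len(tiles):
        raise ConfigurationError("duplicate grid indices in tile list")
    missing = [tid for tid in ((r, c) for r in range(rows) for c in range(cols)) if tid not in by_id]
    if missing:
        raise StitchError(f"incomplete grid, missing tiles: {missing[:5]}")

    if params.flatfield is not None:
        by_id = {
            tid: replace(t, pixels=apply_flatfield(t.pixels, params.flatfield))
            for tid, t in by_id.items()
        }

    offsets: List[PairOffset] = []
    for a_id, b_id, relation in grid_adjacencies(rows, cols):
        off = estimate_pair_offset(
            by_id[a_id],
            by_id[b_id],
            relation,
            search_px=params.search_px,
            score_threshold=params.score_threshold,
            min_peak_ratio=params.min_peak_ratio,
            subpixel=not params.integer_offsets,
        )
        if params.integer_offsets:
            off = replace(off, dx_px=float(round(off.dx_px)), dy_px=float(round(off.dy_px)))
        log.info(
            "pair %s-%s (%s): dx=%.2f dy=%.2f score=%.3f status=%s",
            a_id, b_id, relation, off.dx_px, off.dy_px, off.score, off.status,
        )
        offsets.append(off)

    some_tile = next(iter(by_id.values()))
    layout = solve_layout(offsets, rows, cols, some_tile.pixels.shape)
    return layout, offsets


def layout_table(layout: MosaicLayout, offsets: Optional[List[PairOffset]] = None) -> str:
    """Plain-text table of tile positions (and mean pair score per tile)."""
    scores: Dict[TileId, List[float]] = {}
    for off in offsets or []:
        scores.setdefault(off.a, []).append(off.score)
        scores.setdefault(off.b, []).append(off.score)
    lines = ["# tile_row\ttile_col\tx_px\ty_px\tmean_score"]
    for (r, c), (x, y) in sorted(layout.positions.items()):
        s = scores.get((r, c))
        mean_s = sum(s) / len(s) if s else float("nan")
        lines.append(f"{r}\t{c}\t{x:.3f}\t{y:.3f}\t{mean_s:.3f}")
    return "\n".join(lines) + "\n"
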