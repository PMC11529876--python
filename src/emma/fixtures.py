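"""Deterministic synthetic EM-like montages with exact ground truth.

A phantom image (band-limited texture + dark blobs + curvilinear membranes)
is sliced into an overlapping tile grid with optional stage jitter, per-tile
quadratic shading, brightness offsets and additive noise.  Every corruption
is recorded so downstream stages can be validated against known truth.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import tifffile
from scipy import ndimage

from .errors import ConfigurationError
from .stitcher import MosaicLayout, Tile, TileId, nominal_step

_ORDERS = ("row-major", "serpentine")


def _bit_range(bit_depth: int) -> float:
    if bit_depth == 8:
        return 255.0
    if bit_depth == 16:
        return 65535.0
    raise ConfigurationError("bit_depth must be 8 or 16")


def _dtype_for(bit_depth: int):
    return np.uint8 if bit_depth == 8 else np.uint16


@dataclass(frozen=True)
class PhantomSpec:
    width_px: int = 512
    height_px: int = 512
    n_blobs: int = 12
    membrane_density: float = 0.15
    texture_sigma: float = 12.0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 64 or self.height_px < 64:
            raise ConfigurationError("phantom dimensions must be >= 64 px")
        if self.n_blobs < 0:
            raise ConfigurationError("n_blobs must be non-negative")
        if not 0.0 <= self.membrane_density <= 1.0:
            raise ConfigurationError("membrane_density must lie in [0, 1]")
        _bit_range(self.bit_depth)


@dataclass(frozen=True)
class SliceSpec:
    rows: int = 3
    cols: int = 3
    tile_width: int = 256
    tile_height: int = 256
    overlap_fraction: float = 0.3
    jitter_px: int = 0
    shading_amplitude: float = 0.0
    brightness_jitter: float = 0.0
    noise_sigma: float = 0.0
    order: str = "row-major"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ConfigurationError("grid must have at least one row and column")
        if not 0.0 < self.overlap_fraction < 0.9:
            raise ConfigurationError("overlap_fraction must lie in (0, 0.9)")
        if self.jitter_px < 0:
            raise ConfigurationError("jitter_px must be non-negative")
        if self.order not in _ORDERS:
            raise ConfigurationError(f"order must be one of {_ORDERS}")
        ov_x = self.tile_width - nominal_step(self.tile_width, self.overlap_fraction)
        ov_y = self.tile_height - nominal_step(self.tile_height, self.overlap_fraction)
        if 2 * self.jitter_px >= min(ov_x, ov_y):
            raise ConfigurationError(
                "jitter_px too large for the requested overlap: "
                f"2*{self.jitter_px} >= min overlap {min(ov_x, ov_y)}"
            )

    @property
    def step_x(self) -> int:
        return nominal_step(self.tile_width, self.overlap_fraction)

    @property
    def step_y(self) -> int:
        return nominal_step(self.tile_height, self.overlap_fraction)


@dataclass
class PhantomLayers:
    """Separate constituents of a phantom, kept for oracle-style checks."""

    base: float
    texture: np.ndarray
    blob_mask: np.ndarray
    membrane_mask: np.ndarray


@dataclass
class MontageTruth:
    """Everything injected during slicing, recorded exactly."""

    layout: MosaicLayout  # normalized crop origins (min position at (0,0))
    origins: Dict[TileId, Tuple[int, int]]  # absolute crop origins in the phantom
    jitter: Dict[TileId, Tuple[int, int]]
    shading_coeffs: Dict[TileId, List[float]]
    shading_scale: Dict[TileId, float]
    brightness: Dict[TileId, float]
    step_x: int = 0
    step_y: int = 0

    def shading_field(self, tile_id: TileId, shape: Tuple[int, int]) -> np.ndarray:
        """Reconstruct the exact additive shading field injected into a tile."""
        return _eval_shading(self.shading_coeffs[tile_id], self.shading_scale[tile_id], shape)


def _shading_basis(shape: Tuple[int, int]) -> np.ndarray:
    h, w = shape
    v, u = np.meshgrid(np.linspace(-1, 1, h), np.linspace(-1, 1, w), indexing="ij")
    return np.stack([u, v, u * u, u * v, v * v])


def _eval_shading(coeffs: List[float], scale: float, shape: Tuple[int, int]) -> np.ndarray:
    basis = _shading_basis(shape)
    fld = np.tensordot(np.asarray(coeffs), basis, axes=1)
    fld -= fld.mean()
    return fld * scale


def make_phantom_layers(spec: PhantomSpec) -> PhantomLayers:
    """Generate the phantom's constituent layers (texture, blobs, membranes)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    full = _bit_range(spec.bit_depth)
    base = 0.55 * full

    texture = np.zeros((h, w))
    if spec.texture_sigma > 0:
        texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=3.0)
        std = texture.std()
        if std > 0:
            texture *= spec.texture_sigma * (full / 255.0) / std

    blob_mask = np.zeros((h, w), dtype=bool)
    if spec.n_blobs > 0:
        r_max = max(4, min(h, w) // 25)
        r_min = max(3, min(h, w) // 40)
        centers: List[Tuple[float, float]] = []
        radii: List[float] = []
        min_sep = 2 * r_max + 3  # guarantees blobs never merge
        attempts = 0
        while len(centers) < spec.n_blobs:
            attempts += 1
            if attempts > 20000:
                raise ConfigurationError(
                    f"could not place {spec.n_blobs} non-touching blobs in {w}x{h}"
                )
            cy = rng.uniform(r_max + 1, h - r_max - 1)
            cx = rng.uniform(r_max + 1, w - r_max - 1)
            if all((cy - oy) ** 2 + (cx - ox) ** 2 >= min_sep ** 2 for oy, ox in centers):
                centers.append((cy, cx))
                radii.append(rng.uniform(r_min, r_max))
        yy, xx = np.mgrid[0:h, 0:w]
        for (cy, cx), r in zip(centers, radii):
            blob_mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2

    membrane_mask = np.zeros((h, w), dtype=bool)
    n_curves = int(round(spec.membrane_density * 25))
    for _ in range(n_curves):
        y = rng.uniform(5, h - 5)
        x = rng.uniform(5, w - 5)
        heading = rng.uniform(0, 2 * np.pi)
        curvature = 0.0
        length = int(0.75 * min(h, w))
        for _ in range(length):
            iy, ix = int(round(y)), int(round(x))
            if 0 <= iy < h and 0 <= ix < w:
                membrane_mask[iy, ix] = True
            curvature += rng.normal(0, 0.02)
            curvature = float(np.clip(curvature, -0.12, 0.12))
            heading += curvature
            y += np.sin(heading)
            x += np.cos(heading)
            if not (1 <= y < h - 1 and 1 <= x < w - 1):
                break
    if membrane_mask.any():
        membrane_mask = ndimage.binary_dilation(membrane_mask, iterations=1)

    return PhantomLayers(base, texture, blob_mask, membrane_mask)


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Compose an EM-like grayscale phantom; bit-identical for a fixed spec."""
    layers = make_phantom_layers(spec)
    full = _bit_range(spec.bit_depth)
    img = np.full((spec.height_px, spec.width_px), layers.base, dtype=np.float64)
    img += layers.texture
    blob = ndimage.gaussian_filter(layers.blob_mask.astype(np.float64), sigma=1.0)
    img -= 0.25 * full * blob
    img -= 0.35 * full * layers.membrane_mask
    return np.clip(np.rint(img), 0, full).astype(_dtype_for(spec.bit_depth))


def phantom_size_for(spec: SliceSpec) -> Tuple[int, int]:
    """(width, height) a phantom needs so the grid plus jitter margin fits exactly."""
    w = (spec.cols - 1) * spec.step_x + spec.tile_width + 2 * spec.jitter_px
    h = (spec.rows - 1) * spec.step_y + spec.tile_height + 2 * spec.jitter_px
    return w, h


def acquisition_order(spec: SliceSpec) -> List[TileId]:
    order: List[TileId] = []
    for r in range(spec.rows):
        cs = range(spec.cols)
        if spec.order == "serpentine" and r % 2 == 1:
            cs = range(spec.cols - 1, -1, -1)
        order.extend((r, c) for c in cs)
    return order


def slice_tiles(
    phantom: np.ndarray,
    spec: SliceSpec,
    pixel_size_nm: float = 1.0,
) -> Tuple[List[Tile], MontageTruth]:
    """Crop an overlapping tile grid out of a phantom and corrupt each tile.

    Corruption (shading field, brightness offset, noise) is applied after
    cropping, so the recorded crop origins are exact ground truth.  Jitter is
    an independent uniform integer offset in [-jitter_px, +jitter_px] per
    tile and axis; the nominal grid is inset by the jitter margin so every
    jittered crop stays inside the phantom.
    """
    need_w, need_h = phantom_size_for(spec)
    if phantom.shape[1] < need_w or phantom.shape[0] < need_h:
        raise ConfigurationError(
            f"phantom {phantom.shape[1]}x{phantom.shape[0]} too small for grid "
            f"(needs at least {need_w}x{need_h} including jitter margin)"
        )
    if np.issubdtype(phantom.dtype, np.integer):
        full = float(np.iinfo(phantom.dtype).max)
    else:
        full = 255.0
    rng = np.random.default_rng(spec.seed)
    j = spec.jitter_px

    # deterministic per-tile draws in fixed (row-major) order, independent of
    # the acquisition order, so ground truth does not depend on `order`
    draws: Dict[TileId, dict] = {}
    for r in range(spec.rows):
        for c in range(spec.cols):
            jx = int(rng.integers(-j, j + 1)) if j > 0 else 0
            jy = int(rng.integers(-j, j + 1)) if j > 0 else 0
            coeffs = rng.uniform(-1.0, 1.0, size=5).tolist()
            boff = float(rng.uniform(-1.0, 1.0) * spec.brightness_jitter * full)
            draws[(r, c)] = {"jx": jx, "jy": jy, "coeffs": coeffs, "boff": boff}

    tiles: List[Tile] = []
    origins: Dict[TileId, Tuple[int, int]] = {}
    jitter: Dict[TileId, Tuple[int, int]] = {}
    coeffs_out: Dict[TileId, List[float]] = {}
    scale_out: Dict[TileId, float] = {}
    brightness: Dict[TileId, float] = {}
    shape = (spec.tile_height, spec.tile_width)

    for tid in acquisition_order(spec):
        r, c = tid
        d = draws[tid]
        x0 = j + c * spec.step_x + d["jx"]
        y0 = j + r * spec.step_y + d["jy"]
        crop = phantom[y0:y0 + spec.tile_height, x0:x0 + spec.tile_width].astype(np.float64)

        scale = 0.0
        if spec.shading_amplitude > 0:
            raw = _eval_shading(d["coeffs"], 1.0, shape)
            ptp = float(raw.max() - raw.min())
            scale = spec.shading_amplitude * full / ptp if ptp > 0 else 0.0
            crop = crop + raw * scale
        crop = crop + d["boff"]
        if spec.noise_sigma > 0:
            crop = crop + rng.normal(0.0, spec.noise_sigma * (full / 255.0), size=shape)

        pixels = np.clip(np.rint(crop), 0, full).astype(phantom.dtype)
        tiles.append(
            Tile(pixels, r, c, nominal_overlap=spec.overlap_fraction, pixel_size_nm=pixel_size_nm)
        )
        origins[tid] = (x0, y0)
        jitter[tid] = (d["jx"], d["jy"])
        coeffs_out[tid] = d["coeffs"]
        scale_out[tid] = scale
        brightness[tid] = d["boff"]

    min_x = min(o[0] for o in origins.values())
    min_y = min(o[1] for o in origins.values())
    positions = {tid: (float(x - min_x), float(y - min_y)) for tid, (x, y) in origins.items()}
    canvas_w = int(max(p[0] for p in positions.values()) + spec.tile_width)
    canvas_h = int(max(p[1] for p in positions.values()) + spec.tile_height)
    truth = MontageTruth(
        layout=MosaicLayout(positions, canvas_w, canvas_h),
        origins=origins,
        jitter=jitter,
        shading_coeffs=coeffs_out,
        shading_scale=scale_out,
        brightness=brightness,
        step_x=spec.step_x,
        step_y=spec.step_y,
    )
    return tiles, truth


def make_montage(
    phantom_spec: PhantomSpec, slice_spec: SliceSpec, pixel_size_nm: float = 1.0
) -> Tuple[np.ndarray, List[Tile], MontageTruth]:
    """Convenience: phantom sized to the grid, sliced and corrupted in one call."""
    w, h = phantom_size_for(slice_spec)
    spec = PhantomSpec(
        width_px=w,
        height_px=h,
        n_blobs=phantom_spec.n_blobs,
        membrane_density=phantom_spec.membrane_density,
        texture_sigma=phantom_spec.texture_sigma,
        bit_depth=phantom_spec.bit_depth,
        seed=phantom_spec.seed,
    )
    phantom = make_phantom(spec)
    tiles, truth = slice_tiles(phantom, slice_spec, pixel_size_nm)
    return phantom, tiles, truth


def write_montage(tiles: List[Tile], truth: MontageTruth, out_dir: pathlib.Path) -> None:
    """Write tiles as ``tile_r{row}_c{col}.tif`` plus a ground-truth JSON sidecar."""
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for t in tiles:
        tifffile.imwrite(out_dir / f"tile_r{t.row}_c{t.col}.tif", t.pixels)
    sidecar = {
        "step_x": truth.step_x,
        "step_y": truth.step_y,
        "tiles": {
            f"{r},{c}": {
                "origin": list(truth.origins[(r, c)]),
                "position": list(truth.layout.positions[(r, c)]),
                "jitter": list(truth.jitter[(r, c)]),
                "shading_coeffs": truth.shading_coeffs[(r, c)],
                "shading_scale": truth.shading_scale[(r, c)],
                "brightness": truth.brightness[(r, c)],
            }
            for (r, c) in truth.origins
        },
        "canvas": [truth.layout.canvas_width, truth.layout.canvas_height],
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))


def read_montage(
    in_dir: pathlib.Path,
    rows: int,
    cols: int,
    overlap_fraction: float = 0.3,
    pixel_size_nm: float = 1.0,
    pattern: str = "tile_r{row}_c{col}.tif",
) -> List[Tile]:
    """Load a tile grid written by :func:`write_montage` (or any tool using the pattern)."""
    in_dir = pathlib.Path(in_dir)
    tiles = []
    for r in range(rows):
        for c in range(cols):
            path = in_dir / pattern.format(row=r, col=c)
            if not path.exists():
                raise ConfigurationError(f"missing tile image: {path}")
            tiles.append(
                Tile(
                    tifffile.imread(path),
                    r,
                    c,
                    nominal_overlap=overlap_fraction,
                    pixel_size_nm=pixel_size_nm,
                )
            )
    return tiles
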