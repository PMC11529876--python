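"""Deep Zoom Image (dzi) tile pyramid construction.

Writes the standard layout ``NAME.dzi`` + ``NAME_files/<level>/<col>_<row>.<fmt>``
with exact level/tile geometry: level L-1 is the 2x downsample (Gaussian
pre-blur, then 2x2 area mean) of level L, level 0 is 1x1, and tile overlap
borders follow the common Deep Zoom convention (no border on left/top edge
tiles).
"""

from __future__ import annotations

import math
import pathlib
import shutil
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import ConfigurationError, FormatError, PyramidError

DEEPZOOM_NAMESPACE = "http://schemas.microsoft.com/deepzoom/2008"
_FORMATS = ("png", "jpg")


@dataclass(frozen=True)
class PyramidDescriptor:
    width: int
    height: int
    tile_size: int = 256
    overlap: int = 1
    format: str = "png"

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ConfigurationError("pyramid dimensions must be positive")
        if self.tile_size < 64:
            raise ConfigurationError("tile_size must be >= 64")
        if self.overlap < 0:
            raise ConfigurationError("overlap must be non-negative")
        if self.format not in _FORMATS:
            raise ConfigurationError(f"format must be one of {_FORMATS}")

    @property
    def max_level(self) -> int:
        return max(0, math.ceil(math.log2(max(self.width, self.height))))


def descriptor(
    width: int, height: int, tile_size: int = 256, overlap: int = 1, format: str = "png"
) -> PyramidDescriptor:
    return PyramidDescriptor(width, height, tile_size, overlap, format)


def level_dims(desc: PyramidDescriptor, level: int) -> Tuple[int, int]:
    """(width, height) of a pyramid level; ceiling halving from the top level."""
    if not 0 <= level <= desc.max_level:
        raise ConfigurationError(f"level {level} outside [0, {desc.max_level}]")
    scale = 2 ** (desc.max_level - level)
    return (-(-desc.width // scale), -(-desc.height // scale))


def tile_grid(desc: PyramidDescriptor, level: int) -> Tuple[int, int]:
    """(cols, rows) of tiles on a level."""
    w, h = level_dims(desc, level)
    return (-(-w // desc.tile_size), -(-h // desc.tile_size))


def total_tiles(desc: PyramidDescriptor) -> int:
    return sum(
        tile_grid(desc, lv)[0] * tile_grid(desc, lv)[1] for lv in range(desc.max_level + 1)
    )


def tile_bounds(
    desc: PyramidDescriptor, level: int, col: int, row: int
) -> Tuple[int, int, int, int]:
    """Pixel bounds (x0, y0, x1, y1) of a tile on its level, including overlap borders."""
    w, h = level_dims(desc, level)
    cols, rows = tile_grid(desc, level)
    if not (0 <= col < cols and 0 <= row < rows):
        raise ConfigurationError(f"tile ({col}, {row}) outside level {level} grid {cols}x{rows}")
    ts, ov = desc.tile_size, desc.overlap
    x0 = col * ts - (ov if col > 0 else 0)
    y0 = row * ts - (ov if row > 0 else 0)
    x1 = min((col + 1) * ts + ov, w)
    y1 = min((row + 1) * ts + ov, h)
    return x0, y0, x1, y1


def write_descriptor(desc: PyramidDescriptor) -> str:
    """dzi XML text with bit-stable attribute order."""
    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<Image TileSize="{desc.tile_size}" Overlap="{desc.overlap}" '
        f'Format="{desc.format}" xmlns="{DEEPZOOM_NAMESPACE}">\n'
        f'  <Size Width="{desc.width}" Height="{desc.height}"/>\n'
        "</Image>\n"
    )


def read_descriptor(xml_text: str) -> PyramidDescriptor:
    """Parse and validate a dzi descriptor, naming the offending field on error."""
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        raise FormatError(f"descriptor is not well-formed XML: {exc}") from exc
    expected = f"{{{DEEPZOOM_NAMESPACE}}}Image"
    if root.tag != expected:
        raise FormatError(
            f"root element is {root.tag!r}, expected Image in namespace {DEEPZOOM_NAMESPACE}"
        )
    attrs = {}
    for name in ("TileSize", "Overlap", "Format"):
        if name not in root.attrib:
            raise FormatError(f"missing Image attribute {name!r}")
        attrs[name] = root.attrib[name]
    size = root.find(f"{{{DEEPZOOM_NAMESPACE}}}Size")
    if size is None:
        raise FormatError("missing Size element")
    for name in ("Width", "Height"):
        if name not in size.attrib:
            raise FormatError(f"missing Size attribute {name!r}")
    try:
        return PyramidDescriptor(
            width=int(size.attrib["Width"]),
            height=int(size.attrib["Height"]),
            tile_size=int(attrs["TileSize"]),
            overlap=int(attrs["Overlap"]),
            format=attrs["Format"],
        )
    except ValueError as exc:
        raise FormatError(f"non-integer geometry attribute: {exc}") from exc


def _to_pil(arr: np.ndarray) -> Image.Image:
    return Image.fromarray(arr)


def downsample2x(image: np.ndarray, mode: str = "gaussian") -> np.ndarray:
    """Halve an image: optional Gaussian pre-blur (sigma=0.5), then 2x2 area mean.

    Odd dimensions follow ceiling semantics: the trailing row/column is
    averaged with an edge-replicated copy of itself.
    """
    if mode not in ("gaussian", "box"):
        raise ConfigurationError("downsample mode must be 'gaussian' or 'box'")
    img = image.astype(np.float64)
    channels = img[..., None] if img.ndim == 2 else img
    out_planes = []
    for k in range(channels.shape[2]):
        plane = channels[:, :, k]
        if mode == "gaussian":
            plane = ndimage.gaussian_filter(plane, sigma=0.5, mode="nearest")
        h, w = plane.shape
        if h % 2:
            plane = np.vstack([plane, plane[-1:]])
        if w % 2:
            plane = np.hstack([plane, plane[:, -1:]])
        out_planes.append(plane.reshape(plane.shape[0] // 2, 2, plane.shape[1] // 2, 2).mean(axis=(1, 3)))
    out = np.stack(out_planes, axis=2)
    if image.ndim == 2:
        out = out[:, :, 0]
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        return np.clip(np.rint(out), info.min, info.max).astype(image.dtype)
    return out.astype(image.dtype)


def _write_tile(path: pathlib.Path, arr: np.ndarray, fmt: str) -> None:
    im = _to_pil(arr)
    if fmt == "png":
        im.save(path, format="PNG")
    else:
        if arr.dtype != np.uint8:
            raise PyramidError("jpg output requires 8-bit data")
        if im.mode == "RGBA":
            im = im.convert("RGB")
        im.save(path, format="JPEG", quality=90)


def build(
    mosaic: np.ndarray,
    desc: PyramidDescriptor,
    out_dir: pathlib.Path,
    name: str = "mosaic",
    downsample_mode: str = "gaussian",
) -> Dict:
    """Write ``{name}.dzi`` and ``{name}_files/{level}/{col}_{row}.{fmt}``.

    Each level is cut from the quantized image of that level, so the pyramid
    is exactly reproducible from the written files.  On failure the partial
    output tree is removed before the error propagates.
    """
    if mosaic.shape[0] != desc.height or mosaic.shape[1] != desc.width:
        raise ConfigurationError(
            f"mosaic {mosaic.shape[1]}x{mosaic.shape[0]} does not match descriptor "
            f"{desc.width}x{desc.height}"
        )
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dzi_path = out_dir / f"{name}.dzi"
    files_dir = out_dir / f"{name}_files"
    manifest: Dict = {"name": name, "levels": {}, "total_files": 0}
    try:
        dzi_path.write_text(write_descriptor(desc), encoding="utf-8")
        level_img = mosaic
        for level in range(desc.max_level, -1, -1):
            lw, lh = level_dims(desc, level)
            assert level_img.shape[1] == lw and level_img.shape[0] == lh
            cols, rows = tile_grid(desc, level)
            level_dir = files_dir / str(level)
            level_dir.mkdir(parents=True, exist_ok=True)
            for row in range(rows):
                for col in range(cols):
                    x0, y0, x1, y1 = tile_bounds(desc, level, col, row)
                    _write_tile(
                        level_dir / f"{col}_{row}.{desc.format}",
                        level_img[y0:y1, x0:x1],
                        desc.format,
                    )
            manifest["levels"][str(level)] = {"cols": cols, "rows": rows, "count": cols * rows}
            manifest["total_files"] += cols * rows
            if level > 0:
                level_img = downsample2x(level_img, mode=downsample_mode)
    except Exception:
        shutil.rmtree(files_dir, ignore_errors=True)
        dzi_path.unlink(missing_ok=True)
        raise
    return manifest


def read_tile(out_dir: pathlib.Path, name: str, level: int, col: int, row: int, fmt: str) -> np.ndarray:
    """Load one written tile back as an array (mode I;16 mapped to uint16)."""
    path = pathlib.Path(out_dir) / f"{name}_files" / str(level) / f"{col}_{row}.{fmt}"
    with Image.open(path) as im:
        arr = np.array(im)
    if arr.dtype == np.int32:  # PIL I;16 roundtrip
        arr = arr.astype(np.uint16)
    return arr


def assemble_level(
    out_dir: pathlib.Path, desc: PyramidDescriptor, name: str, level: int
) -> np.ndarray:
    """Reassemble a level image from its written tiles (overlap borders cropped)."""
    w, h = level_dims(desc, level)
    cols, rows = tile_grid(desc, level)
    first = read_tile(out_dir, name, level, 0, 0, desc.format)
    shape = (h, w) if first.ndim == 2 else (h, w, first.shape[2])
    out = np.zeros(shape, dtype=first.dtype)
    ts, ov = desc.tile_size, desc.overlap
    for row in range(rows):
        for col in range(cols):
            arr = read_tile(out_dir, name, level, col, row, desc.format)
            crop_x = ov if col > 0 else 0
            crop_y = ov if row > 0 else 0
            x0, y0 = col * ts, row * ts
            core = arr[crop_y:crop_y + ts, crop_x:crop_x + ts]
            out[y0:y0 + core.shape[0], x0:x0 + core.shape[1]] = core
    return out
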