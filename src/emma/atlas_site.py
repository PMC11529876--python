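"""Static HTML atlas pages: viewer containers, calibrated scalebar, overlays.

Page generation is pure text assembly (never touches pixel data) and is
byte-deterministic for fixed inputs.  The emitted markup is XML-well-formed
so it can be checked with a strict parser.  The deep-zoom viewer engine
itself is an external script: stub assets are written into ``openseadragon/``
so every referenced path resolves, and the README documents dropping in the
real distribution.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import jinja2
import numpy as np

from .dzi_pyramid import PyramidDescriptor, build as build_pyramid
from .errors import ConfigurationError, SiteError

_ENV = jinja2.Environment(
    loader=jinja2.BaseLoader(),
    autoescape=False,
    trim_blocks=True,
    lstrip_blocks=True,
    keep_trailing_newline=True,
)


@dataclass(frozen=True)
class ScalebarOptions:
    location: str = "BOTTOM_LEFT"
    color: str = "black"
    background: str = "rgba(255, 255, 255, 0.5)"
    bar_thickness: int = 4


@dataclass(frozen=True)
class OverlaySpec:
    label: str
    dzi_path: str
    color: str = "rgba(255, 0, 0, 0.35)"
    default_visible: bool = False


@dataclass(frozen=True)
class ViewerConfig:
    container_id: str
    dzi_path: str
    pixels_per_meter: int
    scalebar: ScalebarOptions = field(default_factory=ScalebarOptions)
    overlays: Tuple[OverlaySpec, ...] = ()
    size_css: str = "90%"

    def __post_init__(self) -> None:
        if self.pixels_per_meter < 1:
            raise ConfigurationError("pixels_per_meter must be a positive integer")
        if not self.container_id or not self.container_id.replace("_", "").isalnum():
            raise ConfigurationError(
                f"container_id {self.container_id!r} must be alphanumeric/underscore"
            )


def pixels_per_meter(pixel_size_nm: float) -> int:
    """Integer scalebar calibration: round(1e9 / pixel size in nm)."""
    if pixel_size_nm <= 0:
        raise ConfigurationError("pixel_size_nm must be positive")
    return int(round(1e9 / pixel_size_nm))


def projected_length_cm(feature_length_um: float, magnification: float) -> float:
    """Physical display length in cm of a feature projected at a magnification."""
    if feature_length_um < 0 or magnification < 0:
        raise ConfigurationError("feature length and magnification must be non-negative")
    return feature_length_um * magnification * 1e-4


def projected_length(feature_length_um: float, magnification: float) -> Tuple[float, str]:
    """Display length with a human unit: cm when >= 1 cm, else mm, else µm."""
    um = feature_length_um * magnification
    if um >= 1e4:
        return um * 1e-4, "cm"
    if um >= 1e3:
        return um * 1e-3, "mm"
    return um, "µm"


_PAGE_TEMPLATE = _ENV.from_string(
    """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8"/>
<meta name="viewport" content="width=device-width, initial-scale=1"/>
<title>{{ title|e }}</title>
<style>
body { font-family: sans-serif; margin: 1em; background: #fafafa; }
.emma-row { display: flex; flex-wrap: wrap; gap: 1em; }
.emma-viewer { height: 70vh; background: #222; margin: 0 auto 1em auto; }
.emma-overlay-buttons { margin: 0.3em 0 1em 0; }
@media (max-width: 800px) { .emma-viewer { width: 100% !important; } }
</style>
<script src="openseadragon/openseadragon.min.js"></script>
<script src="openseadragon/openseadragon-scalebar.js"></script>
</head>
<body>
<h1>{{ title|e }}</h1>
<div class="emma-row">
{% for c in configs %}
<div id="{{ c.container_id }}" class="emma-viewer" style="width:{{ c.size_css }};"></div>
{% endfor %}
</div>
{% for c in configs %}
{% if c.overlays %}
<div class="emma-overlay-buttons" id="{{ c.container_id }}_buttons">
{% for ov in c.overlays %}
<button type="button" id="{{ c.container_id }}_overlay_{{ loop.index0 }}" onclick="emmaToggleOverlay({{ outer_index[c.container_id] }}, {{ loop.index0 }})">{{ ov.label|e }}</button>
{% endfor %}
</div>
{% endif %}
{% endfor %}
<script>
var emmaViewers = [];
var emmaOverlays = [];
function emmaToggleOverlay(v, i) {
  var item = emmaOverlays[v][i];
  item.visible = !item.visible;
  item.image.setOpacity(item.visible ? 1.0 : 0.0);
}
{% for c in configs %}
emmaViewers[{{ loop.index0 }}] = OpenSeadragon({
  id: "{{ c.container_id }}",
  prefixUrl: "openseadragon/images/",
  tileSources: "{{ c.dzi_path }}",
  showNavigator: true
});
emmaViewers[{{ loop.index0 }}].scalebar({
  type: OpenSeadragon.ScalebarType.MICROSCOPY,
  pixelsPerMeter: {{ c.pixels_per_meter }},
  location: OpenSeadragon.ScalebarLocation.{{ c.scalebar.location }},
  color: "{{ c.scalebar.color }}",
  backgroundColor: "{{ c.scalebar.background }}",
  barThickness: {{ c.scalebar.bar_thickness }}
});
emmaOverlays[{{ loop.index0 }}] = [];
{% set outer = loop.index0 %}
{% for ov in c.overlays %}
emmaViewers[{{ outer }}].addTiledImage({
  tileSource: "{{ ov.dzi_path }}",
  opacity: {{ "1.0" if ov.default_visible else "0.0" }},
  success: function(ev) { emmaOverlays[{{ outer }}][{{ loop.index0 }}] = { image: ev.item, visible: {{ "true" if ov.default_visible else "false" }} }; }
});
{% endfor %}
{% endfor %}
</script>
</body>
</html>
"""
)

_INDEX_TEMPLATE = _ENV.from_string(
    """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8"/>
<meta name="viewport" content="width=device-width, initial-scale=1"/>
<title>{{ title|e }}</title>
<style>
body { font-family: sans-serif; margin: 1em; }
.emma-grid { display: flex; flex-wrap: wrap; gap: 1.5em; }
.emma-card { width: 240px; text-align: center; }
.emma-card img { width: 100%; border: 1px solid #999; }
</style>
</head>
<body>
<h1>{{ title|e }}</h1>
<div class="emma-grid">
{% for e in entries %}
<div class="emma-card">
<a href="{{ e.link }}"><img src="{{ e.thumbnail }}" alt="{{ e.caption|e }}"/></a>
<p>{{ e.caption|e }}</p>
</div>
{% endfor %}
</div>
</body>
</html>
"""
)


def render_page(configs: Sequence[ViewerConfig], title: str = "EM atlas") -> str:
    """One self-contained index.html with a container + init block per config."""
    ids = [c.container_id for c in configs]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ConfigurationError(f"duplicate container_id(s): {sorted(dupes)}")
    outer_index = {c.container_id: i for i, c in enumerate(configs)}
    return _PAGE_TEMPLATE.render(configs=configs, title=title, outer_index=outer_index)


def render_project_index(entries: Sequence[Dict[str, str]], title: str = "Atlas index") -> str:
    """Thumbnail grid page where each entry links to its atlas page."""
    for e in entries:
        for key in ("thumbnail", "link", "caption"):
            if key not in e:
                raise ConfigurationError(f"project index entry missing {key!r}")
    return _INDEX_TEMPLATE.render(entries=entries, title=title)


# Minimal stand-ins so generated pages have every referenced path present.
# Replace with the real OpenSeadragon distribution + scalebar plugin for a
# working interactive viewer (see README).
_VIEWER_STUB = """/* Placeholder for the OpenSeadragon viewer script.
 * Download openseadragon.min.js from https://openseadragon.github.io/ and
 * replace this file; also copy the distribution's images/ directory here. */
function OpenSeadragon(options) {
  var el = document.getElementById(options.id);
  if (el) { el.textContent = "OpenSeadragon placeholder - install the real viewer script."; }
  return { scalebar: function () {}, addTiledImage: function () {} };
}
OpenSeadragon.ScalebarType = { MICROSCOPY: 1 };
OpenSeadragon.ScalebarLocation = { TOP_LEFT: 1, TOP_RIGHT: 2, BOTTOM_RIGHT: 3, BOTTOM_LEFT: 4 };
"""

_SCALEBAR_STUB = """/* Placeholder for the OpenSeadragonScalebar plugin.
 * Download openseadragon-scalebar.js from
 * https://github.com/usnistgov/OpenSeadragonScalebar and replace this file. */
"""


def write_viewer_assets(site_dir: pathlib.Path) -> None:
    """Create ``openseadragon/`` with stub scripts and the images directory."""
    osd = pathlib.Path(site_dir) / "openseadragon"
    (osd / "images").mkdir(parents=True, exist_ok=True)
    viewer = osd / "openseadragon.min.js"
    scalebar = osd / "openseadragon-scalebar.js"
    if not viewer.exists():
        viewer.write_text(_VIEWER_STUB, encoding="utf-8")
    if not scalebar.exists():
        scalebar.write_text(_SCALEBAR_STUB, encoding="utf-8")


def verify_paths(site_dir: pathlib.Path, configs: Sequence[ViewerConfig]) -> List[str]:
    """Relative paths referenced by the page that do not exist under site_dir."""
    site_dir = pathlib.Path(site_dir)
    wanted = ["openseadragon/openseadragon.min.js", "openseadragon/openseadragon-scalebar.js"]
    for c in configs:
        wanted.append(c.dzi_path)
        wanted.extend(ov.dzi_path for ov in c.overlays)
    return [p for p in wanted if not (site_dir / p).exists()]


def build_site(
    site_dir: pathlib.Path,
    configs: Sequence[ViewerConfig],
    title: str = "EM atlas",
    verify: bool = True,
) -> pathlib.Path:
    """Write index.html plus viewer assets; check referenced paths exist."""
    site_dir = pathlib.Path(site_dir)
    site_dir.mkdir(parents=True, exist_ok=True)
    write_viewer_assets(site_dir)
    html = render_page(configs, title=title)
    missing = verify_paths(site_dir, configs)
    if missing:
        msg = f"referenced paths missing under {site_dir}: {missing}"
        if verify:
            raise SiteError(msg)
        import warnings

        warnings.warn(msg, stacklevel=2)
    out = site_dir / "index.html"
    out.write_text(html, encoding="utf-8")
    return out


def _parse_css_color(color: str) -> Tuple[int, int, int, int]:
    color = color.strip()
    if color.startswith("#"):
        hexpart = color[1:]
        if len(hexpart) == 6:
            r, g, b = (int(hexpart[i:i + 2], 16) for i in (0, 2, 4))
            return r, g, b, 255
        if len(hexpart) == 8:
            r, g, b, a = (int(hexpart[i:i + 2], 16) for i in (0, 2, 4, 6))
            return r, g, b, a
    if color.startswith("rgba(") and color.endswith(")"):
        parts = [p.strip() for p in color[5:-1].split(",")]
        if len(parts) == 4:
            r, g, b = (int(float(p)) for p in parts[:3])
            a = int(round(float(parts[3]) * 255))
            return r, g, b, a
    raise ConfigurationError(f"cannot parse color {color!r} (use #rrggbb, #rrggbbaa or rgba())")


def build_overlay(
    label_image: np.ndarray,
    color: str,
    base_desc: PyramidDescriptor,
    out_dir: pathlib.Path,
    name: str,
    alpha: float = 0.35,
) -> Dict:
    """Build a transparent RGBA overlay pyramid matching the base geometry.

    Pixels where ``label_image`` is nonzero carry ``color`` at the stated
    alpha (a color with its own alpha channel wins); everything else is fully
    transparent.
    """
    if label_image.shape[:2] != (base_desc.height, base_desc.width):
        raise ConfigurationError(
            f"label image {label_image.shape[1]}x{label_image.shape[0]} does not match "
            f"base pyramid {base_desc.width}x{base_desc.height}"
        )
    r, g, b, a = _parse_css_color(color)
    if a == 255:
        a = int(round(alpha * 255))
    rgba = np.zeros((base_desc.height, base_desc.width, 4), dtype=np.uint8)
    labeled = label_image != 0
    rgba[labeled] = (r, g, b, a)
    desc = PyramidDescriptor(
        base_desc.width, base_desc.height, base_desc.tile_size, base_desc.overlap, "png"
    )
    return build_pyramid(rgba, desc, out_dir, name=name)
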