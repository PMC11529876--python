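# emma-atlas

Build browsable, gigapixel electron-microscopy atlases from overlapping tile
images. The pipeline:

1. **flatfield** — per-tile illumination correction (rolling-ball background
   subtraction, polynomial shading correction, or frequency-domain high-pass).
2. **stitcher** — pairwise tile registration by phase correlation on the
   overlap strips (sub-pixel, NCC-scored, with rejection fallback to the
   nominal grid) and a global weighted least-squares layout
   (translation-only model).
3. **compositor** — projection onto one canvas with *irregular*, seeded
   random-walk seams and feathered (linear-ramp) alpha blending, so no
   straight lines or brightness steps remain; a straight-border
   "hard" composite is kept as the comparison baseline, and a seam-step
   metric quantifies the difference.
4. **dzi_pyramid** — Deep Zoom Image tile pyramid (`NAME.dzi` XML descriptor
   plus `NAME_files/<level>/<col>_<row>.<fmt>`), Gaussian-pyramid downscaling
   with exact ceiling-halving geometry.
5. **atlas_site** — static HTML viewer pages: one or several side-by-side
   containers, a calibrated floating scalebar (integer PixelsPerMeter),
   switchable transparent overlay pyramids, and a project index page.
   Pages work from `file://` with no server.
6. **fixtures** — deterministic synthetic EM-like montages (textured phantom,
   grid slicing with stage jitter, per-tile quadratic shading, brightness
   offsets, noise) with exact ground truth, so the whole pipeline is testable
   without a single real micrograph.

## CLI

```sh
emma stitch    --config config.yaml --out out/     # layout.txt / layout.json
emma composite --config config.yaml --out out/     # mosaic.tif + preview
emma pyramid   --config config.yaml --out out/     # out/dzi/NAME.dzi + tiles
emma site      --config config.yaml --out out/     # out/index.html
emma all       --config config.yaml --out out/     # everything above
emma selftest  --seed 1 --out selftest_out/        # synthetic end-to-end check
```

Exit codes: 0 ok, 2 config error, 3 stitch/composite, 4 pyramid, 5 site.
Useful flags: `--integer-offsets` (bit-exact placement), `--no-verify`
(site path checks warn instead of fail), `--log-level`.

### Config file (YAML)

```yaml
input:
  dir: tiles/                      # tile_r{row}_c{col}.tif
grid:
  rows: 3
  cols: 3
  overlap_fraction: 0.3            # ~30% tile overlap
  pixel_size_nm: 2.5               # drives the scalebar calibration
flatfield:
  method: polynomial               # rolling_ball | polynomial | highpass
  degree: 2
stitch:
  search_px: 18
  score_threshold: 0.3
  min_peak_ratio: 1.5
seam:
  roughness_px: 8                  # seam irregularity amplitude
  feather_px: 20                   # alpha ramp half-width
  seed: 0
pyramid:
  tile_size: 256
  overlap: 1
  format: png                      # png (lossless) | jpg
  name: mosaic
site:
  title: My EM atlas
  containers:                      # omit for a single default container
    - id: viewer_0
      dzi: dzi/mosaic.dzi
      pixel_size_nm: 2.5
      scalebar: {location: BOTTOM_LEFT, color: black}
seed: 0
```

The generated site tree is `out/index.html`, `out/dzi/…`, and
`out/openseadragon/…`. The `openseadragon/` directory is created with
placeholder scripts so every referenced path resolves; for a working
interactive viewer, download the real
[OpenSeadragon](https://openseadragon.github.io/) distribution (copy
`openseadragon.min.js` and its `images/` folder there) and
[OpenSeadragonScalebar](https://github.com/usnistgov/OpenSeadragonScalebar)
(`openseadragon-scalebar.js`). To publish, upload the output directory to any
static host (for GitHub Pages: push it to a public repository, then enable
Pages from the main branch in the repository settings).

## Library use

```python
from emma import fixtures, stitcher, compositor, dzi_pyramid, atlas_site

phantom, tiles, truth = fixtures.make_montage(
    fixtures.PhantomSpec(seed=1),
    fixtures.SliceSpec(rows=3, cols=3, jitter_px=8, noise_sigma=5, seed=1),
)
layout, offsets = stitcher.stitch(tiles, 3, 3)
seams = compositor.grid_seams(layout, (256, 256), 3, 3, compositor.SeamSpec(seed=1))
masks = compositor.feather_masks(layout, seams, 20, (256, 256))
mosaic = compositor.composite(tiles, layout, masks)
desc = dzi_pyramid.descriptor(mosaic.shape[1], mosaic.shape[0])
dzi_pyramid.build(mosaic, desc, "out/dzi", name="mosaic")
```

## Limitations

- Translation-only registration: inhomogeneous elastic deformation of
  sections is out of scope (use a specialist elastic aligner first if your
  data needs it).
- Quantify on the raw tiles, not on the blended mosaic — feathering and
  sub-pixel resampling alter grey values by design.
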