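# tactilemesh

Convert photographs of agar plates and micrographs into watertight,
3D-printable tactile relief models. Pixel brightness becomes surface
height: colonies become bumps, growth patterns become textures, and the
result is exported as an STL solid (1 STL unit = 1 mm) ready for any
slicer.

Two generators are provided:

- **plate** — a disc-shaped model of a Petri dish (default 90 mm) with a
  raised rim marking the physical boundary;
- **slide** — a rectangular model of a microscope slide (default
  75 x 25 mm) with a raised frame.

Both support relief-height scaling, intensity inversion (lighter *or*
darker areas become taller), optional Gaussian smoothing, and optional
embossed Grade-1 braille labels (sample name or date). A synthetic-image
module generates plate-like fixtures with a *known* colony count, which
supports counting exercises with a verifiable answer and drives the test
suite without any external data.

## CLI

```sh
# tactile plate from a photo, 3 mm relief over a 2 mm base
tactilemesh plate --input plate.jpg --out plate.stl --relief-mm 3 --base-mm 2

# darker features taller, smoothed, with a braille label on the bottom margin
tactilemesh plate --input plate.jpg --out plate.stl --invert --smooth-sigma 1.5 \
    --label "E COLI 3" --label-position bottom

# microscope slide, explicit physical size, ASCII STL for inspection
tactilemesh slide --input slide.png --out slide.stl --width-mm 75 --height-mm 25 --ascii

# synthetic plate image with exactly 5 colonies (seeded, reproducible)
tactilemesh fixture --out colonies.png --seed 7 --n 5
```

All physical flags carry a `-mm` suffix. A `--config file` of
`key = value` lines can supply defaults; explicit flags win. Each
generator prints a single-line JSON summary (grid size, triangle count,
bounding box, volume) and exits 0 on success, 1 on a processing error
naming the failed stage, 2 on a usage error.

Identical inputs and flags always produce byte-identical STL files.

## Library

```python
from tactilemesh import (
    load_image, to_grayscale, resample_grid,
    ReliefParams, build_heightmap, apply_circular_mask,
    heightmap_to_solid, validate_watertight, mesh_volume, write_stl,
)

grid = resample_grid(to_grayscale(load_image("plate.jpg")), 256)
hm = build_heightmap(grid, ReliefParams(relief_height_mm=3.0), physical_width_mm=90.0)
hm = apply_circular_mask(hm, (hm.width_mm / 2, hm.height_mm / 2), 45.0)
mesh = heightmap_to_solid(hm)
assert validate_watertight(mesh).is_watertight
write_stl(mesh, "plate.stl")
```

Every generated solid is a closed, consistently oriented 2-manifold by
construction (checked by `validate_watertight`), including under
arbitrary masks — diagonal cell contacts are resolved by splitting the
shared vertex.

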