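import numpy as np
import pytest

from tactilemesh import (
    BrailleLabel,
    ParameterError,
    PipelineError,
    PlateSpec,
    ReliefParams,
    SlideSpec,
    generate_plate,
    generate_slide,
    read_stl,
    validate_watertight,
)
from tactilemesh.models import plate_heightmap, slide_heightmap
from tactilemesh.raster_io import IntensityGrid
from tactilemesh.solid_mesh import TriangleMesh


@pytest.fixture
def black_png(tmp_png):
    return tmp_png(np.zeros((64, 64), dtype=np.uint8), "black.png")


@pytest.fixture
def gray_png(tmp_png):
    # 127.5 is not representable in 8 bits; use intensity 51 -> 0.2 exactly
    return tmp_png(np.full((64, 64), 51, dtype=np.uint8), "gray.png")


@pytest.fixture
def disc_png(tmp_png):
    yy, xx = np.mgrid[0:64, 0:64]
    disc = (xx - 31.5) ** 2 + (yy - 31.5) ** 2 <= 12**2
    return tmp_png(np.where(disc, 255, 0).astype(np.uint8), "disc.png")


def _mesh_from(path):
    doc = read_stl(path)
    verts = doc.vectors.reshape(-1, 3)
    uniq, inverse = np.unique(verts, axis=0, return_inverse=True)
    return TriangleMesh(uniq.astype(np.float64), inverse.reshape(-1, 3))


def small_plate(**kw):
    kw.setdefault("resolution", 64)
    kw.setdefault("relief", ReliefParams(3.0, 2.0))
    return PlateSpec(**kw)


def small_slide(**kw):
    kw.setdefault("resolution", 64)
    kw.setdefault("relief", ReliefParams(2.0, 2.0))
    return SlideSpec(**kw)


class TestGeneratePlate:
    def test_black_plate_rim_dominates(self, black_png, tmp_path):
        spec = small_plate(rim_height_mm=2.0)
        summary = generate_plate(black_png, spec, tmp_path / "p.stl")
        (x0, y0, z0), (x1, y1, z1) = summary["bbox_mm"]
        assert z0 == 0.0
        assert z1 == pytest.approx(4.0)  # rim at base + rim height
        node_diag = np.hypot(90.0 / 63, 90.0 / 63)
        assert x1 - x0 <= 90.0 + node_diag
        assert y1 - y0 <= 90.0 + node_diag

    def test_interior_heights(self, black_png):
        from tactilemesh import load_image, resample_grid, to_grayscale

        spec = small_plate()
        grid = resample_grid(to_grayscale(load_image(black_png)), spec.resolution)
        hm = plate_heightmap(grid, spec)
        np.testing.assert_array_equal(hm.z[hm.mask], 2.0)

    def test_white_disc_plateau(self, disc_png):
        # oracle: direct heightmap formula evaluation on the masked grid
        from tactilemesh import load_image, resample_grid, to_grayscale

        spec = small_plate()
        grid = resample_grid(to_grayscale(load_image(disc_png)), spec.resolution)
        hm = plate_heightmap(grid, spec)
        expected = 2.0 + 3.0 * grid.values
        np.testing.assert_allclose(hm.z[hm.mask], expected[hm.mask], atol=1e-12)
        assert hm.z[hm.mask].max() == pytest.approx(5.0)

    def test_output_watertight(self, disc_png, tmp_path):
        summary = generate_plate(disc_png, small_plate(), tmp_path / "p.stl")
        mesh = _mesh_from(tmp_path / "p.stl")
        assert mesh.n_triangles == summary["triangles"]
        report = validate_watertight(mesh)
        assert not report.boundary_edges and not report.nonmanifold_edges

    def test_doubling_diameter_scales_xy(self, disc_png, tmp_path):
        spec1 = small_plate(diameter_mm=90.0, rim_width_mm=2.0)
        spec2 = small_plate(diameter_mm=180.0, rim_width_mm=4.0)
        s1 = generate_plate(disc_png, spec1, tmp_path / "a.stl")
        s2 = generate_plate(disc_png, spec2, tmp_path / "b.stl")
        d1, d2 = read_stl(tmp_path / "a.stl"), read_stl(tmp_path / "b.stl")
        assert s1["triangles"] == s2["triangles"]
        np.testing.assert_array_equal(d2.vectors[..., :2], 2 * d1.vectors[..., :2])
        np.testing.assert_array_equal(d2.vectors[..., 2], d1.vectors[..., 2])

    def test_plate_with_label(self, tmp_png, tmp_path):
        fine_black = tmp_png(np.zeros((192, 192), dtype=np.uint8), "fineblack.png")
        spec = small_plate(resolution=192)
        summary = generate_plate(
            fine_black, spec, tmp_path / "p.stl", label=BrailleLabel("AB 3"),
        )
        assert (tmp_path / "p.stl").exists()
        assert summary["triangles"] > 0

    def test_stage_error_names_stage(self, tmp_path):
        with pytest.raises(PipelineError, match="stage 'load'"):
            generate_plate(tmp_path / "absent.png", small_plate(), tmp_path / "p.stl")

    def test_invalid_spec(self):
        with pytest.raises(ParameterError):
            PlateSpec(diameter_mm=3.0, rim_width_mm=2.0)


class TestGenerateSlide:
    def test_mid_gray_heights(self, tmp_png):
        # intensity 51/255 = 0.2 exactly; interior = 2 + 2*0.2 = 2.4
        p = tmp_png(np.full((64, 64), 51, dtype=np.uint8), "g.png")
        from tactilemesh import load_image, resample_grid, to_grayscale

        spec = small_slide(frame_height_mm=1.5)
        grid = resample_grid(to_grayscale(load_image(p)), spec.resolution)
        hm = slide_heightmap(grid, spec)
        np.testing.assert_allclose(hm.z, 2.4, atol=1e-12)

    def test_bbox_and_frame(self, gray_png, tmp_path):
        spec = small_slide(frame_height_mm=1.5, relief=ReliefParams(2.0, 2.0))
        summary = generate_slide(gray_png, spec, tmp_path / "s.stl")
        (x0, y0, z0), (x1, y1, z1) = summary["bbox_mm"]
        assert (x1 - x0, y1 - y0) == (pytest.approx(75.0), pytest.approx(25.0))
        # interior peaks at base + relief * 0.2 = 2.4; the 3.5 mm frame wins
        assert z1 == pytest.approx(2.0 + max(2.0 * 0.2, 1.5))

    def test_constant_image_frame_tallest(self, gray_png, tmp_path):
        spec = small_slide(relief=ReliefParams(1.0, 2.0), frame_height_mm=1.5)
        summary = generate_slide(gray_png, spec, tmp_path / "s.stl")
        assert summary["bbox_mm"][1][2] == pytest.approx(3.5)

    def test_aspect_derived_height(self, tmp_png, tmp_path):
        p = tmp_png(np.zeros((32, 64), dtype=np.uint8), "wide.png")
        spec = small_slide(height_mm=None)
        summary = generate_slide(p, spec, tmp_path / "s.stl")
        (_, y0, _), (_, y1, _) = summary["bbox_mm"]
        assert y1 - y0 == pytest.approx(75.0 * 31 / 63)

    def test_output_watertight(self, gray_png, tmp_path):
        generate_slide(gray_png, small_slide(), tmp_path / "s.stl")
        report = validate_watertight(_mesh_from(tmp_path / "s.stl"))
        assert not report.boundary_edges and not report.nonmanifold_edges

    def test_slide_with_label(self, tmp_png, tmp_path):
        fine_gray = tmp_png(np.full((192, 192), 51, dtype=np.uint8), "finegray.png")
        summary = generate_slide(
            fine_gray, small_slide(resolution=192), tmp_path / "s.stl",
            label=BrailleLabel("X1"), label_position="top",
        )
        assert summary["triangles"] > 0

    def test_interior_never_exceeds_base_plus_relief(self, disc_png, tmp_path):
        from tactilemesh import load_image, resample_grid, to_grayscale

        spec = small_slide(relief=ReliefParams(2.0, 2.0))
        grid = resample_grid(to_grayscale(load_image(disc_png)), spec.resolution)
        hm = slide_heightmap(grid, spec)
        assert hm.z.max() <= 2.0 + 2.0 + 1e-12


def test_plate_heightmap_respects_intensity_bounds():
    rng = np.random.default_rng(0)
    vals = rng.random((40, 40))
    grid = IntensityGrid(40, 40, vals)
    hm = plate_heightmap(grid, small_plate())
    assert hm.z.min() >= 2.0 - 1e-12
    assert hm.z.max() <= 5.0 + 1e-12
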