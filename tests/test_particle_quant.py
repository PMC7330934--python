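import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ihcquant.errors import ValidationError
from ihcquant.io_calibration import BasalLineAnnotation, CalibratedImage, ExclusionMask
from ihcquant.particle_quant import (
    AreaInterval,
    Particle,
    ParticleSet,
    RegionSpec,
    apply_exclusion,
    calibrate_area_range,
    compute_density,
    depth_band_regions,
    filter_by_area,
    label_particles,
    nucleus_filter,
    particles_in_region,
    sample_hpfs,
)
from ihcquant.stain_separation import deconvolve, default_stain_matrix, rgb_to_od
from ihcquant.synthetic_ihc import SceneSpec, generate_scene


def _flood_fill_components(mask, eight_connected=True):
    """Brute-force BFS labelling oracle; returns sorted component sizes."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    if eight_connected:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    sizes = []
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                queue = [(r0, c0)]
                seen[r0, c0] = True
                size = 0
                while queue:
                    r, c = queue.pop()
                    size += 1
                    for dr, dc in steps:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            queue.append((rr, cc))
                sizes.append(size)
    return sorted(sizes)


def _particle_set(areas_um2, mpp=1.0):
    parts = tuple(
        Particle(label=i + 1, area_px=int(round(a / mpp**2)), area_um2=float(a),
                 centroid=(0.0, float(i)), touches_field_border=False)
        for i, a in enumerate(areas_um2)
    )
    return ParticleSet(particles=parts, microns_per_pixel=mpp, connectivity=8)


class TestApplyExclusion:
    def test_empty_exclusion_identity(self, rng):
        mask = rng.random((20, 20)) > 0.5
        out = apply_exclusion(mask, ExclusionMask(np.zeros((20, 20), dtype=bool)))
        np.testing.assert_array_equal(out, mask)

    def test_full_exclusion_empties(self, rng):
        mask = rng.random((20, 20)) > 0.5
        out = apply_exclusion(mask, ExclusionMask(np.ones((20, 20), dtype=bool)))
        assert not out.any()

    def test_one_of_two_blobs(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:5, 2:5] = True
        mask[10:13, 10:13] = True
        exc = np.zeros((20, 20), dtype=bool)
        exc[9:14, 9:14] = True
        out = apply_exclusion(mask, ExclusionMask(exc))
        assert len(label_particles(out, 1.0)) == 1

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            apply_exclusion(np.zeros((5, 5), dtype=bool),
                            ExclusionMask(np.zeros((6, 6), dtype=bool)))


class TestLabelParticles:
    def test_diagonal_pixels_one_particle(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(label_particles(mask, 1.0, connectivity=8)) == 1
        assert len(label_particles(mask, 1.0, connectivity=4)) == 2

    def test_empty_mask(self):
        assert len(label_particles(np.zeros((5, 5), dtype=bool), 1.0)) == 0

    def test_hundred_squares(self):
        mask = np.zeros((100, 100), dtype=bool)
        for i in range(10):
            for j in range(10):
                mask[i * 10 : i * 10 + 5, j * 10 : j * 10 + 5] = True
        ps = label_particles(mask, 1.0)
        assert len(ps) == 100
        assert all(p.area_um2 == 25.0 for p in ps.particles)
        assert _flood_fill_components(mask) == sorted(p.area_px for p in ps.particles)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_flood_fill_oracle(self, seed):
        mask = np.random.default_rng(seed).random((40, 40)) > 0.7
        ps = label_particles(mask, 0.5)
        assert sorted(p.area_px for p in ps.particles) == _flood_fill_components(mask)
        np.testing.assert_allclose(
            sorted(p.area_um2 for p in ps.particles),
            [a * 0.25 for a in _flood_fill_components(mask)],
        )

    def test_area_um2_exact(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:5, 2:6] = True
        ps = label_particles(mask, 2.0)
        assert ps.particles[0].area_um2 == 12 * 4.0

    def test_border_flag(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, 3] = True
        mask[5, 5] = True
        flags = {p.touches_field_border for p in label_particles(mask, 1.0).particles}
        assert flags == {True, False}


class TestFilterByArea:
    def test_boundary_inclusive(self):
        ps = _particle_set([2, 8, 50, 300, 301, 500])
        kept = filter_by_area(ps, AreaInterval(8, 300))
        assert [p.area_um2 for p in kept.particles] == [8, 50, 300]

    def test_identity_interval(self):
        ps = _particle_set([2, 8, 50, 300, 301, 500])
        kept = filter_by_area(ps, AreaInterval(0, np.inf))
        assert kept.particles == ps.particles

    def test_all_below_min(self):
        ps = _particle_set([1, 2, 3])
        assert len(filter_by_area(ps, AreaInterval(8, 300))) == 0

    def test_idempotent(self):
        ps = _particle_set([2, 8, 50, 300, 301, 500])
        interval = AreaInterval(8, 300)
        once = filter_by_area(ps, interval)
        assert filter_by_area(once, interval).particles == once.particles

    def test_commutes_with_exclusion(self, rng):
        mask = rng.random((60, 60)) > 0.6
        exc = ExclusionMask(rng.random((60, 60)) > 0.8)
        interval = AreaInterval(3, 40)
        a = filter_by_area(label_particles(apply_exclusion(mask, exc), 1.0), interval)
        # excluding first then labelling/filtering equals filtering the same masked field
        b = filter_by_area(label_particles(mask & ~exc.grid, 1.0), interval)
        assert sorted(p.area_px for p in a.particles) == sorted(p.area_px for p in b.particles)

    def test_invalid_interval(self):
        with pytest.raises(ValidationError):
            AreaInterval(300, 8)


@pytest.fixture(scope="module")
def scene_with_anucleate():
    spec = SceneSpec(seed=11, n_cells=10, n_distractors=0, n_specks=0,
                     n_anucleate_foci=8)
    return generate_scene(spec), spec


class TestNucleusFilter:
    def _particles_and_counterstain(self, image, truth):
        stains = default_stain_matrix()
        conc = deconvolve(rgb_to_od(image), stains)
        ps = label_particles(truth.label_image > 0, image.microns_per_pixel)
        return ps, conc[:, :, 0]

    def test_nucleated_kept_anucleate_removed(self, scene_with_anucleate):
        (image, truth), _ = scene_with_anucleate
        ps, counter = self._particles_and_counterstain(image, truth)
        kept = nucleus_filter(ps, counter, overlap_fraction_min=0.2)
        assert len(kept) == truth.count("cell")
        assert all(p.has_nucleus for p in kept.particles)

    def test_zero_overlap_is_identity(self, scene_with_anucleate):
        (image, truth), _ = scene_with_anucleate
        ps, counter = self._particles_and_counterstain(image, truth)
        kept = nucleus_filter(ps, counter, overlap_fraction_min=0.0)
        assert len(kept) == len(ps)


class TestDepthBands:
    def _image(self, h=1400, w=200, mpp=1.0):
        return CalibratedImage(np.zeros((h, w, 3), dtype=np.uint8), mpp)

    def test_straight_line_band_rows(self):
        img = self._image()
        ann = BasalLineAnnotation(vertices=[[50, 0], [50, 199]])
        sub, deep = depth_band_regions(ann, img, [(0, 296), (296, 1184)])
        rows_sub = np.unique(np.nonzero(sub.mask)[0])
        rows_deep = np.unique(np.nonzero(deep.mask)[0])
        assert len(rows_sub) == 296 and rows_sub.min() == 50
        assert len(rows_deep) == 888 and rows_deep.min() == 50 + 296
        assert not (sub.mask & deep.mask).any()
        union_rows = np.unique(np.nonzero(sub.mask | deep.mask)[0])
        assert np.array_equal(union_rows, np.arange(50, 50 + 1184))

    def test_area_mm2(self):
        img = self._image(mpp=2.0)
        ann = BasalLineAnnotation(vertices=[[10, 0], [10, 199]])
        (band,) = depth_band_regions(ann, img, [(0, 100)])
        assert band.area_mm2 == pytest.approx(band.mask.sum() * 4.0 / 1e6)

    def test_tiny_band_never_negative(self):
        img = self._image(h=100)
        ann = BasalLineAnnotation(vertices=[[50, 0], [50, 199]])
        (band,) = depth_band_regions(ann, img, [(0, 0.25)])
        assert band.mask.sum() in (0, np.unique(np.nonzero(band.mask)[0]).size * 200)
        assert band.area_mm2 >= 0

    @pytest.mark.parametrize("amplitude,period", [(15.0, 60.0), (30.0, 150.0)])
    def test_partition_for_curved_line(self, amplitude, period):
        img = self._image(h=600, w=300)
        cols = np.arange(0, 300, 5, dtype=float)
        rows = 80 + amplitude * np.sin(2 * np.pi * cols / period)
        ann = BasalLineAnnotation(np.stack([rows, cols], axis=1))
        sub, deep = depth_band_regions(ann, img, [(0, 100), (100, 300)])
        (full,) = depth_band_regions(ann, img, [(0, 300)])
        assert not (sub.mask & deep.mask).any()
        np.testing.assert_array_equal(sub.mask | deep.mask, full.mask)

    def test_out_of_bounds_polyline(self):
        img = self._image(h=100, w=100)
        ann = BasalLineAnnotation(vertices=[[50, 0], [50, 150]])
        with pytest.raises(ValidationError):
            depth_band_regions(ann, img, [(0, 20)])

    def test_overlapping_bands_rejected(self):
        img = self._image(h=100, w=100)
        ann = BasalLineAnnotation(vertices=[[10, 0], [10, 99]])
        with pytest.raises(ValidationError):
            depth_band_regions(ann, img, [(0, 50), (40, 80)])


class TestSampleHpfs:
    def _region(self, h=200, w=200, mpp=1.0):
        mask = np.zeros((h, w), dtype=bool)
        mask[50:150, 50:150] = True
        return RegionSpec.from_mask("granulation", mask, mpp)

    def test_deterministic(self):
        region = self._region()
        a = sample_hpfs(region, 5, (32, 32), seed=9, microns_per_pixel=1.0)
        b = sample_hpfs(region, 5, (32, 32), seed=9, microns_per_pixel=1.0)
        assert a.rectangles == b.rectangles

    def test_requested_count(self):
        fields = sample_hpfs(self._region(), 5, (20, 20), seed=0, microns_per_pixel=1.0)
        assert len(fields.rectangles) == 5
        assert fields.total_area_mm2 == pytest.approx(5 * 400 / 1e6)

    def test_fields_inside_image(self):
        region = self._region()
        fields = sample_hpfs(region, 5, (40, 40), seed=3, microns_per_pixel=1.0)
        for r, c, h, w in fields.rectangles:
            assert 0 <= r and r + h <= 200 and 0 <= c and c + w <= 200
            assert region.mask[r + h // 2, c + w // 2]

    def test_too_small_region(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[10, 10] = True
        region = RegionSpec.from_mask("custom", mask, 1.0)
        with pytest.raises(ValidationError, match="1"):
            sample_hpfs(region, 5, (10, 10), seed=0, microns_per_pixel=1.0)

    def test_field_larger_than_image(self):
        with pytest.raises(ValidationError):
            sample_hpfs(self._region(), 1, (500, 500), seed=0, microns_per_pixel=1.0)


class TestDensity:
    def test_simple_ratio(self):
        ps = _particle_set([10] * 10)
        n, d = compute_density(ps, 0.5)
        assert (n, d) == (10, 20.0)

    def test_zero_cells(self):
        ps = _particle_set([])
        assert compute_density(ps, 1.0) == (0, 0.0)

    def test_nonpositive_area(self):
        with pytest.raises(ValidationError):
            compute_density(_particle_set([10]), 0.0)

    def test_generator_density(self, default_scene):
        image, truth = default_scene
        from ihcquant.pipeline import RunConfig, run_quantify

        rows, _ = run_quantify(RunConfig(), image, exclusion=truth.appendage_mask)
        (row,) = rows
        assert row.n_cells == truth.count("cell") == 30
        assert row.density_per_mm2 == pytest.approx(30 / image.physical_area_um2 * 1e6)


class TestCalibrateAreaRange:
    def test_min_max(self):
        iv = calibrate_area_range([8, 50, 300], 0.0, 1.0)
        assert (iv.min_um2, iv.max_um2) == (8.0, 300.0)

    def test_degenerate_rejected(self):
        with pytest.raises(ValidationError):
            calibrate_area_range([42, 42, 42], 0.0, 1.0)

    def test_too_few(self):
        with pytest.raises(ValidationError):
            calibrate_area_range([5], 0.0, 1.0)

    def test_quantiles_match_sorted_oracle(self, rng):
        areas = rng.lognormal(np.log(60), 0.5, size=1000)
        iv = calibrate_area_range(areas, 0.01, 0.99)
        inside = np.mean((areas >= iv.min_um2) & (areas <= iv.max_um2))
        assert inside >= 0.98
        srt = np.sort(areas)
        assert srt[9] <= iv.min_um2 <= srt[11]
        assert srt[988] <= iv.max_um2 <= srt[990]

    @given(st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None)
    def test_full_range_contains_all(self, seed):
        areas = np.random.default_rng(seed).uniform(1, 400, size=20)
        iv = calibrate_area_range(areas, 0.0, 1.0)
        assert iv.min_um2 == areas.min() and iv.max_um2 == areas.max()


class TestEndToEndRecovery:
    def test_count_recovery_with_distractors_and_specks(self):
        from ihcquant.pipeline import RunConfig, run_quantify

        spec = SceneSpec(seed=5, n_cells=25, n_distractors=4, n_specks=12)
        image, truth = generate_scene(spec)
        rows, _ = run_quantify(RunConfig(), image, exclusion=truth.appendage_mask)
        assert rows[0].n_cells == 25

    def test_density_upsampling_invariance(self):
        from ihcquant.pipeline import RunConfig, run_quantify

        image, truth = generate_scene(SceneSpec(seed=7))
        rows, _ = run_quantify(RunConfig(), image, exclusion=truth.appendage_mask)
        up = CalibratedImage(
            np.kron(image.pixels, np.ones((2, 2, 1), dtype=np.uint8)),
            image.microns_per_pixel / 2,
        )
        exc_up = ExclusionMask(np.kron(truth.appendage_mask.grid, np.ones((2, 2), dtype=bool)))
        rows_up, _ = run_quantify(RunConfig(), up, exclusion=exc_up)
        rel = abs(rows_up[0].density_per_mm2 - rows[0].density_per_mm2)
        assert rel / rows[0].density_per_mm2 < 0.05
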