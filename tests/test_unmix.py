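"""Linear-combination analyses: segment/triangle fractions, rr, dr, profiles."""

import numpy as np
import pytest

from phasorsnap import (
    CameraModel,
    Fluorophore,
    PhasorField,
    PhasorPoint,
    Segment,
    Triangle,
    WavelengthGrid,
    barycentric_fractions,
    dipolar_relaxation,
    fraction_on_segment,
    gaussian_spectrum,
    halfplane_pair_coloring,
    ideal_filter,
    make_gradient_phantom,
    make_layered_phantom,
    make_uniform_phantom,
    redox_ratio,
    render_triplet,
    slice_profile,
    spectrum_phasor,
    triplet_to_phasor,
    wavelength_window_mapping,
)
from phasorsnap.simulate import gradient_fractions
from phasorsnap.unmix import rank_sum_compare

DYE_A = Fluorophore("A", 470.0, 45.0)
DYE_B = Fluorophore("B", 600.0, 50.0)


def field_from_points(points, grid=None):
    pts = np.asarray(points, dtype=float).reshape(1, 1, -1, 2)
    G = pts[..., 0]
    S = pts[..., 1]
    return PhasorField(G=G, S=S, valid=np.ones(G.shape, dtype=bool),
                       threshold=0.0, offset=0.0, grid=grid or WavelengthGrid())


def dye_endpoints(grid):
    pa = spectrum_phasor(gaussian_spectrum(DYE_A, grid))
    pb = spectrum_phasor(gaussian_spectrum(DYE_B, grid))
    return pa, pb


class TestSegmentFractions:
    def test_degenerate_segment_rejected(self):
        p = PhasorPoint(0.1, 0.1)
        with pytest.raises(ValueError):
            Segment(p, PhasorPoint(0.1, 0.1 + 1e-9))

    def test_endpoint_midpoint_values(self):
        a, b = PhasorPoint(0.8, 0.2), PhasorPoint(-0.4, 0.6)
        f = field_from_points([(0.8, 0.2), (-0.4, 0.6), (0.2, 0.4)])
        t = fraction_on_segment(f, Segment(a, b))
        assert t.value[0, 0, 0] == pytest.approx(1.0)
        assert t.value[0, 0, 1] == pytest.approx(0.0)
        assert t.value[0, 0, 2] == pytest.approx(0.5)

    def test_off_line_point_projects_orthogonally(self):
        a, b = PhasorPoint(1.0, 0.0), PhasorPoint(0.0, 0.0)
        f = field_from_points([(0.3, 0.7)])  # displaced perpendicular to the line
        t = fraction_on_segment(f, Segment(a, b))
        assert t.raw[0, 0, 0] == pytest.approx(0.3)

    def test_raw_kept_value_clamped(self):
        a, b = PhasorPoint(0.0, 0.0), PhasorPoint(1.0, 0.0)
        f = field_from_points([(-0.2, 0.0), (1.4, 0.0)])
        t = fraction_on_segment(f, Segment(b, a))  # t = 1 at (1, 0)
        assert t.raw[0, 0, 0] == pytest.approx(-0.2)
        assert t.value[0, 0, 0] == 0.0
        assert t.raw[0, 0, 1] == pytest.approx(1.4)
        assert t.value[0, 0, 1] == 1.0

    @pytest.mark.parametrize("frac", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_noiseless_mixture_projects_to_programmed_fraction(
            self, grid, sine_filter, cosine_filter, frac):
        """Mixing-line property: a noiseless f:(1-f) intensity mixture lands at
        t = f on the pure-species connecting line, to 1e-9."""
        scene = make_uniform_phantom([(DYE_A, frac), (DYE_B, 1 - frac)],
                                     shape=(1, 2, 2), grid=grid)
        t3 = render_triplet(scene, sine_filter, cosine_filter,
                            CameraModel(offset=100.0), noiseless=True)
        f = triplet_to_phasor(t3)
        pa, pb = dye_endpoints(grid)
        t = fraction_on_segment(f, Segment(pa, pb))
        assert np.allclose(t.value[f.valid], frac, atol=1e-9)

    def test_affine_invariance(self, grid):
        """Translating and rotating points and endpoints together leaves t fixed."""
        rng = np.random.default_rng(3)
        pts = rng.uniform(-0.8, 0.8, size=(20, 2))
        a, b = PhasorPoint(0.5, 0.1), PhasorPoint(-0.3, -0.6)
        t0 = fraction_on_segment(field_from_points(pts), Segment(a, b)).raw
        angle = 0.7
        R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        shift = np.array([0.13, -0.21])
        pts2 = pts @ R.T + shift
        a2 = PhasorPoint(*(R @ [a.G, a.S] + shift))
        b2 = PhasorPoint(*(R @ [b.G, b.S] + shift))
        t1 = fraction_on_segment(field_from_points(pts2), Segment(a2, b2)).raw
        assert np.allclose(t0, t1, atol=1e-9)

    def test_noisy_two_component_recovery(self, grid, sine_filter, cosine_filter):
        """At 1e4 photons/voxel, mean |t_hat - t| <= 0.02 across fractions."""
        pa, pb = dye_endpoints(grid)
        seg = Segment(pa, pb)
        for i, frac in enumerate(np.arange(0.1, 0.95, 0.2)):
            scene = make_uniform_phantom([(DYE_A, frac), (DYE_B, 1 - frac)],
                                         shape=(4, 16, 16), grid=grid, photons=1e4)
            t3 = render_triplet(scene, sine_filter, cosine_filter,
                                CameraModel(offset=100.0, seed=100 + i))
            f = triplet_to_phasor(t3)
            t = fraction_on_segment(f, seg)
            err = np.abs(t.raw[f.valid] - frac)
            assert err.size >= 1000
            assert err.mean() <= 0.02


class TestBarycentricFractions:
    TRI = Triangle((PhasorPoint(-0.5, 0.7), PhasorPoint(0.6, 0.4),
                    PhasorPoint(0.0, -0.6)))

    def test_degenerate_triangle_rejected(self):
        with pytest.raises(ValueError):
            Triangle((PhasorPoint(0, 0), PhasorPoint(0.5, 0.5), PhasorPoint(1, 1)))

    def test_vertex_and_centroid(self):
        v = self.TRI.vertices
        centroid = (np.mean([p.G for p in v]), np.mean([p.S for p in v]))
        f = field_from_points([(v[0].G, v[0].S), centroid])
        f1, f2, f3 = barycentric_fractions(f, self.TRI)
        assert f1.value[0, 0, 0] == pytest.approx(1.0)
        assert f2.value[0, 0, 0] == pytest.approx(0.0)
        for m in (f1, f2, f3):
            assert m.value[0, 0, 1] == pytest.approx(1 / 3)

    def test_raw_fractions_sum_to_one(self):
        rng = np.random.default_rng(8)
        f = field_from_points(rng.uniform(-1, 1, size=(50, 2)))
        maps = barycentric_fractions(f, self.TRI)
        total = sum(m.raw for m in maps)
        assert np.allclose(total[f.valid], 1.0, atol=1e-12)

    def test_outside_points_clamped_and_renormalized(self):
        f = field_from_points([(0.9, -0.9)])  # outside the triangle
        maps = barycentric_fractions(f, self.TRI)
        vals = [m.value[0, 0, 0] for m in maps]
        raws = [m.raw[0, 0, 0] for m in maps]
        assert min(raws) < 0
        assert min(vals) >= 0
        assert sum(vals) == pytest.approx(1.0)

    def test_matches_linear_system_oracle(self):
        """Brute-force 2x2 solve of P = f1 V1 + f2 V2 + (1-f1-f2) V3."""
        rng = np.random.default_rng(12)
        pts = rng.uniform(-1, 1, size=(30, 2))
        f = field_from_points(pts)
        maps = barycentric_fractions(f, self.TRI)
        v = self.TRI.vertices
        A = np.array([[v[0].G - v[2].G, v[1].G - v[2].G],
                      [v[0].S - v[2].S, v[1].S - v[2].S]])
        for k, (g, s) in enumerate(pts):
            f12 = np.linalg.solve(A, [g - v[2].G, s - v[2].S])
            expect = [f12[0], f12[1], 1 - f12.sum()]
            got = [m.raw[0, 0, k] for m in maps]
            assert np.allclose(got, expect, atol=1e-12)

    def test_noiseless_three_dye_mixture_recovered(self, grid, sine_filter,
                                                   cosine_filter):
        dye_c = Fluorophore("C", 530.0, 40.0)
        fractions = (0.5, 0.3, 0.2)
        scene = make_uniform_phantom(
            [(DYE_A, fractions[0]), (dye_c, fractions[1]), (DYE_B, fractions[2])],
            shape=(1, 2, 2), grid=grid)
        t3 = render_triplet(scene, sine_filter, cosine_filter,
                            CameraModel(offset=100.0), noiseless=True)
        f = triplet_to_phasor(t3)
        tri = Triangle(tuple(
            spectrum_phasor(gaussian_spectrum(d, grid)) for d in (DYE_A, dye_c, DYE_B)))
        maps = barycentric_fractions(f, tri)
        for m, expect in zip(maps, fractions):
            assert np.allclose(m.value[f.valid], expect, atol=1e-9)


class TestTrajectoryIndices:
    SEG_NADH = PhasorPoint(0.35, 0.65)
    SEG_FAD = PhasorPoint(-0.45, 0.55)

    def test_midpoint_gives_unit_ratio(self):
        mid = ((self.SEG_NADH.G + self.SEG_FAD.G) / 2,
               (self.SEG_NADH.S + self.SEG_FAD.S) / 2)
        f = field_from_points([mid])
        rr, t = redox_ratio(f, self.SEG_NADH, self.SEG_FAD)
        assert t.value[0, 0, 0] == pytest.approx(0.5)
        assert rr.value[0, 0, 0] == pytest.approx(1.0)

    def test_endpoints_give_zero_and_cap(self):
        f = field_from_points([(self.SEG_NADH.G, self.SEG_NADH.S),
                               (self.SEG_FAD.G, self.SEG_FAD.S)])
        rr, t = redox_ratio(f, self.SEG_NADH, self.SEG_FAD, cap=100.0)
        assert rr.value[0, 0, 0] == 100.0  # t = 1 hits the cap
        assert rr.value[0, 0, 1] == 0.0

    def test_ratio_monotone_in_fraction(self):
        ts = np.linspace(0.05, 0.95, 19)
        pts = [(self.SEG_FAD.G + t * (self.SEG_NADH.G - self.SEG_FAD.G),
                self.SEG_FAD.S + t * (self.SEG_NADH.S - self.SEG_FAD.S)) for t in ts]
        rr, tmap = redox_ratio(field_from_points(pts), self.SEG_NADH, self.SEG_FAD)
        vals_t = tmap.value[0, 0]
        vals_rr = rr.value[0, 0]
        assert np.all(np.diff(vals_t) > 0)
        assert np.all(np.diff(vals_rr) > 0)

    def test_dipolar_relaxation_unrelaxed_endpoint_is_zero(self):
        relaxed, unrelaxed = PhasorPoint(-0.2, 0.8), PhasorPoint(0.5, 0.75)
        f = field_from_points([(0.5, 0.75)])
        dr, t = dipolar_relaxation(f, relaxed, unrelaxed)
        assert dr.value[0, 0, 0] == 0.0
        assert t.value[0, 0, 0] == 0.0

    def test_gradient_phantom_recovers_programmed_ramp(self, grid, sine_filter,
                                                       cosine_filter):
        """Axial NADH-fraction ramp: per-slice mean t is monotone and tracks
        the programmed gradient; lateral profiles stay flat."""
        nadh = Fluorophore("NADH", 460.0, 90.0)
        fad = Fluorophore("FAD", 535.0, 70.0)
        scene = make_gradient_phantom("z", 0.2, 0.8, (nadh, fad),
                                      shape=(12, 12, 12), grid=grid, photons=1e4)
        t3 = render_triplet(scene, sine_filter, cosine_filter,
                            CameraModel(offset=100.0, seed=21))
        f = triplet_to_phasor(t3)
        p_nadh = spectrum_phasor(gaussian_spectrum(nadh, grid))
        p_fad = spectrum_phasor(gaussian_spectrum(fad, grid))
        rr, tmap = redox_ratio(f, p_nadh, p_fad)
        prof_z = slice_profile(tmap, "z")
        programmed = gradient_fractions("z", 12, 0.2, 0.8)
        assert np.all(np.diff(prof_z["mean"]) > 0)
        assert np.allclose(prof_z["mean"], programmed, atol=0.03)
        for axis in ("y", "x"):
            prof = slice_profile(tmap, axis)
            assert prof["mean"].max() - prof["mean"].min() < 0.05

    def test_two_region_difference_flagged_by_rank_sum(self, grid, sine_filter,
                                                       cosine_filter):
        """Blue- vs green-shifted regions differ in dr; Mann-Whitney flags it."""
        blue = Fluorophore("probe_blue", 490.0, 60.0)
        green = Fluorophore("probe_green", 540.0, 60.0)
        scene = make_layered_phantom(
            [(4, [(blue, 0.7), (green, 0.3)]), (4, [(blue, 0.3), (green, 0.7)])],
            ny=8, nx=8, grid=grid, photons=1e4)
        t3 = render_triplet(scene, sine_filter, cosine_filter,
                            CameraModel(offset=100.0, seed=33))
        f = triplet_to_phasor(t3)
        p_rel = spectrum_phasor(gaussian_spectrum(green, grid))
        p_unrel = spectrum_phasor(gaussian_spectrum(blue, grid))
        dr, _ = dipolar_relaxation(f, p_rel, p_unrel)
        lower = dr.value[:4][np.isfinite(dr.value[:4])]
        upper = dr.value[4:][np.isfinite(dr.value[4:])]
        assert np.median(upper) > np.median(lower)  # programmed ordering
        assert rank_sum_compare(lower, upper) < 0.05


class TestHalfplanePairColoring:
    PAIR1 = Segment(PhasorPoint(-0.6, 0.6), PhasorPoint(0.6, 0.6))
    PAIR2 = Segment(PhasorPoint(-0.6, -0.6), PhasorPoint(0.6, -0.6))

    def test_pure_endpoint_assigned_to_own_half(self):
        f = field_from_points([(-0.6, 0.6), (0.6, -0.6)])
        labels, t = halfplane_pair_coloring(f, self.PAIR1, self.PAIR2)
        assert labels[0, 0, 0] == 1 and t[0, 0, 0] == pytest.approx(1.0)
        assert labels[0, 0, 1] == 2 and t[0, 0, 1] == pytest.approx(0.0)

    def test_dividing_line_tie_goes_to_half_one(self):
        # midpoints are (-0.6, 0) and (0.6, 0): the divide is the S = 0 axis
        f = field_from_points([(0.3, 0.0)])
        labels, _ = halfplane_pair_coloring(f, self.PAIR1, self.PAIR2)
        assert labels[0, 0, 0] == 1

    def test_coincident_midpoints_rejected(self):
        pair1 = Segment(PhasorPoint(-0.5, 0.0), PhasorPoint(0.5, 0.0))
        with pytest.raises(ValueError):
            halfplane_pair_coloring(field_from_points([(0, 0.1)]), pair1, pair1)

    def test_four_dye_layers_assigned_to_correct_pairs(self, grid, sine_filter,
                                                       cosine_filter):
        """Layers built from pair1's dyes land in half 1 with the right t, and
        pair2's layers in half 2."""
        d1a = Fluorophore("cfp", 476.0, 40.0)
        d1b = Fluorophore("rfp", 610.0, 45.0)
        d2a = Fluorophore("gfp", 508.0, 35.0)
        d2b = Fluorophore("sytox", 570.0, 40.0)
        scene = make_layered_phantom(
            [(2, [(d1a, 0.8), (d1b, 0.2)]), (2, [(d2a, 0.7), (d2b, 0.3)])],
            ny=4, nx=4, grid=grid)
        t3 = render_triplet(scene, sine_filter, cosine_filter,
                            CameraModel(offset=100.0), noiseless=True)
        f = triplet_to_phasor(t3)
        pair1 = Segment(spectrum_phasor(gaussian_spectrum(d1a, grid)),
                        spectrum_phasor(gaussian_spectrum(d1b, grid)))
        pair2 = Segment(spectrum_phasor(gaussian_spectrum(d2a, grid)),
                        spectrum_phasor(gaussian_spectrum(d2b, grid)))
        labels, t = halfplane_pair_coloring(f, pair1, pair2)
        assert np.all(labels[:2] == 1)
        assert np.all(labels[2:] == 2)
        assert np.allclose(t[:2], 0.8, atol=1e-9)
        assert np.allclose(t[2:], 0.7, atol=1e-9)


class TestWavelengthWindowMapping:
    WINDOWS = [(400.0, 480.0), (480.0, 540.0), (540.0, 600.0), (600.0, 700.0)]

    def delta_field(self, wavelength, grid):
        theta = 2 * np.pi * (wavelength - grid.lambda_min) / grid.span
        return field_from_points([(np.cos(theta), np.sin(theta))], grid)

    def test_blue_voxel_maps_to_first_window(self, grid):
        labels = wavelength_window_mapping(self.delta_field(450.0, grid), self.WINDOWS)
        assert labels[0, 0, 0] == 0

    def test_boundary_belongs_to_upper_window(self, grid):
        labels = wavelength_window_mapping(self.delta_field(480.0, grid), self.WINDOWS)
        assert labels[0, 0, 0] == 1

    def test_uncovered_center_is_unlabeled(self, grid):
        windows = [(400.0, 480.0), (600.0, 700.0)]
        labels = wavelength_window_mapping(self.delta_field(520.0, grid), windows)
        assert labels[0, 0, 0] == -1

    def test_overlapping_windows_rejected(self, grid):
        f = self.delta_field(450.0, grid)
        with pytest.raises(ValueError, match="overlap"):
            wavelength_window_mapping(f, [(400.0, 500.0), (480.0, 600.0)])

    def test_four_structure_phantom_recovered(self, grid, sine_filter, cosine_filter):
        """Spectrally overlapping organelle-like stains separate by window."""
        stains = [
            Fluorophore("nuc", 455.0, 40.0),
            Fluorophore("golgi", 512.0, 35.0),
            Fluorophore("mito", 565.0, 40.0),
            Fluorophore("lyso", 625.0, 45.0),
        ]
        scene = make_layered_phantom([(2, [(s, 1.0)]) for s in stains],
                                     ny=4, nx=4, grid=grid)
        t3 = render_triplet(scene, sine_filter, cosine_filter,
                            CameraModel(offset=100.0), noiseless=True)
        f = triplet_to_phasor(t3)
        labels = wavelength_window_mapping(f, self.WINDOWS)
        for i in range(4):
            layer = labels[2 * i : 2 * i + 2]
            values, counts = np.unique(layer, return_counts=True)
            assert values[np.argmax(counts)] == i


class TestSliceProfile:
    def test_homogeneous_map(self):
        arr = np.full((3, 4, 4), 0.4)
        prof = slice_profile(arr, "z")
        assert np.allclose(prof["mean"], 0.4)
        assert np.allclose(prof["sd"], 0.0)
        assert np.all(prof["n"] == 16)

    def test_programmed_ramp_recovered(self):
        arr = np.zeros((5, 3, 3))
        ramp = np.linspace(0, 1, 5)
        arr += ramp[:, None, None]
        prof = slice_profile(arr, "z")
        assert np.allclose(prof["mean"], ramp)
        for axis in ("y", "x"):
            p = slice_profile(arr, axis)
            assert np.allclose(p["mean"], ramp.mean())

    def test_single_voxel_mask(self):
        arr = np.arange(27, dtype=float).reshape(3, 3, 3)
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 2, 0] = True
        prof = slice_profile(arr, "z", mask=mask)
        assert prof.loc[1, "mean"] == arr[1, 2, 0]
        assert prof.loc[1, "sd"] == 0.0
        assert prof.loc[0, "n"] == 0 and np.isnan(prof.loc[0, "mean"])
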