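"""Forward model: point responses, sinogram synthesis, range compression, J."""

import numpy as np
import pytest

from mwisar import (
    AngularSweep,
    AntennaConfig,
    ForwardConfig,
    ForwardModelError,
    FrequencySweep,
    ImagingGrid,
    Scatterer,
    Scene,
    ScenePoint,
    Sinogram,
    build_sensitivity,
    effective_aperture,
    gain_cosine_power,
    gain_gaussian,
    point_response,
    range_compress,
    simulate_sinogram,
    stack_measurements,
    unstack_measurements,
)
from mwisar.constants import C0, Z0
from mwisar.geometry import bistatic_distances


def scene_of(points, eps_r=80.0, container=0.085):
    return Scene(tuple(Scatterer(p, 1.0) for p in points), eps_r, container)


class TestEffectiveAperture:
    def test_linear_in_wavelength(self):
        assert effective_aperture(1.0, 0.08) == pytest.approx(
            2 * effective_aperture(1.0, 0.04), rel=1e-14
        )

    def test_sqrt_in_power(self):
        assert effective_aperture(4.0, 0.05) == pytest.approx(
            2 * effective_aperture(1.0, 0.05), rel=1e-14
        )

    def test_closed_form(self):
        lam = 0.0335
        expect = np.sqrt(Z0 * 1.0 / (4 * np.pi)) * lam / (4 * np.pi)
        assert effective_aperture(1.0, lam, Z0) == pytest.approx(expect, rel=1e-14)

    def test_domain(self):
        with pytest.raises(ForwardModelError):
            effective_aperture(0.0, 0.05)


class TestPointResponse:
    def test_rcs_sqrt_scaling(self, tiny_cfg):
        sc = scene_of([ScenePoint(0.04, 120.0)])
        s1 = point_response(sc.scatterers[0], 1e9, 33.0, sc, tiny_cfg)
        big = Scatterer(ScenePoint(0.04, 120.0), 4.0)
        s4 = point_response(big, 1e9, 33.0, sc, tiny_cfg)
        assert abs(s4) == pytest.approx(2 * abs(s1), rel=1e-12)
        assert np.angle(s4) == pytest.approx(np.angle(s1), abs=1e-12)

    def test_origin_rotation_invariant(self, tiny_cfg):
        sc = scene_of([ScenePoint(0.0, 0.0)])
        vals = [
            point_response(sc.scatterers[0], 2e9, rot, sc, tiny_cfg)
            for rot in (0.0, 45.0, 133.0, 290.0)
        ]
        assert np.allclose(vals, vals[0], rtol=1e-12)

    def test_phase_equals_delay_oracle(self, tiny_cfg):
        # phase must be (2 pi f sqrt(eps)/c0)(d1+d2) mod 2pi
        sc = scene_of([ScenePoint(0.05, 200.0)])
        f, rot = 3.1e9, 77.0
        s = point_response(sc.scatterers[0], f, rot, sc, tiny_cfg)
        d1, d2 = bistatic_distances(
            ScenePoint(0.05, (200.0 + rot) % 360), tiny_cfg.antenna
        )
        expect = (2 * np.pi * f * np.sqrt(80.0) / C0) * (d1 + d2)
        assert np.angle(s) == pytest.approx(
            np.angle(np.exp(1j * expect)), abs=1e-9
        )

    def test_frequency_outside_sweep_rejected(self, tiny_cfg):
        sc = scene_of([ScenePoint(0.05, 0.0)])
        with pytest.raises(ForwardModelError):
            point_response(sc.scatterers[0], 9e9, 0.0, sc, tiny_cfg)


class TestSimulateSinogram:
    def test_empty_scene_is_zero(self, tiny_cfg):
        sg = simulate_sinogram(Scene((), 80.0, 0.085), tiny_cfg)
        assert np.all(sg.values == 0)
        assert sg.values.shape == (16, 20)

    def test_superposition(self, tiny_cfg):
        a = scene_of([ScenePoint(0.03, 10.0)])
        b = scene_of([ScenePoint(0.05, 250.0)])
        ab = scene_of([ScenePoint(0.03, 10.0), ScenePoint(0.05, 250.0)])
        got = simulate_sinogram(ab, tiny_cfg).values
        expect = simulate_sinogram(a, tiny_cfg).values + simulate_sinogram(b, tiny_cfg).values
        assert np.allclose(got, expect, rtol=1e-12)

    def test_uniform_rcs_scaling_is_degree_half(self, tiny_cfg):
        pts = [ScenePoint(0.03, 10.0), ScenePoint(0.05, 250.0)]
        sc1 = scene_of(pts)
        sc9 = Scene(tuple(Scatterer(p, 9.0) for p in pts), 80.0, 0.085)
        assert np.allclose(
            simulate_sinogram(sc9, tiny_cfg).values,
            3.0 * simulate_sinogram(sc1, tiny_cfg).values,
            rtol=1e-12,
        )

    def test_matches_point_response_entries(self, tiny_cfg):
        sc = scene_of([ScenePoint(0.06, 180.0)])
        sg = simulate_sinogram(sc, tiny_cfg)
        f = tiny_cfg.sweep.frequencies
        ang = tiny_cfg.rotation.angles_deg
        for m, n in [(0, 0), (5, 7), (15, 19)]:
            expect = point_response(sc.scatterers[0], f[m], ang[n], sc, tiny_cfg)
            assert sg.values[m, n] == pytest.approx(expect, rel=1e-12)

    def test_rotation_consistency_column_permutation(self, tiny_cfg):
        # rotating every scatterer by one angular step shifts columns by one
        step = 360.0 / tiny_cfg.rotation.n_positions
        sc = scene_of([ScenePoint(0.04, 77.0), ScenePoint(0.02, 300.0)])
        rot = scene_of([ScenePoint(0.04, 77.0 + step), ScenePoint(0.02, 300.0 + step)])
        a = simulate_sinogram(sc, tiny_cfg).values
        b = simulate_sinogram(rot, tiny_cfg).values
        assert np.allclose(b[:, :-1], a[:, 1:], rtol=1e-10)

    def test_scatterer_outside_container_rejected(self):
        with pytest.raises(ForwardModelError):
            scene_of([ScenePoint(0.09, 0.0)])

    def test_gain_models_reduce_offaxis_amplitude(self, tiny_cfg):
        sc = scene_of([ScenePoint(0.06, 90.0)])
        iso = simulate_sinogram(sc, tiny_cfg).values
        for gain in (gain_cosine_power(2), gain_gaussian(40.0)):
            cfg = ForwardConfig(
                tiny_cfg.antenna, tiny_cfg.sweep, tiny_cfg.rotation, gain=gain
            )
            tapered = simulate_sinogram(sc, cfg).values
            assert np.all(np.abs(tapered) <= np.abs(iso) * (1 + 1e-12))


class TestStacking:
    def test_angle_major_frequency_fastest(self):
        v = np.arange(6).reshape(2, 3)  # M=2 freqs, N=3 angles
        assert list(stack_measurements(v)) == [0, 3, 1, 4, 2, 5]

    def test_round_trip(self, rng):
        v = rng.standard_normal((5, 7)) + 1j * rng.standard_normal((5, 7))
        assert np.array_equal(unstack_measurements(stack_measurements(v), 5), v)


class TestRangeCompress:
    def make_sinogram(self, spectrum_col, sweep):
        vals = np.tile(spectrum_col[:, None], (1, 4))
        return Sinogram(vals, sweep, AngularSweep(4), 80.0)

    def test_flat_spectrum_rect_is_impulse_at_zero(self):
        sweep = FrequencySweep(0.1e9, 4.8e9, 64)
        sg = self.make_sinogram(np.ones(64, dtype=complex), sweep)
        rp = range_compress(sg, window="rect")
        mag = np.abs(rp.values[:, 0])
        assert np.argmax(mag) == 0
        assert mag[1:].max() < 1e-10 * mag[0]

    def test_delay_ramp_peaks_at_nearest_bin(self):
        sweep = FrequencySweep(0.1e9, 4.8e9, 64)
        tau0 = 17 / (64 * sweep.df)  # exactly on bin 17
        spec = np.exp(2j * np.pi * sweep.frequencies * tau0)
        rp = range_compress(self.make_sinogram(spec, sweep), window="rect")
        assert np.argmax(np.abs(rp.values[:, 0])) == 17
        # dense DFT oracle: brute-force correlation over a fine delay grid
        taus = np.linspace(0, 1 / sweep.df, 4096, endpoint=False)
        dense = np.abs(np.exp(-2j * np.pi * np.outer(taus, sweep.frequencies)) @ spec)
        assert abs(taus[np.argmax(dense)] - tau0) < 1 / (64 * sweep.df)

    @pytest.mark.parametrize("window", ["rect", "hann", "hamming"])
    def test_parseval(self, window, rng):
        sweep = FrequencySweep(0.1e9, 4.8e9, 50)
        spec = rng.standard_normal(50) + 1j * rng.standard_normal(50)
        sg = self.make_sinogram(spec, sweep)
        rp = range_compress(sg, window=window)
        from scipy.signal import get_window

        w = get_window({"rect": "boxcar"}.get(window, window), 50, fftbins=False)
        e_spec = np.sum(np.abs(w * spec) ** 2)
        e_prof = np.sum(np.abs(rp.values[:, 0]) ** 2)
        assert e_prof == pytest.approx(e_spec, rel=1e-9)

    def test_unknown_window(self, tiny_cfg):
        sg = simulate_sinogram(scene_of([ScenePoint(0.03, 0.0)]), tiny_cfg)
        with pytest.raises(ForwardModelError):
            range_compress(sg, window="kaiser17")

    def test_target_delay_matches_geometry(self):
        # peak delay per angle tracks the bistatic path of the rotated target;
        # needs enough bins that the water delay stays below the alias limit
        cfg = ForwardConfig(
            AntennaConfig(0.085), FrequencySweep(0.1e9, 4.8e9, 64), AngularSweep(12)
        )
        sc = scene_of([ScenePoint(0.06, 180.0)])
        sg = simulate_sinogram(sc, cfg)
        rp = range_compress(sg, window="rect")
        peaks = rp.delays[np.argmax(np.abs(rp.values), axis=0)]
        expect = np.array(
            [
                sum(bistatic_distances(ScenePoint(0.06, 180.0 + a), cfg.antenna))
                for a in cfg.rotation.angles_deg
            ]
        ) * np.sqrt(80.0) / C0
        assert np.all(np.abs(peaks - expect) <= rp.delay_bin)


class TestSensitivityMatrix:
    def test_shape(self, tiny_cfg):
        g = ImagingGrid(8, 0.08)
        J = build_sensitivity(g, 80.0, tiny_cfg, container_radius=0.085)
        assert J.shape == (16 * 20, 64)

    def test_underdetermined_rejected(self, tiny_cfg):
        with pytest.raises(ForwardModelError, match="under-determined"):
            build_sensitivity(ImagingGrid(32, 0.08), 80.0, tiny_cfg)

    def test_columns_equal_single_scatterer_sinograms(self, tiny_cfg):
        g = ImagingGrid(8, 0.08)
        J = build_sensitivity(g, 80.0, tiny_cfg, container_radius=0.085)
        for k in (0, 27, 36, 63):
            x, y = g.index_to_xy(k)
            if np.hypot(x, y) >= 0.085:
                assert np.all(J.matrix[:, k] == 0)
                continue
            sg = simulate_sinogram(scene_of([ScenePoint.from_xy(x, y)]), tiny_cfg)
            svec = stack_measurements(sg.values)
            assert np.allclose(J.matrix[:, k], svec, rtol=1e-12, atol=0)

    def test_in_container_columns_finite_positive(self, tiny_cfg):
        g = ImagingGrid(8, 0.08)
        J = build_sensitivity(g, 80.0, tiny_cfg, container_radius=0.085)
        inside = np.array(
            [np.hypot(*g.index_to_xy(k)) < 0.085 for k in range(g.n_pixels)]
        )
        mags = np.abs(J.matrix[:, inside])
        assert np.all(np.isfinite(mags)) and np.all(mags > 0)

    def test_forward_consistency_pixel_aligned_scene(self, tiny_cfg):
        # J @ sqrt(rcs)-weights reproduces the sinogram of a pixel-aligned scene
        g = ImagingGrid(8, 0.08)
        J = build_sensitivity(g, 80.0, tiny_cfg, container_radius=0.085)
        ks, rcs = [10, 45], [1.0, 4.0]
        scatterers = tuple(
            Scatterer(ScenePoint.from_xy(*g.index_to_xy(k)), r)
            for k, r in zip(ks, rcs)
        )
        sg = simulate_sinogram(Scene(scatterers, 80.0, 0.085), tiny_cfg)
        w = np.zeros(g.n_pixels)
        for k, r in zip(ks, rcs):
            w[k] = np.sqrt(r)
        assert np.allclose(
            J.matrix @ w, stack_measurements(sg.values), rtol=1e-10
        )

    def test_chunking_invariant(self, tiny_cfg):
        g = ImagingGrid(8, 0.08)
        a = build_sensitivity(g, 80.0, tiny_cfg, container_radius=0.085, chunk_pixels=7)
        b = build_sensitivity(g, 80.0, tiny_cfg, container_radius=0.085, chunk_pixels=64)
        assert np.array_equal(a.matrix, b.matrix)
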