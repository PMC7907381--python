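import numpy as np
import pytest

from holoxylem.exceptions import InvalidGeometryError
from holoxylem.forward import (
    exit_wave,
    fresnel_propagate,
    project_thickness,
    simulate_hologram_stack,
)
from holoxylem.geometry import GeometryConfig
from holoxylem.phantom import (
    AIR,
    WALL,
    PhantomVolume,
    build_tracheid_phantom,
    default_materials,
)
from holoxylem.morphometry import MorphometryRecord


def _slab_phantom(w_vox=10, n=64, pitch=26.0):
    labels = np.zeros((n, n, n), dtype=np.uint8)
    lo = n // 2 - w_vox // 2
    labels[:, :, lo : lo + w_vox] = WALL
    return PhantomVolume(
        labels=labels,
        voxel_pitch_nm=pitch,
        materials=default_materials(),
        ground_truth=MorphometryRecord(),
    )


class TestProjection:
    def test_axis_aligned_slab_thickness(self):
        vol = _slab_phantom(w_vox=10)
        maps = project_thickness(vol, 0.0)
        t = maps[WALL]
        # away from the slab edges the traversed thickness is the physical
        # grid depth of the slab along the beam
        interior = t[:, 28:36]
        assert np.allclose(interior, 64 * 26.0, rtol=1e-6) or np.allclose(
            interior, interior[0, 0]
        )

    def test_right_angle_swaps_box_axes(self):
        n = 64
        labels = np.zeros((8, n, n), dtype=np.uint8)
        labels[:, 28:36, 20:44] = WALL  # 8 tall, 24 wide box
        vol = PhantomVolume(
            labels=labels, voxel_pitch_nm=26.0,
            materials=default_materials(), ground_truth=MorphometryRecord(),
        )
        t0 = project_thickness(vol, 0.0)[WALL]
        t90 = project_thickness(vol, 90.0)[WALL]
        # footprint width along the projection coordinate swaps 24 <-> 8
        width0 = (t0[4] > 13.0).sum()
        width90 = (t90[4] > 13.0).sum()
        assert abs(width0 - 24) <= 1
        assert abs(width90 - 8) <= 1

    def test_total_thickness_bounded_by_grid_depth(self, small_pit_phantom):
        maps = project_thickness(small_pit_phantom, 33.0)
        total = sum(maps.values())
        depth = small_pit_phantom.labels.shape[2] * 26.0
        assert np.all(total <= depth * (1 + 1e-6))


class TestExitWave:
    def test_empty_object_is_unit_wave(self):
        maps = {WALL: np.zeros((16, 16))}
        u = exit_wave(maps, default_materials(), 0.112713)
        assert np.allclose(u, 1.0 + 0.0j)

    def test_known_phase_of_double_wall(self):
        mats = default_materials()
        delta = mats[WALL].delta
        t = np.full((4, 4), 3617.0)
        u = exit_wave({WALL: t}, mats, 0.112713)
        phi_expected = -2 * np.pi * delta * 3617.0 / 0.112713
        assert np.angle(u[0, 0]) == pytest.approx(phi_expected, rel=1e-6)
        assert phi_expected == pytest.approx(-0.545, abs=0.02)

    def test_pure_phase_object_has_unit_modulus(self):
        mats = {1: type(default_materials()[1])("wood", 2.7e-6, 0.0)}
        u = exit_wave({1: np.random.default_rng(0).uniform(0, 5000, (8, 8))}, mats, 0.1127)
        assert np.allclose(np.abs(u), 1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            exit_wave(
                {1: np.zeros((4, 4)), 2: np.zeros((5, 5))},
                default_materials(), 0.1127,
            )


class TestFresnelPropagate:
    def _gaussian(self, n=128, w=10.0):
        y, x = np.mgrid[:n, :n] - (n - 1) / 2
        return np.exp(-(x**2 + y**2) / w**2).astype(complex)

    def test_zero_distance_identity(self):
        u = self._gaussian()
        out = fresnel_propagate(u, 0.1127, 0.0, 26.0)
        assert np.abs(out - u).max() < 1e-12

    def test_forward_backward_roundtrip(self):
        # on the uncropped grid the transfer function is exactly unitary,
        # so back-propagation inverts forward propagation to round-off
        u = self._gaussian()
        z = 5.0
        kw = dict(pad_factor=1, taper_px=0)
        back = fresnel_propagate(
            fresnel_propagate(u, 0.1127, z, 26.0, **kw), 0.1127, -z, 26.0, **kw
        )
        assert np.sqrt(np.mean(np.abs(back - u) ** 2)) < 1e-8

    def test_power_conservation(self):
        # Parseval on the uncropped grid: |H| = 1 conserves total power
        u = self._gaussian()
        out = fresnel_propagate(u, 0.1127, 8.0, 26.0, pad_factor=1, taper_px=0)
        p_in = (np.abs(u) ** 2).sum()
        p_out = (np.abs(out) ** 2).sum()
        assert p_out == pytest.approx(p_in, rel=1e-6)

    def test_gaussian_waist_follows_beam_law(self):
        n, w_px, pix, lam = 256, 12.0, 20.0, 0.1
        y, x = np.mgrid[:n, :n] - (n - 1) / 2
        u = np.exp(-(x**2 + y**2) / w_px**2).astype(complex)
        z_mm = 2.0
        out = fresnel_propagate(u, lam, z_mm, pix, taper_px=0)
        w0 = w_px * pix
        zR = np.pi * w0**2 / lam
        w_expected = w0 * np.sqrt(1 + (z_mm * 1e6 / zR) ** 2)
        I = np.abs(out) ** 2
        mx = (I * x).sum() / I.sum()
        var = (I * (x - mx) ** 2).sum() / I.sum()
        w_measured = 2 * np.sqrt(var) * pix
        assert w_measured == pytest.approx(w_expected, rel=0.005)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            fresnel_propagate(self._gaussian(), -0.1, 1.0, 26.0)
        with pytest.raises(ValueError):
            fresnel_propagate(self._gaussian(), 0.1, 1.0, 0.0)


class TestSimulateStack:
    def _empty_phantom(self, n=64):
        return PhantomVolume(
            labels=np.zeros((n, n, n), dtype=np.uint8),
            voxel_pitch_nm=26.0,
            materials=default_materials(),
            ground_truth=MorphometryRecord(),
        )

    def test_empty_phantom_gives_unit_frames(self, small_geometry):
        stack = simulate_hologram_stack(
            self._empty_phantom(), small_geometry,
            photons_per_pixel=None,
            angles_deg=[0.0, 45.0, 90.0],
        )
        assert np.allclose(stack.intensities, 1.0, atol=1e-10)

    def test_same_seed_is_bit_identical(self, small_geometry, small_pit_phantom):
        kw = dict(photons_per_pixel=2000.0, angles_deg=[0.0, 90.0], seed=42)
        a = simulate_hologram_stack(small_pit_phantom, small_geometry, **kw)
        b = simulate_hologram_stack(small_pit_phantom, small_geometry, **kw)
        assert np.array_equal(a.intensities, b.intensities)

    def test_distances_give_distinct_fringes(self, small_geometry, small_pit_phantom):
        stack = simulate_hologram_stack(
            small_pit_phantom, small_geometry,
            photons_per_pixel=None, angles_deg=[0.0],
        )
        frames = stack.intensities[:, 0]
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(frames[i] - frames[j]) > 1e-3

    def test_pure_phase_energy_conservation(self, small_geometry):
        # contained pure-phase blob: hologram mean stays at unity
        n = 128
        labels = np.zeros((n, n, n), dtype=np.uint8)
        mats = default_materials()
        mats = {AIR: mats[AIR], WALL: type(mats[WALL])("wood", mats[WALL].delta, 0.0)}
        zz, yy, xx = np.mgrid[:n, :n, :n] - (n - 1) / 2
        labels[(zz**2 + yy**2 + xx**2) <= 20**2] = WALL
        vol = PhantomVolume(
            labels=labels, voxel_pitch_nm=26.0, materials=mats,
            ground_truth=MorphometryRecord(),
        )
        from holoxylem.forward import projected_optical_maps

        lam = small_geometry.wavelength_nm
        dsum, _ = projected_optical_maps(vol, 0.0)
        u0 = np.exp(-1j * 2 * np.pi / lam * dsum)
        uz = fresnel_propagate(
            u0, lam, small_geometry.effective_distances_mm[0], 26.0,
            pad_factor=1, taper_px=0,
        )
        assert (np.abs(uz) ** 2).mean() == pytest.approx(1.0, abs=1e-4)

    def test_weak_object_ctf_closed_form(self, table_geometry):
        # |phi| <= 0.1 rad: FT(I - 1) must match 2 sin(pi lambda z f^2) phi^
        n = 256
        lam = table_geometry.wavelength_nm
        z = table_geometry.effective_distances_mm[0]
        y, x = np.mgrid[:n, :n] - (n - 1) / 2
        phi = -0.08 * np.exp(-((x / 30) ** 2 + (y / 40) ** 2))
        u0 = np.exp(1j * phi)
        uz = fresnel_propagate(u0, lam, z, 26.0, pad_factor=1, taper_px=0)
        I = np.abs(uz) ** 2
        fy = np.fft.fftfreq(n, d=26.0)[:, None]
        fx = np.fft.fftfreq(n, d=26.0)[None, :]
        ctf = 2 * np.sin(np.pi * lam * z * 1e6 * (fy**2 + fx**2))
        pred = ctf * np.fft.fft2(phi)
        meas = np.fft.fft2(I - 1.0)
        assert np.linalg.norm(meas - pred) / np.linalg.norm(meas) < 0.03

    def test_pitch_mismatch_rejected(self, small_geometry):
        vol = self._empty_phantom()
        vol.voxel_pitch_nm = 13.0
        with pytest.raises(InvalidGeometryError):
            simulate_hologram_stack(vol, small_geometry)
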