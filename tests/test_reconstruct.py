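import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from holoxylem.exceptions import CannotAlignError
from holoxylem.forward import _rotate_project_slices
from holoxylem.geometry import GeometryConfig
from holoxylem.reconstruct import (
    align_projections,
    fbp_reconstruct,
    find_rotation_center,
)


def _disc_sinogram(n=128, radius=20.0, sigma=2.0, angles=None):
    """Analytic parallel-beam sinogram of a centred disc.

    The disc carries a subpixel Gaussian edge of width ``sigma`` so the
    object is representable at the grid's band limit; its projections are
    the Gaussian-smoothed chord lengths (smoothing commutes with the
    projection).
    """
    if angles is None:
        angles = np.arange(0.0, 180.0, 0.2)
    c = float(n // 2)  # the backprojector's axis column
    s = np.arange(n) - c
    p = gaussian_filter1d(2.0 * np.sqrt(np.clip(radius**2 - s * s, 0.0, None)), sigma)
    projs = np.tile(p, (len(angles), 1))[:, None, :]
    f = 4
    yy, xx = (np.mgrid[: n * f, : n * f] + 0.5) / f - 0.5
    hard = (((yy - c) ** 2 + (xx - c) ** 2) <= radius**2).astype(float)
    ref = gaussian_filter(hard, sigma * f).reshape(n, f, n, f).mean(axis=(1, 3))
    return projs, np.asarray(angles, float), ref


class TestFindRotationCenter:
    def _pair(self, axis_column, n=128):
        # opposing parallel-beam views mirror about the rotation axis:
        # p180(s) = p0(2a - s) for axis column a
        y, x = np.mgrid[:n, :n]
        p0 = np.exp(-((x - 70.0) ** 2 + (y - 50.0) ** 2) / 150.0)
        p0 += 0.6 * np.exp(-((x - 40.0) ** 2 + (y - 90.0) ** 2) / 80.0)
        coords = np.stack(np.mgrid[:n, :n]).astype(float)
        coords[1] = 2.0 * axis_column - coords[1]
        p180 = ndi.map_coordinates(p0, coords, order=3, mode="constant")
        return p0, p180

    def test_centered_pair(self):
        n = 129
        y, x = np.mgrid[:n, :n]
        img = np.exp(-((x - 64.0) ** 2 + (y - 50.0) ** 2) / 150.0)
        center = find_rotation_center(img, img[:, ::-1])
        assert center == pytest.approx((n - 1) / 2.0, abs=0.25)

    def test_recovers_injected_offset(self):
        a = (128 - 1) / 2.0 + 3.7
        p0, p180 = self._pair(axis_column=a)
        assert find_rotation_center(p0, p180) == pytest.approx(a, abs=0.25)

    def test_blank_projections_rejected(self):
        with pytest.raises(CannotAlignError):
            find_rotation_center(np.ones((32, 32)), np.ones((32, 32)))


class TestAlignProjections:
    def _jittered_stack(self, sigma=2.0, seed=0):
        n = 64
        zz, yy, xx = np.mgrid[:48, :n, :n]
        # an axially varying pair of rods so vertical jitter is observable
        vol = (((yy - 25.0) ** 2 + (xx - 38.0) ** 2) <= 12**2) & (zz > 8 + zz * 0)
        vol = vol.astype(float)
        vol += 0.5 * ((((yy - 45.0) ** 2 + (xx - 22.0) ** 2) <= 6**2) & (zz < 40))
        vol *= 1.0 + 0.3 * np.sin(zz / 5.0)
        angles = np.arange(0.0, 180.0, 3.0)
        clean = np.stack([_rotate_project_slices(vol, a) for a in angles])
        rng = np.random.default_rng(seed)
        shifts = rng.normal(0.0, sigma, size=(len(angles), 2))
        jittered = np.stack(
            [
                np.fft.ifftn(ndi.fourier_shift(np.fft.fftn(p), s)).real
                for p, s in zip(clean, shifts)
            ]
        )
        return clean, jittered, shifts, angles

    @staticmethod
    def _gauge_free(residual, angles):
        # a constant plus single-period sinusoid in the shift trajectories
        # is a rigid translation of the object: unobservable, removed
        # before scoring
        theta = np.deg2rad(angles)
        design = np.column_stack(
            [np.cos(theta), np.sin(theta), np.ones_like(theta)]
        )
        ry = residual[:, 0] - residual[:, 0].mean()
        rx = residual[:, 1] - design @ np.linalg.lstsq(
            design, residual[:, 1], rcond=None
        )[0]
        return np.sqrt(ry**2 + rx**2)

    def test_jitter_free_stack_unmoved(self):
        clean, _, _, angles = self._jittered_stack(sigma=0.0)
        _, shifts = align_projections(clean, angles)
        assert np.abs(shifts).max() < 0.1

    @pytest.mark.parametrize("seed", [3, 5])
    def test_recovers_injected_jitter(self, seed):
        _, jittered, true_shifts, angles = self._jittered_stack(sigma=2.0,
                                                                seed=seed)
        aligned, found = align_projections(jittered, angles)
        residual = self._gauge_free(found + true_shifts, angles)
        assert np.quantile(residual, 0.95) < 0.5

    def test_idempotent(self):
        _, jittered, _, angles = self._jittered_stack(sigma=2.0, seed=5)
        aligned, _ = align_projections(jittered, angles)
        _, second = align_projections(aligned, angles)
        assert np.abs(second).max() < 0.1


class TestFbpReconstruct:
    def test_zero_projections_give_zero_volume(self):
        tomo = fbp_reconstruct(np.zeros((8, 4, 32)), np.linspace(0, 179, 8))
        assert np.all(tomo.values == 0)

    def test_analytic_disc_sinogram(self):
        projs, angles, ref = _disc_sinogram()
        tomo = fbp_reconstruct(projs, angles, pixel_nm=1.0, wavelength_nm=None,
                               filter_name="ramp")
        rec = tomo.values[0]
        assert np.sqrt(np.mean((rec - ref) ** 2)) < 0.02  # of unit contrast
        n = rec.shape[0]
        c = float(n // 2)
        yy, xx = np.mgrid[:n, :n]
        interior = ((yy - c) ** 2 + (xx - c) ** 2) <= (20.0 - 4) ** 2
        assert rec[interior].mean() == pytest.approx(1.0, rel=0.05)

    def test_angle_schedule_from_table_configuration(self):
        g = GeometryConfig()
        angles = g.angles_deg
        assert len(angles) == 900
        assert angles[0] == 0.0
        assert angles[-1] == pytest.approx(179.8)

    def test_linearity(self):
        projs, angles, _ = _disc_sinogram(n=64, radius=10.0, angles=np.arange(0, 180, 5.0))
        a = fbp_reconstruct(projs, angles, wavelength_nm=None).values
        b = fbp_reconstruct(3.5 * projs, angles, wavelength_nm=None).values
        assert np.allclose(b, 3.5 * a, atol=1e-6 * np.abs(a).max())

    def test_too_few_angles_rejected(self):
        with pytest.raises(ValueError):
            fbp_reconstruct(np.zeros((2, 4, 16)), [0.0, 90.0])

    def test_delta_scaling_from_phase(self):
        # a phase sinogram divided by -2 pi pitch / lambda estimates delta
        lam, pitch, delta = 0.1127, 26.0, 2.7e-6
        projs, angles, ref = _disc_sinogram(n=64, radius=12.0,
                                            angles=np.arange(0, 180, 1.0))
        phase = projs * (-2 * np.pi * pitch / lam) * delta  # radians
        tomo = fbp_reconstruct(phase, angles, pixel_nm=pitch, wavelength_nm=lam,
                               filter_name="ramp")
        rec = tomo.values[0]
        n = rec.shape[0]
        c = float(n // 2)
        yy, xx = np.mgrid[:n, :n]
        interior = ((yy - c) ** 2 + (xx - c) ** 2) <= 8.0**2
        assert rec[interior].mean() == pytest.approx(delta, rel=0.05)

    def test_contrast_ordering_of_reconstructed_materials(self, small_pit_phantom):
        # gallium > wall > air on the delta scale, mirroring its higher
        # refractive-index decrement (display polarity is a convention)
        from holoxylem.phantom import AIR, GALLIUM, WALL, add_gallium_layer

        vol = add_gallium_layer(small_pit_phantom, 78.0)
        angles = np.arange(0.0, 180.0, 1.0)
        dvol = vol.delta_volume()
        projs = np.stack([_rotate_project_slices(dvol, a) for a in angles])
        tomo = fbp_reconstruct(projs, angles, pixel_nm=26.0, wavelength_nm=None)
        rec = tomo.values
        ga = rec[vol.labels == GALLIUM].mean()
        wall = rec[vol.labels == WALL].mean()
        air = rec[vol.labels == AIR].mean()
        assert ga > wall > air

    def test_angle_decimation_degrades_monotonically(self):
        # decimating the angle schedule into the undersampled regime for
        # this object's band limit grows the reconstruction error
        # monotonically without destroying the image
        n = 128
        yy, xx = np.mgrid[:n, :n] - (n - 1) / 2.0
        img = ((yy**2 + xx**2) <= 40**2).astype(float)
        img[np.abs(yy) < 5] = 0.0  # slit, breaks rotational symmetry
        img += ((yy - 20) ** 2 + (xx - 45) ** 2) <= 8**2
        img = gaussian_filter(np.clip(img, 0, 1) * 2.7e-6, 1.5)
        errors = []
        for n_angles in (180, 45, 24, 12):
            angles = np.linspace(0.0, 180.0, n_angles, endpoint=False)
            projs = np.stack([_rotate_project_slices(img[None], a) for a in angles])
            rec = fbp_reconstruct(projs, angles, wavelength_nm=None,
                                  filter_name="ramp").values[0]
            errors.append(np.sqrt(np.mean((rec - img) ** 2)))
        assert errors[0] <= errors[1] <= errors[2] <= errors[3]
        assert errors[3] < 0.5 * img.max()  # degraded, not destroyed
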