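import numpy as np
import pytest

from holoxylem.forward import fresnel_propagate
from holoxylem.geometry import GeometryConfig
from holoxylem.retrieval import (
    Constraints,
    PhaseProjectionSet,
    ctf_retrieve,
    destripe,
    iterative_retrieve,
)

GEO = GeometryConfig()
LAM = GEO.wavelength_nm
ZS = GEO.effective_distances_mm
PIX = 26.0


def _simulate(phi, photons=None, seed=None, pad_factor=2):
    """Noise-free (or Poisson) 3-distance holograms of a phase map.

    ``pad_factor=1`` gives the circular (periodic) discrete model, exactly
    invertible by a retrieval using the same grid — the right setting for
    fixed-point and equivariance checks.
    """
    u0 = np.exp(1j * phi)
    holos = np.stack(
        [np.abs(fresnel_propagate(u0, LAM, z, PIX, pad_factor=pad_factor,
                                  taper_px=0 if pad_factor == 1 else 16)) ** 2
         for z in ZS]
    )
    if photons is not None:
        rng = np.random.default_rng(seed)
        holos = rng.poisson(holos * photons) / photons
    return holos


def _blob_phase(n=128, amp=-0.08):
    y, x = np.mgrid[:n, :n] - (n - 1) / 2
    return amp * np.exp(-((x / 14) ** 2 + (y / 18) ** 2))


class TestCtfRetrieve:
    def test_unit_holograms_give_zero_phase(self):
        holos = np.ones((3, 64, 64))
        phi = ctf_retrieve(holos, LAM, ZS, PIX)
        assert np.abs(phi).max() < 1e-10

    def test_weak_phantom_recovery(self):
        phi = _blob_phase(128, amp=-0.05)
        holos = _simulate(phi, pad_factor=1)
        phi_hat = ctf_retrieve(holos, LAM, ZS, PIX, pad_factor=1)
        rmse = np.sqrt(np.mean((phi_hat - phi) ** 2))
        assert rmse < 0.05 * np.ptp(phi)

    def test_three_distances_beat_best_single(self):
        phi = _blob_phase(128, amp=-0.05)
        holos = _simulate(phi, pad_factor=1)
        rmse_multi = np.sqrt(
            np.mean((ctf_retrieve(holos, LAM, ZS, PIX, pad_factor=1) - phi) ** 2)
        )
        singles = [
            np.sqrt(np.mean((
                ctf_retrieve(holos[d : d + 1], LAM, ZS[d : d + 1], PIX,
                             pad_factor=1) - phi
            ) ** 2))
            for d in range(3)
        ]
        assert rmse_multi < min(singles)

    def test_single_distance_zero_alpha_warns(self, caplog):
        import logging

        holos = _simulate(_blob_phase(64))
        with caplog.at_level(logging.WARNING, logger="holoxylem.retrieval"):
            ctf_retrieve(holos[:1], LAM, ZS[:1], PIX, alpha=0.0)
        assert any("ill-posed" in r.message for r in caplog.records)


class TestIterativeRetrieve:
    def test_ground_truth_is_fixed_point(self):
        phi = _blob_phase(96)
        holos = _simulate(phi, pad_factor=1)
        res = iterative_retrieve(
            holos, LAM, ZS, PIX, phi_init=phi, n_iter=3, tol=0.0, pad_factor=1
        )
        assert res.misfit[-1] <= res.misfit[0] + 1e-12
        assert np.sqrt(np.mean((res.phase - phi) ** 2)) < 1e-4

    def test_refines_strong_phase_beyond_ctf(self):
        # ~1 rad object: the weak-object linearisation saturates and the
        # projection iterations must do better from that starting point
        phi = 12.0 * _blob_phase(128)  # ~ -0.96 rad peak
        holos = _simulate(phi, pad_factor=1)
        phi_ctf = ctf_retrieve(holos, LAM, ZS, PIX, pad_factor=1)
        e0 = np.sqrt(np.mean((phi_ctf - phi) ** 2))
        res = iterative_retrieve(holos, LAM, ZS, PIX, phi_init=phi_ctf,
                                 n_iter=60, pad_factor=1)
        e1 = np.sqrt(np.mean((res.phase - phi) ** 2))
        assert e1 < e0

    @pytest.mark.parametrize("seed", range(10))
    def test_misfit_decreases_under_noise(self, seed):
        phi = 6.0 * _blob_phase(64)
        holos = _simulate(phi, photons=5000.0, seed=seed)
        res = iterative_retrieve(holos, LAM, ZS, PIX, n_iter=10)
        assert res.misfit[-1] < res.misfit[0]

    def test_negativity_is_exact(self):
        phi = 6.0 * _blob_phase(64)
        holos = _simulate(phi, photons=2000.0, seed=0)
        res = iterative_retrieve(holos, LAM, ZS, PIX, n_iter=5)
        assert res.phase.max() <= 0.0

    def test_translation_equivariance(self):
        # the circular model is exactly equivariant under whole-pixel rolls
        phi = 6.0 * _blob_phase(128)
        holos = _simulate(phi, pad_factor=1)
        rolled = np.roll(holos, (7, -5), axis=(1, 2))
        a = iterative_retrieve(holos, LAM, ZS, PIX, n_iter=8, pad_factor=1)
        b = iterative_retrieve(rolled, LAM, ZS, PIX, n_iter=8, pad_factor=1)
        shifted = np.roll(a.phase, (7, -5), axis=(0, 1))
        assert np.allclose(shifted, b.phase, atol=1e-6)

    def test_all_constraints_disabled_refused(self):
        holos = _simulate(_blob_phase(64))
        empty = Constraints(phi_min=None, phi_max=None, amp_min=None,
                            amp_max=None, support=None)
        with pytest.raises(ValueError, match="under-constrained"):
            iterative_retrieve(holos, LAM, ZS, PIX, constraints=empty)

    def test_nan_input_rejected(self):
        holos = _simulate(_blob_phase(64))
        holos[0, 3, 3] = np.nan
        with pytest.raises(ValueError):
            iterative_retrieve(holos, LAM, ZS, PIX)

    def test_full_retrieval_reaches_ten_percent_on_pit_projection(
        self, pit_phantom
    ):
        # one angle of the reference pit phantom, noise free: CTF + 100
        # projection iterations must reach 10% of the phase range
        from holoxylem.forward import projected_optical_maps

        dsum, bsum = projected_optical_maps(pit_phantom, 0.0)
        k = 2 * np.pi / LAM
        phi = -k * dsum
        u0 = np.exp(-k * bsum) * np.exp(1j * phi)
        holos = np.stack(
            [np.abs(fresnel_propagate(u0, LAM, z, PIX, pad_factor=1,
                                      taper_px=0)) ** 2 for z in ZS]
        )
        res = iterative_retrieve(
            holos, LAM, ZS, PIX, n_iter=100, tol=0.0, pad_factor=1,
            constraints=Constraints(phi_min=-4.0),
        )
        rmse = np.sqrt(np.mean((res.phase - phi) ** 2))
        assert rmse < 0.10 * np.ptp(phi)


class TestDestripe:
    def _structured(self, n=256):
        yy, xx = np.mgrid[:n, :n]
        base = -0.5 * np.exp(
            -((((yy - 130) + 0.3 * (xx - 120)) / 30.0) ** 2
              + (((xx - 120) - 0.2 * (yy - 130)) / 22.0) ** 2)
        )
        base += -0.3 * np.exp(-(((yy - 80) / 18.0) ** 2 + ((xx - 180) / 15.0) ** 2))
        return base

    @staticmethod
    def _stripe_band_energy(frame):
        F = np.fft.fft2(frame)
        m = np.zeros(F.shape, dtype=bool)
        m[:, :2] = True
        m[:, -1:] = True
        m[0, 0] = False
        return (np.abs(F)[m] ** 2).sum()

    def test_near_identity_on_clean_frames(self):
        base = self._structured()
        out = destripe(PhaseProjectionSet(base[None], [0.0])).phases[0]
        change = np.sqrt(np.mean((out - base) ** 2))
        assert change < 0.01 * np.sqrt(np.mean(base**2))

    def test_removes_injected_ripple_energy(self):
        base = self._structured()
        yy = np.mgrid[:256, :256][0]
        ripple = 0.1 * np.ptp(base) * np.sin(2 * np.pi * yy / 16.0 + 0.7)
        out = destripe(PhaseProjectionSet((base + ripple)[None], [0.0])).phases[0]
        injected = self._stripe_band_energy(base + ripple) - self._stripe_band_energy(base)
        residual = self._stripe_band_energy(out) - self._stripe_band_energy(base)
        assert residual <= 0.1 * injected

    def test_rmse_to_clean_strictly_decreases(self):
        base = self._structured()
        yy = np.mgrid[:256, :256][0]
        ripple = 0.1 * np.ptp(base) * np.sin(2 * np.pi * yy / 16.0 + 0.7)
        out = destripe(PhaseProjectionSet((base + ripple)[None], [0.0])).phases[0]
        before = np.sqrt(np.mean(ripple**2))
        after = np.sqrt(np.mean((out - base) ** 2))
        assert after < before

    def test_vertical_orientation_by_symmetry(self):
        base = self._structured()
        xx = np.mgrid[:256, :256][1]
        ripple = 0.1 * np.ptp(base) * np.sin(2 * np.pi * xx / 16.0)
        noisy = PhaseProjectionSet((base + ripple)[None], [0.0])
        out = destripe(noisy, orientation="vertical").phases[0]
        after = np.sqrt(np.mean((out - base) ** 2))
        assert after < np.sqrt(np.mean(ripple**2))

    def test_unknown_orientation_rejected(self):
        ps = PhaseProjectionSet(np.zeros((1, 32, 32)), [0.0])
        with pytest.raises(ValueError):
            destripe(ps, orientation="diagonal")
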