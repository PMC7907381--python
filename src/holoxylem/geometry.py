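"""Cone-beam near-field holography geometry and its parallel-beam equivalent.

A divergent beam from a point focus illuminates the sample at a small
focus-to-sample distance ``z1`` and is recorded far downstream at the
focus-to-detector distance ``z_det``.  By the Fresnel scaling theorem this
cone-beam hologram is equivalent to a parallel-beam hologram taken at the
effective propagation distance ``z_eff = z1 (z_det - z1) / z_det`` with
geometric magnification ``M = z_det / z1`` and effective (demagnified)
detector pixel ``dx = dx_det / M``.  All downstream stages work exclusively
in this effective parallel-beam description.

The propagation regime is characterised by the Fresnel number computed on
the effective pixel, ``F = dx^2 / (lambda * z_eff)`` (conventions differ in
the literature — some authors use a feature size or the field of view; this
package always uses the effective pixel, which for the default beamline
configuration puts ``F`` at the 1e-4 order of magnitude).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import InvalidGeometryError

#: hc in keV * nm; E [keV] = hc / lambda [nm]
HC_KEV_NM = 1.23984193


def wavelength_from_energy(energy_keV: float) -> float:
    """Photon wavelength in nm for a photon energy in keV (lambda = hc/E)."""
    if not energy_keV > 0:
        raise ValueError(f"photon energy must be positive, got {energy_keV}")
    return HC_KEV_NM / energy_keV


def effective_geometry(z1_mm: float, z_det_m: float) -> tuple[float, float]:
    """Magnification and effective propagation distance for one defocus.

    Parameters
    ----------
    z1_mm : focus-to-sample distance in mm.
    z_det_m : focus-to-detector distance in m.

    Returns
    -------
    (M, z_eff_mm) : geometric magnification (dimensionless) and the
        parallel-beam equivalent propagation distance in mm.
    """
    z1_m = z1_mm * 1e-3
    if not 0 < z1_m < z_det_m:
        raise InvalidGeometryError(
            f"need 0 < z1 ({z1_mm} mm) < z_det ({z_det_m} m)"
        )
    M = z_det_m / z1_m
    z_eff_m = z1_m * (z_det_m - z1_m) / z_det_m
    return M, z_eff_m * 1e3


def fresnel_number(pixel_nm: float, wavelength_nm: float, z_eff_mm: float) -> float:
    """Per-pixel Fresnel number F = dx^2 / (lambda * z_eff)."""
    if pixel_nm <= 0 or wavelength_nm <= 0 or z_eff_mm <= 0:
        raise ValueError("pixel, wavelength and effective distance must be positive")
    return pixel_nm**2 / (wavelength_nm * z_eff_mm * 1e6)


@dataclass(frozen=True)
class GeometryConfig:
    """Scan geometry of a multi-distance holotomography acquisition.

    Distances keep the units their field names carry (mm / m / nm); every
    derived quantity (wavelength, magnification, effective distance, Fresnel
    number, angle schedule) is recomputed on access and never stored, so it
    cannot go stale.
    """

    energy_keV: float = 11.0
    focus_to_sample_mm: tuple[float, ...] = (70.0, 71.0, 72.0)
    focus_to_detector_m: float = 16.269
    n_detector_pixels: int = 2048
    effective_pixel_nm: float = 26.0
    n_projections: int = 900
    angle_step_deg: float = 0.2
    exposure_s: float = 1.0

    def __post_init__(self) -> None:
        if self.energy_keV <= 0:
            raise InvalidGeometryError("photon energy must be positive")
        if self.effective_pixel_nm <= 0 or self.focus_to_detector_m <= 0:
            raise InvalidGeometryError("distances and pixel size must be positive")
        object.__setattr__(
            self, "focus_to_sample_mm", tuple(float(z) for z in self.focus_to_sample_mm)
        )
        for z1 in self.focus_to_sample_mm:
            if not 0 < z1 * 1e-3 < self.focus_to_detector_m:
                raise InvalidGeometryError(
                    f"defocus distance {z1} mm not in (0, {self.focus_to_detector_m} m)"
                )
        if self.n_projections < 1 or self.angle_step_deg <= 0:
            raise InvalidGeometryError("need a positive angle schedule")
        span = self.n_projections * self.angle_step_deg
        if abs(span - 180.0) > 1e-6:
            raise InvalidGeometryError(
                f"n_projections * angle_step must cover a 180 deg half-turn, got {span}"
            )

    # ---- derived quantities (recomputed, never stored) -------------------

    @property
    def wavelength_nm(self) -> float:
        return wavelength_from_energy(self.energy_keV)

    @property
    def n_distances(self) -> int:
        return len(self.focus_to_sample_mm)

    @property
    def magnifications(self) -> tuple[float, ...]:
        return tuple(
            effective_geometry(z1, self.focus_to_detector_m)[0]
            for z1 in self.focus_to_sample_mm
        )

    @property
    def effective_distances_mm(self) -> tuple[float, ...]:
        return tuple(
            effective_geometry(z1, self.focus_to_detector_m)[1]
            for z1 in self.focus_to_sample_mm
        )

    @property
    def fresnel_numbers(self) -> tuple[float, ...]:
        lam = self.wavelength_nm
        return tuple(
            fresnel_number(self.effective_pixel_nm, lam, z_eff)
            for z_eff in self.effective_distances_mm
        )

    @property
    def angles_deg(self) -> np.ndarray:
        """Half-turn angle schedule in degrees, [0, 180)."""
        return np.arange(self.n_projections) * self.angle_step_deg

    # ---- config-file boundary -------------------------------------------

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "GeometryConfig":
        """Build from a config mapping with unit-suffixed keys.

        Recognised keys: ``energy_keV``, ``defocus_mm``, ``detector_distance_m``,
        ``n_detector_pixels``, ``effective_pixel_nm``, ``n_projections``,
        ``angle_step_deg``, ``exposure_s``.  Missing keys keep their defaults.
        """
        kw = {}
        mapping = {
            "energy_keV": "energy_keV",
            "defocus_mm": "focus_to_sample_mm",
            "detector_distance_m": "focus_to_detector_m",
            "n_detector_pixels": "n_detector_pixels",
            "effective_pixel_nm": "effective_pixel_nm",
            "n_projections": "n_projections",
            "angle_step_deg": "angle_step_deg",
            "exposure_s": "exposure_s",
        }
        for key, attr in mapping.items():
            if key in cfg:
                val = cfg[key]
                kw[attr] = tuple(val) if isinstance(val, (list, tuple)) else val
        return cls(**kw)
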