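"""Synthetic wood-anatomy phantoms with X-ray optical material properties.

Two reference specimens are modelled, both at the instrument's native
26 nm isotropic voxel pitch:

* a conifer (pine-like) tracheid block — square lumina separated by the
  fused double cell wall of two neighbouring tracheids (default total
  double-wall thickness 3617 nm);
* an angiosperm (beech-like) fibre pit pair — two parallel cell walls fused
  at a pit: a biconvex (lens-shaped) chamber split by a flat, unaspirated
  membrane, drained to the two lumina through slit-shaped canals.

Specimens prepared by focused-ion-beam milling carry a thin implanted
gallium film on the exposed cell-wall surfaces; :func:`add_gallium_layer`
reproduces that as a surface shell with a distinctly higher refractive
index decrement than the organic wall.

Per-material complex refractive indices n = 1 - delta + i*beta are derived
from mass density through the classical electron-density relation
``delta = r_e * lambda^2 * n_e / (2 pi)``; absorption is set as a fixed
(weak) fraction of delta.  Each phantom stores its construction parameters
as a ground-truth morphometry record, so recovery of these numbers through
the full imaging chain can be scored without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Iterable

import numpy as np
from scipy import ndimage as ndi

from .exceptions import InvalidSpecError
from .geometry import wavelength_from_energy
from .morphometry import MorphometryRecord

# classical electron radius [m] and Avogadro constant [1/mol]
R_ELECTRON_M = 2.8179403262e-15
N_AVOGADRO = 6.02214076e23

# voxel labels
AIR, WALL, MEMBRANE, GALLIUM = 0, 1, 2, 3


@dataclass(frozen=True)
class Material:
    """X-ray optical constants of one phantom component."""

    name: str
    delta: float
    beta: float
    density_g_cm3: float | None = None

    def __post_init__(self) -> None:
        if self.delta < 0 or self.beta < 0:
            raise ValueError(f"{self.name}: delta and beta must be non-negative")


VACUUM = Material("air", 0.0, 0.0)


def material_from_density(
    name: str,
    density_g_cm3: float,
    Z_over_A: float,
    energy_keV: float,
    beta_over_delta: float = 0.01,
) -> Material:
    """Material from mass density via the electron-density relation.

    delta = r_e lambda^2 n_e / (2 pi) with electron density
    n_e = rho * N_A * (Z/A); beta is set to ``beta_over_delta * delta``
    (far from absorption edges light-element absorption is a small, roughly
    constant fraction of the phase decrement).
    """
    if density_g_cm3 <= 0:
        raise ValueError("density must be positive")
    if not 0 < Z_over_A <= 1:
        raise ValueError("Z/A must be in (0, 1]")
    lam_m = wavelength_from_energy(energy_keV) * 1e-9
    n_e_per_m3 = density_g_cm3 * 1e6 * N_AVOGADRO * Z_over_A
    delta = R_ELECTRON_M * lam_m**2 * n_e_per_m3 / (2.0 * math.pi)
    return Material(name, delta, beta_over_delta * delta, density_g_cm3)


def default_materials(energy_keV: float = 11.0) -> Dict[int, Material]:
    """Label -> material table for the wood phantoms.

    Cell wall: bulk cellulose-like density 1.5 g/cm3; the pit membrane is a
    slightly less dense primary-wall layer (1.35 g/cm3); gallium metal
    5.91 g/cm3 with a larger absorption fraction.
    """
    return {
        AIR: VACUUM,
        WALL: material_from_density("cell wall", 1.5, 0.53, energy_keV, 0.01),
        MEMBRANE: material_from_density("pit membrane", 1.35, 0.53, energy_keV, 0.01),
        GALLIUM: material_from_density("gallium", 5.91, 31.0 / 69.72, energy_keV, 0.05),
    }


@dataclass(frozen=True)
class PitSpec:
    """Construction parameters of the fibre pit-pair phantom (all nm).

    ``chamber_diameter_nm`` is the maximal (base) diameter of the biconvex
    chamber, ``membrane_thickness_nm`` the flat membrane splitting it,
    ``canal_slit_width_nm`` the long axis of the slit-shaped canal cross
    section (its short axis is ``canal_slit_breadth_nm``),
    ``wall_thickness_nm`` the thickness of each cell's wall (the fused
    double wall is twice that), and ``canal_depth_nm`` the canal length
    from the chamber apex to the lumen.
    """

    chamber_diameter_nm: float = 4230.0
    membrane_thickness_nm: float = 428.0
    canal_slit_width_nm: float = 1053.0
    canal_slit_breadth_nm: float = 300.0
    wall_thickness_nm: float = 1800.0
    canal_depth_nm: float = 900.0
    #: axis index of the pit-canal axis; 2 (in-plane, perpendicular to the
    #: tomographic rotation axis 0) keeps the fused double wall clear of the
    #: horizontal-stripe band that illumination artefacts occupy
    orientation: int = 2
    #: lateral half-extent of the milled specimen pillar (the wall plate is
    #: cut to |y| <= block_halfwidth so it stays inside the field of view
    #: at every rotation angle, like the real free-standing specimen).
    #: None sizes it automatically to the largest rotatable plate;
    #: float("inf") disables the bound (an unbounded wall).
    block_halfwidth_nm: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "chamber_diameter_nm",
            "membrane_thickness_nm",
            "canal_slit_width_nm",
            "canal_slit_breadth_nm",
            "wall_thickness_nm",
            "canal_depth_nm",
        ):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be positive")
        if self.membrane_thickness_nm >= self.chamber_diameter_nm:
            raise InvalidSpecError("membrane thicker than the chamber diameter")
        if self.canal_slit_breadth_nm > self.canal_slit_width_nm:
            raise InvalidSpecError("canal breadth exceeds the slit width")
        cap = self.cap_height_nm
        if cap <= 0:
            raise InvalidSpecError(
                "wall_thickness_nm leaves no room for the chamber cap "
                "(wall <= membrane/2 + canal_depth)"
            )
        if self.block_halfwidth_nm is not None and not self.block_halfwidth_nm > 0:
            raise InvalidSpecError("block_halfwidth_nm must be positive (or None)")

    @property
    def cap_height_nm(self) -> float:
        """Height of each spherical chamber cap above the membrane face."""
        return self.wall_thickness_nm - self.membrane_thickness_nm / 2.0 - self.canal_depth_nm

    @property
    def cap_sphere_radius_nm(self) -> float:
        a = self.chamber_diameter_nm / 2.0
        h = self.cap_height_nm
        return (a * a + h * h) / (2.0 * h)

    def analytic_void_volume_um3(self) -> float:
        """Closed-form void volume: two spherical caps plus two slit canals."""
        a = self.chamber_diameter_nm / 2.0
        h = self.cap_height_nm
        cap = math.pi * h * (3.0 * a * a + h * h) / 6.0
        L, b = self.canal_slit_width_nm, self.canal_slit_breadth_nm
        stadium = (L - b) * b + math.pi * b * b / 4.0
        canal = stadium * self.canal_depth_nm
        return 2.0 * (cap + canal) * 1e-9  # nm^3 -> um^3


@dataclass
class PhantomVolume:
    """Labelled voxel grid plus material table and construction ground truth."""

    labels: np.ndarray
    voxel_pitch_nm: float
    materials: Dict[int, Material]
    ground_truth: MorphometryRecord
    csg_void_volume_um3: float | None = None
    pit_spec: PitSpec | None = None

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.materials)
        if missing:
            raise InvalidSpecError(f"labels without material entry: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def _material_field(self, attr: str) -> np.ndarray:
        lut = np.zeros(max(self.materials) + 1, dtype=np.float32)
        for lab, mat in self.materials.items():
            lut[lab] = getattr(mat, attr)
        return lut[self.labels]

    def delta_volume(self) -> np.ndarray:
        """Per-voxel refractive index decrement delta."""
        return self._material_field("delta")

    def beta_volume(self) -> np.ndarray:
        """Per-voxel absorption index beta."""
        return self._material_field("beta")


def _centered_coords(n: int, pitch_nm: float) -> np.ndarray:
    return (np.arange(n) - (n - 1) / 2.0) * pitch_nm


def build_pit_pair_phantom(
    spec: PitSpec = PitSpec(),
    grid_shape: tuple[int, int, int] = (256, 256, 256),
    pitch_nm: float = 26.0,
    materials: Dict[int, Material] | None = None,
) -> PhantomVolume:
    """Rasterise the pit-pair phantom by constructive solid geometry.

    The fused double wall is a slab perpendicular to the pit-canal axis
    (``spec.orientation``; by default the in-plane x axis), the two lumina
    lie on either side of the slab, and the chamber/membrane/canal void
    system sits on the grid centre.  The solid is rasterised with the
    canal along axis 0 and then transposed so the canal lies along the
    requested axis.
    """
    if spec.orientation not in (0, 1, 2):
        raise InvalidSpecError("orientation must be an axis index 0, 1 or 2")
    grid_shape = tuple(grid_shape)
    build_shape = list(grid_shape)
    build_shape[0], build_shape[spec.orientation] = (
        build_shape[spec.orientation],
        build_shape[0],
    )
    margin_nm = 5.0 * pitch_nm
    nz, ny, nx = build_shape
    if 2.0 * spec.wall_thickness_nm + 2.0 * margin_nm > nz * pitch_nm:
        raise InvalidSpecError("wall_thickness_nm: double wall does not fit the grid")
    if spec.chamber_diameter_nm + 2.0 * margin_nm > min(ny, nx) * pitch_nm:
        raise InvalidSpecError("chamber_diameter_nm does not fit the grid")
    if spec.canal_slit_width_nm + 2.0 * margin_nm > min(ny, nx) * pitch_nm:
        raise InvalidSpecError("canal_slit_width_nm does not fit the grid")

    z = _centered_coords(nz, pitch_nm)[:, None, None]
    y = _centered_coords(ny, pitch_nm)[None, :, None]
    x = _centered_coords(nx, pitch_nm)[None, None, :]

    wt = spec.wall_thickness_nm
    m2 = spec.membrane_thickness_nm / 2.0
    a = spec.chamber_diameter_nm / 2.0
    h = spec.cap_height_nm
    R = spec.cap_sphere_radius_nm
    L, b = spec.canal_slit_width_nm, spec.canal_slit_breadth_nm

    # lateral bound of the milled pillar: the specimen must stay inside
    # the field of view at every rotation angle, so the in-plane diagonal
    # of the wall plate is fitted into the grid extent
    bh = spec.block_halfwidth_nm
    if bh is None:
        extent = min(ny, nx) * pitch_nm - 4.0 * pitch_nm
        diag2 = extent**2 - (2.0 * wt) ** 2
        if diag2 <= 0:
            raise InvalidSpecError(
                "wall_thickness_nm: the double wall cannot rotate inside the grid"
            )
        bh = 0.5 * math.sqrt(diag2)
    if math.isfinite(bh) and bh < a + margin_nm:
        raise InvalidSpecError(
            f"block_halfwidth_nm ({bh:.0f} nm) leaves no margin around the "
            f"chamber radius ({a:.0f} nm)"
        )

    shape = (nz, ny, nx)
    labels = np.zeros(shape, dtype=np.uint8)
    slab = (np.abs(z) <= wt) & (np.abs(y) <= bh)
    labels[np.broadcast_to(slab, shape)] = WALL

    r2 = y * y + x * x
    azab = np.abs(z)
    # biconvex chamber: two spherical caps, base plane at |z| = m/2
    zs = m2 + h - R  # sphere centre offset along +z (mirrored for -z)
    cap = (azab >= m2) & (azab <= m2 + h) & (r2 <= R * R - (azab - zs) ** 2)
    # slit canal: stadium cross-section (long axis along y), apex plane -> lumen
    seg_y = np.clip(np.abs(y), 0.0, (L - b) / 2.0) * np.sign(y)
    stadium = (y - seg_y) ** 2 + x * x <= (b / 2.0) ** 2
    canal = (azab >= m2 + h) & (azab <= wt) & stadium
    void = (cap | canal) & slab
    labels[void] = AIR

    membrane = (azab < m2) & (r2 <= a * a) & ~void
    labels[membrane] = MEMBRANE

    labels = np.ascontiguousarray(np.swapaxes(labels, 0, spec.orientation))
    mats = dict(materials or default_materials())
    voxel_count = int(void.sum())
    gt = MorphometryRecord(
        chamber_diameter_nm=spec.chamber_diameter_nm,
        membrane_thickness_nm=spec.membrane_thickness_nm,
        canal_width_um=spec.canal_slit_width_nm * 1e-3,
        voxel_count=voxel_count,
        void_volume_um3=voxel_count * (pitch_nm * 1e-3) ** 3,
    )
    return PhantomVolume(
        labels=labels,
        voxel_pitch_nm=pitch_nm,
        materials=mats,
        ground_truth=gt,
        csg_void_volume_um3=spec.analytic_void_volume_um3(),
        pit_spec=spec,
    )


def build_tracheid_phantom(
    wall_thickness_nm: float = 3617.0,
    lumen_width_nm: float = 1500.0,
    grid_shape: tuple[int, int, int] = (256, 256, 256),
    pitch_nm: float = 26.0,
    materials: Dict[int, Material] | None = None,
    arm_halflength_nm: float | None = None,
) -> PhantomVolume:
    """Tracheid block: square lumina separated by fused double walls.

    Two orthogonal double-wall plates (each of the full, fused thickness
    ``wall_thickness_nm``) cross at the grid centre and run parallel to
    the rotation axis, carving four square lumina between the arms.  The
    arms end at ``arm_halflength_nm`` from the centre so the milled
    specimen pillar stays inside the field of view at every rotation
    angle (``None`` sizes the arms automatically; ``float("inf")`` lets
    the plates span the full grid).
    """
    nz, ny, nx = grid_shape
    if wall_thickness_nm < 0 or lumen_width_nm <= 0:
        raise InvalidSpecError("wall and lumen dimensions must be non-negative")
    if wall_thickness_nm + 2.0 * lumen_width_nm > min(ny, nx) * pitch_nm:
        raise InvalidSpecError(
            "wall_thickness_nm + 2 lumen_width_nm exceeds the grid extent"
        )
    if arm_halflength_nm is None:
        # the cross's furthest point (an arm-end corner) must stay inside
        # the rotation circle of the grid
        half_extent = (min(ny, nx) * pitch_nm - 4.0 * pitch_nm) / 2.0
        arm_halflength_nm = math.sqrt(
            max(half_extent**2 - (wall_thickness_nm / 2.0) ** 2, 0.0)
        )
    if math.isfinite(arm_halflength_nm) and arm_halflength_nm < wall_thickness_nm / 2.0:
        raise InvalidSpecError("arm_halflength_nm shorter than the wall is solid")
    y = _centered_coords(ny, pitch_nm)[:, None]
    x = _centered_coords(nx, pitch_nm)[None, :]
    ah = arm_halflength_nm
    plane = ((np.abs(x) <= wall_thickness_nm / 2.0) & (np.abs(y) <= ah)) | (
        (np.abs(y) <= wall_thickness_nm / 2.0) & (np.abs(x) <= ah)
    )
    labels = np.zeros(grid_shape, dtype=np.uint8)
    if wall_thickness_nm > 0:
        labels[:, plane] = WALL
    gt = MorphometryRecord(wall_thickness_um=wall_thickness_nm * 1e-3)
    return PhantomVolume(
        labels=labels,
        voxel_pitch_nm=pitch_nm,
        materials=dict(materials or default_materials()),
        ground_truth=gt,
    )


def add_gallium_layer(
    vol: PhantomVolume,
    thickness_nm: float,
    faces: str | Iterable[str] = "all",
) -> PhantomVolume:
    """Relabel a surface shell of exposed cell wall as implanted gallium.

    The shell is the set of wall voxels within ``thickness_nm`` of air,
    found by iterated 6-connected dilation of the air phase — exactly an
    n-iteration boundary peel of the wall.  ``faces`` restricts which air
    region does the implanting: ``"all"`` uses every air voxel, otherwise
    pass face names among ``{"+z","-z","+y","-y","+x","-x"}`` and only air
    connected to those grid faces contributes (an ion beam reaches the
    specimen from outside).  Interior labels are untouched; void stays void.
    """
    if thickness_nm < 0:
        raise InvalidSpecError("gallium layer thickness must be >= 0")
    n_iter = int(round(thickness_nm / vol.voxel_pitch_nm))
    if thickness_nm > 0 and n_iter == 0:
        n_iter = 1
    gt_wall = vol.ground_truth.wall_thickness_um
    limit_nm = gt_wall * 1e3 if gt_wall is not None else (
        vol.pit_spec.wall_thickness_nm if vol.pit_spec is not None else None
    )
    if limit_nm is not None and thickness_nm > limit_nm:
        raise InvalidSpecError(
            f"gallium layer ({thickness_nm} nm) thicker than the wall ({limit_nm} nm)"
        )
    labels = vol.labels.copy()
    if n_iter == 0:
        return replace(vol, labels=labels)

    air = labels == AIR
    if faces != "all":
        face_mask = np.zeros_like(air)
        idx = {"z": 0, "y": 1, "x": 2}
        for face in faces:
            sign, ax = face[0], idx[face[1]]
            sl = [slice(None)] * 3
            sl[ax] = -1 if sign == "+" else 0
            face_mask[tuple(sl)] = True
        lab_air, _ = ndi.label(air, structure=ndi.generate_binary_structure(3, 1))
        keep = np.unique(lab_air[face_mask & air])
        air = np.isin(lab_air, keep[keep > 0])

    struct = ndi.generate_binary_structure(3, 1)
    reach = ndi.binary_dilation(air, structure=struct, iterations=n_iter)
    shell = reach & (labels == WALL)
    labels[shell] = GALLIUM
    return replace(vol, labels=labels)


def make_illumination(
    shape: tuple[int, int],
    ripple_amplitude: float = 0.05,
    ripple_period_px: float = 16.0,
    n_stripes: int = 3,
    seed: int | None = None,
    stripe_amplitude: float = 0.05,
) -> np.ndarray:
    """Structured flat field: horizontal ripple plus sharp random stripes.

    Returns a strictly positive image of mean exactly one (up to float
    rounding): ``1 + A sin(2 pi y / period + phase)`` — constant along each
    row, emulating monochromator stripe artefacts — plus ``n_stripes``
    narrow horizontal lines at seeded random rows.  Deterministic under
    ``seed``.
    """
    if ripple_amplitude >= 1.0 or stripe_amplitude >= 1.0:
        raise ValueError("amplitudes must be < 1 (intensity must stay positive)")
    if ripple_amplitude < 0 or stripe_amplitude < 0:
        raise ValueError("amplitudes must be >= 0")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    rows = np.arange(ny, dtype=np.float64)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    profile = 1.0 + ripple_amplitude * np.sin(2.0 * np.pi * rows / ripple_period_px + phase)
    for _ in range(n_stripes):
        r0 = rng.uniform(0, ny)
        amp = stripe_amplitude * rng.uniform(0.3, 1.0) * rng.choice([-1.0, 1.0])
        width = rng.uniform(0.6, 1.5)
        profile += amp * np.exp(-0.5 * ((rows - r0) / width) ** 2)
    flat = np.repeat(profile[:, None], nx, axis=1)
    flat /= flat.mean()
    return flat
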