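# holoxylem

Near-field X-ray holotomography of wood xylem at the cell-wall scale:
simulation, phase retrieval, tomographic reconstruction and morphometry,
as one tested, reproducible pipeline.

## The problem

Pit membranes — the few-hundred-nanometre primary-wall layers that
control water transport between wood cells — sit below the resolution of
laboratory micro-CT.  Near-field holography (NFH) reaches them: a
focused-ion-beam-milled specimen pillar (tens of µm) sits in a divergent
X-ray beam a few centimetres behind the focus, and the detector 16 m
downstream records magnified in-line holograms at an effective pixel of
26 nm.  By the Fresnel scaling theorem each focus-to-sample distance z1
is equivalent to a parallel beam propagated over
z_eff = z1(z_det − z1)/z_det, so phase retrieval and parallel-beam
tomography apply directly.  Recording each of the 900 half-turn
projections at three defocus distances (70, 71, 72 mm; per-pixel Fresnel
number F = Δx²/λz_eff ≈ 10⁻⁴) makes the phase problem well-posed for a
specimen that mixes weakly refracting cell wall with implanted gallium.

The processing chain is the standard three-stage one: (i) flat-field
correction and geometry refinement, (ii) per-projection phase retrieval —
a linear contrast-transfer-function (CTF) inversion over the distances,
FT[I−1] = 2 sin(πλz|f|²)·FT[φ], refined by iterative projections with
support/range constraints — followed by wavelet–Fourier destriping, and
(iii) aligned, ramp-filtered backprojection into a tomogram of the
refractive-index decrement δ.  Region-growing segmentation and slice
based morphometry then recover the anatomical numbers: double cell-wall
thickness, pit-chamber diameter, pit-membrane thickness, canal slit
width, and the voxel-count pit void volume.

Because no imaging data of this kind are publicly deposited, the package
includes a first-class synthetic-specimen module: voxel phantoms of a
conifer tracheid block and of an angiosperm fibre pit pair, built from
reference anatomical dimensions, with per-material complex refractive
indices and structured, noisy illumination.  Every downstream stage is
validated by recovering the construction parameters through the full
simulated experiment.

## Worked example

```python
from holoxylem import default_config, run_pipeline

cfg = default_config("beech_pit_reference")
result = run_pipeline(cfg, outdir="pit_run", seed=1)
print(result.report.to_json())
```

runs the full chain — pit-pair phantom (256³ voxels at 26 nm), three
defocus distances, 180 projections with Poisson noise and striped flats,
CTF + iterative retrieval, destriping, filtered backprojection,
region-growing morphometry — in about nine minutes on one CPU and prints

```json
{
  "wall_thickness_um": null,
  "chamber_diameter_nm": 4189.95,
  "membrane_thickness_nm": 416.0,
  "canal_width_um": 1.0516,
  "voxel_count": 572756,
  "void_volume_um3": 10.067,
  "polarity_note": "values are proportional to the refractive-index decrement delta; ..."
}
```

The phantom was built with a 4230 nm chamber, a 428 nm membrane and a
1053 nm canal slit, so the simulated experiment recovers all three
dimensions to within two voxels (±52 nm); the void volume (pit canal
plus chamber, lumina excluded) comes back within 5% of the phantom's
analytic value of 10.51 µm³.  The `pine_wall_reference` profile does the
same for a tracheid double wall of 3.617 µm and reports
`wall_thickness_um ≈ 3.642`.

A thin command-line front end wraps the same library calls:

```bash
holoxylem measure --profile beech_pit_reference --seed 1 --out pit_run
holoxylem retrieve --method ctf --out ctf_only     # stop after retrieval
```

Each run writes a JSON manifest (config hash, seed, per-stage wall
times); `run_from_manifest` re-executes a run bit-identically.  Hologram
stacks are stored in HDF5 (`/holograms/d{0,1,2}`, `/flats/d{0,1,2}`,
geometry in attributes), volumes and phase stacks as 32-bit TIFF.

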