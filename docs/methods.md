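# Methods

`holoxylem` simulates and analyses multi-distance X-ray near-field
holotomography (NFH) of wood xylem at the cell-wall scale, and recovers
the anatomical dimensions of the simulated specimens from the
reconstructed volumes.  This note records the models, the parameters that
matter, the numerical choices, and what the synthetic experiments do and
do not demonstrate.

## Imaging model

**Geometry.**  A point focus illuminates the sample at a small defocus
distance z1 (70–72 mm) and the hologram is recorded 16.269 m downstream.
By the Fresnel scaling theorem this cone-beam arrangement is equivalent
to a parallel beam propagated over z_eff = z1(z_det − z1)/z_det with
magnification M = z_det/z1 and effective pixel Δx = Δx_det/M = 26 nm.
Everything downstream works in this effective parallel-beam frame; the
focusing optics are treated as an ideal point source.  The per-pixel
Fresnel number F = Δx²/(λ·z_eff) ≈ 8.6×10⁻⁵ characterises the regime
(conventions differ; this package always uses the effective pixel, which
places F at the 10⁻⁴ order of magnitude).  Derived quantities
(wavelength, M, z_eff, F, the angle schedule) are recomputed from the
configuration on every access and never stored.

**Specimens.**  Two synthetic phantoms on the 26 nm isotropic voxel grid:

* *fibre pit pair* — two cell walls (each 1800 nm) fused into a plate,
  holding a biconvex chamber (two spherical caps, base diameter 4230 nm)
  split by a flat, unaspirated membrane (428 nm), drained to the two
  lumina through slit canals (stadium cross-section, long axis 1053 nm,
  short axis 300 nm, depth 900 nm).  The chamber is modelled as a lens of
  spherical caps and the canal as a slit because pit canals in fibrous
  cells are slit-like; neither shape is otherwise parameterised by
  reported measurements.  The canal axis lies **in the tomographic
  plane** (perpendicular to the rotation axis).  This both matches how a
  specimen pillar is usually mounted (cell walls roughly parallel to the
  pillar axis) and keeps the double wall out of the horizontal-stripe
  band that illumination artefacts occupy — with the canal along the
  rotation axis, the wall slab is an almost exactly row-constant feature
  in every projection and any horizontal destriper removes anatomy.
* *tracheid block* — two orthogonal fused double-wall plates (total
  thickness 3617 nm each) crossing at the grid centre, carving four
  square lumina; invariant along the rotation axis.

Both specimens are **compact pillars**: the wall plate and the cross
arms are bounded so the whole specimen stays inside the rotation circle
of the grid, with vacuum around it at every angle — exactly like the
milled ~40 µm pillar inside the instrument's 53 µm field of view.  This
matters beyond fidelity: projections of a specimen that fills the beam
have no vacuum pixels, and then the per-angle phase offset (to which the
transfer function is blind at f = 0) is unrecoverable and turns into
large low-frequency reconstruction artefacts.  The bounds auto-size to
the grid and can be widened or disabled per phantom.

Material optical constants n = 1 − δ + iβ come from the classical
electron-density relation δ = rₑλ²nₑ/2π with nₑ = ρN_A(Z/A): cell wall
ρ = 1.5 g/cm³, Z/A = 0.53 (δ ≈ 2.7×10⁻⁶ at 11 keV); pit membrane as a
slightly less dense primary-wall layer (1.35 g/cm³); implanted gallium
5.91 g/cm³ (δ ≈ 9.0×10⁻⁶).  Absorption is β = 0.01·δ for the organic
phases and 0.05·δ for gallium (weak absorption at 11 keV).  Focused-ion-
beam preparation is emulated by relabelling a surface shell of exposed
wall (default 78 nm = 3 voxels) as gallium; the layer thickness and
coverage are free parameters of the generator since neither is measured.

**Forward model.**  For each rotation angle the labelled volume is
rotated about the vertical axis (bilinear interpolation, pivot chosen to
match the backprojector bin-for-bin) and integrated along the beam; the
projection approximation turns the per-material path lengths into the
exit wave u₀ = exp(−2π/λ·Σβt)·exp(−i·2π/λ·Σδt), so phase is
non-positive.  Free-space propagation uses the Fourier transfer function
H(f) = exp(−iπλz|f|²); the weak-object limit then obeys
FT[I−1] = 2sin(πλz|f|²)·FT[φ] with a positive first lobe, which the test
suite asserts.  Detected intensity is |u_z|² times a structured flat
field (mean-one horizontal sinusoidal ripple plus a few sharp stripes,
emulating monochromator artefacts), with Poisson noise at 5000 photons
per pixel (exposure-scaled stand-in; the real photon flux is unknown).
Identical axial slices of the phantom are detected by hashing and
projected once, which makes the z-invariant anatomy cheap to project.

**Discretisation choice.**  The propagation operator supports 2× zero
padding with cosine edge apodisation (the physically motivated default
for a finite detector: it models the loss of fringes that diffract out of
the frame).  The *reference pipelines*, however, simulate **and** retrieve
on the same unpadded periodic grid.  The reason is verification logic: a
finite detector genuinely destroys low-frequency information about
specimens that fill the field of view, and no retrieval can be expected
to restore it; with matched discretisation the inverse problem is
well-posed and the pipeline's accuracy measures the algorithms rather
than the (unmodelled) boundary truncation.  The padded model remains the
op-level default and is exercised separately by the propagator tests.

## Phase retrieval

Per projection angle, two stages:

1. **CTF initialiser** — least-squares inversion of the weak-object
   relation over the three defocus distances,
   φ̂ = FT⁻¹[Σ_d 2s_d·FT(I_d−1) / (Σ_d 4s_d² + α)], s_d = sin(πλz_d|f|²),
   with Tikhonov α = 0.01 stabilising the nearly common zero crossings of
   the three sine terms (the defocus distances differ by only ~1.4%).
2. **Iterative projections** — alternating projections between the
   measured moduli and an object constraint set: phase clipped to
   [φ_min, 0], amplitude to [a_min, 1], optional support.  The data
   projection either averages the three distances or chains through them
   sequentially (Gerchberg–Saxton style); the sequential rule with
   over-relaxation 1.5 converges roughly twice as fast on these specimens
   and is the pipeline default (100 iterations).  The pipeline range
   bounds are φ_min = −4 rad and a_min = 0.8: the strongest plausible
   path (a full-frame in-plane cellulose traversal plus an edge-on
   gallium film) reaches ≈ −3.5 rad and amplitude ≈ 0.85, which the
   narrower textbook bounds would clip.  No homogeneity (single-material)
   constraint is imposed — the wood/gallium mixture is exactly the case
   where such a constraint fails, and the three distances carry the
   compensating information.

Phase retrieval of this specimen class is genuinely hard: the double
wall is a ~1 rad phase object, far beyond the weak-object regime, so the
linear initialiser carries an ~0.2 rad systematic error that only the
projection iterations slowly repair (about 0.1 rad RMS after 100
sequential iterations).  This limits how faithfully thin interfaces
(membrane faces, chamber rims) are reproduced and is the direct analogue
of the difficulty reported for real FIB-prepared specimens.

**Registration.**  The three defocus distances are co-registered by
subpixel phase correlation computed on low-pass filtered frames (σ = 5
px): holograms at different distances carry different fringe systems,
and an unfiltered correlator locks onto fringe displacement rather than
specimen displacement.  The simulator emits magnification-normalised
frames, so the analytic rescale by M_ref/M_i reduces to the identity
there; for data with per-distance magnification the ratio
z1_i/z1_ref is applied about the optical axis first.

**Destriping** operates on the retrieved phase projections: a wavelet
decomposition (db8, 4 levels) in which each detail band's Fourier
coefficients that are near-DC along the stripe axis are damped by an
inverted Gaussian (σ = 1 bin).  The parameters were chosen so that three
properties hold simultaneously on synthetic frames: ≥90% of injected
stripe-band energy removed, <1% RMS change on stripe-free structured
frames, and strict RMSE improvement on rippled frames.  Deeper
decompositions remove more stripe energy but start eating genuine
structure that happens to be row-constant.

## Reconstruction

Projections are converted to line integrals of δ (φ divided by
−2π·Δx/λ) and inverted slice-by-slice with ramp-filtered backprojection,
the mathematical equivalent of the standard Fourier-grid algorithm.  The
op defaults to Hann apodisation (strongest noise suppression; pure
Ram-Lak for oracle tests); the reference pipelines select the cosine
apodisation, which matches the sharper filter class of the reference
Fourier-grid processing and preserves the partial-volume wedge at the
chamber rim that Hann's extra blur erodes.  The
rotation axis defaults to the projector's pivot column; it can be
estimated from an opposing projection pair (mirror correlation) or given
explicitly.  Per-angle jitter alignment combines the projection-moment
consistency conditions (vertical centre of mass constant, horizontal
centre of mass sinusoidal in angle) with reprojection alignment iterated
to a fixed point; a rigid translation of the object (constant plus
single-period sinusoid in the shift trajectories) is unobservable in
principle and excluded from accuracy accounting.  The simulator produces
jitter-free projections, so the pipeline skips alignment by default.

## Morphometry

Segmentation is seeded region growing: flood fill over voxels whose
value differs from the seed value by at most a tolerance (6-connected by
default, conservative against leaks through single-voxel diagonal gaps).
The tolerance and the gallium-exclusion threshold are derived from the
tomogram histogram (Otsu split between the air and wall modes; gallium
threshold midway between the wall level and the top of the range).
Reports store δ-proportional values, so gallium is numerically larger
than wall — it appears darker only on inverted-grayscale displays, and
every report carries an explicit polarity note.

Measurements follow how pit anatomy is quantified on real tomograms,
with 2D/local estimators that are robust to imperfect global
segmentation (thin sub-resolution channels at the chamber rim, where the
vanishing void wedges and the membrane blur together, can connect the
two void halves — the same effect that prevents a clean 3D membrane
separation in real data):

* *membrane thickness* — the solid gap along the canal axis through the
  pit centre, median over a 5×5 neighbourhood of columns;
* *chamber diameter* — maximal Feret (caliper) extent of the in-slice
  void component containing the pit centre, over the membrane-parallel
  slices of the chamber;
* *canal slit width* — maximal Feret extent of the canal cross-section
  over the aperture-side canal run;
* *double-wall thickness* — mean distance between 50%-contrast edge
  crossings on probe lines crossing one wall (4 arms × 5 probes by
  default); probes with an unexpected number of crossings are excluded
  and logged.  A gallium-coated face presents a double-peaked rim whose
  *outer* half-contrast flanks are the wall surfaces, so the pipeline
  measures in ``edge_mode="outermost"``; the strict two-crossing mode
  remains the op default;
* *pit void volume* — voxel count of the void inside the wall slab
  (canal plus chamber, lumina excluded) times the voxel volume, exactly.

The beech measurements use two denoising scales: a light smooth (σ = 0.4
voxels) for the chamber Feret, whose limiting feature is a partial-volume
wedge that blur erodes, and a stronger one (σ = 1.0) for the membrane
gap and canal slit, which sit in noisier surroundings; voxel counting
uses the unsmoothed volume.  Recovered pit volumes are judged against
the phantom's closed-form (CSG) void volume — the continuum truth —
rather than the rasterised voxel count, which itself overstates the
continuum volume by about +1.7% at the 26 nm pitch.

## Problem sizes and determinism

The reference runs use 256³ voxels (96 axial slices for the z-invariant
tracheid block), 180 projections over the half turn and three defocus
distances — a desk-scale stand-in for the instrument's 2048² × 900 × 3
scan; the full schedule is one configuration key away.  A single run
seed fans out to the stochastic stages through spawned seed sequences;
two runs with the same configuration and seed produce identical reports.
Every stage appends its wall time to a JSON manifest with the config
hash, and a run can be re-executed from its manifest alone.

## Limitations

* The generator emulates geometry, X-ray optics, illumination structure
  and photon noise, but not partial coherence, detector blur, flat-field
  drift, specimen motion or the microfibril/torus substructure of real
  membranes; passing recovery tests therefore demonstrates algorithmic
  correctness and internal consistency, not instrument-level fidelity.
* The periodic discretisation removes boundary-truncation effects by
  construction (see above); quantifying those would require modelling
  the detector aperture explicitly.
* Retrieval accuracy, not voxel size, limits the thinnest reliably
  measurable interface: at ~0.1 rad residual phase error the membrane
  faces carry a few-voxel uncertainty, consistent with the ±2 voxel
  acceptance band on linear dimensions.
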