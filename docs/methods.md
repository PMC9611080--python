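# Methods

## The phantom

The phantom emulates the structural statistics of a segmented
high-resolution MR model of a human index finger: a 3D label matrix at
0.2 mm isotropic pitch with 6,809,600 voxels in which each of 15 tissue
types is represented by one integer from 1 to 15 (0 is the ambient
medium). Axes: x = finger width (160 voxels, 32 mm), y = finger long
axis (320 voxels, 64 mm), z = depth and light-propagation direction
(133 voxels, 26.6 mm). The published source of those statistics gives
the voxel count and pitch but not the grid factorization; (160, 320, 133)
is this package's choice, with y the long axis.

Geometry is idealized rather than subject-specific:

- **Outer surface**: superellipse cross-section (exponent 2.5, semi-axes
  7.5 × 6.5 mm) with a quarter-ellipse fingertip taper over 10 mm; the
  proximal end is cut open at the grid boundary, as a finger continues
  into the hand.
- **Skin**: epidermis (0.3 mm) and dermis (1.2 mm) shells measured by 3D
  Euclidean distance to ambient. Distance-based shells stay uniformly
  thick over the fingertip cap, where shrinking the superellipse
  semi-axes would leave the cap uncoated; everything deeper is subcutis.
- **Bones**: three capsule-shaped phalanges (radii 2.0 / 2.6 / 3.2 mm);
  distal interphalangeal (DIP) joint at y = 18 mm, proximal
  interphalangeal (PIP) at y = 40 mm. Facing bone ends carry 0.5 mm
  cartilage caps; each joint holds an ellipsoidal synovial cavity wrapped
  in a synovial-membrane / joint-capsule shell.
- **Soft structures**: flexor and extensor tendons as elliptical tubes
  spanning the finger, the A4 pulley as a 0.5 mm ring around the flexor
  tendon over the middle phalanx, collateral ligaments and volar plates
  at both joints, paired digital arteries, veins and nerves, and six
  Pacinian corpuscles (0.55 mm radius) in the volar subcutis whose
  positions take a small seeded jitter — the only randomness in
  generation.

Structures are built as independent binary masks and merged by a
**tissue prioritization list**: every contested voxel goes to the
claimant with the best rank. The default order puts fine structures
first (artery, vein, nerve, corpuscle, cartilage, membrane, cavity,
pulley, ligament, volar plate, tendon, bone, epidermis, dermis, subcutis
last) so that features only one or two voxels thick are never
overwritten by bulk tissue; the order is configurable. A cleanup pass
then removes single-voxel noise: any voxel with no 6-neighbor of its own
label is reassigned to the majority label of its 6 neighbors (ties to
the smaller label, out-of-grid neighbors count as ambient). Voxels are
fixed sequentially in scan order and passes repeat to a fixed point;
each fix strictly reduces the number of discordant neighbor pairs, so
termination and idempotence are guaranteed.

`validate_phantom` reports per-label voxel counts, skin nesting (only
epidermis may touch ambient), bone interiority, joint completeness and
per-label connected-component counts.

## Disease and anatomy transforms

**Joint inflammation.** The arthritic state is specified by target
volume factors: synovial fluid ×7.5 and membrane ×3 in the combined
preset (membrane-only and fluid-only presets exist too). Because labels
are categorical the transform is a slice-wise radial remap rather than a
deformation field: in each transverse (x–z) slice within an 8 mm
cosine-tapered axial window around the joint, squared elliptical radius
u = ((x−xc)/ax)² + ((z−zc)/az)² (center and aspect measured from the
cavity itself) is remapped piecewise linearly — the cavity annulus
[0, uc] stretches by the slice fluid factor, the membrane annulus
[uc, um] by the membrane factor, and everything outside shifts outward
by the added area. Equal-area shifting means interior tissues (bone)
keep their cross-section while being displaced, and the two targets
decouple, so each global amplitude can be solved independently by
bisection on the achieved voxel-count ratio (tolerance 0.3 %).
Resampling is nearest-neighbor; unit factors short-circuit to an exact
identity; targets that would push tissue onto the grid border raise.
On the default phantom the combined preset achieves ratios 7.511 and
2.993.

**Tendon rupture.** Tendon voxels within a half-open y-range are
relabeled as subcutis, the surrounding filler; no contraction or
deformation is modeled, and all other voxels are bit-identical.

**Scaling.** Per-axis nearest-neighbor resampling to round(f·n) voxels
at unchanged pitch, so the anatomy physically grows or shrinks. Labels
are categorical, so no interpolation and no new labels. Note that
nearest-neighbor subsampling of structures a few voxels across (vessels,
corpuscles) is faithful only in expectation: a down/up round trip
preserves bulk-tissue volume fractions to a few percent but can move
trace-tissue counts by tens of percent of their small values.

## Optical properties

Each tissue carries μa (mm⁻¹), μs (mm⁻¹), Henyey–Greenstein anisotropy
g, and refractive index n, tabulated on a shared wavelength grid
(default 400–1100 nm, 10 nm steps, 71 samples) with linear
interpolation and hard range errors. The shipped default table is a
**parametric literature-style reconstruction** — per-tissue volume
fractions of blood, water and melanin over anchor chromophore spectra
plus a power-law reduced-scattering term μs′ = a(λ/500 nm)⁻ᵇ — intended
as a plausible, replaceable default rather than a measurement. Disease
states are named override sets (multiplicative or absolute per
property). CSV I/O accepts mm⁻¹ or cm⁻¹ coefficient columns. All
quantitative transport tests in this repository use explicitly specified
synthetic property sets, never the default table.

## Monte Carlo transport

The engine follows the layered-media MCML algorithm (hop–drop–spin with
weighted packets) extended to fully 3D voxelated geometry:

1. **Launch**: weight 1, direction +z, position uniform over the z = 0
   face; a Fresnel event is applied on entry if the first voxel's index
   differs from ambient (n = 1), which reproduces specular reflectance,
   e.g. 4 % for n 1.0→1.5 at normal incidence.
2. **Hop**: a dimensionless step s = −ln(u) is spent voxel by voxel,
   consuming μt·ℓ per sub-segment, so heterogeneous paths are exact.
   Voxels with μt = 0 (ambient) are crossed ballistically.
3. **Boundary**: at every voxel face where n changes, unpolarized
   Fresnel reflectance decides specular reflection versus Snell
   refraction in the face-normal plane (axis-aligned staircase normals;
   total internal reflection beyond the critical angle; faces hit with
   |direction component| < 10⁻¹² reflect outright). Lateral x/y grid
   limits mirror the direction component, approximating a laterally
   extended medium; packets crossing the z limits exit and deposit their
   remaining weight in the reflectance (backward) or transmittance
   (forward) image at the (x, y) pixel of exit.
4. **Drop**: at an interaction, Δw = w·μa/μt is deposited in the
   containing voxel (recorded in the optional 3D absorption grid).
5. **Spin**: the new direction comes from the HG inverse CDF,
   cos θ = (1+g²−((1−g²)/(1−g+2gu))²)/(2g) (cos θ = 2u−1 for g = 0),
   with azimuth 2πu′ in the local frame.
6. **Roulette**: packets with w < 10⁻⁴ survive with probability 1/10 and
   are reweighted ×10 (MCML convention), which is unbiased, so
   R + T + A closes to 1 within Monte Carlo tolerance.

**RNG and determinism.** A master seed spawns one splitmix64 substream
per packet (state hashed from seed and packet index), so no state is
shared between packets and results are bit-identical for a fixed seed
regardless of scheduling. The kernel is a serial numba routine —
parallel hardware is an implementation detail, not part of the model —
and a pure-Python reference implementation of the traversal
(`mcsim.traverse`) backs the unit tests. Spectral sweeps run wavelength
j with seed + j, making a one-wavelength sweep identical to a single
run.

**Verification.** The engine is checked against: exact vacuum
transmission; Beer–Lambert extinction for pure absorbers at optical
depths 0.5/1/2 (3σ); normal-incidence specular reflectance (3σ); HG
sample-mean cos θ = g for g ∈ {0, 0.75, 0.9} (3σ); energy closure to
10⁻³; mirror-boundary invariance to lateral grid size (3σ); and the
published matched-boundary turbid-slab reference (μa = 1 mm⁻¹,
μs = 9 mm⁻¹, g = 0.75, two optical depths): Rd = 0.09739,
Tt = 0.66096, reproduced within 1 %. That case is often quoted as
"semi-infinite"; the tabulated reference values are for the finite slab
(a semi-infinite medium with the same coefficients gives Rd ≈ 0.166),
which an independent minimal MC script confirmed before this engine was
built.

## Imaging

Thickness projections count matching voxels along an axis times the
pitch, so Σ(map)·pixel-area equals the tissue volume exactly — the
invariant the tests assert for all 15 tissues. Spectral band integration
is an unweighted mean over in-band samples (the 650–760 nm band of the
default grid averages 12 wavelengths); log display is
log10(max(pixel, floor)). "Sagittal" projection maps to the x (width)
axis under this package's axis convention and is configurable.

## Problem sizes and reduced-scale demonstrations

The headline simulation regime for this kind of model (10⁸ packets per
wavelength × 71 wavelengths) is a GPU-cluster workload; this package's
test suite and acceptance script are sized for a single CPU core. The
structural results (15 labels, 6,809,600 voxels, inflammation ratios
7.5/3.0) are exact/deterministic and run at full scale in seconds. The
transillumination demonstration runs a half-scale finger
(`scale_geometry` ×0.5) with a wavelength-flat near-infrared synthetic
property set at 10⁷ packets: the edge-versus-center transmittance
contrast is ≈15 %, while the joint bright spot (light crossing the clear
synovial cavity instead of bone) is a 2–4 % feature at this scale —
diffuse spatial blur is comparable to finger thickness, so the 2 mm
joint gap is heavily smoothed and needs ≥10⁷ packets to resolve above
Monte Carlo noise. Both effects are asserted as ordering relations on
region means, never pixel values.

## Limitations

- The anatomy is idealized (superellipse sections, capsule bones,
  ellipsoid joints); it reproduces the tissue inventory, topology and
  scale of a real segmented finger, not any subject's true shapes, so
  passing tests demonstrate correct mechanics of generation, transforms
  and transport — not anatomical fidelity.
- Fresnel events use axis-aligned voxel-face normals; smooth oblique
  interfaces are staircase-approximated, which overestimates interface
  scattering for grazing rays at coarse pitch.
- Absorbed weight is deposited at the interaction voxel, not spread
  along the path; for voxel sizes well below the transport mean free
  path the difference is negligible.
- The default optical spectra are plausible reconstructions; any
  quantitative use should supply measured spectra via the CSV interface.
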