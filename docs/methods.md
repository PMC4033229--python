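# Methods

This note records the models, the numerical choices, and what the synthetic
experiments do and do not establish.

## Dosimetry model

Radioembolization is treated as a permanent implant with no biological
clearance: a voxel with initial activity concentration `A₀` undergoes
`A₀·V/λ` decays over all time (`λ` per second internally; hours at every
interface, consistent with the J·s committed-energy coefficient). Two
transformations of the PET image are implemented on top of this premise.

**Local deposition (LDM).** All β energy is absorbed in the voxel of decay:
`D = A₀·K_X·exp(λ_c t)`. The conversion table for ⁹⁰Y and the surrogate
radionuclides (²²Na, ⁸⁶Y, ⁶⁸Ge-in-equilibrium-with-⁶⁸Ga) ships with the
published constants verbatim — they are what a user should see bit-exact in
reports — while `derive_nuclide_params` recomputes every entry from the
half-life, branching ratios, mean β energy and liver density as a standing
validation. The printed set is not self-consistent to four digits
(`ln 2 / 64.24 h = 1.079×10⁻² h⁻¹` vs the printed `1.083×10⁻²`; the printed
`λ_c` of ²²Na is the rounded difference), which is why the derivation is
checked at 0.1–1% rather than bit-exactness.

**DPK convolution.** `D = (V_voxel/λ)·(A ⊗ DPK)` with zero-padded FFT
convolution cropped to the input extent (phantom-in-air boundary: dose
leaving the grid is lost, none enters). The voxel-volume factor makes the
concentration → per-voxel activity conversion explicit; without it the
uniform-field identity below cannot hold dimensionally. In any uniform
region wider than the kernel support, `Σ kernel energy = E_avg` forces
DPK dose = LDM dose (charged-particle equilibrium); this identity, verified
voxelwise to 0.01%, anchors the two methods to each other and is the main
guard against unit errors.

## β spectrum

⁹⁰Y→⁹⁰Zr (2⁻→0⁺) is first-forbidden *unique*, so the default spectral shape
is `ψ(E) ∝ F(Z,W)·pWq²·[q² + λ₂(W)p²]` with the relativistic point-charge
Fermi function and `λ₂` computed as the ratio of generalized Coulomb
functions for the k=2 and k=1 partial waves (normalized to 1 at Z=0).
Screening and finite-size corrections beyond the nuclear-radius term are
omitted. The builder reproduces evaluated mean energies for three test
nuclides: ³²P (allowed) 0.6948 vs 0.6949 MeV, ⁹⁰Sr (unique) 0.1956 vs
0.1958, and ⁹⁰Y 0.93390 vs 0.9337 MeV. The plain allowed shape is retained
as an option; it lands 0.7% low for ⁹⁰Y, which is why the forbidden shape is
the default.

## Dose-point kernel

The radial kernel is computed by deterministic continuous-slowing-down
transport instead of Monte Carlo. Electrons sampled across the spectrum
deposit energy at the Berger–Seltzer collision stopping-power rate
(Bragg-additivity `⟨Z/A⟩` and mean excitation energy from the elemental
composition; no density-effect correction — ≲2% at the endpoint and
absorbed by the final renormalization; no bremsstrahlung, by scope). Radial
penetration advances more slowly than path length through a mean-forward-
depth factor `exp(−⟨θ²⟩/2)` driven by the Rossi–Highland scattering power
over the radiation length. The bare factor over-contracts because it
ignores lateral diffusion once scattering saturates, so the scattering
power carries an effective strength **κ = 0.2**, calibrated once against
the published Monte Carlo benchmark that ~90% of ⁹⁰Y β energy is absorbed
within ≈5.3 mm of a point source in water. With κ = 0.2 the model gives
X50 = 2.36 mm, X90 = 5.31 mm and a mean radial penetration of 2.7 mm in
water (literature ≈2.5 mm); κ = 0 recovers the straight-ahead limit
(X90 = 6.3 mm, the longest defensible tail).

The kernel is renormalized so the interpolated function satisfies
`∫4πr²ρ·k(r)dr = E_avg` exactly — the quadrature runs on the *interpolated*
kernel so that every consumer (voxelization, tests, loaders) sees an
energy-consistent object even though `k ~ 1/r²` near the origin. Defaults:
radial step 0.02 mm, support radius 12 mm (beyond the 11.1 mm CSDA range of
the 2.28 MeV endpoint in liver at 1.04 g/mL; smaller supports are rejected).

**Voxelization.** Off-center voxels take the double average of `k(|t−s|)`
over source and target voxels, computed exactly as a weighted sum over the
(2m−1)³ pairwise-offset grid of two m-point midpoint stratifications
(deterministic; no RNG anywhere). One sorted-index representative per octant
triple is computed and mirrored, making reflection and permutation symmetry
exact to the bit. The default m = 25 puts every off-center voxel within
0.5% of a converged continuous oracle; the face-adjacent voxels see a
near-singular integrand, which is what pushes m this high (m = 7 is ~2%
off). The self-dose voxel is closed by energy balance,
`E_self = E_avg − Σ off-center`, avoiding the r→0 singularity and making
`Σ values·ρ·V = E_avg` exact by construction; a kernel whose off-center
energy already exceeds `E_avg` is rejected as inconsistent.

**Medium.** Default liver is a four-component soft-tissue composition at
1.04 g/mL. The published conversion factor implies ρ ≈ 1.043 g/mL, and the
ICRU report value for liver is 1.06; density is therefore an explicit
parameter, and 1.04 reproduces the printed K to 0.1%.

## Phantom and PSF simulation

The mathematical NEMA IEC phantom is spheres + homogeneous elliptical
background only — no sphere walls, lung insert, attenuation or noise. That
is deliberate: it is the dosimetric ground-truth object, and no generative
noise model is defined (the published noise characterization relies on
repeated physical scans). Consequently the sweep results describe the
*noiseless* ranking of LDM vs DPK; on real scans, image noise is expected to
obscure much of the difference.

Defaults: six spheres (10/13/17/22/28/37 mm) on a 57.2 mm ring in the
central transaxial plane, hot 2.2 MBq/mL, background 0.74 MBq/mL; body
ellipse half-axes 180×140 mm over a 180 mm axial extent; in-plane matrices
200² at 4 mm and 400² at 2 mm voxels. Region rasterization uses fractional
occupancy with 5³ subvoxel supersampling and antialiased (clamped
signed-distance) boundary fractions, giving ≤0.2% volume error for the
10 mm sphere at 2 mm voxels; a binary mode (supersample = 1) exists for
comparison with threshold-type ROI tools. The sphere-center plane sits at
the grid's axial midplane, which at even slice counts is a voxel boundary;
aligning it to a slice center changes the small-sphere sweep statistics by
well under the effects discussed below and is not done.

Scanner blur is a shift-invariant 3-D Gaussian (σ = FWHM/2.355, truncated
at 4σ, unit-sum kernel, zero-padded), applied to the activity grid. The TDS
is the DPK convolution of the *unblurred* phantom and never sees the PSF.

## DVH analysis and the sweep

Each sphere is scored over a spherical VOI concentric with it and 20%
larger *in diameter* (a volume interpretation is available as a switch).
The differential DVH is the mask-weighted histogram over 15 bins spanning
[0, max TDS dose in the VOI]; doses outside the range are clipped into the
edge bins so the distribution always sums to 1; the IDVH is its running
sum. The percentage-error metric is applied to the cumulative curve by
default (a differential mode exists), excluding reference bins at or below
a 10⁻⁴ floor. The crossover finder locates, by linear interpolation on the
0.25 mm FWHM grid, the point where the LDM and DPK mean errors are equal in
magnitude and opposite in sign, per sphere and pooled (sphere-averaged).

Problem sizes used by the shipped analyses: the 4 mm sweep runs the full
200²×45 grid; the 2 mm sweep runs the full 400²×90 grid over FWHM
2.0–5.0 mm in 0.25 mm steps, which brackets both the crossover and the
best-LDM region; unit tests use a cropped 100²×31 grid at 4 mm that still
contains the whole body contour.

### What the sweep reproduces, and one caveat

With these defaults the noiseless comparison shows: LDM mean IDVH error
within 10% for all reported spheres at FWHM 5.25 mm / 4 mm voxels (measured
max |mean| 0.7%); an equal-and-opposite LDM/DPK crossover at 3.0–3.5 mm
FWHM (pooled 3.17 mm) at 2 mm voxels; error-trend shapes (LDM error falls
to a minimum then grows; DPK error grows monotonically past the crossover;
the two methods' dose maps converge as the PSF widens far beyond the
kernel).

The one reference figure not reproduced is the "<3% LDM mean error for all
spheres at FWHM 4.5 mm / 2 mm voxels": this package measures −7.8% (10 mm),
−6.3% (17 mm), −1.1% (37 mm) at that point, with the per-sphere minima
(<1.2% for 17/37 mm) sitting nearer 4.0 mm. The statistic is dominated by
the first cumulative bins above the floor, where the reference value is
0.02–0.03 and the relative error is hypersensitive to the far tail of the
kernel at the VOI rim; a Monte Carlo kernel with full scatter, straggling
and bremsstrahlung has a softer tail there than this deterministic model.
This sensitivity should be kept in mind when reading small-sphere IDVH
errors generally.

## Limitations

* Homogeneous media only: no CT-density scaling, no tissue interfaces.
* Electron collision losses only: no bremsstrahlung or internal pair
  components in the kernel.
* The kernel's multiple-scattering treatment is a calibrated mean-forward-
  depth model, not transport; its X90 matches Monte Carlo but the detailed
  tail shape does not (see the caveat above).
* No noise model; results characterize the noiseless limit.
* DICOM support covers quantitative PET series with standard rescale and
  timing tags; decay correction is assumed to reference scan start.
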