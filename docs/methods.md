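# Methods

This note records the physical model implemented by `simfocus`, the
conventions and defaults it commits to, and what the synthetic tests do and
do not demonstrate about real data.

## Image formation model

Raw latticeSIM data are modeled as

    D(r) = Σ_m [(H · I_m,δz) ⊗ (S · J_m,φ)](r),

where H(r) is the detection PSF, S(r) ≥ 0 the fluorophore density,
J_m(x) = exp(i·2π·m·p·x) the m-th lateral harmonic of the illumination at
starting phase φ, and I_m(z) the axial factor of order m. The split into a
z-only factor convolved with H and an x-only factor multiplying S reflects
the acquisition geometry: the excitation pattern is fixed in the instrument
frame axially (the sample is scanned through it in z) while the lateral
modulation is imprinted on the sample. Two consequences the tests exercise:
the forward model is exactly linear and shift-covariant in S along z and y,
but along x only modulo the lateral period T_x, because the pattern does not
move with the sample.

An axial offset δz of the excitation pattern relative to the detection focal
plane multiplies each axial harmonic n·q of I_m by exp(−i·2π·n·q·δz) — a
pure phase ramp in the pupil, which is how both misaligned acquisitions and
calibration transfer functions at chosen offsets δz′ are produced. Transfer
functions are the bands of a point sample at lateral phase zero:
O′_m = FT{H(r)·I_m,δz′(z)}.

**Sign and unit conventions.** Frequencies are in cycles/μm. The forward FFT
maps real space to frequency space, with orthonormal scaling (Parseval holds
exactly) and zero-centered array layout (origin at index n//2). Positive δz
translates the excitation pattern toward +z. k-space radii are NA/λ_vacuum;
the medium index enters only the curvature of the Debye detection cap.
Offsets are quoted both in μm and in "π units", offset_π = 2·δz/T_z, so
1.0 π is half an axial lattice period and the half-period twin solution is
always 1.0 π away.

## Optics

**Detection.** The detection objective (NA 1.0, n 1.33, λ_det 0.605 μm) is a
Debye spherical cap of radius n/λ_det bounded by NA/λ_det, sampled one kz
sample thick onto the 3D frequency grid; the PSF is |FT|² of the cap,
normalized to unit sum. Scalar theory only: no polarization/vectorial
effects, no aberrations beyond the offset ramps.

**Excitation.** The hexagonal lattice is six beams at the vertices of a
hexagon of radius NA_mid = (0.55+0.5)/2 = 0.525 in the back pupil, two
vertices on the kz axis. The lateral and axial fundamentals are then
p = (√3/2)·NA_mid/λ_exc and q = (NA_mid/2)/λ_exc, giving axial period
T_z = 2λ_exc/NA_mid. The excitation wavelength is not fixed by the NA
alone; the default λ_exc = 0.560 μm is chosen because it reproduces the
instrument's 2.13 μm axial period to 0.2% (2·0.560/0.525 = 2.133 μm). A
square-lattice variant (four beams) is available through the config.

Each beam is a thin vertical line segment in the pupil: one lateral
frequency sample wide (an idealized plane-wave set; a Gaussian transverse
profile is available via `pupil_line_sigma`), extended along kz
symmetrically about the lattice wavevector as far as the annulus allows.
The symmetric clip matters: a raw annulus chord is asymmetric about the
off-axis vertices and would split the axial harmonics away from exact
multiples of q, destroying the clean n·q comb the retrieval algebra (and
the instrument's quoted periods) assume. On the default grids the annulus
is thin enough that each beam collapses to a single sample — an ideal
harmonic comb.

**Grid snapping.** The pupil is a sampled array, so beam positions snap to
the frequency grid: kx to the nearest sample (p_grid = 0.78125 cycles/μm at
the default field of view, i.e. T_x = 1.28 μm), kz preserving the exact 2:1
ratio of the hexagon's two rings so that q and the n(m) comb are
grid-exact. Simulator, transfer functions and retrieval all share the
snapped geometry, making every band shift an integer roll and the
calibration identity exact. The axial order content per lateral order is
emergent, not hard-coded: n ∈ {0,±2,±4} for m = 0, {±1,±3} for m = ±1,
{0,±2} for m = ±2, and the tests verify it numerically from the pupil
autocorrelation.

**Axial period measurement.** The pattern's axial period is measured as
1/(lowest significant peak frequency) of the per-column axial power spectra
averaged over x. Averaging the *intensity* over x first would cancel the
m ≠ 0 orders and leave only the {2q, 4q} content of the m = 0 order — the
fundamental q (hence the full period) is carried by the m = ±1 orders, which
is also why the x-averaged profile shows side lobes half a period from the
central peak.

## Simulation pipeline

Physics is continuous, cameras are not: the forward model runs on a grid
upsampled 2× along every axis (0.05 μm voxels by default) and is block-mean
integrated onto camera pixels (0.1 μm). The block mean of an even factor
places the effective camera origin half a fine voxel off the grid center,
which shows up as a known linear phase ramp on every camera-side spectrum;
it is common to data and calibration bands and cancels identically in the
overlap ratio. Boundaries are periodic (FFT-native); bead placement keeps a
guard margin of two axial periods (capped at 30% of the axial extent on
small grids) so detection tails do not wrap through beads. Negative
intensities from ringing are verified < 1e−9 of peak before clipping to 0.

The bead generator places unit-intensity single-voxel emitters uniformly at
random with rejection sampling to a minimum separation (default 0.5 μm),
deterministic per seed. Noise is i.i.d. zero-mean Gaussian with
σ = peak signal / SNR — "SNR" in this package always means peak-to-sigma.
(A Gaussian *floor* could also mean offset + noise; zero-mean is the
implemented reading.) No Poisson/sCMOS statistics, photobleaching or stage
drift are modeled.

Default problem sizes: 128 (x) × 32 (y) × 128 (z) camera voxels at 0.1 μm —
about six axial lattice periods — for the headline runs, and a 64×16×64
variant with identical voxel sizes and periods for the statistical test
suites. These sizes keep full retrieval sweeps in the minutes range on a
single CPU while holding several axial periods.

## Offset retrieval

Bands are separated per frequency sample by inverting the mixing matrix
M[j,m] = exp(i·m·φ_j); for five equally spaced phases M is a scaled DFT
matrix (condition number 1, exact inverse, energy-preserving). The overlap
ratio for order pair (m₁, m₂) is evaluated as N·conj(D)/(|D|² + ε·max|D|²)
with ε = 1e−6 — the phase, which is all the metric consumes, is arg(N·conj D)
and the regularization only prevents blowups at the support edge. The
support mask keeps voxels where |O′_m₁|·|O′_m₂| exceeds 1e−3 of its maximum,
and those products are also the weights.

The residual-phase metric is the magnitude-weighted circular deviation

    Φ(δz′, φ) = Σ w·(1 − cos(arg R − (m₁−m₂)·φ)) / Σ w,

a weighted *mean* (not sum) so masks of different sizes compare across
library entries; it is zero exactly when the kz-dependent term of the
residual phase vanishes (δz′ = δz) and the constant term is absorbed by φ.
Wrapping-safe by construction; absolute or squared wrapped-phase variants
would serve too, but 1−cos is smooth at the optimum and needs no unwrapping.
Pairs (0,1) and (1,2) contribute with equal weight; negative-m pairs are
conjugate-redundant. Because the metric is 1 − Re[Z·e^{−iΔmφ}] for one
weighted circular mean Z per (entry, pair), the full φ axis (64 candidates
over (−π, π]) costs nothing beyond the per-entry ratio.

The default library spans ±1.0 π in 0.1 π steps (21 entries). The estimate
is the grid minimum with φ restricted to (−π/2, π/2]; an optional 3-point
parabolic refinement along δz′ exists but is off by default, so estimates
land on library nodes. Exact metric ties break toward smaller |δz| with a
warning (offsets are only defined modulo one axial period, so ±1.0 π label
the same physical pattern).

**The twin minimum.** Shifting an axially periodic pattern by T_z/2 flips
the sign of every odd axial harmonic; combined with a π lateral shift this
reproduces the data almost exactly, so the unrestricted map always has a
second minimum at (δz + T_z/2, φ ± π). With ideal single-sample beams the
two minima are *exactly* degenerate in noise-free data; the kz extent of
real (envelope-confined) beams breaks the tie only weakly. This is why the
lateral search restriction, not the metric gap, is the default
disambiguator, and why both minima plus their normalized gap
(`ambiguity_ratio`) are always reported. Under noise the metric floor rises
and the map's relative modulation depth shrinks — the regime where even the
restricted choice becomes unreliable; the tests verify the depth decrease
and that the median recovery error stays within one library node for SNR
4–25 over ten noise seeds.

## Reconstruction and the ghost-lobe score

Generalized Wiener combination: each transfer function is normalized so
|O′₀(0)| = 1, bands and transfer functions are shifted by m·p, and

    Ŝ(k) = Σ_m conj(O′_m)·D̃_m·e^{−imφ} / (Σ_m |O′_m|² + w²),

with w² = 1e−3 by default, optionally apodized by a triangular radial
window to the extended support cutoffs (2·NA_det/λ_det + 2p laterally,
detection axial cutoff + 4q axially). No zero-order damping or notch
filtering. Per-order weights are uniform.

The ghost-lobe score quantifies the misalignment artifact: for each known
bead position the axial profile through the bead is examined; the score is
the mean over beads of (maximum side lobe within ±1 axial period, excluding
the central ±0.25 period) / (central peak). Matched transfer functions
drive it well below the mismatched (zero-offset) reconstruction on every
offset tested, and the half-period twin reconstructs nearly as cleanly as
the matched one — both behaviors are asserted in the tests.

## What the synthetic tests do and do not show

The generator reproduces the statistical structure the method relies on:
sparse point emitters (plus dense-bead and filament scenes for the
sample-independence checks), five-phase stepping, camera-pixel integration,
and additive Gaussian noise. Retrieval correctness, sample independence,
the dual-minimum geometry, SNR degradation and artifact suppression
demonstrated here therefore validate the *algebra and the pipeline*, under
the assumption that calibration and acquisition share the same pattern up
to translation. They do not probe: pattern-shape aberrations (refractive
index mismatch in thick samples distorts the lattice and biases the
estimate), beam divergence along the propagation direction (an optional
angular-spectrum defocus exists in the optics module but is not part of the
retrieval contract), spatially varying offsets within a field of view, or
detector noise beyond additive Gaussian. Offsets beyond ±1.0 π alias toward
the twin solutions and would require a wider library plus envelope
information to disambiguate.
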