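# Methods

`spirecon` implements the predicted-model (PM)-aided reconstruction pipeline
for XFEL single-particle imaging: snapshot diffraction patterns of one
molecule at unknown random orientations are simulated (or loaded), oriented
by correlation maximization against a reference Fourier volume, merged into
a 3D intensity, and phased with HIO-ER iterations.  The package's claim to
test is that seeding both stages with a *predicted* atomic model — its
intensities for orientation determination, its phases for phase retrieval —
converges faster and survives weaker data than random starts.

## Diffraction model

A snapshot at orientation `R = Rz(alpha) Rx(beta) Rz(gamma)` (intrinsic
z-x'-z'' angles; alpha, gamma in [0, 2pi), beta in [0, pi]) records

    I(pixel) = J * r_e^2 * Omega(pixel) * |F(R q_pixel)|^2

where `J` is the fluence of a uniform-disc focus (photons/A^2), `r_e` the
classical electron radius, `Omega = A cos^3(2 theta) / D^2` the solid angle
of a flat-detector pixel, and `q = (s_hat - z_hat)/lambda` the Ewald-sphere
scattering vector in the crystallographic convention `|q| = 2 sin(theta) /
lambda` (resolution `d = 1/|q|`).  The rotation is applied to the Ewald
sphere (`F` evaluated at `R q`), which makes `gamma` exactly an in-plane
pattern rotation — the property the FFT in-plane search relies on.  Poisson
noise is sampled per pattern from a stream spawned from `(master seed,
pattern index)`; a central square "beam stop" can be masked out.

Atoms are isotropic Gaussians of width `sigma` (default 1 A) weighted by
electron count, so `F(q) = sum_j w_j exp(-2 pi^2 sigma^2 q^2) exp(-2 pi i
q.r_j)` in closed form.  Structure factors at the Ewald-curved pixel
positions and at reference-volume voxels are computed by exact vectorized
direct summation; at the hundreds-of-atoms scale this package targets it
meets a 1e-5 accuracy contract trivially and avoids gridding error
entirely.  Cromer-Mann form factors, B-factors, solvent contrast and
polarization are out of scope.

## Grids

Patterns are 2x2 binned (block sums; a binned pixel is masked if any
contributor is).  The cubic reciprocal volume uses voxel pitch `dq =
(binned centre-pixel pitch)/2` (oversampling 2) and dimension `2 x binned
detector size`, so a 512^2 detector yields a 512^3 volume and the desk 64^2
detector a 64^3 one.  q = 0 sits at voxel index `m/2`.  The conjugate
real-space pitch is `dx = 1/(m dq)`.

## Orientation determination (correlation maximization)

1. Each binned pattern is resampled onto rings `r_min..r_max` (1 binned
   pixel apart, `n_theta` uniform azimuths; `n_theta` defaults to the next
   power of two at or above the outer-ring circumference, at least 64).
   Every ring is normalized to zero mean / unit variance over its valid
   samples so intense low-resolution rings cannot dominate; invalid samples
   are zero-filled (neutral under the zero-mean inner product).  Defaults:
   `r_min` = binned beam-stop radius + 2, `r_max` = 0.85 x Nyquist ring.
2. Slice-normal directions `(alpha, beta)` come from a quasi-uniform grid:
   beta rings every `delta_beta` (default 0.1 rad) with
   `max(1, round(2 pi sin(beta)/delta_beta))` alpha samples per ring
   (`round` chosen; one direction per pole, where the ring formula is
   singular).  For each direction a polar slice of the current volume is
   extracted by trilinear interpolation directly at the ring sample
   positions `Rz(a) Rx(b) q(r, theta)` — Ewald curvature included — and
   ring-normalized.  Matching against a complex reference volume uses
   |F|^2, since patterns are intensities.
3. The Pearson correlation for *all* in-plane angles at once is the inverse
   FFT of `conj(FFT(pattern ring)) * FFT(slice ring)` summed over usable
   rings, divided by `n_theta * n_rings`; gamma is read at the FFT bin with
   an optional parabolic sub-bin refinement (on by default).  Ties break at
   the first grid maximum.
4. Each measured binned pixel deposits its value at `R q` (and, the
   diffracting density being real, at `-R q`) with trilinear weights; voxel
   intensity is the weighted mean, zero-weight voxels form the missing
   mask.
5. Assignment and merging alternate until the mean best correlation
   (CC_mean) changes by less than `tol` (1e-3) or `max_iters` is reached;
   a final refinement pass re-searches a geodesic cap of radius
   `3 delta_beta` around each pattern's direction at `refine_delta_beta`
   (default 0.02 rad), followed by one more merge.

The PM-aided run starts from the reference volume of the predicted model
(centred, Gaussian-broadened, analytically transformed, optionally Gaussian
low-passed with 1/e^2 gain at a chosen resolution); the classical run
starts from smoothed, Friedel-symmetrized positive uniform noise.

## Phase retrieval

Amplitudes are `sqrt` of the merged intensity.  The support is a fixed
centred cube sized from the particle extent with a margin factor (default
1.2; no shrink-wrap).  Each iteration: inverse FFT; discard the imaginary
part; apply the real-space rule on the violating set {outside support} or
{negative inside} — ER zeroes it, HIO feeds back `x_prev - 0.9 rho` (Fienup
feedback 0.9, constant; a relaxation schedule would be an alternative
reading of "slowly pushed to zero") — then FFT and replace the modulus by
the measured amplitude on measured voxels, keeping the phase; missing
voxels (beam-stop cube, never-touched voxels) float entirely.  Random
starts use Friedel-consistent random phases and 1000 HIO + 100 ER; prior
starts take the predicted model's phases voxel-for-voxel and run 1100 ER
(HIO's exploratory feedback can kick a good start away).  For partial
multimer models the prior phases may not match the converged volume's
frame; the package surfaces this caveat in the docstrings rather than
auto-correcting it ("molecular replacement" for SPI is future work).
The phased map can be Fourier-zero-padded to a finer pitch (default 1 A);
the scaling preserves density values for band-limited maps.

## Evaluation metrics

All shell metrics use 1-voxel |q| shells and read resolutions at the first
threshold crossing from low q, linearly interpolated; curves that never
cross report the band limit with a flag.  CC shell: per-shell Pearson of
two intensity volumes (missing voxels excluded pairwise).  FSC: per-shell
`|sum F_a conj(F_b)| / sqrt(sum|F_a|^2 sum|F_b|^2)` of two maps, threshold
0.5 against ground truth and 0.143 between half maps.  PRTF: shell average
of the magnitude of the run-averaged unit phasors `F/|F|`, threshold 1/e.
Angular deviation: geodesic angle of `R_assigned R_true^T`.  CC map: the
per-direction maxima of the gamma-searched correlation.  Overall density CC
is computed after aligning over the trivial ambiguities — the 48 cubic
axis-permutation/flip operations (point inversion included) combined with
the best integer translation from FFT cross-correlation; success threshold
0.5.  The half-map protocol splits a stack randomly in two, reconstructs
each half independently (orientation + phasing), aligns, and reports the
FSC.

## Synthetic study conditions

Real PDB inputs are replaced by seeded phantoms: carbon-like atom clouds
(blob, self-avoiding chain, or two-lobe styles) rescaled to an exact target
radius of gyration.  The "predicted" model is the truth perturbed either by
a smooth correlated displacement field scaled to an exact RMSD (the
reference discrepancy scale being ~9.4 A for a large monomer prediction) or
by rigidly shifting half the atoms (a mis-assembled multimer).

Desk datasets (all 1 A wavelength, 300 um pixels):

| name   | detector | camera  | patterns | atoms | Rg    | sigma | noise        |
|--------|----------|---------|----------|-------|-------|-------|--------------|
| tiny   | 32^2     | 0.025 m | 50       | 60    | 9 A   | 2 A   | none         |
| small  | 64^2     | 0.1 m   | 500      | 150   | 12 A  | 1 A   | Poisson      |
| medium | 128^2    | 0.1 m   | 2000     | 400   | 16 A  | 1 A   | Poisson      |

The small recipe's pulse energy (2e15 photons) is chosen so the phantom —
which carries ~200x fewer electrons than a 472 kDa protein — detects ~2400
photons per pattern, the operating point at which the reference success-rate
studies sit; the fluence sweep halves from there.  The tiny recipe uses a
short camera and 2 A atoms so the particle spans several resolution
elements and its band-limited density is positive and support-compact;
without that, support-constrained phasing cannot reproduce even perfect
data (the band-limited truth itself violates the constraints), which is a
physical statement about barely-resolved particles, not an algorithm
defect.

What the phantoms do *not* emulate: element diversity, secondary structure,
solvent and background scattering, detector artifacts, hit-finding,
conformational heterogeneity, and fluence jitter.  Passing tests therefore
demonstrate the correctness and the qualitative orderings of the algorithms
(PM-aided >= random, more fluence >= less), not detector-grade realism.

## Numerical choices and degenerate inputs

Trilinear/bilinear interpolation drops invalid corners and renormalizes,
declaring a sample invalid below 25% valid corner weight.  Rings with < 2
valid samples or zero variance are excluded from correlations.  The merged
volume's weighted mean leaves zero-weight voxels in the missing mask.
matrix-to-Euler at the beta in {0, pi} degeneracy folds the whole in-plane
angle into alpha.  CC_mean traces are monitored for NaN (divergence) and
the phasing loop aborts on NaN spectra.  At weak Ewald curvature with few
rings (tiny's 16^2 binned patterns) a pattern correlates equally with its
inversion-partner orientation; assignments then split between the two,
which inflates raw angular deviations while leaving the merged intensity
and the phased map correct (I(q) = I(-q)); angular-deviation claims are
therefore made on the small dataset, whose curvature and ring count break
the tie.

## Known limitations

Single-threaded (no MPI); no EMC-style soft assignment; no per-pattern
intensity rescaling during merging (constant simulated fluence); static
support; no symmetry exploitation; no pattern classification.  The
beam-stop-size-to-resolution bookkeeping of the reference setup's largest
table could not be reproduced from its stated parameters under any
convention we tried (our `1/dq_voxel` for the 0.5 m setup is 167 nm, which
would make a 4-voxel stop's half-width resolution 83 nm, not the 167 nm
printed); we document our convention rather than match that mapping.
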