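# Methods

This note documents the models behind each module, the defaults that
matter, what the synthetic data emulate, and the numerical choices a user
or maintainer would otherwise have to reverse-engineer from the code.

## Photophysics

The Förster radius is computed as R₀ = 0.211 (κ² n⁻⁴ Φ_D J)^(1/6) Å with J
in nm⁴ M⁻¹ cm⁻¹ — the standard prefactor for these units. κ² defaults to
2/3 (isotropic dynamic orientational averaging) and is an explicit
parameter: for gas-phase ions with slowly tumbling dyes this assumption is
a recognized source of systematic error and the leading candidate
explanation when FRET distances exceed model distances. The refractive
index defaults to the vacuum value 1.0; use 1.33 for aqueous solution.

The overlap integral uses trapezoid quadrature on the intersection of the
two wavelength ranges after linear interpolation onto the union grid.
Convergence with grid resolution is the caller's responsibility; against a
dense-grid oracle the default treatment is accurate to ~0.1% for smooth
spectra sampled at nanometer spacing.

Decay fitting minimizes Poisson-weighted residuals, σᵢ = √max(countᵢ, 1);
zero-count bins get unit weight. The GaussMod model is the exact closed
form of an exponential convolved with a Gaussian instrument response,
evaluated piecewise through the scaled complementary error function to
avoid overflow in the tail. The double-exponential model shares one
Gaussian (μ, σ) across components and reports them ordered τ₁ < τ₂ with
fractional amplitudes. Multi-start initialization draws lifetimes from a
log-spaced grid (bin width to record length); the converged candidate with
the lowest χ² wins, ties broken by smaller τ₁; everything is deterministic
given the seed. Parameter covariance comes from the Gauss-Newton
approximation at the optimum scaled by reduced χ².

Two caveats are inherent to the weighting scheme: observed-count weights
bias lifetimes slightly low when many bins hold few counts (keep tail bins
above ~10 counts; at 10⁵ photons over 128 bins spanning ~4.4 lifetimes the
bias is below 0.5% and the 95% intervals cover at roughly nominal rate),
and fitting two components to one-component data is ill-conditioned — the
fit warns when the recovered lifetimes fall within 20% of each other or
one amplitude collapses below 1%. Model selection (`select_model`)
therefore uses the Schwarz criterion (χ² + p ln n) rather than raw χ²: the
two-parameter penalty is what keeps a one-component model from losing to
an overfit on its own data. A constant background term is not fitted by
default. The donor-only reference lifetime is always explicit user input —
pairing a donor-acceptor species with a donor-only species from a
different charge state is a scientific judgment the code does not make.

## Collision cross sections

The projection approximation treats each atom as a disk of radius
(vdW + probe); the CCS is the mean projected area of the disk union over
orientations. Orientations come from a seeded scrambled Sobol sequence
mapped to uniform rotations (Shoemake's method); per-orientation areas use
rejection sampling (default 10⁴ points) in the projected bounding box; the
reported standard error is the spread of per-orientation areas over √n and
falls as 1/√n_orientations (default 300, giving σ/mean ≲ 0.5% for compact
peptides). An independent rasterization estimator (`pa_ccs_grid`, 0.05 Å
cells) exists purely as a cross-check. The PA systematically reads low
versus trajectory methods for large ions; `scale_factor` (default 1.0)
lets users apply a published rescaling, and no attempt is made to
reproduce any particular tool's internal PA→trajectory scaling. vdW radii
default to a Bondi-type table (H 1.1, C 1.7, N 1.55, O 1.52, S 1.8 Å) with
a 1.0 Å probe radius for a N₂-like buffer gas; both are overridable.

TWIM calibration fits ln CCS′ = a ln t′ + b where CCS′ = CCS·√μ/z removes
the charge and reduced-mass dependence (buffer gas N₂, 28.0134 Da) and
t′ = t_D − c·√(m/z) corrects the post-mobility flight delay; the
instrument coefficient c defaults to 0 and must be supplied when known.
Calibrations at different wave heights are separate fits, never pooled.
The fit warns below r² = 0.98 and on extrapolation beyond the calibrated
drift range.

## Conformer model and sampling

The reduced representation — backbone N, CA, C, O; one unified side-chain
pseudo-atom (2.0 Å from CA along the tetrahedral direction); one marker
pseudo-atom per labeled residue, 5 Å out along the side-chain vector,
standing in for a dye chromophore center — replaces an all-atom
force-field model. It exists to make CCS, marker distances, and relative
energies computable at desk scale; it is not a reimplementation of any
force field, and its absolute energies are validated only by ordering and
recovery properties, never against a published energy scale.

The stand-in energy is 12-6 Lennard-Jones (σ from vdW radius sums, ε from
a per-element table, Lorentz-Berthelot-style combination) plus Coulomb
(dielectric 1, in vacuo) over pairs separated by ≥ 3 bonds, plus a
backbone hydrogen-bond well: depth 1 kcal/mol at 2.9 Å O···N separation,
Gaussian width 0.3 Å, weighted by cos² of the C=O···N alignment, for
residues ≥ 3 apart. Charges are backbone dipoles ±0.4 e (CA/C positive,
N/O negative) and +1 e per user-specified protonation site. Pairs closer
than 0.1 Å return a 10⁶ kcal/mol clash penalty instead of overflowing.

Sampling is Metropolis MC over (φ, ψ) and marker-linker torsions. Moves
are implemented as rigid rotations of the downstream atom set about the
bond axis, which is exactly equivalent to rebuilding from internal
coordinates (verified to 10⁻¹⁴ Å) but O(1) per move; states are
re-synchronized by an exact rebuild at segment boundaries. Step width is
10°·√(T/T_max), floored at 1° so the 0 K hold still quenches downhill.
One annealing cycle ramps linearly to T_max = 1500 K, holds, cools
linearly to 0 K, and holds again; the default step counts
(50/3950/500/500) are a 1/100-scale version of a
5000/395000/50000/50000-step protocol, chosen so a default run stays
interactive — the full-scale counts are plain configuration. The
branching tree (default 10 roots × 5 children; 100 × 50 reproduces a
5000-member search) chains roots from the start structure and children
from each root; every leaf is minimized (steepest descent with
backtracking line search, switching to Polak-Ribière conjugate gradient
after 1000 of at most 5000 energy evaluations; uphill steps are never
accepted). Per-branch RNG streams derive from the master seed via
SeedSequence spawn keys, so ensembles are bit-for-bit reproducible.

## Refinement cascade

The energy cutoff keeps the lowest ⌈f·N⌉ conformers by rank (default
f = 0.2). Rank, not energy range, because a percentile is scale-free —
appropriate when the energy model is a stand-in. CCS peak windows default
to ±2% (per-peak override); a conformer joins every window containing its
calculated CCS, so overlapping windows can share members, and unmatched
conformers are reported rather than dropped. Distance selection supports
`closest` (smallest |r_calc − r_exp|) and `closest_below` (largest r_calc
among those below r_exp — the right rule when the experimental distance is
suspected to be biased high, e.g. by the κ² assumption above); a shortfall
under `closest_below` falls back to `closest` with a warning rather than
aborting a batch. Overestimation is signed, positive when experiment
exceeds the model mean. All selections are deterministic with label
tie-breaks, and on small ensembles the cascade is tested to coincide with
exhaustive enumeration of the stage predicates.

## Microsolvation

Full grid-based solvation thermodynamics from explicit-solvent
trajectories is out of scope; what the workflow actually consumes is the
location of favorable modifier-binding sites and a comparable interaction
energy, so the module computes those directly. The probe is a rigid
3-site acetonitrile-like model (united methyl / C / N collinear, 1.46 and
1.17 Å bonds, charges +0.269/+0.129/−0.398 e summing to zero). Each grid
voxel (spacing 0.25-1.0 Å, default 0.5; margin 4 Å) stores the minimum
probe-solute LJ+Coulomb energy over 32 seeded quasi-random orientations by
default; poses with any site-atom distance below 0.7× the radius sum clamp
to +50 kcal/mol, keeping maps finite. Sites are local minima
(26-neighborhood) below −1.5 kcal/mol, accepted greedily by ascending
energy subject to ≥ 3.5 Å pairwise separation — the grid spacing and
separation radius are engineering choices, exposed as parameters. Probes
are placed at their map-minimizing orientation and relaxed by a bounded
(≤ 1 Å) rigid translation; unresolvable clashes skip the site with a
warning. The linear interaction energy is the direct probe-solute
nonbonded sum, excluding probe-probe terms. The bulk acetonitrile
solvent-solvent energy (−7.006 kcal/mol) is carried as probe metadata so
per-site energies can be compared against the cost of leaving bulk; a
config flag can force-add marker-adjacent sites for workflows that treat
the charged chromophores as guaranteed interaction sites. Orientation
discretization means map minima sit slightly above the true orientational
optimum (a few % against the closed-form ion-dipole case at 32-64
orientations); absolute energies are on the stand-in's own scale and only
orderings between conformers are meaningful.

## DMS analysis

Ionograms are treated empirically: Gaussian smoothing (default FWHM
0.5 V), prominence-gated maxima (default 5% of the trace maximum),
parabolic apex refinement, FWHM from interpolated half-height crossings
(model-agnostic, so asymmetric peaks are not forced Gaussian). The
modifier series reduces to the dominant-peak CV per concentration and a
least-squares slope; a larger |slope| ranks a species as the stronger
clusterer. No differential-mobility transport model and no CV-from-
structure prediction is attempted — the DMS axis enters the workflow as a
qualitative ranking only.

## Synthetic data: what it does and does not emulate

Every experimental input has a generator: decay histograms
(model-generated expected counts, Poisson-sampled at a photon budget),
calibrant tables (exact power law), ionograms (Gaussian peaks, linear CV
shift, additive noise), and conformer ensembles (the annealing sampler
itself). These emulate the statistical structure the estimators face —
shot noise, multi-start sensitivity, peak overlap, decoy-dominated
ensembles — but not instrument systematics: detector afterpulsing, IRF
asymmetry, drift-time calibration curvature, space-charge effects, or
real force-field energetics. Passing tests therefore demonstrate that the
estimators are correct and well-conditioned under their stated noise
models, not that any particular instrument's data will match.

## Pipeline

`run_all` executes sampling → energy → CCS → FRET distance → cascade →
microsolvation → DMS summary from one validated configuration (unknown
keys rejected, all problems reported at once, every applied default
logged at debug level). One master seed fans out to per-stage seeds via
SeedSequence spawn keys; reports carry a config hash and the derived
seeds, store raw values (rounding only at presentation), and are
byte-identical across reruns of the same configuration. Stage failures
abort with the stage name; partial outputs already written are preserved.
The shipped example pipeline uses a 12-mer with a 4×3 tree and reduced
grid settings (map spacing 0.75 Å, 8-12 orientations) so it completes in
well under a minute; these sizes are presentation choices, and every knob
scales up by configuration.

## Known limitations

- The energy model has no torsional, solvation, or polarization terms;
  energies are comparative only.
- PA CCS ignores long-range ion-neutral interactions and multiple
  scattering; no trajectory-method CCS is provided.
- Lifetime fits assume a Gaussian IRF and Poisson counting; no
  photon-by-photon likelihood.
- Site counting depends on the separation radius: reported absolute site
  numbers are operational, comparisons between conformers are the robust
  output.
- The DMS module never predicts compensation voltages from structure.
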