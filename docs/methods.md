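# Methods

`plumage` re-implements, as a tested pipeline, the computational chain used
to study why male and female *Ramphocelus* tanagers look so different when
their carotenoid pigments are so similar: spectral color metrics,
electromagnetic simulation of idealized feather cross-sections, spectral
curve manipulation, LC-MS pigment processing, and phylogenetic comparative
statistics. This note records the models, the parameters that matter, and
the choices made where the design was genuinely open.

## Spectral color metrics (`plumage.spectra`)

A reflectance spectrum is a wavelength grid (300–700 nm) plus fractional
reflectance for one plumage patch at one incidence angle (90° or 45°);
three instrument replicates are averaged pointwise before any metric is
computed, and averaging refuses to interpolate across mismatched grids.

* **Brightness** B = ∫₃₀₀⁷⁰⁰ R(λ) dλ / 400, computed by the trapezoid rule
  on the native grid. B is linear in R, so metric-of-average equals
  average-of-metric for replicates.
* **Saturation (LWHM)** = λ_max − λ_half, the leftwards width at
  half-maximum: λ_max is the first sample attaining the maximum (stable on
  noisy sigmoid plateaus), λ_half the nearest left crossing of R_max/2,
  located by linear interpolation between bracketing samples
  (grid-spacing-independent). A narrower left shoulder means a sharper
  carotenoid edge, i.e. a purer color. If R never reaches half-maximum left
  of the peak the width falls back to λ_max − λ_min with a warning flag.
* **Velvet classes**: *super black* = reflectance < 0.5 % everywhere and
  spectrally flat (absolute range < 0.3 %, configurable — only the 0.5 %
  level and "flatter curves" are externally constrained); *velvet red* =
  < 5 % everywhere with the mean above 600 nm exceeding the mean below
  500 nm.
* **Directionality** = brightness(45°) − brightness(90°) and their ratio; a
  positive difference marks structurally absorbing, directional patches.

Reflectance is stored as a fraction; readers auto-detect percent input (any
value > 1.5) and convert, recording the detected unit. CSV writers use
`%.17g` so written spectra re-read bit-identically.

## 2D FDTD feather optics (`plumage.fdtd`)

The solver time-steps Maxwell's equations on a 2D Yee grid in natural units
(c = ε₀ = μ₀ = 1, lengths in µm): TM (E out of plane) and TE (H out of
plane) polarizations, periodic boundaries in x (a feather tiled into a
plumage), split-field PML in y (polynomial grade 3, theoretical reflection
1e-8, 20 cells). Keratin is non-dispersive with n = 1.56 (standard feather
keratin; configurable); no pigment absorption is modelled — the simulations
isolate structure. Courant number 0.65/√2-safe (dt = 0.65 h). The default
polarization mode averages TE and TM.

**Source and measurement.** Each wavelength is run as a separate
continuous-wave solve: a soft line source is ramped on over four periods
(raised-cosine), the run continues until the per-period monitor fluxes
change by < 1e-3 relative (steady state), and complex field phasors are
then extracted by a DFT over an integer number of periods (H phasors at
half-steps; colocated by averaging). Reflectance is the upward flux of the
scattered field (total minus an empty-domain reference run) at a monitor
between source and structure over the incident downward flux; transmittance
is the net downward flux below the structure. For scenes whose material
extends through the lower PML the "transmitted" light is the flux carried
down into the substrate.

**Numerical dispersion compensation.** At coarse meshes the discrete grid
propagates light with an index slightly above the physical one, which
biases interface reflectances (e.g. a flat keratin surface reads ~5.6 %
instead of the Fresnel 4.79 % at 50 nm mesh). Because every run is
single-frequency, the permittivity map is rescaled per run so that the
discrete dispersion relation yields exactly k = n_phys ω for axial
propagation, in air and keratin alike. Residual error (impedance mismatch,
oblique directions) is below 0.3 percentage points at 25 nm mesh.

**Validity surface.** The solver is accepted against closed forms: vacuum
(R = 0, T = 1), Fresnel half-space (4.79 % at n = 1.56), and the Airy
transfer-matrix reflectance of a 1 µm slab at 500/600/700 nm, all within
1 % absolute, with R + T = 1 ± 0.02; plus invariance checks (periodic
translation, TE = TM on layered scenes, grid-refinement stability).
x-invariant scenes are automatically collapsed to a four-column periodic
cell — exactly equivalent, and it makes fine-mesh layered runs essentially
free (the collapse is disabled when absolute region areas matter).

### Campaign (i): dihedral barbule array

"Dihedral" barbules are strap-shaped barbules angled up out of the feather
plane; paired mirrored barbules form a triangular (roof-and-groove) relief.
The scene is solid keratin below that relief: the feather's underside is
extended through the lower PML because in a plumage feathers rest on other
feathers, so there is no bottom feather–air interface. One period holds one
ridge (period 2·L·cosθ for barbule length L and angle θ). At θ = 0 the
surface is flat (Fresnel reflectance); as θ grows the grooves trap light —
each wall bounce turns a ray by the apex angle and transmits ≈ 96 % of its
power into the keratin, which carries it down and out.

A literal strap-array reading (straps with air wedges beneath) was tested
and rejected: the tilted 2 µm straps act as thin films whose reflectance
*rises* with angle, the opposite of the observed behaviour of these
feathers.

Desk-scale protocol (the package default for tests and the acceptance
script): mesh 40 nm, L = 20 µm (full geometry: 80 µm), wavelengths
500/600/700 nm, TE+TM averaged; θ = 0 runs collapse to 1D and use a 15 nm
mesh at negligible cost. Under this protocol the wavelength-averaged
reflectance falls from ≈ 4.9 % at θ = 0 to ≈ 0.4 % at θ = 80°, monotone
through 60°. A caveat the package states openly: at the 80° tail the
desk-mesh value is staircase-scattering dominated — mesh-refined runs
(25 nm, L = 10 µm) are strictly monotone through 80° but reach ≈ 0.02 %,
i.e. the idealized sharp-ridge groove is a nearly perfect trap, and the
residual ~0.5 % reflectance of real feathers must come from geometry the
idealization omits (barbule end caps, the barb dome, packing disorder).

The angle sweep doubles as the source of *structural divisors* for the
curve matching below: divisor(θ) = R(0°)/R(θ), interpolated linearly
between simulated angles.

### Campaign (ii): oblong expanded barb

The pigment-bearing barb is modelled as an ellipse of keratin in cross
section — female-typical 22.2 µm tall × 18.9 µm wide, male-typical
39.8 × 27.7 µm (SEM averages) — with three sensitivity variants: whole
feather, truncated base (the barb silhouette extended through the lower PML,
removing the bottom interface), and a 10 µm circular air vacuole at the
center. The periodic cell is exactly one barb wide: adjacent feathers lie
flush, so barbs tile edge to edge.

The barb acts as a cylindrical lens: the larger male barb focuses the
incident plane wave into its interior, increasing the light–pigment
interaction for the same pigment content — the structural amplifier of
color saturation. Power transmission is measured through four
7.5 × 7.5 µm² squares anchored to each barb's own landmarks: center, side
edge midpoint, the ellipse point along the 45° ray, and top edge. (For the
male barb these landmarks are, to rounding, the published offsets of 15 µm
in x, 10 + 10 µm diagonal, and 20 µm in y; anchoring keeps the monitors on
the smaller female barb too.)

**Power convention.** Region power is the area integral of the magnitude of
the time-averaged Poynting vector, for a unit-amplitude (1 V/m) source in
the peak convention S = Re(E × H*), expressed per reference mesh cell of
25 × 25 nm: a square of undisturbed air then carries
(7.5 µm/25 nm)² · |E₀|²/η₀ = 238.9 W/m². The magnitude (not the net
downward component) is used because the quantity of interest is how much
light energy passes through the pigmented area regardless of direction;
with net-downward flux, regions in open air simply read the incident value.
Under this convention the female center region at 700 nm carries
≈ 420–425 W/m² and the male ≈ 650–670 W/m² (desk meshes 50–75 nm), a
male/female focusing ratio of ≈ 1.55–1.6. The mean of the 11 paired
female-minus-male differences is ≈ −21 W/m²: the center pairs are strongly
male-favoured (≈ −220 to −245 each) while the flank regions are
female-favoured in this idealization, because the stronger male lens sweeps
its flank light into the center. The one-sided paired t-test (female <
male) is computed alongside.

## Spectral curve manipulation (`plumage.curvefit`)

Carotenoid reflectance edges follow a logistic step
R(λ) = r₀ + a/(1 + exp(−(λ − b)/c)) with amplitude a (fraction), inflection
b (nm), width c (nm), and broadband baseline r₀. Typical fitted values for
these tanagers: a_female ≈ 0.02, a_male ≈ 0.06, b ≈ 590–630 nm,
c ≈ 14–25 nm. The two structure/pigment manipulations are:

* **Melanin removal**: melanin depresses the curve broadband; the
  manipulation replaces the measured curve by its fitted sigmoid with
  r₀ = 0 (female amplitude retained).
* **Barb enhancement**: the oblong expanded barb acts as an amplitude gain,
  so the sigmoid is regenerated at the male amplitude with b, c unchanged.
* **Structural division**: matte (velvet/super-black) patches are compared
  after dividing the female curve by the dihedral divisor R(0°)/R(θ) from
  campaign (i) — e.g. ÷4 for ≈ 35° barbules, ÷8 for ≈ 60°.

Matches are scored by the symmetric Hausdorff distance between the two
curves as planar point sets with wavelength in nm and reflectance in
percent, after linear resampling to a shared 1 nm grid (instrument grids
differ between files). The (nm, percent) coordinate choice reproduces the
magnitude range of published distances; it weights 1 nm of wavelength equal
to 1 percentage point of reflectance, which is the main open convention in
this metric. Fits use bounded least squares with tolerances at 1e-14 so
that exact synthetic sigmoids are recovered to ≈ 1e-6.

## Pigment profiles (`plumage.pigments`)

LC-MS signal intensities are comparable within, never across, carotenoid
families. Processing: per specimen, each molecule's signal is divided by
the sample weight and then by the specimen's maximum (idempotent; the
specimen maximum becomes 1); molecules are grouped into families by
accurate mass within 5 ppm against a reference catalog (a catalog must keep
families at least twice the tolerance apart, making assignment
unambiguous); isomers are summed within family, with an optional base-10
log transform using ε = (smallest positive signal)/10 for zeros; replicate
repeatability and within-bird patch comparisons are ordinary least squares
of one normalized profile on another. The eight-family catalog that ships
with the package carries representative monoisotopic masses of common avian
carotenoids; it is fixture data for synthetic tables, not study-derived
reference chemistry.

## Phylogenetic comparative statistics (`plumage.phylo`)

Brownian-motion trait evolution on a tree implies a species covariance
C_ij = shared root-to-ancestor path length; Pagel's λ scales the
off-diagonals (λ = 0 star phylogeny, λ = 1 full BM).

* **Phylogenetic paired t-test**: species differences d = x − y are
  MVN(μ·1, σ²·C(λ)); μ, σ², λ maximum likelihood (λ profiled on [0, 1] by
  bounded scalar search, tolerance 1e-6, with explicit boundary checks); μ
  tested against 0 with n − 1 df and an unbiased σ̂². On a star tree this
  reduces exactly to the ordinary paired t-test. A `fix_lambda` argument
  covers the fixed-λ reading as well.
* **PGLS**: β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y with σ̂² = RSS_GLS/(n − k) and t-tests on
  n − k df; with C = I it equals OLS to machine precision. The OU option
  fits a single attraction strength α by ML on the stationary OU
  covariance (robustness check only).
* **PCA**: SVD of the optionally log10-transformed, centered, scaled
  matrix; rows with missing values are dropped and reported; constant
  columns with scaling requested are an error. Scores × loadingsᵀ
  reconstructs the transformed matrix exactly.
* **Phylogenetic PCA**: the evolutionary rate matrix
  R = (X − 1â)ᵀC(λ)⁻¹(X − 1â)/(n − 1) with â the GLS ancestral mean and λ
  fitted by joint ML over all traits; eigen-decomposition of R (covariance
  mode by default), scores = centered data on R's eigenvectors. On a star
  tree it coincides with standard covariance PCA of species means.
* **Ancestral states**: under BM the ML states minimize
  Σ (Δ along branch)²/branch length, a weighted graph-Laplacian linear
  system solved exactly; zero-length branches are collapsed via a tiny
  floor. States are interpolated linearly along each branch. Cross-checked
  in the tests against R's `ape`/`nlme` (GLS coefficients; REML root state)
  on small fixtures.

## Cross-sex pigment mixed model (`plumage.mixedmodel`)

female = b₀ + b₁·male + u_family + u_species + e on normalized log10
signals, with u_family ~ N(0, σ_f² I), u_species ~ N(0, σ_p² C) (C from the
tree; the species effect is shared by all rows of a species), and e ~
N(0, σ_e² I). All conditionals are conjugate, so the sampler is blocked
Gibbs: one joint multivariate-normal draw of (b, u) per iteration and
scaled-inverse-χ² draws for the three variances, with inverse-gamma priors
(V = 1, ν = 0.002 — the conventional weakly informative parameterization,
configurable for stronger-belief sensitivity runs) and an effectively flat
prior on the fixed effects. Default chain: 1,000,000 iterations, 100,000
burn-in, thinning 500; the `fast` profile (50,000/5,000/50) is the test
and desk default and yields ≈ 900 near-independent draws for this small
conjugate model. Reported per parameter: posterior mean, 95 % credible
interval, effective sample size (initial-positive-sequence estimator),
pMCMC = 2·min(P(β>0), P(β<0)); plus DIC = 2·D̄ − D(θ̄) from the conditional
Gaussian deviance, and phylogenetic signal λ = posterior mean of
σ_p²/(σ_p² + σ_f² + σ_e²) (one reasonable definition; recorded as an
interpretation). The female:male ratio predictor repeatedly subsamples rows
(default 50 per draw, 100 draws, seeded) and forms Σ(predicted female)/
Σ(real male) from the posterior-mean effects.

Calibration: across 100 synthetic replicates at true slope 0.55 (fast
chains), the nominal 95 % intervals cover the truth in ≥ 90 % of fits.

## Microstructure tables (`plumage.microstructure`)

Six positive continuous SEM measurements per feather plus two coded
booleans. Numeric flags are derived against medians pooled over both sexes
and all patches (the pooling domain is configurable in principle; pooled is
the default reading): *oblong* = max width / top-down width above the
median ratio, *expanded* = max width above the median width, both strict
inequalities (identical values flag nothing). The PCA matrix is the log of
the per-(species, sex, patch) means of the six measurements. The
male/female centroid-separation permutation test (10,000 seeded label
shuffles) is diagnostic plumbing; the inferential analyses run through
PGLS.

## Synthetic data (`plumage.synth`)

Seeded pure functions emulate every input with known truth:

* **Tree**: Yule (pure-birth) process conditioned on n = 10 species,
  rooted at the first split and scaled to unit depth, emitted as newick.
* **Spectra**: 3 replicates × 7 patches × {90°, 45°} × 2 sexes × n species.
  Colorful patches (rump, breast) use the logistic edge with a_f = 0.02,
  a_m = 0.06, b = 620 nm, c = 22 nm, and a female melanin baseline
  r₀ = 0.01; black patches are flat at 0.3 % (males) or 1.5 % with a gentle
  red tilt (females, +0.5 % toward 700 nm); matte male blacks gain +5.5 %
  at 45° incidence (directionality). Gaussian noise of 0.1 % (0.05 % on
  black patches — photon noise scales with signal; the values are
  instrument-scale for a scan-averaged spectrometer), clipped at zero.
  These choices make the generated data reproduce the study's qualitative
  contrasts (males more saturated in ≥ 95 % of species, male blacks
  classified super black after replicate averaging).
* **Pigments**: 29 molecules in 8 families; male log10 signals
  N(−1, 1) (normalized intensities live in (0, 1], hence negative logs,
  and a mean away from zero keeps ratio denominators stable); female log =
  0.55·male + family effect (SD 0.3) + Brownian species effect on the tree
  (SD 0.2) + residual (SD 0.3). Tables carry raw intensities (10^log);
  the truth record stores the realized effects.
* **Microstructure**: male rows drawn around larger/more oblong means,
  coded flags true with probability 0.9 (females 0.1), and exactly one
  female species (the first) built male-like — the known real-world outlier
  pattern.

What passing tests on these data do *not* show: the generators produce
clean logistic edges, balanced designs and Gaussian noise; real spectra
carry specular glints, patch heterogeneity and instrument drift, real LC-MS
tables carry censoring at the detection limit, and real measurement error
is not homoscedastic. Recovery results here validate the estimators'
arithmetic and calibration, not robustness to those artifacts.

## Pipeline and problem sizes

`plumage run` executes: spectral metrics → phylogenetic paired tests
(saturation of the most colorful patch, darkness of the darkest patch, per
species and sex) → pigment normalization → mixed model + female:male
ratio → microstructure flags + PCA + permutation diagnostic + PGLS
(saturation ~ PC2 + PC1; cross-sex PC1) → ancestral reconstruction of
summed log pigment families → FDTD angle sweep and barb power experiment →
curve matching, writing plain CSV/JSON per stage plus a provenance log
(config hash, seed, version). Desk problem sizes throughout: 10 species,
29 molecules, the 40/50–75 nm FDTD meshes with 20 µm barbules, and the
50k-iteration chains; the paper-scale profiles (25 nm mesh, 80 µm
barbules, 10⁶-iteration chains) are available by flag.

## Known limitations

* The FDTD campaigns are 2D and pigment-free by design; absolute power
  values depend on an unknowable commercial-tool monitor convention, so the
  documented convention (peak-field, Poynting magnitude, 25 nm reference
  cell) should be treated as the package's own unit. Flank-region
  male/female orderings disagree with the published qualitative claim under
  every monitor reading tried; center-region physics reproduces well.
* The sharp-ridge dihedral idealization over-traps at steep angles once
  mesh-converged; desk-mesh values at 80° carry a staircase-scattering
  contribution of similar size to the real feathers' residual reflectance.
* Hausdorff distances depend on the (nm, percent) axis convention.
* The mixed model is Gaussian-response only, with a single phylogenetic
  variance shared across families.
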