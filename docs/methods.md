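# Methods

This note documents the models, numerical choices, and limitations behind
`crossmodalfc`, in the order the pipeline runs them.

## The cross-modal mapping model

For a parcellation of N regions, the haemodynamic FC profile of region
*i* (its row of the N×N correlation matrix, self-connection excluded) is
modelled as a linear combination of the region's band-limited
electromagnetic FC profiles in the six canonical bands (δ 2–4, θ 5–7,
α 8–12, β 15–29, lo-γ 30–59, hi-γ 60–90 Hz), with intercept. Each region
is fitted separately by ordinary least squares on its N−1 profile
entries; goodness of fit is the Ezekiel-adjusted R²,
1 − (1−R²)(n−1)/(n−p−1), with n = N−1 and p = 6. A global variant fits
the N(N−1)/2 upper-triangle edges of all matrices in one regression, and
band-specific variants use a single band as sole predictor (p = 1).

Choices made where the design was open:

- Predictors and target enter on their raw correlation scales; adjusted
  R² is invariant to affine rescaling of either, so standardization would
  change coefficients but not the correspondence map.
- Negative FC edges are retained; no thresholding before regression.
- Rank-deficient designs (possible in degenerate synthetic sweeps) fall
  back to the minimum-norm least-squares solution with a logged warning
  rather than failing.
- Model-profile observations are network edges and are not independent;
  as in comparable work, fits and dominance values are used only to
  compare regions estimated under identical conditions, not for
  edge-level inference.

## Dominance analysis and band contrasts

Each regional model's explained variance is decomposed over predictors by
classical dominance analysis: all 2⁶−1 = 63 non-empty predictor subsets
are refitted, and a predictor's incremental gain in adjusted R² is
averaged within each subset size and then across sizes. The empty model
is assigned fit 0, which makes the per-predictor total dominances sum
exactly to the full-model adjusted R² (a telescoping identity that holds
for any set function); negative incremental gains are kept rather than
floored to preserve this identity. Percent relative importance divides a
predictor's total dominance by the summed dominance. With mutually
orthogonal predictors the decomposition reduces to marginal fits up to
the O(p/n) drift of the adjusted-R² penalty across subset sizes.

Band contrasts treat regions as observations and bands as groups: a
one-way ANOVA (between df = 5, within df = 6N−6), then all 15 pairwise
two-sample t tests, two-tailed p values multiplied by 15 and capped at 1,
and pooled-SD Cohen's d. Mean differences and d are reported as absolute
values; t keeps its sign (first band minus second).

## Connectivity measures

Band-pass filtering is a zero-phase forward–backward 4th-order
Butterworth (SOS form). AEC correlates analytic-signal amplitude
envelopes; with leakage correction, each signal of a pair is
orthogonalized against the other by time-domain least-squares projection
(both directions, averaged), which removes all shared zero-lag signal. A
pair whose residual is numerically zero (duplicated channels) gets entry
0 with a warning. PLV is the modulus of the time-averaged unit phasor of
the instantaneous phase difference. Haemodynamic FC is the Pearson
correlation matrix. The source SNR utility returns
10·log₁₀((a²/N)·Σₖbₖ²/sₖ²) dB for source amplitude a, per-sensor gains
bₖ, and noise variances sₖ².

Numerical choices: envelopes and phases discard one effective filter
length at each end — 32 cycles of the band's lower edge, capped at a
quarter of the record — because the narrowband filter's ring-down scales
with inverse bandwidth and phase estimates near the edges are
contaminated well beyond one carrier period. AEC is computed statically
over the full recording (no sliding windows). The analytic signal uses
the FFT-based transform on the full record; reflection padding was
evaluated and rejected (the padding kink injects more distributed phase
error than the circular wrap it removes).

## Distance-dependent and subject-level cross-validation

Random train/test splits of spatially autocorrelated maps leak
information, so region-level validation splits each region's profile by
distance: for a source region s, the ⌊0.75(N−1)⌋ entries closest to s
(s itself first, at distance 0) form the train set. Every one of the N−1
candidate sources is enumerated — the construction is deterministic, so
no seed enters. Per split, the model is fitted on train edges and the
Pearson correlation between empirical and predicted values is recorded on
both sets, then averaged over splits per region. Floor rounding fixes the
train size; distances are Euclidean between parcel centroids.

Subject-level validation is leave-one-out over the subject ensemble: fit
on the mean matrices of n−1 subjects, evaluate per region on the held-out
subject, using the held-out subject's own band profiles as predictors
(the alternative — group band FC — was considered and rejected as it
leaks group information into the test fold).

## Spin-permutation null models

Map–map associations are tested against nulls that preserve spatial
autocorrelation: a Haar-uniform random rotation is applied to one
hemisphere's unit-sphere parcel coordinates and its midline-mirrored
conjugate to the other, and each parcel takes the value of the original
same-hemisphere parcel nearest to its rotated position (duplicates
permitted; no rematching). The two-tailed permutation p value is
(1 + #{|r_null| ≥ |r_emp|})/(n_spin + 1), so p is never zero and the
smallest attainable p with 10,000 spins is ≈ 0.0001. Rank correlation is
the default association measure; product–moment is available by flag.
BH-FDR (step-up) controls families of such tests. Under matched-smoothness
independent maps the empirical type-I error at α = 0.05 is within
Monte-Carlo error of α (verified at N = 200 over 1,000 pairs in the test
suite).

## Cortical context statistics

The principal FC gradient follows the standard diffusion-map recipe: each
row thresholded to its top 10% of connections (ties broken by index
order), cosine similarity of thresholded rows, negative similarities
clipped to zero, anisotropic normalization α = 0.5, eigenvalue-scaled
(λ/(1−λ)) automatic diffusion time, first non-trivial component. The sign
is aligned to a user-supplied anchor map when given. A uniform 1e-8
offset is added to the affinity before normalization: it keeps the
diffusion chain irreducible, so block-diagonal affinities (possible in
synthetic toys where thresholding isolates modules) yield the component
indicator as the leading mode instead of a degenerate eigenproblem, while
perturbing connected graphs at O(1e-8); a warning reports disconnected
component sizes.

Structure–function coupling is the per-region Spearman correlation of
structural and functional profiles restricted to nonzero structural
edges (NaN with a warning below 3 such edges). Depth-profile association
rank-correlates a region map with staining intensity at each of 50
equivolumetric depths, attaches a spin p value per depth (shared
ensemble), and controls FDR across the 50 comparisons. Expression
normalization uses the robust sigmoid 1/(1+exp(−(x−⟨x⟩)/IQRₓ)) with
IQRₓ the interquartile range divided by 1.349 (the IQR of a standard
normal, making the scale estimate SD-consistent — the normalization
constant is a package choice), followed by unit-interval rescaling.
Differential stability is the mean cross-donor Spearman correlation of a
gene's regional pattern over all donor pairs.

## The synthetic generator

The generator emulates the structure of a parcellated multimodal resting
state study so that every downstream stage has a planted answer. It does
not attempt biophysical realism (no forward model, no vertex-level
surfaces, no subject-level physiology).

- **Geometry.** N/2 quasi-uniform Fibonacci-lattice points on one unit
  hemisphere, mirrored across the midline; a seeded rotation about the
  mirror axis randomizes the lattice. Coordinates are unit-norm because
  the spin nulls rotate them on the sphere; distances (and the
  `decay_length` constant, default 0.5) are therefore in unit-sphere
  chord units rather than millimetres.
- **Band FC.** Each band matrix is amplitude·exp(−d/decay_length) plus a
  band-specific smooth spatial modulation (Gaussian field, squared-
  exponential kernel, correlation length `weight_smoothness` = 0.5) and
  symmetric edge noise (SD 0.15), clipped to [−1, 1], diagonal 0. The
  edge noise doubles as the decorrelating component that makes the six
  bands distinguishable predictors.
- **Haemodynamic FC and ground truth.** A smooth hierarchy field
  (rescaled to [0, 1]) stands in for the unimodal→transmodal axis. Mixing
  weights are β-dominant (base profile 0.10/0.16/0.14/0.30/0.08/0.06),
  tilt smoothly along the hierarchy, and carry an overall amplitude that
  declines along it (factor 1.4 − 0.8h): transmodal regions have
  genuinely weaker cross-modal signal. Row-wise Gaussian noise with
  per-region SD graded quadratically along the hierarchy (0 → 0.5) is
  added and the matrix symmetrized by averaging. The analytic target R²
  regresses the symmetrized noiseless row on the band profiles and
  divides the fitted-value variance by fitted + structural-residual +
  closed-form noise variance (the symmetrized noise at edge (i,j) has
  variance (sdᵢ²+sdⱼ²)/4). Under these defaults at N = 200 the fitted
  adjusted-R² map spans roughly 0 to 0.7 and declines steeply along the
  hierarchy, the regime the pipeline is designed to characterize. The
  noise symmetrization couples regions (every region inherits half its
  partners' noise), which caps the dynamic range of the effective noise
  — the quadratic grading and amplitude decline are what widen the
  target-R² range to realistic spreads.
- **Subject ensembles.** Group matrix plus symmetric iid Gaussian edge
  noise per subject (SD 0.05). This is a stand-in: no claim is made about
  how band networks actually combine across subjects.
- **Context maps.** Depth profiles mix the anchor map with smooth noise
  fields using a Gaussian depth loading (peak strength 0.9, width 3
  depths) so the association peaks at a configurable depth; the
  expression panel mixes smooth per-gene base patterns with per-donor
  noise (consistency 0.8) and plants one designated gene at a configurable
  anchor correlation (default −0.6). Noise fields are residualized
  against the anchor in-sample before mixing — smooth fields have few
  effective spatial degrees of freedom, and without residualization
  planted correlations would jitter by ±0.2 at N = 200. The structural
  matrix keeps the closest 40% of distance-decaying edges.
- **Time series.** Narrowband Gaussian carriers per region; envelope-
  coupled pairs share a slow Rayleigh envelope modulating pure-tone
  carriers at distinct in-band frequencies (so leakage correction removes
  almost nothing and the planted AEC survives); phase-locked pairs share
  one narrowband carrier with a fixed phasor rotation (PLV 1 by
  construction).

All randomness flows from per-operation child generators of a single
seed; identical configurations reproduce outputs bit for bit.

### What passing tests do and do not show

The generator's fields are Gaussian, isotropic, and stationary on the
sphere; its noise is additive and independent across edges. Real cortical
maps are non-Gaussian, anisotropic (e.g. stronger autocorrelation along
the hierarchy), and measured on irregular parcel geometries, and real
MEG–fMRI divergence includes physiological structure (vascular,
laminar) that no additive-noise model captures. Recovery of planted
quantities therefore validates the estimators' correctness and
calibration, not the substantive conclusions one would draw on empirical
data.

## Problem sizes

The test suite and the acceptance script run the full study at N = 200
parcels with 1,000 spin repetitions, the spin-calibration study at 1,000
map pairs × 500 spins, and structural checks at N = 400; these sizes give
stable statistics while keeping a complete run in the low minutes on one
core.

## Known limitations

- Pairwise (not multivariate symmetric) leakage orthogonalization; strong
  common components (≳30% of signal RMS) bias the corrected AEC.
- The distance-dependent CV enumerates sources deterministically; with
  very small N the 75/25 split leaves few test edges per split.
- The gradient's ε-regularization makes embeddings of disconnected
  affinities well-defined but assigns near-unity eigenvalues; the
  λ/(1−λ) scaling then produces large score magnitudes (the component
  shape, which is what downstream correlations use, is unaffected).
- The ANOVA treats regions as independent observations, ignoring spatial
  autocorrelation of contribution maps; its F statistic is descriptive,
  as in the analyses it mirrors.
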