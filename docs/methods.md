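# Methods

This note documents the models implemented in `wmbold`, the assumptions
behind them, the design choices made where conventions were open, and
what the synthetic-data generator does and does not emulate.

## Signal model

The BOLD signal is modelled through the deoxyhemoglobin (dHb)
contribution δR2\*(t) to the effective transverse relaxation rate.  For
small perturbations (TE·δR2\* ≪ 1) the signal is linear in δR2\*:

    S(t) = S̄ · (1 − TE · δR2*(t)) + ε(t)

so the inversion implemented in `biophys.delta_r2star_from_signal` is

    δR2*(t) = (S̄ − S(t)) / (TE · S̄).

**Sign convention.** δR2\* is positive when the signal drops below
baseline (more dHb).  The convention is explicit and can be flipped with
`sign="signal_positive"`.  **Baseline.** When a series carries a known
baseline (as simulated series do) it is used; otherwise the series mean
is substituted, which removes the DC component of δR2\* and leaves only
fluctuations.  With the true baseline the inversion is exact in the
noise-free linear model; with the series-mean baseline it is accurate to
first order in TE·δR2\*.

To first order, dHb content is the product of the oxygen extraction
fraction and blood volume, δR2\* = β·OEF·CBV, with β a constant
susceptibility coefficient.  For independent stationary fluctuations
this propagates to the supply-side variance

    σ²(δR2*) = β² (CBV² σ²_OEF + OEF² σ²_CBV),

and, after substituting the coupling identities CMRO2 = α·OEF·CBF and
CBF = CBV/MTT, to the demand-side form δR2\* = (β/α)·CMRO2·MTT with

    σ²(δR2*) = (β²/α²) (MTT² σ²_CMRO2 + CMRO2² σ²_MTT),

which reduces to (β²/α²)·MTT²·σ²_CMRO2 when transit-time fluctuations
are negligible.  These are *first-order* propagation formulas: they omit
the variance of the product of two fluctuations (order CV² relative to
the retained terms) and any OEF–CBV covariance.  The test suite checks
them against Monte-Carlo sample variances at coefficients of variation
≤ 0.1, where the neglected terms are ≪ 3 Monte-Carlo standard errors at
10⁵ draws; at larger CV the discrepancy grows quadratically.

## fALFF

`spectral.welch_spectrum` computes a Hann-windowed, mean-removed Welch
estimate (defaults: 256-sample segments, 50% overlap — standard values;
no specific Welch parameters are prescribed by the analysis itself) and
reports *amplitude*, the square root of the power density, the canonical
fALFF convention.  `spectral.falff` is the mean amplitude over
0.01–0.1 Hz divided by the mean amplitude over the full range above
0.01 Hz.  The denominator's lower bound is a parameter (`denom_lo`): the
strictly-above-band variant (above 0.1 Hz) is obtained with
`denom_lo=0.1`.  The default follows the more precise of the two
conventions in circulation; both are one argument apart.

Bundle-wise fALFF (`spectral.bundle_falff`) repeatedly draws the same
number of voxels (default n = 500, matching the minimum bundle size)
without replacement, averages their series, computes fALFF, and reports
the mean over 50 repeats with the per-repeat values.  Sampling a fixed
voxel count removes the dependence of the estimate on bundle volume.
One seeded RNG stream drives all repeats; when the sample size equals
the bundle size every repeat uses the full bundle and the estimate is
seed-invariant (sampled indices are sorted before averaging so identical
voxel sets average in identical order).

`spectral.find_peak` returns the highest *strict* local maximum within
0.02–0.15 Hz; when the spectrum is monotone in the band, the band
maximum is returned with `is_local_max=False` so callers can tell a true
peak from an edge.

## Bundle construction

Streamline endpoints are mapped to parcels through the NIfTI affine
(0-based voxel indices, world coordinates in mm, superior–inferior =
third world axis).  Endpoints landing on background or WM are reassigned
to the nearest parcel voxel within a configurable search radius (default
2 mm, one voxel), ties broken by lowest label id.  This nearest-label
convention is this package's choice of a standard reassignment rule; it
is exposed as a parameter rather than hard-coded.  Streamlines whose two
endpoints resolve to the same parcel (self-loops) or to no parcel are
discarded.

Bundle voxel masks rasterize every segment of every member streamline
(dense sampling at a quarter of the voxel size), not just the vertices,
so masks are connected and volume-faithful at 2 mm.  Pairs are
unordered; bundles may overlap (shared voxels are allowed, which is why
Dice overlap is a meaningful measure).  Bundles with fewer than 500
voxels (4000 mm³ at 2 mm) are excluded by default.  Classification is a
pure function of the parcel pair: association if neither parcel is
pseudo-GM, projection otherwise.  Orientation is the angle between the
first principal axis (SVD of pooled streamline points) and the S-I unit
vector, folded into [0°, 90°]; for a bundle with two exactly balanced
orthogonal directions the principal axis, and hence the angle, is the
diagonal of the pair.

## Moderation analysis

`moderation.fit_moderation` fits fALFF = β0 + β1·X + β2·M + β3·X·M + e
by OLS with an intercept and two-sided p-values.  Conventions that
matter:

* The response, predictor and moderator are z-scored (sample SD, n−1);
  the **interaction is the product of the z-scored main effects and is
  not re-standardized**.  This keeps the threshold −β1/β3 interpretable
  on the moderator's z-scale, which is what allows converting it to raw
  moderator units as mean + threshold_z·SD.
* With `z_score=False` the columns are used as-is.  This is the correct
  mode for tables generated directly on the z-scale (as
  `synthetic.simulate_moderation_table` does): re-standardizing the
  response would rescale every coefficient by 1/SD(y) and the fitted
  values would no longer estimate the generating coefficients.
* The threshold is undefined (None, with a recorded reason) when
  |β3| ≤ 10⁻¹⁰; separately, a flag reports whether β3 is significant at
  the configured α.
* Raw-scale conversion uses the moderator's sample moments.  When only
  printed group statistics are available, `moderation.pooled_moments`
  reconstructs the mixture mean and SD (within- plus between-group
  variance, n−1 denominator) — for 120 bundles at 0.09±0.01 and 40 at
  0.12±0.02 this gives mean 0.0975 and SD ≈ 0.0185, and a z-threshold of
  1.78 converts to ≈ 0.13.

Simple slopes are β1 + β3·m_z at requested raw moderator levels; the
slope is exactly zero at the threshold by construction.

## Variance-model regressions

`biophys.fit_supply_model` / `fit_demand_model` square the raw
predictors first, then z-score the squared quantities and the response,
and fit OLS *without* an intercept by default (all variables are centred
by z-scoring, and the no-intercept form keeps the two-coefficient
decomposition symmetric; an intercept flag is provided since the
convention is not universal).  Contributions are |γi|/Σ|γj|·100 — the
simplest decomposition consistent with z-scored designs, and invariant
to joint rescaling of the regressors.  This definition is an
interpretation: contribution shares computed from real atlas data depend
on the (unstated) decomposition rule used there, so only the machinery,
not any particular published share, is a reproduction target.

## Resting-state HRF and the initial dip

`hrf.detect_events` marks strict local maxima of the standardized series
exceeding `k_sd` (default 1.0) standard deviations, thinned greedily by
height so retained events are ≥ 4 s apart.  `hrf.estimate_hrf` averages
epochs from 4 s before to 24 s after the epoch origin, normalizing each
epoch to percent change from its own pre-window mean (rejecting slow
drifts).  This event-triggered average deliberately replaces full blind
deconvolution: it does not unmix overlapping responses, so recovered
amplitudes are attenuated when events are dense, but the *ordering* of
dip magnitudes — the quantity used downstream — is preserved, and the
test suite verifies monotone recovery of generator dip depths
{0, 0.25, 0.5}.

Detected peaks lag the underlying events by roughly the HRF peak time;
`onset_shift_s` (default 0) shifts the epoch origin back by an assumed
lag so the curve is aligned at event onset.  The *initial dip* is the
magnitude of the most negative value at lags in (0, peak time), floored
at 0 — dips are reported as positive magnitudes, and the post-peak
undershoot is never mistaken for the dip because the search stops at the
peak.  An estimate whose global maximum is not at a positive lag has no
identifiable response and dip extraction raises an error.

## Evoked block analysis

`evoked.paper_paradigm` encodes the eight-direction bar paradigm:
16 s rest, four 32-s blocks, 12 s rest, four 32-s blocks, 16 s rest —
exactly 300 s at TR 1 s, with each block ending in a 4-s blank tail.
Construction validates that blocks and rests are disjoint and tile the
run exactly.  The percent-change baseline pools all rest intervals
(pooling maximizes baseline stability; the alternative of per-rest
baselines is not offered).  Block averages are time-locked at block
onset with no hemodynamic lag shift by default; blank tails are included
in block windows by default and excludable by flag.

## The synthetic-data generator

The generator's defaults are the study conditions: TR 0.72 s,
TE 33.1 ms, 1200 time points, 120 association and 40 projection bundles,
association MWF 0.09±0.01 vs projection 0.12±0.02, and a low-frequency
spectral component at 0.055 Hz.  Quantities the conditions do not pin
down were fixed once at values realistic for resting-state WM imaging:

* **Hemodynamic levels.** CBV 2.0±0.3 (relative units, typical of WM
  relative-CBV maps), MTT 4.0±0.5 s, OEF 0.40±0.05 between bundles;
  α = β = 1 (both are scale factors that cancel in every dimensionless
  quantity the pipeline reports).
* **Fluctuations.** OEF(t) and CBV(t) are independent stationary AR(1)
  (discretized Ornstein–Uhlenbeck) processes with marginal SDs 0.01 and
  0.05 and a 10-s correlation time — a two-parameter family giving
  direct control of SD and timescale, sufficient for a model that only
  requires stationary low-frequency variation.  The AR(1) recursion uses
  the exact stationary discretization, so the marginal SD equals the
  parameter.
* **The 0.055-Hz bump** is a Gaussian-envelope narrowband process
  (width 0.005 Hz, SD 0.05 in CBV units) *added to CBV(t)*; attributing
  it to CBV rather than OEF is an arbitrary but inconsequential choice
  since only the product enters δR2\*.  Its amplitude and width are free
  parameters; the defaults make the bump the dominant local maximum of
  the 0.02–0.15 Hz band in most realizations.
* **Events.** Spontaneous events are a homogeneous Poisson train
  (default 0.05 events/s — sparse, so individual responses are mostly
  resolvable) convolved with the HRF kernel and added in fractional
  signal units (default amplitude 0: off).
* **HRF kernel.** A canonical double-gamma (peak 6 s, 10% undershoot at
  16 s) minus a gamma-shaped pre-peak lobe whose scale is solved by
  root-finding so the kernel minimum before the peak is *exactly*
  −dip_depth after unit-peak normalization; the kernel starts at exactly
  0.  No functional form is prescribed for the dip, so this explicit
  parameterization is the package's own.
* **Thermal noise** is i.i.d. Gaussian at 0.2% of baseline, a typical
  single-voxel-average noise floor after preprocessing.
* **Positivity.** Negative draws of strictly positive quantities (CBV,
  MTT, OEF, MWF) are resampled, not clipped, to avoid point masses at
  the bound.
* **Moderation tables** are generated directly on the z-scale from
  (β0, β1, β2, β3) with configurable residual SD (default 0.5, giving
  R² ≈ 0.65 at the printed coefficient magnitudes — a strong but noisy
  bundle-level regression) and optional
  predictor–moderator correlation (default 0).
* **Geometry.** Parcels are deterministic cubes on the grid faces
  (cortical GM on the left/right faces, pseudo-GM on the inferior face,
  interior WM labelled distinctly); streamlines are jittered quadratic
  arcs between random voxel centres of their two parcels, resampled to
  half-voxel spacing.  The default 16 cortical parcels supply exactly
  C(16,2) = 120 association pairs, and 3 pseudo-GM parcels supply 48
  candidate projection pairs of which 40 are used.
* **MWF independence.** MWF is generated independently of the
  hemodynamic variables; couplings observed in real data are emulated
  only if explicitly configured (not by default).

**Reproducibility.** Each generator function draws from an independent,
named sub-stream of the config seed (`SeedSequence(seed, spawn_key)`),
so identical config + seed gives bit-identical output and adding a new
consumer does not perturb existing streams.

**What the generator does not emulate** — and therefore what passing
tests do not establish about real data: scanner physics and artifacts,
physiological noise structure (cardiac/respiratory), motion,
multi-subject registration error, spatial autocorrelation within
bundles (voxels share one bundle signal plus white noise),
non-Gaussian or non-stationary hemodynamics, and any empirical coupling
between myelin and hemodynamics beyond what is explicitly configured.
Tests against this generator establish correctness of the estimators
under the stated model, not the model's adequacy for real tissue.

## Numerical choices and degenerate inputs

* z-scores use the sample SD (ddof = 1) throughout; constant columns are
  rejected with an explicit error.
* The Welch spectrum of a constant series is all-zero with a warning;
  fALFF of such a spectrum raises (zero denominator).
* Dice of two empty masks is undefined and raises; map sampling ignores
  non-finite voxels (count logged) and raises only when all are
  non-finite.
* Linearization guard: configs (and simulated series) where
  TE·β·OEF·CBV can reach 0.1 are rejected, naming the offending product.
* fALFF repeat values that are bitwise identical report an SD of exactly
  0 (the naive SD of n identical floats can round to ~1 ulp).
* Problem sizes in the test and acceptance runs (200 replicates of 160
  bundles for coefficient recovery, 50 seeds for spectral calibration,
  10⁵ draws for the variance oracle, 20 seeds per dip level) were chosen
  so Monte-Carlo standard errors sit well below the effect sizes being
  checked while the full suite runs in seconds.

## Known limitations

* The event-triggered HRF estimator attenuates amplitudes under event
  overlap; only dip *ordering* across conditions is claimed.
* The variance formulas are first-order and carry no covariance term;
  OEF–CBV dependence in real tissue would bias both predictions.
* Contribution percentages depend on the z-score-and-|γ| decomposition
  convention documented above.
* No bootstrap confidence interval is provided for the moderation
  threshold (a ratio of coefficients; its sampling distribution is
  heavy-tailed when β3 is small) — future work.
* The streamline-endpoint reassignment rule (nearest parcel within a
  radius) is a declared convention, not a reproduction of any particular
  pipeline's unpublished rule.
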