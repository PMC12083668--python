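# wmbold

Biophysical analysis of BOLD signal fluctuations in white matter.

Resting-state BOLD signals are robustly detectable in white matter (WM),
but their physiological drivers are far less understood than in cortex.
`wmbold` implements a bundle-level analysis of WM BOLD fluctuations for
researchers working with resting-state fMRI, tractography and
hemodynamic/metabolic maps:

* **GM-WM-GM units** — streamlines are grouped into bundles by their
  connected gray-matter parcel pair, classified as *association*
  (cortex–cortex) or *projection* (one endpoint in a pseudo-GM parcel:
  cerebellar cortex or cervical spinal cord), filtered by a minimum voxel
  count (default 500 voxels = 4000 mm³ at 2 mm), and measured (volume,
  mean streamline length, deviation from the superior–inferior axis,
  Dice overlap, bundle-wise means of any voxel-wise scalar map).
* **Bundle-wise fALFF** — the fractional amplitude of low-frequency
  fluctuations: mean Welch spectral amplitude in 0.01–0.1 Hz divided by
  the mean amplitude over the full range above 0.01 Hz, estimated by
  repeatedly sampling a fixed number of voxels (n = 500, 50 repeats) from
  each bundle to remove bundle-volume bias.
* **A susceptibility variance model** — for echo time TE and baseline
  signal S̄, the deoxyhemoglobin contribution to the transverse
  relaxation rate is δR2\*(t) ≈ (S̄ − S(t))/(TE·S̄), and to first order
  δR2\* = β·OEF·CBV. Independent fluctuations give

  σ²(δR2\*) = β²(CBV²·σ²OEF + OEF²·σ²CBV)            (supply side)

  σ²(δR2\*) = (β²/α²)(MTT²·σ²CMRO2 + CMRO2²·σ²MTT)   (demand side)

  using the coupling identities CMRO2 = α·OEF·CBF and CBF = CBV/MTT.
  Two regressions decompose bundle-wise fALFF accordingly:
  Model 1: fALFF = γ1·CBV² + γ2·OEF² + e1 and
  Model 2: fALFF = γ3·MTT² + γ4·CMRO2² + e2, all variables z-scored,
  with per-term contributions |γi|/Σ|γj|·100.
* **Myelin moderation** — the interaction model
  fALFF = β0 + β1·X + β2·MWF + β3·X·MWF + e on z-scored variables, where
  MWF is the myelin water fraction; the moderation threshold −β1/β3 is
  reported on the z-scale and converted to raw MWF units.
* **Resting-state HRF dip** — spontaneous-event detection and
  event-triggered averaging yield an empirical hemodynamic response whose
  *initial dip* (the negative deflection before the main peak) is
  extracted per bundle.
* **Evoked responses** — percent-signal-change analysis of the
  eight-block visual paradigm (16 s rest, 4×32 s blocks, 12 s rest,
  4×32 s blocks, 16 s rest; 300 s at TR 1 s), with time-locked
  block averaging, e.g. for unmyelinated vs myelinated optic-nerve ROIs.
* **A forward simulator** (`wmbold.synthetic`) that generates
  parcellations, streamlines, feature tables and BOLD series with this
  exact statistical structure (TR 0.72 s, TE 33.1 ms, 1200 time points,
  120 association + 40 projection bundles, MWF 0.09±0.01 vs 0.12±0.02, a
  narrowband spectral component at 0.055 Hz, HRF kernels with a
  parameterized initial dip), so the whole pipeline runs and is tested
  with no external data.

## Worked example

```python
import wmbold as w

# simulate one resting-state bundle series and locate its spectral peak
cfg = w.SyntheticConfig(seed=0)
features = w.simulate_hemo_features(cfg)
series = w.simulate_bold(features.iloc[0], cfg)
spectrum = w.welch_spectrum(series)
peak = w.find_peak(spectrum)
print(f"fALFF           : {w.falff(spectrum):.3f}")
print(f"spectral peak   : {peak.freq_hz:.4f} Hz (height {peak.height:.2f})")

# fit the myelin moderation model on a table simulated from printed
# relative-CBV coefficients (beta1=0.57, beta3=-0.32)
cfg = w.SyntheticConfig(seed=0, moderation_truth=(0.0, 0.57, -0.18, -0.32),
                        moderation_resid_sd=0.5)
table = w.simulate_moderation_table(cfg)
fit = w.fit_moderation(table, response="falff_z", predictor="predictor_z",
                       moderator="mwf_z", z_score=False)
print(f"beta1, beta3    : {fit.beta1:.3f}, {fit.beta3:.3f}")
print(f"threshold (z)   : {fit.threshold_z:.3f}")

# convert the printed coefficients to a raw myelin-water-fraction threshold
mean, sd = w.pooled_moments([120, 40], [0.09, 0.12], [0.01, 0.02])
_, traw = w.threshold_from_coefficients(0.57, -0.32, mean, sd)
print(f"raw threshold   : {traw:.3f}")
```

Output:

```
fALFF           : 1.707
spectral peak   : 0.0543 Hz (height 9.40)
beta1, beta3    : 0.651, -0.299
threshold (z)   : 2.179
raw threshold   : 0.130
```

The simulated bundle's spectrum peaks at 0.0543 Hz — the Welch frequency
bin (width 1/(256·0.72 s) ≈ 0.0054 Hz) closest to the injected 0.055-Hz
component — and its fALFF exceeds 1 because power is concentrated at low
frequencies. A single 160-bundle replicate estimates the moderation
coefficients with sampling noise (0.651 and −0.299 here, around the true
0.57 and −0.32); averaging over replicates recovers them closely.  The
raw-scale moderation threshold of 0.130 is the myelin water fraction
above which the predictor–fALFF slope changes sign: only projection
bundles are this heavily myelinated.

## Command line

File-based access to each stage:

```sh
wmbold simulate   --seed 0 --out data/
wmbold bundles    --streamlines data/streamlines.tck --parcels data/parcellation.nii.gz \
                  --pseudo-gm 17 18 19 --wm-label 20 --min-voxels 500 --out bundles/
wmbold falff      --bold run.nii.gz --masks-dir bundles/ --n-sample 500 --out falff.tsv
wmbold fit-models --table features.tsv --out fits.json
wmbold moderation --table features.tsv --response falff --predictor rcbv \
                  --moderator mwf --out fit.json
wmbold hrf        --bold run.nii.gz --masks-dir bundles/ --k-sd 1.0 --out hrf.tsv
wmbold evoked     --bold task.nii.gz --rois head.nii.gz body.nii.gz --out evoked.tsv
```

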