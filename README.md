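# metartiq

Objective quantification of metal artifacts in CT volumes around a
high-density implant — built for photon-counting CT of patients with a left
ventricular assist device (LVAD), where the titanium pump degrades image
quality through streaks, blooming and attenuation bias — together with the
statistical machinery of a visual-grading reader study.

The package is aimed at medical physicists and imaging scientists who need
to compare acquisition and reconstruction settings (kVp, dose/IQ level,
reconstruction kernel, iterative metal-artifact-reduction preset, virtual
mono-energetic keV, slice thickness) by how much metal artifact they leave
behind.

## What it computes

**Three objective artifact metrics** on a 3-D HU volume:

- **Diff_HU** — signed mean-attenuation difference between an ROI placed
  where the artifact is most pronounced and a reference ROI in comparable
  artifact-free tissue, and **SD_ARTIFACT**, the sample standard deviation
  inside the artifact ROI (HU).
- **AmplitudeLowFreq** — HU is sampled along a closed contour traced a fixed
  offset outside the metal boundary and resampled by arc length to N = 141
  points; the discrete Fourier transform X_k = Σ_t h_t e^(−2πikt/N) is taken
  and the unnormalised low-frequency amplitude |X₁| + |X₂| (bins 1–2, i.e.
  0–0.0142 cycles/sample) is averaged over three sequential slices, with its
  coefficient of variation. Bright/dark streaks radiating from metal are
  low-angular-frequency modulations along such a contour.
- **BloomVol** — the apparent implant volume: voxels inside an HU band
  (default lower bound 800 HU for phantom-type data, 2500 HU for in-vivo,
  upper bound 32 762), largest 26-connected component, voxel count ×
  voxel volume (cm³). Blooming inflates this volume above the true implant
  volume.

**Reader-study statistics**: per-case tallies of scores ≥ 3 on the 5-point
scale per question (Q1–Q6) and their sum VG_SUM; inter-reader ICC(C,k)
(two-way random effects, average-measures consistency, (MS_R − MS_E)/MS_R)
and intra-reader ICC(A,k) (absolute agreement,
(MS_R − MS_E)/(MS_R + (MS_C − MS_E)/n)); baseline-category multinomial
logit models ln P(score = j)/P(score = 1) = β₀ + β₁kVp + Σβ₂ᵢkeVᵢ + β₃IQ +
Σβ₄ᵢiMARᵢ + Σβ₅ᵢkernelᵢ + β₆·slice; Spearman correlation matrices with
pairwise-complete deletion; and (log-)linear regressions of each artifact
metric on the covariates (power-law form under the log link, e.g.
BloomVol = kVp^β₁·keV^β₂·kernel^β₃·iMAR^β₄·slice^β₅·e^(β₀+ε)) with
bidirectional stepwise AIC selection and percent-change coefficient
reporting ((e^β − 1)·100).

**A synthetic phantom generator** produces thorax-like volumes with a metal
cylinder of known volume, controllable blooming (Gaussian blur), sinusoidal
streak fields, noise, and simulated ordinal reader scores from a latent
quality model — so every metric and statistic can be validated against an
analytic or closed-form oracle.

Two per-case study tables (a 36-case phantom arm and a 27-case in-vivo
arm) ship with the package and drive the end-to-end reproduction.

## Worked example

```sh
$ metartiq reproduce --out results/
wrote results/reproduction.json
[phantom] VG_SUM max = 25, BloomVol 42.3-92.7 cm^3
[patient] VG_SUM max = 14, BloomVol 27.0-96.3 cm^3
```

The best phantom reconstructions reach a visual-grading sum of 25 (of a
maximum 36 = 6 readers × 6 questions), and blooming alone moves the
apparent implant volume between 27.0 and 96.3 cm³ across in-vivo
reconstruction settings — the headline motivation for treating BloomVol as
an artifact metric.

From Python, the streak metric on a synthetic phantom with a known
first-order cosine streak field of 50 HU:

```python
>>> from metartiq import PhantomSpec, StreakSpec, generate_phantom
>>> from metartiq.metrics import compute_amplitude_low_freq
>>> spec = PhantomSpec(noise_sd=0, bloom_sigma_mm=0,
...                    streak=StreakSpec(amplitude_hu=50, angular_order=1,
...                                      radial_decay_mm=1e6))
>>> vol, truth = generate_phantom(spec)
>>> res = compute_amplitude_low_freq(vol, center_slice=16)
>>> round(res.amplitude_low_freq, 1)
3524.6
```

which matches the closed form A·N/2 = 50 × 141/2 = 3525 to 0.01 %.

Other commands: `metartiq metrics` (all metrics for one NIfTI/DICOM
volume), `metartiq correlate`, `metartiq icc`, `metartiq regress`, and
`metartiq validate` (the synthetic property battery; nonzero exit on any
failure).

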