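# wavemotif

Waveform-shape analysis of non-sinusoidal EEG alpha oscillations.

## The problem

Cortical alpha rhythms (7–14 Hz) are not sinusoids: their peaks and troughs
differ in width, and their rising and falling edges differ in speed. These
waveform features carry physiological information that conventional Fourier
band power throws away, but measuring them in scalp EEG is hard — sensors mix
many sources, amplitude varies wildly between cycles, and shape differences
live in higher-order structure that mean-based statistics miss.

`wavemotif` implements a complete cycle-by-cycle shape pipeline for resting
multichannel EEG, together with a synthetic-data generator that injects
*known* shape asymmetries, so every stage can be verified by parameter
recovery:

1. **Spectral parameterization** — multitaper power spectra decomposed into an
   aperiodic component `log10 P(f) = b − χ·log10 f` plus Gaussian peaks;
   yields the individual alpha frequency (IAF) and alpha SNR in dB.
2. **Spatio-spectral decomposition (SSD)** — spatial filters maximizing
   alpha-band against flanking-band power via the generalized eigenproblem
   `C_s w = λ C_n w`, with forward-model patterns `A = C_s W (WᵀC_s W)⁻¹`.
3. **Leadfield matching** — each pattern is assigned to a source and cortical
   lobe by absolute cosine distance `1 − |a·b|/(‖a‖‖b‖)` against a supplied
   leadfield (accepted below distance 0.15).
4. **Masked EMD and cycle QC** — the alpha mode is isolated with a masked sift
   (masks at 120, 64, 32, 11, 7, 2 Hz); the normalized Hilbert transform
   gives instantaneous phase, amplitude, and frequency (IF); cycles pass QC
   only with top-quartile amplitude, unique control points, and no phase
   reversal.
5. **Phase-aligned IF motifs** — each cycle's IF is resampled onto a common
   48-bin phase grid (IF_PA), normalized by the mean IF, and decomposed with
   PCA into *waveform motifs* (e.g. peak–trough width asymmetry, edge-speed
   asymmetry) with per-cycle scores and split-half reliability.
6. **Distributional statistics** — pre/post score distributions are compared
   with two-sample Cramér–von Mises ω² tests, bootstrap confidence intervals,
   Bonferroni correction, and a 10th/90th-percentile tail analysis that
   catches "more extreme shapes" even when means do not move.

The generator writes shape through the *phase velocity*
`dφ/dt = 2π f₀ (1 + a_pt·cos φ + a_rd·sin φ)`, `signal = cos φ`, so the
injected IF-by-phase profile lives in exactly the space the pipeline
measures; intervention transforms (alpha power scaling, aperiodic
flattening, shape shifts, tail inflation) emulate pharmacological effects.

## Worked example

A simulated pre/post session: one 10 Hz alpha source (peak–trough asymmetry
`a_pt = 0.1`, cycle-to-cycle jitter 0.05) in 1/f^1.5 noise across 8 channels;
the "post" recording shifts `a_pt` by +0.15 and draws 20% of cycles with
3-fold jitter (tail inflation).

```yaml
# session.yaml
seed: 7
simulate:
  n_channels: 8
  fs: 250.0
  duration: 60.0
  chi: 1.5
  noise_amp: 1.0
  sources:
    - {f0: 10.0, a_pt: 0.1, jitter_sd: 0.05, amplitude: 3.0}
  intervention: {a_pt_shift: 0.15, tail_fraction: 0.2, tail_k: 3.0}
stats:
  n_boot: 2000
```

```
$ wavemotif run-all --config session.yaml --out out/
IAF = 9.69 Hz
components: 4 SSD, 1 past SNR, 1 matched
cycles: 1169 detected, 293 accepted
artifacts in out/
```

The pipeline found the alpha peak at 9.69 Hz (slightly below 10 Hz because
asymmetric phase velocity lengthens the mean cycle), kept one of four SSD
components after the alpha-SNR criterion, matched it to the leadfield, and
accepted 293 top-quartile cycles. `out/stats.csv` then shows, per lobe and
principal component:

```
     lobe  pc  omega2      p   ci_lo   ci_hi  mean_shift  prop_below_p10  prop_above_p90  significant
occipital pc1  5.6886  <1e-6  3.3978  8.4568     -0.1518          0.5000          0.0764         True
occipital pc2  1.9385  <1e-6  0.9000  3.8367      0.0370          0.1250          0.4167         True
occipital pc3  2.5908  <1e-6  1.3326  4.6809      0.0265          0.1667          0.3403         True
occipital pc4 21.0146  <1e-6 18.9614 22.8157     -0.0686          0.9306          0.0139         True
```

All four motif-score distributions change significantly (the Bonferroni
threshold over the 4 tests is 0.0125): the injected asymmetry shift moves the
mean score of the peak–trough motif, and the tail inflation pushes post-drug
mass past the pre-drug 10th/90th percentile cuts (`prop_*` columns, nominal
0.10 each).

Every stage is also available as its own verb (`simulate`, `spectra`, `ssd`,
`match`, `cycles`, `motifs`, `stats`) and as library functions
(`wavemotif.ssd.fit_ssd`, `wavemotif.emdcycles.masked_sift`, ...).

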