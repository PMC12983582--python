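# Methods

This note documents the models and procedures implemented in `wavemotif`, the
parameter choices that matter, what the synthetic generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Synthetic alpha sources

A source's shape is injected through its phase velocity,

    dφ/dt = 2π f₀ (1 + a_pt cos φ + a_rd sin φ),      x(t) = cos φ(t),

with the cycle starting at the ascending zero crossing (φ = −π/2). The
`cos φ` term (`a_pt`) modulates speed symmetrically around the peak versus
the trough: positive values traverse the peak faster, producing narrow peaks
and broad troughs. The `sin φ` term (`a_rd`) modulates the rising versus the
falling edge: since sin φ < 0 on the trough→peak half, a positive `a_rd`
*slows the rising edge* and speeds the falling one. Positivity of the phase
velocity requires |a_pt| + |a_rd| < 1; realized per-cycle draws (mean ±
`jitter_sd`, optionally with a `tail_fraction` of cycles at `tail_k`-fold
jitter) are rescaled into an L1 ball of radius 0.95 so integration never
stalls. The phase is integrated per sample with classical RK4; with zero
asymmetry the integration is exact and the output is a machine-precision
sinusoid, which anchors several tests.

Injecting shape through phase velocity rather than waveform warping means the
ground truth lives in exactly the IF-by-phase space the pipeline measures, so
recovery is a direct correlation, not a model fit.

Recordings mix sources (unit-norm channel patterns, either supplied or drawn
once per session) with sinusoidal amplitude envelopes (default 0.1 Hz, depth
0.5 — enough to make the top-quartile amplitude criterion selective), scaled
to a target RMS, plus 1/f^χ noise made by frequency-domain shaping of white
Gaussian noise, independent per channel with an optional shared field for
spatial correlation. Defaults for desk-scale studies: 8 channels, 250 Hz,
60–120 s, χ = 1.5, source RMS 3 µV over noise RMS 1 µV (alpha SNR ≈ 20–35 dB
after spectral fitting, comfortably inside the ≥10 dB regime the recovery
properties target). Intervention transforms change only the requested fields:
`power_scale` multiplies band power (amplitude × √scale), `chi_delta` tilts
the background, `a_pt_shift`/`a_rd_shift` move mean shape, and
`tail_fraction`/`tail_k` inflate the cycle-to-cycle shape distribution's
tails without moving its mean.

What the generator does *not* emulate: head-model geometry (patterns are
abstract weight vectors), artifacts (blinks, muscle, line noise),
non-stationary χ, or multiple interacting rhythms. Passing tests demonstrate
that the analysis chain recovers known shape structure under linear mixing
and 1/f noise; they do not certify performance on artifact-laden clinical
recordings.

## Spectral parameterization

PSDs use DPSS multitapers (time-half-bandwidth 4 per 10 s epoch, i.e. 0.8 Hz
smoothing bandwidth; eigenvalue-weighted, epochs and channels averaged; via
MNE). The log10-power spectrum over 2–40 Hz is modeled as an aperiodic line
`b − χ log10 f` (fixed mode, no knee) plus up to 6 Gaussian peaks with width
limits 1–12 Hz and a minimum height of 0.2 log10 units (2 dB, with
dB ≡ 10·log10 power ratio). The aperiodic fit is made robust to peaks by
fitting once, clipping negative residuals, and refitting on the points at or
below the 2.5th percentile of the clipped residuals — in practice the points
not elevated above the line. Peaks are extracted iteratively from the
flattened spectrum (largest residual, half-height bandwidth guess), refit
jointly as a multi-Gaussian, and the aperiodic component is refit on the
peak-removed spectrum. On noise-free constructed spectra the exponent is
recovered to machine precision; r² ≥ 0.95 on all generative fixtures.

The IAF is the center of the largest peak in 7–14 Hz of the channel-collapsed
model (linear power averaged across channels before fitting — the most stable
order of operations); its absence is a value, not an error. Alpha SNR is the
peak's height above the aperiodic fit, in dB. Note that an asymmetric source
with base frequency f₀ has mean rate f₀·√(1 − a_pt² − a_rd²), so the spectral
peak sits slightly below f₀ by construction, not by bias.

## SSD

Signal covariance comes from zero-phase Butterworth order-2 band-pass at
IAF ± 2 Hz; noise covariance from data band-passed over the full flank span
(±4 Hz) and band-stopped over the signal band widened by 1 Hz. Both get
shrinkage `C ← (1−γ)C + γ·tr(C)/n·I` with γ = 1e−6 before
`scipy.linalg.eigh(C_s, C_n)`. Filters are sorted by eigenvalue (the
band-power ratio each filter attains — verified maximal against 1000 random
probes); patterns use the Haufe identity exactly. Filters are applied to the
*broadband* data so component waveforms keep their harmonics. Components are
kept when their own spectral model shows an alpha peak with SNR strictly
above the threshold (default 3.87 dB, exposed as a parameter); the number of
filters carried into selection defaults to those with λ above the median λ.

**Polarity.** An SSD filter's sign is arbitrary, but waveform shape is not:
an inverted component swaps peaks and troughs and negates peak–trough
asymmetry. The pipeline therefore orients each retained component so that its
spatial pattern is positively aligned with its matched leadfield row. Without
such a convention a pre/post shape shift can appear with inverted sign.

## Masked EMD and instantaneous attributes

One IMF is extracted per mask frequency (120, 64, 32, 11, 7, 2 Hz, skipping
masks at/above Nyquist): the mask sinusoid (amplitude 1× the residual's SD,
4 phases averaged) is added, one mode is sifted out (Rilling stopping rule
0.05/0.5 with 5% tolerance, 15-iteration cap; cubic-spline envelopes with
mirrored edge extrema), and the mask subtracted. The residual update makes
`sum(modes) + residual = input` exact by construction. The alpha mode is the
one whose mask is nearest 11 Hz.

Instantaneous attributes use the normalized Hilbert transform: a spline
envelope through the maxima of |x| (iterated ≤3 times until the carrier stays
within 1+1e−3) separates amplitude from phase; IF is the smoothed derivative
(5-sample Savitzky–Golay, order 2) of the unwrapped analytic phase. The first
and last max(window, 0.1 s) samples are flagged as Hilbert edge effects and
cycles touching them are discarded.

Cycles run between ascending zero crossings of the phase. QC requires
(i) mean amplitude at or above the percentile threshold (default 75th,
computed within each component × time point), (ii) peak, descending zero, and
trough each crossed exactly once and in order, (iii) strictly increasing
unwrapped phase. Acceptance is monotonically non-increasing in the amplitude
percentile.

**Known limitation — harmonic attenuation.** A non-sinusoidal 10 Hz waveform
carries its shape in harmonics near 20–30 Hz; the 32 Hz mask stage removes
roughly three quarters of the 20 Hz harmonic, so the alpha mode's IF-by-phase
modulation is attenuated about five-fold relative to the injected profile
(e.g. a_pt = 0.2 injected ≈ 0.04 measured). The *profile shape* survives
(round-trip correlation > 0.95 at ≈20 dB alpha SNR with ≥300 accepted
cycles), and orderings/signs of shape differences are preserved, which is
what the motif statistics consume. Near 10–12 dB SNR the measured profile
correlation degrades to ≈0.9 because slow narrowband noise perturbs each
realization coherently; quantitative IF_PA amplitudes should therefore be
read as relative, not absolute, shape measurements.

## Motifs and statistics

IF_PA uses 48 phase bins spanning [−π, π) (bin centers), interpolating each
accepted cycle's IF against its unwrapped phase. Normalization divides by the
grand-mean IF_PA of the normalization group — default group: component ×
time point, making each group's mean relative IF exactly 1 while preserving
within-group variance ratios; per-cycle and global grouping are available
(per-cycle normalization additionally removes between-cycle frequency
offsets, at the cost of discarding cycle-rate information). PCA is computed
once on the pooled column-demeaned matrix; motif signs are fixed by making
each motif's largest-|loading| bin positive, with the flips recorded so
polarity is reproducible. Split-half reliability (default 500 splits) refits
PCA on random halves and reports sign-aligned |loading correlations| after
greedy matching. A relative-IF profile maps back to a normalized waveform via
dt ∝ dφ/IF(φ) and resampling cos φ to uniform time.

The two-sample Cramér–von Mises statistic and its asymptotic p-value are
computed with SciPy (`cramervonmises_2samp`; midrank ties; the exact method
is exposed for n+m ≤ 20); the test suite verifies the statistic against a
brute-force empirical-CDF evaluation and checks the empirical type-I error at
n = m = 100 (0.05 ± 0.015 over 2000 simulations). Bootstrap CIs resample x
and y independently with replacement (percentile interval, default 10,000
resamples, seeded). Bonferroni thresholds divide α by the number of tests in
the family (0.05/16 = 0.003125 for 4 PCs × 4 lobes). The tail report cuts at
the pre-distribution's 10th/90th percentiles and reports post-sample mass
beyond each cut against the nominal 0.10 — the statistic that exposes
symmetric tail inflation invisible to mean contrasts.

## Pipeline

`run_pipeline` performs a within-session pre/post analysis: IAF from
channel-collapsed spectra averaged over time points; SSD fit once on the
concatenated time points; SNR selection; leadfield matching (frontal sources
excluded by default, configurable) and polarity orientation; masked-EMD
cycle extraction per component × time point; pooled IF_PA and PCA; per-lobe ×
per-PC CvM table. No between-session component matching is attempted —
sessions are analyzed independently. Configs are YAML with unknown keys
rejected and Nyquist-violating bands refused before any computation; the same
config and seed reproduce byte-identical CSV outputs.

Verification problem sizes (chosen for one-CPU, minutes-scale runs): the
round-trip study uses 1600 cycles at 250 Hz (400 accepted); SSD recovery uses
8 channels × 60 s; the end-to-end intervention study runs 20 seeded sessions
of 60 s per time point with a_pt shift +0.15 and tail inflation (20%,
3-fold), scoring success as a correctly-signed mean shift on the
cos φ-matched PC together with a family-Bonferroni-significant CvM test.
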