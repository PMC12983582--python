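"""Synthetic EEG with non-sinusoidal alpha sources of known shape.

Shape asymmetries are injected through the *phase velocity* of each cycle
rather than by warping a waveform: the phase of a source evolves as

    dφ/dt = 2π f0 (1 + a_pt cos φ + a_rd sin φ),    signal = cos φ

so the injected instantaneous-frequency-by-phase profile *is* the ground
truth that the downstream sift → Hilbert → phase-alignment chain measures.
The ``cos φ`` term modulates speed symmetrically around the peak versus the
trough (peak-trough width asymmetry); the ``sin φ`` term modulates the rising
versus falling edge (rise-decay / edge-speed asymmetry). Positivity of the
phase velocity requires |a_pt| + |a_rd| < 1.

Recordings mix one or more such sources through channel-weight patterns and
add 1/f^χ background noise, emulating the aperiodic component of resting EEG.
An :class:`InterventionEffect` transforms a generation spec the way a
GABAergic drug transforms resting alpha: scaling alpha power, flattening the
aperiodic slope, shifting the mean shape coefficients, and inflating the
tails of their cycle-to-cycle distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from wavemotif.recording import RawRecording

__all__ = [
    "ShapeParams",
    "SourceSpec",
    "SimulationSpec",
    "GroundTruth",
    "InterventionEffect",
    "make_cycle_train",
    "make_recording",
    "apply_intervention",
    "pink_noise",
]

# ascending zero crossing of cos φ: cycles span [-π/2, 3π/2), matching the
# cycle convention used by the detection stage
PHASE_START = -np.pi / 2

# realized per-cycle coefficients are rescaled into this L1 ball so the phase
# velocity keeps a positive margin even in inflated tails
MAX_ASYM_L1 = 0.95


@dataclass(frozen=True)
class ShapeParams:
    """Ground-truth shape of a non-sinusoidal oscillator.

    Parameters
    ----------
    f0 : float
        Base cycle frequency in Hz.
    a_pt : float
        Peak-trough width asymmetry coefficient (multiplies cos φ in the
        phase velocity). Positive values speed the cycle up around the peak,
        narrowing it relative to the trough.
    a_rd : float
        Rise-decay (edge-speed) asymmetry coefficient (multiplies sin φ).
        Positive values speed up the rising edge.
    jitter_sd : float
        Cycle-to-cycle standard deviation applied independently to each
        coefficient.
    tail_fraction : float
        Fraction of cycles drawn from an inflated-jitter distribution.
    tail_k : float
        Jitter inflation factor for those tail cycles.
    """

    f0: float
    a_pt: float = 0.0
    a_rd: float = 0.0
    jitter_sd: float = 0.0
    tail_fraction: float = 0.0
    tail_k: float = 1.0

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError(f"f0 must be positive, got {self.f0}")
        if abs(self.a_pt) + abs(self.a_rd) >= 1:
            raise ValueError(
                "phase velocity must stay positive: require |a_pt| + |a_rd| < 1, "
                f"got {abs(self.a_pt) + abs(self.a_rd):.3f}"
            )
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if not 0 <= self.tail_fraction <= 1:
            raise ValueError("tail_fraction must lie in [0, 1]")
        if self.tail_k < 1:
            raise ValueError("tail_k must be >= 1")


@dataclass(frozen=True)
class SourceSpec:
    """One alpha source: shape, slow amplitude envelope, gain, and topography.

    ``pattern`` is the channel-weight vector mixing the source into the
    sensors; ``amplitude`` is the RMS of the mixed source signal (µV) at unit
    pattern norm; the envelope is sinusoidal amplitude modulation with
    ``env_freq`` Hz and depth ``env_depth`` in [0, 1] (envelope ranges over
    [1 - depth, 1]), phase drawn uniformly per realization.
    """

    shape: ShapeParams
    amplitude: float = 1.0
    env_freq: float = 0.1
    env_depth: float = 0.5
    pattern: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if not 0 <= self.env_depth <= 1:
            raise ValueError("env_depth must lie in [0, 1]")
        if self.pattern is not None:
            pat = np.asarray(self.pattern, dtype=float)
            if pat.ndim != 1 or not np.any(pat != 0):
                raise ValueError("pattern must be a 1-D vector with a nonzero entry")
            object.__setattr__(self, "pattern", pat)


@dataclass(frozen=True)
class SimulationSpec:
    """Full generation spec for one recording (sources plus background)."""

    sources: tuple[SourceSpec, ...] = ()
    n_channels: int = 8
    duration: float = 120.0
    fs: float = 250.0
    chi: float = 1.5
    noise_amp: float = 1.0
    noise_spatial_corr: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", tuple(self.sources))
        if self.duration < 10.0:
            raise ValueError("duration must be at least 10 s")
        if self.n_channels < max(1, len(self.sources)):
            raise ValueError("need at least as many channels as sources")
        if not 0 <= self.noise_spatial_corr <= 1:
            raise ValueError("noise_spatial_corr must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Everything needed to score recovery: per-cycle shape table and mixing.

    ``cycles`` has one row per generated cycle with columns ``source``,
    ``cycle``, ``start``, ``end`` (sample span, end exclusive), ``a_pt``,
    ``a_rd`` (realized coefficients) and ``amplitude`` (mean envelope µV over
    the span). ``mixing`` is sources x channels.
    """

    cycles: pd.DataFrame
    mixing: np.ndarray
    chi: float
    seed: int
    source_signals: np.ndarray | None = None


@dataclass(frozen=True)
class InterventionEffect:
    """Pre-to-post transform of a generation spec ("drug effect").

    ``power_scale`` multiplies alpha-band power (amplitude scales by its
    square root); ``chi_delta`` is added to the aperiodic exponent (negative
    = flattening); ``a_pt_shift`` / ``a_rd_shift`` move the mean shape
    coefficients; ``tail_fraction``/``tail_k`` draw that fraction of cycles
    with k-fold jitter, inflating distribution tails.
    """

    power_scale: float = 1.0
    chi_delta: float = 0.0
    a_pt_shift: float = 0.0
    a_rd_shift: float = 0.0
    tail_fraction: float = 0.0
    tail_k: float = 1.0

    def __post_init__(self) -> None:
        if self.power_scale <= 0:
            raise ValueError("power_scale must be positive")


def _phase_velocity(phi: float | np.ndarray, f0: float, a_pt: float, a_rd: float):
    return 2 * np.pi * f0 * (1.0 + a_pt * np.cos(phi) + a_rd * np.sin(phi))


def _draw_coefficients(
    shape: ShapeParams, n_cycles: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Realized per-cycle (a_pt, a_rd), with optional tail inflation."""
    sd = np.full(n_cycles, shape.jitter_sd)
    if shape.tail_fraction > 0 and shape.tail_k > 1:
        tail = rng.random(n_cycles) < shape.tail_fraction
        sd[tail] *= shape.tail_k
    a_pt = shape.a_pt + sd * rng.standard_normal(n_cycles)
    a_rd = shape.a_rd + sd * rng.standard_normal(n_cycles)
    # rescale any draw that would stall or reverse the phase
    l1 = np.abs(a_pt) + np.abs(a_rd)
    bad = l1 >= MAX_ASYM_L1
    if np.any(bad):
        scale = MAX_ASYM_L1 / l1[bad]
        a_pt[bad] *= scale
        a_rd[bad] *= scale
    return a_pt, a_rd


def make_cycle_train(
    shape: ShapeParams,
    n_cycles: int,
    fs: float,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Generate ``n_cycles`` cycles of a shaped oscillation at ``fs`` Hz.

    The phase starts at the ascending zero crossing (φ = -π/2) and is
    integrated sample-by-sample with classical RK4; the per-cycle coefficients
    switch when the unwrapped phase crosses each 2π boundary. Returns the
    signal ``cos φ`` and a per-cycle ground-truth table (columns ``cycle``,
    ``start``, ``end``, ``a_pt``, ``a_rd``).

    With zero asymmetry the integration is exact and the output is a pure
    sinusoid at ``f0``.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if fs <= 4 * shape.f0:
        raise ValueError(f"fs must exceed 4*f0 = {4 * shape.f0} Hz, got {fs}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a_pts, a_rds = _draw_coefficients(shape, n_cycles, rng)

    dt = 1.0 / fs
    phases: list[float] = []
    phi = PHASE_START
    cyc = 0
    starts = [0]
    # hard cap: the slowest admissible cycle is 1/(f0*sqrt(1-MAX^2)) seconds
    max_samples = int(np.ceil(n_cycles / (shape.f0 * np.sqrt(1 - MAX_ASYM_L1**2)) * fs)) + 16
    while cyc < n_cycles:
        phases.append(phi)
        a, b = a_pts[cyc], a_rds[cyc]
        k1 = _phase_velocity(phi, shape.f0, a, b)
        k2 = _phase_velocity(phi + 0.5 * dt * k1, shape.f0, a, b)
        k3 = _phase_velocity(phi + 0.5 * dt * k2, shape.f0, a, b)
        k4 = _phase_velocity(phi + dt * k3, shape.f0, a, b)
        phi = phi + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        boundary = PHASE_START + 2 * np.pi * (cyc + 1)
        if phi >= boundary - 1e-12:
            cyc += 1
            starts.append(len(phases))
        if len(phases) > max_samples:
            raise RuntimeError("phase integration failed to advance")

    phase = np.array(phases)
    signal = np.cos(phase)
    table = pd.DataFrame(
        {
            "cycle": np.arange(n_cycles),
            "start": starts[:-1],
            "end": starts[1:],
            "a_pt": a_pts,
            "a_rd": a_rds,
        }
    )
    return signal, table


def pink_noise(
    n_samples: int,
    fs: float,
    chi: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One realization of 1/f^chi noise, unit RMS, by spectral shaping.

    White Gaussian noise is shaped in the frequency domain with amplitude
    ∝ f^(-chi/2) (DC removed), giving power spectral density ∝ 1/f^chi.
    """
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-chi / 2.0)
    shaped = np.fft.irfft(spec * gain, n=n_samples)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def make_recording(
    spec: SimulationSpec, seed: int = 0
) -> tuple[RawRecording, GroundTruth]:
    """Simulate a multichannel recording from a generation spec.

    Each source's cycle train is amplitude-modulated by its slow envelope,
    scaled to the requested RMS, and mixed into the channels through its
    pattern; 1/f^χ noise (independent per channel plus an optional shared
    spatially correlated field) is added at RMS ``noise_amp`` per channel.
    Identical spec and seed give bit-identical output.
    """
    nyq = spec.fs / 2.0
    for src in spec.sources:
        if src.shape.f0 >= nyq:
            raise ValueError(
                f"source frequency {src.shape.f0} Hz violates Nyquist ({nyq} Hz)"
            )
    rng = np.random.default_rng(seed)
    n_samples = int(round(spec.duration * spec.fs))
    t = np.arange(n_samples) / spec.fs

    mixing = np.zeros((len(spec.sources), spec.n_channels))
    source_signals = np.zeros((len(spec.sources), n_samples))
    cycle_tables: list[pd.DataFrame] = []

    for i, src in enumerate(spec.sources):
        # enough cycles to cover the recording even for slowed (asymmetric) cycles
        n_cycles = int(np.ceil(spec.duration * src.shape.f0 * 1.3)) + 2
        raw, table = make_cycle_train(src.shape, n_cycles, spec.fs, rng)
        if raw.size < n_samples:  # pragma: no cover - margin above is generous
            raise RuntimeError("cycle train shorter than recording")
        raw = raw[:n_samples]

        env_phase = rng.uniform(0, 2 * np.pi)
        env = 1.0 - src.env_depth * (
            0.5 - 0.5 * np.cos(2 * np.pi * src.env_freq * t + env_phase)
        )
        modulated = raw * env
        scale = src.amplitude / np.sqrt(np.mean(modulated**2))
        source_signals[i] = modulated * scale

        if src.pattern is not None:
            pat = np.asarray(src.pattern, dtype=float)
            if pat.size != spec.n_channels:
                raise ValueError(
                    f"source {i} pattern has {pat.size} weights for "
                    f"{spec.n_channels} channels"
                )
        else:
            pat = rng.standard_normal(spec.n_channels)
        mixing[i] = pat / np.linalg.norm(pat)

        table = table[table["end"] <= n_samples].copy()
        table.insert(0, "source", i)
        amp = np.array(
            [np.mean(env[s:e]) * scale for s, e in zip(table["start"], table["end"])]
        )
        table["amplitude"] = amp
        cycle_tables.append(table)

    data = mixing.T @ source_signals if len(spec.sources) else np.zeros(
        (spec.n_channels, n_samples)
    )

    if spec.noise_amp > 0:
        rho = spec.noise_spatial_corr
        shared = pink_noise(n_samples, spec.fs, spec.chi, rng) if rho > 0 else 0.0
        for ch in range(spec.n_channels):
            indep = pink_noise(n_samples, spec.fs, spec.chi, rng)
            noise = np.sqrt(1 - rho**2) * indep + rho * shared
            data[ch] += spec.noise_amp * noise

    cycles = (
        pd.concat(cycle_tables, ignore_index=True)
        if cycle_tables
        else pd.DataFrame(
            columns=["source", "cycle", "start", "end", "a_pt", "a_rd", "amplitude"]
        )
    )
    rec = RawRecording(data, spec.fs, [f"ch{i + 1:02d}" for i in range(spec.n_channels)])
    truth = GroundTruth(
        cycles=cycles,
        mixing=mixing,
        chi=spec.chi,
        seed=seed,
        source_signals=source_signals,
    )
    return rec, truth


def apply_intervention(
    spec: SimulationSpec, effect: InterventionEffect
) -> SimulationSpec:
    """Return the post-"drug" generation spec; only requested fields change.

    Raises if a shape shift would push |a_pt| + |a_rd| to 1 or beyond.
    """
    new_sources = []
    for src in spec.sources:
        shape = src.shape
        new_shape = replace(
            shape,
            a_pt=shape.a_pt + effect.a_pt_shift,
            a_rd=shape.a_rd + effect.a_rd_shift,
            tail_fraction=(
                effect.tail_fraction if effect.tail_fraction > 0 else shape.tail_fraction
            ),
            tail_k=effect.tail_k if effect.tail_fraction > 0 else shape.tail_k,
        )  # ShapeParams validation enforces the asymmetry invariant
        new_sources.append(
            replace(src, shape=new_shape, amplitude=src.amplitude * np.sqrt(effect.power_scale))
        )
    return replace(
        spec, sources=tuple(new_sources), chi=spec.chi + effect.chi_delta
    )
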