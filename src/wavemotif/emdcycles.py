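"""Masked empirical mode decomposition and cycle detection.

EMD decomposes a signal into intrinsic mode functions (IMFs) — oscillatory
modes locally symmetric about zero — by iteratively subtracting the mean of
the upper and lower extrema envelopes ("sifting"). Plain sifting suffers
from mode mixing when nearby rhythms share extrema; the *masked* sift adds a
known sinusoid before sifting and subtracts it afterwards, averaging over
several mask phases, so each IMF collects only content faster than its mask
frequency. With the default mask ladder (120, 64, 32, 11, 7, 2 Hz) the alpha
rhythm lands in the 11 Hz-mask mode.

Instantaneous attributes come from the normalized Hilbert transform: the IMF
is divided by a spline envelope through the maxima of its absolute value
(iterated until unit amplitude), the analytic-signal phase of the normalized
carrier gives instantaneous phase, and its smoothed derivative gives
instantaneous frequency in Hz.

Cycles are delimited by ascending zero crossings (phase passing -π/2) and
pass quality control only if (i) their mean amplitude reaches the requested
percentile over all cycles in the segment, (ii) the four control points
(ascending zero, peak, descending zero, trough) are present and unique, and
(iii) the unwrapped phase never reverses within the cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal
from scipy.interpolate import CubicSpline

__all__ = [
    "IMFSet",
    "InstAttributes",
    "masked_sift",
    "instantaneous_attributes",
    "detect_cycles",
    "alpha_imf_index",
    "DEFAULT_MASK_FREQS",
]

DEFAULT_MASK_FREQS = (120.0, 64.0, 32.0, 11.0, 7.0, 2.0)

# cycle start convention: ascending zero crossing of cos phase
CYCLE_START_PHASE = -np.pi / 2


@dataclass
class IMFSet:
    """Modes ordered fast to slow, plus the residual and the masks used."""

    modes: np.ndarray  # (n_modes, n_samples)
    residual: np.ndarray
    mask_freqs: list[float]

    def reconstruct(self) -> np.ndarray:
        total = self.residual.copy()
        if len(self.modes):
            total = total + self.modes.sum(axis=0)
        return total


@dataclass
class InstAttributes:
    """Instantaneous phase/amplitude/frequency of one IMF.

    ``phase`` is wrapped to [-π, π); ``phase_unwrapped`` is the monotone-ish
    accessor used for cycle detection. ``edge`` samples at the segment
    boundaries carry Hilbert end effects and are excluded from cycles.
    """

    phase_unwrapped: np.ndarray
    amplitude: np.ndarray
    if_hz: np.ndarray
    fs: float
    n_edge: int = 0

    @property
    def phase(self) -> np.ndarray:
        return np.angle(np.exp(1j * self.phase_unwrapped))


def _local_maxima(x: np.ndarray) -> np.ndarray:
    idx, _ = scipy.signal.find_peaks(x)
    return idx


def _spline_envelope(x: np.ndarray, ext: np.ndarray) -> np.ndarray | None:
    """Cubic spline through extrema, edges handled by mirroring extrema."""
    n = x.size
    if ext.size < 2:
        return None
    k = min(ext.size - 1, 2)
    t = ext.astype(float)
    v = x[ext]
    left_t = -t[1 : k + 1][::-1]
    left_v = v[1 : k + 1][::-1]
    right_t = 2 * (n - 1) - t[-k - 1 : -1][::-1]
    right_v = v[-k - 1 : -1][::-1]
    tt = np.concatenate([left_t, t, right_t])
    vv = np.concatenate([left_v, v, right_v])
    keep = np.concatenate([[True], np.diff(tt) > 0])
    spline = CubicSpline(tt[keep], vv[keep])
    return spline(np.arange(n))


def _sift_next_imf(
    x: np.ndarray,
    max_iters: int = 15,
    rilling_thresh: tuple[float, float] = (0.05, 0.5),
    rilling_alpha: float = 0.05,
) -> np.ndarray:
    """Extract one IMF by sifting with a Rilling-style stopping rule."""
    h = x.astype(float).copy()
    for _ in range(max_iters):
        maxima = _local_maxima(h)
        minima = _local_maxima(-h)
        if maxima.size + minima.size < 3:
            break
        upper = _spline_envelope(h, maxima)
        lower = -_spline_envelope(-h, minima)
        if upper is None or lower is None:
            break
        mean_env = 0.5 * (upper + lower)
        amp = 0.5 * (upper - lower)
        amp = np.where(np.abs(amp) < 1e-12, 1e-12, np.abs(amp))
        sigma = np.abs(mean_env) / amp
        theta1, theta2 = rilling_thresh
        if (np.mean(sigma < theta1) >= 1 - rilling_alpha) and np.all(sigma < theta2):
            break
        h = h - mean_env
    return h


def masked_sift(
    x: np.ndarray,
    fs: float,
    mask_freqs: tuple[float, ...] = DEFAULT_MASK_FREQS,
    max_imfs: int = 6,
    n_phases: int = 4,
    mask_amp: float = 1.0,
) -> IMFSet:
    """Masked EMD: one IMF per mask frequency, fast to slow.

    For each mask frequency a sinusoid with amplitude ``mask_amp`` x the
    current residual's standard deviation is added at ``n_phases`` equally
    spaced phases; one IMF is sifted from each masked signal, the mask
    subtracted, and the results averaged. Masks at or above Nyquist are
    skipped with a warning. ``sum(modes) + residual`` reproduces the input to
    machine precision by construction.
    """
    x = np.asarray(x, dtype=float).ravel()
    usable = [f for f in mask_freqs if f < fs / 2]
    if len(usable) < len(mask_freqs):
        warnings.warn(
            f"skipping mask frequencies at/above Nyquist ({fs / 2} Hz): "
            f"{sorted(set(mask_freqs) - set(usable), reverse=True)}"
        )
    if usable and x.size < 4 * fs / min(usable):
        raise ValueError(
            f"signal too short: need at least {4 * fs / min(usable):.0f} samples "
            f"for the slowest mask ({min(usable)} Hz)"
        )
    if np.ptp(x) == 0:
        return IMFSet(modes=np.empty((0, x.size)), residual=x.copy(), mask_freqs=[])

    t = np.arange(x.size) / fs
    residual = x.copy()
    modes: list[np.ndarray] = []
    for f_mask in usable[:max_imfs]:
        amp = mask_amp * np.std(residual)
        if amp == 0:
            break
        acc = np.zeros_like(residual)
        for p in range(n_phases):
            mask = amp * np.cos(2 * np.pi * f_mask * t + 2 * np.pi * p / n_phases)
            acc += _sift_next_imf(residual + mask) - mask
        imf = acc / n_phases
        modes.append(imf)
        residual = residual - imf
    return IMFSet(
        modes=np.array(modes) if modes else np.empty((0, x.size)),
        residual=residual,
        mask_freqs=list(usable[: len(modes)]),
    )


def alpha_imf_index(imfset: IMFSet, target: float = 11.0) -> int:
    """Index of the mode whose mask frequency is closest to the alpha mask."""
    if not imfset.mask_freqs:
        raise ValueError("no modes in IMF set")
    return int(np.argmin(np.abs(np.array(imfset.mask_freqs) - target)))


def instantaneous_attributes(
    imf: np.ndarray,
    fs: float,
    max_norm_iters: int = 3,
    smooth_window: int = 5,
) -> InstAttributes:
    """Normalized-Hilbert instantaneous phase, amplitude, and frequency.

    The amplitude envelope is a cubic spline through the maxima of |imf|;
    dividing by it (up to ``max_norm_iters`` times, until the normalized
    signal stays within 1 + 1e-3) leaves a unit-amplitude carrier whose
    analytic-signal angle is the instantaneous phase. IF is the phase
    derivative in Hz, smoothed with a short Savitzky-Golay window to suppress
    point spikes without distorting within-cycle structure.
    """
    x = np.asarray(imf, dtype=float).ravel()
    peaks = _local_maxima(np.abs(x))
    env = _spline_envelope(np.abs(x), peaks)
    if env is None or np.all(env <= 0):
        raise ValueError("degenerate envelope: signal has no usable extrema")
    env = np.maximum(env, 1e-12 * np.max(env))
    carrier = x / env
    for _ in range(max_norm_iters):
        if np.max(np.abs(carrier)) <= 1 + 1e-3:
            break
        pk2 = _local_maxima(np.abs(carrier))
        env2 = _spline_envelope(np.abs(carrier), pk2)
        if env2 is None:
            break
        env2 = np.maximum(env2, 1e-12)
        carrier = carrier / env2
    carrier = np.clip(carrier, -1.0, 1.0)

    analytic = scipy.signal.hilbert(carrier)
    phase = np.unwrap(np.angle(analytic))
    if_raw = np.gradient(phase) * fs / (2 * np.pi)
    window = max(smooth_window, 3)
    if window % 2 == 0:
        window += 1
    if_hz = scipy.signal.savgol_filter(if_raw, window, polyorder=2)
    n_edge = max(window, int(round(0.1 * fs)))
    return InstAttributes(
        phase_unwrapped=phase, amplitude=env, if_hz=if_hz, fs=fs, n_edge=n_edge
    )


def _crossings(phi: np.ndarray, target: float) -> int:
    """Number of times phi crosses the target level (either direction)."""
    s = np.sign(phi - target)
    s[s == 0] = 1
    return int(np.sum(s[1:] != s[:-1]))


def detect_cycles(
    attr: InstAttributes, amplitude_percentile: float = 75.0
) -> pd.DataFrame:
    """Delimit cycles at ascending zero crossings of phase and QC them.

    Returns one row per complete interior cycle with sample span, control
    point indices, mean amplitude, the three QC flags, and ``accepted``
    (their conjunction). Cycles touching the segment's Hilbert edge region
    are discarded outright. No complete cycle gives an empty table.
    """
    phi = attr.phase_unwrapped
    n = phi.size
    # boundary k: phase passing CYCLE_START_PHASE + 2πk (ascending)
    count = np.floor((phi - CYCLE_START_PHASE) / (2 * np.pi))
    bumps = np.nonzero(np.diff(count) > 0)[0] + 1  # first sample of each new cycle
    cols = [
        "start", "end", "peak", "desc_zero", "trough", "mean_amplitude",
        "amplitude_ok", "controls_ok", "no_phase_reversal", "accepted",
    ]
    if bumps.size < 2:
        return pd.DataFrame(columns=cols)

    rows = []
    for s, e in zip(bumps[:-1], bumps[1:]):
        if s < attr.n_edge or e > n - attr.n_edge:
            continue
        k = count[s]
        base = CYCLE_START_PHASE + 2 * np.pi * k
        seg = phi[s : e + 1]
        targets = {
            "peak": base + np.pi / 2,  # phase 0 of cos
            "desc_zero": base + np.pi,
            "trough": base + 3 * np.pi / 2,
        }
        points = {}
        unique = True
        for name, tgt in targets.items():
            nc = _crossings(seg, tgt)
            unique &= nc == 1
            points[name] = s + int(np.argmin(np.abs(seg - tgt)))
        monotone = bool(np.all(np.diff(seg) > 0))
        ordered = s <= points["peak"] <= points["desc_zero"] <= points["trough"] <= e
        rows.append(
            {
                "start": int(s),
                "end": int(e),
                "peak": points["peak"],
                "desc_zero": points["desc_zero"],
                "trough": points["trough"],
                "mean_amplitude": float(np.mean(attr.amplitude[s:e])),
                "controls_ok": bool(unique and ordered),
                "no_phase_reversal": monotone,
            }
        )
    if not rows:
        return pd.DataFrame(columns=cols)
    table = pd.DataFrame(rows)
    thresh = np.percentile(table["mean_amplitude"], amplitude_percentile)
    table["amplitude_ok"] = table["mean_amplitude"] >= thresh
    table["accepted"] = (
        table["amplitude_ok"] & table["controls_ok"] & table["no_phase_reversal"]
    )
    return table[cols]
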