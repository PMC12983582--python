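"""Spatio-spectral decomposition (SSD).

SSD finds spatial filters ``w`` maximizing narrowband alpha power against the
power in flanking bands by solving the generalized eigenproblem

    C_s w = λ C_n w

where ``C_s`` is the covariance of the signal-band-filtered data and ``C_n``
the covariance of flanking-band ("noise") data. Eigenvalues λ order the
components by band-power ratio. Forward-model spatial patterns are obtained
with the Haufe transform ``A = C_s W (Wᵀ C_s W)⁻¹``; patterns — not filters —
are comparable to leadfield topographies and feed the template-matching
stage. Filters are applied to the *broadband* data so the component time
series keep their non-sinusoidal waveform content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.signal

from wavemotif.recording import RawRecording
from wavemotif.spectral import (
    ALPHA_BAND,
    FitSettings,
    SpectrumModel,
    alpha_snr,
    fit_spectral_model,
    multitaper_psd,
)

__all__ = [
    "BandDefinition",
    "SSDResult",
    "ComponentSeries",
    "define_bands",
    "fit_ssd",
    "apply_filters",
    "select_components",
]


@dataclass(frozen=True)
class BandDefinition:
    """Signal band of interest and its two flanking bands (Hz)."""

    center: float
    signal: tuple[float, float]
    flank_lo: tuple[float, float]
    flank_hi: tuple[float, float]


@dataclass
class SSDResult:
    """Spatial filters W, Haufe patterns A (both channels x components),
    generalized eigenvalues (descending), and the band that produced them."""

    filters: np.ndarray
    patterns: np.ndarray
    eigenvalues: np.ndarray
    band: BandDefinition
    labels: list[str] = field(default_factory=list)


@dataclass
class ComponentSeries:
    """Broadband component time series (components x samples) with provenance."""

    data: np.ndarray
    fs: float
    ssd: SSDResult
    indices: list[int]
    spectrum_models: list[SpectrumModel] | None = None


def define_bands(
    iaf: float, half_width: float = 2.0, flank_width: float = 2.0
) -> BandDefinition:
    """Band of interest iaf ± half_width with abutting flanks of flank_width Hz.

    An IAF of 10 Hz yields the 8-12 Hz signal band with 6-8 and 12-14 Hz
    flanks.
    """
    lo = iaf - half_width - flank_width
    if lo <= 0:
        raise ValueError(
            f"lower flank bound must be positive; iaf={iaf} gives {lo:.2f} Hz"
        )
    return BandDefinition(
        center=iaf,
        signal=(iaf - half_width, iaf + half_width),
        flank_lo=(lo, iaf - half_width),
        flank_hi=(iaf + half_width, iaf + half_width + flank_width),
    )


def _bandpass(data: np.ndarray, fs: float, lo: float, hi: float, order: int = 2):
    sos = scipy.signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return scipy.signal.sosfiltfilt(sos, data, axis=-1)


def _bandstop(data: np.ndarray, fs: float, lo: float, hi: float, order: int = 2):
    sos = scipy.signal.butter(order, [lo, hi], btype="bandstop", fs=fs, output="sos")
    return scipy.signal.sosfiltfilt(sos, data, axis=-1)


def _covariance(data: np.ndarray, shrinkage: float) -> np.ndarray:
    data = data - data.mean(axis=1, keepdims=True)
    cov = data @ data.T / data.shape[1]
    n = cov.shape[0]
    return (1 - shrinkage) * cov + shrinkage * np.trace(cov) / n * np.eye(n)


def fit_ssd(
    rec: RawRecording,
    band: BandDefinition,
    shrinkage: float = 1e-6,
) -> SSDResult:
    """Fit SSD filters and Haufe patterns for a band definition.

    The signal covariance comes from signal-band-filtered data (zero-phase
    Butterworth order 2). The noise covariance comes from data band-passed
    over the full flank span and then band-stopped over the signal band
    widened by 1 Hz on each side. Both covariances receive light shrinkage
    regularization before the generalized eigendecomposition.
    """
    if rec.duration < 10.0:
        raise ValueError("SSD requires at least 10 s of data")
    nyq = rec.fs / 2
    if band.flank_hi[1] >= nyq:
        raise ValueError(f"band extends to {band.flank_hi[1]} Hz, >= Nyquist {nyq} Hz")

    sig = _bandpass(rec.data, rec.fs, *band.signal)
    noise = _bandpass(rec.data, rec.fs, band.flank_lo[0], band.flank_hi[1])
    noise = _bandstop(noise, rec.fs, band.signal[0] - 1.0, band.signal[1] + 1.0)

    c_s = _covariance(sig, shrinkage)
    c_n = _covariance(noise, shrinkage)
    try:
        eigvals, eigvecs = scipy.linalg.eigh(c_s, c_n)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise np.linalg.LinAlgError(
            "noise covariance is rank deficient beyond regularization; "
            "increase shrinkage or drop duplicate channels"
        ) from exc
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    filters = eigvecs[:, order]

    wtcw = filters.T @ c_s @ filters
    patterns = c_s @ filters @ np.linalg.inv(wtcw)
    return SSDResult(
        filters=filters,
        patterns=patterns,
        eigenvalues=eigvals,
        band=band,
        labels=list(rec.labels),
    )


def apply_filters(
    rec_broadband: RawRecording, ssd: SSDResult, k: int | None = None
) -> ComponentSeries:
    """Project broadband data through the first ``k`` SSD filters.

    Component i is ``W[:, i]ᵀ x(t)``; broadband content is preserved so the
    downstream cycle analysis sees the full waveform, not its narrowband
    caricature. ``k=0`` returns an empty set.
    """
    if ssd.labels and list(rec_broadband.labels) != list(ssd.labels):
        raise ValueError("channel labels/order differ from those used to fit SSD")
    n_comp = ssd.filters.shape[1]
    k = n_comp if k is None else k
    if k > n_comp:
        raise ValueError(f"requested {k} components, only {n_comp} available")
    series = ssd.filters[:, :k].T @ rec_broadband.data
    return ComponentSeries(
        data=series, fs=rec_broadband.fs, ssd=ssd, indices=list(range(k))
    )


def select_components(
    comps: ComponentSeries,
    snr_threshold: float = 3.87,
    band: tuple[float, float] = ALPHA_BAND,
    epoch_len: float = 10.0,
    fit_settings: FitSettings | None = None,
) -> tuple[ComponentSeries, list[dict]]:
    """Keep components with an in-band alpha peak and SNR strictly above threshold.

    Each component time series gets a multitaper spectrum and a spectral
    parameterization; components without an alpha-band peak are dropped with
    reason ``"no-peak"``, those whose peak SNR does not exceed the threshold
    (dB) with reason ``"low-snr"``. Returns the retained subset and a report
    of one dict per input component.
    """
    report: list[dict] = []
    keep: list[int] = []
    models: list[SpectrumModel] = []
    for row, idx in enumerate(comps.indices):
        rec = RawRecording(comps.data[row : row + 1], comps.fs, [f"comp{idx}"])
        spectrum = multitaper_psd(rec, epoch_len=epoch_len)
        model = fit_spectral_model(spectrum, settings=fit_settings)
        snr = alpha_snr(model, band)
        if np.isnan(snr):
            report.append({"component": idx, "kept": False, "reason": "no-peak",
                           "snr_db": None})
            continue
        if snr > snr_threshold:
            report.append({"component": idx, "kept": True, "reason": None,
                           "snr_db": snr})
            keep.append(row)
            models.append(model)
        else:
            report.append({"component": idx, "kept": False, "reason": "low-snr",
                           "snr_db": snr})
    retained = ComponentSeries(
        data=comps.data[keep],
        fs=comps.fs,
        ssd=comps.ssd,
        indices=[comps.indices[i] for i in keep],
        spectrum_models=models,
    )
    return retained, report
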