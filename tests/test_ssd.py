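"""SSD: band arithmetic, generalized-eigen oracle, pattern recovery, selection."""

import numpy as np
import pytest

from wavemotif.matching import cosine_distance
from wavemotif.recording import RawRecording
from wavemotif.ssd import (
    SSDResult,
    _bandpass,
    _bandstop,
    _covariance,
    apply_filters,
    define_bands,
    fit_ssd,
    select_components,
)
from wavemotif.synthetic import ShapeParams, SimulationSpec, SourceSpec, make_recording


class TestBands:
    def test_worked_example_iaf_10(self):
        band = define_bands(10.0)
        assert band.signal == (8.0, 12.0)
        assert band.flank_lo == (6.0, 8.0)
        assert band.flank_hi == (12.0, 14.0)

    def test_low_iaf_arithmetic(self):
        band = define_bands(7.0)
        assert band.signal == (5.0, 9.0)
        assert band.flank_lo == (3.0, 5.0)
        assert band.flank_hi == (9.0, 11.0)

    def test_nonpositive_lower_bound_rejected(self):
        with pytest.raises(ValueError):
            define_bands(2.0)


def _covariances(rec, band):
    sig = _bandpass(rec.data, rec.fs, *band.signal)
    noise = _bandpass(rec.data, rec.fs, band.flank_lo[0], band.flank_hi[1])
    noise = _bandstop(noise, rec.fs, band.signal[0] - 1.0, band.signal[1] + 1.0)
    return _covariance(sig, 1e-6), _covariance(noise, 1e-6)


class TestFit:
    def test_eigen_oracle_on_small_instance(self):
        """SSD must agree with a brute-force eig of inv(C_n) C_s on <=6 channels."""
        spec = SimulationSpec(
            sources=(SourceSpec(shape=ShapeParams(f0=10.0), amplitude=3.0),),
            n_channels=6, duration=30.0, fs=250.0, noise_amp=1.0,
        )
        rec, _ = make_recording(spec, seed=3)
        band = define_bands(10.0)
        res = fit_ssd(rec, band)
        c_s, c_n = _covariances(rec, band)
        vals, vecs = np.linalg.eig(np.linalg.inv(c_n) @ c_s)
        order = np.argsort(vals.real)[::-1]
        vals, vecs = vals.real[order], vecs.real[:, order]
        assert np.allclose(vals, res.eigenvalues, rtol=1e-8)
        for j in range(6):
            cos = abs(res.filters[:, j] @ vecs[:, j]) / (
                np.linalg.norm(res.filters[:, j]) * np.linalg.norm(vecs[:, j])
            )
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_single_source_pattern_recovery(self, single_source_recording):
        rec, truth = single_source_recording
        res = fit_ssd(rec, define_bands(10.0))
        assert 1 - cosine_distance(res.patterns[:, 0], truth.mixing[0]) > 0.95
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_two_source_recovery_with_orthogonal_mixing(self):
        p1 = np.array([1.0, 1.0, 1.0, 1.0, 0, 0, 0, 0])
        p2 = np.array([1.0, -1.0, 1.0, -1.0, 0, 0, 0, 0])
        spec = SimulationSpec(
            sources=(
                SourceSpec(shape=ShapeParams(f0=9.0), amplitude=3.0, pattern=p1),
                SourceSpec(shape=ShapeParams(f0=11.0), amplitude=3.0, pattern=p2),
            ),
            n_channels=8, duration=60.0, fs=250.0, noise_amp=0.5,
        )
        rec, truth = make_recording(spec, seed=4)
        res = fit_ssd(rec, define_bands(10.0))
        for mix_col in truth.mixing:
            best = min(
                cosine_distance(res.patterns[:, j], mix_col) for j in range(2)
            )
            assert 1 - best > 0.9

    def test_haufe_identity_holds(self, single_source_recording):
        rec, _ = single_source_recording
        band = define_bands(10.0)
        res = fit_ssd(rec, band)
        c_s, _ = _covariances(rec, band)
        expected = c_s @ res.filters @ np.linalg.inv(res.filters.T @ c_s @ res.filters)
        assert np.allclose(res.patterns, expected, atol=1e-10)

    def test_top_eigenvalue_is_max_power_ratio_over_random_probes(self):
        spec = SimulationSpec(
            sources=(SourceSpec(shape=ShapeParams(f0=10.0), amplitude=2.0),),
            n_channels=4, duration=30.0, fs=250.0, noise_amp=1.0,
        )
        rec, _ = make_recording(spec, seed=5)
        band = define_bands(10.0)
        res = fit_ssd(rec, band)
        c_s, c_n = _covariances(rec, band)
        rng = np.random.default_rng(0)
        for _ in range(1000):
            w = rng.standard_normal(4)
            ratio = (w @ c_s @ w) / (w @ c_n @ w)
            assert ratio <= res.eigenvalues[0] * (1 + 1e-9)


class TestApplyAndSelect:
    def test_identity_filter_selects_channel(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((3, 1000))
        rec = RawRecording(data, 250.0, ["a", "b", "c"])
        w = np.zeros((3, 1))
        w[1, 0] = 1.0
        ssd = SSDResult(filters=w, patterns=w, eigenvalues=np.array([1.0]),
                        band=define_bands(10.0), labels=["a", "b", "c"])
        comps = apply_filters(rec, ssd)
        assert np.allclose(comps.data[0], data[1])

    def test_k_zero_is_empty_not_error(self, single_source_recording):
        rec, _ = single_source_recording
        res = fit_ssd(rec, define_bands(10.0))
        comps = apply_filters(rec, res, k=0)
        assert comps.data.shape[0] == 0

    def test_channel_mismatch_raises(self, single_source_recording):
        rec, _ = single_source_recording
        res = fit_ssd(rec, define_bands(10.0))
        other = RawRecording(rec.data, rec.fs, [f"x{i}" for i in range(8)])
        with pytest.raises(ValueError, match="labels"):
            apply_filters(other, res)

    def test_noise_free_component_recovers_source(self):
        spec = SimulationSpec(
            sources=(SourceSpec(shape=ShapeParams(f0=10.0), amplitude=2.0),),
            n_channels=4, duration=30.0, fs=250.0, noise_amp=0.0,
        )
        rec, truth = make_recording(spec, seed=6)
        res = fit_ssd(rec, define_bands(10.0))
        comps = apply_filters(rec, res, k=1)
        corr = np.corrcoef(comps.data[0], truth.source_signals[0])[0, 1]
        assert abs(corr) > 0.99

    def test_selection_drops_no_peak_and_respects_strict_threshold(
        self, single_source_recording
    ):
        rec, _ = single_source_recording
        res = fit_ssd(rec, define_bands(10.0))
        comps = apply_filters(rec, res, k=4)
        retained, report = select_components(comps, snr_threshold=3.87)
        by_comp = {r["component"]: r for r in report}
        assert by_comp[0]["kept"] and by_comp[0]["snr_db"] > 3.87
        assert any(r["reason"] == "no-peak" for r in report if not r["kept"])
        # "exceeding" is strict: a threshold equal to the measured SNR drops it
        snr0 = by_comp[0]["snr_db"]
        _, report_eq = select_components(comps, snr_threshold=snr0)
        assert not [r for r in report_eq if r["component"] == 0][0]["kept"]
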