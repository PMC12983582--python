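"""Generator ground truth: exact sinusoid limit, asymmetry semantics, noise slope."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.signal import welch
from scipy.stats import kurtosis

from wavemotif.synthetic import (
    InterventionEffect,
    ShapeParams,
    SimulationSpec,
    SourceSpec,
    apply_intervention,
    make_cycle_train,
    make_recording,
)

FS = 250.0


class TestCycleTrain:
    def test_zero_asymmetry_is_exact_sinusoid(self):
        sig, table = make_cycle_train(ShapeParams(f0=10.0), 10, FS, seed=0)
        t = np.arange(sig.size) / FS
        # phase starts at the ascending zero crossing: cos(2π f t - π/2) = sin
        assert np.allclose(sig, np.sin(2 * np.pi * 10 * t), atol=1e-10)
        assert np.all((table["end"] - table["start"]) == 25)

    def test_peak_trough_half_durations_match_quadrature(self):
        """a_pt speeds the peak half relative to the trough half by the
        injected velocity profile; compare sample counts with the quadrature
        oracle for dt = dφ / (2π f0 (1 + a cos φ))."""
        a = 0.3
        fs = 2000.0
        sig, table = make_cycle_train(ShapeParams(f0=10.0, a_pt=a), 50, fs, seed=1)
        t_peak = quad(lambda p: 1 / (2 * np.pi * 10 * (1 + a * np.cos(p))),
                      -np.pi / 2, np.pi / 2)[0]
        t_trough = quad(lambda p: 1 / (2 * np.pi * 10 * (1 + a * np.cos(p))),
                        np.pi / 2, 3 * np.pi / 2)[0]
        # measured: within each cycle the signal is positive on the peak half
        fracs = [
            np.mean(sig[s:e] > 0) for s, e in zip(table["start"], table["end"])
        ]
        expected = t_peak / (t_peak + t_trough)
        assert np.mean(fracs) == pytest.approx(expected, abs=0.01)

    def test_rise_decay_ratio_matches_quadrature(self):
        """a_rd shortens the rising edge; the rise/fall duration ratio equals
        the quadrature of dt = dφ / (2π f0 (1 + b sin φ)) over the two edges."""
        b = 0.2
        fs = 2000.0
        sig, table = make_cycle_train(ShapeParams(f0=10.0, a_rd=b), 50, fs, seed=1)
        rise_oracle = quad(lambda p: 1 / (1 + b * np.sin(p)), -np.pi, 0)[0]
        fall_oracle = quad(lambda p: 1 / (1 + b * np.sin(p)), 0, np.pi)[0]
        ratios = []
        for s, e in zip(table["start"], table["end"]):
            seg = sig[s:e]
            peak = int(np.argmax(seg))
            trough = int(np.argmin(seg))
            fall = trough - peak  # peak precedes trough within a cycle
            rise = seg.size - fall
            ratios.append(rise / fall)
        assert np.mean(ratios) == pytest.approx(rise_oracle / fall_oracle, rel=0.02)
        # positive a_rd slows the rising half (sin φ < 0 there), so rise > fall
        assert rise_oracle > fall_oracle

    def test_realized_coefficients_recorded_and_bounded(self):
        _, table = make_cycle_train(
            ShapeParams(f0=10.0, a_pt=0.2, jitter_sd=0.1), 200, FS, seed=2
        )
        assert np.all(np.abs(table["a_pt"]) + np.abs(table["a_rd"]) < 1)
        assert table["a_pt"].std() > 0

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            ShapeParams(f0=10.0, a_pt=0.7, a_rd=0.4)
        with pytest.raises(ValueError):
            ShapeParams(f0=-1.0)
        with pytest.raises(ValueError):
            make_cycle_train(ShapeParams(f0=10.0), 5, fs=30.0)  # fs <= 4 f0


class TestRecording:
    def test_noise_free_peak_at_source_frequency(self):
        pattern = np.array([0.1, 0.2, 3.0, 0.5, 0.1, 0.0, 0.0, 0.1])
        spec = SimulationSpec(
            sources=(SourceSpec(shape=ShapeParams(f0=10.0), pattern=pattern),),
            n_channels=8, duration=20.0, fs=FS, noise_amp=0.0,
        )
        rec, truth = make_recording(spec, seed=0)
        ch = int(np.argmax(np.abs(truth.mixing[0])))
        freqs, pxx = welch(rec.data[ch], fs=FS, nperseg=2048)
        assert freqs[np.argmax(pxx)] == pytest.approx(10.0, abs=freqs[1] - freqs[0])

    def test_background_noise_slope_matches_chi(self):
        """Mean periodogram of 50 pure-noise realizations has log-log slope -χ."""
        chi = 1.5
        spec = SimulationSpec(sources=(), n_channels=1, duration=20.0, fs=FS,
                              chi=chi, noise_amp=1.0)
        pxx_sum = None
        for seed in range(50):
            rec, _ = make_recording(spec, seed=seed)
            freqs, pxx = welch(rec.data[0], fs=FS, nperseg=1024)
            pxx_sum = pxx if pxx_sum is None else pxx_sum + pxx
        sel = (freqs >= 2) & (freqs <= 40)
        slope = np.polyfit(np.log10(freqs[sel]), np.log10(pxx_sum[sel] / 50), 1)[0]
        assert slope == pytest.approx(-chi, abs=0.15)

    def test_seeded_reproducibility(self):
        spec = SimulationSpec(
            sources=(SourceSpec(shape=ShapeParams(f0=10.0, jitter_sd=0.05)),),
            n_channels=4, duration=12.0, fs=FS,
        )
        rec1, truth1 = make_recording(spec, seed=5)
        rec2, truth2 = make_recording(spec, seed=5)
        rec3, _ = make_recording(spec, seed=6)
        assert np.array_equal(rec1.data, rec2.data)
        assert truth1.cycles.equals(truth2.cycles)
        assert not np.array_equal(rec1.data, rec3.data)

    def test_nyquist_violation_raises(self):
        spec = SimulationSpec(
            sources=(SourceSpec(shape=ShapeParams(f0=130.0)),),
            n_channels=2, duration=12.0, fs=FS,
        )
        with pytest.raises(ValueError, match="Nyquist"):
            make_recording(spec, seed=0)

    def test_ground_truth_spans_disjoint(self, single_source_recording):
        _, truth = single_source_recording
        cyc = truth.cycles.sort_values("start")
        assert np.all(cyc["end"].values[:-1] <= cyc["start"].values[1:])


class TestIntervention:
    BASE = SimulationSpec(
        sources=(SourceSpec(shape=ShapeParams(f0=10.0, a_pt=0.1, jitter_sd=0.05),
                            amplitude=2.0),),
        n_channels=2, duration=12.0, fs=FS, noise_amp=0.0,
    )

    def test_identity_effect_is_noop(self):
        post = apply_intervention(self.BASE, InterventionEffect())
        assert post == self.BASE

    def test_power_scale_halves_alpha_band_power(self):
        post = apply_intervention(self.BASE, InterventionEffect(power_scale=0.5))
        ratios = []
        for seed in range(20):
            rec_pre, _ = make_recording(self.BASE, seed=seed)
            rec_post, _ = make_recording(post, seed=seed)

            def band_power(rec):
                freqs, pxx = welch(rec.data[0], fs=FS, nperseg=1024)
                sel = (freqs >= 8) & (freqs <= 12)
                return np.trapezoid(pxx[sel], freqs[sel])
            ratios.append(band_power(rec_post) / band_power(rec_pre))
        assert np.mean(ratios) == pytest.approx(0.5, abs=0.05)

    def test_tail_inflation_raises_spread_and_kurtosis(self):
        shape = ShapeParams(f0=10.0, a_pt=0.1, jitter_sd=0.05)
        inflated = ShapeParams(f0=10.0, a_pt=0.1, jitter_sd=0.05,
                               tail_fraction=0.2, tail_k=3.0)
        base_vals, tail_vals = [], []
        for seed in range(20):
            _, t1 = make_cycle_train(shape, 200, FS, seed=seed)
            _, t2 = make_cycle_train(inflated, 200, FS, seed=seed)
            base_vals.append(t1["a_pt"].to_numpy())
            tail_vals.append(t2["a_pt"].to_numpy())
        base_vals = np.concatenate(base_vals)
        tail_vals = np.concatenate(tail_vals)
        assert tail_vals.std() > base_vals.std()
        assert kurtosis(tail_vals) > 0

    def test_shape_shift_applied_and_validated(self):
        post = apply_intervention(self.BASE, InterventionEffect(a_pt_shift=0.2))
        assert post.sources[0].shape.a_pt == pytest.approx(0.3)
        with pytest.raises(ValueError):
            apply_intervention(self.BASE, InterventionEffect(a_pt_shift=0.95))
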