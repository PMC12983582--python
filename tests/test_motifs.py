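"""IF_PA projection, PCA motifs, reliability, waveform reconstruction."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from wavemotif.emdcycles import detect_cycles, instantaneous_attributes
from wavemotif.motifs import (
    IFPAMatrix,
    fit_motifs,
    normalize_ifpa,
    phase_align_if,
    phase_grid,
    reconstruct_waveform,
    split_half_reliability,
)
from wavemotif.synthetic import ShapeParams, make_cycle_train

FS = 250.0


def _ifpa_from_shape(shape: ShapeParams, n_cycles=200, seed=0, n_bins=48):
    sig, _ = make_cycle_train(shape, n_cycles, FS, seed=seed)
    attr = instantaneous_attributes(sig, FS)
    cycles = detect_cycles(attr, amplitude_percentile=0)
    return phase_align_if(cycles, attr, n_bins=n_bins)


class TestPhaseAlign:
    def test_pure_sinusoid_rows_are_flat(self):
        mat = _ifpa_from_shape(ShapeParams(f0=10.0))
        assert mat.values.shape[1] == 48
        assert np.all(mat.values.std(axis=1) < 0.01 * 10.0)
        assert np.abs(mat.values.mean() - 10.0) < 0.1

    def test_mean_row_tracks_injected_profile(self):
        mat = _ifpa_from_shape(ShapeParams(f0=10.0, a_pt=0.2))
        mean_row = mat.values.mean(axis=0)
        assert np.corrcoef(mean_row, np.cos(mat.phase))[0, 1] > 0.95

    def test_bin_count_contract(self):
        mat = _ifpa_from_shape(ShapeParams(f0=10.0), n_bins=32)
        assert mat.values.shape[1] == 32


class TestNormalize:
    def test_constant_matrix_becomes_ones(self):
        mat = IFPAMatrix(np.full((5, 48), 10.0), phase_grid())
        out = normalize_ifpa(mat)
        assert np.allclose(out.values, 1.0)
        assert out.relative

    def test_group_means_are_one(self):
        rng = np.random.default_rng(0)
        values = np.vstack([10 + rng.random((20, 48)), 12 + rng.random((20, 48))])
        meta = pd.DataFrame({"grp": ["a"] * 20 + ["b"] * 20})
        out = normalize_ifpa(IFPAMatrix(values, phase_grid(), meta), group_cols=["grp"])
        assert out.values[:20].mean() == pytest.approx(1.0, abs=1e-12)
        assert out.values[20:].mean() == pytest.approx(1.0, abs=1e-12)

    def test_within_group_shape_variance_ratio_preserved(self):
        """Groups at 10 and 12 Hz overlap after normalization but keep their
        relative within-group variance along the shape direction."""
        rng = np.random.default_rng(1)
        grid = phase_grid()
        s_a = 0.05 * rng.standard_normal(200)
        s_b = 0.10 * rng.standard_normal(200)
        rows_a = 10.0 * (1.0 + np.outer(s_a, np.cos(grid)))
        rows_b = 12.0 * (1.0 + np.outer(s_b, np.cos(grid)))
        meta = pd.DataFrame({"grp": ["a"] * 200 + ["b"] * 200})
        out = normalize_ifpa(
            IFPAMatrix(np.vstack([rows_a, rows_b]), grid, meta), group_cols=["grp"]
        )
        proj = out.values @ np.cos(grid)
        ratio = np.var(proj[:200]) / np.var(proj[200:])
        assert ratio == pytest.approx(np.var(s_a) / np.var(s_b), rel=0.05)

    def test_nonpositive_entries_rejected(self):
        with pytest.raises(ValueError):
            normalize_ifpa(IFPAMatrix(np.zeros((3, 48)), phase_grid()))


class TestMotifs:
    def test_rank_one_matrix_dominated_by_first_component(self):
        rng = np.random.default_rng(0)
        grid = phase_grid()
        values = 1 + np.outer(rng.standard_normal(100), np.cos(grid))
        values += 1e-6 * rng.standard_normal(values.shape)
        model = fit_motifs(IFPAMatrix(values, grid))
        assert model.explained_variance_ratio[0] > 0.99

    def test_planted_orthogonal_motifs_recovered(self):
        from wavemotif.experiments import planted_motif_recovery

        res = planted_motif_recovery(seed=0, n_rows=400, n_splits=50)
        assert res["loading_corr_pc1"] > 0.9
        assert res["loading_corr_pc2"] > 0.9

    def test_pca_contract_and_full_reconstruction(self):
        rng = np.random.default_rng(2)
        values = 1 + 0.1 * rng.standard_normal((60, 48))
        mat = IFPAMatrix(values, phase_grid())
        model = fit_motifs(mat, n_keep=48)
        evr = model.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1 + 1e-9
        score_sd = model.scores.std(axis=0)
        assert np.all(np.abs(model.scores.mean(axis=0)) < 1e-8 * np.maximum(score_sd, 1e-12))
        recon = model.mean + model.scores @ model.components
        assert np.allclose(recon, values, atol=1e-10)

    def test_sign_convention_fixed(self):
        rng = np.random.default_rng(3)
        values = 1 + 0.1 * rng.standard_normal((60, 48))
        model = fit_motifs(IFPAMatrix(values, phase_grid()), n_keep=3)
        for comp in model.components:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_too_few_rows_raise(self):
        with pytest.raises(ValueError):
            fit_motifs(IFPAMatrix(np.ones((1, 48)), phase_grid()))


class TestReliability:
    def test_planted_signal_reliable_noise_not(self):
        rng = np.random.default_rng(0)
        grid = phase_grid()
        s = 0.1 * rng.standard_normal(300)
        planted = 1 + np.outer(s, np.cos(grid)) + 0.01 * rng.standard_normal((300, 48))
        noise = 1 + 0.05 * rng.standard_normal((300, 48))
        rel_sig = split_half_reliability(IFPAMatrix(planted, grid),
                                         n_splits=100, n_components=1, seed=1)
        rel_noise = split_half_reliability(IFPAMatrix(noise, grid),
                                           n_splits=100, n_components=1, seed=1)
        assert rel_sig.median[0] > 0.95
        assert rel_noise.median[0] < 0.7

    def test_seeded_determinism(self):
        rng = np.random.default_rng(4)
        values = 1 + 0.1 * rng.standard_normal((50, 48))
        mat = IFPAMatrix(values, phase_grid())
        r1 = split_half_reliability(mat, n_splits=20, n_components=2, seed=9)
        r2 = split_half_reliability(mat, n_splits=20, n_components=2, seed=9)
        assert np.array_equal(r1.correlations, r2.correlations)


class TestReconstruct:
    def test_flat_profile_is_cosine(self):
        wave = reconstruct_waveform(np.ones(48), n_samples=480)
        t = np.arange(480) / 480
        assert np.max(np.abs(wave - np.cos(-np.pi / 2 + 2 * np.pi * t))) < 1e-6

    def test_elevated_peak_if_narrows_peak(self):
        """Fraction of the cycle spent in the positive half matches the
        quadrature of dt = dφ / profile(φ) and is below the sinusoid's 1/2."""
        grid = phase_grid()
        profile = 1 + 0.3 * np.cos(grid)
        wave = reconstruct_waveform(profile, n_samples=4800)
        total = quad(lambda p: 1 / (1 + 0.3 * np.cos(p)), -np.pi, np.pi)[0]
        peak_half = quad(lambda p: 1 / (1 + 0.3 * np.cos(p)), -np.pi / 2, np.pi / 2)[0]
        assert np.mean(wave > 0) == pytest.approx(peak_half / total, abs=0.005)
        assert np.mean(wave > 0) < 0.5

    def test_roundtrip_edge_speed_asymmetry(self):
        """Generator a_rd > 0 slows the rising edge (phase velocity dips where
        sin φ < 0); the reconstructed waveform from the measured profile must
        show the same edge-duration ordering as the injected signal."""
        mat = _ifpa_from_shape(ShapeParams(f0=10.0, a_rd=0.2), n_cycles=300)
        profile = normalize_ifpa(mat).values.mean(axis=0)
        wave = reconstruct_waveform(profile, n_samples=4800)
        peak, trough = int(np.argmax(wave)), int(np.argmin(wave))
        fall = trough - peak
        rise = wave.size - fall
        assert rise > fall

    def test_nonpositive_profile_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_waveform(np.linspace(-1, 1, 48))
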