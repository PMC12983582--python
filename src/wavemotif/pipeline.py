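"""End-to-end orchestration: simulate → spectra → SSD → match → cycles → motifs → stats.

A :class:`PipelineConfig` (typically parsed from YAML) drives a full pre/post
analysis run. In simulation mode the generator produces a "pre" recording and
a "post" recording transformed by an intervention effect, plus a leadfield
built from the ground-truth mixing matrix, so the whole chain is exercised
with known answers. All stage outputs are written as delimited text/CSV/JSON
with provenance columns; identical config + seed gives identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from wavemotif import __version__
from wavemotif.emdcycles import (
    DEFAULT_MASK_FREQS,
    alpha_imf_index,
    detect_cycles,
    instantaneous_attributes,
    masked_sift,
)
from wavemotif.matching import Leadfield, match_patterns, save_matches
from wavemotif.motifs import concat_ifpa, fit_motifs, normalize_ifpa, phase_align_if
from wavemotif.recording import RawRecording, read_recording, write_recording
from wavemotif.spectral import fit_spectral_model, individual_alpha_frequency, multitaper_psd
from wavemotif.ssd import apply_filters, define_bands, fit_ssd, select_components
from wavemotif.stats import compare_groups
from wavemotif.synthetic import (
    InterventionEffect,
    ShapeParams,
    SimulationSpec,
    SourceSpec,
    apply_intervention,
    make_recording,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_config", "PipelineError"]

DEFAULT_LOBES = ("occipital", "sensorimotor", "parietal", "temporal")


class PipelineError(RuntimeError):
    """Structured stage failure: names the stage and the offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    seed: int = 0
    out: str = "wavemotif_out"
    # simulation mode (ignored when input files are given)
    simulate: dict = field(default_factory=dict)
    # file mode: {"pre": path, "post": path, "leadfield": path, "lobes": path}
    inputs: dict = field(default_factory=dict)
    spectral: dict = field(default_factory=dict)
    ssd: dict = field(default_factory=dict)
    matching: dict = field(default_factory=dict)
    cycles: dict = field(default_factory=dict)
    motifs: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)


_ALLOWED = {
    "simulate": {"n_channels", "fs", "duration", "chi", "noise_amp",
                 "noise_spatial_corr", "sources", "intervention", "lobes"},
    "inputs": {"pre", "post", "leadfield", "lobes"},
    "spectral": {"epoch_len", "fmin", "fmax", "channels"},
    "ssd": {"half_width", "flank_width", "snr_threshold", "n_components"},
    "matching": {"threshold", "exclude_frontal"},
    "cycles": {"amplitude_percentile", "mask_freqs"},
    "motifs": {"n_bins", "n_keep"},
    "stats": {"alpha", "n_boot"},
    "source": {"f0", "a_pt", "a_rd", "jitter_sd", "tail_fraction", "tail_k",
               "amplitude", "env_freq", "env_depth", "pattern"},
    "intervention": {"power_scale", "chi_delta", "a_pt_shift", "a_rd_shift",
                     "tail_fraction", "tail_k"},
}


def _check_keys(section: str, d: dict, allowed_key: str | None = None) -> None:
    allowed = _ALLOWED[allowed_key or section]
    unknown = set(d) - allowed
    if unknown:
        raise PipelineError("config", f"unknown keys in '{section}': {sorted(unknown)}")


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config; unknown keys are rejected."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError("config", f"unknown top-level keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    validate_config(cfg)
    return cfg


def validate_config(cfg: PipelineConfig) -> None:
    """Validate every section before any stage runs."""
    for section in ("simulate", "inputs", "spectral", "ssd", "matching",
                    "cycles", "motifs", "stats"):
        _check_keys(section, getattr(cfg, section))
    for i, src in enumerate(cfg.simulate.get("sources", [])):
        _check_keys(f"simulate.sources[{i}]", src, "source")
    if "intervention" in cfg.simulate:
        _check_keys("simulate.intervention", cfg.simulate["intervention"], "intervention")
    # the band must fit under Nyquist before any computation starts
    fs = float(cfg.simulate.get("fs", 250.0))
    hw = float(cfg.ssd.get("half_width", 2.0))
    fw = float(cfg.ssd.get("flank_width", 2.0))
    for src in cfg.simulate.get("sources", []):
        f0 = float(src.get("f0", 10.0))
        if f0 + hw + fw >= fs / 2:
            raise PipelineError(
                "config",
                f"signal band around {f0} Hz extends past Nyquist ({fs / 2} Hz)",
            )


@dataclass
class RunReport:
    """Per-stage counts, parameter echo, and timing for one pipeline run."""

    version: str
    seed: int
    iaf: float = float("nan")
    n_components_total: int = 0
    n_components_snr: int = 0
    n_components_matched: int = 0
    cycles_detected: dict = field(default_factory=dict)
    cycles_accepted: dict = field(default_factory=dict)
    cycles_rejected: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=float)


def _build_spec(sim: dict) -> SimulationSpec:
    sources = []
    for src in sim.get("sources", []):
        shape = ShapeParams(
            f0=float(src.get("f0", 10.0)),
            a_pt=float(src.get("a_pt", 0.0)),
            a_rd=float(src.get("a_rd", 0.0)),
            jitter_sd=float(src.get("jitter_sd", 0.0)),
            tail_fraction=float(src.get("tail_fraction", 0.0)),
            tail_k=float(src.get("tail_k", 1.0)),
        )
        pattern = np.asarray(src["pattern"], float) if "pattern" in src else None
        sources.append(
            SourceSpec(
                shape=shape,
                amplitude=float(src.get("amplitude", 2.0)),
                env_freq=float(src.get("env_freq", 0.1)),
                env_depth=float(src.get("env_depth", 0.5)),
                pattern=pattern,
            )
        )
    return SimulationSpec(
        sources=tuple(sources),
        n_channels=int(sim.get("n_channels", 8)),
        duration=float(sim.get("duration", 120.0)),
        fs=float(sim.get("fs", 250.0)),
        chi=float(sim.get("chi", 1.5)),
        noise_amp=float(sim.get("noise_amp", 1.0)),
        noise_spatial_corr=float(sim.get("noise_spatial_corr", 0.0)),
    )


def _simulate_session(cfg: PipelineConfig, out: Path):
    """Generate pre/post recordings and a leadfield from ground truth.

    Sources keep one topography across time points: patterns not given in the
    config are drawn once from the session seed and shared by pre and post.
    """
    spec_pre = _build_spec(cfg.simulate)
    rng = np.random.default_rng(cfg.seed)
    fixed = []
    for src in spec_pre.sources:
        if src.pattern is None:
            pat = rng.standard_normal(spec_pre.n_channels)
            src = dataclasses.replace(src, pattern=pat)
        fixed.append(src)
    spec_pre = dataclasses.replace(spec_pre, sources=tuple(fixed))
    effect = InterventionEffect(**cfg.simulate.get("intervention", {}))
    spec_post = apply_intervention(spec_pre, effect)
    rec_pre, truth_pre = make_recording(spec_pre, seed=cfg.seed)
    rec_post, truth_post = make_recording(spec_post, seed=cfg.seed + 1)

    lobes = list(cfg.simulate.get("lobes", []))
    if not lobes:
        lobes = [DEFAULT_LOBES[i % len(DEFAULT_LOBES)] for i in range(len(spec_pre.sources))]
    lf = Leadfield(gain=truth_pre.mixing, labels=lobes)

    write_recording(rec_pre, out / "recording_pre.tsv")
    write_recording(rec_post, out / "recording_post.tsv")
    truth_pre.cycles.to_csv(out / "ground_truth_pre.csv", index=False)
    truth_post.cycles.to_csv(out / "ground_truth_post.csv", index=False)
    (out / "ground_truth.json").write_text(
        json.dumps(
            {"chi_pre": truth_pre.chi, "chi_post": truth_post.chi,
             "seed": cfg.seed, "mixing": truth_pre.mixing.tolist()},
            indent=2,
        )
    )
    lf.save(out / "leadfield.tsv", out / "lobes.csv")
    return rec_pre, rec_post, lf


def _load_session(cfg: PipelineConfig):
    inputs = cfg.inputs
    for key in ("pre", "post", "leadfield", "lobes"):
        if key not in inputs:
            raise PipelineError("inputs", f"file mode requires '{key}' path")
    rec_pre = read_recording(inputs["pre"])
    rec_post = read_recording(inputs["post"])
    lf = Leadfield.load(inputs["leadfield"], inputs["lobes"])
    return rec_pre, rec_post, lf


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Run the full analysis and write all artifacts under ``cfg.out``.

    Stages mirror a within-session pre/post analysis: IAF from channel-
    collapsed spectra (averaged over time points), SSD on the concatenated
    time points, SNR-based component selection, leadfield matching, masked-EMD
    cycle extraction per component x time point, pooled IF_PA + PCA motifs,
    and a per-lobe x per-PC Cramér-von Mises table.
    """
    validate_config(cfg)
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, seed=cfg.seed,
                       parameters={"config": dataclasses.asdict(cfg)})
    t0 = time.perf_counter()

    stage = "input"
    try:
        if cfg.inputs:
            rec_pre, rec_post, lf = _load_session(cfg)
        else:
            rec_pre, rec_post, lf = _simulate_session(cfg, out)
        report.stage_seconds[stage] = time.perf_counter() - t0

        # --- spectra / IAF ------------------------------------------------
        stage = "spectral"
        t0 = time.perf_counter()
        sp = cfg.spectral
        iafs = []
        for name, rec in (("pre", rec_pre), ("post", rec_post)):
            spectrum = multitaper_psd(
                rec,
                channels=sp.get("channels"),
                epoch_len=float(sp.get("epoch_len", 10.0)),
                fmin=float(sp.get("fmin", 2.0)),
                fmax=float(sp.get("fmax", 40.0)),
            )
            model = fit_spectral_model(spectrum)
            summary = individual_alpha_frequency(model)
            pd.DataFrame({"freq_hz": spectrum.freqs, "power": spectrum.power}).to_csv(
                out / f"spectrum_{name}.csv", index=False
            )
            if summary.present:
                iafs.append(summary.iaf)
        if not iafs:
            raise PipelineError(stage, "no alpha peak found in either time point")
        report.iaf = float(np.mean(iafs))
        report.stage_seconds[stage] = time.perf_counter() - t0

        # --- SSD on concatenated time points -------------------------------
        stage = "ssd"
        t0 = time.perf_counter()
        band = define_bands(
            report.iaf,
            half_width=float(cfg.ssd.get("half_width", 2.0)),
            flank_width=float(cfg.ssd.get("flank_width", 2.0)),
        )
        concat = RawRecording(
            np.hstack([rec_pre.data, rec_post.data]), rec_pre.fs, rec_pre.labels
        )
        ssd_res = fit_ssd(concat, band)
        n_comp = cfg.ssd.get("n_components")
        k = int(n_comp) if n_comp else int(np.sum(
            ssd_res.eigenvalues > np.median(ssd_res.eigenvalues)))
        comps = apply_filters(concat, ssd_res, k=max(k, 1))
        report.n_components_total = comps.data.shape[0]
        retained, sel_report = select_components(
            comps, snr_threshold=float(cfg.ssd.get("snr_threshold", 3.87))
        )
        report.n_components_snr = retained.data.shape[0]
        np.savetxt(out / "ssd_filters.tsv", ssd_res.filters, delimiter="\t")
        np.savetxt(out / "ssd_patterns.tsv", ssd_res.patterns, delimiter="\t")
        np.savetxt(out / "ssd_eigenvalues.tsv", ssd_res.eigenvalues, delimiter="\t")
        (out / "ssd_band.json").write_text(json.dumps(dataclasses.asdict(band)))
        pd.DataFrame(sel_report).to_csv(out / "component_selection.csv", index=False)
        if retained.data.shape[0] == 0:
            raise PipelineError(stage, "no component passed the alpha-SNR criterion")
        report.stage_seconds[stage] = time.perf_counter() - t0

        # --- leadfield matching -------------------------------------------
        stage = "matching"
        t0 = time.perf_counter()
        patterns = ssd_res.patterns[:, retained.indices]
        matches = match_patterns(
            patterns, lf,
            threshold=float(cfg.matching.get("threshold", 0.15)),
            component_ids=retained.indices,
        )
        save_matches(matches, out / "matches.csv")
        exclude_frontal = bool(cfg.matching.get("exclude_frontal", True))
        kept = [
            m for m in matches
            if m.accepted and not (exclude_frontal and m.lobe == "frontal")
        ]
        # SSD filter sign is arbitrary, but waveform polarity is not: an
        # inverted component swaps peaks and troughs and therefore negates
        # peak-trough asymmetry. Orient each kept component so its pattern is
        # positively aligned with its matched leadfield row.
        for m in kept:
            j = retained.indices.index(m.component)
            if patterns[:, j] @ lf.gain[m.source] < 0:
                retained.data[j] = -retained.data[j]
        report.n_components_matched = len(kept)
        if not kept:
            raise PipelineError(stage, "no component matched the leadfield")
        report.stage_seconds[stage] = time.perf_counter() - t0

        # --- cycles + IF_PA per component x time point ----------------------
        stage = "cycles"
        t0 = time.perf_counter()
        n_pre = rec_pre.n_samples
        mask_freqs = tuple(cfg.cycles.get("mask_freqs", DEFAULT_MASK_FREQS))
        pct = float(cfg.cycles.get("amplitude_percentile", 75.0))
        n_bins = int(cfg.motifs.get("n_bins", 48))
        ifpas, metas, cycle_frames = [], [], []
        for m in kept:
            row = retained.indices.index(m.component)
            series = retained.data[row]
            for tp, seg in (("pre", series[:n_pre]), ("post", series[n_pre:])):
                imfset = masked_sift(seg, rec_pre.fs, mask_freqs=mask_freqs)
                alpha = imfset.modes[alpha_imf_index(imfset)]
                attr = instantaneous_attributes(alpha, rec_pre.fs)
                table = detect_cycles(attr, amplitude_percentile=pct)
                key = f"comp{m.component}_{tp}"
                report.cycles_detected[key] = int(len(table))
                report.cycles_accepted[key] = int(table["accepted"].sum()) if len(table) else 0
                report.cycles_rejected[key] = (
                    report.cycles_detected[key] - report.cycles_accepted[key]
                )
                tagged = table.copy()
                tagged.insert(0, "component", m.component)
                tagged.insert(1, "lobe", m.lobe)
                tagged.insert(2, "timepoint", tp)
                cycle_frames.append(tagged)
                if len(table) and table["accepted"].any():
                    mat = phase_align_if(table, attr, n_bins=n_bins)
                    mat = normalize_ifpa(mat)
                    ifpas.append(mat)
                    metas.append(
                        {"component": m.component, "lobe": m.lobe, "timepoint": tp}
                    )
        if cycle_frames:
            pd.concat(cycle_frames, ignore_index=True).to_csv(
                out / "cycles.csv", index=False
            )
        if not ifpas:
            raise PipelineError(stage, "no accepted cycles in any component")
        report.stage_seconds[stage] = time.perf_counter() - t0

        # --- motifs ---------------------------------------------------------
        stage = "motifs"
        t0 = time.perf_counter()
        pooled = concat_ifpa(ifpas, metas)
        model = fit_motifs(pooled, n_keep=int(cfg.motifs.get("n_keep", 4)))
        scores = pooled.meta.copy()
        for j in range(model.scores.shape[1]):
            scores[f"pc{j + 1}"] = model.scores[:, j]
        score_long = scores.melt(
            id_vars=[c for c in scores.columns if not c.startswith("pc")],
            value_vars=[c for c in scores.columns if c.startswith("pc")],
            var_name="pc",
            value_name="score",
        )
        score_long.to_csv(out / "scores.csv", index=False)
        pd.DataFrame(
            model.components.T,
            columns=[f"pc{j + 1}" for j in range(model.components.shape[0])],
        ).assign(phase=model.phase, mean_profile=model.mean).to_csv(
            out / "motifs.csv", index=False
        )
        (out / "motif_model.json").write_text(
            json.dumps(
                {
                    "explained_variance_ratio": model.explained_variance_ratio.tolist(),
                    "signs": model.signs.tolist(),
                    "n_cycles": int(pooled.n_cycles),
                },
                indent=2,
            )
        )
        report.stage_seconds[stage] = time.perf_counter() - t0

        # --- stats ----------------------------------------------------------
        stage = "stats"
        t0 = time.perf_counter()
        table = compare_groups(
            score_long,
            group_cols=["lobe", "pc"],
            alpha=float(cfg.stats.get("alpha", 0.05)),
            n_boot=int(cfg.stats.get("n_boot", 2000)),
            seed=cfg.seed,
        )
        table.to_csv(out / "stats.csv", index=False)
        report.stage_seconds[stage] = time.perf_counter() - t0
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    (out / "report.json").write_text(report.to_json())
    return report
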