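"""Phase-aligned instantaneous frequency and PCA waveform motifs.

Each accepted cycle's instantaneous frequency is resampled onto a common
phase grid (IF_PA), so peaks compare with peaks across cycles of different
duration. After normalizing by the group-mean IF (yielding dimensionless
relative IF), principal component analysis of the cycle x phase-bin matrix
produces *waveform motifs*: orthogonal axes of cycle-shape variation such as
peak-trough width asymmetry and rise-decay (edge-speed) asymmetry. Per-cycle
PC scores locate every cycle in this shape space and feed the distributional
statistics stage.

A relative-IF profile maps back to a normalized waveform: time spent per
phase bin is proportional to 1/IF, so integrating dt = dφ / IF(φ) and
resampling cos φ onto a uniform time grid reconstructs the cycle shape the
profile implies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from wavemotif.emdcycles import CYCLE_START_PHASE, InstAttributes

__all__ = [
    "IFPAMatrix",
    "MotifModel",
    "ReliabilityReport",
    "phase_align_if",
    "normalize_ifpa",
    "fit_motifs",
    "split_half_reliability",
    "reconstruct_waveform",
    "phase_grid",
]

N_BINS_DEFAULT = 48


def phase_grid(n_bins: int = N_BINS_DEFAULT) -> np.ndarray:
    """Bin-center phase grid spanning [-π, π)."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    return 0.5 * (edges[:-1] + edges[1:])


@dataclass
class IFPAMatrix:
    """Cycles x phase-bins matrix of (relative) instantaneous frequency."""

    values: np.ndarray
    phase: np.ndarray
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    relative: bool = False

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("IF_PA matrix contains non-finite entries")
        if self.values.shape[1] != self.phase.size:
            raise ValueError("column count does not match the phase grid")
        if len(self.meta) == 0:
            self.meta = pd.DataFrame(index=range(self.values.shape[0]))

    @property
    def n_cycles(self) -> int:
        return self.values.shape[0]


@dataclass
class MotifModel:
    """PCA of the IF_PA matrix: mean profile, motif loadings, scores.

    ``components`` rows are unit-norm motif vectors over phase bins,
    sign-fixed so each motif's largest-|loading| element is positive
    (``signs`` records the flips applied to the raw SVD output).
    """

    mean: np.ndarray
    components: np.ndarray  # (n_keep, n_bins)
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # (n_cycles, n_keep)
    signs: np.ndarray
    phase: np.ndarray


@dataclass
class ReliabilityReport:
    """Split-half loading correlations per component across random splits."""

    correlations: np.ndarray  # (n_splits, n_components)
    median: np.ndarray
    iqr: np.ndarray
    n_splits: int
    seed: int


def phase_align_if(
    cycles: pd.DataFrame,
    attr: InstAttributes,
    n_bins: int = N_BINS_DEFAULT,
    accepted_only: bool = True,
) -> IFPAMatrix:
    """Interpolate each cycle's IF onto the common phase grid.

    For every (accepted) cycle, IF samples are interpolated against the
    unwrapped phase, evaluated at the grid phases mapped into the cycle's own
    2π span. Cycles spanning fewer than 4 samples are skipped with a row
    dropped. Metadata rows carry the cycle's source row index and span.
    """
    grid = phase_grid(n_bins)
    sel = cycles[cycles["accepted"]] if accepted_only and "accepted" in cycles else cycles
    rows, meta = [], []
    phi = attr.phase_unwrapped
    for _, cyc in sel.iterrows():
        s, e = int(cyc["start"]), int(cyc["end"])
        if e - s < 4:
            continue
        lo, hi = max(s - 1, 0), min(e + 1, phi.size)
        seg_phi = phi[lo:hi]
        seg_if = attr.if_hz[lo:hi]
        base = seg_phi[s - lo]  # phase at cycle start, = -π/2 mod 2π
        # grid phase g (wrapped) -> cycle-relative phase offset in [0, 2π)
        rel = np.mod(grid - CYCLE_START_PHASE, 2 * np.pi)
        query = base + rel
        row = np.interp(query, seg_phi, seg_if)
        rows.append(row)
        meta.append({"start": s, "end": e,
                     "mean_amplitude": cyc.get("mean_amplitude", np.nan)})
    values = np.array(rows) if rows else np.empty((0, n_bins))
    return IFPAMatrix(values=values, phase=grid, meta=pd.DataFrame(meta))


def concat_ifpa(matrices: list[IFPAMatrix], metas: list[dict] | None = None) -> IFPAMatrix:
    """Stack IF_PA matrices row-wise, tagging each block with provenance columns."""
    if not matrices:
        raise ValueError("nothing to concatenate")
    n_bins = matrices[0].phase.size
    frames = []
    for i, m in enumerate(matrices):
        if m.phase.size != n_bins:
            raise ValueError("phase grids differ between matrices")
        meta = m.meta.copy()
        if metas is not None:
            for key, val in metas[i].items():
                meta[key] = val
        frames.append(meta)
    values = np.vstack([m.values for m in matrices])
    meta = pd.concat(frames, ignore_index=True)
    rel = all(m.relative for m in matrices)
    return IFPAMatrix(values=values, phase=matrices[0].phase, meta=meta, relative=rel)


def normalize_ifpa(
    m: IFPAMatrix, group_cols: list[str] | None = None
) -> IFPAMatrix:
    """Divide IF by the grand-mean IF_PA of its normalization group.

    With no grouping columns the whole matrix is one group; otherwise rows
    sharing values of ``group_cols`` in the metadata (e.g. component x time
    point) are normalized by their own grand mean, making each group's mean
    relative IF exactly 1 while preserving within-group shape variance
    ratios.
    """
    if np.any(m.values <= 0):
        raise ValueError("IF values must be strictly positive to normalize")
    values = m.values.copy()
    if group_cols:
        missing = [c for c in group_cols if c not in m.meta.columns]
        if missing:
            raise ValueError(f"grouping columns missing from metadata: {missing}")
        for _, idx in m.meta.groupby(group_cols, sort=False).groups.items():
            loc = m.meta.index.get_indexer(idx)
            values[loc] /= values[loc].mean()
    else:
        values /= values.mean()
    return IFPAMatrix(values=values, phase=m.phase, meta=m.meta.copy(), relative=True)


def fit_motifs(m: IFPAMatrix | np.ndarray, n_keep: int = 4) -> MotifModel:
    """Column-demeaned PCA of the (pooled) IF_PA matrix.

    Motifs are the right singular vectors; scores are the projections of the
    demeaned rows. Component signs are fixed so the largest-|loading| bin of
    each motif is positive, and the applied flips are recorded.
    """
    values = m.values if isinstance(m, IFPAMatrix) else np.atleast_2d(np.asarray(m))
    phase = m.phase if isinstance(m, IFPAMatrix) else phase_grid(values.shape[1])
    if values.shape[0] < 2:
        raise ValueError("PCA needs at least 2 cycles")
    if n_keep > values.shape[1]:
        raise ValueError("cannot keep more components than phase bins")
    mean = values.mean(axis=0)
    centered = values - mean
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    var = svals**2
    ratio = var / var.sum() if var.sum() > 0 else var
    comps = vt[:n_keep]
    signs = np.ones(n_keep)
    for i in range(n_keep):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            signs[i] = -1.0
    scores = centered @ comps.T
    return MotifModel(
        mean=mean,
        components=comps,
        explained_variance_ratio=ratio[:n_keep],
        scores=scores,
        signs=signs,
        phase=phase,
    )


def _match_components(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Greedy matching of component sets by |loading correlation|.

    Returns, for each row of ``a``, the signed correlation with its matched
    row of ``b`` (sign-aligned, so perfect recovery gives +1).
    """
    n = a.shape[0]
    corr = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            corr[i, j] = np.corrcoef(a[i], b[j])[0, 1]
    out = np.zeros(n)
    free = set(range(n))
    order = np.argsort(-np.max(np.abs(corr), axis=1))
    for i in order:
        j = max(free, key=lambda jj: abs(corr[i, jj]))
        out[i] = abs(corr[i, j])
        free.remove(j)
    return out


def split_half_reliability(
    m: IFPAMatrix | np.ndarray,
    n_splits: int = 500,
    n_components: int = 4,
    seed: int = 0,
) -> ReliabilityReport:
    """Split-half reliability of the PCA motifs.

    Rows are randomly halved ``n_splits`` times; PCA is fit on each half and
    components matched greedily by absolute loading correlation. High median
    correlations indicate the motifs are stable features of the data rather
    than noise fits.
    """
    values = m.values if isinstance(m, IFPAMatrix) else np.atleast_2d(np.asarray(m))
    n_rows = values.shape[0]
    if n_rows < 4:
        raise ValueError("split-half reliability needs at least 4 cycles")
    rng = np.random.default_rng(seed)
    cors = np.zeros((n_splits, n_components))
    for s in range(n_splits):
        perm = rng.permutation(n_rows)
        half = n_rows // 2
        m1 = fit_motifs(IFPAMatrix(values[perm[:half]], phase_grid(values.shape[1])),
                        n_keep=n_components)
        m2 = fit_motifs(IFPAMatrix(values[perm[half : 2 * half]],
                                   phase_grid(values.shape[1])),
                        n_keep=n_components)
        cors[s] = _match_components(m1.components, m2.components)
    q25, q75 = np.percentile(cors, [25, 75], axis=0)
    return ReliabilityReport(
        correlations=cors,
        median=np.median(cors, axis=0),
        iqr=q75 - q25,
        n_splits=n_splits,
        seed=seed,
    )


def reconstruct_waveform(
    profile: np.ndarray, n_samples: int = 480, phase: np.ndarray | None = None
) -> np.ndarray:
    """Normalized waveform implied by a relative-IF-by-phase profile.

    Time per phase bin is proportional to 1/IF; the cumulative time maps
    phase to time, and cos(phase) resampled onto a uniform grid over one
    cycle (duration normalized to 1) is the waveform. A flat profile gives a
    pure cosine starting at the ascending zero crossing.
    """
    profile = np.asarray(profile, dtype=float).ravel()
    if np.any(profile <= 0):
        raise ValueError("IF profile must be strictly positive")
    n_bins = profile.size
    if phase is None:
        phase = phase_grid(n_bins)
    # phase bin edges in cycle order (starting at the ascending zero crossing)
    order = np.argsort(np.mod(phase - CYCLE_START_PHASE, 2 * np.pi))
    prof = profile[order]
    dphi = 2 * np.pi / n_bins
    dt = dphi / prof
    edges_t = np.concatenate([[0.0], np.cumsum(dt)])
    edges_phi = CYCLE_START_PHASE + dphi * np.arange(n_bins + 1)
    total = edges_t[-1]
    t_uniform = np.linspace(0.0, total, n_samples, endpoint=False)
    phi_uniform = np.interp(t_uniform, edges_t, edges_phi)
    return np.cos(phi_uniform)
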