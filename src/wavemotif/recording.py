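"""Multichannel recording container and file round-trip.

A :class:`RawRecording` is the pipeline entry point: a channels x samples
voltage matrix (µV) with a sampling rate and unique channel labels. On disk a
recording is either an EDF file (read through MNE) or a tab-delimited numeric
matrix accompanied by a JSON sidecar ``{"fs": ..., "labels": [...]}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class RawRecording:
    """Channels x samples voltage matrix with sampling metadata.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltages in µV.
    fs : float
        Sampling rate in Hz, > 0.
    labels : list of str
        Unique channel names, one per row of ``data``.
    """

    data: np.ndarray
    fs: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if not self.labels:
            self.labels = [f"ch{i + 1:02d}" for i in range(self.data.shape[0])]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def pick(self, channels: list[str]) -> "RawRecording":
        """Return a copy restricted to the named channels, in the given order."""
        missing = [c for c in channels if c not in self.labels]
        if missing:
            raise ValueError(f"channels not in recording: {missing}")
        idx = [self.labels.index(c) for c in channels]
        return RawRecording(self.data[idx].copy(), self.fs, list(channels))


def write_recording(rec: RawRecording, path: str | Path) -> tuple[Path, Path]:
    """Write a recording as a delimited matrix plus JSON sidecar.

    ``path`` is the matrix file (``.tsv``); the sidecar is written next to it
    with suffix ``.json``. Returns both paths.
    """
    path = Path(path)
    sidecar = path.with_suffix(".json")
    np.savetxt(path, rec.data, delimiter="\t")
    sidecar.write_text(json.dumps({"fs": rec.fs, "labels": rec.labels}))
    return path, sidecar


def read_recording(path: str | Path, sidecar: str | Path | None = None) -> RawRecording:
    """Load a recording from EDF or a delimited matrix + JSON sidecar.

    EDF files (suffix ``.edf``, any case) are read with MNE and converted to
    µV. For delimited matrices the sidecar defaults to ``<path>.json`` and
    must provide ``fs`` and ``labels``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # MNE holds volts
        return RawRecording(data, float(raw.info["sfreq"]), list(raw.ch_names))

    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar for {path}: {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"unparseable sidecar {sidecar}: {exc}") from exc
    for key in ("fs", "labels"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} missing required field '{key}'")
    try:
        data = np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise ValueError(f"unparseable matrix file {path}: {exc}") from exc
    if data.shape[0] != len(meta["labels"]):
        raise ValueError(
            f"matrix has {data.shape[0]} rows but sidecar lists "
            f"{len(meta['labels'])} labels"
        )
    return RawRecording(data, float(meta["fs"]), list(meta["labels"]))
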