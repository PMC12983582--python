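"""Template matching of SSD patterns against a leadfield.

A component's Haufe pattern is compared with every row of a sources x
channels leadfield using the absolute cosine distance

    d(a, b) = 1 - |a . b| / (||a|| ||b||)

which is invariant to (positive or negative) rescaling of either vector —
source polarity and filter scale are arbitrary. The component is assigned to
the source minimizing this distance, accepted only if the minimum falls below
a threshold (0.15 by default), and labeled with that source's cortical lobe.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Leadfield", "MatchResult", "cosine_distance", "match_component",
           "match_patterns"]

LOBES = ("occipital", "temporal", "sensorimotor", "parietal", "frontal", "other")


@dataclass
class Leadfield:
    """Sources x channels gain matrix with per-source lobe labels."""

    gain: np.ndarray
    labels: list[str]
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gain = np.atleast_2d(np.asarray(self.gain, dtype=float))
        if len(self.labels) != self.gain.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.gain.shape[0]} sources"
            )
        norms = np.linalg.norm(self.gain, axis=1)
        if np.any(norms == 0):
            raise ValueError("leadfield contains an all-zero source row")

    @classmethod
    def load(cls, gain_path: str | Path, labels_path: str | Path) -> "Leadfield":
        gain = np.loadtxt(gain_path, delimiter="\t", ndmin=2)
        labels = pd.read_csv(labels_path)["lobe"].tolist()
        return cls(gain, labels)

    def save(self, gain_path: str | Path, labels_path: str | Path) -> None:
        np.savetxt(gain_path, self.gain, delimiter="\t")
        pd.DataFrame({"source": range(len(self.labels)), "lobe": self.labels}).to_csv(
            labels_path, index=False
        )


@dataclass
class MatchResult:
    component: int
    source: int
    distance: float
    lobe: str | None
    accepted: bool

    def to_dict(self) -> dict:
        return {
            "component": self.component,
            "source": self.source,
            "distance": self.distance,
            "lobe": self.lobe,
            "accepted": self.accepted,
        }


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Absolute cosine distance in [0, 1]; 0 for (anti)parallel, 1 for orthogonal."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine distance undefined for a zero vector")
    return float(1.0 - abs(a @ b) / (na * nb))


def match_component(
    pattern: np.ndarray,
    lf: Leadfield,
    threshold: float = 0.15,
    component: int = 0,
) -> MatchResult:
    """Assign a pattern to the leadfield source at minimum absolute cosine distance.

    Ties break to the lowest source index; the match is accepted iff the
    minimum distance is strictly below ``threshold``. Rejected matches carry
    no lobe.
    """
    pattern = np.asarray(pattern, dtype=float).ravel()
    if pattern.size != lf.gain.shape[1]:
        raise ValueError(
            f"pattern has {pattern.size} channels, leadfield {lf.gain.shape[1]}"
        )
    dists = np.array([cosine_distance(pattern, row) for row in lf.gain])
    best = int(np.argmin(dists))  # argmin returns the first (lowest) index on ties
    accepted = bool(dists[best] < threshold)
    return MatchResult(
        component=component,
        source=best,
        distance=float(dists[best]),
        lobe=lf.labels[best] if accepted else None,
        accepted=accepted,
    )


def match_patterns(
    patterns: np.ndarray,
    lf: Leadfield,
    threshold: float = 0.15,
    component_ids: list[int] | None = None,
) -> list[MatchResult]:
    """Match each column of a channels x components pattern matrix."""
    patterns = np.atleast_2d(patterns)
    ids = component_ids or list(range(patterns.shape[1]))
    return [
        match_component(patterns[:, j], lf, threshold, component=ids[j])
        for j in range(patterns.shape[1])
    ]


def save_matches(matches: list[MatchResult], path: str | Path) -> None:
    pd.DataFrame([m.to_dict() for m in matches]).to_csv(path, index=False)
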