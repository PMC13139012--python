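"""SPXY calibration/prediction partitioning.

SPXY (sample set partitioning based on joint x-y distances) is a
Kennard-Stone-style greedy max-min selection run on a distance that
weights spectral and reference-value dissimilarity equally:

    D_ij = Dx_ij / max(Dx) + Dy_ij / max(Dy)

with Dx the Euclidean distance between spectra and Dy = |y_i - y_j|.
The calibration set is seeded with the pair attaining the maximum joint
distance; each subsequent pick is the sample whose minimum distance to
the already-selected set is largest.  Ties are broken toward the
smallest sample id so splits are fully deterministic, including under
row permutation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .specio import SpectralDataset


class SplitError(ValueError):
    pass


@dataclass
class SplitResult:
    """Outcome of one partition: disjoint id lists covering the input."""

    calibration_ids: list[int]
    prediction_ids: list[int]
    calibration_fraction: float
    distance_definition: str = "spxy"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "calibration_ids": self.calibration_ids,
                    "prediction_ids": self.prediction_ids,
                    "calibration_fraction": self.calibration_fraction,
                    "distance_definition": self.distance_definition,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitResult":
        doc = json.loads(Path(path).read_text())
        return cls(
            calibration_ids=[int(i) for i in doc["calibration_ids"]],
            prediction_ids=[int(i) for i in doc["prediction_ids"]],
            calibration_fraction=float(doc["calibration_fraction"]),
            distance_definition=str(doc.get("distance_definition", "spxy")),
        )


def joint_distance_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """The SPXY joint distance: range-normalized Dx plus normalized Dy.

    Symmetric with zero diagonal; entries lie in [0, 2].  Raises when
    either block is degenerate (all spectra identical, or constant y),
    since the normalization is then undefined.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 2:
        raise SplitError("need at least 2 samples")
    if y.size != n:
        raise SplitError(f"y length {y.size} != {n} rows")
    dx = squareform(pdist(X, metric="euclidean"))
    dy = np.abs(y[:, None] - y[None, :])
    dx_max, dy_max = dx.max(), dy.max()
    if dx_max == 0:
        raise SplitError("all spectra identical: spectral distances degenerate")
    if dy_max == 0:
        raise SplitError("constant reference values: y distances degenerate")
    return dx / dx_max + dy / dy_max


def _greedy_maxmin(D: np.ndarray, ids: np.ndarray, n_select: int) -> list[int]:
    """Greedy max-min selection on a distance matrix.

    Seeds with the maximum-distance pair, then repeatedly adds the sample
    whose minimum distance to the selected set is largest.  All ties are
    broken toward the smallest sample id.
    """
    n = D.shape[0]
    order = np.argsort(ids)  # scan candidates in id order so argmax tie-break = smallest id
    # seed pair: maximum entry; ties toward the lexicographically smallest id pair
    best = (-np.inf, None, None)
    for a in order:
        for b in order:
            if ids[a] >= ids[b]:
                continue
            if D[a, b] > best[0] + 1e-15:
                best = (D[a, b], a, b)
    selected = [best[1], best[2]]
    selected_mask = np.zeros(n, dtype=bool)
    selected_mask[selected] = True
    min_dist = np.minimum(D[best[1]], D[best[2]])
    while len(selected) < n_select:
        pick = -1
        pick_val = -np.inf
        for idx in order:
            if selected_mask[idx]:
                continue
            if min_dist[idx] > pick_val + 1e-15:
                pick_val = min_dist[idx]
                pick = idx
        selected.append(pick)
        selected_mask[pick] = True
        min_dist = np.minimum(min_dist, D[pick])
    return [int(ids[i]) for i in selected]


def spxy_split(
    X: np.ndarray,
    y: np.ndarray,
    sample_ids: np.ndarray | None = None,
    fraction: float = 0.75,
) -> SplitResult:
    """Partition samples into calibration and prediction sets.

    The calibration set holds ``floor(fraction * n)`` samples chosen by
    greedy max-min on the joint x-y distance; the rest form the
    prediction set.  Deterministic, including under input reordering.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 4:
        raise SplitError(f"need at least 4 samples to split, got {n}")
    if not 0 < fraction < 1:
        raise SplitError(f"fraction must be in (0, 1), got {fraction}")
    ids = (
        np.arange(1, n + 1)
        if sample_ids is None
        else np.asarray(sample_ids, dtype=int)
    )
    if ids.size != n:
        raise SplitError("sample_ids length mismatch")
    n_cal = int(np.floor(fraction * n))
    if n_cal < 2 or n_cal >= n:
        raise SplitError(f"fraction {fraction} leaves a degenerate set (n_cal={n_cal})")
    D = joint_distance_matrix(X, y)
    calibration = _greedy_maxmin(D, ids, n_cal)
    cal_set = set(calibration)
    prediction = [int(i) for i in ids if int(i) not in cal_set]
    return SplitResult(
        calibration_ids=sorted(calibration),
        prediction_ids=sorted(prediction),
        calibration_fraction=fraction,
    )


def split_dataset(
    dataset: SpectralDataset, fraction: float = 0.75
) -> tuple[SplitResult, SpectralDataset, SpectralDataset]:
    """Convenience wrapper: split a dataset and return both subsets."""
    if dataset.reference is None:
        raise SplitError("SPXY needs reference values")
    result = spxy_split(
        dataset.absorbance, dataset.reference, dataset.sample_ids, fraction
    )
    return (
        result,
        dataset.subset(result.calibration_ids),
        dataset.subset(result.prediction_ids),
    )
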