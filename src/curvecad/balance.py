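"""SMOTE over-sampling to rebalance the ROI feature table.

For each minority row, synthetic rows are generated on the segment to a
randomly chosen one of its k (default 5) Euclidean nearest same-class
neighbours: ``synthetic = x + u * (neighbour - x)`` with u ~ Uniform(0, 1).
Only over-sampling is performed — original rows are never altered or
dropped.

``balance_dataset`` supports the standard minority-to-majority target and
an explicit per-class count; with an explicit target larger than both
class counts, *both* classes are over-sampled (the published counts this
package reproduces grew the majority class as well).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["LabeledTable", "smote", "balance_dataset"]


@dataclass
class LabeledTable:
    """Feature matrix with class labels and per-row provenance."""

    X: np.ndarray
    y: np.ndarray
    provenance: np.ndarray  # {"original", "synthetic"}

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.provenance = np.asarray(self.provenance)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.y) != len(self.X) or len(self.provenance) != len(self.X):
            raise ValueError("X, y and provenance lengths differ")

    @classmethod
    def from_arrays(cls, X: np.ndarray, y: Sequence) -> "LabeledTable":
        X = np.asarray(X, dtype=float)
        return cls(X, np.asarray(y), np.full(len(X), "original", dtype=object))

    def class_counts(self) -> dict:
        labels, counts = np.unique(self.y, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def smote(
    X_min: np.ndarray,
    rate_percent: int,
    k: int = 5,
    seed: int = 0,
    zscore_distance: bool = False,
) -> np.ndarray:
    """Generate ``(rate_percent/100) * m`` synthetic minority rows.

    Parameters
    ----------
    X_min : m x d minority feature matrix (m >= 2).
    rate_percent : positive multiple of 100; 200 doubles the class.
    k : neighbours considered; effective k is min(k, m - 1).
    zscore_distance : compute neighbours on per-column z-scored features
        (interpolation still happens in the raw feature space).
    """
    X_min = np.asarray(X_min, dtype=float)
    if X_min.ndim != 2:
        raise ValueError("X_min must be 2-D")
    m = len(X_min)
    if m < 2:
        raise ValueError("cannot interpolate with fewer than 2 minority rows")
    if rate_percent <= 0 or rate_percent % 100 != 0:
        raise ValueError("rate_percent must be a positive multiple of 100")
    if k < 1:
        raise ValueError("k must be >= 1")
    k_eff = min(k, m - 1)

    space = X_min
    if zscore_distance:
        sd = X_min.std(axis=0)
        sd[sd == 0] = 1.0
        space = (X_min - X_min.mean(axis=0)) / sd
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(space)
    neighbours = nn.kneighbors(space, return_distance=False)[:, 1:]  # drop self

    rng = np.random.default_rng(seed)
    per_row = rate_percent // 100
    out = np.empty((per_row * m, X_min.shape[1]), dtype=float)
    pos = 0
    for i in range(m):
        picks = rng.integers(0, k_eff, size=per_row)
        u = rng.uniform(0.0, 1.0, size=per_row)
        base = X_min[i]
        for j in range(per_row):
            out[pos] = base + u[j] * (X_min[neighbours[i, picks[j]]] - base)
            pos += 1
    return out


def _augment_class(
    X: np.ndarray, target: int, k: int, seed: int, rng: np.random.Generator
) -> np.ndarray:
    """SMOTE one class up to exactly ``target`` rows; returns synthetic rows."""
    m = len(X)
    needed = target - m
    if needed <= 0:
        return np.empty((0, X.shape[1]))
    rate = 100 * int(np.ceil(needed / m))
    synth = smote(X, rate, k=k, seed=seed)
    if len(synth) > needed:  # subsample the surplus uniformly
        keep = rng.choice(len(synth), size=needed, replace=False)
        synth = synth[np.sort(keep)]
    return synth


def balance_dataset(
    t: LabeledTable,
    target: Union[str, int] = "match_majority",
    k: int = 5,
    seed: int = 0,
    round_binary: Optional[Sequence[int]] = None,
) -> LabeledTable:
    """Over-sample until both classes hit ``target`` rows.

    target : "match_majority" (minority grows to the majority count) or an
        explicit integer count applied to every class (classes already at
        or above it are left as they are).
    round_binary : optional column indices to round to {0, 1} in synthetic
        rows (binary covariates interpolated as continuous otherwise).
    """
    labels = np.unique(t.y)
    if len(labels) < 2:
        raise ValueError("both classes must be present")
    counts = t.class_counts()
    if target == "match_majority":
        goal = max(counts.values())
    elif isinstance(target, (int, np.integer)) and int(target) > 0:
        goal = int(target)
    else:
        raise ValueError(f"invalid target {target!r}")

    rng = np.random.default_rng(seed)
    X_parts: List[np.ndarray] = [t.X]
    y_parts: List[np.ndarray] = [t.y]
    prov_parts: List[np.ndarray] = [t.provenance]
    for offset, lab in enumerate(labels):
        X_lab = t.X[t.y == lab]
        synth = _augment_class(X_lab, goal, k, seed + 1 + offset, rng)
        if len(synth) == 0:
            continue
        if round_binary is not None:
            synth[:, list(round_binary)] = np.round(synth[:, list(round_binary)])
        X_parts.append(synth)
        y_parts.append(np.full(len(synth), lab, dtype=t.y.dtype))
        prov_parts.append(np.full(len(synth), "synthetic", dtype=object))
    return LabeledTable(
        np.vstack(X_parts), np.concatenate(y_parts), np.concatenate(prov_parts)
    )
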