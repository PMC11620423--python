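"""Hotspot-series extraction: windowed-variance feature selection.

A spectrum of N intensities yields N - l + 1 contiguous windows ("intensity
series") of length l. Each window j is scored by its population variance

    V_j = (1/l) * sum_{i=j}^{j+l-1} (I_i - mean_j)^2

and the k highest-variance windows per sample are the "hotspot series" —
the locally volatile stretches that carry class-discriminative structure.
The union of all indices covered by selected windows, across every sample,
forms one shared index mask; applying it reduces each spectrum to the
retained columns. The method shortens the input without transforming it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import AxisMismatch, EmptyDataset, InvalidWindow
from .io import SpectraDataset


@dataclass
class WindowStats:
    """Per-window summary: start index, length, mean, population variance."""

    start_index: int
    length: int
    mean: float
    variance: float


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, SpectraDataset):
        return data.intensity_matrix()
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ValueError("expected a (n_samples, n_points) matrix")
    return X


def _window_moments(X: np.ndarray, l: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-window mean and population variance, rows x windows."""
    windows = sliding_window_view(X, l, axis=-1)
    means = windows.mean(axis=-1)
    variances = np.maximum(((windows - means[..., None]) ** 2).mean(axis=-1), 0.0)
    return means, variances


def compute_window_stats(spectrum, l: int) -> list[WindowStats]:
    """Enumerate all N - l + 1 windows of one spectrum, in start-index order.

    ``spectrum`` may be a :class:`~ramanglu.io.Spectrum` or a 1-D array.
    Mean and variance use the 1/l (population) normalization.
    """
    y = np.asarray(getattr(spectrum, "intensities", spectrum), dtype=float)
    n = y.size
    if not 1 <= l <= n:
        raise InvalidWindow(f"window length {l} not in [1, {n}]")
    means, variances = _window_moments(y[None, :], l)
    return [
        WindowStats(j, l, float(means[0, j]), float(variances[0, j]))
        for j in range(n - l + 1)
    ]


def _window_scores(X: np.ndarray, l: int) -> np.ndarray:
    """Rank-equivalent variance scores: l * sum(w^2) - sum(w)^2 = l^2 * V.

    Avoiding the division and the centered subtraction makes the score
    exact for integer-valued intensities, so mathematically tied windows
    compare exactly equal regardless of the order of their values.
    """
    windows = sliding_window_view(X, l, axis=-1)
    sums = windows.sum(axis=-1)
    sumsq = (windows**2).sum(axis=-1)
    return l * sumsq - sums**2


def _top_k_starts(scores: np.ndarray, k: int) -> np.ndarray:
    """Start indices of the k largest-variance windows of one sample.

    Ties are broken toward the smaller start index: a stable sort on
    descending score keeps earlier windows first among equals.
    """
    order = np.argsort(-scores, kind="stable")
    return order[: min(k, scores.size)]


@dataclass
class IndexMask:
    """Sorted unique retained indices, shared by every sample in a dataset."""

    indices: np.ndarray
    n_total: int
    l: int | None = None
    k: int | None = None

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=int))
        if idx.size and (idx[0] < 0 or idx[-1] >= self.n_total):
            raise ValueError("mask indices out of range")
        self.indices = idx

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def retained_fraction(self) -> float:
        return len(self) / self.n_total

    def segments(self) -> list[tuple[int, int]]:
        """Maximal runs of consecutive indices as inclusive (start, end) pairs."""
        if not len(self):
            return []
        breaks = np.flatnonzero(np.diff(self.indices) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(self) - 1]))
        return [
            (int(self.indices[a]), int(self.indices[b]))
            for a, b in zip(starts, ends)
        ]

    @classmethod
    def from_segments(
        cls, segments: Sequence[tuple[int, int]], n_total: int, **kw
    ) -> "IndexMask":
        """Build a mask from inclusive (start, end) index segments."""
        idx = np.concatenate(
            [np.arange(a, b + 1) for a, b in segments]
        ) if segments else np.empty(0, dtype=int)
        return cls(indices=idx, n_total=n_total, **kw)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_total": self.n_total,
            "l": self.l,
            "k": self.k,
            "n_retained": len(self),
            "segments": self.segments(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "IndexMask":
        try:
            payload = json.loads(str(source))
        except json.JSONDecodeError:
            payload = json.loads(Path(source).read_text())
        return cls.from_segments(
            [tuple(seg) for seg in payload["segments"]],
            payload["n_total"],
            l=payload.get("l"),
            k=payload.get("k"),
        )


class HotspotSelector(TransformerMixin, BaseEstimator):
    """Window-variance feature selector over a spectral matrix.

    Parameters
    ----------
    l : int, default=10
        Window (intensity-series) length.
    k : int, default=500
        Number of highest-variance windows retained per sample.

    ``fit`` scores every length-``l`` window of every row, keeps each
    row's ``k`` top-variance windows (ties resolved toward the smaller
    start index) and unions the covered column indices over all rows into
    ``mask_``; ``transform`` reduces a matrix to those columns. One mask
    is shared by all samples, so the selector composes with scikit-learn
    pipelines and cross-validation (fitting inside train folds gives the
    leakage-safe variant; fitting once on the full dataset mirrors the
    global-mask protocol).

    Attributes
    ----------
    mask_ : IndexMask
        Retained column indices.
    n_features_in_ : int
        Axis length seen during fit.
    """

    def __init__(self, l: int = 10, k: int = 500):
        self.l = l
        self.k = k

    def fit(self, X, y=None) -> "HotspotSelector":
        X = _as_matrix(X)
        if X.shape[0] == 0:
            raise EmptyDataset("cannot select hotspots from zero samples")
        n = X.shape[1]
        if not 1 <= self.l <= n:
            raise InvalidWindow(f"window length {self.l} not in [1, {n}]")
        if self.k < 1:
            raise InvalidWindow("k must be >= 1")
        scores = _window_scores(X, self.l)
        covered = np.zeros(n, dtype=bool)
        for row in scores:
            for j in _top_k_starts(row, self.k):
                covered[j : j + self.l] = True
        self.n_features_in_ = n
        self.mask_ = IndexMask(
            indices=np.flatnonzero(covered), n_total=n, l=self.l, k=self.k
        )
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "mask_")
        X = _as_matrix(X)
        if X.shape[1] != self.mask_.n_total:
            raise AxisMismatch(
                f"matrix has {X.shape[1]} columns, mask expects "
                f"{self.mask_.n_total}"
            )
        return X[:, self.mask_.indices]


def select_hotspots(dataset, l: int = 10, k: int = 500) -> IndexMask:
    """Global hotspot mask of a dataset (union over all samples)."""
    return HotspotSelector(l=l, k=k).fit(dataset).mask_


def apply_mask(dataset, mask: IndexMask) -> np.ndarray:
    """Reduce every sample to the mask's columns, preserving axis order."""
    X = _as_matrix(dataset)
    if X.shape[1] != mask.n_total:
        raise AxisMismatch(
            f"matrix has {X.shape[1]} columns, mask expects {mask.n_total}"
        )
    return X[:, mask.indices]
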