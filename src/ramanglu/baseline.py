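"""Fluorescence-background removal by iterative modified polynomial fitting.

The Vancouver Raman Algorithm couples two steps: (1) light smoothing of
the raw spectrum and (2) an iterative modified polynomial fit (IModPoly,
Zhao et al.) that estimates the broad fluorescence baseline while
progressively excluding Raman peaks. Each iteration least-squares-fits a
low-order polynomial to the working spectrum, computes DEV (the standard
deviation of the residuals), and clips every point above ``fit + DEV``
down to that ceiling, so peaks are flattened while the smooth background
is tracked. Iteration stops when DEV stabilizes; the final polynomial is
subtracted from the smoothed input.

Corrected intensities may undershoot zero near peak shoulders; they are
retained unclipped so downstream models see the full residual signal
(the positivity rule applies to raw detector counts, not to residuals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import EmptyDataset, InvalidParams, InvalidWindow, SingularFit
from .io import SpectraDataset, Spectrum


@dataclass
class VraParams:
    """Tunables of the Vancouver Raman Algorithm.

    poly_order
        Degree of the baseline polynomial; fluorescence backgrounds are
        conventionally fitted at order five or six (default 5).
    smooth_window
        Odd boxcar width for the pre-smoothing step; 1 disables smoothing.
    tol
        Convergence threshold on the relative DEV change between
        iterations (default 0.5%).
    max_iter
        Iteration cap; hitting it returns a result with converged=False
        rather than raising.
    """

    poly_order: int = 5
    smooth_window: int = 7
    tol: float = 0.005
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.poly_order < 1:
            raise InvalidParams("poly_order must be >= 1")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise InvalidWindow("smooth_window must be odd and >= 1")
        if self.tol <= 0:
            raise InvalidParams("tol must be > 0")
        if self.max_iter < 1:
            raise InvalidParams("max_iter must be >= 1")


@dataclass
class BaselineResult:
    """Outcome of one IModPoly run on one spectrum."""

    baseline: np.ndarray
    corrected: np.ndarray
    n_iterations: int
    converged: bool
    dev_history: list[float] = field(default_factory=list)


def smooth(spectrum, window: int):
    """Boxcar moving average with edge truncation.

    Boundary points average over the part of the window that fits inside
    the spectrum, so constants are preserved exactly and no padding value
    is invented. ``window=1`` is the identity. Accepts a
    :class:`~ramanglu.io.Spectrum` (returns one) or a 1-D array.
    """
    y = np.asarray(getattr(spectrum, "intensities", spectrum), dtype=float)
    n = y.size
    if window % 2 == 0 or not 1 <= window <= n:
        raise InvalidWindow(f"window must be odd and in [1, {n}]")
    if window == 1:
        out = y.copy()
    else:
        kernel = np.ones(window)
        # Truncated-window normalization: divide by how many samples each
        # position actually averaged.
        out = np.convolve(y, kernel, mode="same") / np.convolve(
            np.ones(n), kernel, mode="same"
        )
    if isinstance(spectrum, Spectrum):
        return spectrum.copy(intensities=out)
    return out


def _fit_poly(x: np.ndarray, y: np.ndarray, order: int) -> np.ndarray:
    # Polynomial.fit maps x onto [-1, 1] internally, which keeps the
    # normal equations well conditioned for wavenumber-scale axes.
    series = np.polynomial.Polynomial.fit(x, y, order)
    return series(x)


def fit_baseline_imodpoly(
    spectrum, params: VraParams | None = None
) -> BaselineResult:
    """Estimate and subtract the fluorescence baseline of one spectrum.

    Implements IModPoly with a pre-smoothing pass: fit an order-p
    polynomial, compute DEV = sd(residuals), clip the working spectrum at
    ``fit + DEV``, repeat until ``|DEV_t - DEV_{t-1}| / DEV_t < tol`` or
    ``max_iter``. Points flagged as peaks by the first fit (above
    ``fit + DEV``) are excluded from later fits — the major-peak
    elimination step of the original algorithm. DEV = 0 (an exactly
    polynomial input) converges immediately. Raises :class:`SingularFit` when the axis has fewer
    distinct values than the polynomial needs; non-convergence is reported
    via ``converged=False``, never raised.
    """
    params = params or VraParams()
    y = np.asarray(getattr(spectrum, "intensities", spectrum), dtype=float)
    x = np.asarray(
        getattr(spectrum, "shifts", np.arange(y.size)), dtype=float
    )
    if np.unique(x).size < params.poly_order + 1:
        raise SingularFit(
            f"need > {params.poly_order} distinct axis values for an order-"
            f"{params.poly_order} fit"
        )
    smoothed = smooth(y, params.smooth_window)
    work = smoothed.copy()
    keep = np.ones(work.size, dtype=bool)
    dev_history: list[float] = []
    fit = work
    converged = False
    n_iter = 0
    prev_dev = None
    for n_iter in range(1, params.max_iter + 1):
        coef_fit = np.polynomial.Polynomial.fit(
            x[keep], work[keep], params.poly_order
        )
        fit = coef_fit(x)
        dev = float(np.std(work[keep] - fit[keep]))
        dev_history.append(dev)
        if dev == 0.0:
            converged = True
            break
        if n_iter == 1:
            # Major-peak elimination: points the first fit flags as peaks
            # (above fit + DEV) are excluded from all subsequent fits, so
            # strong Raman bands cannot drag the polynomial upward.
            keep = work <= fit + dev
            if keep.sum() < params.poly_order + 1:
                keep[:] = True  # pathological; fall back to clipping only
        # Peak clipping: remaining points above fit + DEV are pulled down
        # to the ceiling; background points are left alone.
        work = np.minimum(work, fit + dev)
        if prev_dev is not None and abs(dev - prev_dev) / dev < params.tol:
            converged = True
            break
        prev_dev = dev
    baseline = fit
    return BaselineResult(
        baseline=baseline,
        corrected=smoothed - baseline,
        n_iterations=n_iter,
        converged=converged,
        dev_history=dev_history,
    )


class VancouverBaselineCorrector(TransformerMixin, BaseEstimator):
    """Row-wise VRA baseline removal as a scikit-learn transformer.

    Stateless per row — ``fit`` only records the input width; ``transform``
    smooths each spectrum, estimates its IModPoly baseline and returns the
    difference. Exposes ``results_`` (per-row :class:`BaselineResult`)
    after the most recent transform for convergence diagnostics.
    """

    def __init__(
        self,
        poly_order: int = 5,
        smooth_window: int = 7,
        tol: float = 0.005,
        max_iter: int = 100,
    ):
        self.poly_order = poly_order
        self.smooth_window = smooth_window
        self.tol = tol
        self.max_iter = max_iter

    def _params(self) -> VraParams:
        return VraParams(
            poly_order=self.poly_order,
            smooth_window=self.smooth_window,
            tol=self.tol,
            max_iter=self.max_iter,
        )

    def fit(self, X, y=None) -> "VancouverBaselineCorrector":
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[-1]
        self._params()  # validate early
        return self

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        params = self._params()
        self.results_ = [fit_baseline_imodpoly(row, params) for row in X]
        return np.vstack([r.corrected for r in self.results_])

    def fit_transform(self, X, y=None, **kw) -> np.ndarray:
        return self.fit(X, y).transform(X)


def correct_dataset(
    dataset: SpectraDataset, params: VraParams | None = None
) -> SpectraDataset:
    """Baseline-correct every spectrum of a dataset.

    Labels, sample ids and the shift axis are preserved; intensities are
    replaced by the corrected residuals (which may be negative). Errors in
    individual spectra are re-raised with the sample id attached.
    """
    params = params or VraParams()
    if len(dataset) == 0:
        raise EmptyDataset("cannot correct an empty dataset")
    corrected = []
    for s in dataset:
        try:
            result = fit_baseline_imodpoly(s, params)
        except Exception as exc:
            raise type(exc)(f"sample {s.sample_id!r}: {exc}") from exc
        corrected.append(s.copy(intensities=result.corrected))
    return SpectraDataset(corrected, label_map=dict(dataset.label_map))


def convergence_log(results: Sequence[BaselineResult]) -> list[dict]:
    """Per-sample convergence records, JSON-lines friendly."""
    return [
        {
            "index": i,
            "n_iterations": r.n_iterations,
            "converged": bool(r.converged),
            "final_dev": r.dev_history[-1] if r.dev_history else 0.0,
        }
        for i, r in enumerate(results)
    ]
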