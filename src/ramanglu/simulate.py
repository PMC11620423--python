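"""Synthetic glucose-solution Raman spectra.

The laboratory datasets this package targets are glucose/deionized-water
phantoms: ten concentration levels between 5 and 20 mmol/L, five replicate
acquisitions per level, 2048 points per spectrum. The generator emulates
that design statistically — concentration-scaled Gaussian analyte bands
riding on a strong, smooth fluorescence background, with per-sample
multiplicative gain, baseline variability and additive detector noise:

    I(x) = gain * (baseline(x) + sum_p beta * c * exp(-(x - mu_p)^2 / (2 w_p^2)))
           + eps,   eps ~ N(0, noise_sd),  clipped at 0

It is a statistical stand-in, not an optics model: no cosmic-ray spikes,
etaloning or wavelength drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import InvalidParams
from .io import TABLE1_LABEL_MAP, SpectraDataset, Spectrum

#: Ten glucose levels (mmol/L) of the standard phantom design.
TABLE1_LEVELS: tuple[float, ...] = tuple(sorted(TABLE1_LABEL_MAP))

# Degree-5 fluorescence template on the normalized axis u in [0, 1]
# (ascending powers). Shaped like a typical autofluorescence hump: steep
# rise, maximum near u ~ 0.17 (index ~343 of 2048), slow decay, positive
# everywhere. Per-sample baselines jitter these coefficients.
_BASELINE_TEMPLATE = np.array(
    [0.81309618, 2.16842326, -6.14816041, -4.31918094, 15.30645775, -7.77365714]
)


@dataclass
class GeneratorParams:
    """Knobs of the synthetic-spectrum generator.

    Defaults reproduce the qualitative shape of phantom glucose spectra:
    the fluorescence maximum and the discriminative analyte bands both fall
    in the first ~60% of the 2048-point axis. Band centers are the
    prominent glucose Raman bands near 1060/1125/1366/1460 cm^-1
    (C-O/C-C stretches and CH/OH deformations).

    Attributes
    ----------
    n_points : int
        Axis length (2048 matches the target instrument readout).
    shift_range : (float, float)
        Raman-shift axis span in cm^-1.
    peak_centers, peak_widths : sequence of float
        Gaussian band centers and standard deviations, cm^-1. A scalar
        width is broadcast over all bands.
    response_slope : float
        beta — intensity counts per mmol/L contributed at each band apex.
    baseline_order : int
        Degree of the fluorescence polynomial (5 by default, matching the
        order the baseline corrector fits).
    baseline_scale : float
        Peak height of the fluorescence template in counts.
    baseline_jitter : float
        S.d. of the per-sample perturbation of each baseline coefficient,
        expressed as a fraction of the fluorescence peak height and damped
        with increasing power (sample-to-sample fluorescence variability).
    gain_sd : float
        Relative s.d. of the per-sample multiplicative gain.
    noise_sd : float
        Additive Gaussian noise s.d. in counts.
    """

    n_points: int = 2048
    shift_range: tuple[float, float] = (200.0, 3200.0)
    peak_centers: Sequence[float] = (1060.0, 1125.0, 1366.0, 1460.0)
    peak_widths: Sequence[float] | float = 20.0
    response_slope: float = 10.0
    baseline_order: int = 5
    baseline_scale: float = 1000.0
    baseline_jitter: float = 0.05
    gain_sd: float = 0.02
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise InvalidParams("n_points must be >= 2")
        if np.isscalar(self.peak_widths):
            self.peak_widths = (float(self.peak_widths),) * len(
                tuple(self.peak_centers)
            )
        self.peak_centers = tuple(float(c) for c in self.peak_centers)
        self.peak_widths = tuple(float(w) for w in self.peak_widths)
        if len(self.peak_widths) != len(self.peak_centers):
            raise InvalidParams("one width per peak center required")
        if any(w <= 0 for w in self.peak_widths):
            raise InvalidParams("peak widths must be positive")
        if self.noise_sd < 0 or self.gain_sd < 0 or self.baseline_jitter < 0:
            raise InvalidParams("noise/gain/jitter s.d. must be >= 0")
        if self.shift_range[1] <= self.shift_range[0]:
            raise InvalidParams("shift_range must be increasing")

    def axis(self) -> np.ndarray:
        return np.linspace(*self.shift_range, self.n_points)

    def baseline_template_coeffs(self) -> np.ndarray:
        """Template coefficients (ascending powers of u), scaled to counts."""
        coeffs = _BASELINE_TEMPLATE
        if self.baseline_order != coeffs.size - 1:
            # Re-fit the template shape at the requested degree.
            u = np.linspace(0.0, 1.0, 512)
            shape = np.polynomial.polynomial.polyval(u, coeffs)
            coeffs = np.polynomial.polynomial.polyfit(
                u, shape, self.baseline_order
            )
        return self.baseline_scale * coeffs


def _peak_profile(shifts: np.ndarray, params: GeneratorParams) -> np.ndarray:
    """Sum of unit-height Gaussian kernels over all bands."""
    total = np.zeros_like(shifts)
    for center, width in zip(params.peak_centers, params.peak_widths):
        total += np.exp(-0.5 * ((shifts - center) / width) ** 2)
    return total


def evaluate_clean_spectrum(
    concentration: float,
    params: GeneratorParams,
    baseline_coeffs: np.ndarray | None = None,
) -> np.ndarray:
    """Closed-form noiseless spectrum: baseline + beta * c * kernel sum."""
    shifts = params.axis()
    u = (shifts - shifts[0]) / (shifts[-1] - shifts[0])
    coeffs = (
        params.baseline_template_coeffs()
        if baseline_coeffs is None
        else baseline_coeffs
    )
    baseline = np.polynomial.polynomial.polyval(u, coeffs)
    return baseline + params.response_slope * concentration * _peak_profile(
        shifts, params
    )


def generate_spectrum(
    concentration: float,
    params: GeneratorParams | None = None,
    seed: int | None = None,
) -> Spectrum:
    """Draw one synthetic spectrum at the given glucose concentration.

    Deterministic given ``(params, seed)``; all random draws (baseline
    coefficient jitter, gain, additive noise) come from one
    ``numpy.random.default_rng(seed)`` stream. Intensities are clipped at
    zero, as for raw detector counts.
    """
    params = params or GeneratorParams()
    if concentration < 0:
        raise InvalidParams("concentration must be >= 0")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    template = params.baseline_template_coeffs()
    # Jitter each coefficient on the scale of the curve itself (the
    # template's peak height), damped with increasing power so the
    # perturbation stays a smooth low-order wobble. Relative jitter on the
    # raw coefficients would be unstable: the template's tail is a near
    # cancellation of large terms.
    powers = np.arange(template.size)
    coeffs = template + (
        params.baseline_jitter
        * params.baseline_scale
        * rng.standard_normal(template.size)
        / (1.0 + powers)
    )
    gain = 1.0 + params.gain_sd * rng.standard_normal()
    clean = evaluate_clean_spectrum(concentration, params, coeffs)
    noise = (
        rng.normal(0.0, params.noise_sd, params.n_points)
        if params.noise_sd > 0
        else 0.0
    )
    intensities = np.clip(gain * clean + noise, 0.0, None)
    return Spectrum(
        shifts=params.axis(),
        intensities=intensities,
        concentration=concentration,
        sample_id=f"c{concentration:g}",
    )


def _level_codes(levels: Sequence[float]) -> dict[float, int]:
    """Standard-design codes when applicable, else rank order from 1."""
    if all(lv in TABLE1_LABEL_MAP for lv in levels):
        return {lv: TABLE1_LABEL_MAP[lv] for lv in levels}
    return {lv: i + 1 for i, lv in enumerate(sorted(set(levels)))}


def generate_dataset(
    levels: Sequence[float] | None = None,
    replicates: int = 5,
    params: GeneratorParams | None = None,
    seed: int = 0,
) -> SpectraDataset:
    """Generate ``len(levels) * replicates`` spectra.

    Per-replicate seeds are spawned deterministically from the master seed
    via :class:`numpy.random.SeedSequence`, so the dataset is bit-identical
    across runs and independent of generation order.
    """
    params = params or GeneratorParams()
    levels = TABLE1_LEVELS if levels is None else tuple(levels)
    if replicates < 0:
        raise InvalidParams("replicates must be >= 0")
    codes = _level_codes(levels)
    n = len(levels) * replicates
    child_seeds = np.random.SeedSequence(seed).generate_state(max(n, 1))
    spectra = []
    i = 0
    for level in levels:
        for rep in range(replicates):
            s = generate_spectrum(level, params, int(child_seeds[i] & 0x7FFFFFFF))
            s.label_code = codes[level]
            s.sample_id = f"{codes[level]}-c{level:g}-rep{rep + 1}"
            spectra.append(s)
            i += 1
    return SpectraDataset(spectra, label_map={lv: codes[lv] for lv in levels})


def default_study_dataset(seed: int = 0, **overrides) -> SpectraDataset:
    """The standard study design: 10 levels x 5 replicates, 2048 points."""
    params = replace(GeneratorParams(), **overrides) if overrides else None
    return generate_dataset(TABLE1_LEVELS, 5, params, seed)
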