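"""Apparent diffusion coefficient (ADC) mapping and its time-trend.

The ADC map uses the mono-exponential Stejskal-Tanner signal model
``S(b) = S0 * exp(-b * ADC)`` evaluated in closed form from exactly two
b-values: ``ADC = ln(S(b_low)/S(b_high)) / (b_high - b_low)``.  The study
convention is b = 150/500 s/mm^2 for the 5-point sequence and 300/800 for
the 7-point sequence.

A per-patient longitudinal summary is an ordinary least-squares line of
the within-GTV median ADC against fraction number: the slope plus the
value at fraction one enter the survival analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import DWIFraction, GTVMask
from .preprocess import stat_within_mask

logger = logging.getLogger(__name__)

__all__ = ["ADCMap", "fit_adc", "adc_trend", "median_adc_series"]


@dataclass
class ADCMap:
    """Voxelwise ADC (mm^2/s) from a two-b-value fit.

    ``invalid_mask`` marks voxels where the fit is undefined (signal <= 0
    at either b-value); those voxels hold NaN.
    """

    adc: np.ndarray
    b_pair: tuple[float, float]
    invalid_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.b_pair[1] <= self.b_pair[0]:
            raise ValueError("b_pair must be (b_low, b_high) with b_high > b_low")


def fit_adc(fraction: DWIFraction, b_low: float, b_high: float) -> ADCMap:
    """Closed-form two-point ADC map.

    Negative ADC values (signal increasing with b, e.g. from noise) are
    retained — they contribute honestly to within-GTV medians — while
    non-positive signals are marked invalid because the logarithm is
    undefined there.
    """
    if b_low >= b_high:
        raise ValueError("b_low must be smaller than b_high")
    s_low = fraction.volume_at_b(b_low)
    s_high = fraction.volume_at_b(b_high)
    invalid = (s_low <= 0) | (s_high <= 0) | ~np.isfinite(s_low) | ~np.isfinite(s_high)
    adc = np.full(s_low.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc[~invalid] = np.log(s_low[~invalid] / s_high[~invalid]) / (b_high - b_low)
    n_neg = int((adc[~invalid] < 0).sum())
    if n_neg:
        logger.info("fit_adc: %d voxels with negative ADC retained", n_neg)
    return ADCMap(adc=adc, b_pair=(float(b_low), float(b_high)), invalid_mask=invalid)


def median_adc_series(
    fractions: list[DWIFraction],
    masks: list[GTVMask],
    b_low: float,
    b_high: float,
) -> list[tuple[int, float]]:
    """Within-GTV median ADC per fraction, as ``(fraction_index, median)``."""
    series = []
    for frac, mask in zip(fractions, masks, strict=True):
        adc_map = fit_adc(frac, b_low, b_high)
        series.append(
            (frac.fraction_index, stat_within_mask(adc_map.adc, mask, "median"))
        )
    return series


def adc_trend(
    per_fraction_medians: list[tuple[int, float]],
    trend_value: str = "observed",
) -> tuple[float, float]:
    """Linear time-trend of the median ADC over fractions.

    Returns ``(adc_frac1, adc_slope)``: the value at fraction one and the
    OLS slope per fraction.  ``adc_frac1`` is the *observed* fraction-1
    median by default; if fraction one is missing (or
    ``trend_value="fitted"``), the fitted line evaluated at index 1 is
    substituted and a warning logged.
    """
    if trend_value not in ("observed", "fitted"):
        raise ValueError("trend_value must be 'observed' or 'fitted'")
    pts = [(int(i), float(v)) for i, v in per_fraction_medians if np.isfinite(v)]
    if len(pts) < 2:
        raise ValueError("need at least two fractions with finite medians")
    idx = np.array([p[0] for p in pts], dtype=float)
    val = np.array([p[1] for p in pts], dtype=float)
    slope, intercept = np.polyfit(idx, val, 1)
    observed_f1 = {i: v for i, v in pts}.get(1)
    if trend_value == "observed" and observed_f1 is not None:
        frac1 = observed_f1
    else:
        frac1 = float(slope * 1.0 + intercept)
        if trend_value == "observed":
            logger.warning(
                "adc_trend: fraction 1 missing; substituted the fitted value at index 1"
            )
    return float(frac1), float(slope)
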