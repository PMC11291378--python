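"""Patient-level feature extraction for survival modelling.

From the decomposition weight maps, the 10th and 90th percentiles of each
component's within-GTV weight distribution are tracked over treatment
fractions; an ordinary least-squares line per series yields the value at
fraction one and the slope ("time-trend").  Together with the two ADC
parameters and six clinical covariates this gives the 20-column feature
table: 12 decomposition-based + 2 ADC + 6 clinical.

Continuous columns are standardized (zero mean, unit SD over the cohort;
the constants are stored so effects read as "per SD" and the transform is
invertible); categorical covariates enter as 0/1 indicators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GTVMask, WeightMap
from .preprocess import stat_within_mask

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "percentile_series",
    "linear_trend",
    "decomposition_features",
    "assemble_features",
    "DECOMPOSITION_COLUMNS",
    "CLINICAL_CONTINUOUS",
    "CLINICAL_BINARY",
]

DEFAULT_PERCENTILES = (10, 90)

#: the 12 decomposition parameter names for k=3, percentiles {10, 90}
DECOMPOSITION_COLUMNS = [
    f"Component{j}_prc{p}_{kind}"
    for j in (1, 2, 3)
    for p in DEFAULT_PERCENTILES
    for kind in ("frac1", "time-trend")
]
ADC_COLUMNS = ["ADC_frac1", "ADC_time-trend"]
CLINICAL_CONTINUOUS = ["age", "gtv_volume_cm3", "time_diagnosis_to_rt_months"]
CLINICAL_BINARY = ["sex_male", "ps_1plus", "recurrence"]


@dataclass
class FeatureTable:
    """Patient-by-parameter matrix with its standardization record.

    ``data`` holds the standardized values (continuous columns mean 0,
    SD 1 over the cohort; binary columns 0/1).  ``means``/``stds`` map
    continuous column names to the cohort constants used, enabling the
    inverse transform.
    """

    data: pd.DataFrame
    means: dict[str, float] = field(default_factory=dict)
    stds: dict[str, float] = field(default_factory=dict)

    @property
    def patients(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def columns(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    def destandardize(self) -> pd.DataFrame:
        """Recover the raw-scale table."""
        raw = self.data.copy()
        for col, mu in self.means.items():
            raw[col] = raw[col] * self.stds[col] + mu
        return raw

    def subset(self, names: list[str]) -> pd.DataFrame:
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise KeyError(f"unknown feature names: {missing}")
        return self.data[list(names)]

    def to_csv(self, path, sidecar_path=None) -> None:
        self.data.to_csv(path, float_format="%.12g")
        if sidecar_path is not None:
            import json

            payload = {"means": self.means, "stds": self.stds}
            with open(sidecar_path, "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)


def percentile_series(
    weight_maps: list[WeightMap],
    masks: list[GTVMask] | GTVMask,
    component: int,
    percentile: float,
) -> list[tuple[int, float]]:
    """Per-fraction percentile of one component's within-GTV weights.

    ``masks`` may be a single mask (shared across fractions) or one per
    fraction.  Missing fractions simply shorten the series; at least two
    entries are needed downstream for a trend.
    """
    if isinstance(masks, GTVMask):
        masks = [masks] * len(weight_maps)
    if len(masks) != len(weight_maps):
        raise ValueError("need one mask per weight map (or a single shared mask)")
    series = []
    for wm, mask in zip(weight_maps, masks):
        vol = wm.component_volume(component)
        series.append((wm.fraction_index, stat_within_mask(vol, mask, percentile)))
    return series


def linear_trend(
    series: list[tuple[int, float]], trend_value: str = "observed"
) -> tuple[float, float]:
    """OLS line of a per-fraction series: returns ``(value_frac1, slope)``.

    The fraction-one value is the observed one when present; otherwise
    (or with ``trend_value="fitted"``) the fitted line at index 1.
    """
    from .adc import adc_trend  # same convention, shared implementation

    return adc_trend(series, trend_value=trend_value)


def decomposition_features(
    weight_maps_per_fraction: list[WeightMap],
    masks: list[GTVMask] | GTVMask,
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES,
    trend_value: str = "observed",
) -> dict[str, float]:
    """All percentile/time-trend parameters of one patient.

    For each component j and percentile p: ``Componentj_prcp_frac1`` and
    ``Componentj_prcp_time-trend``.
    """
    if not weight_maps_per_fraction:
        raise ValueError("no weight maps given")
    k = weight_maps_per_fraction[0].component_ref.k
    out: dict[str, float] = {}
    for j in range(1, k + 1):
        for p in percentiles:
            series = percentile_series(weight_maps_per_fraction, masks, j, p)
            frac1, slope = linear_trend(series, trend_value=trend_value)
            out[f"Component{j}_prc{int(p)}_frac1"] = frac1
            out[f"Component{j}_prc{int(p)}_time-trend"] = slope
    return out


def assemble_features(
    percentile_trends: pd.DataFrame,
    adc_trends: pd.DataFrame,
    clinical: pd.DataFrame,
) -> FeatureTable:
    """Join the three per-patient sources and standardize.

    ``percentile_trends``: patients x decomposition parameters;
    ``adc_trends``: patients x [ADC_frac1, ADC_time-trend];
    ``clinical``: patients x [age, gtv_volume_cm3,
    time_diagnosis_to_rt_months, sex_male, ps_1plus, recurrence]
    (binary columns already 0/1 or boolean).

    Every patient must appear in all three sources.  Continuous columns
    (everything except the binary clinical indicators) are standardized by
    the cohort mean and SD; zero-SD columns raise.
    """
    frames = {"decomposition": percentile_trends, "adc": adc_trends, "clinical": clinical}
    patients = None
    for name, df in frames.items():
        ids = set(map(str, df.index))
        patients = ids if patients is None else patients
        if ids != patients:
            missing = sorted(patients.symmetric_difference(ids))
            raise ValueError(f"patient sets differ between sources ({name}): {missing}")
    merged = pd.concat(
        [df.set_axis([str(i) for i in df.index]) for df in frames.values()], axis=1
    )
    merged = merged.sort_index()
    binary = [c for c in CLINICAL_BINARY if c in merged.columns]
    continuous = [c for c in merged.columns if c not in binary]

    means: dict[str, float] = {}
    stds: dict[str, float] = {}
    out = merged.copy()
    for col in continuous:
        x = merged[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(x)):
            raise ValueError(f"non-finite values in feature column '{col}'")
        mu, sd = float(x.mean()), float(x.std(ddof=1)) if x.size > 1 else 0.0
        if not sd > 0:
            raise ValueError(
                f"zero standard deviation in column '{col}'; cannot standardize "
                "(cohort too small or degenerate)"
            )
        out[col] = (x - mu) / sd
        means[col], stds[col] = mu, sd
    for col in binary:
        vals = merged[col].astype(float)
        if not set(np.unique(vals)) <= {0.0, 1.0}:
            raise ValueError(f"binary column '{col}' must be coded 0/1")
        out[col] = vals
    out.index.name = "patient_id"
    return FeatureTable(data=out, means=means, stds=stds)
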