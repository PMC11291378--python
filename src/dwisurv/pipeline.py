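"""End-to-end analysis pipeline.

Chains the stages on an in-memory cohort (synthetic or loaded from disk):

1. preprocessing — slice cross-talk smoothing, 5 mm GTV margin;
2. ADC maps and their median time-trend per patient;
3. pooled-matrix msNMF decomposition (fitted on the patients sharing the
   primary b-grid, projected onto everyone) and percentile time-trends;
4. feature assembly (12 decomposition + 2 ADC + 6 clinical, standardized);
5. cohort Kaplan-Meier / reverse Kaplan-Meier summaries;
6. bootstrap cross-validated best-subset Cox selection, with optional
   bootstrap CIs and risk-group calibration.

Outputs (feature table CSV, selection JSON, survival summaries) are
written with fixed numeric formatting so identical inputs and seed yield
byte-identical files.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adc import adc_trend, median_adc_series
from .data import ComponentSet
from .features import FeatureTable, assemble_features, decomposition_features
from .msnmf import build_pooled_matrix, fit_msnmf, project_weights, variance_explained
from .preprocess import crosstalk_correct, dilate_mask
from .selection import CalibrationResult, SelectionResult, best_subset_search, calibration, univariable_screen
from .survival import KMResult, km, reverse_km
from .synthetic import SyntheticCohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_outputs"]

#: two-b-value ADC conventions per acquisition grid
DEFAULT_ADC_PAIRS = {
    (0.0, 30.0, 80.0, 150.0, 500.0): (150.0, 500.0),
    (0.0, 20.0, 60.0, 100.0, 300.0, 800.0, 1000.0): (300.0, 800.0),
    (0.0, 20.0, 60.0, 100.0, 300.0): (100.0, 300.0),
}


@dataclass
class PipelineConfig:
    crosstalk: bool = True
    margin_mm: float = 5.0
    n_components: int = 3
    variance_explained_ks: tuple[int, ...] = (2, 3, 4)
    nmf_max_iter: int = 500
    nmf_tol: float = 1e-8
    nmf_restarts: int = 10
    percentiles: tuple[float, ...] = (10, 90)
    max_subset_size: int = 3
    n_outer: int = 50
    compute_ci: bool = False
    n_boot_ci: int = 2000
    ties: str = "breslow"
    cv_loglik: str = "oob"
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("variance_explained_ks", "percentiles"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class PipelineResult:
    feature_table: FeatureTable
    selection: SelectionResult
    km_result: KMResult
    followup: KMResult
    variance_explained: dict[int, float]
    components: ComponentSet
    calibration: CalibrationResult | None = None
    univariable: pd.DataFrame | None = None
    survival: pd.DataFrame | None = None


def _adc_pair_for(b_values: np.ndarray) -> tuple[float, float]:
    key = tuple(float(b) for b in b_values)
    if key in DEFAULT_ADC_PAIRS:
        return DEFAULT_ADC_PAIRS[key]
    pair = (float(b_values[-2]), float(b_values[-1]))
    logger.warning("no ADC b-pair convention for grid %s; using %s", key, pair)
    return pair


def run_pipeline(cohort: SyntheticCohort, config: PipelineConfig | None = None) -> PipelineResult:
    cfg = config or PipelineConfig()
    pids = sorted(cohort.fractions)

    # ---------------------------------------------------------- preprocess
    fractions = {
        pid: [crosstalk_correct(f) for f in fr] if cfg.crosstalk else list(fr)
        for pid, fr in cohort.fractions.items()
    }
    analysis_masks = {
        pid: dilate_mask(cohort.masks[pid], cfg.margin_mm) for pid in pids
    }

    # ----------------------------------------------------------------- ADC
    adc_features = {}
    for pid in pids:
        b = fractions[pid][0].b_values
        b_low, b_high = _adc_pair_for(b)
        series = median_adc_series(
            fractions[pid], [analysis_masks[pid]] * len(fractions[pid]), b_low, b_high
        )
        frac1, slope = adc_trend(series)
        adc_features[pid] = {"ADC_frac1": frac1, "ADC_time-trend": slope}
    adc_df = pd.DataFrame(adc_features).T

    # --------------------------------------------------------------- msNMF
    grids = Counter(tuple(float(b) for b in fractions[pid][0].b_values) for pid in pids)
    primary_grid = np.asarray(grids.most_common(1)[0][0])
    seq1 = [
        pid for pid in pids
        if np.array_equal(fractions[pid][0].b_values, primary_grid)
    ]
    studies = [(f, analysis_masks[pid]) for pid in seq1 for f in fractions[pid]]
    pooled = build_pooled_matrix(studies)
    ve: dict[int, float] = {}
    for k in sorted(set(cfg.variance_explained_ks) | {cfg.n_components}):
        comps_k = fit_msnmf(
            pooled, k, max_iter=cfg.nmf_max_iter, tol=cfg.nmf_tol,
            n_restarts=cfg.nmf_restarts, seed=cfg.seed,
        )
        ve[k] = variance_explained(pooled, comps_k)
        if k == cfg.n_components:
            components = comps_k
    components.fit_variance_explained = dict(ve)

    decomp_features = {}
    for pid in pids:
        wmaps = [
            project_weights(f, analysis_masks[pid], components) for f in fractions[pid]
        ]
        decomp_features[pid] = decomposition_features(
            wmaps, analysis_masks[pid], percentiles=cfg.percentiles
        )
    decomp_df = pd.DataFrame(decomp_features).T

    # ------------------------------------------------------------ features
    clinical = cohort.clinical.copy()
    # the GTV-volume covariate is the unexpanded pre-plan volume
    clinical["gtv_volume_cm3"] = [cohort.masks[p].volume_cm3 for p in clinical.index]
    table = assemble_features(decomp_df, adc_df, clinical)

    # ------------------------------------------------------------ survival
    surv = cohort.survival.loc[table.data.index]
    km_res = km(surv)
    followup = reverse_km(surv)

    # ----------------------------------------------------------- selection
    selection = best_subset_search(
        table,
        surv,
        max_subset_size=cfg.max_subset_size,
        n_outer=cfg.n_outer,
        seed=cfg.seed,
        ties=cfg.ties,
        cv_loglik=cfg.cv_loglik,
        compute_ci=cfg.compute_ci,
        n_boot_ci=cfg.n_boot_ci,
    )
    calib = None
    try:
        calib = calibration(selection.final_model, table, surv)
    except ValueError as exc:
        logger.warning("calibration skipped: %s", exc)
    uni = univariable_screen(table, surv, ties=cfg.ties)
    return PipelineResult(
        feature_table=table,
        selection=selection,
        km_result=km_res,
        followup=followup,
        variance_explained=ve,
        components=components,
        calibration=calib,
        univariable=uni,
        survival=surv,
    )


def write_outputs(result: PipelineResult, outdir) -> dict[str, Path]:
    """Write deterministic text outputs; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["features"] = outdir / "features.csv"
    result.feature_table.to_csv(paths["features"], outdir / "standardization.json")
    paths["standardization"] = outdir / "standardization.json"
    paths["selection"] = outdir / "selection.json"
    def _num(v):
        v = float(v)
        return v if np.isfinite(v) else None  # "not reached"

    payload = result.selection.to_dict()
    payload["median_os_months"] = _num(result.km_result.median)
    payload["median_os_ci_months"] = [_num(v) for v in result.km_result.median_ci]
    payload["median_followup_months"] = _num(result.followup.median)
    payload["variance_explained"] = {
        str(k): float(v) for k, v in sorted(result.variance_explained.items())
    }
    paths["selection"].write_text(json.dumps(payload, indent=2, sort_keys=True))
    paths["components"] = outdir / "components.json"
    result.components.to_json(paths["components"])
    if result.univariable is not None:
        paths["univariable"] = outdir / "univariable.csv"
        result.univariable.to_csv(paths["univariable"], float_format="%.12g")
    return paths
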