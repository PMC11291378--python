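"""Synthetic longitudinal DWI cohorts with known ground truth.

Real MR-Linac DWI and survival records of this kind are not publicly
shareable, so every downstream stage is exercised on simulated cohorts
whose generating truth is known: decay components, per-voxel weight
fields, per-fraction weight drift, and the proportional-hazards link
between imaging features and survival.

The generative model per voxel is the mixture assumed by the
decomposition: ``S(b) = s0 * sum_j w_j * C_j(b)`` plus Gaussian (optionally
Rician) noise, with smooth low-frequency spatial weight fields inside an
ellipsoidal tumour mask and multiplicative per-fraction drift of the
weights.  Survival times are drawn from an exponential proportional-
hazards model on standardized ground-truth imaging features, with
independent exponential censoring.

Defaults emulate the study conditions: 45 patients (39 on the 5-point
b-grid {0,30,80,150,500} s/mm^2, 6 on a second sequence), 5 fractions of
which two patients miss some, three components (slow decay, fast decay,
b=0-driven spike), a median survival of 15.5 months at the cohort-average
feature value, and hazard ratio 2 per SD for the two linked features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .data import ComponentSet, DWIFraction, GTVMask

logger = logging.getLogger(__name__)

__all__ = [
    "make_components",
    "GroundTruth",
    "CohortConfig",
    "SyntheticCohort",
    "simulate_fraction",
    "simulate_cohort",
    "simulate_survival_features",
]


def make_components(
    k: int,
    b_values,
    decay_rates,
    spike_at_b0: bool = False,
    spike_floor: float = 0.01,
) -> ComponentSet:
    """Exponential decay components, optionally plus a b=0-driven spike.

    Rows are ``exp(-b * D_j)`` (unit value at the smallest b), one per decay
    rate in mm^2/s; with ``spike_at_b0`` an extra component equal to 1 at
    the first b-value and ``spike_floor`` elsewhere is appended.  Rows are
    ordered slowest decay first.
    """
    b = np.asarray(b_values, dtype=float)
    if b.ndim != 1 or (b.size > 1 and np.any(np.diff(b) <= 0)):
        raise ValueError("b_values must be strictly increasing")
    rates = np.asarray(decay_rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("decay rates must be non-negative")
    if rates.size > 1 and np.any(np.diff(rates) <= 0):
        raise ValueError("decay rates must be strictly increasing")
    expected = rates.size + (1 if spike_at_b0 else 0)
    if k != expected:
        raise ValueError(
            f"k={k} inconsistent with {rates.size} decay rates"
            + (" plus a spike component" if spike_at_b0 else "")
        )
    rows = [np.exp(-(b - b[0]) * d) for d in rates]
    if spike_at_b0:
        spike = np.full(b.size, float(spike_floor))
        spike[0] = 1.0
        rows.append(spike)
    C = np.vstack(rows)
    order = np.argsort(-np.trapezoid(C, b, axis=1), kind="stable")
    return ComponentSet(components=C[order], b_values=b)


@dataclass
class GroundTruth:
    """Generating truth of a synthetic cohort.

    ``weight_fields[pid]`` is the fraction-1 weight field (nx, ny, nz, k);
    ``drift_slopes[pid]`` holds per-component relative drifts per fraction,
    so the field at fraction f is ``base * max(0, 1 + slope*(f-1))`` —
    non-negative at every fraction by construction.
    """

    components: ComponentSet
    weight_fields: dict[str, np.ndarray]
    drift_slopes: dict[str, np.ndarray]
    beta_true: dict[str, float]
    noise_sigma: float
    seed: int | None
    masks: dict[str, GTVMask] = field(default_factory=dict)
    b_values_by_patient: dict[str, np.ndarray] = field(default_factory=dict)
    s0: float = 100.0
    noise_model: str = "gaussian"

    def weights_at_fraction(self, patient: str, fraction: int) -> np.ndarray:
        base = self.weight_fields[patient]
        drift = self.drift_slopes[patient]
        factors = np.clip(1.0 + drift * (fraction - 1), 0.0, None)
        return base * factors[None, None, None, :]


def simulate_fraction(
    truth: GroundTruth,
    patient: str,
    fraction: int,
    s0: float | None = None,
    seed: int | None = None,
) -> DWIFraction:
    """One fraction's noisy 4D DWI volume from the generating truth."""
    if patient not in truth.weight_fields:
        raise KeyError(f"unknown patient '{patient}'")
    if fraction < 1:
        raise ValueError("fraction is 1-based")
    s0 = truth.s0 if s0 is None else float(s0)
    b = truth.b_values_by_patient.get(patient, truth.components.b_values)
    comps = (
        truth.components
        if np.array_equal(b, truth.components.b_values)
        else truth.components.interpolated_to(b)
    )
    w = truth.weights_at_fraction(patient, fraction)
    clean = s0 * np.tensordot(w, comps.components, axes=(3, 0))
    rng = np.random.default_rng(seed)
    if truth.noise_sigma > 0:
        if truth.noise_model == "rician":
            n1 = rng.normal(0.0, truth.noise_sigma, clean.shape)
            n2 = rng.normal(0.0, truth.noise_sigma, clean.shape)
            signal = np.sqrt((clean + n1) ** 2 + n2**2)
        else:
            signal = clean + rng.normal(0.0, truth.noise_sigma, clean.shape)
    else:
        signal = clean
    mask = truth.masks.get(patient)
    spacing = mask.spacing if mask is not None else (1.0, 1.0, 1.0)
    return DWIFraction(
        signal=signal,
        b_values=b,
        spacing=spacing,
        fraction_index=fraction,
        patient_id=patient,
    )


@dataclass
class CohortConfig:
    """Study-condition defaults for the synthetic cohort generator."""

    n_patients: int = 45
    n_fractions: int = 5
    n_sequence2: int = 6
    grid_shape: tuple[int, int, int] = (24, 24, 12)
    spacing: tuple[float, float, float] = (3.0, 3.0, 5.0)
    b_values: tuple[float, ...] = (0.0, 30.0, 80.0, 150.0, 500.0)
    #: second-sequence grid kept inside the primary b-range so fitted
    #: components can be interpolated (never extrapolated) onto it
    b_values_seq2: tuple[float, ...] = (0.0, 20.0, 60.0, 100.0, 300.0)
    decay_rates: tuple[float, ...] = (0.8e-3, 3.0e-3)
    spike_at_b0: bool = True
    s0: float = 100.0
    noise_sigma: float = 5.0
    noise_model: str = "gaussian"
    #: mean weight level per component (slow, fast, spike) and their
    #: within-GTV heterogeneity (SD as a fraction of the mean)
    weight_means: tuple[float, ...] = (0.5, 0.35, 0.15)
    weight_cv: float = 0.4
    smoothness_voxels: float = 1.5
    drift_sd: float = 0.04
    mean_gtv_volume_cm3: float = 21.6
    sd_gtv_volume_cm3: float = 15.8
    median_os_months: float = 15.5
    censor_rate: float = 0.2
    hr_per_sd: float = 2.0
    n_patients_with_missing: int = 2


@dataclass
class SyntheticCohort:
    fractions: dict[str, list[DWIFraction]]
    masks: dict[str, GTVMask]
    clinical: pd.DataFrame
    survival: pd.DataFrame
    truth: GroundTruth


def _ellipsoid_mask(shape, spacing, volume_cm3, rng) -> np.ndarray:
    """Ellipsoid of roughly the requested volume, centred with jitter."""
    target_mm3 = volume_cm3 * 1000.0
    r = (3.0 * target_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    semi = r * rng.uniform(0.75, 1.3, 3)
    semi *= (target_mm3 / (4.0 / 3.0 * np.pi * np.prod(semi))) ** (1.0 / 3.0)
    centre = (np.array(shape) - 1) / 2.0 + rng.uniform(-1.5, 1.5, 3)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    dist2 = sum(
        ((g - c) * sp / a) ** 2 for g, c, sp, a in zip(grids, centre, spacing, semi)
    )
    return dist2 <= 1.0


def _smooth_field(shape, mean, cv, smooth, rng) -> np.ndarray:
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), smooth)
    raw /= raw.std() if raw.std() > 0 else 1.0
    return np.clip(mean * (1.0 + cv * raw), 0.0, None)


def simulate_cohort(
    n_patients: int | None = None,
    n_fractions: int | None = None,
    config: CohortConfig | None = None,
    censor_rate: float | None = None,
    seed: int | None = None,
) -> SyntheticCohort:
    """Generate a full synthetic cohort: volumes, masks, clinical and
    survival tables, plus the generating truth.

    The hazard of patient i is ``h_i = h0 * exp(beta^T x_i)`` with ``x``
    the standardized ground-truth imaging features (baseline 90th
    percentile of the fast component's weights, and the slow component's
    drift slope) and ``h0 = ln 2 / median_os``.  Censoring is independent
    exponential with rate ``h0 * r / (1 - r)``, giving a censored fraction
    of about ``r`` under the null.
    """
    cfg = config or CohortConfig()
    if n_patients is not None:
        cfg.n_patients = n_patients
    if n_fractions is not None:
        cfg.n_fractions = n_fractions
    if censor_rate is not None:
        cfg.censor_rate = censor_rate
    if config is None and n_patients is not None:
        # default config scaled down for small demo cohorts
        cfg.n_sequence2 = min(cfg.n_sequence2, cfg.n_patients // 4)
        cfg.n_patients_with_missing = min(cfg.n_patients_with_missing, cfg.n_patients)
    if cfg.n_fractions < 2:
        raise ValueError("need at least two fractions for time-trends")
    if not 0.0 <= cfg.censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    if cfg.n_sequence2 > cfg.n_patients:
        raise ValueError("n_sequence2 may not exceed n_patients")

    rng = np.random.default_rng(seed)
    k = len(cfg.decay_rates) + (1 if cfg.spike_at_b0 else 0)
    components = make_components(
        k, np.asarray(cfg.b_values), cfg.decay_rates, spike_at_b0=cfg.spike_at_b0
    )
    pids = [f"P{i + 1:03d}" for i in range(cfg.n_patients)]
    seq2 = set(pids[cfg.n_patients - cfg.n_sequence2:]) if cfg.n_sequence2 else set()

    masks: dict[str, GTVMask] = {}
    weight_fields: dict[str, np.ndarray] = {}
    drift_slopes: dict[str, np.ndarray] = {}
    b_by_patient: dict[str, np.ndarray] = {}
    volumes = {}
    for pid in pids:
        vol = float(
            np.clip(
                rng.normal(cfg.mean_gtv_volume_cm3, cfg.sd_gtv_volume_cm3), 3.0, 80.0
            )
        )
        mask = _ellipsoid_mask(cfg.grid_shape, cfg.spacing, vol, rng)
        masks[pid] = GTVMask(mask, cfg.spacing, margin_applied=0.0)
        volumes[pid] = masks[pid].volume_cm3
        fields = np.stack(
            [
                _smooth_field(cfg.grid_shape, m, cfg.weight_cv, cfg.smoothness_voxels, rng)
                for m in cfg.weight_means
            ],
            axis=-1,
        )
        weight_fields[pid] = fields
        drift_slopes[pid] = rng.normal(0.0, cfg.drift_sd, k)
        b_by_patient[pid] = np.asarray(
            cfg.b_values_seq2 if pid in seq2 else cfg.b_values, dtype=float
        )

    truth = GroundTruth(
        components=components,
        weight_fields=weight_fields,
        drift_slopes=drift_slopes,
        beta_true={},
        noise_sigma=cfg.noise_sigma,
        seed=seed,
        masks=masks,
        b_values_by_patient=b_by_patient,
        s0=cfg.s0,
        noise_model=cfg.noise_model,
    )

    # --- survival linked to ground-truth imaging features ------------------
    base_feat = []
    for pid in pids:
        w2 = weight_fields[pid][..., 1][masks[pid].mask]
        base_feat.append(
            [float(np.percentile(w2, 90)), float(drift_slopes[pid][0])]
        )
    x = np.asarray(base_feat)
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    beta = np.array([np.log(cfg.hr_per_sd), -np.log(cfg.hr_per_sd)])
    truth.beta_true = {
        "Component2_prc90_frac1": float(beta[0]),
        "Component1_prc10_time-trend": float(beta[1]),
    }
    h0 = np.log(2.0) / cfg.median_os_months
    hazard = h0 * np.exp(x @ beta)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censor_rate > 0:
        c_rate = h0 * cfg.censor_rate / (1.0 - cfg.censor_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=cfg.n_patients)
    else:
        t_cens = np.full(cfg.n_patients, np.inf)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    survival = pd.DataFrame(
        {"time_months": time, "event": event.astype(int)}, index=pids
    )
    survival.index.name = "patient_id"

    # --- clinical table (Table-1-like distributions) -----------------------
    clinical = pd.DataFrame(
        {
            "age": np.clip(rng.normal(67.5, 10.1, cfg.n_patients), 40.0, 90.0),
            "gtv_volume_cm3": [volumes[p] for p in pids],
            "time_diagnosis_to_rt_months": np.clip(
                rng.lognormal(np.log(6.5), 0.6, cfg.n_patients), 1.0, 36.0
            ),
            "sex_male": (rng.uniform(size=cfg.n_patients) < 0.42).astype(int),
            "ps_1plus": (rng.uniform(size=cfg.n_patients) < 0.62).astype(int),
            "recurrence": (rng.uniform(size=cfg.n_patients) < 0.18).astype(int),
        },
        index=pids,
    )
    clinical.index.name = "patient_id"

    # --- image volumes per fraction ---------------------------------------
    kept_fractions: dict[str, list[int]] = {p: list(range(1, cfg.n_fractions + 1)) for p in pids}
    if cfg.n_patients_with_missing and cfg.n_patients >= cfg.n_patients_with_missing:
        chosen = rng.choice(cfg.n_patients, cfg.n_patients_with_missing, replace=False)
        for rank, ci in enumerate(np.sort(chosen)):
            keep = max(2, min(cfg.n_fractions, 2 + rank))
            kept = np.sort(rng.choice(cfg.n_fractions, keep, replace=False)) + 1
            kept_fractions[pids[ci]] = [int(f) for f in kept]

    child_seeds = np.random.SeedSequence(seed).spawn(cfg.n_patients)
    fractions: dict[str, list[DWIFraction]] = {}
    for pid, ss in zip(pids, child_seeds):
        frac_seeds = ss.spawn(cfg.n_fractions)
        fractions[pid] = [
            simulate_fraction(
                truth, pid, f, seed=int(frac_seeds[f - 1].generate_state(1)[0] % (2**31))
            )
            for f in kept_fractions[pid]
        ]
    return SyntheticCohort(
        fractions=fractions,
        masks=masks,
        clinical=clinical,
        survival=survival,
        truth=truth,
    )


def simulate_survival_features(
    n: int,
    n_features: int = 1,
    beta=None,
    censor_rate: float = 0.2,
    baseline_hazard: float = np.log(2.0) / 15.5,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature-level survival cohort: iid standard-normal features and an
    exponential proportional-hazards outcome.

    Returns ``(X, survival)`` where X has columns ``f01..f<n_features>``
    and survival has ``time_months``/``event``.  ``beta`` may be a scalar
    (applied to the first feature), an array, or None (all-null).
    """
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, n_features))
    b = np.zeros(n_features)
    if beta is not None:
        beta = np.atleast_1d(np.asarray(beta, dtype=float))
        b[: beta.size] = beta
    hazard = baseline_hazard * np.exp(X @ b)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        c_rate = baseline_hazard * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    cols = [f"f{i + 1:02d}" for i in range(n_features)]
    ids = [f"S{i + 1:04d}" for i in range(n)]
    Xdf = pd.DataFrame(X, columns=cols, index=ids)
    ydf = pd.DataFrame({"time_months": time, "event": event}, index=ids)
    return Xdf, ydf
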