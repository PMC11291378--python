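"""Core data containers for longitudinal multi-b-value DWI studies.

A *fraction* is one radiotherapy treatment session; a diffusion-weighted
scan is acquired before each, giving a 4D signal volume indexed
``(x, y, z, b)`` over a fixed b-value grid (s/mm^2).  The gross tumour
volume (GTV) is a 3D boolean mask on the same grid, usually analysed with
a safety margin.

Volumes round-trip through NIfTI (via :mod:`nibabel`) with a JSON sidecar
holding the b-value grid, so external tools can read them directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["DWIFraction", "GTVMask", "ComponentSet", "WeightMap"]


def _validate_b_grid(b_values: np.ndarray) -> np.ndarray:
    b = np.asarray(b_values, dtype=float)
    if b.ndim != 1 or b.size < 1:
        raise ValueError("b_values must be a non-empty 1D array")
    if np.any(b < 0):
        raise ValueError("b_values must be non-negative")
    if b.size > 1 and np.any(np.diff(b) <= 0):
        raise ValueError("b_values must be strictly increasing")
    return b


@dataclass
class DWIFraction:
    """One fraction's diffusion-weighted scan.

    Parameters
    ----------
    signal : ndarray, shape (nx, ny, nz, n_b)
        Signal volume per b-value, arbitrary units.
    b_values : ndarray, shape (n_b,)
        Diffusion weightings in s/mm^2, strictly increasing.
    spacing : tuple of 3 floats
        Voxel size in mm per spatial axis.
    fraction_index : int
        1-based treatment fraction number.
    patient_id : str
    """

    signal: np.ndarray
    b_values: np.ndarray
    spacing: tuple[float, float, float]
    fraction_index: int
    patient_id: str

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.b_values = _validate_b_grid(self.b_values)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, b)")
        if self.signal.shape[3] != self.b_values.size:
            raise ValueError(
                f"signal has {self.signal.shape[3]} b-volumes but "
                f"{self.b_values.size} b-values were given"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be 3 positive lengths (mm)")
        if int(self.fraction_index) < 1:
            raise ValueError("fraction_index is 1-based and must be >= 1")
        self.fraction_index = int(self.fraction_index)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    def volume_at_b(self, b: float) -> np.ndarray:
        """Return the 3D volume acquired at b-value ``b`` (must be on the grid)."""
        idx = np.flatnonzero(np.isclose(self.b_values, b))
        if idx.size == 0:
            raise ValueError(f"b={b} not in grid {self.b_values.tolist()}")
        return self.signal[..., idx[0]]

    # ------------------------------------------------------------------ I/O
    def to_nifti(self, path: str | Path) -> None:
        """Write as 4D NIfTI plus a ``.json`` sidecar with b-values."""
        path = Path(path)
        affine = np.diag([*self.spacing, 1.0])
        nib.save(nib.Nifti1Image(self.signal, affine), str(path))
        sidecar = {
            "b_values": self.b_values.tolist(),
            "fraction_index": self.fraction_index,
            "patient_id": self.patient_id,
        }
        path.with_suffix("").with_suffix(".json").write_text(
            json.dumps(sidecar, indent=2)
        )

    @classmethod
    def from_nifti(cls, path: str | Path) -> "DWIFraction":
        path = Path(path)
        img = nib.load(str(path))
        sidecar = json.loads(path.with_suffix("").with_suffix(".json").read_text())
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(
            signal=np.asanyarray(img.dataobj, dtype=float),
            b_values=np.asarray(sidecar["b_values"], dtype=float),
            spacing=spacing,
            fraction_index=int(sidecar.get("fraction_index", 1)),
            patient_id=str(sidecar.get("patient_id", path.stem)),
        )


@dataclass
class GTVMask:
    """Gross tumour volume mask on the DWI grid.

    ``margin_applied`` records the isotropic physical margin (mm) already
    added to the clinical delineation; 0 for the raw GTV.
    """

    mask: np.ndarray
    spacing: tuple[float, float, float]
    margin_applied: float = 0.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be 3 positive lengths (mm)")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_cm3(self) -> float:
        return self.n_voxels * float(np.prod(self.spacing)) / 1000.0

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag([*self.spacing, 1.0])
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, margin_applied: float = 0.0) -> "GTVMask":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(
            mask=np.asanyarray(img.dataobj) > 0,
            spacing=spacing,
            margin_applied=margin_applied,
        )


@dataclass
class ComponentSet:
    """A set of k cohort-level decay components over a b-value grid.

    Rows are ordered slowest-decaying first (C1 ... Ck) and normalised to
    value 1 at the smallest b-value; per-voxel weights absorb the scale.
    """

    components: np.ndarray  # (k, n_b)
    b_values: np.ndarray
    fit_variance_explained: dict[int, float] = field(default_factory=dict)
    normalization: str = "unit_at_min_b"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.components = np.atleast_2d(np.asarray(self.components, dtype=float))
        self.b_values = _validate_b_grid(self.b_values)
        if self.components.shape[1] != self.b_values.size:
            raise ValueError("component rows must match the b-value grid length")
        if np.any(self.components < -1e-10):
            raise ValueError("components must be non-negative")

    @property
    def k(self) -> int:
        return self.components.shape[0]

    def interpolated_to(self, b_values: np.ndarray) -> "ComponentSet":
        """Linearly interpolate components onto another b grid (no extrapolation)."""
        b_new = _validate_b_grid(b_values)
        if b_new.min() < self.b_values.min() - 1e-9 or b_new.max() > self.b_values.max() + 1e-9:
            raise ValueError(
                "requested b-values extend beyond the fitted component grid "
                f"[{self.b_values.min()}, {self.b_values.max()}]; cannot extrapolate"
            )
        comps = np.vstack(
            [np.interp(b_new, self.b_values, row) for row in self.components]
        )
        return ComponentSet(
            comps, b_new, dict(self.fit_variance_explained), self.normalization, self.seed
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "b_values": self.b_values.tolist(),
            "components": self.components.tolist(),
            "fit_variance_explained": {str(k): v for k, v in self.fit_variance_explained.items()},
            "normalization": self.normalization,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ComponentSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            components=np.asarray(payload["components"], dtype=float),
            b_values=np.asarray(payload["b_values"], dtype=float),
            fit_variance_explained={
                int(k): float(v) for k, v in payload.get("fit_variance_explained", {}).items()
            },
            normalization=payload.get("normalization", "unit_at_min_b"),
            seed=payload.get("seed"),
        )


@dataclass
class WeightMap:
    """Per-voxel non-negative component weights for one fraction.

    ``weights`` is ``(nx, ny, nz, k)``; voxels outside the analysed mask
    are NaN so within-mask statistics cannot silently include them.
    """

    weights: np.ndarray
    component_ref: ComponentSet
    fraction_index: int
    patient_id: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 4:
            raise ValueError("weights must be 4D (x, y, z, k)")
        if self.weights.shape[3] != self.component_ref.k:
            raise ValueError("weight channels must match the number of components")
        finite = self.weights[np.isfinite(self.weights)]
        if finite.size and finite.min() < -1e-10:
            raise ValueError("weights must be non-negative")

    def component_volume(self, j: int) -> np.ndarray:
        """3D weight map of component ``j`` (1-based, as in W1..Wk)."""
        if not 1 <= j <= self.component_ref.k:
            raise ValueError(f"component index {j} out of range 1..{self.component_ref.k}")
        return self.weights[..., j - 1]

    def to_nifti(self, path: str | Path, spacing: tuple[float, float, float]) -> None:
        affine = np.diag([*spacing, 1.0])
        nib.save(nib.Nifti1Image(self.weights, affine), str(path))
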