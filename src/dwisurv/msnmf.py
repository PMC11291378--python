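"""Monotonous-slope non-negative matrix factorization (msNMF) of DWI decay data.

Multi-b-value DWI signals are modelled as positive mixtures of a small
number of cohort-level decay components: ``X ~ W @ C`` with voxel weights
``W >= 0`` and each component row constrained to the cone of physically
admissible decay curves — non-negative, non-increasing in b, with
non-decreasing (monotonous) slope, i.e. convex in b.  One component set is
fitted to the pooled voxel-by-b matrix of the whole cohort and then
projected (by non-negative least squares) onto every voxel of every
patient and fraction to obtain weight maps.

Algorithm
---------
Alternating minimisation of ``||X - W C||_F^2``:

* weight step — exact NNLS per voxel row (vectorised over voxels by
  enumerating active sets, exact for the small k used here);
* component step — HALS-style row updates: for each component, the
  unconstrained row optimum is a weighted residual average, and the cone
  constraint enters as an exact Euclidean projection.

The projection is computed exactly by re-parametrising the cone as the
non-negative span of hinge functions ``max(b_j - b, 0)`` plus a constant,
reducing it to a small NNLS problem.  Both half-steps solve their
subproblem exactly, so the objective is non-increasing by construction.

Scale/permutation ambiguity is fixed by normalising components to 1 at the
smallest b-value (weights absorb the scale) and ordering rows by area
under the curve, slowest decay first (C1).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _scipy_nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .data import ComponentSet, DWIFraction, GTVMask, WeightMap

logger = logging.getLogger(__name__)

__all__ = [
    "PooledMatrix",
    "MonotoneSlopeNMF",
    "build_pooled_matrix",
    "fit_msnmf",
    "variance_explained",
    "project_weights",
    "nnls_weights",
    "project_decay_cone",
]


# --------------------------------------------------------------------------
# Exact batched NNLS for small k
# --------------------------------------------------------------------------

def nnls_weights(components: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Exact non-negative least-squares weights of each row of ``X`` on ``components``.

    Solves ``argmin_{w>=0} ||x - C^T w||`` for every row x.  For small k
    (<= 10) all candidate active sets are enumerated and solved in batch:
    the NNLS optimum restricted to its support satisfies that support's
    unconstrained normal equations, so the best feasible candidate over
    all supports is the exact solution.
    """
    C = np.atleast_2d(np.asarray(components, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    k = C.shape[0]
    if X.shape[1] != C.shape[1]:
        raise ValueError("X and components disagree on the number of b-values")
    if k > 10:  # enumeration blows up; fall back to per-row scipy
        return np.vstack([_scipy_nnls(C.T, x)[0] for x in X])
    G = C @ C.T
    F = X @ C.T
    x2 = np.einsum("ij,ij->i", X, X)
    best_r2 = x2.copy()
    W = np.zeros((X.shape[0], k))
    for size in range(1, k + 1):
        for support in itertools.combinations(range(k), size):
            S = np.array(support)
            try:
                inv_g = np.linalg.inv(G[np.ix_(S, S)])
            except np.linalg.LinAlgError:
                continue
            F_s = F[:, S]
            w_s = F_s @ inv_g  # symmetric inverse: solves the normal equations
            feasible = np.all(w_s >= -1e-12, axis=1)
            if not feasible.any():
                continue
            # at the restricted LS solution, ||r||^2 = ||x||^2 - w.F
            r2 = x2 - np.einsum("ij,ij->i", w_s, F_s)
            better = feasible & (r2 < best_r2 - 1e-12 * np.maximum(x2, 1.0))
            if better.any():
                best_r2[better] = r2[better]
                W[better] = 0.0
                W[np.ix_(better, S)] = np.clip(w_s[better], 0.0, None)
    return W


# --------------------------------------------------------------------------
# Exact projection onto the admissible-decay cone
# --------------------------------------------------------------------------

def _hinge_basis(b: np.ndarray) -> np.ndarray:
    """Generators of the cone of non-negative, non-increasing, convex curves.

    Columns: a constant, plus hinges ``max(b_j - b, 0)`` for j = 2..n.  Every
    admissible curve on the grid is a non-negative combination of these
    (piecewise-linear representation by its kinks), and conversely.
    """
    n = b.size
    B = np.empty((n, n))
    B[:, 0] = 1.0
    for j in range(1, n):
        B[:, j] = np.maximum(b[j] - b, 0.0)
    return B


def project_decay_cone(y: np.ndarray, b_values: np.ndarray) -> np.ndarray:
    """Euclidean projection of a curve onto the admissible-decay cone.

    The cone is {c : c >= 0, c non-increasing in b, discrete slope
    non-decreasing in b}.  Implemented exactly as NNLS in the hinge basis;
    idempotent by construction.
    """
    b = np.asarray(b_values, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.shape != b.shape:
        raise ValueError("curve and b grid lengths differ")
    B = _hinge_basis(b)
    alpha, _ = _scipy_nnls(B, y)
    return B @ alpha


def _is_admissible(c: np.ndarray, b: np.ndarray, tol: float = 1e-9) -> bool:
    if np.any(c < -tol):
        return False
    slopes = np.diff(c) / np.diff(b)
    return bool(np.all(slopes <= tol) and np.all(np.diff(slopes) >= -tol))


# --------------------------------------------------------------------------
# Pooled cohort matrix
# --------------------------------------------------------------------------

@dataclass
class PooledMatrix:
    """All masked GTV voxels of all patients and fractions, one row per voxel.

    ``provenance`` records (patient_id, fraction_index, x, y, z) per row so
    any row can be traced back to its originating voxel.
    """

    data: np.ndarray
    provenance: pd.DataFrame
    b_values: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.b_values = np.asarray(self.b_values, dtype=float)
        if self.data.shape[1] != self.b_values.size:
            raise ValueError("data columns must match the b-value grid")
        if len(self.provenance) != self.data.shape[0]:
            raise ValueError("provenance must have one row per data row")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    def lookup(self, row: int) -> tuple[str, int, tuple[int, int, int]]:
        rec = self.provenance.iloc[row]
        return (
            str(rec["patient_id"]),
            int(rec["fraction_index"]),
            (int(rec["x"]), int(rec["y"]), int(rec["z"])),
        )


def build_pooled_matrix(
    studies: list[tuple[DWIFraction, GTVMask]],
) -> PooledMatrix:
    """Pool masked voxel signals from many fractions into one matrix.

    All fractions must share one b-value grid; cohorts acquired with a
    different sequence must be filtered out by the caller before pooling
    (their voxels are later projected onto the fitted components instead).
    """
    if not studies:
        raise ValueError("no studies given")
    b0 = studies[0][0].b_values
    rows, prov = [], []
    for fraction, mask in studies:
        if fraction.b_values.size != b0.size or not np.allclose(fraction.b_values, b0):
            raise ValueError(
                "mixed b-value grids in pooled matrix; filter the input to a "
                "single DWI sequence before pooling"
            )
        if mask.mask.shape != fraction.shape:
            raise ValueError("mask and fraction grids differ")
        idx = np.argwhere(mask.mask)
        if idx.size == 0:
            logger.warning(
                "build_pooled_matrix: empty mask for patient %s fraction %d "
                "contributes no rows",
                fraction.patient_id,
                fraction.fraction_index,
            )
            continue
        rows.append(fraction.signal[mask.mask])
        prov.append(
            pd.DataFrame(
                {
                    "patient_id": fraction.patient_id,
                    "fraction_index": fraction.fraction_index,
                    "x": idx[:, 0],
                    "y": idx[:, 1],
                    "z": idx[:, 2],
                }
            )
        )
    if not rows:
        raise ValueError("all masks empty; pooled matrix has no rows")
    return PooledMatrix(
        data=np.vstack(rows),
        provenance=pd.concat(prov, ignore_index=True),
        b_values=b0.copy(),
    )


# --------------------------------------------------------------------------
# The estimator
# --------------------------------------------------------------------------

class MonotoneSlopeNMF(TransformerMixin, BaseEstimator):
    """Constrained NMF with monotonous-slope decay components.

    Parameters
    ----------
    n_components : int
        Number of decay components k (must not exceed the grid length).
    b_values : array-like
        The shared b-value grid (s/mm^2) of the training rows.
    max_iter : int
        Maximum alternating iterations per restart.
    tol : float
        Relative change of the residual norm below which a restart stops.
    n_restarts : int
        Random restarts; the factorization with the lowest residual wins.
    random_state : int or None
        Seed for the restart initialisations.

    Attributes
    ----------
    components_ : ndarray of shape (k, n_b)
        Fitted components, unit value at the smallest b, ordered slowest
        decay first.
    variance_explained_ : float
        ``1 - ||X - W C||_F^2 / ||X||_F^2`` on the training matrix.
    objective_history_ : list of float
        Residual sum of squares per iteration of the winning restart
        (non-increasing).
    n_iter_ : int
    """

    def __init__(
        self,
        n_components: int = 3,
        b_values=None,
        max_iter: int = 500,
        tol: float = 1e-8,
        n_restarts: int = 10,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.b_values = b_values
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.random_state = random_state

    # -------------------------------------------------------------- fitting
    def _init_components(self, b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        b_max = b.max() if b.max() > 0 else 1.0
        rates = np.sort(np.exp(rng.uniform(np.log(0.2 / b_max), np.log(20.0 / b_max),
                                           self.n_components)))
        return np.exp(-np.outer(rates, b))

    def _single_fit(
        self, X: np.ndarray, b: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray, list[float]]:
        C = self._init_components(b, rng)
        W = nnls_weights(C, X)
        R = X - W @ C
        x2 = float(np.einsum("ij,ij->", X, X))
        history = [float(np.einsum("ij,ij->", R, R))]
        for _ in range(self.max_iter):
            W = nnls_weights(C, X)
            R = X - W @ C
            # exact per-component row updates (HALS with cone projection)
            for j in range(self.n_components):
                wj = W[:, j]
                denom = float(wj @ wj)
                if denom < 1e-300:
                    continue  # unused component; leave its curve in place
                y = (R.T @ wj) / denom + C[j]
                c_new = project_decay_cone(y, b)
                R += np.outer(wj, C[j] - c_new)
                C[j] = c_new
            obj = float(np.einsum("ij,ij->", R, R))
            history.append(obj)
            # decrement measured against the data norm: meaningful both when
            # the residual vanishes (noiseless) and when it plateaus (noisy)
            if history[-2] - obj <= self.tol * max(x2, 1e-300):
                break
        return W, C, history

    def fit(self, X, y=None):
        """Fit components to the pooled voxel-by-b matrix ``X``."""
        if isinstance(X, PooledMatrix):
            if self.b_values is None:
                self.b_values = X.b_values
            X = X.data
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.b_values is None:
            raise ValueError("b_values must be provided (constructor or PooledMatrix)")
        b = np.asarray(self.b_values, dtype=float)
        if X.shape[1] != b.size:
            raise ValueError("X columns must match the b-value grid length")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_components > b.size:
            raise ValueError("n_components may not exceed the number of b-values")
        n_neg = int((X < 0).sum())
        if n_neg:
            logger.warning("fit: clipped %d negative entries to 0 before factorization", n_neg)
            X = np.clip(X, 0.0, None)
        if not np.any(X > 0):
            raise ValueError("matrix is all zero; nothing to factorize")

        seeds = np.random.SeedSequence(self.random_state).spawn(max(self.n_restarts, 1))
        best = None
        for ss in seeds:
            W, C, history = self._single_fit(X, b, np.random.default_rng(ss))
            if best is None or history[-1] < best[2][-1]:
                best = (W, C, history)
        W, C, history = best
        C = C.copy()
        W = W.copy()

        # Minimal-cone refinement.  An exact factorization is only unique up
        # to non-negative recombination of the components (the fitted cone
        # may strictly contain the data cone).  Tighten it by absorbing as
        # much of every other component into c_j as weight non-negativity
        # allows: c_j += t*c_i with t = min_rows(w_i / w_j) keeps W C exactly
        # unchanged, keeps W >= 0, and keeps c_j in the (convex) cone.  On
        # noisy data NNLS leaves many exact-zero weights, so t = 0 and this
        # is a no-op; on exact mixture data it recovers the extreme rays of
        # the data cone.
        k = self.n_components
        for _ in range(10):
            moved = False
            for j in range(k):
                support = W[:, j] > 1e-12 * max(float(W[:, j].max()), 1e-300)
                if not support.any():
                    continue
                for i in range(k):
                    if i == j:
                        continue
                    t = float((W[support, i] / W[support, j]).min())
                    if t > 1e-12:
                        C[j] += t * C[i]
                        W[:, i] = np.clip(W[:, i] - t * W[:, j], 0.0, None)
                        moved = True
            if not moved:
                break

        # normalise to 1 at min b and order by area under the curve (slowest first)
        for j in range(C.shape[0]):
            scale = C[j, 0]
            if scale > 1e-12:
                C[j] /= scale
            else:
                logger.warning("fit: component %d vanishes at min(b); left unnormalised", j)
        order = np.argsort(-np.trapezoid(C, b, axis=1), kind="stable")
        C = C[order]

        # refresh the weights against the final components (the last inner
        # half-step updated C after W); exact NNLS can only lower the objective
        W = nnls_weights(C, X)
        R = X - W @ C
        history.append(float(np.einsum("ij,ij->", R, R)))

        self.components_ = C
        self.weights_ = W
        self.objective_history_ = history
        self.n_iter_ = len(history) - 1
        x2 = float(np.einsum("ij,ij->", X, X))
        self.variance_explained_ = 1.0 - history[-1] / x2
        self.b_values_ = b
        return self

    # ---------------------------------------------------------- projection
    def transform(self, X) -> np.ndarray:
        """Non-negative least-squares weights of new rows on the fitted components."""
        if isinstance(X, PooledMatrix):
            X = X.data
        return nnls_weights(self.components_, np.asarray(X, dtype=float))

    def component_set(self) -> ComponentSet:
        """Fitted components packaged with their grid and metadata."""
        return ComponentSet(
            components=self.components_.copy(),
            b_values=self.b_values_.copy(),
            fit_variance_explained={self.n_components: float(self.variance_explained_)},
            seed=self.random_state,
        )


# --------------------------------------------------------------------------
# Module-level wrappers
# --------------------------------------------------------------------------

def fit_msnmf(
    matrix: PooledMatrix,
    k: int,
    max_iter: int = 500,
    tol: float = 1e-8,
    n_restarts: int = 10,
    seed: int | None = None,
) -> ComponentSet:
    """Fit a k-component msNMF to a pooled cohort matrix."""
    est = MonotoneSlopeNMF(
        n_components=k,
        b_values=matrix.b_values,
        max_iter=max_iter,
        tol=tol,
        n_restarts=n_restarts,
        random_state=seed,
    ).fit(matrix)
    return est.component_set()


def variance_explained(matrix: PooledMatrix, components: ComponentSet) -> float:
    """Fraction of the pooled matrix's variance captured by the components.

    ``1 - ||X - W C||_F^2 / ||X||_F^2`` where W is the exact non-negative
    projection of each row onto the components.
    """
    if matrix.b_values.size != components.b_values.size or not np.allclose(
        matrix.b_values, components.b_values
    ):
        raise ValueError("component grid does not match the pooled matrix grid")
    X = np.clip(matrix.data, 0.0, None)
    W = nnls_weights(components.components, X)
    resid = X - W @ components.components
    x2 = float(np.einsum("ij,ij->", X, X))
    if x2 == 0:
        raise ValueError("matrix is all zero")
    return 1.0 - float(np.einsum("ij,ij->", resid, resid)) / x2


def project_weights(
    fraction: DWIFraction, mask: GTVMask, components: ComponentSet
) -> WeightMap:
    """Per-voxel NNLS weights of one fraction on the cohort components.

    If the fraction was acquired on a different b grid (other DWI
    sequence), the components are first linearly interpolated in b; grids
    extending beyond the fitted range raise rather than extrapolate.
    """
    comps = components
    if not np.array_equal(fraction.b_values, components.b_values):
        logger.info(
            "project_weights: interpolating components from grid %s to %s",
            components.b_values.tolist(),
            fraction.b_values.tolist(),
        )
        comps = components.interpolated_to(fraction.b_values)
    if mask.mask.shape != fraction.shape:
        raise ValueError("mask and fraction grids differ")
    if not mask.mask.any():
        raise ValueError("mask is empty")
    signals = fraction.signal[mask.mask]
    w = nnls_weights(comps.components, signals)
    weights = np.full(fraction.shape + (comps.k,), np.nan)
    weights[mask.mask] = w
    return WeightMap(
        weights=weights,
        component_ref=components,
        fraction_index=fraction.fraction_index,
        patient_id=fraction.patient_id,
    )
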