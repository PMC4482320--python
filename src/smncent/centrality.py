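"""Voxel-wise network centrality within a mask.

Two centrality metrics on the voxel-wise Pearson correlation graph:

* **Degree centrality (DC)** — for voxel i, the sum over all other in-mask
  voxels j of r_ij, restricted to r_ij above a threshold r0 (weighted form)
  or the count of such j (binary form).  The N x N correlation matrix is
  never materialised: correlations are formed in column blocks from the
  row-standardised time-series matrix Z, using r_ij = z_i . z_j / (T - 1).

* **Eigenvector centrality (EC)** — the unique nonnegative principal
  eigenvector of A = (C + 1) / 2, where C is the in-mask correlation
  matrix.  The affine shift maps correlations from [-1, 1] into [0, 1], so
  A is entrywise nonnegative and Perron-Frobenius guarantees a unique
  nonnegative principal eigenvector.  Power iteration runs matrix-free via
  A v = (Z (Z^T v) / (T - 1) + 1 * sum(v)) / 2.

Per-subject maps are normalised by the in-mask global mean (k/k0, u/u0),
rank-Gaussianised, and/or converted (z-standardisation or Fisher's
atanh) before group statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special, stats

from .errors import DegenerateMapError, ParameterError
from .imaging import BrainMask, VoxelMatrix

__all__ = [
    "CentralityMap",
    "ThresholdSet",
    "standardize_rows",
    "degree_centrality",
    "multi_threshold_dc",
    "fast_eigenvector_centrality",
    "normalize_global_mean",
    "convert_for_group",
    "rank_gauss",
    "DEFAULT_R0",
    "DEFAULT_THRESHOLDS",
]

#: Primary correlation threshold for the weighted-positive DC analysis.
DEFAULT_R0 = 0.25
#: Threshold sweep used for the robustness analysis.
DEFAULT_THRESHOLDS = (0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4)


@dataclass
class CentralityMap:
    """Per-voxel centrality values with explicit normalisation provenance.

    ``normalization`` lists, in application order, the transforms already
    applied: any of {"raw", "global_mean", "rank_gauss", "z_standardized",
    "fisher_z"}.
    """

    mask: BrainMask
    values: np.ndarray
    metric: str  # "DC" or "EC"
    r0: float | None = None
    normalization: list[str] = field(default_factory=lambda: ["raw"])
    lambda1: float | None = None  # EC only: principal-eigenvalue estimate
    n_iterations: int | None = None  # EC only
    converged: bool | None = None  # EC only

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.mask.n_voxels,):
            raise ValueError(
                f"expected {self.mask.n_voxels} values, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("centrality values must be finite")


@dataclass(frozen=True)
class ThresholdSet:
    """Strictly increasing correlation thresholds in (0, 1)."""

    r0_values: tuple[float, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.r0_values)
        if not vals:
            raise ParameterError("threshold set must not be empty")
        if any(not (0.0 < v < 1.0) for v in vals):
            raise ParameterError(f"thresholds must lie in (0, 1), got {vals}")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ParameterError("thresholds must be strictly increasing")
        object.__setattr__(self, "r0_values", vals)


def standardize_rows(vm: VoxelMatrix) -> tuple[VoxelMatrix, np.ndarray]:
    """Centre and scale rows so that z_i . z_j / (T - 1) = Pearson r_ij.

    Rows with zero variance cannot be correlated; they are set to all-zero
    (so every correlation involving them is 0, and their centrality is 0)
    and reported in the returned QC index array.

    Returns
    -------
    (standardized VoxelMatrix, array of flagged zero-variance row indices)
    """
    X = vm.data
    T = X.shape[1]
    centered = X - X.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", centered, centered)
    flagged = np.flatnonzero(ss <= 0)
    scale = np.sqrt(ss / (T - 1))
    scale[flagged] = 1.0  # rows zeroed below; avoid divide-by-zero
    Z = centered / scale[:, None]
    Z[flagged] = 0.0
    return VoxelMatrix(vm.mask, Z, standardized=True), flagged


def _require_standardized(vm: VoxelMatrix) -> None:
    if not vm.standardized:
        raise ParameterError(
            "input must be row-standardized (call standardize_rows first)"
        )


def degree_centrality(
    vm: VoxelMatrix,
    r0: float = DEFAULT_R0,
    mode: str = "weighted_positive",
    block_size: int = 1024,
) -> CentralityMap:
    """Thresholded degree centrality (single threshold convenience wrapper)."""
    maps = multi_threshold_dc(vm, ThresholdSet((float(r0),)), mode=mode, block_size=block_size)
    return maps[0]


def multi_threshold_dc(
    vm: VoxelMatrix,
    thresholds: ThresholdSet = ThresholdSet(),
    mode: str = "weighted_positive",
    block_size: int = 1024,
) -> list[CentralityMap]:
    """DC maps for every threshold in one blockwise pass.

    For each voxel i and threshold r0:
    weighted_positive: DC_i = sum_{j != i} r_ij * [r_ij > r0];
    binary:            DC_i = sum_{j != i} [r_ij > r0].
    Self-correlation is excluded.  Column blocks of the correlation matrix
    are formed from the standardized time series and reduced immediately,
    so memory stays O(N * block_size).
    """
    _require_standardized(vm)
    if mode not in ("weighted_positive", "binary"):
        raise ParameterError(f"unknown DC mode {mode!r}")
    if block_size < 1:
        raise ParameterError("block_size must be >= 1")
    r0s = np.asarray(thresholds.r0_values)

    Z = vm.data
    N, T = Z.shape
    dc = np.zeros((len(r0s), N))
    for start in range(0, N, block_size):
        stop = min(start + block_size, N)
        # (N, b) block of correlations between all voxels and block columns
        R = Z @ Z[start:stop].T / (T - 1)
        # exclude self-correlation
        cols = np.arange(start, stop)
        R[cols, cols - start] = 0.0
        for t, r0 in enumerate(r0s):
            supra = R > r0
            if mode == "weighted_positive":
                dc[t] += np.where(supra, R, 0.0).sum(axis=1)
            else:
                dc[t] += supra.sum(axis=1)
    return [
        CentralityMap(vm.mask, dc[t], metric="DC", r0=float(r0s[t]))
        for t in range(len(r0s))
    ]


def fast_eigenvector_centrality(
    vm: VoxelMatrix,
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> CentralityMap:
    """Matrix-free eigenvector centrality of the shifted correlation matrix.

    Power iteration on A = (C + 1)/2 with the deterministic uniform start
    1/sqrt(N).  Each product uses two (N x T) multiplications plus a rank-one
    all-ones term; the N x N matrix is never formed.  Iteration stops when
    successive unit vectors differ by less than ``tol`` in Euclidean norm.
    The returned map carries the principal-eigenvalue (Rayleigh) estimate
    and the iteration count; non-convergence yields a warning and a map
    flagged ``converged=False``.
    """
    _require_standardized(vm)
    Z = vm.data
    N, T = Z.shape
    if N < 2:
        raise ParameterError("eigenvector centrality needs at least 2 voxels")

    def matvec(v: np.ndarray) -> np.ndarray:
        return (Z @ (v @ Z) / (T - 1) + v.sum()) / 2.0

    v = np.full(N, 1.0 / np.sqrt(N))
    lam = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = matvec(v)
        lam = float(v @ w)  # Rayleigh quotient (A is PSD so lam >= 0)
        norm = np.linalg.norm(w)
        if norm == 0.0:
            raise DegenerateMapError("power iteration hit the zero vector")
        w /= norm
        if np.linalg.norm(w - v) < tol:
            v = w
            converged = True
            break
        v = w
    if not converged:
        warnings.warn(
            f"power iteration did not converge in {max_iter} iterations "
            f"(last eigenvalue estimate {lam:.6g}); returning partial result",
            RuntimeWarning,
            stacklevel=2,
        )
    # A is entrywise nonnegative; clip tiny negative round-off
    v = np.clip(v, 0.0, None)
    v /= np.linalg.norm(v)
    return CentralityMap(
        vm.mask, v, metric="EC", lambda1=lam, n_iterations=it, converged=converged
    )


# ---------------------------------------------------------------------------
# Normalisation and conversion
# ---------------------------------------------------------------------------

def normalize_global_mean(cm: CentralityMap) -> CentralityMap:
    """Divide by the in-mask global mean (the k/k0 and u/u0 step)."""
    mean = cm.values.mean()
    if mean == 0.0 or not np.isfinite(mean):
        raise DegenerateMapError("in-mask mean is zero; cannot normalize")
    return replace(
        cm,
        values=cm.values / mean,
        normalization=cm.normalization + ["global_mean"],
    )


def convert_for_group(cm: CentralityMap, method: str = "z_standardize") -> CentralityMap:
    """Convert a subject map to the scale used for group comparison.

    ``z_standardize`` maps to zero-mean/unit-SD over the mask; ``fisher_z``
    applies atanh and requires every value strictly inside (-1, 1) —
    globally normalised DC (k/k0) routinely exceeds 1, in which case
    z-standardisation is the usable conversion.
    """
    if method == "z_standardize":
        sd = cm.values.std(ddof=0)
        if sd == 0.0:
            raise DegenerateMapError("constant map cannot be z-standardized")
        vals = (cm.values - cm.values.mean()) / sd
        tag = "z_standardized"
    elif method == "fisher_z":
        if np.any(np.abs(cm.values) >= 1.0):
            raise DegenerateMapError(
                "fisher_z requires all values strictly inside (-1, 1); "
                "use method='z_standardize' for maps on other scales"
            )
        vals = np.arctanh(cm.values)
        tag = "fisher_z"
    else:
        raise ParameterError(f"unknown conversion method {method!r}")
    return replace(cm, values=vals, normalization=cm.normalization + [tag])


def rank_gauss(cm: CentralityMap) -> CentralityMap:
    """Map values through tied ranks to standard-normal quantiles.

    Average ranks for ties, Blom plotting position (rank - 3/8)/(N + 1/4),
    then the standard-normal quantile function.  Rank order is preserved
    and the output is approximately N(0, 1) for distinct inputs; an
    all-tied input maps to all zeros.
    """
    n = cm.values.size
    if n < 2:
        raise ParameterError("rank normalisation needs at least 2 voxels")
    ranks = stats.rankdata(cm.values, method="average")
    quantiles = (ranks - 0.375) / (n + 0.25)
    vals = special.ndtri(quantiles)
    return replace(cm, values=vals, normalization=cm.normalization + ["rank_gauss"])
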