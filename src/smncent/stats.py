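"""Voxel-wise group inference with Monte-Carlo cluster-size correction.

Mass-univariate OLS with a design shared across voxels gives t-maps for
arbitrary contrasts (two-sample comparisons with age/gender covariates,
paired differences via the one-sample route) and partial F-maps for a
multi-level group factor (ANCOVA).  Supra-threshold voxels at an
uncorrected per-voxel p are grouped into clusters under an rmm-defined
neighbourhood, and cluster extent is calibrated by Monte-Carlo simulation
of smoothed Gaussian null fields: the critical size k is the smallest
cluster extent whose family-wise occurrence rate under the null is below
the requested alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .errors import ConfigurationError, ParameterError, SampleSizeError
from .imaging import BrainMask
from .preprocess import fwhm_to_sigma

__all__ = [
    "DesignMatrix",
    "StatMap",
    "Cluster",
    "ClusterResult",
    "AlphaSimResult",
    "make_group_design",
    "glm_tmap",
    "paired_tmap",
    "ancova_fmap",
    "neighbors_from_rmm",
    "label_clusters",
    "alphasim_threshold",
    "apply_cluster_correction",
    "stack_maps",
]


@dataclass(frozen=True)
class DesignMatrix:
    """Subjects-by-predictors design with a named contrast."""

    X: np.ndarray
    columns: tuple[str, ...]
    contrast: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        c = np.asarray(self.contrast, dtype=float)
        if X.ndim != 2:
            raise ParameterError("design must be 2D")
        if len(self.columns) != X.shape[1]:
            raise ParameterError("column names must match design width")
        if c.shape != (X.shape[1],):
            raise ParameterError("contrast length must equal design width")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ParameterError(
                "design is rank deficient; remove collinear columns before fitting"
            )
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "contrast", c)


@dataclass
class StatMap:
    """Per-voxel test statistics over a mask."""

    mask: BrainMask
    values: np.ndarray
    dof: float
    kind: str = "t"  # "t" or "F"
    df_num: float | None = None  # F only
    flagged: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.mask.n_voxels,):
            raise ParameterError("statistic vector must match mask size")
        if self.dof < 1:
            raise ParameterError("dof must be >= 1")


@dataclass
class Cluster:
    """One supra-threshold connected component."""

    voxel_indices: np.ndarray  # grid linear indices (canonical order subset)
    peak_stat: float
    peak_voxel: int  # grid linear index
    tail: str  # "pos" or "neg"
    surviving: bool | None = None

    @property
    def size(self) -> int:
        return int(self.voxel_indices.size)


@dataclass
class ClusterResult:
    mask: BrainMask
    clusters: list[Cluster]
    voxel_p: float
    stat_threshold: float
    rmm: float

    @property
    def surviving(self) -> list[Cluster]:
        return [c for c in self.clusters if c.surviving]


@dataclass
class AlphaSimResult:
    """Monte-Carlo null distribution of the maximum cluster extent."""

    voxel_p: float
    fwhm_mm: float
    rmm: float
    iterations: int
    alpha: float
    critical_k: int
    null_max_sizes: np.ndarray
    alpha_to_k: dict

    def k_for(self, alpha: float) -> int:
        """Smallest k whose null family-wise rate is <= alpha."""
        if not (0.0 < alpha <= 1.0):
            raise ParameterError("alpha must be in (0, 1]")
        sizes = self.null_max_sizes
        for k in range(1, int(sizes.max()) + 2):
            if (sizes >= k).mean() <= alpha:
                return k
        return int(sizes.max()) + 1


# ---------------------------------------------------------------------------
# Designs and mass-univariate fits
# ---------------------------------------------------------------------------

def make_group_design(
    group: np.ndarray,
    age: np.ndarray | None = None,
    gender: np.ndarray | None = None,
) -> DesignMatrix:
    """Two-group design [intercept, group(0/1), age_centred, gender].

    The contrast tests the group column (group 1 minus group 0).  Age is
    centred so the intercept stays interpretable; the contrast is
    unaffected.
    """
    group = np.asarray(group, dtype=float)
    n = group.size
    cols = [np.ones(n), group]
    names = ["intercept", "group"]
    if age is not None:
        age = np.asarray(age, dtype=float)
        cols.append(age - age.mean())
        names.append("age")
    if gender is not None:
        cols.append(np.asarray(gender, dtype=float))
        names.append("gender")
    X = np.column_stack(cols)
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    return DesignMatrix(X, tuple(names), contrast)


def stack_maps(maps) -> np.ndarray:
    """Stack per-subject centrality maps into an (n_subjects, N) array."""
    mask = maps[0].mask
    for m in maps[1:]:
        if m.mask.n_voxels != mask.n_voxels:
            raise ParameterError("all maps must share one mask")
    return np.stack([m.values for m in maps])


def _ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Shared-design OLS over all voxels: returns (beta, rss, rank)."""
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    return beta, rss, int(rank)


def glm_tmap(Y: np.ndarray, design: DesignMatrix, mask: BrainMask) -> StatMap:
    """Voxel-wise t statistic for the design's contrast.

    t = c'b / sqrt(s2 * c'(X'X)^-1 c), dof = n - rank(X).  Voxels with zero
    residual variance get a non-finite statistic and are listed in
    ``flagged``.
    """
    Y = np.asarray(Y, dtype=float)
    X, c = design.X, design.contrast
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ParameterError("response rows must match design rows")
    beta, rss, rank = _ols(X, Y)
    dof = n - rank
    if dof < 1:
        raise SampleSizeError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    cvar = float(c @ xtx_inv @ c)
    sigma2 = rss / dof
    # numerically-zero residual variance => statistic undefined, flag it
    floor = 1e-12 * np.maximum(np.einsum("ij,ij->j", Y, Y), 1e-300)
    degenerate = rss < floor
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (c @ beta) / np.sqrt(sigma2 * cvar)
    t[degenerate] = np.nan
    flagged = np.flatnonzero(~np.isfinite(t))
    return StatMap(mask, t, dof=dof, kind="t", flagged=flagged)


def paired_tmap(Ya: np.ndarray, Yb: np.ndarray, mask: BrainMask) -> StatMap:
    """One-sample t on within-pair differences (b minus a); dof = n - 1."""
    Ya = np.asarray(Ya, dtype=float)
    Yb = np.asarray(Yb, dtype=float)
    if Ya.shape != Yb.shape:
        raise ParameterError("paired map lists must match in shape and order")
    n = Ya.shape[0]
    if n < 2:
        raise SampleSizeError("paired test needs at least 2 pairs")
    D = Yb - Ya
    mean = D.mean(axis=0)
    sd = D.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    flagged = np.flatnonzero(~np.isfinite(t))
    return StatMap(mask, t, dof=n - 1, kind="t", flagged=flagged)


def ancova_fmap(
    Y: np.ndarray,
    group_labels: np.ndarray,
    mask: BrainMask,
    covariates: np.ndarray | None = None,
) -> StatMap:
    """Partial F for a multi-level group factor adjusting for covariates.

    Model comparison of [intercept, group dummies, covariates] against
    [intercept, covariates]; df = (g - 1, n - rank(full)).
    """
    Y = np.asarray(Y, dtype=float)
    labels = np.asarray(group_labels)
    levels = np.unique(labels)
    g = levels.size
    if g < 2:
        raise ParameterError("need at least 2 group levels")
    n = labels.size
    if Y.shape[0] != n:
        raise ParameterError("response rows must match label count")
    for lv in levels:
        if (labels == lv).sum() < 2:
            raise SampleSizeError(f"group {lv!r} has fewer than 2 members")
    dummies = np.column_stack([(labels == lv).astype(float) for lv in levels[1:]])
    cov = (
        np.asarray(covariates, dtype=float).reshape(n, -1)
        if covariates is not None
        else np.empty((n, 0))
    )
    cov = cov - cov.mean(axis=0, keepdims=True) if cov.size else cov
    X_full = np.column_stack([np.ones(n), dummies, cov])
    X_red = np.column_stack([np.ones(n), cov])
    _, rss_full, rank_full = _ols(X_full, Y)
    _, rss_red, _ = _ols(X_red, Y)
    q = g - 1
    dof = n - rank_full
    if dof < 1:
        raise SampleSizeError("no residual degrees of freedom")
    floor = 1e-12 * np.maximum(np.einsum("ij,ij->j", Y, Y), 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_red - rss_full) / q) / (rss_full / dof)
    F[rss_full < floor] = np.nan
    flagged = np.flatnonzero(~np.isfinite(F))
    return StatMap(mask, F, dof=dof, kind="F", df_num=q, flagged=flagged)


# ---------------------------------------------------------------------------
# Cluster formation
# ---------------------------------------------------------------------------

def neighbors_from_rmm(voxel_size, rmm: float) -> np.ndarray:
    """Voxel offsets with centre-to-centre distance in (0, rmm] mm.

    For 3 mm isotropic voxels, rmm = 5 yields 18-connectivity (faces at
    3 mm and edges at 4.243 mm in, corners at 5.196 mm out).
    """
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    if rmm <= 0:
        raise ParameterError("rmm must be > 0")
    reach = np.floor(rmm / vs).astype(int)
    if np.all(reach == 0):
        raise ParameterError(
            f"rmm {rmm} mm is below the smallest voxel size {vs.min()} mm: empty neighbourhood"
        )
    offs = []
    for di in range(-reach[0], reach[0] + 1):
        for dj in range(-reach[1], reach[1] + 1):
            for dk in range(-reach[2], reach[2] + 1):
                if di == dj == dk == 0:
                    continue
                d = np.sqrt((di * vs[0]) ** 2 + (dj * vs[1]) ** 2 + (dk * vs[2]) ** 2)
                if d <= rmm + 1e-9:
                    offs.append((di, dj, dk))
    if not offs:
        raise ParameterError("empty neighbourhood")
    return np.array(sorted(offs), dtype=int)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _connected_components(
    coords: np.ndarray, shape: tuple[int, int, int], offsets: np.ndarray
) -> list[np.ndarray]:
    """Components of a voxel set under an arbitrary offset neighbourhood."""
    lin = np.ravel_multi_index(coords.T, shape)
    index = {int(v): i for i, v in enumerate(lin)}
    uf = _UnionFind(len(lin))
    for i, c in enumerate(coords):
        for off in offsets:
            nb = c + off
            if np.any(nb < 0) or np.any(nb >= shape):
                continue
            j = index.get(int(np.ravel_multi_index(nb, shape)))
            if j is not None:
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(lin)):
        groups.setdefault(uf.find(i), []).append(i)
    return [np.sort(lin[np.array(g)]) for g in groups.values()]


def _stat_threshold(statmap: StatMap, voxel_p: float) -> float:
    """One-tailed statistic cutoff for the per-voxel p."""
    if statmap.kind == "t":
        return float(sps.t.ppf(1.0 - voxel_p, statmap.dof))
    return float(sps.f.ppf(1.0 - voxel_p, statmap.df_num, statmap.dof))


def label_clusters(
    statmap: StatMap,
    voxel_p: float = 0.01,
    tail: str = "both",
    offsets: np.ndarray | None = None,
    rmm: float = 5.0,
) -> ClusterResult:
    """Connected supra-threshold components, positive/negative tails separate.

    The statistic cutoff is the one-tailed quantile at ``voxel_p`` for the
    map's dof.  Clusters are ordered by descending size, ties broken by the
    smallest contained voxel index.  F maps only have a positive tail.
    """
    if offsets is None:
        offsets = neighbors_from_rmm(statmap.mask.grid.voxel_size, rmm)
    thr = _stat_threshold(statmap, voxel_p)
    shape = statmap.mask.grid.shape
    lin = statmap.mask.linear_indices
    vals = statmap.values
    val_by_lin = dict(zip(lin.tolist(), vals.tolist()))

    tails = []
    if statmap.kind == "F":
        tails = [("pos", vals > thr)]
    else:
        if tail in ("pos", "both"):
            tails.append(("pos", vals > thr))
        if tail in ("neg", "both"):
            tails.append(("neg", vals < -thr))
        if not tails:
            raise ParameterError(f"unknown tail {tail!r}")

    clusters: list[Cluster] = []
    for tname, supra in tails:
        supra = supra & np.isfinite(vals)
        if not supra.any():
            continue
        sel = lin[supra]
        coords = np.stack(np.unravel_index(sel, shape), axis=1)
        for comp in _connected_components(coords, shape, offsets):
            cvals = np.array([val_by_lin[int(v)] for v in comp])
            peak_pos = int(np.argmax(cvals)) if tname == "pos" else int(np.argmin(cvals))
            clusters.append(
                Cluster(
                    voxel_indices=comp,
                    peak_stat=float(cvals[peak_pos]),
                    peak_voxel=int(comp[peak_pos]),
                    tail=tname,
                )
            )
    clusters.sort(key=lambda c: (-c.size, int(c.voxel_indices.min())))
    return ClusterResult(statmap.mask, clusters, voxel_p, thr, rmm)


# ---------------------------------------------------------------------------
# Monte-Carlo cluster-size calibration
# ---------------------------------------------------------------------------

def alphasim_threshold(
    mask: BrainMask,
    fwhm_mm: float = 6.0,
    voxel_p: float = 0.01,
    rmm: float = 5.0,
    iterations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> AlphaSimResult:
    """Critical cluster size under smoothed Gaussian null fields.

    Each iteration fills the mask's bounding box with unit white noise,
    smooths to ``fwhm_mm``, restricts to the mask, re-standardises the
    in-mask values (so kernel-edge variance loss cannot deflate the
    threshold), thresholds at the one-tailed z for ``voxel_p`` and records
    the maximum cluster extent under the rmm neighbourhood.  The critical
    k at ``alpha`` is the smallest extent whose exceedance rate is <= alpha.
    """
    if iterations < 100:
        raise ParameterError("need at least 100 iterations")
    if not (0.0 < voxel_p < 1.0) or not (0.0 < alpha < 1.0):
        raise ParameterError("voxel_p and alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    ind = mask.indicator
    ii, jj, kk = np.nonzero(ind)
    lo = np.array([ii.min(), jj.min(), kk.min()])
    hi = np.array([ii.max(), jj.max(), kk.max()]) + 1
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub = ind[box]
    sigma_vox = fwhm_to_sigma(fwhm_mm) / mask.grid.voxel_size if fwhm_mm > 0 else None
    zthr = float(sps.norm.ppf(1.0 - voxel_p))
    offsets = neighbors_from_rmm(mask.grid.voxel_size, rmm)
    shape = sub.shape

    max_sizes = np.zeros(iterations, dtype=int)
    for it in range(iterations):
        field_ = rng.standard_normal(shape)
        if sigma_vox is not None:
            field_ = ndimage.gaussian_filter(field_, sigma=sigma_vox)
        vals = field_[sub]
        vals = (vals - vals.mean()) / vals.std()
        supra = vals > zthr
        if not supra.any():
            continue
        coords = np.stack(np.nonzero(sub), axis=1)[supra]
        comps = _connected_components(coords, shape, offsets)
        max_sizes[it] = max(len(c) for c in comps)

    result = AlphaSimResult(
        voxel_p=voxel_p,
        fwhm_mm=fwhm_mm,
        rmm=rmm,
        iterations=iterations,
        alpha=alpha,
        critical_k=0,
        null_max_sizes=max_sizes,
        alpha_to_k={},
    )
    result.critical_k = result.k_for(alpha)
    result.alpha_to_k = {a: result.k_for(a) for a in (0.1, 0.05, 0.01)} | {
        alpha: result.critical_k
    }
    return result


def apply_cluster_correction(
    clusters: ClusterResult, asr: AlphaSimResult, alpha: float = 0.05
) -> ClusterResult:
    """Flag clusters whose extent reaches the Monte-Carlo critical size."""
    if abs(clusters.voxel_p - asr.voxel_p) > 1e-12 or abs(clusters.rmm - asr.rmm) > 1e-9:
        raise ConfigurationError(
            "cluster formation and AlphaSim calibration used different voxel_p/rmm"
        )
    k = asr.k_for(alpha)
    out = [replace(c, surviving=c.size >= k) for c in clusters.clusters]
    return ClusterResult(
        clusters.mask, out, clusters.voxel_p, clusters.stat_threshold, clusters.rmm
    )
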