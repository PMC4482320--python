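"""Morphometry (BPF, TWMLL) and cluster-level clinical regression.

BPF (brain parenchymal fraction) is parenchymal volume / intracranial
volume, an atrophy index; TWMLL (total white-matter lesion load) is the
summed lesion volume in ml.  For clusters with significant group
differences, mean centrality per subject is regressed on a clinical
metric (EDSS, BPF, TWMLL or disease duration) with age and gender as
covariates; p-values are Bonferroni-corrected over the declared family
(clusters x metrics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateMapError, ParameterError, SampleSizeError
from .imaging import BrainMask
from .stats import ClusterResult

__all__ = [
    "RegressionResult",
    "compute_bpf",
    "compute_twmll",
    "cluster_mean_extract",
    "clinical_regression",
]


@dataclass(frozen=True)
class RegressionResult:
    cluster_id: int
    metric: str
    slope: float
    partial_correlation: float
    p_uncorrected: float
    p_bonferroni: float
    n: int
    family_size: int


def _volume(arr, voxel_volume_mm3: float) -> float:
    """Volume in mm3 of a binary mask or probability map."""
    if isinstance(arr, BrainMask):
        arr = arr.indicator
    arr = np.asarray(arr, dtype=float)
    if arr.min() < 0 or arr.max() > 1:
        raise ParameterError("tissue values must be probabilities in [0, 1]")
    return float(arr.sum() * voxel_volume_mm3)


def compute_bpf(gm, wm, csf, voxel_volume_mm3: float = 1.0) -> float:
    """Brain parenchymal fraction: (GM + WM) / (GM + WM + CSF).

    Accepts binary masks or tissue-probability volumes; probabilities are
    integrated (probability mass x voxel volume) rather than thresholded.
    """
    gm_v = _volume(gm, voxel_volume_mm3)
    wm_v = _volume(wm, voxel_volume_mm3)
    csf_v = _volume(csf, voxel_volume_mm3)
    icv = gm_v + wm_v + csf_v
    if icv <= 0:
        raise DegenerateMapError("intracranial volume is zero")
    return (gm_v + wm_v) / icv


def compute_twmll(lesion, voxel_volume_mm3: float = 1.0) -> float:
    """Total white-matter lesion load in ml from a binary lesion mask."""
    if isinstance(lesion, BrainMask):
        lesion = lesion.indicator
    lesion = np.asarray(lesion)
    if not np.isin(np.unique(lesion), (0, 1)).all():
        raise ParameterError("lesion mask must be binary")
    return float(lesion.sum()) * voxel_volume_mm3 / 1000.0


def cluster_mean_extract(maps, clusters: ClusterResult) -> pd.DataFrame:
    """Mean centrality over each cluster's voxels, per subject map.

    Returns a (subjects x clusters) frame with columns ``cluster_<i>``
    following the cluster ordering of ``clusters``.
    """
    if not clusters.clusters:
        raise ParameterError("no clusters to extract")
    mask_lin = maps[0].mask.linear_indices
    pos = {int(v): i for i, v in enumerate(mask_lin)}
    cols = {}
    for ci, cl in enumerate(clusters.clusters):
        try:
            rows = np.array([pos[int(v)] for v in cl.voxel_indices])
        except KeyError as exc:
            raise ParameterError("cluster voxel outside the map mask") from exc
        if rows.size == 0:
            raise ParameterError(f"cluster {ci} is empty")
        cols[f"cluster_{ci}"] = [float(m.values[rows].mean()) for m in maps]
    return pd.DataFrame(cols)


def clinical_regression(
    cluster_means: pd.DataFrame,
    metrics: pd.DataFrame,
    age: np.ndarray,
    gender: np.ndarray,
    family_size: int | None = None,
) -> list[RegressionResult]:
    """OLS of cluster-mean centrality on each clinical metric.

    Model per (cluster, metric): mean ~ intercept + metric + age + gender.
    The partial correlation is derived from the metric's t statistic,
    r = sign(slope) * sqrt(t^2 / (t^2 + dof)).  The Bonferroni family
    defaults to (number of clusters) x (number of metrics) and is reported
    alongside every result so the correction can be re-scoped.
    """
    n = len(cluster_means)
    age = np.asarray(age, dtype=float)
    gender = np.asarray(gender, dtype=float)
    if len(metrics) != n or age.size != n or gender.size != n:
        raise ParameterError("cluster means, metrics and covariates must align")
    if family_size is None:
        family_size = cluster_means.shape[1] * metrics.shape[1]
    if family_size < 1:
        raise ParameterError("family size must be >= 1")
    if n < 5:  # intercept + metric + age + gender + 1 residual dof
        raise SampleSizeError(f"n={n} too small for a 4-parameter model")

    results: list[RegressionResult] = []
    for ci, ccol in enumerate(cluster_means.columns):
        y = cluster_means[ccol].to_numpy(dtype=float)
        for mcol in metrics.columns:
            X = sm.add_constant(
                pd.DataFrame(
                    {
                        "metric": metrics[mcol].to_numpy(dtype=float),
                        "age": age - age.mean(),
                        "gender": gender,
                    }
                )
            )
            fit = sm.OLS(y, X).fit()
            t = float(fit.tvalues["metric"])
            dof = float(fit.df_resid)
            slope = float(fit.params["metric"])
            pr = np.sign(slope) * np.sqrt(t**2 / (t**2 + dof)) if np.isfinite(t) else np.nan
            p = float(fit.pvalues["metric"])
            results.append(
                RegressionResult(
                    cluster_id=ci,
                    metric=str(mcol),
                    slope=slope,
                    partial_correlation=float(pr),
                    p_uncorrected=p,
                    p_bonferroni=min(1.0, p * family_size),
                    n=n,
                    family_size=family_size,
                )
            )
    return results
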