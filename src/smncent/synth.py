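"""Synthetic resting-state studies with known network ground truth.

The generator emulates the structure the centrality pipeline measures, not
the biophysics of BOLD: each in-mask voxel's time course is a weighted sum
of community latent signals plus AR(1) noise,

    x_i(t) = sum_c W[i, c] * s_c(t) + e_i(t),

with unit-variance white latents s_c and stationary AR(1) noise e_i of
standard deviation ``noise_sd``.  Two voxels sharing a single latent with
weights w1, w2 have expected correlation
r = w1 w2 / sqrt((w1^2 + sd^2)(w2^2 + sd^2)) — w^2/(w^2 + sd^2) for equal
weights — giving closed forms for every planted quantity.  Hub voxels load
on several latents and therefore accumulate a larger correlation sum than
community members.

Group differences are planted by perturbing the loading weights of a
designated voxel set in affected subjects/sessions; paired sessions share
a subject-level loading scale, which induces the within-pair dependence a
paired design exploits.  Clinical covariates are linear in each subject's
true (expected) cluster centrality plus Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import CapacityError, ParameterError
from .imaging import BrainMask, ImageGrid, TimeSeriesImage, VoxelMatrix, insert_matrix

__all__ = [
    "HubSpec",
    "GroupEffect",
    "SubjectRecord",
    "SyntheticTruth",
    "Segmentation",
    "make_toy_mask",
    "default_hub_spec",
    "expected_correlation",
    "expected_dc",
    "simulate_subject_timeseries",
    "simulate_group_study",
    "simulate_motion",
    "simulate_segmentation",
    "simulate_clinical_coupling",
    "subject_table",
]

_FACE_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


@dataclass(frozen=True)
class HubSpec:
    """Community structure of the planted connectivity graph.

    ``communities`` is a list of (voxel-index array, loading weight) pairs;
    indices refer to the canonical in-mask ordering.  A voxel listed in
    several communities loads on several latents and is thereby a hub.
    ``noise_sd`` is the *stationary* standard deviation of the AR(1) voxel
    noise; ``ar1_coefficient`` its lag-1 autocorrelation.
    """

    communities: tuple[tuple[np.ndarray, float], ...]
    noise_sd: float = 1.0
    ar1_coefficient: float = 0.3

    def __post_init__(self) -> None:
        if not self.communities:
            raise ParameterError("at least one community is required")
        comms = []
        for idx, w in self.communities:
            idx = np.asarray(idx, dtype=int)
            if idx.size == 0:
                raise ParameterError("empty community voxel set")
            if not np.isfinite(w):
                raise ParameterError("community weight must be finite")
            comms.append((idx, float(w)))
        object.__setattr__(self, "communities", tuple(comms))
        if not (0.0 <= self.ar1_coefficient < 1.0):
            raise ParameterError("ar1_coefficient must be in [0, 1)")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    def loading_matrix(self, n_voxels: int) -> np.ndarray:
        """(N, K) loading weights onto the K community latents."""
        W = np.zeros((n_voxels, self.n_communities))
        for c, (idx, w) in enumerate(self.communities):
            if idx.max() >= n_voxels:
                raise ParameterError("community index exceeds mask size")
            W[idx, c] += w
        return W

    def hub_voxels(self, n_voxels: int) -> np.ndarray:
        """Voxels loading on more than one latent."""
        W = self.loading_matrix(n_voxels)
        return np.flatnonzero((W != 0).sum(axis=1) > 1)


@dataclass(frozen=True)
class GroupEffect:
    """Planted group difference: extra loading at a voxel set.

    In affected subjects/sessions every nonzero loading of the listed
    voxels is increased by ``delta``, raising those voxels' correlations
    with their communities and hence their degree/eigenvector centrality.
    """

    voxels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    delta: float = 0.0
    affected_groups: tuple[str, ...] = ("relapsing",)

    def __post_init__(self) -> None:
        object.__setattr__(self, "voxels", np.asarray(self.voxels, dtype=int))


@dataclass
class SubjectRecord:
    """One scanning session of one subject plus clinical covariates."""

    id: str
    group: str  # relapsing | remitting | control
    age: float
    gender: int  # 0/1
    edss: float
    bpf: float
    twmll_ml: float
    duration_months: float
    session: str = "single"
    pair_id: int | None = None

    def __post_init__(self) -> None:
        if self.group not in ("relapsing", "remitting", "control"):
            raise ParameterError(f"unknown group {self.group!r}")
        if not (0.0 <= self.edss <= 10.0):
            raise ParameterError("EDSS must lie in [0, 10]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated study, for recovery tests."""

    hub_map: np.ndarray  # per-voxel expected DC (ranking reference)
    group_effect: np.ndarray  # per-voxel planted loading increment
    covariate_slopes: dict
    seed: int
    subject_centrality: np.ndarray  # per-session true mean centrality over effect voxels


@dataclass(frozen=True)
class Segmentation:
    """Disjoint tissue masks plus a lesion mask nested in white matter."""

    grid: ImageGrid
    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    lesion: np.ndarray


# ---------------------------------------------------------------------------
# Masks and structure
# ---------------------------------------------------------------------------

def _grow_blob(
    shape: tuple[int, int, int], start: np.ndarray, n_target: int, rng: np.random.Generator
) -> np.ndarray:
    """Randomised BFS growth of a 6-connected blob; returns boolean array."""
    chosen = np.zeros(shape, dtype=bool)
    chosen[tuple(start)] = True
    frontier = []
    seen = {tuple(start)}

    def push_neighbors(vox: np.ndarray) -> None:
        for off in _FACE_OFFSETS:
            nb = vox + off
            key = tuple(nb)
            if key in seen:
                continue
            if np.any(nb < 0) or np.any(nb >= shape):
                continue
            seen.add(key)
            frontier.append(nb)

    push_neighbors(start)
    count = 1
    while count < n_target:
        if not frontier:
            raise CapacityError("blob growth exhausted the grid")
        pick = int(rng.integers(len(frontier)))
        vox = frontier.pop(pick)
        chosen[tuple(vox)] = True
        count += 1
        push_neighbors(vox)
    return chosen


def make_toy_mask(
    shape: tuple[int, int, int],
    target_voxels: int,
    seed: int,
    voxel_size: float = 3.0,
) -> BrainMask:
    """A single connected blob-like mask with exactly ``target_voxels`` voxels.

    Stands in for an ICA-derived network template at desk scale.  Growth is
    a seeded randomised breadth-first expansion from the grid centre, so
    the mask is 6-connected and bit-identical for a given seed.
    """
    shape = tuple(int(s) for s in shape)
    capacity = int(np.prod(shape))
    if target_voxels < 1 or target_voxels > capacity:
        raise CapacityError(
            f"target {target_voxels} voxels infeasible in grid of {capacity}"
        )
    rng = np.random.default_rng(seed)
    start = np.array([s // 2 for s in shape])
    blob = _grow_blob(shape, start, target_voxels, rng)
    return BrainMask(ImageGrid.from_voxel_size(shape, voxel_size), blob)


def default_hub_spec(
    mask: BrainMask,
    n_communities: int = 4,
    weight: float = 1.0,
    noise_sd: float = 1.0,
    ar1: float = 0.3,
    n_hub_voxels: int = 5,
    seed: int = 0,
) -> HubSpec:
    """Partition the mask into contiguous communities plus a global hub set.

    Communities are grown around randomly seeded centres (nearest-centre
    assignment in voxel space, which keeps them spatially compact); the
    first ``n_hub_voxels`` voxels of community 0 additionally join every
    other community, making them hubs.
    """
    if n_communities < 1:
        raise ParameterError("need at least one community")
    rng = np.random.default_rng(seed)
    coords = mask.voxel_coords.astype(float)
    N = coords.shape[0]
    centers = coords[rng.choice(N, size=n_communities, replace=False)]
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    # guarantee non-empty communities
    for c in range(n_communities):
        if not np.any(assign == c):
            assign[rng.integers(N)] = c
    hub = np.flatnonzero(assign == 0)[: max(0, n_hub_voxels)]
    communities = []
    for c in range(n_communities):
        idx = np.flatnonzero(assign == c)
        if c > 0 and hub.size:
            idx = np.union1d(idx, hub)
        communities.append((idx, weight))
    return HubSpec(tuple(communities), noise_sd=noise_sd, ar1_coefficient=ar1)


# ---------------------------------------------------------------------------
# Closed-form ground truth
# ---------------------------------------------------------------------------

def expected_correlation(W: np.ndarray, noise_sd: float) -> np.ndarray:
    """Population correlation matrix implied by loadings W and noise sd."""
    cov = W @ W.T
    cov[np.diag_indices_from(cov)] += noise_sd**2
    d = np.sqrt(np.diag(cov))
    d = np.where(d > 0, d, 1.0)
    return cov / np.outer(d, d)


def expected_dc(
    hubs: HubSpec,
    n_voxels: int,
    r0: float = 0.25,
    extra_loading: np.ndarray | None = None,
    loading_scale: float = 1.0,
) -> np.ndarray:
    """Population weighted-positive DC implied by the planted structure."""
    W = hubs.loading_matrix(n_voxels) * loading_scale
    if extra_loading is not None:
        W = _apply_extra_loading(W, extra_loading)
    C = expected_correlation(W, hubs.noise_sd)
    np.fill_diagonal(C, 0.0)
    return np.where(C > r0, C, 0.0).sum(axis=1)


def _apply_extra_loading(W: np.ndarray, extra: np.ndarray) -> np.ndarray:
    """Add per-voxel increments to each nonzero loading of that voxel."""
    W = W.copy()
    extra = np.asarray(extra, dtype=float)
    nz = W != 0
    W[nz] += (extra[:, None] * nz)[nz] * np.sign(W[nz])
    return W


# ---------------------------------------------------------------------------
# Time-series simulation
# ---------------------------------------------------------------------------

def _ar1_noise(
    n_voxels: int, T: int, sd: float, phi: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros((n_voxels, T))
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    innov = rng.normal(0.0, innov_sd, size=(n_voxels, T))
    if phi == 0.0:
        return innov
    e0 = rng.normal(0.0, sd, size=n_voxels)  # stationary initial state
    zi = (phi * e0)[:, None]
    out, _ = signal.lfilter([1.0], [1.0, -phi], innov, axis=1, zi=zi)
    return out


def simulate_subject_timeseries(
    mask: BrainMask,
    hubs: HubSpec,
    T: int = 240,
    tr_seconds: float = 2.0,
    seed: int = 0,
    loading_scale: float = 1.0,
    extra_loading: np.ndarray | None = None,
) -> TimeSeriesImage:
    """One subject's masked 4D time series under the planted structure.

    ``loading_scale`` multiplies all community weights (subject-level random
    effect); ``extra_loading`` adds a per-voxel increment to each nonzero
    loading (planted group effect).  Out-of-mask voxels are zero.
    """
    if T < 20:
        raise ParameterError("need at least 20 volumes")
    rng = np.random.default_rng(seed)
    N = mask.n_voxels
    W = hubs.loading_matrix(N) * loading_scale
    if extra_loading is not None:
        W = _apply_extra_loading(W, extra_loading)
    latents = rng.normal(size=(hubs.n_communities, T))
    X = W @ latents + _ar1_noise(N, T, hubs.noise_sd, hubs.ar1_coefficient, rng)
    return insert_matrix(VoxelMatrix(mask, X), tr_seconds=tr_seconds)


# ---------------------------------------------------------------------------
# Whole-study simulation
# ---------------------------------------------------------------------------

def _round_edss(x: np.ndarray) -> np.ndarray:
    return np.clip(np.round(x * 2.0) / 2.0, 0.0, 10.0)


def simulate_group_study(
    mask: BrainMask,
    hubs: HubSpec,
    design: dict | None = None,
    effect: GroupEffect | None = None,
    covariate_slopes: dict | None = None,
    T: int = 240,
    tr_seconds: float = 2.0,
    seed: int = 0,
    subject_sd: float = 0.1,
) -> tuple[list[tuple[SubjectRecord, TimeSeriesImage]], SyntheticTruth]:
    """Simulate a two-group study with an optional paired sub-cohort.

    ``design`` gives cohort sizes {n_control, n_remitting, n_paired}; each
    paired subject contributes a "relapse" and a "remit" session sharing a
    subject-level loading scale (Gaussian with SD ``subject_sd`` around 1).
    ``effect`` perturbs loadings at its voxel set in sessions whose group is
    in ``effect.affected_groups``.  Clinical covariates are linear in each
    subject's true mean centrality over the effect voxels (z-scored across
    the cohort) with the given slopes plus unit-free Gaussian noise; EDSS
    is rounded to 0.5 steps and clipped to [0, 10].
    """
    design = {"n_control": 8, "n_remitting": 8, "n_paired": 0, **(design or {})}
    effect = effect or GroupEffect()
    slopes = {"edss": 0.0, "bpf": 0.0, "twmll": 0.0, **(covariate_slopes or {})}
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root.spawn(1)[0])

    N = mask.n_voxels
    extra = np.zeros(N)
    if effect.voxels.size:
        extra[effect.voxels] = effect.delta

    sessions: list[tuple[str, str, str, int | None]] = []  # (id, group, session, pair)
    for i in range(design["n_control"]):
        sessions.append((f"ctl{i:03d}", "control", "single", None))
    for i in range(design["n_remitting"]):
        sessions.append((f"rem{i:03d}", "remitting", "single", None))
    for i in range(design["n_paired"]):
        sessions.append((f"pat{i:03d}", "relapsing", "relapse", i))
        sessions.append((f"pat{i:03d}", "remitting", "remit", i))

    # subject-level loading scales (shared by paired sessions)
    subj_ids = sorted({s[0] for s in sessions})
    scales = {
        sid: 1.0 + subject_sd * rng.normal() for sid in subj_ids
    }

    # true mean centrality over the effect voxels, per session
    ref_voxels = effect.voxels if effect.voxels.size else np.arange(N)
    true_cent = np.empty(len(sessions))
    for k, (sid, group, _sess, _pair) in enumerate(sessions):
        e = extra if group in effect.affected_groups else None
        dc = expected_dc(hubs, N, extra_loading=e, loading_scale=scales[sid])
        true_cent[k] = dc[ref_voxels].mean()

    # covariates per subject (first session's truth used for paired subjects)
    first_idx = {sid: next(k for k, s in enumerate(sessions) if s[0] == sid) for sid in subj_ids}
    cvals = np.array([true_cent[first_idx[sid]] for sid in subj_ids])
    cz = (cvals - cvals.mean()) / (cvals.std() if cvals.std() > 0 else 1.0)
    covars = {}
    for j, sid in enumerate(subj_ids):
        is_patient = not sid.startswith("ctl")
        edss = _round_edss(3.0 + slopes["edss"] * cz[j] + 0.5 * rng.normal()) if is_patient else 0.0
        bpf = float(np.clip(0.85 + slopes["bpf"] * cz[j] + 0.01 * rng.normal(), 0.5, 0.999))
        twmll = float(max(0.0, 8.0 + slopes["twmll"] * cz[j] + 1.0 * rng.normal()))
        covars[sid] = dict(
            age=float(np.clip(45 + 10 * rng.normal(), 18, 80)),
            gender=int(rng.integers(2)),
            edss=float(edss),
            bpf=bpf,
            twmll_ml=twmll if is_patient else 0.0,
            duration_months=float(rng.uniform(6, 180)) if is_patient else 0.0,
        )

    out: list[tuple[SubjectRecord, TimeSeriesImage]] = []
    child_seeds = root.spawn(len(sessions) + 1)[1:]
    for k, (sid, group, sess, pair) in enumerate(sessions):
        e = extra if group in effect.affected_groups else None
        img = simulate_subject_timeseries(
            mask,
            hubs,
            T=T,
            tr_seconds=tr_seconds,
            seed=int(child_seeds[k].generate_state(1)[0] % (2**31)),
            loading_scale=scales[sid],
            extra_loading=e,
        )
        rec = SubjectRecord(
            id=sid, group=group, session=sess, pair_id=pair, **covars[sid]
        )
        out.append((rec, img))

    truth = SyntheticTruth(
        hub_map=expected_dc(hubs, N),
        group_effect=extra,
        covariate_slopes=slopes,
        seed=seed,
        subject_centrality=true_cent,
    )
    return out, truth


def subject_table(records: list[SubjectRecord]) -> pd.DataFrame:
    """Tidy subject/session table (one row per session)."""
    return pd.DataFrame(
        [
            dict(
                id=r.id,
                group=r.group,
                session=r.session,
                pair_id=-1 if r.pair_id is None else r.pair_id,
                age=r.age,
                gender=r.gender,
                edss=r.edss,
                bpf=r.bpf,
                twmll_ml=r.twmll_ml,
                duration_months=r.duration_months,
            )
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# Motion and segmentation
# ---------------------------------------------------------------------------

def simulate_motion(T: int, amplitude_mm: float = 0.05, seed: int = 0) -> np.ndarray:
    """Random-walk motion table: (T, 6) = 3 translations mm, 3 rotations deg.

    ``amplitude_mm`` is the per-step standard deviation (the same numeric
    scale is used for the rotation columns, in degrees); 0 gives an
    all-zero table.
    """
    if T < 2:
        raise ParameterError("need at least 2 volumes")
    if amplitude_mm == 0.0:
        return np.zeros((T, 6))
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, amplitude_mm, size=(T, 6))
    steps[0] = 0.0  # reference volume at origin
    return np.cumsum(steps, axis=0)


def simulate_segmentation(
    grid: ImageGrid,
    volumes_ml: dict,
    lesion_ml: float = 0.0,
    seed: int = 0,
) -> Segmentation:
    """Disjoint GM/WM/CSF masks of exact voxel-rounded volume, lesion in WM.

    Requested ml volumes are converted to whole voxel counts with the
    grid's voxel volume.  A single connected head-like blob is grown and
    assigned inside-out: WM first (innermost), then GM, then CSF; the
    lesion takes the innermost WM voxels.
    """
    vv = grid.voxel_volume_mm3
    counts = {
        k: int(round(volumes_ml.get(k, 0.0) * 1000.0 / vv)) for k in ("gm", "wm", "csf")
    }
    lesion_count = int(round(lesion_ml * 1000.0 / vv))
    total = sum(counts.values())
    if total > grid.n_voxels:
        raise CapacityError(
            f"requested {total} tissue voxels exceed grid capacity {grid.n_voxels}"
        )
    if lesion_count > counts["wm"]:
        raise CapacityError("lesion volume exceeds white-matter volume")
    rng = np.random.default_rng(seed)
    gm = np.zeros(grid.shape, dtype=bool)
    wm = np.zeros(grid.shape, dtype=bool)
    csf = np.zeros(grid.shape, dtype=bool)
    lesion = np.zeros(grid.shape, dtype=bool)
    if total > 0:
        blob = _grow_blob(grid.shape, np.array([s // 2 for s in grid.shape]), total, rng)
        # inside-out ordering: distance from centre, ties by linear index
        idx = np.flatnonzero(blob)
        coords = np.stack(np.unravel_index(idx, grid.shape), axis=1).astype(float)
        center = np.array([s // 2 for s in grid.shape], dtype=float)
        order = np.lexsort((idx, ((coords - center) ** 2).sum(axis=1)))
        ordered = idx[order]
        wm_idx = ordered[: counts["wm"]]
        gm_idx = ordered[counts["wm"] : counts["wm"] + counts["gm"]]
        csf_idx = ordered[counts["wm"] + counts["gm"] : total]
        wm.flat[wm_idx] = True
        gm.flat[gm_idx] = True
        csf.flat[csf_idx] = True
        lesion.flat[wm_idx[:lesion_count]] = True
    return Segmentation(grid, gm=gm, wm=wm, csf=csf, lesion=lesion)


# ---------------------------------------------------------------------------
# Clinical-coupling generator (cluster level)
# ---------------------------------------------------------------------------

def simulate_clinical_coupling(
    n_subjects: int,
    slope: float,
    noise_sd: float = 1.0,
    seed: int = 0,
    intercept: float = 3.0,
    age_beta: float = 0.02,
    gender_beta: float = 0.3,
) -> pd.DataFrame:
    """Cluster-mean centrality linearly coupled to a clinical metric.

    The coupling direction matches the regression model (cluster mean as
    the outcome):

        cluster_mean = intercept + slope * (metric - 3) +
                       age_beta * (age - 45) + gender_beta * gender +
                       N(0, noise_sd),

    with the metric drawn as N(3, 1) (an EDSS-like score).  Used for
    slope-recovery and null-calibration checks of the clinical regression
    without simulating full 4D data.
    """
    rng = np.random.default_rng(seed)
    metric = 3.0 + rng.normal(size=n_subjects)
    age = 45 + 10 * rng.normal(size=n_subjects)
    gender = rng.integers(2, size=n_subjects)
    cluster_mean = (
        intercept
        + slope * (metric - 3.0)
        + age_beta * (age - 45)
        + gender_beta * gender
        + noise_sd * rng.normal(size=n_subjects)
    )
    return pd.DataFrame(
        dict(cluster_mean=cluster_mean, metric=metric, age=age, gender=gender)
    )
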