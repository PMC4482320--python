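"""Configuration-driven end-to-end runs at desk scale.

``run_study`` executes the full analysis shape on a synthetic study:
simulation -> preprocessing (discard, smooth, band-pass, nuisance
regression) -> centrality (DC at all thresholds + EC) -> group statistics
(two-sample GLM, paired test where pairs exist, ANCOVA where three groups
exist) -> Monte-Carlo cluster correction -> cluster tables -> clinical
regression.  Every run writes a machine-readable manifest (parameters,
seed, package version, per-output SHA-256 checksums) from which it can be
reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .centrality import (
    DEFAULT_THRESHOLDS,
    ThresholdSet,
    convert_for_group,
    fast_eigenvector_centrality,
    multi_threshold_dc,
    normalize_global_mean,
    rank_gauss,
    standardize_rows,
)
from .clinical import clinical_regression, cluster_mean_extract
from .errors import ConfigurationError
from .imaging import BrainMask, extract_matrix, insert_map, write_volume
from .preprocess import (
    NuisanceSet,
    bandpass,
    discard_volumes,
    motion_summary,
    regress_nuisance,
    smooth_gaussian,
)
from .stats import (
    alphasim_threshold,
    ancova_fmap,
    apply_cluster_correction,
    glm_tmap,
    label_clusters,
    make_group_design,
    paired_tmap,
    stack_maps,
)
from .synth import (
    GroupEffect,
    default_hub_spec,
    make_toy_mask,
    simulate_group_study,
    simulate_motion,
    subject_table,
)

log = logging.getLogger("smncent")

__all__ = ["RunConfig", "run_study", "run_from_manifest"]


@dataclass
class RunConfig:
    """All knobs of a study run.  Defaults are the standard analysis
    parameters:

    discard 10 volumes, band-pass 0.01-0.08 Hz, FWHM 6 mm smoothing,
    DC thresholds {0.1 ... 0.4} with 0.25 primary, per-voxel P = 0.01,
    rmm = 5 mm, 1000 Monte-Carlo iterations, corrected alpha = 0.05.
    The synthetic-study block is sized for a desk-scale demonstration.
    """

    seed: int = 0
    # synthetic study
    mask_shape: tuple[int, int, int] = (12, 12, 12)
    mask_voxels: int = 1000
    voxel_size_mm: float = 3.0
    n_control: int = 8
    n_remitting: int = 8
    n_paired: int = 0
    n_volumes: int = 120
    tr_seconds: float = 2.0
    n_communities: int = 4
    community_weight: float = 1.0
    noise_sd: float = 1.0
    ar1: float = 0.3
    subject_sd: float = 0.1
    effect_voxels: int = 0
    effect_delta: float = 0.0
    motion_amplitude_mm: float = 0.02
    # preprocessing
    discard: int = 10
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    fwhm_mm: float = 6.0
    # centrality
    r0_primary: float = 0.25
    r0_set: tuple[float, ...] = DEFAULT_THRESHOLDS
    dc_mode: str = "weighted_positive"
    ec_tol: float = 1e-12
    ec_max_iter: int = 1000
    conversion: str = "z_standardize"
    # group statistics
    voxel_p: float = 0.01
    rmm: float = 5.0
    alphasim_iterations: int = 1000
    alpha: float = 0.05
    # clinical regression
    metrics: tuple[str, ...] = ("edss", "bpf", "twmll_ml")

    def validate(self) -> None:
        if self.discard >= self.n_volumes:
            raise ConfigurationError("discard must leave at least 2 volumes")
        if not (0 < self.voxel_p < 1) or not (0 < self.alpha < 1):
            raise ConfigurationError("voxel_p and alpha must lie in (0, 1)")
        if self.band_high_hz > 1.0 / (2 * self.tr_seconds):
            raise ConfigurationError("band exceeds Nyquist")
        if self.r0_primary not in self.r0_set:
            raise ConfigurationError("primary r0 must be in the threshold set")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        for key in ("mask_shape", "r0_set", "metrics"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("mask_shape", "r0_set", "metrics"):
            d[key] = list(d[key])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _subject_maps(config: RunConfig, mask: BrainMask, sessions):
    """Preprocess each session and compute converted DC/EC maps."""
    rng_root = np.random.SeedSequence(config.seed ^ 0x5EED)
    motion_seeds = rng_root.spawn(len(sessions))
    dc_maps, ec_maps, motion_rows = [], [], []
    for k, (rec, img) in enumerate(sessions):
        img = discard_volumes(img, config.discard)
        img = smooth_gaussian(img, config.fwhm_mm, mask)
        vm = extract_matrix(img, mask)
        vm = bandpass(vm, config.tr_seconds, config.band_low_hz, config.band_high_hz)
        T = vm.n_timepoints
        mseed = int(motion_seeds[k].generate_state(1)[0] % (2**31))
        motion = simulate_motion(T, config.motion_amplitude_mm, seed=mseed)
        rng = np.random.default_rng(mseed + 1)
        nuis = NuisanceSet(
            wm_signal=vm.data.mean(axis=0),  # global-parenchyma proxy
            csf_signal=rng.normal(size=T),  # synthetic ventricular signal
            motion=motion,
        )
        vm = regress_nuisance(vm, nuis)
        ms = motion_summary(motion)
        motion_rows.append(
            dict(
                id=rec.id,
                session=rec.session,
                mean_displacement_mm=ms.mean_displacement_mm,
                max_translation_mm=ms.max_translation_mm,
                max_rotation_deg=ms.max_rotation_deg,
                excluded=ms.excluded,
            )
        )
        zvm, _ = standardize_rows(vm)
        dc_all = multi_threshold_dc(zvm, ThresholdSet(config.r0_set), mode=config.dc_mode)
        primary = next(m for m in dc_all if m.r0 == config.r0_primary)
        dc = convert_for_group(normalize_global_mean(primary), config.conversion)
        ec_raw = fast_eigenvector_centrality(zvm, tol=config.ec_tol, max_iter=config.ec_max_iter)
        ec = convert_for_group(rank_gauss(ec_raw), "z_standardize")
        dc_maps.append(dc)
        ec_maps.append(ec)
    return dc_maps, ec_maps, pd.DataFrame(motion_rows)


def _cluster_table(clusters, grid) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(clusters.clusters):
        ijk = np.unravel_index(c.peak_voxel, grid.shape)
        mm = grid.voxel_to_mm(np.array(ijk))[0]
        rows.append(
            dict(
                label=i,
                tail=c.tail,
                size=c.size,
                peak_stat=c.peak_stat,
                peak_i=ijk[0],
                peak_j=ijk[1],
                peak_k=ijk[2],
                peak_x_mm=mm[0],
                peak_y_mm=mm[1],
                peak_z_mm=mm[2],
                surviving=bool(c.surviving),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label", "tail", "size", "peak_stat", "peak_i", "peak_j", "peak_k",
            "peak_x_mm", "peak_y_mm", "peak_z_mm", "surviving",
        ],
    )


def run_study(config: RunConfig, outdir) -> Path:
    """Execute the full pipeline for ``config``; returns the run directory."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage_times: dict[str, float] = {}

    def tick(stage: str) -> None:
        stage_times[stage] = round(time.time() - t0 - sum(stage_times.values()), 3)
        log.info("stage %-12s done (%.2fs)", stage, stage_times[stage])

    root = np.random.SeedSequence(config.seed)
    s_mask, s_hub, s_study, s_alphasim = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(4)
    )

    mask = make_toy_mask(config.mask_shape, config.mask_voxels, s_mask, config.voxel_size_mm)
    hubs = default_hub_spec(
        mask,
        n_communities=config.n_communities,
        weight=config.community_weight,
        noise_sd=config.noise_sd,
        ar1=config.ar1,
        seed=s_hub,
    )
    effect = GroupEffect()
    if config.effect_voxels > 0:
        effect = GroupEffect(
            voxels=np.arange(min(config.effect_voxels, mask.n_voxels)),
            delta=config.effect_delta,
        )
    sessions, truth = simulate_group_study(
        mask,
        hubs,
        design=dict(
            n_control=config.n_control,
            n_remitting=config.n_remitting,
            n_paired=config.n_paired,
        ),
        effect=effect,
        T=config.n_volumes,
        tr_seconds=config.tr_seconds,
        seed=s_study,
        subject_sd=config.subject_sd,
    )
    records = [rec for rec, _ in sessions]
    write_volume(mask, outdir / "mask.nii")
    subject_table(records).to_csv(outdir / "subjects.tsv", sep="\t", index=False)
    tick("simulate")

    dc_maps, ec_maps, motion_df = _subject_maps(config, mask, sessions)
    motion_df.to_csv(outdir / "motion_summary.tsv", sep="\t", index=False)
    tick("preprocess+centrality")

    asr = alphasim_threshold(
        mask,
        fwhm_mm=config.fwhm_mm,
        voxel_p=config.voxel_p,
        rmm=config.rmm,
        iterations=config.alphasim_iterations,
        alpha=config.alpha,
        seed=s_alphasim,
    )
    pd.DataFrame(
        dict(alpha=list(asr.alpha_to_k), critical_k=list(asr.alpha_to_k.values()))
    ).to_csv(outdir / "alphasim.tsv", sep="\t", index=False)
    tick("alphasim")

    groups = np.array([r.group for r in records])
    age = np.array([r.age for r in records])
    gender = np.array([r.gender for r in records])
    comparisons: dict[str, dict] = {}

    def analyse(name: str, statmap) -> None:
        clusters = label_clusters(statmap, config.voxel_p, "both", rmm=config.rmm)
        clusters = apply_cluster_correction(clusters, asr, config.alpha)
        table = _cluster_table(clusters, mask.grid)
        table.to_csv(outdir / f"clusters_{name}.tsv", sep="\t", index=False)
        comparisons[name] = dict(clusters=clusters, statmap=statmap)

    for metric_name, maps in (("dc", dc_maps), ("ec", ec_maps)):
        Y = stack_maps(maps)
        write_volume(
            insert_map(Y.mean(axis=0), mask), outdir / f"group_mean_{metric_name}.nii",
            grid=mask.grid,
        )
        # two-sample: remitting (single-session) vs control
        sel = np.array([(r.group in ("remitting", "control")) and r.session == "single"
                        for r in records])
        if sel.sum() >= 4 and len(set(groups[sel])) == 2:
            design = make_group_design(
                (groups[sel] == "remitting").astype(float), age[sel], gender[sel]
            )
            tmap = glm_tmap(Y[sel], design, mask)
            write_volume(insert_map(tmap.values, mask), outdir / f"tmap_{metric_name}.nii",
                         grid=mask.grid)
            analyse(f"{metric_name}_twosample", tmap)
        # paired: relapse vs remit sessions of paired subjects
        pair_ids = sorted({r.pair_id for r in records if r.pair_id is not None})
        if len(pair_ids) >= 2:
            ia = [next(i for i, r in enumerate(records)
                       if r.pair_id == p and r.session == "relapse") for p in pair_ids]
            ib = [next(i for i, r in enumerate(records)
                       if r.pair_id == p and r.session == "remit") for p in pair_ids]
            pmap = paired_tmap(Y[ia], Y[ib], mask)
            analyse(f"{metric_name}_paired", pmap)
        else:
            log.info("no paired subjects: paired stage skipped for %s", metric_name)
        # ANCOVA across 3 groups where present
        if len(set(groups)) == 3:
            fmap = ancova_fmap(Y, groups, mask, covariates=np.column_stack([age, gender]))
            analyse(f"{metric_name}_ancova", fmap)

    tick("group_stats")

    # clinical regression on surviving clusters of the primary two-sample DC map
    regression_rows = []
    primary = comparisons.get("dc_twosample")
    if primary is not None and primary["clusters"].surviving:
        surv = primary["clusters"]
        surv_only = type(surv)(
            surv.mask, surv.surviving, surv.voxel_p, surv.stat_threshold, surv.rmm
        )
        patient = np.array([r.group != "control" for r in records])
        means = cluster_mean_extract(dc_maps, surv_only).loc[patient].reset_index(drop=True)
        pats = [r for r in records if r.group != "control"]
        metrics_df = pd.DataFrame(
            {m: [getattr(r, m) for r in pats] for m in config.metrics}
        )
        results = clinical_regression(
            means,
            metrics_df,
            age=np.array([r.age for r in pats]),
            gender=np.array([r.gender for r in pats]),
        )
        regression_rows = [dataclasses.asdict(r) for r in results]
    pd.DataFrame(
        regression_rows,
        columns=["cluster_id", "metric", "slope", "partial_correlation",
                 "p_uncorrected", "p_bonferroni", "n", "family_size"],
    ).to_csv(outdir / "clinical_regression.tsv", sep="\t", index=False)
    tick("clinical")

    outputs = sorted(
        p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = dict(
        software="smncent",
        version=__version__,
        seed=config.seed,
        config=config.to_dict(),
        n_sessions=len(records),
        planted_effect_voxels=int(truth.group_effect.astype(bool).sum()),
        stage_seconds=stage_times,
        checksums={name: _sha256(outdir / name) for name in outputs},
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("run complete in %.1fs -> %s", time.time() - t0, outdir)
    return outdir


def run_from_manifest(manifest_path, outdir) -> Path:
    """Re-execute a run from its manifest (bit-identical for equal seeds)."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    raw = manifest["config"]
    for key in ("mask_shape", "r0_set", "metrics"):
        raw[key] = tuple(raw[key])
    return run_study(RunConfig(**raw), outdir)
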