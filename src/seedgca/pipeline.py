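"""End-to-end orchestration: simulate -> preprocess -> influence maps ->
group statistics -> post-hoc correlations, with provenance capture.

Every stage is deterministic given the run configuration's master seed;
the manifest written at the end lists every artifact with its SHA-256
hash so two runs with identical settings can be compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import gca, group_stats, preprocess, synthetic
from . import io as sio

__all__ = ["RunConfig", "run_pipeline", "simulate_dataset", "PAPER_DEFAULTS"]

log = logging.getLogger("seedgca")

#: The canonical study-fixed settings, with plain-language descriptions.
PAPER_DEFAULTS = {
    "n_discard": (5, "initial volumes discarded for T1 saturation"),
    "n_volumes": (205, "volumes acquired per run (200 analyzed)"),
    "tr_seconds": (2.0, "repetition time in seconds"),
    "band_low_hz": (0.01, "band-pass lower edge, Hz"),
    "band_high_hz": (0.08, "band-pass upper edge, Hz"),
    "smoothing_fwhm_mm": (8.0, "isotropic Gaussian smoothing kernel FWHM, mm"),
    "motion_limit_mm": (1.5, "exclusion limit on any translation parameter, mm"),
    "motion_limit_deg": (1.5, "exclusion limit on any rotation angle, degrees"),
    "order": (1, "autoregressive model order (Schwarz criterion)"),
    "n_perm": (500, "permutation reshuffles for the null distribution"),
    "q_fdr": (0.05, "false discovery rate for voxel-level correction"),
    "min_cluster_size": (10, "minimum cluster extent in voxels"),
    "n_group_a": (22, "patient group size"),
    "n_group_b": (21, "control group size"),
    "correlation_alpha": (0.05, "uncorrected threshold for post-hoc correlations"),
}


@dataclass
class RunConfig:
    """Settings for a full pipeline run. Defaults are the canonical values."""

    out_dir: str = "seedgca_out"
    dataset_dir: str | None = None  # None -> simulate into out_dir/dataset
    rng_seed: int = 0
    # preprocessing
    n_discard: int = 5
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    smooth: bool = False
    smoothing_fwhm_mm: float = 8.0
    motion_limit_mm: float = 1.5
    motion_limit_deg: float = 1.5
    # connectivity
    order: int = 1
    n_perm: int = 500
    # group statistics
    q_fdr: float = 0.05
    min_cluster_size: int = 10
    connectivity: int = 26
    t_variant: str = "pooled"
    group_sig_method: str = "t_vs_null"
    # pooled permutation-null mean is estimated from this many randomly
    # sampled in-mask voxels per subject (the full grid is configurable
    # by setting it to a huge value)
    null_voxel_sample: int = 64
    correlation_alpha: float = 0.05
    correlation_scores: tuple[str, ...] = ("lsas_total", "lsas_fear", "lsas_avoidance")
    # synthetic cohort (used when dataset_dir is None)
    n_group_a: int = 22
    n_group_b: int = 21
    grid_dims: tuple[int, int, int] = (24, 24, 12)
    n_volumes: int = 205
    tr_seconds: float = 2.0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = (
            json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        ) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if "grid_dims" in data:
            cfg.grid_dims = tuple(data["grid_dims"])
        return cfg

    def preprocess_config(self) -> preprocess.PreprocessConfig:
        return preprocess.PreprocessConfig(
            n_discard=self.n_discard,
            band_low_hz=self.band_low_hz,
            band_high_hz=self.band_high_hz,
            smoothing_fwhm_mm=self.smoothing_fwhm_mm,
            apply_smoothing=self.smooth,
            motion_limit_mm=self.motion_limit_mm,
            motion_limit_deg=self.motion_limit_deg,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_dataset(config: RunConfig, dataset_dir: str | Path | None = None) -> Path:
    """Generate the default synthetic cohort and serialize it to disk.

    Layout: ``participants.csv``, ``masks/*.nii.gz``, and per subject
    ``sub-XX_bold.nii.gz`` + ``sub-XX_motion.txt`` (+ unit sidecar).
    """
    out = Path(dataset_dir or Path(config.out_dir) / "dataset")
    out.mkdir(parents=True, exist_ok=True)
    cohort = synthetic.synthesize_cohort(
        synthetic.default_cohort_config(
            n_group_a=config.n_group_a,
            n_group_b=config.n_group_b,
            grid_dims=config.grid_dims,
            n_volumes=config.n_volumes,
            tr_seconds=config.tr_seconds,
            rng_seed=config.rng_seed,
        )
    )
    masks_dir = out / "masks"
    masks_dir.mkdir(exist_ok=True)
    sio.write_mask(masks_dir / "brain.nii.gz", cohort.brain_mask)
    sio.write_mask(masks_dir / "wm.nii.gz", cohort.wm_mask)
    sio.write_mask(masks_dir / "csf.nii.gz", cohort.csf_mask)
    for name, mask in cohort.roi_masks.items():
        if name not in synthetic.NUISANCE_NODES:
            sio.write_mask(masks_dir / f"roi_{name}.nii.gz", mask)
    for sub in cohort.subjects:
        sid = sub.record.subject_id
        sio.write_volume(
            out / f"{sid}_bold.nii.gz", sub.volume, tr_seconds=config.tr_seconds
        )
        sio.write_motion(out / f"{sid}_motion.txt", sub.motion, rotation_unit="deg")
    sio.write_subject_table(out / "participants.csv", cohort.records_frame())
    return out


def _load_dataset(dataset_dir: Path):
    records = sio.read_subject_table(dataset_dir / "participants.csv")
    masks_dir = dataset_dir / "masks"
    brain, _ = sio.read_mask(masks_dir / "brain.nii.gz")
    wm, _ = sio.read_mask(masks_dir / "wm.nii.gz")
    csf, _ = sio.read_mask(masks_dir / "csf.nii.gz")
    seeds = {}
    for path in sorted(masks_dir.glob("roi_seed_*.nii.gz")):
        label = path.name[len("roi_") : -len(".nii.gz")]
        seeds[label], _ = sio.read_mask(path)
    if not seeds:
        raise ValueError(f"no seed ROI masks (masks/roi_seed_*.nii.gz) in {dataset_dir}")
    return records, brain, wm, csf, seeds


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the artifact manifest.

    Stages: (optional) simulation, per-subject preprocessing + motion QC,
    per-subject bidirectional influence maps per seed, group mean maps
    (two groups x two seeds x two directions = eight), group significance
    masks, patient-vs-control t maps inside the union mask, cluster
    extraction, post-hoc correlations, and the behavioral summary table.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    timings: dict[str, float] = {}

    if config.dataset_dir is None:
        t0 = time.time()
        dataset_dir = simulate_dataset(config)
        timings["simulate"] = time.time() - t0
        artifacts.extend(sorted(dataset_dir.rglob("*.*")))
    else:
        dataset_dir = Path(config.dataset_dir)
        if not (dataset_dir / "participants.csv").exists():
            raise FileNotFoundError(f"missing subject table in {dataset_dir}")

    records, brain, wm, csf, seed_masks = _load_dataset(dataset_dir)
    pp_cfg = config.preprocess_config()

    maps_dir = out / "maps"
    maps_dir.mkdir(exist_ok=True)
    t0 = time.time()
    qc_rows = []
    subject_maps: dict[tuple[str, str], list[np.ndarray]] = {
        (s, d): [] for s in seed_masks for d in ("from_seed", "to_seed")
    }
    null_means: dict[tuple[str, str], list[float]] = {
        (s, d): [] for s in seed_masks for d in ("from_seed", "to_seed")
    }
    kept_records = []
    for row in records.itertuples(index=False):
        sid = row.subject_id
        vol_path = dataset_dir / f"{sid}_bold.nii.gz"
        volume, _, tr = sio.read_volume(vol_path)
        tr = tr or config.tr_seconds
        sio.check_grid(volume.shape[:3], brain.shape, f"{sid} volume", "brain mask")
        motion = sio.read_motion(dataset_dir / f"{sid}_motion.txt")
        decision = preprocess.motion_exclusion(
            motion, (config.motion_limit_mm, config.motion_limit_deg)
        )
        trans_sum, rot_sum = preprocess.motion_summary(motion)
        qc_rows.append(
            {
                "subject_id": sid,
                "translation_summary_mm": trans_sum,
                "rotation_summary_deg": rot_sum,
                "excluded": decision.exclude,
                "offending_axis": decision.offending_axis or "",
            }
        )
        if decision.exclude:
            log.warning("excluding %s: %s exceeds motion limit", sid, decision.offending_axis)
            continue
        kept_records.append(row)

        cleaned, _ = preprocess.preprocess_voxelwise(
            volume, motion, wm, csf, brain, pp_cfg, tr
        )
        for seed_label, seed_mask in seed_masks.items():
            seed_series = preprocess.extract_mean_series(cleaned, seed_mask, tr)
            maps = gca.influence_maps(
                seed_series, cleaned, brain, config.order, seed_label
            )
            for direction, arr in (
                ("from_seed", maps.map_from_seed),
                ("to_seed", maps.map_to_seed),
            ):
                subject_maps[(seed_label, direction)].append(arr)
                path = maps_dir / f"{sid}_{seed_label}_{direction}.nii.gz"
                sio.write_volume(path, np.nan_to_num(arr, nan=-1.0))
                sidecar = path.with_name(path.name.replace(".nii.gz", ".json"))
                sidecar.write_text(
                    json.dumps(
                        {
                            "order": config.order,
                            "n_perm": config.n_perm,
                            "rng_seed": config.rng_seed,
                            "missing_value": -1.0,
                            "version": __version__,
                        }
                    )
                )
                artifacts.extend([path, sidecar])
                null_means[(seed_label, direction)].append(
                    gca.permutation_null_maps(
                        seed_series.samples,
                        cleaned,
                        brain,
                        direction=direction,
                        n_perm=config.n_perm,
                        rng_seed=config.rng_seed + 1,
                        pooled=True,
                        voxel_sample=config.null_voxel_sample,
                    )
                    if config.group_sig_method == "t_vs_null"
                    else 0.0
                )
    timings["subject_level"] = time.time() - t0

    qc_path = out / "qc_motion.tsv"
    pd.DataFrame(qc_rows).to_csv(qc_path, sep="\t", index=False)
    artifacts.append(qc_path)
    kept = pd.DataFrame(kept_records)

    # ---- group level ----------------------------------------------------
    t0 = time.time()
    group_dir = out / "group"
    group_dir.mkdir(exist_ok=True)
    is_sad = (kept["group"] == "SAD").to_numpy()
    cluster_rows = []
    for (seed_label, direction), stack in subject_maps.items():
        stack_arr = np.asarray(stack)
        tag = f"{seed_label}_{direction}"
        sig_masks = {}
        for grp, sel in (("SAD", is_sad), ("HC", ~is_sad)):
            mean_map, _ = group_stats.group_mean_map(stack_arr[sel])
            path = group_dir / f"mean_{grp}_{tag}.nii.gz"
            sio.write_volume(path, np.nan_to_num(mean_map, nan=-1.0))
            artifacts.append(path)
            null_mu = float(np.mean([null_means[(seed_label, direction)][i]
                                     for i in np.nonzero(sel)[0]])) if config.group_sig_method == "t_vs_null" else 0.0
            sig_masks[grp] = group_stats.significance_mask_for_group(
                stack_arr[sel],
                q=config.q_fdr,
                min_cluster_size=config.min_cluster_size,
                connectivity=config.connectivity,
                null_mean=null_mu,
            )
        union = group_stats.union_analysis_mask(sig_masks["SAD"], sig_masks["HC"])
        path = group_dir / f"analysis_mask_{tag}.nii.gz"
        sio.write_mask(path, union)
        artifacts.append(path)
        if not union.any():
            log.info("no significant voxels for %s: group comparison skipped", tag)
            continue
        stat_map = group_stats.two_sample_t_map(
            stack_arr[is_sad], stack_arr[~is_sad], union,
            q=config.q_fdr, variant=config.t_variant,
        )
        tmap_path = group_dir / f"tmap_{tag}.nii.gz"
        sio.write_volume(tmap_path, np.nan_to_num(stat_map.t_values, nan=0.0))
        artifacts.append(tmap_path)
        clusters = group_stats.extract_clusters(
            stat_map, config.min_cluster_size, config.connectivity
        )
        for ci, cluster in enumerate(clusters):
            row = {
                "cluster_id": f"{tag}_c{ci + 1}",
                "seed": seed_label,
                "direction_of_map": direction,
                "effect": cluster.direction,
                "size": cluster.size,
                "peak_voxel": "/".join(str(i) for i in cluster.peak_index),
            }
            for score in config.correlation_scores:
                res = group_stats.cluster_correlation(
                    cluster, stack_arr, kept, score,
                    alpha=config.correlation_alpha,
                )
                for grp, vals in res.items():
                    row[f"{score}_{grp}_r"] = vals["r"]
                    row[f"{score}_{grp}_p"] = vals["p"]
            cluster_rows.append(row)
    clusters_path = out / "clusters.tsv"
    pd.DataFrame(cluster_rows).to_csv(clusters_path, sep="\t", index=False)
    artifacts.append(clusters_path)

    table1 = group_stats.table1_summary(kept)
    table1_path = out / "behavioral_summary.tsv"
    table1.to_csv(table1_path, sep="\t", index=False)
    artifacts.append(table1_path)
    timings["group_level"] = time.time() - t0

    # the manifest is fully deterministic given config + seed; wall-clock
    # timings go to a separate log file that is not part of the manifest
    manifest = {
        "version": __version__,
        "settings": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in asdict(config).items()},
        "rng_seed": config.rng_seed,
        "n_subjects_analyzed": int(len(kept)),
        "n_group_maps": sum(
            1 for p in artifacts if p.name.startswith("mean_")
        ),
        "artifacts": {
            str(p.relative_to(out)) if p.is_relative_to(out) else str(p): _sha256(p)
            for p in artifacts
            if p.is_file()
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    timings["total"] = time.time() - t_start
    (out / "run_log.json").write_text(
        json.dumps({"timings_s": {k: round(v, 3) for k, v in timings.items()}})
    )
    for stage, seconds in timings.items():
        log.info("stage %s: %.2f s", stage, seconds)
    return manifest
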