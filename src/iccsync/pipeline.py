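"""End-to-end orchestration of the synchronization analysis.

Stages: (optional) simulation -> voxelwise ICC maps with surrogate/FDR
inference -> stationarity screen -> ROI extraction and network
clustering -> connectivity -> cortisol association.  Every artifact is
written as NIfTI or TSV with headers, stamped with a hash of the
configuration, and the whole run is a deterministic function of the
configuration plus master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, connectivity, simulate, stationarity, surrogates

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Configuration failed validation (missing path, bad parameter)."""


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    output_dir: str = "iccsync_out"
    #: directory of sub*_bold.nii volumes plus atlas/mask/labels; when
    #: None the synthetic generator provides the inputs
    data_dir: str | None = None
    subjects_table: str | None = None
    use_synthetic: bool = True
    n_surrogates: int = 50
    alpha: float = 0.05
    K_range: tuple[int, int] = (2, 6)
    lag_grid: tuple[int, ...] = stationarity.DEFAULT_LAG_GRID
    #: 1-based condition onset volumes
    ec_onset: int = 1
    eo_onset: int = 121
    covariates: tuple[str, ...] = connectivity.DEFAULT_COVARIATES
    #: cap on voxels entering the per-voxel KPSS/ADF screen (they are
    #: evenly subsampled beyond it); None = all voxels
    stationarity_max_voxels: int | None = 200
    seed: int = 0
    log_level: str = "INFO"
    design: simulate.SyntheticDesign = field(default_factory=simulate.SyntheticDesign)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        design = simulate.SyntheticDesign(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("design", {}).items()
        })
        for key in ("K_range", "lag_grid", "covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(design=design, **raw)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_surrogates < 2:
            raise ConfigError("n_surrogates must be >= 2")
        if not self.use_synthetic:
            if self.data_dir is None:
                raise ConfigError("data_dir is required when use_synthetic is false")
            d = Path(self.data_dir)
            for name in ("atlas.nii", "mask.nii", "atlas_labels.tsv"):
                if not (d / name).exists():
                    raise ConfigError(f"missing input: {d / name}")
            if not sorted(d.glob("sub*_bold.nii*")):
                raise ConfigError(f"no sub*_bold.nii volumes under {d}")
        if self.subjects_table is not None and not Path(self.subjects_table).exists():
            raise ConfigError(f"missing input: {self.subjects_table}")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


#: voxel size used for synthetic volumes (mm, mm, mm, unitless)
DEFAULT_AFFINE = np.diag([3.0, 3.0, 3.74, 1.0])


def _load_inputs(cfg: PipelineConfig):
    if cfg.use_synthetic:
        ds = simulate.simulate_dataset(cfg.design, rng=cfg.seed)
        return ds["data"], ds["atlas"], ds["mask"], ds["roi_table"], ds, DEFAULT_AFFINE

    import nibabel as nib

    d = Path(cfg.data_dir)
    vols = sorted(d.glob("sub*_bold.nii*"))
    first = nib.load(vols[0])
    data = np.stack([np.asarray(nib.load(p).dataobj, dtype=float) for p in vols])
    atlas = np.asarray(nib.load(d / "atlas.nii").dataobj).astype(np.int32)
    mask = np.asarray(nib.load(d / "mask.nii").dataobj).astype(bool)
    roi_table = pd.read_csv(d / "atlas_labels.tsv", sep="\t").set_index(
        "label_id", drop=False
    )
    if data.shape[1:4] != atlas.shape or atlas.shape != mask.shape:
        raise ConfigError(
            f"grid mismatch: data {data.shape[1:4]}, atlas {atlas.shape}, mask {mask.shape}"
        )
    return data, atlas, mask, roi_table, None, first.affine


def _write_nifti(path: Path, vol: np.ndarray, affine: np.ndarray | None = None) -> None:
    import nibabel as nib

    if affine is None:
        affine = DEFAULT_AFFINE
    nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine), path)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage; returns the output directory."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    rng = np.random.default_rng(cfg.seed)

    data, atlas, mask, roi_table, ds, affine = _load_inputs(cfg)
    M = data.shape[0]
    n = data.shape[-1]
    voxels = np.moveaxis(data[:, mask, :], 0, 2)  # (V, n, M)

    # --- voxelwise agreement maps + surrogate/FDR inference -------------
    vm, null, fdr_cfg = surrogates.stat_maps(
        voxels, mask, n_surrogates=cfg.n_surrogates, alpha=cfg.alpha,
        rng=rng.integers(2**31),
    )
    for name, vol in (
        ("A", vm.A_map), ("se", vm.se_map), ("t", vm.t_map), ("p", vm.p_map),
        ("supra_mask", vm.suprathreshold_mask.astype(np.float32)),
    ):
        _write_nifti(out / f"icc_{name}.nii", vol, affine)
    coords = np.argwhere(vm.suprathreshold_mask)
    pd.DataFrame(
        {
            "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
            "A": vm.A_map[vm.suprathreshold_mask],
            "t": vm.t_map[vm.suprathreshold_mask],
            "p": vm.p_map[vm.suprathreshold_mask],
        }
    ).to_csv(out / "suprathreshold.tsv", sep="\t", index=False)
    summary = {
        "n_subjects": int(M), "n_volumes": int(n),
        "n_voxels": int(mask.sum()),
        "n_suprathreshold": int(vm.suprathreshold_mask.sum()),
        "surrogate_critical_value": null.critical_value,
        "fdr_C_K": fdr_cfg.C_K,
        "config_hash": cfg.config_hash(),
    }

    # --- stationarity screen --------------------------------------------
    V = voxels.shape[0]
    if cfg.stationarity_max_voxels is not None and V > cfg.stationarity_max_voxels:
        step = V // cfg.stationarity_max_voxels
        sub = voxels[::step][: cfg.stationarity_max_voxels]
    else:
        sub = voxels
    report = stationarity.screen_report(sub, alpha=cfg.alpha)
    lag_grid = tuple(l for l in cfg.lag_grid if l < n - 3)
    profile = stationarity.lagged_corr_profile(sub, lag_grid)
    kpss_counts = report["kpss_reject"].sum(axis=1)
    M_sub = report["kpss_reject"].shape[1]
    stat_tab = pd.DataFrame(
        {
            "voxel": np.arange(sub.shape[0]),
            "n_subjects_rejected_kpss": kpss_counts,
            "n_subjects_rejected_kpss_fdr": report["kpss_reject_fdr"].sum(axis=1),
            "n_subjects_accepted_adf": report["adf_accept"].sum(axis=1),
        }
    )
    for frac in (0.5, 0.6, 0.7):
        stat_tab[f"flag_{int(frac * 100)}pct"] = kpss_counts >= np.ceil(frac * M_sub)
    stat_tab.to_csv(out / "stationarity.tsv", sep="\t", index=False)
    pd.DataFrame({"lag": lag_grid, "max_abs_corr": profile}).to_csv(
        out / "lagged_correlation.tsv", sep="\t", index=False
    )
    summary["kpss_proportions"] = {str(k): v for k, v in report["proportions"].items()}
    summary["kpss_proportions_fdr"] = {
        str(k): v for k, v in report["proportions_fdr"].items()
    }

    # --- ROI extraction, splitting, network clustering -------------------
    labels = {
        int(r.label_id): (str(r.roi_name), str(r.hemisphere) if pd.notna(r.hemisphere) else "")
        for r in roi_table.itertuples()
    }
    rois = clustering.roi_mean_timecourses(data, vm.suprathreshold_mask, atlas, labels)
    entries = []
    for e in rois:
        sel3d = (atlas == e.roi_id) & vm.suprathreshold_mask
        vox = data[:, sel3d, :]  # (M, nv, n)
        entries.extend(
            clustering.homogeneity_split(e, vox.mean(axis=0), subject_data=vox)
        )
    rois = clustering.ROISeriesSet(entries)
    if len(rois) >= 3:
        part = clustering.network_partition(
            rois.group_matrix(), K_range=cfg.K_range, random_state=cfg.seed
        )
        net_labels = part.labels
        summary["n_networks"] = int(part.K)
        summary["silhouette"] = float(part.silhouette_mean)
    else:
        net_labels = np.zeros(len(rois), dtype=int)
        logger.warning("fewer than 3 ROI entries; skipping network partition")
    pd.DataFrame(
        {
            "roi_id": [e.roi_id for e in rois],
            "sub_roi_id": [e.sub_roi for e in rois],
            "roi_name": [e.roi_name for e in rois],
            "hemisphere": [e.hemisphere for e in rois],
            "network_label": net_labels,
            "n_supra_voxels": [e.n_supra_voxels for e in rois],
            "supra_fraction": [e.supra_fraction for e in rois],
        }
    ).to_csv(out / "networks.tsv", sep="\t", index=False)
    tc = pd.DataFrame(
        rois.group_matrix().T, columns=[e.roi_name for e in rois]
    )
    tc.insert(0, "volume", np.arange(n) + 1)
    tc.to_csv(out / "group_timecourses.tsv", sep="\t", index=False)
    subj_cols = {
        f"{e.roi_name}@sub{s:03d}": e.subject_tcs[s]
        for e in rois
        for s in range(M)
    }
    subj_tc = pd.DataFrame(subj_cols)
    subj_tc.insert(0, "volume", np.arange(n) + 1)
    subj_tc.to_csv(out / "subject_timecourses.tsv", sep="\t", index=False)

    # --- connectivity + cortisol -----------------------------------------
    if len(rois) >= 2:
        tcs = {e.roi_name: e.subject_tcs for e in rois}
        table = connectivity.pairwise_connectivity(tcs)
        table.to_csv(out / "connectivity.tsv", sep="\t", index=False)
        # per-condition windows (1-based onsets -> half-open volume ranges)
        for cond, win in (
            ("EC", (cfg.ec_onset - 1, cfg.eo_onset - 1)),
            ("EO", (cfg.eo_onset - 1, n)),
        ):
            if 0 <= win[0] < win[1] <= n:
                connectivity.pairwise_connectivity(tcs, window=win).to_csv(
                    out / f"connectivity_{cond}.tsv", sep="\t", index=False
                )
        group = connectivity.group_connectivity_test(table, alpha=cfg.alpha)
        group.to_csv(out / "connectivity_group.tsv", sep="\t", index=False)
        hemi = {e.roi_name: e.hemisphere for e in rois if e.hemisphere in ("L", "R")}
        try:
            summaries = connectivity.hemispheric_summaries(table, hemi)
        except ValueError:
            summaries = None
        if summaries is not None:
            summaries.to_csv(out / "hemispheric_summaries.tsv", sep="\t")
            if cfg.subjects_table is not None:
                subjects = pd.read_csv(cfg.subjects_table, sep="\t")
            elif ds is not None and "inter" in summaries and len(summaries) >= 8:
                subjects = simulate.simulate_cortisol(
                    cfg.design, summaries["inter"].to_numpy(),
                    rng=rng.integers(2**31),
                )
                subjects.to_csv(out / "subjects.tsv", sep="\t", index=False)
            else:
                subjects = None
            if subjects is not None and len(subjects) >= len(summaries):
                subjects = subjects.reset_index(drop=True)
                assoc = connectivity.cortisol_association(
                    summaries, subjects.loc[summaries.index],
                    covariates=cfg.covariates,
                )
                assoc.to_csv(out / "cortisol_association.tsv", sep="\t", index=False)

    (out / "manifest.json").write_text(json.dumps(summary, indent=2))
    return out
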