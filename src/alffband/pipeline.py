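"""End-to-end orchestration: simulate -> metrics -> group stats -> classify.

Reads and writes the standard formats (NIfTI-1 images, TSV tables, JSON
results) and records a manifest (config echo + seed + version) sufficient
to reproduce a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .classify import CvConfig, make_views, nested_cv
from .metrics import (DEFAULT_BANDS, MetricMap, build_feature_table,
                      compute_metric_maps, normalize_map, region_means)
from .preprocess import preprocess_subject, qc_frame, qc_screen
from .stats import (CLUSTER_ALPHA, VOXEL_P, DesignInfo, bonferroni_gate,
                    estimate_smoothness, fit_voxelwise_ancova,
                    grf_cluster_threshold, partial_correlation,
                    posthoc_pairwise)
from .synthetic import (BoldDataset, GroupDesign, MotionTrace, Parcellation,
                        SyntheticCohort, VoxelGrid, gen_cohort, records_frame)

log = logging.getLogger(__name__)

COVARIATE_COLS = ("age", "sex", "education", "gm_volume_l", "mean_fd_mm")
SCORE_COLS = ("avlt_i", "avlt_d", "avlt_r", "mmse", "moca")


class ConfigError(Exception):
    """Bad configuration (CLI exit code 2)."""


class DataError(Exception):
    """Missing or inconsistent data on disk (CLI exit code 3)."""


@dataclass
class RunConfig:
    outdir: Path = Path("alffband_run")
    seed: int = 0
    sizes: tuple[int, ...] = (8, 8, 8, 8)
    n_regions: int = 116
    dims: tuple[int, int, int] = (24, 24, 18)
    n_drop: int = 10
    fwhm_mm: float = 4.0
    voxel_p: float = VOXEL_P
    cluster_alpha: float = CLUSTER_ALPHA
    bonferroni_m: int = 5
    cv: CvConfig = field(default_factory=CvConfig)

    @classmethod
    def from_toml(cls, path: Path) -> "RunConfig":
        import tomllib

        try:
            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        except FileNotFoundError as e:
            raise ConfigError(f"config file not found: {path}") from e
        except tomllib.TOMLDecodeError as e:
            raise ConfigError(f"invalid TOML in {path}: {e}") from e
        cfg = cls()
        cv_raw = raw.pop("cv", {})
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ConfigError(f"unknown config key {k!r}")
            cur = getattr(cfg, k)
            if isinstance(cur, tuple):
                v = tuple(v)
            if isinstance(cur, Path):
                v = Path(v)
            setattr(cfg, k, v)
        for k, v in cv_raw.items():
            if not hasattr(cfg.cv, k):
                raise ConfigError(f"unknown cv config key {k!r}")
            cur = getattr(cfg.cv, k)
            if isinstance(cur, tuple):
                v = tuple(v)
            setattr(cfg.cv, k, v)
        return cfg


# ----------------------------------------------------------------- NIfTI IO


def save_nifti(data: np.ndarray, grid: VoxelGrid, path: Path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine)
    img.header.set_zooms(tuple(grid.voxel_size) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def load_bold(path: Path, tr_seconds: float) -> BoldDataset:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = img.header.get_zooms()[:3]
    grid = VoxelGrid(dims=data.shape[:3], voxel_size=tuple(float(z) for z in zooms),
                     affine=np.asarray(img.affine))
    return BoldDataset(data=data, tr_seconds=tr_seconds, grid=grid)


def load_mask(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata()) > 0.5


def _manifest(outdir: Path, stage: str, cfg: RunConfig, extra: dict) -> None:
    payload = dict(stage=stage, version=__version__, seed=cfg.seed,
                   config=json.loads(json.dumps(dataclasses.asdict(cfg),
                                                default=str)),
                   **extra)
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def _log_stage(stage: str, seed: int, t0: float, **kw) -> None:
    log.info("stage=%s seed=%d elapsed_s=%.2f %s", stage, seed,
             time.time() - t0, " ".join(f"{k}={v}" for k, v in kw.items()))


# ------------------------------------------------------------------ stages


def cmd_simulate(cfg: RunConfig) -> SyntheticCohort:
    """Generate the synthetic cohort and write it to disk."""
    t0 = time.time()
    out = cfg.outdir / "cohort"
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise DataError(f"cannot create output directory {out}: {e}") from e
    design = GroupDesign(sizes=cfg.sizes, n_regions=cfg.n_regions,
                         dims=cfg.dims, seed=cfg.seed)
    cohort = gen_cohort(design)
    grid = cohort.parcellation.grid
    save_nifti(cohort.parcellation.labels, grid, out / "parcellation.nii.gz")
    cohort.parcellation.lookup.to_csv(out / "region_lookup.tsv", sep="\t",
                                      index=False)
    for name, mask in cohort.masks.items():
        save_nifti(mask.astype(np.float32), grid, out / f"mask_{name}.nii.gz")
    records_frame(list(cohort.records)).to_csv(out / "participants.tsv",
                                               sep="\t", index=False)
    for i, rec in enumerate(cohort.records):
        save_nifti(cohort.bold(i).data, grid, out / f"{rec.subject_id}_bold.nii.gz")
        motion = cohort.motion(i)
        pd.DataFrame(motion.params,
                     columns=["trans_x_mm", "trans_y_mm", "trans_z_mm",
                              "rot_x_rad", "rot_y_rad", "rot_z_rad"]).to_csv(
            out / f"{rec.subject_id}_motion.tsv", sep="\t", index=False)
    _manifest(cfg.outdir, "simulate", cfg, dict(n_subjects=len(cohort)))
    _log_stage("simulate", cfg.seed, t0, n_subjects=len(cohort))
    return cohort


def _load_cohort_inputs(cfg: RunConfig):
    out = cfg.outdir / "cohort"
    part = out / "participants.tsv"
    if not part.exists():
        raise DataError(f"missing subject table {part}; run simulate first")
    table = pd.read_csv(part, sep="\t")
    parc_img = nib.load(str(out / "parcellation.nii.gz"))
    labels = np.asarray(parc_img.get_fdata()).astype(int)
    lookup = pd.read_csv(out / "region_lookup.tsv", sep="\t")
    grid = VoxelGrid(dims=labels.shape,
                     voxel_size=tuple(float(z) for z in parc_img.header.get_zooms()[:3]),
                     affine=np.asarray(parc_img.affine))
    parc = Parcellation(labels=labels, lookup=lookup, grid=grid)
    masks = {name: load_mask(out / f"mask_{name}.nii.gz")
             for name in ("brain", "gm", "wm", "csf")}
    return out, table, parc, masks


def cmd_metrics(cfg: RunConfig, tr_seconds: float = 2.0) -> pd.DataFrame:
    """Preprocess every kept subject and build the feature table.

    Subjects failing motion QC are excluded with a logged reason; their
    rows are absent from the feature table.
    """
    t0 = time.time()
    out, table, parc, masks = _load_cohort_inputs(cfg)
    mdir = cfg.outdir / "metrics"
    mdir.mkdir(parents=True, exist_ok=True)

    from .synthetic import SubjectRecord

    qc_rows = []
    kept_records: list[SubjectRecord] = []
    kept_maps = []
    mean_maps: dict[tuple[str, str], list[np.ndarray]] = {}
    for _, row in table.iterrows():
        sid = row["subject_id"]
        mpath = out / f"{sid}_motion.tsv"
        bpath = out / f"{sid}_bold.nii.gz"
        if not mpath.exists():
            raise DataError(f"missing motion file for subject {sid}: {mpath}")
        if not bpath.exists():
            raise DataError(f"missing BOLD file for subject {sid}: {bpath}")
        motion = MotionTrace(params=pd.read_csv(mpath, sep="\t").to_numpy(float))
        qc = qc_screen(motion, subject_id=sid)
        qc_rows.append(qc)
        if qc.excluded:
            log.warning("excluding %s: %s", sid, qc.reason)
            continue
        ds = load_bold(bpath, tr_seconds)
        ds = preprocess_subject(ds, motion, masks, n_drop=cfg.n_drop,
                                fwhm_mm=cfg.fwhm_mm)
        raw = compute_metric_maps(ds, masks["brain"], DEFAULT_BANDS)
        maps = {}
        for (metric, band), m in raw.items():
            norm = normalize_map(m)
            maps[(norm.metric, band)] = norm
            mean_maps.setdefault((norm.metric, band), []).append(norm.data)
        kept_maps.append(maps)
        rec = SubjectRecord(**{k: row[k] for k in row.index})
        kept_records.append(rec)
    qc_frame(qc_rows).to_csv(mdir / "qc_report.tsv", sep="\t", index=False)
    if not kept_records:
        raise DataError("all subjects were excluded by motion QC")
    feats = build_feature_table(kept_records, kept_maps, parc, DEFAULT_BANDS)
    feats.to_csv(mdir / "features.tsv", sep="\t", index=False)
    # per-(metric, band) subject-stacked maps for the group stage
    for (metric, band), stack in mean_maps.items():
        arr = np.stack(stack)
        np.save(mdir / f"maps_{metric}_{band}.npy", arr.astype(np.float32))
    _manifest(cfg.outdir, "metrics", cfg,
              dict(n_kept=len(kept_records), n_excluded=len(table) - len(kept_records)))
    _log_stage("metrics", cfg.seed, t0, n_kept=len(kept_records))
    return feats


def cmd_groupstats(cfg: RunConfig) -> dict[tuple[str, str], pd.DataFrame]:
    """Voxelwise ANCOVA + GRF cluster report per (metric, band), ROI tables."""
    t0 = time.time()
    _, table, parc, masks = _load_cohort_inputs(cfg)
    mdir = cfg.outdir / "metrics"
    fpath = mdir / "features.tsv"
    if not fpath.exists():
        raise DataError(f"missing feature table {fpath}; run metrics first")
    feats = pd.read_csv(fpath, sep="\t")
    if feats["group"].nunique() < 2:
        raise DataError("need at least 2 groups for group statistics")
    gdir = cfg.outdir / "groupstats"
    gdir.mkdir(parents=True, exist_ok=True)
    design = DesignInfo(groups=feats["group"].to_numpy(),
                        covariates=feats[list(COVARIATE_COLS)].to_numpy(float),
                        covariate_names=COVARIATE_COLS)
    grid = parc.grid
    reports: dict[tuple[str, str], pd.DataFrame] = {}
    for metric in ("mALFF", "mfALFF"):
        for band in [b.name for b in DEFAULT_BANDS]:
            path = mdir / f"maps_{metric}_{band}.npy"
            if not path.exists():
                raise DataError(f"missing metric maps {path}")
            maps = np.load(path).astype(float)
            statmap, resid = fit_voxelwise_ancova(maps, design, masks["gm"])
            smooth = estimate_smoothness(resid, masks["gm"], grid.voxel_size,
                                         error_df=statmap.df2)
            clusters = grf_cluster_threshold(statmap, smooth, grid,
                                             cfg.voxel_p, cfg.cluster_alpha)
            rows = []
            for c in clusters:
                parcels = parc.labels[tuple(c.voxels.T)]
                parcels = parcels[parcels > 0]
                modal = int(np.bincount(parcels).argmax()) if len(parcels) else 0
                name = ""
                if modal:
                    name = parc.lookup.set_index("region_id")["region_name"].get(
                        modal, "")
                rows.append(dict(band=band, metric=metric, region_label=name,
                                 region_id=modal,
                                 peak_x_mm=c.peak_world_mm[0],
                                 peak_y_mm=c.peak_world_mm[1],
                                 peak_z_mm=c.peak_world_mm[2],
                                 cluster_size=c.size, peak_f=c.peak_stat,
                                 corrected_p=c.corrected_p))
            rep = pd.DataFrame(rows, columns=["band", "metric", "region_label",
                                              "region_id", "peak_x_mm", "peak_y_mm",
                                              "peak_z_mm", "cluster_size",
                                              "peak_f", "corrected_p"])
            rep.to_csv(gdir / f"clusters_{metric}_{band}.tsv", sep="\t", index=False)
            reports[(metric, band)] = rep
            # ROI post-hoc and score correlations for surviving clusters
            ph_rows, corr_rows = [], []
            for c in clusters:
                roi_vals = maps[:, c.voxels[:, 0], c.voxels[:, 1],
                                c.voxels[:, 2]].mean(axis=1)
                ph = posthoc_pairwise(roi_vals, design)
                ph.insert(0, "band", band)
                ph.insert(1, "metric", metric)
                ph.insert(2, "cluster_size", c.size)
                ph_rows.append(ph)
                cov_full = np.column_stack(
                    [feats[list(COVARIATE_COLS)].to_numpy(float),
                     pd.get_dummies(feats["group"], drop_first=True).to_numpy(float)])
                for score in SCORE_COLS:
                    r, p = partial_correlation(roi_vals,
                                               feats[score].to_numpy(float),
                                               cov_full)
                    sig, p_adj = bonferroni_gate(p, cfg.bonferroni_m)
                    corr_rows.append(dict(band=band, metric=metric,
                                          cluster_size=c.size, score=score,
                                          partial_r=r, p=p, p_bonferroni=p_adj,
                                          significant=sig))
            if ph_rows:
                pd.concat(ph_rows).to_csv(gdir / f"posthoc_{metric}_{band}.tsv",
                                          sep="\t", index=False)
            if corr_rows:
                pd.DataFrame(corr_rows).to_csv(
                    gdir / f"correlations_{metric}_{band}.tsv", sep="\t", index=False)
    _manifest(cfg.outdir, "groupstats", cfg,
              dict(n_reports=len(reports),
                   n_clusters=int(sum(len(r) for r in reports.values()))))
    _log_stage("groupstats", cfg.seed, t0, n_reports=len(reports))
    return reports


def cmd_classify(cfg: RunConfig, pair: tuple[str, str]) -> dict[str, dict]:
    """Three classifier runs for one group pair: ALFF-only, fALFF-only, fused."""
    t0 = time.time()
    fpath = cfg.outdir / "metrics" / "features.tsv"
    if not fpath.exists():
        raise DataError(f"missing feature table {fpath}; run metrics first")
    feats = pd.read_csv(fpath, sep="\t")
    for g in pair:
        if not (feats["group"] == g).any():
            raise DataError(f"unknown or empty group {g!r}")
    cdir = cfg.outdir / "classify"
    cdir.mkdir(parents=True, exist_ok=True)
    runs = {
        "alff": ("mALFF",),
        "falff": ("mfALFF",),
        "fused": ("mALFF", "mfALFF"),
    }
    results: dict[str, dict] = {}
    for mode, modalities in runs.items():
        views = make_views(feats, pair, modalities=modalities)
        res = nested_cv(views, cfg.cv)
        payload = dict(pair=list(pair), mode=mode,
                       means=res.means, sds=res.sds,
                       per_repeat=res.per_repeat.to_dict(orient="list"),
                       chosen_C=res.chosen_params["C"].value_counts().to_dict(),
                       chosen_beta1=res.chosen_params["beta1"].value_counts().to_dict())
        tag = f"{pair[0]}_vs_{pair[1]}_{mode}"
        (cdir / f"result_{tag}.json").write_text(json.dumps(payload, indent=2))
        res.roc_points.to_csv(cdir / f"roc_{tag}.tsv", sep="\t", index=False)
        results[mode] = payload
    _manifest(cfg.outdir, f"classify_{pair[0]}_vs_{pair[1]}", cfg,
              dict(modes=list(runs)))
    _log_stage("classify", cfg.seed, t0, pair="%s_vs_%s" % pair)
    return results


def file_sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
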