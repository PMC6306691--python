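"""Preprocessing chain for resting-state BOLD.

Stages, in pipeline order: initial-volume dropping, framewise-displacement
computation and head-motion screening (exclusion at >3 mm translation or
>3 deg rotation), Gaussian spatial smoothing (4 mm FWHM default), linear
detrending, and nuisance regression of the global, white-matter and CSF
mean signals together with the 24 Friston motion regressors.

Framewise displacement follows the Power convention: the sum of absolute
volume-to-volume changes of the three translations plus the three rotations
converted to arc length on a 50 mm sphere.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .synthetic import BoldDataset, MotionTrace

log = logging.getLogger(__name__)

#: QC exclusion thresholds
MAX_TRANSLATION_MM = 3.0
MAX_ROTATION_DEG = 3.0
#: sphere radius converting rotations to displacement in the FD formula
FD_ROTATION_RADIUS_MM = 50.0
#: FWHM-to-sigma conversion, 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class QcReport:
    subject_id: str
    max_trans_mm: float
    max_rot_deg: float
    mean_fd_mm: float
    excluded: bool
    reason: str


def drop_initial_volumes(ds: BoldDataset, n: int = 10) -> BoldDataset:
    """Remove the first ``n`` time points (scanner-equilibration volumes)."""
    if not (0 <= n < ds.n_volumes):
        raise ValueError(f"cannot drop {n} of {ds.n_volumes} volumes")
    if n == 0:
        return ds
    return BoldDataset(data=ds.data[..., n:], tr_seconds=ds.tr_seconds, grid=ds.grid)


def compute_fd(motion: MotionTrace, radius_mm: float = FD_ROTATION_RADIUS_MM) -> np.ndarray:
    """Power-style framewise displacement series (mm); FD of volume 1 is 0."""
    p = motion.params
    fd = np.zeros(p.shape[0])
    if p.shape[0] > 1:
        d = np.abs(np.diff(p, axis=0))
        fd[1:] = d[:, :3].sum(axis=1) + radius_mm * d[:, 3:].sum(axis=1)
    return fd


def qc_screen(motion: MotionTrace, subject_id: str = "") -> QcReport:
    """Apply the 3 mm / 3 degree exclusion rule and record mean FD."""
    max_trans = float(np.max(np.abs(motion.translations_mm))) if motion.n_volumes else 0.0
    max_rot_deg = float(np.degrees(np.max(np.abs(motion.rotations_rad)))) if motion.n_volumes else 0.0
    mean_fd = float(np.mean(compute_fd(motion)))
    reasons = []
    if max_trans > MAX_TRANSLATION_MM:
        reasons.append(f"max translation {max_trans:.2f} mm > {MAX_TRANSLATION_MM} mm")
    if max_rot_deg > MAX_ROTATION_DEG:
        reasons.append(f"max rotation {max_rot_deg:.2f} deg > {MAX_ROTATION_DEG} deg")
    return QcReport(subject_id=subject_id, max_trans_mm=max_trans,
                    max_rot_deg=max_rot_deg, mean_fd_mm=mean_fd,
                    excluded=bool(reasons), reason="; ".join(reasons))


def qc_frame(reports: list[QcReport]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in reports])


def build_friston24(motion: MotionTrace) -> np.ndarray:
    """Friston 24-parameter motion regressors.

    Columns 1-6 the parameters R, 7-12 R lagged one volume (first row
    zero-padded), 13-18 R squared, 19-24 lagged R squared.
    """
    if motion.n_volumes < 2:
        raise ValueError("need at least 2 volumes for Friston-24 regressors")
    r = motion.params
    lag = np.vstack([np.zeros((1, 6)), r[:-1]])
    return np.hstack([r, lag, r**2, lag**2])


def extract_nuisance_signals(ds: BoldDataset,
                             global_mask: np.ndarray,
                             wm_mask: np.ndarray,
                             csf_mask: np.ndarray,
                             motion: MotionTrace | None = None) -> pd.DataFrame:
    """Mean in-mask series for global/WM/CSF, joined with Friston-24 columns."""
    cols: dict[str, np.ndarray] = {}
    for name, mask in (("global", global_mask), ("wm", wm_mask), ("csf", csf_mask)):
        if mask.shape != ds.data.shape[:3]:
            raise ValueError(f"{name} mask shape {mask.shape} does not match grid")
        if not mask.any():
            raise ValueError(f"{name} mask is empty")
        cols[name] = ds.data[mask].mean(axis=0)
    out = pd.DataFrame(cols)
    if motion is not None:
        if motion.n_volumes != ds.n_volumes:
            raise ValueError("motion trace and dataset volume counts differ")
        f24 = build_friston24(motion)
        for j in range(24):
            out[f"friston{j + 1:02d}"] = f24[:, j]
    return out


def regress_nuisance(ds: BoldDataset, nuisance: pd.DataFrame | np.ndarray) -> BoldDataset:
    """Voxelwise least-squares removal of [intercept | nuisance regressors].

    Zero-variance and linearly redundant regressor columns are dropped with
    a logged warning; residuals are orthogonal to every kept regressor.
    """
    R = np.asarray(nuisance, dtype=float)
    if R.ndim != 2 or R.shape[0] != ds.n_volumes:
        raise ValueError("nuisance matrix rows must equal n_volumes")
    n = ds.n_volumes
    X = np.column_stack([np.ones(n), R])
    # drop redundant columns (keep intercept) via rank-revealing QR on the fly
    keep = [0]
    for j in range(1, X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
        else:
            log.warning("dropping redundant nuisance column %d", j - 1)
    X = X[:, keep]
    shape3 = ds.data.shape[:3]
    Y = ds.data.reshape(-1, n).T  # (n, V)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return BoldDataset(data=resid.T.reshape(shape3 + (n,)),
                       tr_seconds=ds.tr_seconds, grid=ds.grid)


def detrend_linear(ds: BoldDataset) -> BoldDataset:
    """Subtract each voxel's best-fit line over the volume index."""
    if ds.n_volumes < 3:
        raise ValueError("need at least 3 volumes to detrend")
    n = ds.n_volumes
    t = np.arange(n, dtype=float)
    X = np.column_stack([np.ones(n), t])
    Y = ds.data.reshape(-1, n).T
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return BoldDataset(data=resid.T.reshape(ds.data.shape),
                       tr_seconds=ds.tr_seconds, grid=ds.grid)


def smooth_gaussian(ds: BoldDataset, fwhm_mm: float = 4.0,
                    mask: np.ndarray | None = None) -> BoldDataset:
    """Isotropic Gaussian smoothing of each volume.

    With a foreground ``mask``, normalized (mask-weighted) convolution is
    used so edge voxels are not diluted by the zero background; without a
    mask, nearest-edge replication handles the array boundary.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return ds
    sigma_vox = [fwhm_mm / (FWHM_TO_SIGMA * v) for v in ds.grid.voxel_size]
    out = np.empty_like(ds.data)
    if mask is not None:
        m = mask.astype(float)
        norm = gaussian_filter(m, sigma_vox, mode="nearest")
        with np.errstate(invalid="ignore", divide="ignore"):
            for t in range(ds.n_volumes):
                sm = gaussian_filter(ds.data[..., t] * m, sigma_vox, mode="nearest")
                vol = np.where(norm > 1e-12, sm / np.where(norm > 0, norm, 1.0), 0.0)
                out[..., t] = np.where(mask, vol, 0.0)
    else:
        for t in range(ds.n_volumes):
            out[..., t] = gaussian_filter(ds.data[..., t], sigma_vox, mode="nearest")
    return BoldDataset(data=out, tr_seconds=ds.tr_seconds, grid=ds.grid)


def preprocess_subject(ds: BoldDataset, motion: MotionTrace,
                       masks: dict[str, np.ndarray],
                       n_drop: int = 10, fwhm_mm: float = 4.0) -> BoldDataset:
    """Full chain: drop -> smooth -> detrend -> nuisance regression.

    Motion QC is a screening decision made by the caller (excluded subjects
    never reach this function).  The motion trace is truncated to match the
    dropped volumes before building the Friston-24 block.
    """
    if motion.n_volumes != ds.n_volumes:
        raise ValueError("motion trace and dataset volume counts differ")
    ds = drop_initial_volumes(ds, n_drop)
    motion = MotionTrace(params=motion.params[n_drop:])
    ds = smooth_gaussian(ds, fwhm_mm=fwhm_mm, mask=masks.get("brain"))
    ds = detrend_linear(ds)
    nuis = extract_nuisance_signals(ds, masks["brain"], masks["wm"], masks["csf"],
                                    motion=motion)
    return regress_nuisance(ds, nuis)
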