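"""Synthetic resting-state BOLD cohorts with known band-limited amplitudes.

Emulates a four-group disease-severity cohort (normal controls, subjective
cognitive decline, amnestic mild cognitive impairment and Alzheimer-type
dementia analogues) on a desk-scale voxel grid.  Each subject's BOLD series
is a sum of region- and band-specific sinusoid mixtures with controlled
amplitude, shared low-frequency nuisance components (global / white-matter /
CSF), a linear drift, and Gaussian white noise.  Because band power is
planted analytically, amplitude-recovery and group-difference tests
downstream have known ground truth.

Sinusoid frequencies are snapped to DFT bins of the default analysis length
(229 volumes after the initial-volume drop) so spectral leakage does not
blur recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import cKDTree

from ._atlas import AAL116_NAMES

# ---------------------------------------------------------------- geometry

DEFAULT_DIMS: tuple[int, int, int] = (24, 24, 18)
DEFAULT_VOXEL_MM: float = 3.0
DEFAULT_TR_S: float = 2.0
DEFAULT_DURATION_S: float = 478.0
DEFAULT_N_VOLUMES: int = int(DEFAULT_DURATION_S / DEFAULT_TR_S)  # 239
#: analysis length after dropping the first 10 volumes; sinusoid frequencies
#: are snapped to DFT bins of this length by default
DEFAULT_SNAP_LENGTH: int = DEFAULT_N_VOLUMES - 10  # 229

#: canonical low-frequency bands (Hz): classic 0.01-0.1, slow-4, slow-5
BAND_EDGES: dict[str, tuple[float, float]] = {
    "classic": (0.01, 0.1),
    "slow4": (0.027, 0.073),
    "slow5": (0.01, 0.027),
}


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3-D voxel grid with a world (mm) affine."""

    dims: tuple[int, int, int] = DEFAULT_DIMS
    voxel_size: tuple[float, float, float] = (DEFAULT_VOXEL_MM,) * 3
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.dims):
            raise ValueError(f"all dims must be >= 1, got {self.dims}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size}")
        if self.affine is None:
            aff = np.diag(list(self.voxel_size) + [1.0])
            # world origin at the grid centre
            aff[:3, 3] = [-(d - 1) / 2.0 * v for d, v in zip(self.dims, self.voxel_size)]
            object.__setattr__(self, "affine", aff)
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]


@dataclass(frozen=True)
class Parcellation:
    """Integer label field (0 = background) plus a region lookup table."""

    labels: np.ndarray
    lookup: pd.DataFrame  # columns: region_id, region_name
    grid: VoxelGrid

    def __post_init__(self) -> None:
        present = np.unique(self.labels)
        present = present[present > 0]
        known = set(self.lookup["region_id"].tolist())
        missing = [int(r) for r in present if int(r) not in known]
        if missing:
            raise ValueError(f"labels {missing} not present in lookup table")

    @property
    def region_ids(self) -> np.ndarray:
        return self.lookup["region_id"].to_numpy()


@dataclass(frozen=True)
class BoldDataset:
    """4-D BOLD intensity field (x, y, z, t) with its repetition time."""

    data: np.ndarray
    tr_seconds: float
    grid: VoxelGrid

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be > 0")
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, t)")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 volumes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class MotionTrace:
    """Per-volume rigid-body parameters: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray  # (n_volumes, 6)

    def __post_init__(self) -> None:
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion params must have shape (n_volumes, 6)")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_rad(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass(frozen=True)
class SubjectRecord:
    """Demographics, covariates and neuropsychological scores for one subject."""

    subject_id: str
    group: str
    age: float
    sex: int  # 0 = male, 1 = female
    education: float
    gm_volume_l: float
    mean_fd_mm: float
    avlt_i: float
    avlt_d: float
    avlt_r: float
    mmse: float
    moca: float

    def __post_init__(self) -> None:
        if not (0 <= self.mmse <= 30):
            raise ValueError(f"MMSE must lie in [0, 30], got {self.mmse}")
        if not (0 <= self.moca <= 30):
            raise ValueError(f"MoCA must lie in [0, 30], got {self.moca}")
        for name in ("avlt_i", "avlt_d", "avlt_r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ------------------------------------------------------------ group design

#: per-group means/SDs of covariates and scores for the default cohort:
#: age (y), education (y), GM volume (L), AVLT-I/D/R, MMSE, MoCA, and the
#: fraction of female subjects.  Values mirror the published four-group
#: Alzheimer-spectrum cohort demographics.
_GROUP_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "NC": dict(age=(63.77, 8.09), education=(11.05, 4.92), gm=(0.60, 0.07),
               avlt_i=(9.16, 1.91), avlt_d=(10.19, 2.78), avlt_r=(12.05, 2.55),
               mmse=(28.14, 2.13), moca=(26.10, 3.12)),
    "SCD": dict(age=(65.13, 8.57), education=(11.80, 4.65), gm=(0.59, 0.07),
                avlt_i=(8.27, 1.79), avlt_d=(8.50, 2.72), avlt_r=(10.96, 2.73),
                mmse=(27.93, 1.86), moca=(25.17, 2.91)),
    "aMCI": dict(age=(67.51, 9.62), education=(10.13, 4.98), gm=(0.56, 0.07),
                 avlt_i=(6.15, 1.71), avlt_d=(4.06, 2.88), avlt_r=(7.96, 3.74),
                 mmse=(24.66, 4.20), moca=(19.77, 4.30)),
    "dAD": dict(age=(70.99, 10.07), education=(8.89, 5.75), gm=(0.49, 0.05),
                avlt_i=(3.59, 1.61), avlt_d=(1.00, 1.64), avlt_r=(3.73, 3.39),
                mmse=(16.55, 6.21), moca=(12.55, 5.11)),
}
_FEMALE_FRACTION = {"NC": 35 / 57, "SCD": 25 / 44, "aMCI": 28 / 55, "dAD": 32 / 47}
#: motion severity per group, calibrated so mean FD lands near the cohort's
#: reported 0.21-0.27 mm
_MOTION_SEVERITY = {"NC": 1.1, "SCD": 0.93, "aMCI": 1.1, "dAD": 1.2}


def default_effect_multipliers() -> dict[str, dict[tuple[int, str], float]]:
    """Graded amplitude multipliers planted in designated regions.

    The default plants monotone disease-severity effects in a precuneus
    analogue (slow-5), a mid-cingulate analogue (slow-4) and a posterior
    cerebellar analogue (slow-4 and slow-5), plus a mild increase in a
    hippocampal analogue in the classic band — qualitatively mirroring the
    graded decreases/increases the method is designed to detect.  Effect
    sizes are calibration choices of this generator, not measured values.
    """
    precuneus_l, cingulum_mid_r, cereb8_l, hippocampus_l = 67, 34, 103, 37
    out: dict[str, dict[tuple[int, str], float]] = {g: {} for g in _GROUP_TABLE}
    grades = {"NC": 1.0, "SCD": 0.85, "aMCI": 0.70, "dAD": 0.55}
    for g, m in grades.items():
        out[g][(precuneus_l, "slow5")] = m
        out[g][(cingulum_mid_r, "slow4")] = m
        out[g][(cereb8_l, "slow4")] = m
        out[g][(cereb8_l, "slow5")] = m
    increases = {"NC": 1.0, "SCD": 1.1, "aMCI": 1.25, "dAD": 1.4}
    for g, m in increases.items():
        out[g][(hippocampus_l, "classic")] = m
    return out


@dataclass
class GroupDesign:
    """Everything that determines a synthetic cohort, including its seed.

    ``multipliers[group][(region_id, band)]`` scales the region's planted
    band amplitude relative to ``base_amplitude``; unlisted pairs keep the
    base amplitude.
    """

    groups: tuple[str, ...] = ("NC", "SCD", "aMCI", "dAD")
    sizes: tuple[int, ...] = (8, 8, 8, 8)
    multipliers: dict[str, dict[tuple[int, str], float]] = field(
        default_factory=default_effect_multipliers)
    score_table: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {g: dict(v) for g, v in _GROUP_TABLE.items()})
    base_amplitude: float = 1.0
    noise_sd: float = 0.5
    drift_slope_range: tuple[float, float] = (-0.002, 0.002)  # per volume
    nuisance_gain: float = 0.2
    motion_severity: Mapping[str, float] = field(
        default_factory=lambda: dict(_MOTION_SEVERITY))
    spike_subjects: Mapping[str, float] = field(default_factory=dict)
    #: spike_subjects maps subject id -> spike size (mm)
    n_volumes: int = DEFAULT_N_VOLUMES
    tr_seconds: float = DEFAULT_TR_S
    dims: tuple[int, int, int] = DEFAULT_DIMS
    n_regions: int = 116
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group names must be unique")
        if len(self.sizes) != len(self.groups):
            raise ValueError("sizes and groups must align")
        if any(s < 1 for s in self.sizes):
            raise ValueError("all group sizes must be >= 1")
        for g, d in self.multipliers.items():
            for k, m in d.items():
                if m <= 0:
                    raise ValueError(f"multiplier for {g}{k} must be > 0, got {m}")


# -------------------------------------------------------------- operations


def ellipsoid_mask(dims: tuple[int, int, int], radius_frac: float = 0.9) -> np.ndarray:
    """Central ellipsoidal foreground with semi-axes ``radius_frac*dims/2``."""
    return _normalized_radius(dims, radius_frac) <= 1.0


def _normalized_radius(dims: tuple[int, int, int], radius_frac: float = 0.9) -> np.ndarray:
    centre = [(d - 1) / 2.0 for d in dims]
    semi = [radius_frac * d / 2.0 for d in dims]
    grids = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    rho2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semi))
    return np.sqrt(rho2)


def compartment_masks(dims: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Brain, GM, WM and CSF masks: CSF is a central core, WM an outer ring,
    GM the shell between them (all inside the ellipsoidal foreground)."""
    rho = _normalized_radius(dims)
    brain = rho <= 1.0
    csf = rho < 0.3
    wm = (rho >= 0.85) & brain
    gm = brain & ~csf & ~wm
    return {"brain": brain, "gm": gm, "wm": wm, "csf": csf}


def gen_parcellation(dims: tuple[int, int, int] = DEFAULT_DIMS,
                     n_regions: int = 116, seed: int = 0,
                     voxel_size: tuple[float, float, float] = (DEFAULT_VOXEL_MM,) * 3,
                     ) -> Parcellation:
    """Nearest-seed (Voronoi) partition of the ellipsoidal foreground.

    Every id ``1..n_regions`` occurs at least once (each seed voxel is its
    own nearest seed).  Deterministic for a fixed seed.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    fg = ellipsoid_mask(dims)
    coords = np.argwhere(fg)
    if n_regions > len(coords):
        raise ValueError(
            f"n_regions={n_regions} exceeds foreground voxel count {len(coords)}")
    rng = np.random.default_rng(seed)
    seed_idx = rng.choice(len(coords), size=n_regions, replace=False)
    tree = cKDTree(coords[seed_idx])
    _, nearest = tree.query(coords)
    labels = np.zeros(dims, dtype=np.int32)
    labels[tuple(coords.T)] = nearest + 1
    if n_regions == 116:
        names = list(AAL116_NAMES)
    else:
        names = [f"region_{i:03d}" for i in range(1, n_regions + 1)]
    lookup = pd.DataFrame({"region_id": np.arange(1, n_regions + 1),
                           "region_name": names})
    grid = VoxelGrid(dims=dims, voxel_size=voxel_size)
    return Parcellation(labels=labels, lookup=lookup, grid=grid)


#: per-volume motion step SDs at severity 1 (mm, rad); with the AR(1)
#: mean-reversion below these give a mean FD near 0.23 mm
_TRANS_STEP_SD = 0.06
_ROT_STEP_SD = 0.0007
_AR_COEF = 0.98


def gen_motion(n_volumes: int, severity: float = 1.0,
               spike_mm: float | None = None, seed: int = 0) -> MotionTrace:
    """Smooth mean-reverting random-walk motion trace scaled by ``severity``.

    If ``spike_mm`` is given, one mid-scan volume carries a translation step
    of that size (which persists, as real head repositioning does).
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    if severity < 0:
        raise ValueError("severity must be >= 0")
    rng = np.random.default_rng(seed)
    steps = np.empty((n_volumes, 6))
    steps[:, :3] = rng.normal(0.0, _TRANS_STEP_SD, (n_volumes, 3))
    steps[:, 3:] = rng.normal(0.0, _ROT_STEP_SD, (n_volumes, 3))
    steps *= severity
    params = np.zeros((n_volumes, 6))
    for t in range(1, n_volumes):
        params[t] = _AR_COEF * params[t - 1] + steps[t]
    if spike_mm is not None:
        t0 = n_volumes // 2
        params[t0:, 0] += spike_mm
    return MotionTrace(params=params)


def _band_bins(band: tuple[float, float], snap_length: int, tr: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(snap_length, d=tr)
    k = np.nonzero((freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0))[0]
    return freqs[k]


def _sinusoid_mixture(freqs_hz: np.ndarray, t_seconds: np.ndarray,
                      rng: np.random.Generator, n_sinusoids: int) -> np.ndarray:
    """Unit-variance mixture of ``n_sinusoids`` random in-band sinusoids."""
    n_pick = min(n_sinusoids, len(freqs_hz))
    f = rng.choice(freqs_hz, size=n_pick, replace=False)
    phases = rng.uniform(0, 2 * np.pi, size=n_pick)
    s = np.sin(2 * np.pi * f[:, None] * t_seconds[None, :] + phases[:, None]).sum(axis=0)
    return s / np.sqrt(n_pick / 2.0)


def _smooth_nuisance(n_volumes: int, rng: np.random.Generator,
                     sigma_vols: float = 15.0) -> np.ndarray:
    """Low-frequency smooth random series, standardized to unit variance."""
    x = gaussian_filter1d(rng.standard_normal(n_volumes), sigma_vols, mode="reflect")
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_bold_subject(parc: Parcellation,
                     amplitudes: Mapping[str, Mapping[int, float]],
                     n_volumes: int = DEFAULT_N_VOLUMES,
                     tr_seconds: float = DEFAULT_TR_S,
                     noise_sd: float = 0.5,
                     drift_slope: float = 0.0,
                     nuisance_gain: float = 0.2,
                     seed: int = 0,
                     snap_length: int = DEFAULT_SNAP_LENGTH,
                     n_sinusoids: int = 5,
                     masks: Mapping[str, np.ndarray] | None = None,
                     ) -> BoldDataset:
    """Generate one subject's 4-D BOLD dataset.

    Each foreground voxel's series is the sum over bands of its region's
    amplitude times a unit-variance sinusoid mixture, plus shared
    global/WM/CSF nuisance components, a linear drift of ``drift_slope``
    per volume, and white noise.

    ``amplitudes`` maps band name -> {region_id: amplitude >= 0}.
    """
    dims = parc.labels.shape
    known = set(int(r) for r in parc.region_ids)
    for band, per_region in amplitudes.items():
        if band not in BAND_EDGES:
            raise ValueError(f"unknown band {band!r}; expected {sorted(BAND_EDGES)}")
        for r, a in per_region.items():
            if int(r) not in known:
                raise ValueError(f"region id {r} absent from parcellation")
            if a < 0:
                raise ValueError(f"amplitude for region {r} must be >= 0, got {a}")
    if n_volumes * tr_seconds < 1.0 / 0.01:
        raise ValueError("scan too short to resolve 0.01 Hz")

    rng = np.random.default_rng(seed)
    if masks is None:
        masks = compartment_masks(dims)
    fg = parc.labels > 0

    t = np.arange(n_volumes) * tr_seconds
    region_ids = [int(r) for r in parc.region_ids]
    # per-region composite series over all bands
    region_series = np.zeros((len(region_ids), n_volumes))
    for i, r in enumerate(region_ids):
        for band, (lo, hi) in BAND_EDGES.items():
            amp = float(amplitudes.get(band, {}).get(r, 0.0))
            if amp == 0.0:
                continue
            freqs = _band_bins((lo, hi), snap_length, tr_seconds)
            if len(freqs) == 0:
                raise ValueError(f"band {band} resolves no DFT bins at length "
                                 f"{snap_length}, TR {tr_seconds}")
            region_series[i] += amp * _sinusoid_mixture(freqs, t, rng, n_sinusoids)

    glob = _smooth_nuisance(n_volumes, rng)
    wm_sig = _smooth_nuisance(n_volumes, rng)
    csf_sig = _smooth_nuisance(n_volumes, rng)

    data = np.zeros(dims + (n_volumes,))
    label_of = parc.labels
    idx_of = {r: i for i, r in enumerate(region_ids)}
    flat_labels = label_of[fg]
    series_rows = np.array([idx_of[int(l)] for l in flat_labels])
    voxel_signal = region_series[series_rows]  # (n_fg, n_volumes)
    voxel_signal = voxel_signal + nuisance_gain * glob[None, :]
    wm_rows = masks["wm"][fg]
    csf_rows = masks["csf"][fg]
    voxel_signal[wm_rows] += nuisance_gain * wm_sig[None, :]
    voxel_signal[csf_rows] += nuisance_gain * csf_sig[None, :]
    if drift_slope != 0.0:
        voxel_signal = voxel_signal + drift_slope * np.arange(n_volumes)[None, :]
    if noise_sd > 0:
        voxel_signal = voxel_signal + rng.normal(0.0, noise_sd, voxel_signal.shape)
    data[fg] = voxel_signal
    grid = VoxelGrid(dims=dims, voxel_size=parc.grid.voxel_size)
    return BoldDataset(data=data, tr_seconds=tr_seconds, grid=grid)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    """Draw and clip to the invariant range (simple truncation by clipping)."""
    return float(np.clip(rng.normal(mean, sd), lo, hi))


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: records plus on-demand per-subject image data.

    Image data are synthesized lazily (deterministically per subject) so a
    full cohort never has to live in memory at once.
    """

    design: GroupDesign
    parcellation: Parcellation
    masks: dict[str, np.ndarray]
    records: tuple[SubjectRecord, ...]
    _subject_seeds: tuple[int, ...]
    _severities: tuple[float, ...]
    _drifts: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.records)

    def motion(self, i: int) -> MotionTrace:
        rec = self.records[i]
        spike = self.design.spike_subjects.get(rec.subject_id)
        return gen_motion(self.design.n_volumes, severity=self._severities[i],
                          spike_mm=spike, seed=self._subject_seeds[i])

    def bold(self, i: int) -> BoldDataset:
        d = self.design
        rec = self.records[i]
        amplitudes: dict[str, dict[int, float]] = {b: {} for b in BAND_EDGES}
        mult = d.multipliers.get(rec.group, {})
        for r in self.parcellation.region_ids:
            for b in BAND_EDGES:
                amplitudes[b][int(r)] = d.base_amplitude * mult.get((int(r), b), 1.0)
        return gen_bold_subject(
            self.parcellation, amplitudes, n_volumes=d.n_volumes,
            tr_seconds=d.tr_seconds, noise_sd=d.noise_sd,
            drift_slope=self._drifts[i], nuisance_gain=d.nuisance_gain,
            seed=self._subject_seeds[i] + 1, masks=self.masks)

    def subjects(self) -> Iterator[tuple[SubjectRecord, BoldDataset, MotionTrace]]:
        for i in range(len(self)):
            yield self.records[i], self.bold(i), self.motion(i)


def gen_cohort(design: GroupDesign | None = None) -> SyntheticCohort:
    """Generate the full four-group cohort (records, parcels, masks, images).

    Covariates and scores are drawn from group-specific normals truncated to
    their admissible ranges; the design seed fully determines the output.
    """
    if design is None:
        design = GroupDesign()
    rng = np.random.default_rng(design.seed)
    parc = gen_parcellation(design.dims, design.n_regions, seed=design.seed)
    masks = compartment_masks(design.dims)

    # avoid circular import at module load
    from .preprocess import compute_fd

    records: list[SubjectRecord] = []
    seeds: list[int] = []
    sevs: list[float] = []
    drifts: list[float] = []
    sid = 0
    for group, size in zip(design.groups, design.sizes):
        tab = design.score_table.get(group)
        for _ in range(size):
            sid += 1
            subject_id = f"sub-{sid:03d}"
            sub_seed = int(rng.integers(0, 2**31 - 1))
            severity = float(design.motion_severity.get(group, 1.0))
            drift = float(rng.uniform(*design.drift_slope_range))
            motion = gen_motion(design.n_volumes, severity=severity,
                                spike_mm=design.spike_subjects.get(subject_id),
                                seed=sub_seed)
            mean_fd = float(np.mean(compute_fd(motion)))
            if tab is None:  # unknown group name: generic healthy-range draws
                tab = design.score_table.get("NC", _GROUP_TABLE["NC"])
            rec = SubjectRecord(
                subject_id=subject_id, group=group,
                age=_truncated_normal(rng, *tab["age"], 18, 100),
                sex=int(rng.random() < _FEMALE_FRACTION.get(group, 0.5)),
                education=_truncated_normal(rng, *tab["education"], 0, 25),
                gm_volume_l=_truncated_normal(rng, *tab["gm"], 0.2, 1.0),
                mean_fd_mm=mean_fd,
                avlt_i=_truncated_normal(rng, *tab["avlt_i"], 0, 15),
                avlt_d=_truncated_normal(rng, *tab["avlt_d"], 0, 15),
                avlt_r=_truncated_normal(rng, *tab["avlt_r"], 0, 15),
                mmse=_truncated_normal(rng, *tab["mmse"], 0, 30),
                moca=_truncated_normal(rng, *tab["moca"], 0, 30),
            )
            records.append(rec)
            seeds.append(sub_seed)
            sevs.append(severity)
            drifts.append(drift)
    return SyntheticCohort(design=design, parcellation=parc, masks=masks,
                           records=tuple(records), _subject_seeds=tuple(seeds),
                           _severities=tuple(sevs), _drifts=tuple(drifts))


def records_frame(records: tuple[SubjectRecord, ...]) -> pd.DataFrame:
    """Subject table with the fixed on-disk header."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records],
                        columns=["subject_id", "group", "age", "sex", "education",
                                 "gm_volume_l", "mean_fd_mm", "avlt_i", "avlt_d",
                                 "avlt_r", "mmse", "moca"])
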