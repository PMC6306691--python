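"""Amplitude spectra, ALFF/fALFF and their normalized maps, region features.

ALFF in a band is the *mean* one-sided spectral amplitude over the band's
DFT bins (the REST convention); fALFF is the band amplitude sum divided by
the amplitude sum over all non-DC bins up to Nyquist.  Band edges are
closed intervals.  The DC bin is always excluded; when the series length is
even the Nyquist bin is included with its 2/N scaling halved (it has no
conjugate partner).  mALFF / mfALFF divide each in-mask voxel by the
in-mask mean, producing maps with mean 1.

No taper or window is applied before the transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import (BAND_EDGES, BoldDataset, Parcellation, SubjectRecord)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandSpec:
    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ValueError(f"need 0 < f_low < f_high, got {self}")


DEFAULT_BANDS: tuple[BandSpec, ...] = tuple(
    BandSpec(name, lo, hi) for name, (lo, hi) in BAND_EDGES.items())


@dataclass(frozen=True)
class AmplitudeSpectrum:
    """One-sided amplitude spectrum, DC excluded; ``floor(N/2)`` bins."""

    frequencies_hz: np.ndarray
    amplitudes: np.ndarray


@dataclass(frozen=True)
class MetricMap:
    """3-D scalar field of one metric in one band, with its analysis mask."""

    metric: str  # ALFF | fALFF | mALFF | mfALFF
    band: str
    data: np.ndarray
    mask: np.ndarray


def _one_sided_amplitudes(Y: np.ndarray, axis: int = -1) -> np.ndarray:
    """``(2/N)|X_k|`` for k=1..floor(N/2); Nyquist bin scaling halved for even N."""
    N = Y.shape[axis]
    X = np.fft.rfft(Y, axis=axis)
    amp = (2.0 / N) * np.abs(X)
    amp = np.take(amp, np.arange(1, N // 2 + 1), axis=axis)
    if N % 2 == 0:
        sl = [slice(None)] * amp.ndim
        sl[axis] = -1
        amp[tuple(sl)] /= 2.0
    return amp


def amplitude_spectrum(series: np.ndarray, tr_seconds: float) -> AmplitudeSpectrum:
    """One-sided DFT amplitude spectrum of a single series."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < 4:
        raise ValueError("series must be 1-D with at least 4 samples")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    N = series.size
    freqs = np.fft.rfftfreq(N, d=tr_seconds)[1:N // 2 + 1]
    return AmplitudeSpectrum(frequencies_hz=freqs,
                             amplitudes=_one_sided_amplitudes(series))


def _band_bin_mask(freqs: np.ndarray, band: BandSpec) -> np.ndarray:
    m = (freqs >= band.f_low) & (freqs <= band.f_high)
    if not m.any():
        df = freqs[0] if len(freqs) else float("nan")
        raise ValueError(
            f"band {band.name} [{band.f_low}, {band.f_high}] Hz contains no DFT "
            f"bins at frequency resolution {df:.6f} Hz")
    return m


def alff(series: np.ndarray, tr_seconds: float, band: BandSpec) -> float:
    """Mean one-sided amplitude over the band's DFT bins (closed interval)."""
    spec = amplitude_spectrum(series, tr_seconds)
    m = _band_bin_mask(spec.frequencies_hz, band)
    return float(spec.amplitudes[m].mean())


def falff(series: np.ndarray, tr_seconds: float, band: BandSpec) -> float:
    """Band amplitude sum over the total non-DC amplitude sum, in [0, 1].

    A zero-variance (degenerate) series yields 0.
    """
    series = np.asarray(series, dtype=float)
    if np.ptp(series) == 0:
        return 0.0
    spec = amplitude_spectrum(series, tr_seconds)
    m = _band_bin_mask(spec.frequencies_hz, band)
    total = spec.amplitudes.sum()
    if total == 0:
        return 0.0
    return float(spec.amplitudes[m].sum() / total)


def check_band_resolution(n_volumes: int, tr_seconds: float) -> None:
    """Band metrics need a frequency resolution of at most 0.01 Hz."""
    res = 1.0 / (n_volumes * tr_seconds)
    if res > 0.01:
        raise ValueError(
            f"frequency resolution 1/(N*TR) = {res:.5f} Hz exceeds 0.01 Hz; "
            "the scan is too short for low-frequency band metrics")


def compute_metric_maps(ds: BoldDataset, mask: np.ndarray,
                        bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
                        ) -> dict[tuple[str, str], MetricMap]:
    """Voxelwise ALFF and fALFF maps per band; out-of-mask voxels are 0.

    Returns a dict keyed by ``(metric, band_name)`` with 2 x len(bands)
    entries.  Zero-variance voxels get ALFF 0 and fALFF 0.
    """
    if mask.shape != ds.data.shape[:3]:
        raise ValueError("mask shape does not match dataset grid")
    if not mask.any():
        raise ValueError("analysis mask is empty")
    check_band_resolution(ds.n_volumes, ds.tr_seconds)
    N = ds.n_volumes
    freqs = np.fft.rfftfreq(N, d=ds.tr_seconds)[1:N // 2 + 1]
    Y = ds.data[mask]  # (V, N)
    amp = _one_sided_amplitudes(Y, axis=1)
    degenerate = np.ptp(Y, axis=1) == 0
    total = amp.sum(axis=1)
    out: dict[tuple[str, str], MetricMap] = {}
    for band in bands:
        m = _band_bin_mask(freqs, band)
        a = amp[:, m].mean(axis=1)
        a[degenerate] = 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(total > 0, amp[:, m].sum(axis=1) / total, 0.0)
        f[degenerate] = 0.0
        for metric, vals in (("ALFF", a), ("fALFF", f)):
            field = np.zeros(ds.data.shape[:3])
            field[mask] = vals
            out[(metric, band.name)] = MetricMap(metric=metric, band=band.name,
                                                 data=field, mask=mask.copy())
    return out


def normalize_map(m: MetricMap, mask: np.ndarray | None = None) -> MetricMap:
    """Divide each in-mask voxel by the in-mask mean (mALFF / mfALFF).

    Degenerate voxels (exact zeros inside the mask) are excluded from the
    normalizing mean but remain zero in the output.
    """
    mask = m.mask if mask is None else mask
    vals = m.data[mask]
    nonzero = vals != 0
    if not nonzero.any() or vals[nonzero].mean() <= 0:
        raise ValueError(f"cannot normalize {m.metric}/{m.band}: "
                         "nonpositive in-mask mean")
    mean = vals[nonzero].mean()
    field = np.zeros_like(m.data)
    field[mask] = vals / mean
    return MetricMap(metric="m" + m.metric, band=m.band, data=field, mask=mask.copy())


def region_means(m: MetricMap, parc: Parcellation) -> pd.Series:
    """Mean in-mask metric value per region; empty regions are NaN."""
    if parc.labels.shape != m.data.shape:
        raise ValueError("parcellation grid does not match metric map")
    ids = parc.region_ids
    out = pd.Series(np.nan, index=pd.Index(ids, name="region_id"), dtype=float)
    lab = np.where(m.mask, parc.labels, 0)
    counts = np.bincount(lab.ravel(), minlength=int(ids.max()) + 1)
    sums = np.bincount(lab.ravel(), weights=m.data.ravel(),
                       minlength=int(ids.max()) + 1)
    for r in ids:
        if counts[r] > 0:
            out[r] = sums[r] / counts[r]
    return out


METRIC_ORDER = ("mALFF", "mfALFF")


def feature_columns(parc: Parcellation,
                    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
                    metrics: tuple[str, ...] = METRIC_ORDER) -> list[str]:
    """Deterministic column order: metric -> band -> region id."""
    return [f"{metric}__{band.name}__r{int(r):03d}"
            for metric in metrics for band in bands for r in parc.region_ids]


def subject_features(maps: dict[tuple[str, str], MetricMap],
                     parc: Parcellation,
                     bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
                     metrics: tuple[str, ...] = METRIC_ORDER) -> pd.Series:
    """Flatten one subject's normalized maps into the fixed feature order."""
    vals: list[float] = []
    for metric in metrics:
        for band in bands:
            rm = region_means(maps[(metric, band.name)], parc)
            vals.extend(rm.to_numpy())
    return pd.Series(vals, index=feature_columns(parc, bands, metrics))


def build_feature_table(records: list[SubjectRecord],
                        per_subject_maps: list[dict[tuple[str, str], MetricMap]],
                        parc: Parcellation,
                        bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
                        metrics: tuple[str, ...] = METRIC_ORDER) -> pd.DataFrame:
    """Subjects x (metadata + metric__band__region features) table.

    Rows are sorted by subject id.  A feature missing for any subject (a
    region with no in-mask voxels) is dropped for all subjects, logged.
    """
    if len(records) != len(per_subject_maps):
        raise ValueError("records and maps must align")
    from .synthetic import records_frame

    meta = records_frame(list(records))
    feats = pd.DataFrame(
        [subject_features(m, parc, bands, metrics) for m in per_subject_maps])
    feats.index = meta.index
    bad = feats.columns[feats.isna().any(axis=0)]
    if len(bad):
        log.warning("dropping %d feature columns with missing regions: %s",
                    len(bad), list(bad[:5]))
        feats = feats.drop(columns=bad)
    table = pd.concat([meta, feats], axis=1)
    return table.sort_values("subject_id").reset_index(drop=True)
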