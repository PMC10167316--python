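"""Depression biomarkers from epoched EEG.

Per subject, band and channel (or channel pair) this module computes the
measures commonly screened as resting-EEG depression markers:

* band power and relative band power (Welch);
* frontal alpha asymmetry  ln P_alpha(right) - ln P_alpha(left);
* functional connectivity: Pearson correlation, magnitude and imaginary
  part of coherency, phase-locking value (PLV) and phase-lag index (PLI);
* signal complexity: Higuchi fractal dimension (HFD) and the detrended
  fluctuation analysis (DFA) scaling exponent.

Bands tile the 0.5-40 Hz filtered range: delta 0.5-4, theta 4-8, alpha
8-13, beta 13-30, gamma 30-40 Hz; "raw" is the full 0.5-40 Hz signal.

Welch estimates use 2-s Hann windows with 50 % overlap (0.5 Hz resolution,
enough to resolve delta), shortened when epochs are shorter.  Phase
measures use the analytic signal of band-filtered data with 5 % of samples
trimmed at each edge to suppress filter transients; connectivity is
computed per epoch and averaged across epochs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .containers import EpochSet
from .preprocess import bandpass_array

__all__ = [
    "BandDefinition",
    "BANDS",
    "ConnectivityMatrix",
    "FeatureTable",
    "band_filter",
    "band_power",
    "relative_band_power",
    "alpha_asymmetry",
    "connectivity_correlation",
    "connectivity_coherence",
    "connectivity_phase",
    "higuchi_fd",
    "dfa_exponent",
    "extract_feature_table",
    "PAIR_MEASURES",
    "CHANNEL_MEASURES",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not self.low_hz < self.high_hz:
            raise ValueError("band low edge must be below high edge")


BANDS: dict[str, BandDefinition] = {
    "raw": BandDefinition("raw", 0.5, 40.0),
    "delta": BandDefinition("delta", 0.5, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 40.0),
}

PAIR_MEASURES = ("correlation", "coherence_mag", "coherence_imag", "plv", "pli")
CHANNEL_MEASURES = ("band_power", "log_power", "relative_power", "hfd", "dfa")


def _as_band(band: str | BandDefinition) -> BandDefinition:
    if isinstance(band, BandDefinition):
        return band
    try:
        return BANDS[band]
    except KeyError:
        raise ValueError(f"unknown band {band!r}") from None


def band_filter(ep: EpochSet, band: str | BandDefinition) -> EpochSet:
    """Zero-phase band-pass of every trial and channel; 'raw' is the identity."""
    band = _as_band(band)
    if band.name == "raw":
        return ep.copy()
    if band.high_hz >= ep.fs / 2:
        raise ValueError(f"band {band.name} exceeds Nyquist at fs={ep.fs}")
    out = ep.copy()
    if ep.n_trials:
        out.data = bandpass_array(ep.data, ep.fs, band.low_hz, band.high_hz, axis=-1)
    return out


# ---------------------------------------------------------------------------
# Spectral power
# ---------------------------------------------------------------------------


def _welch_params(n_times: int, fs: float) -> tuple[int, int]:
    nperseg = min(int(round(2 * fs)), n_times)
    return nperseg, nperseg // 2


def _psd(ep: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD per trial and channel: (freqs, psd[trial, chan, freq])."""
    nperseg, noverlap = _welch_params(ep.n_times, ep.fs)
    if ep.n_times < nperseg or ep.n_times < 8:
        raise ValueError("epoch too short for spectral estimation")
    f, p = _sig.welch(ep.data, fs=ep.fs, window="hann", nperseg=nperseg, noverlap=noverlap, axis=-1)
    return f, p


def band_power(ep: EpochSet, band: str | BandDefinition) -> np.ndarray:
    """Per-channel band power (uV^2), Welch PSD integrated over [low, high), trial-averaged."""
    band = _as_band(band)
    f, p = _psd(ep)
    df = f[1] - f[0]
    sel = (f >= band.low_hz) & (f < band.high_hz)
    if not sel.any():
        raise ValueError(f"no spectral bins inside band {band.name}")
    return (p[:, :, sel].sum(axis=-1) * df).mean(axis=0)


def relative_band_power(ep: EpochSet, band: str | BandDefinition) -> np.ndarray:
    """Band power divided by total 0.5-40 Hz power, per channel; values in [0, 1]."""
    band = _as_band(band)
    f, p = _psd(ep)
    df = f[1] - f[0]
    sel = (f >= band.low_hz) & (f < band.high_hz)
    tot_sel = (f >= BANDS["raw"].low_hz) & (f < BANDS["raw"].high_hz)
    num = (p[:, :, sel].sum(axis=-1) * df).mean(axis=0)
    den = (p[:, :, tot_sel].sum(axis=-1) * df).mean(axis=0)
    if np.any(den <= 0):
        raise ValueError("zero total power in some channel")
    return num / den


def alpha_asymmetry(ep: EpochSet, left: str = "F3", right: str = "F4") -> float:
    """Frontal alpha asymmetry: ln(alpha power right) - ln(alpha power left)."""
    p = band_power(ep, "alpha")
    pl = p[ep.channel_index(left)]
    pr = p[ep.channel_index(right)]
    if pl <= 0 or pr <= 0:
        raise ValueError("alpha power must be positive for log asymmetry")
    return float(np.log(pr) - np.log(pl))


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric channel x channel connectivity values for one measure and band."""

    measure: str
    band: str
    channels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.channels), len(self.channels)):
            raise ValueError("values must be square over channels")
        if not np.allclose(v, v.T, atol=1e-9, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")

    def pair(self, a: str, b: str) -> float:
        i = self.channels.index(a)
        j = self.channels.index(b)
        return float(self.values[i, j])

    def pairs_flat(self) -> tuple[list[str], np.ndarray]:
        """Upper-triangle labels 'A-B' and values, in channel order."""
        labels, vals = [], []
        n = len(self.channels)
        for i in range(n):
            for j in range(i + 1, n):
                labels.append(f"{self.channels[i]}-{self.channels[j]}")
                vals.append(self.values[i, j])
        return labels, np.array(vals)


def _scalp_view(ep: EpochSet) -> tuple[np.ndarray, tuple[str, ...]]:
    idx = ep.scalp_indices
    if len(idx) < 2:
        raise ValueError("connectivity needs at least 2 scalp channels")
    names = tuple(ep.channel_names[i] for i in idx)
    return ep.data[:, idx, :], names


def connectivity_correlation(ep: EpochSet, band: str | BandDefinition = "raw") -> ConnectivityMatrix:
    """Pearson correlation per trial, averaged across trials (scalp channels)."""
    band = _as_band(band)
    epf = band_filter(ep, band)
    x, names = _scalp_view(epf)
    if np.any(x.std(axis=-1) == 0):
        raise ValueError("zero-variance channel in some trial")
    acc = np.zeros((len(names), len(names)))
    for t in range(x.shape[0]):
        acc += np.corrcoef(x[t])
    vals = acc / x.shape[0]
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 1.0)
    return ConnectivityMatrix("correlation", band.name, names, vals)


def _stft_segments(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Hann-windowed rFFTs of 50 %-overlapping segments.

    x: (trials, channels, time) -> (freqs, Z[segments_total, channels, freqs])
    """
    n_times = x.shape[-1]
    nperseg, noverlap = _welch_params(n_times, fs)
    step = nperseg - noverlap
    win = np.hanning(nperseg)
    starts = range(0, n_times - nperseg + 1, step)
    segs = np.stack([x[:, :, s : s + nperseg] * win for s in starts], axis=0)
    # (n_seg, trials, chan, nperseg) -> flatten segment/trial axes
    z = np.fft.rfft(segs, axis=-1)
    z = z.reshape(-1, x.shape[1], z.shape[-1])
    f = np.fft.rfftfreq(nperseg, 1.0 / fs)
    return f, z


def connectivity_coherence(
    ep: EpochSet, band: str | BandDefinition = "raw"
) -> tuple[ConnectivityMatrix, ConnectivityMatrix]:
    """Magnitude and imaginary part of the coherency, band-averaged.

    Coherency = cross-spectrum / sqrt(product of auto-spectra), Welch
    averaged over segments of all trials; |coherency| and Im(coherency)
    are then averaged over the band's frequency bins.
    """
    band = _as_band(band)
    x, names = _scalp_view(ep)
    nperseg, _ = _welch_params(ep.n_times, ep.fs)
    if ep.n_times < nperseg or x.shape[0] * (ep.n_times // max(1, nperseg - nperseg // 2)) < 2:
        raise ValueError("too few spectral windows for coherence")
    f, z = _stft_segments(x, ep.fs)
    sel = (f >= band.low_hz) & (f < band.high_hz)
    if not sel.any():
        raise ValueError(f"no spectral bins inside band {band.name}")
    zb = z[:, :, sel]  # (windows, channels, bins)
    sxx = np.mean(np.abs(zb) ** 2, axis=0)  # (channels, bins)
    sxy = np.einsum("wab,wcb->acb", zb, np.conj(zb)) / zb.shape[0]
    denom = np.sqrt(sxx[:, None, :] * sxx[None, :, :])
    coh = sxy / np.where(denom > 0, denom, np.inf)
    mag = np.abs(coh).mean(axis=-1)
    imag = np.imag(coh).mean(axis=-1)
    mag = np.clip((mag + mag.T) / 2, 0.0, 1.0)
    # Im(coherency) is antisymmetric in the channel order; report |Im|
    imag = np.abs(imag)
    imag = (imag + imag.T) / 2
    np.fill_diagonal(mag, 1.0)
    np.fill_diagonal(imag, 0.0)
    return (
        ConnectivityMatrix("coherence_mag", band.name, names, mag),
        ConnectivityMatrix("coherence_imag", band.name, names, imag),
    )


def connectivity_phase(
    ep: EpochSet, band: str | BandDefinition = "alpha", edge_fraction: float = 0.05
) -> tuple[ConnectivityMatrix, ConnectivityMatrix]:
    """Phase-locking value and phase-lag index from the analytic signal.

    PLV = |mean_t exp(i dphi)|; PLI = |mean_t sign(sin dphi)|, averaged over
    trials.  Requires a narrow band ('raw' is rejected).  PLI is zero for
    strictly zero-lag coupling, which makes it robust to volume conduction.
    """
    band = _as_band(band)
    if band.name == "raw":
        raise ValueError("phase connectivity needs a narrow band, not 'raw'")
    epf = band_filter(ep, band)
    x, names = _scalp_view(epf)
    n_trim = int(round(edge_fraction * x.shape[-1]))
    analytic = _sig.hilbert(x, axis=-1)
    if n_trim:
        analytic = analytic[:, :, n_trim:-n_trim]
    phase = np.angle(analytic)
    n = len(names)
    plv = np.eye(n)
    pli = np.zeros((n, n))
    for i in range(n):
        dphi = phase[:, i : i + 1, :] - phase[:, i + 1 :, :]  # (trials, n-i-1, time)
        if dphi.shape[1] == 0:
            continue
        plv_row = np.abs(np.mean(np.exp(1j * dphi), axis=(0, 2)))
        s = np.sin(dphi)
        # dead zone: float-level phase noise between (near-)identical signals
        # must not register as a consistent lead/lag
        sgn = np.where(np.abs(s) < 1e-9, 0.0, np.sign(s))
        pli_row = np.abs(np.mean(sgn, axis=(0, 2)))
        plv[i, i + 1 :] = plv_row
        plv[i + 1 :, i] = plv_row
        pli[i, i + 1 :] = pli_row
        pli[i + 1 :, i] = pli_row
    return (
        ConnectivityMatrix("plv", band.name, names, plv),
        ConnectivityMatrix("pli", band.name, names, pli),
    )


# ---------------------------------------------------------------------------
# Complexity measures
# ---------------------------------------------------------------------------


def higuchi_fd(x: np.ndarray, kmax: int = 8) -> float | np.ndarray:
    """Higuchi fractal dimension of a series (vectorised over leading axes).

    Normalised curve lengths L(k) are averaged over the k offsets for
    k = 1..kmax; the dimension is the slope of ln L(k) against ln(1/k).
    Typical values: ~1 for smooth trends, ~2 for white noise.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 10 * kmax:
        raise ValueError(f"series length {n} too short for kmax={kmax}")
    if np.any(np.ptp(x, axis=-1) == 0):
        raise ValueError("constant signal has no fractal dimension")
    lk = []
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            diffs = np.abs(np.diff(x[..., idx], axis=-1)).sum(axis=-1)
            norm = (n - 1) / ((len(idx) - 1) * k)
            lengths.append(diffs * norm / k)
        lk.append(np.mean(lengths, axis=0))
    lk = np.stack(lk, axis=-1)  # (..., kmax)
    logs = np.log(1.0 / np.arange(1, kmax + 1))
    slope = np.polynomial.polynomial.polyfit(logs, np.log(lk.reshape(-1, kmax)).T, 1)[1]
    out = slope.reshape(x.shape[:-1])
    return float(out) if out.ndim == 0 else out


def dfa_exponent(x: np.ndarray, scales: Sequence[int] | None = None) -> float | np.ndarray:
    """DFA scaling exponent alpha (vectorised over leading axes).

    Profile = cumulative sum of the mean-removed series; per scale s the
    fluctuation F(s) is the RMS residual of per-window linear detrending;
    alpha is the slope of ln F against ln s.  White noise gives ~0.5, pink
    noise ~1.0, a random walk ~1.5.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if scales is None:
        n_scales = 10
        scales = np.unique(np.round(np.geomspace(4, n // 4, n_scales)).astype(int))
    scales = np.asarray(sorted(set(int(s) for s in scales)))
    if len(scales) < 4:
        raise ValueError("need at least 4 distinct scales")
    if n < 4 * scales.max():
        raise ValueError(f"series length {n} too short for max scale {scales.max()}")
    if np.any(np.ptp(x, axis=-1) == 0):
        raise ValueError("constant signal has no DFA exponent")
    prof = np.cumsum(x - x.mean(axis=-1, keepdims=True), axis=-1)
    t_full = np.arange(n, dtype=float)
    fs_vals = []
    for s in scales:
        n_win = n // s
        segs = prof[..., : n_win * s].reshape(*prof.shape[:-1], n_win, s)
        t = t_full[:s] - t_full[:s].mean()
        # least-squares line fit per window via closed form
        seg_mean = segs.mean(axis=-1, keepdims=True)
        slope = (segs * t).sum(axis=-1, keepdims=True) / (t * t).sum()
        resid = segs - seg_mean - slope * t
        fs_vals.append(np.sqrt((resid**2).mean(axis=(-1, -2))))
    fvals = np.stack(fs_vals, axis=-1)  # (..., n_scales)
    logs = np.log(scales.astype(float))
    alpha = np.polynomial.polynomial.polyfit(logs, np.log(fvals.reshape(-1, len(scales))).T, 1)[1]
    out = alpha.reshape(x.shape[:-1])
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

_DESCRIPTOR_SEP = "|"


@dataclass
class FeatureTable:
    """Observations x features with descriptor-labelled columns and group labels.

    Column descriptors are ``measure|band|channel`` or
    ``measure|band|chanA-chanB`` strings; rows are subjects (or
    subject x epoch observations).
    """

    values: pd.DataFrame  # index: observation id; columns: descriptors
    groups: pd.Series  # aligned with values.index; 'high' | 'low'

    def __post_init__(self) -> None:
        if list(self.values.index) != list(self.groups.index):
            raise ValueError("values and groups must share an index")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature descriptors")

    @property
    def n_observations(self) -> int:
        return len(self.values)

    @property
    def descriptors(self) -> list[str]:
        return list(self.values.columns)

    def select(self, columns: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.values[list(columns)].copy(), self.groups.copy())

    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Feature matrix and binary labels (high=1, low=0)."""
        y = (self.groups == "high").to_numpy().astype(int)
        return self.values.to_numpy(), y

    def blocks(self) -> dict[str, list[str]]:
        """Columns grouped by biomarker block, i.e. by (measure, band)."""
        out: dict[str, list[str]] = {}
        for c in self.values.columns:
            measure, band = c.split(_DESCRIPTOR_SEP)[:2]
            out.setdefault(f"{measure}{_DESCRIPTOR_SEP}{band}", []).append(c)
        return out

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        df = self.values.copy()
        df.insert(0, "group", self.groups)
        df.to_csv(path, sep="\t", index_label="observation")
        return path

    @staticmethod
    def from_tsv(path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col="observation")
        groups = df.pop("group")
        return FeatureTable(df, groups)


def _channel_measure(ep: EpochSet, measure: str, band: str) -> tuple[list[str], np.ndarray]:
    scalp = ep.scalp_indices
    names = [ep.channel_names[i] for i in scalp]
    if measure == "band_power":
        vals = band_power(ep, band)[scalp]
    elif measure == "log_power":
        # power is ~log-normal across subjects; group statistics use the log scale
        p = band_power(ep, band)[scalp]
        if np.any(p <= 0):
            raise ValueError("nonpositive band power; cannot log-transform")
        vals = np.log10(p)
    elif measure == "relative_power":
        vals = relative_band_power(ep, band)[scalp]
    elif measure in ("hfd", "dfa"):
        epf = band_filter(ep, band)
        x = epf.data[:, scalp, :]
        fn = higuchi_fd if measure == "hfd" else dfa_exponent
        vals = np.asarray(fn(x)).mean(axis=0)
    else:
        raise ValueError(f"unknown channel measure {measure!r}")
    labels = [f"{measure}{_DESCRIPTOR_SEP}{band}{_DESCRIPTOR_SEP}{n}" for n in names]
    return labels, np.asarray(vals)


def _pair_measure(ep: EpochSet, measure: str, band: str) -> tuple[list[str], np.ndarray]:
    if measure == "correlation":
        cm = connectivity_correlation(ep, band)
    elif measure in ("coherence_mag", "coherence_imag"):
        mag, imag = connectivity_coherence(ep, band)
        cm = mag if measure == "coherence_mag" else imag
    elif measure in ("plv", "pli"):
        plv, pli = connectivity_phase(ep, band)
        cm = plv if measure == "plv" else pli
    else:
        raise ValueError(f"unknown pair measure {measure!r}")
    pair_labels, vals = cm.pairs_flat()
    labels = [f"{measure}{_DESCRIPTOR_SEP}{band}{_DESCRIPTOR_SEP}{p}" for p in pair_labels]
    return labels, vals


def _features_one(ep: EpochSet, measures: Sequence[str], bands: Sequence[str]) -> tuple[list[str], np.ndarray]:
    labels: list[str] = []
    vals: list[np.ndarray] = []
    for measure in measures:
        if measure == "alpha_asymmetry":
            labels.append(f"alpha_asymmetry{_DESCRIPTOR_SEP}alpha{_DESCRIPTOR_SEP}F4-F3")
            vals.append(np.array([alpha_asymmetry(ep)]))
            continue
        for band in bands:
            if measure in ("plv", "pli") and band == "raw":
                continue  # phase measures need a narrow band
            fn = _channel_measure if measure in CHANNEL_MEASURES else _pair_measure
            if measure not in CHANNEL_MEASURES and measure not in PAIR_MEASURES:
                raise ValueError(f"unknown measure {measure!r}")
            lab, v = fn(ep, measure, band)
            labels.extend(lab)
            vals.append(np.asarray(v))
    return labels, np.concatenate(vals)


def extract_feature_table(
    epoch_sets: Iterable[EpochSet],
    measures: Sequence[str],
    bands: Sequence[str] = ("raw", "delta", "theta", "alpha", "beta", "gamma"),
    granularity: str = "subject",
) -> FeatureTable:
    """Build a feature table over a cohort of per-subject epoch sets.

    ``granularity='subject'`` yields one row per subject (measures averaged
    over that subject's epochs, which the measures already do internally);
    ``'subject_epoch'`` yields one row per subject x epoch.
    """
    if granularity not in ("subject", "subject_epoch"):
        raise ValueError(f"unknown granularity {granularity!r}")
    rows, groups, index = [], [], []
    columns: list[str] | None = None
    for ep in epoch_sets:
        if granularity == "subject":
            units = [ep]
            ids = [ep.subject_id]
        else:
            units = [
                EpochSet(
                    data=ep.data[t : t + 1],
                    tmin_s=ep.tmin_s,
                    fs=ep.fs,
                    channel_names=ep.channel_names,
                    channel_roles=ep.channel_roles,
                    info=ep.info.iloc[t : t + 1].reset_index(drop=True),
                    subject_id=ep.subject_id,
                    group=ep.group,
                )
                for t in range(ep.n_trials)
            ]
            ids = [f"{ep.subject_id}:{t}" for t in range(ep.n_trials)]
        for unit, uid in zip(units, ids):
            labels, vals = _features_one(unit, measures, bands)
            if columns is None:
                columns = labels
            elif labels != columns:
                raise ValueError("inconsistent feature descriptors across observations")
            rows.append(vals)
            groups.append(ep.group)
            index.append(uid)
    values = pd.DataFrame(rows, index=index, columns=columns)
    return FeatureTable(values, pd.Series(groups, index=index, name="group"))
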