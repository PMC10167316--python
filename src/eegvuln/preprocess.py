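"""Preprocessing of continuous EEG into analysis-ready epochs.

The default chain mirrors standard event-related practice: zero-phase
band-pass filter (0.5-40 Hz), segmentation around stimulus onsets
(-500..+1300 ms), baseline correction on the pre-stimulus interval,
automatic peak-to-peak artifact rejection, bad-channel interpolation from
montage neighbours, average re-referencing over scalp (non-EOG) channels,
and a final crop to -200..+1300 ms.

All operations are pure: they return new containers and leave their inputs
untouched.  Filtering uses a 4th-order Butterworth applied forward and
backward (``sosfiltfilt``), so the pass band has unit gain and zero phase
shift.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EpochSet, Recording, RejectionReport, TrialEvent, events_to_frame
from .montage import Montage

__all__ = [
    "butter_bandpass_sos",
    "bandpass_array",
    "bandpass_filter",
    "segment_epochs",
    "baseline_correct",
    "trim_epochs",
    "reject_artifacts",
    "interpolate_bad_channels",
    "rereference_average",
    "preprocess_recording",
]

FILTER_ORDER = 4  # per-direction order of the zero-phase Butterworth


def butter_bandpass_sos(low_hz: float, high_hz: float, fs: float, order: int = FILTER_ORDER):
    """Second-order sections of the band-pass Butterworth design."""
    nyq = fs / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2; got ({low_hz}, {high_hz}) at fs={fs}"
        )
    return signal.butter(order, [low_hz / nyq, high_hz / nyq], btype="bandpass", output="sos")


def bandpass_array(arr: np.ndarray, fs: float, low_hz: float, high_hz: float, axis: int = -1) -> np.ndarray:
    """Zero-phase band-pass an array along *axis*."""
    sos = butter_bandpass_sos(low_hz, high_hz, fs)
    return signal.sosfiltfilt(sos, arr, axis=axis)


def bandpass_filter(rec: Recording, low_hz: float = 0.5, high_hz: float = 40.0) -> Recording:
    """Zero-phase band-pass of every channel (EOG included) of a recording."""
    out = rec.copy()
    out.data = bandpass_array(rec.data, rec.fs, low_hz, high_hz, axis=-1)
    return out


def segment_epochs(
    rec: Recording,
    events: Sequence[TrialEvent],
    tmin_s: float = -0.5,
    tmax_s: float = 1.3,
) -> EpochSet:
    """Cut stimulus-locked epochs ``[onset+tmin, onset+tmax)`` out of a recording.

    Sample convention: the epoch starts at ``onset_sample + round(tmin*fs)``
    and spans ``round((tmax-tmin)*fs)`` samples (half-open interval).
    Events whose window would leave the recording are dropped; the returned
    ``info`` covers the kept events in input order.
    """
    if not tmin_s < tmax_s:
        raise ValueError("tmin_s must be < tmax_s")
    n_len = int(round((tmax_s - tmin_s) * rec.fs))
    kept_events, slabs = [], []
    for ev in events:
        onset = int(round(ev.onset_s * rec.fs))
        start = onset + int(round(tmin_s * rec.fs))
        if start < 0 or start + n_len > rec.n_samples:
            continue
        kept_events.append(ev)
        slabs.append(rec.data[:, start : start + n_len])
    data = np.stack(slabs) if slabs else np.empty((0, rec.n_channels, n_len))
    info = events_to_frame(kept_events)
    info["kept"] = True
    return EpochSet(
        data=data,
        tmin_s=tmin_s,
        fs=rec.fs,
        channel_names=rec.channel_names,
        channel_roles=rec.channel_roles,
        info=info,
        subject_id=rec.subject_id,
        group=rec.group,
    )


def _window_slice(ep: EpochSet, t0_s: float, t1_s: float) -> slice:
    i0 = int(round((t0_s - ep.tmin_s) * ep.fs))
    i1 = int(round((t1_s - ep.tmin_s) * ep.fs))
    if i0 < 0 or i1 > ep.n_times or i0 >= i1:
        raise ValueError(f"window ({t0_s}, {t1_s}) s not inside epoch [{ep.tmin_s}, {ep.tmax_s}) s")
    return slice(i0, i1)


def baseline_correct(ep: EpochSet, window: tuple[float, float] | None = None) -> EpochSet:
    """Subtract the per-trial, per-channel mean over *window* (default: tmin..0)."""
    if window is None:
        window = (ep.tmin_s, 0.0)
    t0, t1 = window
    if t1 > 0:
        raise ValueError("baseline window must end at or before stimulus onset")
    sl = _window_slice(ep, t0, t1)
    out = ep.copy()
    out.data = ep.data - ep.data[:, :, sl].mean(axis=2, keepdims=True)
    return out


def trim_epochs(ep: EpochSet, tmin_s: float, tmax_s: float) -> EpochSet:
    """Crop the epoch time axis to the nested window ``[tmin_s, tmax_s)``."""
    sl = _window_slice(ep, tmin_s, tmax_s)
    out = ep.copy()
    out.data = ep.data[:, :, sl].copy()
    out.tmin_s = ep.tmin_s + sl.start / ep.fs
    return out


def reject_artifacts(ep: EpochSet, ptp_threshold_uv: float = 150.0) -> tuple[EpochSet, RejectionReport]:
    """Drop trials whose scalp peak-to-peak amplitude exceeds the threshold.

    A stand-in for manual artifact marking: a trial is rejected iff any
    scalp channel's max-min range within the epoch exceeds
    ``ptp_threshold_uv``.
    """
    if ptp_threshold_uv <= 0:
        raise ValueError("ptp_threshold_uv must be positive")
    scalp = ep.scalp_indices
    if ep.n_trials == 0:
        return ep.copy(), RejectionReport(0, 0, ())
    ptp = ep.data[:, scalp, :].max(axis=2) - ep.data[:, scalp, :].min(axis=2)
    bad = (ptp > ptp_threshold_uv).any(axis=1)
    reasons = tuple("ptp" if b else "" for b in bad)
    out = ep.copy()
    out.data = ep.data[~bad].copy()
    out.info = ep.info.loc[~bad].reset_index(drop=True)
    return out, RejectionReport(n_total=ep.n_trials, n_rejected=int(bad.sum()), reasons=reasons)


def interpolate_bad_channels(ep: EpochSet, bad: Iterable[str], montage: Montage) -> EpochSet:
    """Replace each bad channel by the samplewise mean of its non-bad montage neighbours."""
    bad = list(bad)
    out = ep.copy()
    if not bad:
        return out
    bad_set = set(bad)
    for name in bad:
        neigh = [n for n in montage.neighbors[name] if n not in bad_set]
        if not neigh:
            raise ValueError(f"all montage neighbours of {name!r} are bad; cannot interpolate")
        idx = [ep.channel_index(n) for n in neigh]
        out.data[:, ep.channel_index(name), :] = ep.data[:, idx, :].mean(axis=1)
    return out


def rereference_average(ep: EpochSet) -> EpochSet:
    """Re-reference scalp channels to their common average; EOG channels untouched."""
    scalp = ep.scalp_indices
    if len(scalp) < 2:
        raise ValueError("average reference needs at least 2 scalp channels")
    out = ep.copy()
    avg = ep.data[:, scalp, :].mean(axis=1, keepdims=True)
    out.data[:, scalp, :] = ep.data[:, scalp, :] - avg
    return out


def preprocess_recording(
    rec: Recording,
    events: Sequence[TrialEvent],
    montage: Montage | None = None,
    *,
    band: tuple[float, float] = (0.5, 40.0),
    segment_window: tuple[float, float] = (-0.5, 1.3),
    baseline_window: tuple[float, float] | None = None,
    ptp_threshold_uv: float = 150.0,
    bad_channels: Sequence[str] = (),
    final_window: tuple[float, float] = (-0.2, 1.3),
) -> tuple[EpochSet, RejectionReport]:
    """Default chain: filter -> segment -> baseline -> reject -> interpolate -> re-reference -> trim."""
    filtered = bandpass_filter(rec, *band)
    ep = segment_epochs(filtered, events, *segment_window)
    ep = baseline_correct(ep, baseline_window)
    ep, report = reject_artifacts(ep, ptp_threshold_uv)
    if bad_channels:
        if montage is None:
            raise ValueError("bad-channel interpolation requires a montage")
        ep = interpolate_bad_channels(ep, bad_channels, montage)
    ep = rereference_average(ep)
    ep = trim_epochs(ep, *final_window)
    return ep, report


def rest_to_epochs(rec: Recording, epoch_length_s: float = 2.0) -> EpochSet:
    """Cut a continuous (resting) recording into consecutive fixed-length pseudo-epochs."""
    n_len = int(round(epoch_length_s * rec.fs))
    n_ep = rec.n_samples // n_len
    if n_ep == 0:
        raise ValueError("recording shorter than one epoch")
    data = rec.data[:, : n_ep * n_len].reshape(rec.n_channels, n_ep, n_len).transpose(1, 0, 2).copy()
    info = pd.DataFrame({"onset_s": np.arange(n_ep) * epoch_length_s, "kept": True})
    return EpochSet(
        data=data,
        tmin_s=0.0,
        fs=rec.fs,
        channel_names=rec.channel_names,
        channel_roles=rec.channel_roles,
        info=info,
        subject_id=rec.subject_id,
        group=rec.group,
    )
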