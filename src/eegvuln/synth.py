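"""Synthetic two-group EEG cohorts with planted, recoverable group effects.

The generator emulates the study design this package analyses: two groups
of 20 subjects ("high" and "low" vulnerability to depression), 5-minute
eyes-closed resting recordings and a sustained-attention task (SART; 8
blocks x 90 trials, Go proportion 8/9, thought probes rated 1-9 for the
stickiness of ongoing thought), recorded from a 32-channel 10-20 cap at
512 Hz plus two EOG channels.

Signals are 1/f-shaped ("pink") background noise per channel, with
optional planted group differences:

* amplitude effects — a named frequency band at a named channel is scaled
  by a multiplicative factor for the high-vulnerability group only;
* coupling effects — a shared band-limited noise carrier is mixed into
  both channels of a named pair with a fixed phase lag, with separate
  mixing coefficients per group (a nonzero lag makes the coupling visible
  to the phase-lag index, which is blind to zero-lag mixtures).

Carriers are filtered noise, not sinusoids, so spectral and phase-based
connectivity estimates stay non-degenerate.  Questionnaire scores (PTQ,
RRS, CES-D, plus intensity/frequency ratings of a nominated negative
event) are drawn from untruncated normal distributions with the cohort's
group means and SDs; by default 3 high-group and 1 low-group subjects are
missing the two event ratings.

Everything is deterministic given ``(spec.seed, subject_seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .containers import (
    CROSS_CHOICES_MS,
    ISI_MS,
    MASK_MS,
    WORD_MS,
    Recording,
    TrialEvent,
)
from .montage import Montage, build_montage

__all__ = [
    "AmplitudeEffect",
    "CouplingEffect",
    "EffectSpec",
    "NoiseModel",
    "CohortSpec",
    "QUESTIONNAIRE_MEANS_SD",
    "generate_sart_events",
    "generate_recording",
    "generate_questionnaires",
    "generate_cohort",
]

EOG_CHANNELS = ("EOG1", "EOG2")
#: scalp channels that receive attenuated blink activity
BLINK_LEAK_CHANNELS = {"Fp1": 0.4, "Fp2": 0.4, "AF3": 0.25, "AF4": 0.25}

# Group means (SD) of the questionnaire scores the cohort generator draws:
# perseverative thinking (PTQ), rumination (RRS), depression severity
# (CES-D) and the intensity / frequency ratings of a nominated negative
# life event, for the high- and low-vulnerability groups respectively.
QUESTIONNAIRE_MEANS_SD: dict[str, dict[str, tuple[float, float]]] = {
    "PTQ": {"high": (45.85, 4.70), "low": (25.10, 8.33)},
    "RRS": {"high": (67.05, 7.34), "low": (41.75, 8.34)},
    "CESD": {"high": (51.65, 6.47), "low": (35.45, 3.71)},
    "intensity": {"high": (4.76, 0.97), "low": (4.11, 0.74)},
    "frequency": {"high": (4.35, 0.86), "low": (3.84, 0.83)},
}

# Canonical band edges, Hz (kept in sync with features.BANDS).
_BAND_EDGES = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 40.0),
    "raw": (0.5, 40.0),
}


@dataclass(frozen=True)
class AmplitudeEffect:
    """Scale `band` at `channel` by `factor` (amplitude) in the high group."""

    channel: str
    band: str
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("amplitude factor must be positive")
        if self.band not in _BAND_EDGES:
            raise ValueError(f"unknown band {self.band!r}")


@dataclass(frozen=True)
class CouplingEffect:
    """Mix a shared band-limited carrier into a channel pair with a phase lag.

    ``mix_high`` / ``mix_low`` in [0, 1] give the carrier's amplitude
    relative to the channel's background SD for each group; ``phase_lag_rad``
    in (-pi, pi] is the lag applied to the second channel of the pair.
    """

    pair: tuple[str, str]
    band: str
    phase_lag_rad: float
    mix_high: float
    mix_low: float = 0.0

    def __post_init__(self) -> None:
        for m in (self.mix_high, self.mix_low):
            if not 0.0 <= m <= 1.0:
                raise ValueError("mixing coefficients must be in [0, 1]")
        if not -np.pi < self.phase_lag_rad <= np.pi:
            raise ValueError("phase lag must be in (-pi, pi]")
        if self.band not in _BAND_EDGES:
            raise ValueError(f"unknown band {self.band!r}")


@dataclass(frozen=True)
class EffectSpec:
    amplitude_effects: tuple[AmplitudeEffect, ...] = ()
    coupling_effects: tuple[CouplingEffect, ...] = ()

    @staticmethod
    def none() -> "EffectSpec":
        return EffectSpec()


@dataclass(frozen=True)
class NoiseModel:
    """1/f background and nuisance parameters of the synthetic EEG.

    ``exponent`` is the power-spectral slope (PSD ~ 1/f^exponent).
    ``scalp_sigma_uv`` / ``eog_sigma_uv`` are baseline per-channel SDs in
    microvolts.  ``subject_gain_sd`` / ``channel_gain_sd`` are SDs of
    log-normal gains that create realistic between-subject and
    between-channel amplitude variability.  Blinks are smooth bump
    transients on the EOG channels, leaking attenuated into frontal scalp
    channels, at ``blink_rate_hz`` events per second.
    """

    exponent: float = 1.0
    scalp_sigma_uv: float = 10.0
    eog_sigma_uv: float = 15.0
    subject_gain_sd: float = 0.15
    channel_gain_sd: float = 0.1
    blink_rate_hz: float = 0.07
    blink_amplitude_uv: float = 150.0
    blink_width_s: float = 0.15


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of one synthetic cohort."""

    n_high: int = 20
    n_low: int = 20
    rest_duration_s: float = 300.0
    fs: float = 512.0
    effect: EffectSpec = field(default_factory=EffectSpec)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_high < 1 or self.n_low < 1:
            raise ValueError("n_high and n_low must be >= 1")
        if self.fs <= 2 * 40.0:
            raise ValueError("fs must exceed twice the highest band edge (40 Hz)")


# ---------------------------------------------------------------------------
# SART event sequences
# ---------------------------------------------------------------------------


def generate_sart_events(
    n_blocks: int = 8,
    trials_per_block: int = 90,
    probe_rate: float = 0.1,
    seed: int = 0,
    nogo_rate: float = 1.0 / 9.0,
) -> list[TrialEvent]:
    """Generate a SART trial sequence with embedded thought probes.

    Each trial is cross (duration sampled from {1480, 1640, 1800, 1960,
    2020} ms) + word 320 ms + mask 880 ms + ISI 3020 ms; ``onset_s`` marks
    word (stimulus) onset.  Trials are no-go with probability 1/9.  After
    each trial a thought probe occurs with probability ``probe_rate``; the
    probe's stickiness rating (uniform 1-9) is assigned to the five trials
    preceding it.
    """
    if n_blocks < 1 or trials_per_block < 1:
        raise ValueError("n_blocks and trials_per_block must be >= 1")
    if not 0.0 <= probe_rate <= 1.0:
        raise ValueError("probe_rate must be in [0, 1]")
    rng = np.random.default_rng([seed % (2**31), 0x5A27])
    n = n_blocks * trials_per_block
    crosses = rng.choice(CROSS_CHOICES_MS, size=n)
    nogo = rng.random(n) < nogo_rate
    probes = rng.random(n) < probe_rate
    probe_ratings = rng.integers(1, 10, size=n)

    ratings: list[Optional[int]] = [None] * n
    for i in np.flatnonzero(probes):
        for j in range(max(0, i - 4), i + 1):
            ratings[j] = int(probe_ratings[i])

    events: list[TrialEvent] = []
    t = 0.0
    for i in range(n):
        onset = t + crosses[i] / 1000.0
        events.append(
            TrialEvent(
                onset_s=round(onset, 6),
                trial_type="nogo" if nogo[i] else "go",
                block=i // trials_per_block + 1,
                cross_duration_ms=int(crosses[i]),
                stickiness_rating=ratings[i],
            )
        )
        t = onset + (WORD_MS + MASK_MS + ISI_MS) / 1000.0
    return events


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _phase_shift(x: np.ndarray, phi: float) -> np.ndarray:
    """Shift every spectral component of a (narrowband) signal by phi radians."""
    analytic = _sig.hilbert(x)
    return np.real(analytic * np.exp(-1j * phi))


def _band_carrier(rng: np.random.Generator, n: int, fs: float, band: str) -> np.ndarray:
    lo, hi = _BAND_EDGES[band]
    sos = _sig.butter(4, [lo / (fs / 2), hi / (fs / 2)], btype="bandpass", output="sos")
    x = _sig.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _blink_template(fs: float, width_s: float) -> np.ndarray:
    # smooth positive bump (Hann-squared), ~width_s at half amplitude
    n = max(3, int(round(3 * width_s * fs)))
    w = np.hanning(n)
    return w**2


def generate_recording(
    spec: CohortSpec,
    group: str,
    subject_seed: int,
    events: Sequence[TrialEvent] = (),
    montage: Montage | None = None,
    subject_id: str | None = None,
) -> Recording:
    """Simulate one subject's recording under the cohort's study conditions.

    With *events* the recording covers the task (last trial offset + 2 s
    margin); without, it is a resting recording of ``rest_duration_s``.
    Deterministic given ``(spec.seed, subject_seed, group)``.
    """
    if group not in ("high", "low"):
        raise ValueError(f"group must be 'high' or 'low', got {group!r}")
    montage = montage or build_montage()
    names = montage.channel_names + EOG_CHANNELS
    roles = ("scalp",) * len(montage.channel_names) + ("eog",) * len(EOG_CHANNELS)
    for eff in spec.effect.amplitude_effects:
        if eff.channel not in names:
            raise KeyError(f"unknown channel {eff.channel!r} in amplitude effect")
    for eff in spec.effect.coupling_effects:
        for ch in eff.pair:
            if ch not in names:
                raise KeyError(f"unknown channel {ch!r} in coupling effect")

    fs = spec.fs
    if events:
        last = max(e.onset_s for e in events)
        duration = last + (WORD_MS + MASK_MS + ISI_MS) / 1000.0 + 2.0
    else:
        duration = spec.rest_duration_s
    n = int(round(duration * fs))

    rng = np.random.default_rng([spec.seed % (2**31), subject_seed % (2**31), 1 if group == "high" else 0])
    nm = spec.noise
    subj_gain = float(np.exp(rng.normal(0.0, nm.subject_gain_sd)))
    data = np.zeros((len(names), n))
    for i, role in enumerate(roles):
        sigma = nm.scalp_sigma_uv if role == "scalp" else nm.eog_sigma_uv
        gain = np.exp(rng.normal(0.0, nm.channel_gain_sd))
        data[i] = _pink_noise(rng, n, nm.exponent) * sigma * subj_gain * gain

    # planted amplitude effects (high group only)
    for eff in spec.effect.amplitude_effects:
        if group != "high" or eff.factor == 1.0:
            continue
        i = names.index(eff.channel)
        lo, hi = _BAND_EDGES[eff.band]
        sos = _sig.butter(4, [lo / (fs / 2), hi / (fs / 2)], btype="bandpass", output="sos")
        band_part = _sig.sosfiltfilt(sos, data[i])
        data[i] = data[i] + (eff.factor - 1.0) * band_part

    # planted phase-lagged coupling
    for eff in spec.effect.coupling_effects:
        carrier = _band_carrier(rng, n, fs, eff.band)
        mix = eff.mix_high if group == "high" else eff.mix_low
        if mix == 0.0:
            continue
        ia = names.index(eff.pair[0])
        ib = names.index(eff.pair[1])
        amp = mix * nm.scalp_sigma_uv * subj_gain
        data[ia] = data[ia] + amp * carrier
        data[ib] = data[ib] + amp * _phase_shift(carrier, eff.phase_lag_rad)

    # blinks on EOG with frontal leakage
    if nm.blink_rate_hz > 0 and nm.blink_amplitude_uv > 0:
        tmpl = _blink_template(fs, nm.blink_width_s)
        n_blinks = rng.poisson(nm.blink_rate_hz * duration)
        starts = rng.integers(0, max(1, n - len(tmpl)), size=n_blinks)
        eog_rows = [names.index(c) for c in EOG_CHANNELS]
        leak_rows = {names.index(c): g for c, g in BLINK_LEAK_CHANNELS.items() if c in names}
        for s in starts:
            amp = nm.blink_amplitude_uv * float(np.exp(rng.normal(0.0, 0.2)))
            seg = slice(s, s + len(tmpl))
            for r in eog_rows:
                data[r, seg] += amp * tmpl[: data.shape[1] - s]
            for r, g in leak_rows.items():
                data[r, seg] += g * amp * tmpl[: data.shape[1] - s]

    sid = subject_id or f"{group[0].upper()}{subject_seed:02d}"
    return Recording(
        data=data,
        fs=fs,
        channel_names=names,
        channel_roles=roles,
        subject_id=sid,
        group=group,
    )


# ---------------------------------------------------------------------------
# Questionnaires and full cohorts
# ---------------------------------------------------------------------------


def generate_questionnaires(
    spec: CohortSpec,
    subject_ids_high: Sequence[str],
    subject_ids_low: Sequence[str],
    n_missing_high: int = 3,
    n_missing_low: int = 1,
) -> pd.DataFrame:
    """Draw per-subject questionnaire scores from the group normal models.

    ``n_missing_high`` / ``n_missing_low`` subjects per group get missing
    intensity and frequency ratings (the two ratings tied to the writing
    task), emulating incomplete writing-task compliance.
    """
    rng = np.random.default_rng([spec.seed % (2**31), 0x71])
    rows = []
    for group, ids in (("high", subject_ids_high), ("low", subject_ids_low)):
        for sid in ids:
            row = {"subject_id": sid, "group": group}
            for col, params in QUESTIONNAIRE_MEANS_SD.items():
                mu, sd = params[group]
                row[col] = rng.normal(mu, sd)
            rows.append(row)
    df = pd.DataFrame(rows)
    for group, k in (("high", n_missing_high), ("low", n_missing_low)):
        idx = df.index[df["group"] == group]
        if k > len(idx):
            raise ValueError(f"cannot blank {k} subjects in a group of {len(idx)}")
        chosen = rng.choice(idx, size=k, replace=False)
        df.loc[chosen, ["intensity", "frequency"]] = np.nan
    return df


def generate_cohort(
    spec: CohortSpec,
    events: Sequence[TrialEvent] = (),
    montage: Montage | None = None,
) -> tuple[list[Recording], pd.DataFrame]:
    """Generate all recordings plus the questionnaire table for a cohort."""
    montage = montage or build_montage()
    recs: list[Recording] = []
    ids_high = [f"H{i:02d}" for i in range(1, spec.n_high + 1)]
    ids_low = [f"L{i:02d}" for i in range(1, spec.n_low + 1)]
    for k, sid in enumerate(ids_high):
        recs.append(generate_recording(spec, "high", k + 1, events, montage, subject_id=sid))
    for k, sid in enumerate(ids_low):
        recs.append(generate_recording(spec, "low", k + 1, events, montage, subject_id=sid))
    # default missingness 3 high / 1 low, capped so >= 2 rated subjects remain
    quest = generate_questionnaires(
        spec, ids_high, ids_low,
        n_missing_high=min(3, max(0, spec.n_high - 2)),
        n_missing_low=min(1, max(0, spec.n_low - 2)),
    )
    return recs, quest
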