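"""Synthetic multi-participant rubber-hand-illusion study generator.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without any recording: 1-Hz visuo-tactile event
trains (180 events per 3-min trial at full scale), 128-channel EEG at
200 Hz with spatially correlated AR(1) background noise, a condition-shared
evoked response, condition-specific spatial effect patterns active inside
defined post-stimulus windows, right-skewed illusion-onset latencies, and
100-Hz skin-conductance traces whose local standard deviation changes in a
window locked to the illusion onset.

The effect model: each :class:`EffectSpec` names a contrast of conditions;
a unit-norm channel pattern (shared across participants, participant-
specific, or orthogonal to another spec's pattern) times a smooth raised-
cosine bump inside the effect window is added to the first condition of the
contrast.  In Illusion conditions the effect is only present for events
after the trial's illusion onset -- the illusory state, not the condition
label, carries the effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .preprocessing import ILLUSION_CONDITIONS
from .scr import SkinTrace

DEFAULT_CONDITIONS = (
    "IllusionNext",
    "IllusionUnder",
    "IncongruentNext",
    "IncongruentUnder",
    "Real",
)

#: family labels accepted in EffectSpec contrasts, expanded to condition lists
CONDITION_FAMILIES = {
    "Illusion": ("IllusionNext", "IllusionUnder"),
    "Incongruent": ("IncongruentNext", "IncongruentUnder"),
}


@dataclass
class StudyConfig:
    """Sizes, rates and labels of one simulated study.

    Defaults reproduce the full design: 128 channels at 200 Hz, five
    conditions with four 3-min trials each, 180 events per trial at 1 Hz,
    100-Hz skin conductance.  ``noise_std`` is the per-channel background
    EEG standard deviation in microvolt; ``ar_coef`` the lag-one temporal
    autocorrelation of the noise; ``spatial_mix`` the strength of the random
    channel-mixing that induces spatial correlation.
    """

    n_participants: int = 22
    n_channels: int = 128
    fs_eeg: float = 200.0
    fs_scr: float = 100.0
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    trials_per_condition: int = 4
    events_per_trial: int = 180
    isi: float = 1.0
    rng_seed: int = 0
    noise_std: float = 10.0
    ar_coef: float = 0.95
    spatial_mix: float = 0.5
    evoked_amplitude: float = 4.0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.fs_eeg <= 0 or self.fs_scr <= 0:
            raise ValueError("sampling rates must be positive")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if self.events_per_trial < 1 or self.trials_per_condition < 1:
            raise ValueError("counts must be positive")

    @property
    def trial_duration(self) -> float:
        """Trial length in seconds (events x inter-stimulus interval)."""
        return self.events_per_trial * self.isi


@dataclass
class EffectSpec:
    """One injected condition difference.

    ``contrast`` is a pair of condition labels (or the family labels
    "Illusion"/"Incongruent"); the pattern is added to the first member.
    ``window`` is the active interval in seconds post-stimulus, within the
    -0.4..0.4 s epoch span.  ``pattern_mode`` is one of
    ``"shared-across-participants"``, ``"participant-specific"`` or
    ``"orthogonal-to:<other id>"``.
    """

    id: str
    contrast: tuple[str, str]
    window: tuple[float, float] = (0.08, 0.30)
    amplitude: float = 1.0
    pattern_mode: str = "participant-specific"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        lo, hi = self.window
        if not (-0.4 <= lo < hi <= 0.4):
            raise ValueError(
                f"effect window {self.window} outside the epoch span [-0.4, 0.4] s"
            )

    def target_conditions(self) -> tuple[str, ...]:
        return CONDITION_FAMILIES.get(self.contrast[0], (self.contrast[0],))


@dataclass
class GroundTruth:
    """What was injected: per-participant patterns, onsets, SCR multipliers."""

    patterns: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    onsets: pd.DataFrame | None = None
    scr_effect: dict[str, float] = field(default_factory=dict)


@dataclass
class TrialRecording:
    """One continuous 3-min (at full scale) trial of one participant."""

    participant: str
    condition: str
    trial_index: int
    data: np.ndarray  # channels x samples, uV
    fs: float
    event_times: np.ndarray  # seconds within trial
    onset_s: float | None = None  # illusion onset (Illusion conditions only)


def _raised_cosine(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Smooth bump of unit peak, supported on [center - width/2, center + width/2]."""
    x = (t - center) / width
    out = 0.5 * (1.0 + np.cos(2 * np.pi * x))
    out[np.abs(x) > 0.5] = 0.0
    return out


def _participant_ids(n: int) -> list[str]:
    return [f"P{i:02d}" for i in range(1, n + 1)]


def _make_patterns(
    config: StudyConfig, effects: list[EffectSpec], rng: np.random.Generator
) -> dict[str, dict[str, np.ndarray]]:
    """Unit-norm channel patterns per effect and participant."""
    ids = _participant_ids(config.n_participants)
    patterns: dict[str, dict[str, np.ndarray]] = {}
    shared_cache: dict[str, np.ndarray] = {}
    for eff in effects:
        patterns[eff.id] = {}
        if eff.pattern_mode == "shared-across-participants":
            v = rng.standard_normal(config.n_channels)
            shared_cache[eff.id] = v / np.linalg.norm(v)
        for pid in ids:
            if eff.pattern_mode == "shared-across-participants":
                v = shared_cache[eff.id]
            elif eff.pattern_mode == "participant-specific":
                v = rng.standard_normal(config.n_channels)
                v /= np.linalg.norm(v)
            elif eff.pattern_mode.startswith("orthogonal-to:"):
                ref_id = eff.pattern_mode.split(":", 1)[1]
                if ref_id not in patterns or pid not in patterns[ref_id]:
                    raise ValueError(
                        f"effect {eff.id!r} is orthogonal-to {ref_id!r}, which must "
                        "be listed before it"
                    )
                ref = patterns[ref_id][pid]
                v = rng.standard_normal(config.n_channels)
                v -= ref * (ref @ v)
                v /= np.linalg.norm(v)
            else:
                raise ValueError(f"unknown pattern_mode {eff.pattern_mode!r}")
            patterns[eff.id][pid] = v
    return patterns


def _noise(
    n_channels: int,
    n_samples: int,
    config: StudyConfig,
    mixing: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spatially correlated AR(1) Gaussian noise, channels x samples, in uV."""
    white = rng.standard_normal((n_channels, n_samples))
    # AR(1) along time: x[t] = a x[t-1] + e[t], variance-normalized
    a = config.ar_coef
    ar = signal.lfilter([np.sqrt(1 - a**2)], [1, -a], white, axis=1)
    return config.noise_std * (mixing @ ar)


def _mixing_matrix(n_channels: int, strength: float, rng: np.random.Generator) -> np.ndarray:
    """Row-normalized (I + strength*G) mixer: correlated channels, equal variance."""
    m = np.eye(n_channels) + strength * rng.standard_normal((n_channels, n_channels)) / np.sqrt(
        n_channels
    )
    return m / np.linalg.norm(m, axis=1, keepdims=True)


def generate_onsets(
    config: StudyConfig,
    median_next: float = 42.0,
    median_under: float = 30.0,
    sigma: float = 0.55,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw per-trial illusion-onset latencies for both Illusion conditions.

    Latencies are log-normal with the requested per-condition medians (the
    latency distribution is right-skewed: a handful of trials take much
    longer than the typical ~30-40 s) and are clipped to
    ``[5 s, trial_duration - 10 s]``.  ``sigma`` is the log-scale spread.
    """
    rng = np.random.default_rng(rng if not isinstance(rng, np.random.Generator) else None) \
        if not isinstance(rng, np.random.Generator) else rng
    lo, hi = 5.0, config.trial_duration - 10.0
    for name, med in (("median_next", median_next), ("median_under", median_under)):
        if not (lo < med < hi):
            raise ValueError(f"{name}={med} outside the admissible range ({lo}, {hi}) s")
    rows = []
    medians = {"IllusionNext": median_next, "IllusionUnder": median_under}
    for pid in _participant_ids(config.n_participants):
        for cond, med in medians.items():
            if cond not in config.conditions:
                continue
            draws = np.exp(np.log(med) + sigma * rng.standard_normal(config.trials_per_condition))
            for k, onset in enumerate(np.clip(draws, lo, hi)):
                rows.append(
                    {"participant": pid, "condition": cond, "trial_index": k,
                     "onset_s": float(onset)}
                )
    return pd.DataFrame(rows)


def generate_dataset(
    config: StudyConfig,
    effects: list[EffectSpec] | None = None,
    onsets: pd.DataFrame | None = None,
    onset_kwargs: dict | None = None,
) -> tuple[dict[str, list[TrialRecording]], GroundTruth]:
    """Simulate continuous per-trial EEG plus event tables for every participant.

    Each trial holds ``events_per_trial`` events at ``isi`` spacing; every
    event evokes a condition-independent response (two raised-cosine
    components near 100 and 250 ms with a participant-fixed topography)
    plus, for conditions targeted by an :class:`EffectSpec`, the injected
    pattern x amplitude x bump.  Deterministic given ``config.rng_seed``.

    Returns a dict participant -> list of :class:`TrialRecording` and the
    :class:`GroundTruth` record of injected patterns and onsets.
    """
    effects = list(effects or [])
    root = np.random.SeedSequence(config.rng_seed)
    pattern_rng = np.random.default_rng(root.spawn(1)[0])
    onset_rng, *participant_seeds = root.spawn(config.n_participants + 1)

    patterns = _make_patterns(config, effects, pattern_rng)
    if onsets is None:
        onsets = generate_onsets(config, rng=np.random.default_rng(onset_rng),
                                 **(onset_kwargs or {}))
    truth = GroundTruth(patterns=patterns, onsets=onsets)

    fs = config.fs_eeg
    n_trial_samples = int(round(config.trial_duration * fs)) + int(round(0.5 * fs))
    event_times = np.arange(config.events_per_trial) * config.isi + 0.45
    # events offset by 0.45 s so the first pre-stimulus window fits in-trial
    epoch_rel = np.arange(int(round(-0.4 * fs)), int(round(0.4 * fs)) + 1) / fs
    evoked_wave = config.evoked_amplitude * (
        _raised_cosine(epoch_rel, 0.10, 0.10) + 0.6 * _raised_cosine(epoch_rel, 0.25, 0.14)
    )
    effect_waves = {
        eff.id: eff.amplitude
        * _raised_cosine(epoch_rel, (eff.window[0] + eff.window[1]) / 2,
                         eff.window[1] - eff.window[0])
        for eff in effects
    }

    dataset: dict[str, list[TrialRecording]] = {}
    for pid, seed in zip(_participant_ids(config.n_participants), participant_seeds):
        prng = np.random.default_rng(seed)
        mixing = _mixing_matrix(config.n_channels, config.spatial_mix, prng)
        evoked_topo = prng.standard_normal(config.n_channels)
        evoked_topo /= np.linalg.norm(evoked_topo)

        # pseudorandomized trial order per participant
        trial_list = [
            (cond, k) for cond in config.conditions for k in range(config.trials_per_condition)
        ]
        prng.shuffle(trial_list)

        p_onsets = onsets[onsets["participant"] == pid]
        onset_lookup = {
            (r["condition"], int(r["trial_index"])): float(r["onset_s"])
            for _, r in p_onsets.iterrows()
        }

        recordings = []
        for cond, k in trial_list:
            data = _noise(config.n_channels, n_trial_samples, config, mixing, prng)
            onset_s = onset_lookup.get((cond, k)) if cond in ILLUSION_CONDITIONS else None
            event_samples = np.round(event_times * fs).astype(int)
            rel0 = int(round(-0.4 * fs))
            for ev_i, s in enumerate(event_samples):
                sl = slice(s + rel0, s + rel0 + epoch_rel.size)
                data[:, sl] += np.outer(evoked_topo, evoked_wave)
                for eff in effects:
                    if cond not in eff.target_conditions():
                        continue
                    if onset_s is not None and event_times[ev_i] <= onset_s:
                        continue  # illusory state not yet established
                    data[:, sl] += np.outer(patterns[eff.id][pid], effect_waves[eff.id])
            recordings.append(
                TrialRecording(
                    participant=pid, condition=cond, trial_index=k,
                    data=data, fs=fs, event_times=event_times.copy(), onset_s=onset_s,
                )
            )
        dataset[pid] = recordings
    return dataset, truth


def event_table(recordings: list[TrialRecording]) -> pd.DataFrame:
    """TSV-ready event table (trial, condition, event_time_s, onset_time_s)."""
    rows = []
    for rec in recordings:
        for t in rec.event_times:
            rows.append(
                {"trial": rec.trial_index, "condition": rec.condition,
                 "event_time_s": float(t),
                 "onset_time_s": rec.onset_s if rec.onset_s is not None else np.nan}
            )
    return pd.DataFrame(rows)


def generate_scr(
    config: StudyConfig,
    onsets: pd.DataFrame,
    scr_effect: dict[str, float] | None = None,
    effect_window: tuple[float, float] = (-3.0, 0.0),
    noise_std: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> list[SkinTrace]:
    """Skin-conductance traces for every trial of every participant.

    Band-limited (0.5-2 Hz) Gaussian noise at ``config.fs_scr`` whose local
    standard deviation is multiplied by ``scr_effect[condition]`` inside
    ``effect_window`` (seconds relative to the trial's onset; control trials
    use the participant's trial-number-matched surrogate onset).  A
    multiplier of 1 everywhere gives a stationary trace.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    scr_effect = scr_effect or {}
    fs = config.fs_scr
    n = int(round(config.trial_duration * fs))
    sos = signal.butter(3, [0.5, 2.0], btype="bandpass", fs=fs, output="sos")
    t = np.arange(n) / fs

    # surrogate onsets for control conditions: trial-number-matched Illusion onset
    from .scr import surrogate_onsets  # local import to avoid a cycle

    controls = [c for c in config.conditions if c not in ILLUSION_CONDITIONS]
    full = pd.concat(
        [onsets, surrogate_onsets(onsets, controls, config.trials_per_condition)],
        ignore_index=True,
    )
    lookup = {
        (r["participant"], r["condition"], int(r["trial_index"])): float(r["onset_s"])
        for _, r in full.iterrows()
    }

    traces = []
    for pid in _participant_ids(config.n_participants):
        for cond in config.conditions:
            for k in range(config.trials_per_condition):
                x = signal.sosfiltfilt(sos, rng.standard_normal(n))
                x *= noise_std / x.std()
                mult = scr_effect.get(cond, 1.0)
                onset = lookup.get((pid, cond, k))
                if mult != 1.0 and onset is not None:
                    w = (t >= onset + effect_window[0]) & (t < onset + effect_window[1])
                    x[w] *= mult
                traces.append(
                    SkinTrace(samples=x + 2.0, fs=fs, participant=pid,
                              trial_index=k, condition=cond, onset_s=onset)
                )
    return traces
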