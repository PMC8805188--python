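"""Event-locked epoching, filtering, artifact rejection and onset-based epoch selection.

The analysis operates on short epochs of multichannel EEG aligned to each
visuo-tactile stimulation event (1 Hz trains, 180 events per 3-min trial in
the full design).  Epochs span -400..+400 ms around each event, are band-pass
filtered 1-40 Hz with a two-pass third-order Butterworth filter, and epochs
whose absolute amplitude exceeds 165 uV on any EEG channel are discarded.
Because the illusory state only exists after the participant's button press,
Illusion-condition epochs are restricted to events after the trial-specific
onset; control conditions are restricted using the participant's median
Illusion onset as a surrogate cut-off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

#: conditions in which participants can experience the illusion
ILLUSION_CONDITIONS = ("IllusionNext", "IllusionUnder")

DEFAULT_EPOCH_WINDOW = (-0.4, 0.4)


class EmptyDatasetError(RuntimeError):
    """Raised when an operation would leave no epochs to analyze."""


@dataclass
class EpochedDataset:
    """Epochs x channels x samples for one participant and condition.

    Attributes
    ----------
    data : ndarray, shape (n_epochs, n_channels, n_samples)
        Epoch amplitudes in microvolt.
    times : ndarray, shape (n_samples,)
        Time axis in seconds relative to stimulus onset (closed interval,
        both endpoints included; 161 samples for -0.4..0.4 s at 200 Hz).
    fs : float
        Sampling rate in Hz.
    condition, participant : str
        Condition label and participant identifier.
    event_times : ndarray, shape (n_epochs,)
        Stimulus-onset time of each epoch in seconds within its trial.
    trial_index : ndarray, shape (n_epochs,)
        Repeat number of the trial each epoch came from.
    ch_names : list of str, optional
    """

    data: np.ndarray
    times: np.ndarray
    fs: float
    condition: str
    participant: str
    event_times: np.ndarray
    trial_index: np.ndarray
    ch_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.trial_index = np.asarray(self.trial_index, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis length does not match data")
        if self.data.shape[0] != self.event_times.size:
            raise ValueError("event_times length does not match epoch count")
        if self.data.shape[0] != self.trial_index.size:
            raise ValueError("trial_index length does not match epoch count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def select(self, mask: np.ndarray) -> "EpochedDataset":
        """Return a copy restricted to the epochs where ``mask`` is True."""
        mask = np.asarray(mask)
        return replace(
            self,
            data=self.data[mask],
            event_times=self.event_times[mask],
            trial_index=self.trial_index[mask],
        )


@dataclass
class RejectionLog:
    """Book-keeping for amplitude-based artifact rejection."""

    n_input: int
    n_rejected: int
    threshold: float
    rejected_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))


def epoch(
    continuous: np.ndarray,
    fs: float,
    event_times: np.ndarray,
    window: tuple[float, float] = DEFAULT_EPOCH_WINDOW,
    *,
    condition: str = "",
    participant: str = "",
    trial_index: int = 0,
    ch_names: list[str] | None = None,
) -> EpochedDataset:
    """Cut event-locked epochs out of a continuous recording.

    The epoch covers the closed interval ``[window[0], window[1]]`` so that an
    0.8-s window at 200 Hz yields 161 samples.  Events whose window is not
    fully inside the recording are dropped with a logged warning.
    """
    continuous = np.asarray(continuous, dtype=float)
    if continuous.ndim != 2:
        raise ValueError("continuous must be channels x samples")
    event_times = np.atleast_1d(np.asarray(event_times, dtype=float))
    pre = int(round(-window[0] * fs))
    post = int(round(window[1] * fs))
    n_samples = continuous.shape[1]

    samples = np.round(event_times * fs).astype(int)
    ok = (samples - pre >= 0) & (samples + post < n_samples)
    if not ok.all():
        logger.warning(
            "dropping %d of %d events too close to the recording edge",
            int((~ok).sum()), event_times.size,
        )
    kept = samples[ok]
    times = np.arange(-pre, post + 1) / fs
    data = np.stack([continuous[:, s - pre : s + post + 1] for s in kept], axis=0) \
        if kept.size else np.empty((0, continuous.shape[0], pre + post + 1))
    return EpochedDataset(
        data=data,
        times=times,
        fs=fs,
        condition=condition,
        participant=participant,
        event_times=event_times[ok],
        trial_index=np.full(kept.size, trial_index, dtype=int),
        ch_names=ch_names,
    )


def concatenate_epochs(datasets: list[EpochedDataset]) -> EpochedDataset:
    """Stack epochs of the same participant/condition across trials."""
    if not datasets:
        raise EmptyDatasetError("no epoch sets to concatenate")
    first = datasets[0]
    for d in datasets[1:]:
        if d.data.shape[1:] != first.data.shape[1:] or d.fs != first.fs:
            raise ValueError("epoch sets are not compatible")
    return replace(
        first,
        data=np.concatenate([d.data for d in datasets], axis=0),
        event_times=np.concatenate([d.event_times for d in datasets]),
        trial_index=np.concatenate([d.trial_index for d in datasets]),
    )


def bandpass_epochs(
    epochs: EpochedDataset, low: float = 1.0, high: float = 40.0, order: int = 3
) -> EpochedDataset:
    """Zero-phase (two-pass) Butterworth band-pass, applied per epoch and channel.

    The forward-backward application squares the magnitude response, so a
    third-order design acts with an effective sixth-order roll-off.
    """
    if high >= epochs.fs / 2:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {epochs.fs / 2} Hz")
    # transfer-function form is numerically safe at this low order and
    # noticeably faster than second-order sections on many short epochs
    b, a = signal.butter(order, [low, high], btype="bandpass", fs=epochs.fs)
    flat = np.ascontiguousarray(epochs.data.reshape(-1, epochs.data.shape[-1]))
    filtered = signal.filtfilt(b, a, flat, axis=-1).reshape(epochs.data.shape)
    return replace(epochs, data=filtered)


def reject_artifacts(
    epochs: EpochedDataset, threshold: float = 165.0, eeg_mask: np.ndarray | None = None
) -> tuple[EpochedDataset, RejectionLog]:
    """Drop epochs whose absolute amplitude exceeds ``threshold`` (uV) on any EEG channel.

    ``eeg_mask`` restricts the criterion to EEG channels (True entries);
    auxiliary channels such as EOG are ignored when deciding rejection.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    data = epochs.data
    if eeg_mask is not None:
        data = data[:, np.asarray(eeg_mask, bool), :]
    bad = np.abs(data).max(axis=(1, 2)) > threshold
    log = RejectionLog(
        n_input=epochs.n_epochs,
        n_rejected=int(bad.sum()),
        threshold=threshold,
        rejected_indices=np.flatnonzero(bad),
    )
    if log.n_rejected:
        logger.info("rejected %d/%d epochs above %.1f uV", log.n_rejected, log.n_input, threshold)
    return epochs.select(~bad), log


def _illusion_onsets(onset_table: pd.DataFrame, participant: str) -> pd.DataFrame:
    tab = onset_table[onset_table["participant"].astype(str) == str(participant)]
    return tab[tab["condition"].isin(ILLUSION_CONDITIONS) & tab["onset_s"].notna()]


def participant_median_onset(onset_table: pd.DataFrame, participant: str) -> float:
    """Median button-press latency over all Illusion trials of one participant."""
    ill = _illusion_onsets(onset_table, participant)
    if ill.empty:
        raise ValueError(f"no Illusion onsets for participant {participant!r}")
    return float(ill["onset_s"].median())


def select_epochs_by_onset(
    epochs: EpochedDataset, onset_table: pd.DataFrame
) -> EpochedDataset:
    """Keep only epochs recorded during the illusory state (or its surrogate window).

    Illusion-condition epochs are kept iff their event time exceeds the
    trial-specific button-press onset; Incongruent/Real epochs are kept iff
    their event time exceeds the participant's median Illusion onset.
    """
    if epochs.condition in ILLUSION_CONDITIONS:
        ill = _illusion_onsets(onset_table, epochs.participant)
        ill = ill[ill["condition"] == epochs.condition]
        onset_by_trial = dict(zip(ill["trial_index"].astype(int), ill["onset_s"]))
        missing = set(np.unique(epochs.trial_index)) - set(onset_by_trial)
        if missing:
            raise ValueError(
                f"missing illusion onset for participant {epochs.participant!r} "
                f"trials {sorted(missing)}"
            )
        cutoffs = np.array([onset_by_trial[t] for t in epochs.trial_index])
    else:
        cutoffs = np.full(epochs.n_epochs, participant_median_onset(onset_table, epochs.participant))
    keep = epochs.event_times > cutoffs
    if not keep.any():
        logger.warning(
            "onset selection removed every epoch for %s/%s",
            epochs.participant, epochs.condition,
        )
    return epochs.select(keep)


def split_pre_post_onset(
    epochs: EpochedDataset, onset_table: pd.DataFrame
) -> tuple[EpochedDataset, EpochedDataset]:
    """Partition Illusion-trial epochs into pre-onset and illusory-state epochs.

    Epochs with ``event_time <= onset`` go to the pre-onset set, the rest to
    the post-onset set; the two parts are a partition of the input.
    """
    if epochs.condition not in ILLUSION_CONDITIONS:
        raise ValueError("pre/post split is defined for Illusion trials only")
    ill = _illusion_onsets(onset_table, epochs.participant)
    ill = ill[ill["condition"] == epochs.condition]
    onset_by_trial = dict(zip(ill["trial_index"].astype(int), ill["onset_s"]))
    missing = set(np.unique(epochs.trial_index)) - set(onset_by_trial)
    if missing:
        raise ValueError(f"missing illusion onset for trials {sorted(missing)}")
    cutoffs = np.array([onset_by_trial[t] for t in epochs.trial_index])
    post = epochs.event_times > cutoffs
    return epochs.select(~post), epochs.select(post)


def compute_evoked(epochs: EpochedDataset) -> np.ndarray:
    """Arithmetic mean over epochs -> channels x samples evoked response."""
    if epochs.n_epochs == 0:
        raise EmptyDatasetError("cannot average an empty epoch set")
    return epochs.data.mean(axis=0)
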