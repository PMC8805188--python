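"""Skin-conductance preprocessing and the onset-locked SD-ratio response.

Skin conductance is recorded at 100 Hz in micro-Siemens, resampled to 50 Hz
and band-pass filtered 0.5-2 Hz (one-pass third-order Butterworth).  The
"skin response" for a trial is the ratio of the signal's standard deviation
in two adjacent 3-s windows placed relative to the reported illusion onset:
either around the onset ([-3, 0] s vs [0, +3] s) or entirely before it
([-6, -3] s vs [-3, 0] s), always later window over earlier window.
Control conditions without a button press use surrogate onsets copied from
the trial-number-matched Illusion trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

#: (earlier, later) analysis windows in seconds relative to the onset
WINDOW_PAIRS = {
    "around_onset": ((-3.0, 0.0), (0.0, 3.0)),
    "before_onset": ((-6.0, -3.0), (-3.0, 0.0)),
}


@dataclass
class SkinTrace:
    """One trial's conductance time series (micro-Siemens)."""

    samples: np.ndarray
    fs: float
    participant: str = ""
    trial_index: int = 0
    condition: str = ""
    onset_s: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class SkinResponse:
    """SD ratio (later/earlier window) for one trial and window pair."""

    ratio: float
    window_pair: str
    participant: str = ""
    trial_index: int = 0
    condition: str = ""


def preprocess_scr(
    trace: SkinTrace, target_fs: float = 50.0, band: tuple[float, float] = (0.5, 2.0)
) -> SkinTrace:
    """Resample to 50 Hz and band-pass 0.5-2 Hz (one-pass third-order Butterworth).

    The single forward pass mirrors how slow electrodermal traces are
    conventionally conditioned; the resulting phase lag is identical for all
    trials and cancels in the ratio statistic.
    """
    if trace.fs < target_fs:
        raise ValueError("input sampling rate must be at least the target rate")
    if trace.duration < 6.0:
        raise ValueError("trace shorter than the filter warm-up (need >= 6 s)")
    frac = Fraction(target_fs / trace.fs).limit_denominator(1000)
    x = signal.resample_poly(trace.samples, frac.numerator, frac.denominator)
    sos = signal.butter(3, band, btype="bandpass", fs=target_fs, output="sos")
    return replace(trace, samples=signal.sosfilt(sos, x), fs=target_fs)


def skin_response(
    trace: SkinTrace, onset_s: float | None = None, pair: str = "around_onset"
) -> SkinResponse:
    """SD-ratio response of one trial: SD(later window) / SD(earlier window)."""
    if pair not in WINDOW_PAIRS:
        raise ValueError(f"unknown window pair {pair!r}; choose from {sorted(WINDOW_PAIRS)}")
    onset = trace.onset_s if onset_s is None else onset_s
    if onset is None:
        raise ValueError("trace has no onset and none was given")
    (e0, e1), (l0, l1) = WINDOW_PAIRS[pair]
    sds = []
    for w0, w1 in ((e0, e1), (l0, l1)):
        i0 = int(round((onset + w0) * trace.fs))
        i1 = int(round((onset + w1) * trace.fs))
        if i0 < 0 or i1 > trace.samples.size:
            raise ValueError(
                f"window [{w0}, {w1}] s relative to onset {onset} s falls outside the trace"
            )
        sds.append(trace.samples[i0:i1].std())
    if sds[0] == 0:
        raise ValueError("earlier window has zero standard deviation; response undefined")
    return SkinResponse(
        ratio=float(sds[1] / sds[0]), window_pair=pair,
        participant=trace.participant, trial_index=trace.trial_index,
        condition=trace.condition,
    )


def surrogate_onsets(
    onset_table: pd.DataFrame,
    control_conditions: list[str],
    n_trials: int | None = None,
) -> pd.DataFrame:
    """Assign onsets to control trials from trial-number-matched Illusion trials.

    Control trial ``k`` of a participant receives the mean of that
    participant's Illusion-condition onsets for trial number ``k`` (averaged
    over the two Illusion conditions when both exist).  If no Illusion trial
    ``k`` exists, the participant's median Illusion onset is used and a
    warning logged.
    """
    ill = onset_table[onset_table["onset_s"].notna()]
    rows = []
    for pid, tab in ill.groupby("participant"):
        by_trial = tab.groupby("trial_index")["onset_s"].mean()
        median = float(tab["onset_s"].median())
        n = n_trials if n_trials is not None else int(tab["trial_index"].max()) + 1
        for cond in control_conditions:
            for k in range(n):
                if k in by_trial.index:
                    onset = float(by_trial.loc[k])
                else:
                    logger.warning(
                        "participant %s has no Illusion trial %d; using median onset %.1f s",
                        pid, k, median,
                    )
                    onset = median
                rows.append(
                    {"participant": pid, "condition": cond, "trial_index": k,
                     "onset_s": onset}
                )
    return pd.DataFrame(rows)


def trial_responses(
    traces: list[SkinTrace], pair: str = "around_onset", preprocess: bool = True
) -> pd.DataFrame:
    """Compute the SD-ratio response for every trial with a usable onset.

    Trials whose analysis windows do not fit inside the trace are skipped
    with a warning (mirroring manual trial exclusion in practice).
    """
    rows = []
    for tr in traces:
        if tr.onset_s is None:
            continue
        try:
            resp = skin_response(preprocess_scr(tr) if preprocess else tr, pair=pair)
        except ValueError as err:
            logger.warning("skipping trial %s/%s/%d: %s",
                           tr.participant, tr.condition, tr.trial_index, err)
            continue
        rows.append(
            {"participant": resp.participant, "condition": resp.condition,
             "trial_index": resp.trial_index, "pair": pair, "ratio": resp.ratio}
        )
    return pd.DataFrame(rows)


def contrast_skin_responses(
    responses: pd.DataFrame,
    contrasts: list[tuple[str, str]] | None = None,
    condition_groups: dict[str, tuple[str, ...]] | None = None,
):
    """Paired Wilcoxon tests on per-participant mean responses, BH-corrected.

    ``responses`` must hold columns participant/condition/ratio.  Conditions
    are pooled into groups (by default Illusion = both Illusion conditions,
    Incongruent likewise, Real alone), trial ratios averaged within
    participant and group, then each contrast is tested with the Wilcoxon
    signed-rank test; p-values are Benjamini-Hochberg corrected across the
    contrast family.

    Returns a dict contrast-name -> PairedTestResult (with ``p_corrected``).
    """
    from .group_stats import benjamini_hochberg, wilcoxon_signed_rank

    condition_groups = condition_groups or {
        "Illusion": ("IllusionNext", "IllusionUnder"),
        "Incongruent": ("IncongruentNext", "IncongruentUnder"),
        "Real": ("Real",),
    }
    contrasts = contrasts or [("Illusion", "Incongruent"), ("Illusion", "Real")]

    cond_to_group = {c: g for g, cs in condition_groups.items() for c in cs}
    df = responses.copy()
    df["group"] = df["condition"].map(cond_to_group)
    means = df.dropna(subset=["group"]).groupby(["participant", "group"])["ratio"].mean()

    results = {}
    for a, b in contrasts:
        wide = means.unstack("group")[[a, b]].dropna()
        if len(wide) < 2:
            raise ValueError(f"contrast {a} vs {b}: need at least 2 participants")
        results[f"{a}_vs_{b}"] = wilcoxon_signed_rank(
            wide[a].to_numpy(), wide[b].to_numpy()
        )
    _, p_adj = benjamini_hochberg([r.p_value for r in results.values()])
    for res, p in zip(results.values(), p_adj):
        res.p_corrected = float(p)
    return results
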