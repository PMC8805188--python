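"""End-to-end study orchestration at desk scale.

``run_study`` wires the stages together: simulate a multi-participant study
(or load one), epoch and preprocess every trial, decode all configured
condition contrasts per participant, cross-classify between contrasts,
run group-level sign-flip cluster statistics, analyze the skin-conductance
responses, and correlate the EEG decoding effect with the skin-response
effect across participants.  A master seed deterministically spawns
per-stage seeds, so the whole study is reproducible and individual stages
can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decoding import DecodingConfig, DecodingCurve, cross_classify, decode_timecourse
from .group_stats import (
    ClusterResult,
    ClusterTestConfig,
    PairedTestResult,
    correlation_cluster_test,
    signflip_cluster_test,
    wilcoxon_signed_rank,
)
from .preprocessing import (
    ILLUSION_CONDITIONS,
    EpochedDataset,
    bandpass_epochs,
    concatenate_epochs,
    epoch,
    reject_artifacts,
    select_epochs_by_onset,
    split_pre_post_onset,
)
from .scr import contrast_skin_responses, trial_responses
from .synthetic import EffectSpec, StudyConfig, generate_dataset, generate_scr

logger = logging.getLogger(__name__)

#: decoding contrasts of the full design, name -> (positive side, negative side);
#: each side is a tuple of condition labels pooled together
DEFAULT_CONTRASTS = {
    "illusion_vs_incongruent": (("IllusionNext", "IllusionUnder"),
                                ("IncongruentNext", "IncongruentUnder")),
    "illusion_vs_real": (("IllusionNext", "IllusionUnder"), ("Real",)),
    "illusion_vs_incongruent_next": (("IllusionNext",), ("IncongruentNext",)),
    "illusion_vs_incongruent_under": (("IllusionUnder",), ("IncongruentUnder",)),
    "within_illusion": ("POST_ONSET", "PRE_ONSET"),
}

#: cross-classification pairs, name -> (train contrast, test contrast)
DEFAULT_CROSS = {
    "cross_incongruent_to_real": ("illusion_vs_incongruent", "illusion_vs_real"),
    "cross_next_to_under": ("illusion_vs_incongruent_next",
                            "illusion_vs_incongruent_under"),
    "cross_within_to_incongruent": ("within_illusion", "illusion_vs_incongruent"),
}


@dataclass
class RunConfig:
    """Everything one study run needs; nested blocks mirror the stages."""

    study: StudyConfig = field(default_factory=StudyConfig)
    effects: list[EffectSpec] = field(default_factory=list)
    decoding: DecodingConfig = field(default_factory=DecodingConfig)
    cluster: ClusterTestConfig = field(default_factory=ClusterTestConfig)
    onset_median_next: float = 42.0
    onset_median_under: float = 30.0
    onset_sigma: float = 0.55
    scr_effect: dict = field(default_factory=dict)
    scr_effect_window: tuple[float, float] = (-3.0, 0.0)
    scr_missing_participants: int = 0
    contrasts: dict = field(default_factory=lambda: dict(DEFAULT_CONTRASTS))
    cross: dict = field(default_factory=lambda: dict(DEFAULT_CROSS))
    reject_threshold: float = 165.0
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "study" in kwargs:
            study = dict(kwargs["study"])
            if "conditions" in study:
                study["conditions"] = tuple(study["conditions"])
            kwargs["study"] = StudyConfig(**study)
        if "effects" in kwargs:
            kwargs["effects"] = [
                EffectSpec(**{**e, "contrast": tuple(e["contrast"]),
                              "window": tuple(e.get("window", (0.08, 0.30)))})
                for e in kwargs["effects"]
            ]
        if "decoding" in kwargs:
            kwargs["decoding"] = DecodingConfig(**kwargs["decoding"])
        if "cluster" in kwargs:
            kwargs["cluster"] = ClusterTestConfig(**kwargs["cluster"])
        if "scr_effect_window" in kwargs:
            kwargs["scr_effect_window"] = tuple(kwargs["scr_effect_window"])
        for name in ("contrasts", "cross"):
            if name in kwargs:
                kwargs[name] = {
                    k: tuple(tuple(s) if isinstance(s, list) else s for s in v)
                    for k, v in kwargs[name].items()
                }
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class StudyResult:
    """Bundle of everything a study run produces."""

    curves: dict[str, list[DecodingCurve]] = field(default_factory=dict)
    cluster_results: dict[str, ClusterResult] = field(default_factory=dict)
    scr_tests: dict[str, dict[str, PairedTestResult]] = field(default_factory=dict)
    scr_responses: pd.DataFrame | None = None
    onset_test: PairedTestResult | None = None
    onset_medians: dict[str, float] = field(default_factory=dict)
    eeg_scr_correlation: ClusterResult | None = None
    provenance: dict = field(default_factory=dict)

    def auc_matrix(self, contrast: str) -> tuple[np.ndarray, np.ndarray]:
        curves = self.curves[contrast]
        return np.stack([c.auc for c in curves]), curves[0].bin_centers

    def report(self) -> dict:
        """Table-style summary: per contrast the cluster p, summed statistic,
        interval, max AUC and its time."""
        out = {}
        for name, res in self.cluster_results.items():
            out[name] = {
                "max_auc": res.max_stat,
                "time_of_max_s": res.time_of_max,
                "clusters": [
                    {"p": c.p_value, "auc_sum": c.stat_sum,
                     "interval_s": [c.start_s, c.end_s]}
                    for c in res.clusters
                ],
            }
        return out


def _seed_from(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] % (2**31))


def preprocess_study(
    dataset: dict,
    onsets: pd.DataFrame,
    reject_threshold: float = 165.0,
) -> dict[str, dict[str, EpochedDataset]]:
    """Epoch, filter, reject and onset-select every participant's data.

    Returns participant -> {condition: selected epochs, plus the
    ``PRE_ONSET``/``POST_ONSET`` split of the pooled Illusion trials}.
    """
    out: dict[str, dict[str, EpochedDataset]] = {}
    for pid, recordings in dataset.items():
        by_condition: dict[str, list[EpochedDataset]] = {}
        for rec in recordings:
            ep = epoch(rec.data, rec.fs, rec.event_times,
                       condition=rec.condition, participant=pid,
                       trial_index=rec.trial_index)
            by_condition.setdefault(rec.condition, []).append(ep)
        conds: dict[str, EpochedDataset] = {}
        pres = []
        for cond in sorted(by_condition):
            combined = concatenate_epochs(by_condition[cond])
            filtered = bandpass_epochs(combined)
            clean, _ = reject_artifacts(filtered, reject_threshold)
            conds[cond] = select_epochs_by_onset(clean, onsets)
            if cond in ILLUSION_CONDITIONS:
                pre, _post = split_pre_post_onset(clean, onsets)
                pres.append(pre)
        if pres:
            conds["PRE_ONSET"] = dataclasses.replace(
                concatenate_epochs(pres), condition="PRE_ONSET")
        out[pid] = conds
    return out


class _Pooler:
    """Per-participant cache of pooled condition sets.

    Pooling through a cache guarantees that a condition side appearing in
    several contrasts (e.g. the pooled Illusion epochs on both the train
    and the test side of a cross-classification) is the *same* object, so
    ``cross_classify`` recognizes it as shared and splits it disjointly.
    ``POST_ONSET`` (the illusory-state epochs of the within-trial contrast)
    is by construction the pooled onset-selected Illusion data.
    """

    def __init__(self, conds: dict[str, EpochedDataset]):
        self.conds = conds
        self._cache: dict[tuple, EpochedDataset] = {}

    def __call__(self, side) -> EpochedDataset:
        if side == "PRE_ONSET":
            return self.conds["PRE_ONSET"]
        if side == "POST_ONSET":
            side = tuple(c for c in ILLUSION_CONDITIONS if c in self.conds)
        if isinstance(side, str):
            side = (side,)
        side = tuple(side)
        if side not in self._cache:
            if len(side) == 1:
                self._cache[side] = self.conds[side[0]]
            else:
                self._cache[side] = dataclasses.replace(
                    concatenate_epochs([self.conds[c] for c in side]),
                    condition="+".join(side))
        return self._cache[side]


def run_study(config: RunConfig) -> StudyResult:
    """Execute the full study on synthetic data and return the result bundle."""
    root = np.random.SeedSequence(config.master_seed)
    seeds = {name: s for name, s in zip(
        ("simulate", "scr", "decode", "stats"), root.spawn(4))}

    logger.info("simulating study (%d participants)", config.study.n_participants)
    study_cfg = dataclasses.replace(config.study, rng_seed=_seed_from(seeds["simulate"]))
    dataset, truth = generate_dataset(
        study_cfg, config.effects,
        onset_kwargs={"median_next": config.onset_median_next,
                      "median_under": config.onset_median_under,
                      "sigma": config.onset_sigma},
    )
    onsets = truth.onsets

    logger.info("preprocessing")
    prepared = preprocess_study(dataset, onsets, config.reject_threshold)
    participants = sorted(prepared)

    result = StudyResult(provenance={
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "package_version": __version__,
        "n_participants": len(participants),
    })

    decode_seq = seeds["decode"].spawn(len(participants))
    poolers = {pid: _Pooler(prepared[pid]) for pid in participants}
    for name, (side_a, side_b) in config.contrasts.items():
        logger.info("decoding contrast %s", name)
        curves = []
        for pid, pseed in zip(participants, decode_seq):
            cfg = dataclasses.replace(config.decoding, rng_seed=_seed_from(pseed))
            try:
                curves.append(decode_timecourse(
                    poolers[pid](side_a), poolers[pid](side_b), cfg))
            except ValueError as err:
                raise RuntimeError(f"stage decode[{name}] participant {pid}: {err}") from err
        result.curves[name] = curves

    for name, (train_name, test_name) in config.cross.items():
        logger.info("cross-classification %s", name)
        tr_a, tr_b = config.contrasts[train_name]
        te_c, te_d = config.contrasts[test_name]
        curves = []
        for pid, pseed in zip(participants, decode_seq):
            cfg = dataclasses.replace(config.decoding, rng_seed=_seed_from(pseed) + 1)
            pool = poolers[pid]
            try:
                curves.append(cross_classify(
                    pool(tr_a), pool(tr_b), pool(te_c), pool(te_d), cfg))
            except ValueError as err:
                raise RuntimeError(f"stage cross[{name}] participant {pid}: {err}") from err
        result.curves[name] = curves

    stats_cfg = dataclasses.replace(config.cluster, rng_seed=_seed_from(seeds["stats"]))
    for name in list(config.contrasts) + list(config.cross):
        mat, centers = result.auc_matrix(name)
        result.cluster_results[name] = signflip_cluster_test(mat, centers, stats_cfg)

    # ---- onset latencies -------------------------------------------------
    med = onsets.groupby(["participant", "condition"])["onset_s"].median().unstack()
    if set(ILLUSION_CONDITIONS) <= set(med.columns):
        both = med.dropna()
        result.onset_medians = {
            c: float(onsets[onsets["condition"] == c]["onset_s"].median())
            for c in ILLUSION_CONDITIONS
        }
        try:
            result.onset_test = wilcoxon_signed_rank(
                both["IllusionNext"].to_numpy(), both["IllusionUnder"].to_numpy())
        except ValueError as err:
            logger.warning("onset latency test skipped: %s", err)

    # ---- skin conductance ------------------------------------------------
    logger.info("skin-conductance analysis")
    traces = generate_scr(
        study_cfg, onsets, scr_effect=config.scr_effect,
        effect_window=config.scr_effect_window,
        rng=np.random.default_rng(_seed_from(seeds["scr"])),
    )
    drop = set(participants[len(participants) - config.scr_missing_participants:]) \
        if config.scr_missing_participants else set()
    traces = [t for t in traces if t.participant not in drop]
    frames = [trial_responses(traces, pair=p) for p in ("around_onset", "before_onset")]
    responses = pd.concat(frames, ignore_index=True)
    result.scr_responses = responses
    for pair in ("around_onset", "before_onset"):
        try:
            result.scr_tests[pair] = contrast_skin_responses(
                responses[responses["pair"] == pair])
        except ValueError as err:
            logger.warning("skin-response contrast (%s) skipped: %s", pair, err)

    # ---- EEG effect vs skin response across participants ----------------
    try:
        result.eeg_scr_correlation = correlate_eeg_scr(result, stats_cfg)
    except ValueError as err:
        logger.warning("EEG-SCR correlation skipped: %s", err)
    return result


def correlate_eeg_scr(
    result: StudyResult,
    config: ClusterTestConfig | None = None,
    contrast: str = "illusion_vs_incongruent",
    pair: str = "before_onset",
) -> ClusterResult | None:
    """Between-participant correlation of decoding AUC and the skin-response
    difference (Illusion minus Incongruent), cluster-corrected along time.

    Participants without usable skin responses are dropped (intersection of
    the two participant sets); returns None when the overlap is below 4.
    """
    if result.scr_responses is None or contrast not in result.curves:
        return None
    resp = result.scr_responses
    resp = resp[resp["pair"] == pair].copy()
    group_of = {c: "Illusion" for c in ("IllusionNext", "IllusionUnder")}
    group_of.update({c: "Incongruent" for c in ("IncongruentNext", "IncongruentUnder")})
    resp["group"] = resp["condition"].map(group_of)
    means = resp.dropna(subset=["group"]).groupby(
        ["participant", "group"])["ratio"].mean().unstack()
    if not {"Illusion", "Incongruent"} <= set(means.columns):
        return None
    diff = (means["Illusion"] - means["Incongruent"]).dropna()

    curves = result.curves[contrast]
    auc_by_pid = {c.participant: c.auc for c in curves}
    common = [p for p in sorted(auc_by_pid) if p in diff.index]
    logger.info("EEG-SCR correlation over %d participants", len(common))
    if len(common) < 4:
        raise ValueError(
            f"only {len(common)} participants have both EEG and skin data; need >= 4")
    mat = np.stack([auc_by_pid[p] for p in common])
    cov = diff.loc[common].to_numpy()
    return correlation_cluster_test(mat, cov, curves[0].bin_centers, config)


def save_result(result: StudyResult, out_dir) -> None:
    """Write the study report (JSON) and per-bin group AUC tables (TSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {
        "provenance": result.provenance,
        "contrasts": result.report(),
        "onset_medians_s": result.onset_medians,
        "onset_test": dataclasses.asdict(result.onset_test) if result.onset_test else None,
        "scr_tests": {
            pair: {k: dataclasses.asdict(v) for k, v in tests.items()}
            for pair, tests in result.scr_tests.items()
        },
        "eeg_scr_correlation": dataclasses.asdict(result.eeg_scr_correlation)
        if result.eeg_scr_correlation else None,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    for name in result.curves:
        mat, centers = result.auc_matrix(name)
        df = pd.DataFrame({"bin_center_s": centers, "group_mean_auc": mat.mean(axis=0)})
        res = result.cluster_results.get(name)
        member = np.zeros(centers.size, int)
        if res:
            for i, c in enumerate(res.significant, start=1):
                member[c.bins[0]: c.bins[1] + 1] = i
        df["cluster"] = member
        df.to_csv(out / f"group_auc_{name}.tsv", sep="\t", index=False)
    if result.scr_responses is not None:
        result.scr_responses.to_csv(out / "scr_responses.tsv", sep="\t", index=False)
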