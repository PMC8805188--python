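"""Sliding-window single-trial classification of event-locked EEG.

Epochs are summarized in overlapping 60-ms bins advanced in 10-ms steps
(the per-bin feature is the per-channel mean amplitude, keeping the feature
dimension equal to the channel count).  Within each bin, "pseudo-trials" --
averages of four same-condition epochs -- are classified with a shrinkage-
regularized linear discriminant: the pooled within-class covariance S is
shrunk toward a scaled identity, S' = (1-l)S + l (tr S / d) I, and the
weights solve S' w = mu1 - mu0.  Performance is the ROC area (AUC) from
stratified sixfold cross-validation, with decision values pooled over test
folds; because condition epoch counts differ, both classes are subsampled
to 80% of the smaller count and everything is repeated 50 times with fresh
subsampling, pseudo-trial grouping and folds.  Per bin the classifier's
forward model -- the correlation between the discriminant component and
each channel -- gives an interpretable topography.  Cross-classification
trains on one condition contrast and tests on another, splitting any
condition shared between the two contrasts into disjoint halves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .preprocessing import EpochedDataset

logger = logging.getLogger(__name__)


@dataclass
class DecodingConfig:
    """Knobs of the sliding-window decoder (defaults = the study's settings)."""

    bin_width: float = 0.06  # s
    bin_step: float = 0.01  # s
    pseudo_trial_size: int = 4
    reg_lambda: float = 0.1
    n_folds: int = 6
    n_repeats: int = 50
    subsample_fraction: float = 0.8
    rng_seed: int = 0
    compute_forward: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.reg_lambda <= 1:
            raise ValueError("reg_lambda must lie in [0, 1]")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if self.pseudo_trial_size < 1 or self.n_repeats < 1:
            raise ValueError("counts must be positive")


@dataclass
class LdaModel:
    """Fitted shrinkage-LDA: weights, bias, and the moments behind them."""

    weights: np.ndarray
    bias: float
    means: np.ndarray  # (2, n_channels): class 0 and class 1 means
    covariance: np.ndarray  # shrunk pooled covariance

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """w.x + b; monotone in class-1 evidence."""
        return np.asarray(X) @ self.weights + self.bias


@dataclass
class DecodingCurve:
    """Per-participant AUC time course plus forward-model topographies."""

    participant: str
    bin_centers: np.ndarray
    auc: np.ndarray
    forward_model: np.ndarray | None = None  # channels x bins
    meta: dict = field(default_factory=dict)


def bin_epochs(
    epochs: EpochedDataset, bin_width: float = 0.06, bin_step: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean amplitude inside overlapping time bins.

    Returns ``(features, bin_centers)`` with features of shape
    (n_bins, n_epochs, n_channels).  A bin is the closed interval of
    ``bin_width`` seconds centered on a sample (13 samples for 60 ms at
    200 Hz), so the bin with center c covers exactly [c - 0.03, c + 0.03] s
    at the default width.  Width and step are snapped to the sample grid
    with a warning when they are not multiples of ``1/fs``.
    """
    fs = epochs.fs
    width = int(round(bin_width * fs)) + 1  # closed interval, both ends included
    step = int(round(bin_step * fs))
    for name, req, got in (("bin_width", bin_width, (width - 1) / fs),
                           ("bin_step", bin_step, step / fs)):
        if abs(req - got) > 1e-9:
            warnings.warn(f"{name}={req} s snapped to the sample grid ({got} s)")
    if width < 1 or width > epochs.times.size:
        raise ValueError("bin width must fit inside the epoch")
    if step < 1:
        raise ValueError("bin step below one sample")
    n_bins = (epochs.times.size - width) // step + 1
    starts = np.arange(n_bins) * step
    csum = np.concatenate(
        [np.zeros(epochs.data.shape[:2] + (1,)), np.cumsum(epochs.data, axis=-1)], axis=-1
    )
    feats = (csum[..., starts + width] - csum[..., starts]) / width  # (ep, ch, bins)
    centers = (epochs.times[starts] + epochs.times[starts + width - 1]) / 2
    return np.moveaxis(feats, -1, 0), centers


def make_pseudo_trials(
    features: np.ndarray,
    labels: np.ndarray,
    group_size: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Average random disjoint groups of same-class observations.

    ``features`` has observations on its second-to-last axis when 3-D
    (bins, observations, channels) or its first axis when 2-D.  Within each
    class, a fresh random partition into groups of ``group_size`` is drawn;
    leftovers smaller than a full group are discarded.
    """
    labels = np.asarray(labels)
    obs_axis = 0 if features.ndim == 2 else 1
    out_feats, out_labels = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < group_size:
            raise ValueError(
                f"class {cls!r} has {idx.size} observations, fewer than the "
                f"pseudo-trial size {group_size}"
            )
        perm = rng.permutation(idx)
        n_groups = idx.size // group_size
        grouped = perm[: n_groups * group_size].reshape(n_groups, group_size)
        for g in grouped:
            out_feats.append(np.take(features, g, axis=obs_axis).mean(axis=obs_axis))
            out_labels.append(cls)
    stacked = np.stack(out_feats, axis=obs_axis)
    return stacked, np.asarray(out_labels)


def fit_lda(X: np.ndarray, y: np.ndarray, reg_lambda: float = 0.1) -> LdaModel:
    """Shrinkage-regularized linear discriminant for two classes.

    Pooled within-class covariance S (denominator n-2) is shrunk as
    S' = (1 - l) S + l (tr S / d) I; weights solve S' w = mu1 - mu0 and the
    bias centers the decision boundary between the class means.  With l = 0
    a singular S raises rather than silently pseudo-inverting.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("fit_lda needs exactly two classes")
    X0, X1 = X[y == classes[0]], X[y == classes[1]]
    if len(X0) < 2 or len(X1) < 2:
        raise ValueError("need at least 2 observations per class")
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n, d = X.shape
    scatter = (X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)
    cov = scatter / (n - 2)
    lam = reg_lambda
    shrunk = (1 - lam) * cov + lam * (np.trace(cov) / d) * np.eye(d)
    try:
        weights = np.linalg.solve(shrunk, mu1 - mu0)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; use reg_lambda > 0"
        ) from err
    if lam == 0 and not np.all(np.isfinite(weights)):
        raise np.linalg.LinAlgError("pooled covariance is singular; use reg_lambda > 0")
    bias = float(-weights @ (mu0 + mu1) / 2)
    return LdaModel(weights=weights, bias=bias, means=np.stack([mu0, mu1]), covariance=shrunk)


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC area via the rank (Mann-Whitney) formulation; ties get half credit."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("compute_auc needs scores from both classes")
    pos = labels == classes[1]
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2
    return float(u / (n0 * n1))


def forward_model(model: LdaModel, X: np.ndarray) -> np.ndarray:
    """Topography of the decoded signal: corr(discriminant component, channel).

    Per channel, the Pearson correlation across observations between
    ``X @ weights`` and that channel's activity.  Zero-variance channels map
    to 0 with a warning instead of NaN.
    """
    X = np.asarray(X, float)
    s = X @ model.weights
    s_c = s - s.mean()
    s_norm = np.linalg.norm(s_c)
    Xc = X - X.mean(axis=0)
    ch_norm = np.linalg.norm(Xc, axis=0)
    dead = ch_norm == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance channel(s) mapped to 0")
    if s_norm == 0:
        warnings.warn("discriminant component has zero variance; topography set to 0")
        return np.zeros(X.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc.T @ s_c) / (ch_norm * s_norm)
    corr[dead] = 0.0
    return corr


def _fit_lda_batch(
    X: np.ndarray, y: np.ndarray, reg_lambda: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`fit_lda` over the leading (bins) axis.

    ``X`` is (bins, observations, channels); returns per-bin weights
    (bins, channels) and biases (bins,).  Agrees with :func:`fit_lda`
    applied bin by bin to machine precision.
    """
    pos = y == np.unique(y)[1]
    X0, X1 = X[:, ~pos, :], X[:, pos, :]
    n, d = X.shape[1], X.shape[2]
    mu0, mu1 = X0.mean(axis=1), X1.mean(axis=1)
    r0 = X0 - mu0[:, None, :]
    r1 = X1 - mu1[:, None, :]
    cov = (np.einsum("boc,bod->bcd", r0, r0) + np.einsum("boc,bod->bcd", r1, r1)) / (n - 2)
    lam = reg_lambda
    tr = np.trace(cov, axis1=1, axis2=2) / d
    shrunk = (1 - lam) * cov + (lam * tr)[:, None, None] * np.eye(d)
    try:
        weights = np.linalg.solve(shrunk, (mu1 - mu0)[..., None])[..., 0]
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; use reg_lambda > 0"
        ) from err
    bias = -0.5 * np.einsum("bc,bc->b", weights, mu0 + mu1)
    return weights, bias


def _forward_model_batch(X: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Vectorized forward model: (bins, obs, ch) x (bins, ch) -> (ch, bins)."""
    s = np.einsum("boc,bc->bo", X, weights)
    s_c = s - s.mean(axis=1, keepdims=True)
    Xc = X - X.mean(axis=1, keepdims=True)
    num = np.einsum("bo,boc->bc", s_c, Xc)
    denom = np.linalg.norm(Xc, axis=1) * np.linalg.norm(s_c, axis=1)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / np.where(denom == 0, 1, denom), 0.0)
    return corr.T


def _auc_rows(scores: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Rank-based AUC per row of (bins, observations) decision values."""
    ranks = rankdata(scores, axis=1)
    n1 = int(pos.sum())
    n0 = pos.size - n1
    u = ranks[:, pos].sum(axis=1) - n1 * (n1 + 1) / 2
    return u / (n0 * n1)


def _check_compatible(*datasets: EpochedDataset) -> None:
    ref = datasets[0]
    for d in datasets[1:]:
        if d.data.shape[1] != ref.data.shape[1] or d.fs != ref.fs \
                or d.times.size != ref.times.size:
            raise ValueError("datasets must share channels, sampling rate and time axis")


def _stratified_folds(
    n_by_class: tuple[int, int], n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Fold assignment over concatenated [class0, class1] pseudo-trials."""
    fold_sets: list[list[int]] = [[] for _ in range(n_folds)]
    offset = 0
    for n in n_by_class:
        perm = rng.permutation(n) + offset
        for f, chunk in enumerate(np.array_split(perm, n_folds)):
            fold_sets[f].extend(chunk.tolist())
        offset += n
    return [np.asarray(sorted(f), dtype=int) for f in fold_sets]


def decode_timecourse(
    epochs_a: EpochedDataset,
    epochs_b: EpochedDataset,
    config: DecodingConfig | None = None,
) -> DecodingCurve:
    """Cross-validated sliding-window AUC for discriminating two conditions.

    Per repeat: both conditions are subsampled without replacement to
    ``floor(subsample_fraction * min(nA, nB))`` epochs, pseudo-trials are
    formed fresh, and stratified k-fold CV is run per bin with the test
    folds' decision values pooled into one AUC.  AUC and forward models are
    averaged over repeats (condition A is the positive class).
    """
    config = config or DecodingConfig()
    _check_compatible(epochs_a, epochs_b)
    rng = np.random.default_rng(config.rng_seed)

    feats_a, centers = bin_epochs(epochs_a, config.bin_width, config.bin_step)
    feats_b, _ = bin_epochs(epochs_b, config.bin_width, config.bin_step)
    n_a, n_b = epochs_a.n_epochs, epochs_b.n_epochs
    n_sub = int(np.floor(config.subsample_fraction * min(n_a, n_b)))
    n_pseudo = n_sub // config.pseudo_trial_size
    if n_pseudo < config.n_folds:
        raise ValueError(
            f"{n_pseudo} pseudo-trials per class from {n_sub} subsampled epochs "
            f"cannot fill {config.n_folds} folds; lower pseudo_trial_size or "
            "n_folds, or provide more epochs"
        )

    n_bins, n_ch = centers.size, epochs_a.n_channels
    auc = np.zeros(n_bins)
    fwd = np.zeros((n_ch, n_bins)) if config.compute_forward else None
    labels = np.concatenate([np.ones(n_pseudo), np.zeros(n_pseudo)])

    for _ in range(config.n_repeats):
        sel_a = rng.choice(n_a, n_sub, replace=False)
        sel_b = rng.choice(n_b, n_sub, replace=False)
        pa, _ = make_pseudo_trials(feats_a[:, sel_a, :], np.zeros(n_sub),
                                   config.pseudo_trial_size, rng)
        pb, _ = make_pseudo_trials(feats_b[:, sel_b, :], np.zeros(n_sub),
                                   config.pseudo_trial_size, rng)
        X = np.concatenate([pa, pb], axis=1)  # (bins, 2*n_pseudo, ch)
        folds = _stratified_folds((n_pseudo, n_pseudo), config.n_folds, rng)
        scores = np.empty((n_bins, 2 * n_pseudo))
        for test_idx in folds:
            train = np.ones(2 * n_pseudo, bool)
            train[test_idx] = False
            W, bias = _fit_lda_batch(X[:, train, :], labels[train], config.reg_lambda)
            scores[:, test_idx] = (
                np.einsum("boc,bc->bo", X[:, test_idx, :], W) + bias[:, None]
            )
            if fwd is not None:
                fwd += _forward_model_batch(X[:, train, :], W)
        auc += _auc_rows(scores, labels == 1)

    auc /= config.n_repeats
    if fwd is not None:
        fwd /= config.n_repeats * config.n_folds
    return DecodingCurve(
        participant=epochs_a.participant, bin_centers=centers, auc=auc,
        forward_model=fwd,
        meta={"n_epochs": (n_a, n_b), "n_pseudo": n_pseudo,
              "conditions": (epochs_a.condition, epochs_b.condition)},
    )


def cross_classify(
    train_a: EpochedDataset,
    train_b: EpochedDataset,
    test_c: EpochedDataset,
    test_d: EpochedDataset,
    config: DecodingConfig | None = None,
) -> DecodingCurve:
    """Train on one contrast (A vs B), test AUC on another (C vs D), per bin.

    The first dataset of each pair is the positive class.  A condition that
    appears on both the train and the test side (same participant and
    condition label, e.g. Illusion in (Illusion vs Incongruent) ->
    (Illusion vs Real)) is split 50/50 at the epoch level, disjointly, fresh
    each repeat.  Both directions (contrast roles swapped) are run and the
    per-bin AUC averaged over directions and repeats.  A dataset appearing
    twice on the same side is an overlap error.
    """
    config = config or DecodingConfig()
    _check_compatible(train_a, train_b, test_c, test_d)
    rng = np.random.default_rng(config.rng_seed)

    def _key(ds: EpochedDataset) -> tuple[str, str]:
        return (str(ds.participant), ds.condition)

    for pair in ((train_a, train_b), (test_c, test_d)):
        if _key(pair[0]) == _key(pair[1]):
            raise ValueError(
                "the two classes of one contrast overlap in the same condition; "
                "train/test trials of a shared condition must be disjoint"
            )

    binned: dict[int, np.ndarray] = {}
    centers = None
    for ds in (train_a, train_b, test_c, test_d):
        if id(ds) not in binned:
            feats, centers = bin_epochs(ds, config.bin_width, config.bin_step)
            binned[id(ds)] = feats

    shared_train_test = {
        (i, j)
        for i, tr in enumerate((train_a, train_b))
        for j, te in enumerate((test_c, test_d))
        if tr is te or _key(tr) == _key(te)
    }

    n_bins = centers.size
    auc = np.zeros(n_bins)
    g = config.pseudo_trial_size

    def _one_direction(
        tr_pair: tuple[EpochedDataset, EpochedDataset],
        te_pair: tuple[EpochedDataset, EpochedDataset],
        shared: set[tuple[int, int]],
    ) -> np.ndarray:
        # split shared datasets into disjoint train/test halves
        tr_idx = [np.arange(d.n_epochs) for d in tr_pair]
        te_idx = [np.arange(d.n_epochs) for d in te_pair]
        for i, j in shared:
            n = tr_pair[i].n_epochs
            perm = rng.permutation(n)
            tr_idx[i] = perm[: n // 2]
            te_idx[j] = perm[n // 2 :]
        n_tr = min(len(ix) for ix in tr_idx)
        n_te = min(len(ix) for ix in te_idx)
        tr_idx = [rng.choice(ix, n_tr, replace=False) for ix in tr_idx]
        te_idx = [rng.choice(ix, n_te, replace=False) for ix in te_idx]
        if n_tr // g < 2 or n_te // g < 2:
            raise ValueError("too few epochs per class for cross-classification")

        tr_feats = [binned[id(d)][:, ix, :] for d, ix in zip(tr_pair, tr_idx)]
        te_feats = [binned[id(d)][:, ix, :] for d, ix in zip(te_pair, te_idx)]
        ptr = [make_pseudo_trials(f, np.zeros(f.shape[1]), g, rng)[0] for f in tr_feats]
        pte = [make_pseudo_trials(f, np.zeros(f.shape[1]), g, rng)[0] for f in te_feats]
        Xtr = np.concatenate(ptr, axis=1)
        ytr = np.concatenate([np.ones(ptr[0].shape[1]), np.zeros(ptr[1].shape[1])])
        Xte = np.concatenate(pte, axis=1)
        yte = np.concatenate([np.ones(pte[0].shape[1]), np.zeros(pte[1].shape[1])])
        W, bias = _fit_lda_batch(Xtr, ytr, config.reg_lambda)
        scores = np.einsum("boc,bc->bo", Xte, W) + bias[:, None]
        return _auc_rows(scores, yte == 1)

    reverse_shared = {(j, i) for i, j in shared_train_test}
    for _ in range(config.n_repeats):
        auc += _one_direction((train_a, train_b), (test_c, test_d), shared_train_test)
        auc += _one_direction((test_c, test_d), (train_a, train_b), reverse_shared)
    auc /= 2 * config.n_repeats
    return DecodingCurve(
        participant=train_a.participant, bin_centers=centers, auc=auc,
        meta={"train": (train_a.condition, train_b.condition),
              "test": (test_c.condition, test_d.condition)},
    )
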