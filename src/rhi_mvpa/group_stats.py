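"""Group-level nonparametric inference on decoding time courses.

The decoding null hypothesis is chance performance: per participant the
effect is the chance-corrected AUC (AUC - 0.5) per time bin.  Inference is
a sign-flip cluster-based permutation test: each of 5000 randomizations
flips the sign of whole participant time courses, the cluster-forming
threshold is the 99th percentile of all randomized group means (pooled over
bins and randomizations), candidate clusters are runs of at least 3
consecutive supra-threshold bins, the cluster statistic is the summed
chance-corrected group-mean AUC, and family-wise valid p-values come from
the maximum-cluster-statistic null distribution with the add-one convention
p = (1 + exceedances) / (1 + n_randomizations).  The test is one-sided
toward above-chance decoding.

Also here: the Wilcoxon signed-rank test with rank-biserial effect size,
Benjamini-Hochberg FDR correction, and a between-participant correlation
cluster test (per-bin Pearson r against a covariate, first-level p < 0.01,
null by shuffling the covariate's participant assignment).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class ClusterTestConfig:
    """Randomization-test settings (defaults = the study's)."""

    n_randomizations: int = 5000
    cluster_alpha: float = 99.0  # percentile of the randomization distribution
    min_cluster_bins: int = 3
    chance_level: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_randomizations < 1:
            raise ValueError("need at least one randomization")
        if self.min_cluster_bins < 1:
            raise ValueError("min_cluster_bins must be >= 1")


@dataclass
class Cluster:
    start_s: float
    end_s: float
    stat_sum: float  # summed chance-corrected group-mean statistic
    p_value: float
    bins: tuple[int, int] = (0, 0)  # [first, last] bin index, inclusive


@dataclass
class ClusterResult:
    clusters: list[Cluster] = field(default_factory=list)
    threshold_used: float = np.nan
    max_stat: float = np.nan  # max group-mean AUC (or correlation)
    time_of_max: float = np.nan

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < 0.05]


@dataclass
class PairedTestResult:
    statistic_z: float
    p_value: float
    r_rb: float
    n: int
    p_corrected: float | None = None


def _runs_above(x: np.ndarray, threshold: float, min_bins: int) -> list[tuple[int, int]]:
    """Start/end (inclusive) indices of runs of >= min_bins supra-threshold bins."""
    above = np.concatenate([[False], x > threshold, [False]])
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts, ends = edges[::2], edges[1::2] - 1
    return [(s, e) for s, e in zip(starts, ends) if e - s + 1 >= min_bins]


def _max_cluster_stat(rows: np.ndarray, threshold: float, min_bins: int) -> np.ndarray:
    """Per row, the largest summed statistic over supra-threshold runs (0 if none)."""
    out = np.zeros(rows.shape[0])
    for i, row in enumerate(rows):
        runs = _runs_above(row, threshold, min_bins)
        if runs:
            out[i] = max(row[s : e + 1].sum() for s, e in runs)
    return out


def signflip_cluster_test(
    auc_matrix: np.ndarray,
    bin_centers: np.ndarray,
    config: ClusterTestConfig | None = None,
) -> ClusterResult:
    """Sign-flip cluster permutation test on participants x bins AUC values.

    Effects are chance-corrected (AUC - chance_level); each randomization
    flips each participant's whole time course independently.  See the
    module docstring for the full recipe.
    """
    config = config or ClusterTestConfig()
    auc_matrix = np.asarray(auc_matrix, float)
    if auc_matrix.ndim != 2 or auc_matrix.shape[0] < 2:
        raise ValueError("need a participants x bins matrix with >= 2 participants")
    bin_centers = np.asarray(bin_centers, float)
    n_part, n_bins = auc_matrix.shape
    if n_bins != bin_centers.size:
        raise ValueError("bin_centers length does not match the AUC matrix")
    if n_bins < config.min_cluster_bins:
        logger.warning("fewer bins than min_cluster_bins; no cluster can form")

    effects = auc_matrix - config.chance_level
    observed = effects.mean(axis=0)
    rng = np.random.default_rng(config.rng_seed)
    signs = rng.choice([-1.0, 1.0], size=(config.n_randomizations, n_part))
    rand_means = signs @ effects / n_part
    threshold = float(np.percentile(rand_means, config.cluster_alpha))
    null_max = _max_cluster_stat(rand_means, threshold, config.min_cluster_bins)

    clusters = []
    for s, e in _runs_above(observed, threshold, config.min_cluster_bins):
        stat = float(observed[s : e + 1].sum())
        p = float((1 + (null_max >= stat).sum()) / (1 + config.n_randomizations))
        clusters.append(
            Cluster(start_s=float(bin_centers[s]), end_s=float(bin_centers[e]),
                    stat_sum=stat, p_value=p, bins=(int(s), int(e)))
        )
    i_max = int(np.argmax(observed))
    return ClusterResult(
        clusters=clusters,
        threshold_used=threshold,
        max_stat=float(observed[i_max] + config.chance_level),
        time_of_max=float(bin_centers[i_max]),
    )


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test with rank-biserial effect size.

    Zero differences are dropped.  For n <= 12 retained pairs without ties
    among |differences| the p-value is an exact enumeration over all sign
    assignments; otherwise the normal approximation with tie-corrected
    variance and continuity correction is used.  The reported Z is the
    (signed) normal-approximation statistic; r_rb = (W+ - W-)/(W+ + W-).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    if n < 5:
        raise ValueError("need at least 5 nonzero paired differences")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    total = n * (n + 1) / 2
    r_rb = (w_plus - w_minus) / total

    mean = total / 2
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24 - (tie_counts**3 - tie_counts).sum() / 48
    z = (w_plus - mean) / math.sqrt(var)

    has_ties = np.unique(np.abs(d)).size < n
    if n <= 12 and not has_ties:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        cc = 0.5 * np.sign(w_plus - mean)
        z_cc = (w_plus - mean - cc) / math.sqrt(var) if var > 0 else 0.0
        p = float(2 * stats.norm.sf(abs(z_cc)))
    return PairedTestResult(statistic_z=float(z), p_value=min(1.0, p),
                            r_rb=float(r_rb), n=n)


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p over all 2^n sign assignments of the ranks."""
    # enumerate all sign assignments (n <= 12 -> at most 4096)
    w_all = np.zeros(1)
    for r in ranks:
        w_all = np.concatenate([w_all, w_all + r])
    total = w_all.size
    p_ge = (w_all >= w_plus - 1e-12).sum() / total
    p_le = (w_all <= w_plus + 1e-12).sum() / total
    return min(1.0, 2 * min(p_ge, p_le))


def rank_biserial(x: np.ndarray, y: np.ndarray) -> float:
    """Matched-pairs rank-biserial correlation, (W+ - W-)/(W+ + W-)."""
    return wilcoxon_signed_rank(x, y).r_rb


def benjamini_hochberg(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(reject, p_adjusted)``; adjusted p-values are monotone.
    Empty input yields empty output.
    """
    p_values = np.asarray(p_values, float)
    if p_values.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p_values, alpha=q, method="fdr_bh")
    return reject, p_adj


def correlation_cluster_test(
    auc_matrix: np.ndarray,
    covariate: np.ndarray,
    bin_centers: np.ndarray,
    config: ClusterTestConfig | None = None,
    first_level_p: float = 0.01,
) -> ClusterResult:
    """Cluster test on the between-participant correlation of AUC and a covariate.

    Per bin, the Pearson r across participants between decoding performance
    and the covariate; bins with |r| above the two-sided parametric
    first-level threshold (p < 0.01, df = n - 2) form candidate clusters of
    either sign (>= min_cluster_bins consecutive bins); the cluster
    statistic is the summed r.  The null shuffles the covariate's
    participant assignment; family-wise p-values use the maximum |cluster
    statistic| distribution with the add-one convention.
    """
    config = config or ClusterTestConfig()
    auc_matrix = np.asarray(auc_matrix, float)
    covariate = np.asarray(covariate, float)
    n_part, n_bins = auc_matrix.shape
    if covariate.size != n_part:
        raise ValueError("covariate length must equal the number of participants")
    if n_part < 4:
        raise ValueError("need at least 4 participants")
    if covariate.std() == 0:
        raise ValueError("covariate has zero variance")
    bin_centers = np.asarray(bin_centers, float)

    def _corr(cov: np.ndarray) -> np.ndarray:
        cov_c = cov - cov.mean()
        A = auc_matrix - auc_matrix.mean(axis=0)
        denom = np.linalg.norm(A, axis=0) * np.linalg.norm(cov_c)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (cov_c @ A) / denom
        return np.nan_to_num(r)

    observed = _corr(covariate)
    t_crit = stats.t.ppf(1 - first_level_p / 2, df=n_part - 2)
    r_crit = t_crit / math.sqrt(n_part - 2 + t_crit**2)

    rng = np.random.default_rng(config.rng_seed)
    null_max = np.zeros(config.n_randomizations)
    for i in range(config.n_randomizations):
        r = _corr(covariate[rng.permutation(n_part)])
        pos = _max_cluster_stat(r[None, :], r_crit, config.min_cluster_bins)[0]
        neg = _max_cluster_stat(-r[None, :], r_crit, config.min_cluster_bins)[0]
        null_max[i] = max(pos, neg)

    clusters = []
    for sign in (1.0, -1.0):
        for s, e in _runs_above(sign * observed, r_crit, config.min_cluster_bins):
            stat = float(observed[s : e + 1].sum())
            p = float((1 + (null_max >= abs(stat)).sum()) / (1 + config.n_randomizations))
            clusters.append(
                Cluster(start_s=float(bin_centers[s]), end_s=float(bin_centers[e]),
                        stat_sum=stat, p_value=p, bins=(int(s), int(e)))
            )
    clusters.sort(key=lambda c: c.start_s)
    i_max = int(np.argmax(np.abs(observed)))
    return ClusterResult(
        clusters=clusters, threshold_used=float(r_crit),
        max_stat=float(observed[i_max]), time_of_max=float(bin_centers[i_max]),
    )
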