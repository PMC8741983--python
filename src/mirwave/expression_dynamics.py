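"""Expression normalization, time-point structure and fuzzy clustering.

Counts are normalized by the median-of-ratios method (per-sample size
factor = median, over features nonzero in all samples, of the ratio of
the count to the feature's geometric mean).  Features are called
expressed when their per-time-point mean normalized count reaches a
threshold (default 10) in at least one time-point.  Time-point structure
is summarized by all-versus-all Spearman correlations; z-scored
time-point profiles are grouped by fuzzy c-means (Bezdek alternating
optimization, fuzzifier m = 2) with the number of clusters chosen by the
elbow method (maximal second difference of the log objective curve), and
cluster composition (novel vs conserved members) is tested against the
population ratio with chi-squared statistics (df = 1, no continuity
correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist


def normalize_median_of_ratios(counts: pd.DataFrame) -> Tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios normalization; returns (normalized, size_factors)."""
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no feature has nonzero counts in every sample; "
            "median-of-ratios size factors are undefined"
        )
    ref = mat[all_nonzero]
    log_geo_mean = np.log(ref).mean(axis=1)
    log_ratios = np.log(ref) - log_geo_mean[:, None]
    size_factors = np.exp(np.median(log_ratios, axis=0))
    normalized = counts / size_factors
    return normalized, pd.Series(size_factors, index=counts.columns, name="size_factor")


def timepoint_means(
    normalized: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Average normalized counts over replicates within each time-point."""
    tp_of = dict(zip(samples["sample_id"], samples["time_point"]))
    groups = normalized.T.groupby(normalized.columns.map(tp_of))
    return groups.mean().T


def expressed_filter(
    normalized: pd.DataFrame, samples: pd.DataFrame, threshold: float = 10.0
) -> pd.Index:
    """Features whose time-point mean reaches ``threshold`` at least once."""
    means = timepoint_means(normalized, samples)
    return means.index[(means >= threshold).any(axis=1)]


def timepoint_correlation(
    normalized: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """All-versus-all Spearman correlation between time-point profiles."""
    means = timepoint_means(normalized, samples)
    tps = list(means.columns)
    n = len(tps)
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            a, b = means.iloc[:, i], means.iloc[:, j]
            if a.nunique() < 2 or b.nunique() < 2:
                r = 1.0 if i == j else np.nan
            else:
                r = stats.spearmanr(a, b).statistic
            out[i, j] = out[j, i] = r
    np.fill_diagonal(out, 1.0)
    return pd.DataFrame(out, index=tps, columns=tps)


def zscore_profiles(
    normalized: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Per-feature z-scores of time-point mean profiles (constant rows -> 0)."""
    means = timepoint_means(normalized, samples)
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=0)
    z = (means.sub(mu, axis=0)).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


@dataclass
class ClusterAssignment:
    memberships: pd.DataFrame        # features x clusters, rows sum to 1
    hard_labels: pd.Series           # argmax cluster per feature
    high_confidence: pd.Series       # max membership >= membership_cutoff
    centers: pd.DataFrame            # clusters x time-points
    objective_path: np.ndarray       # objective value per iteration
    n_iter: int


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    k: int,
    fuzzifier: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    rng_seed: int = 0,
    membership_cutoff: float = 0.6,
    n_init: int = 5,
) -> ClusterAssignment:
    """Bezdek fuzzy c-means on z-score profiles.

    Memberships are initialized uniformly at random; of ``n_init``
    seeded restarts the run with the lowest final objective is kept
    (the alternating optimization only finds local optima).  Centers and
    memberships alternate until the largest membership change falls
    below ``tol``.  A feature exactly at a center receives membership 1
    for that center (limit convention).
    """
    best = None
    for restart in range(n_init):
        result = _fuzzy_cmeans_once(profiles, k, fuzzifier, tol, max_iter,
                                    (rng_seed, restart), membership_cutoff)
        if best is None or result.objective_path[-1] < best.objective_path[-1]:
            best = result
    return best


def _fuzzy_cmeans_once(
    profiles: pd.DataFrame,
    k: int,
    fuzzifier: float,
    tol: float,
    max_iter: int,
    rng_seed,
    membership_cutoff: float,
) -> ClusterAssignment:
    X = profiles.to_numpy(dtype=float)
    n, _ = X.shape
    if k < 2:
        raise ValueError("k must be >= 2")
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must be > 1")
    if n < k:
        raise ValueError("need at least k features")
    rng = np.random.default_rng(rng_seed)
    U = rng.random((n, k))
    U /= U.sum(axis=1, keepdims=True)
    objective_path = []
    for iteration in range(1, max_iter + 1):
        W = U ** fuzzifier
        centers = (W.T @ X) / W.sum(axis=0)[:, None]
        d2 = cdist(X, centers, metric="sqeuclidean")
        zero = d2 <= 1e-300
        with np.errstate(divide="ignore"):
            # u_ij proportional to d_ij^{-2/(m-1)} with d2 = d^2
            inv = np.where(zero, np.inf, d2 ** (-1.0 / (fuzzifier - 1.0)))
        U_new = inv / inv.sum(axis=1, keepdims=True)
        rows_zero = zero.any(axis=1)
        if rows_zero.any():
            U_new[rows_zero] = 0.0
            U_new[rows_zero, np.argmax(zero[rows_zero], axis=1)] = 1.0
        objective_path.append(float(((U_new ** fuzzifier) * d2).sum()))
        delta = np.abs(U_new - U).max()
        U = U_new
        if delta < tol:
            break
    memberships = pd.DataFrame(
        U, index=profiles.index, columns=[f"cluster{c + 1}" for c in range(k)]
    )
    hard = memberships.idxmax(axis=1)
    high = memberships.max(axis=1) >= membership_cutoff
    centers_df = pd.DataFrame(centers, index=memberships.columns, columns=profiles.columns)
    return ClusterAssignment(
        memberships, hard, high, centers_df, np.array(objective_path), iteration
    )


@dataclass
class ElbowResult:
    k: int
    k_range: Sequence[int]
    objectives: np.ndarray
    flagged: bool  # True when no positive curvature exists (no clear elbow)


def elbow_select_k(
    profiles: pd.DataFrame,
    k_range: Sequence[int] = range(2, 11),
    rng_seed: int = 0,
    **cmeans_kwargs,
) -> ElbowResult:
    """Choose k by the elbow rule.

    The fuzzy c-means objective is computed for each k and the selected k
    maximizes the second difference of the *log* objective curve, i.e.
    the point where the relative improvement from adding a cluster
    collapses.  (Absolute second differences systematically prefer the
    smallest k whenever cluster separations are hierarchical, because
    the first split removes the most variance.)  When the curve has no
    positive curvature the smallest k is returned, flagged.
    """
    ks = [k for k in k_range if k <= len(profiles)]
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 feasible values")
    objectives = np.array([
        fuzzy_cmeans(profiles, k, rng_seed=rng_seed, **cmeans_kwargs).objective_path[-1]
        for k in ks
    ])
    k_sel, flagged = select_elbow_from_curve(ks, objectives)
    return ElbowResult(k_sel, ks, objectives, flagged)


def select_elbow_from_curve(ks: Sequence[int], objectives: np.ndarray) -> Tuple[int, bool]:
    """Elbow rule on a precomputed objective curve; see elbow_select_k."""
    log_obj = np.log(np.maximum(np.asarray(objectives, dtype=float), 1e-300))
    second_diff = log_obj[:-2] - 2 * log_obj[1:-1] + log_obj[2:]
    if (second_diff > 1e-12).any():
        return ks[1 + int(np.argmax(second_diff))], False
    return ks[0], True


def composition_test(
    assignment: ClusterAssignment,
    conservation: pd.Series,
    population_ratio: float,
) -> pd.DataFrame:
    """Chi-squared test of novel/conserved composition per cluster.

    ``population_ratio`` is the novel fraction in the expressed
    population; expected counts per cluster of size N are (N*p, N*(1-p));
    df = 1, no continuity correction.  A warning flag marks clusters with
    an expected cell below 1.
    """
    if not 0.0 < population_ratio < 1.0:
        raise ValueError("population_ratio must be in (0, 1)")
    rows = []
    for cluster, members in assignment.hard_labels.groupby(assignment.hard_labels):
        ids = members.index
        n = len(ids)
        obs_novel = int((conservation.loc[ids] == "novel").sum())
        obs_cons = n - obs_novel
        exp_novel = n * population_ratio
        exp_cons = n * (1.0 - population_ratio)
        x2 = (obs_novel - exp_novel) ** 2 / exp_novel + (obs_cons - exp_cons) ** 2 / exp_cons
        rows.append(
            dict(cluster=cluster, n=n, observed_novel=obs_novel,
                 observed_conserved=obs_cons, expected_novel=exp_novel,
                 expected_conserved=exp_cons, chi2=x2,
                 pvalue=float(stats.chi2.sf(x2, df=1)),
                 low_expected_warning=min(exp_novel, exp_cons) < 1.0)
        )
    return pd.DataFrame(rows)


def pca_coordinates(normalized: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Sample coordinates on the leading principal components (log scale)."""
    X = np.log1p(normalized.to_numpy(dtype=float)).T
    X = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    coords = X @ vt[:n_components].T
    return pd.DataFrame(coords, index=normalized.columns,
                        columns=[f"PC{i + 1}" for i in range(n_components)])
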