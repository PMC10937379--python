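"""De novo signature discovery: regularization tuning, replicate filtering and
clustering, and automatic selection of the number of signatures.

The discovery protocol for a fixed rank r is: tune the dimensionless
regularization weight once, run mvNMF many times from different random
initializations, discard badly converged replicates, pool the resulting
signature columns and cluster them. Whether r matches the data is judged by
letting the gap statistic pick the number of clusters k among the pooled
signatures: at the true r replicates keep finding the same r signatures
(k = r, tight clusters); at over-specified r replicates disagree (k != r
and/or poor silhouettes). The largest r with k = r and adequate silhouettes
is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import nnls as _scipy_nnls
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import silhouette_samples

from .matrices import l1_normalize_columns
from .nmf import FactorizationResult, mvnmf
from .stats import significantly_worse
from .utils import derive_seed

DEFAULT_LAMBDA_GRID = tuple(float(10.0**k) for k in range(-10, 1)) + (2.0,)


@dataclass
class LambdaSelection:
    """Result of tuning the dimensionless regularization weight."""

    grid: tuple[float, ...]
    sample_errors: dict[float, np.ndarray]
    pvalues: dict[float, tuple[float, float]]  # (Mann-Whitney, tail test)
    chosen: float
    warning: str | None = None


def select_lambda_tilde(
    X,
    r: int,
    grid=DEFAULT_LAMBDA_GRID,
    n_rep_per_value: int = 1,
    seed: int = 0,
    alpha: float = 0.05,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> LambdaSelection:
    """Choose the largest regularization weight that does not significantly
    hurt reconstruction.

    mvNMF is run for each grid value; sample-wise reconstruction errors are
    compared with the smallest grid value (nearly unregularized NMF) via a
    Mann-Whitney U test and a tail test. A value is significantly worse if
    either p < ``alpha``; the largest value not significantly worse wins.
    """
    grid = tuple(sorted(float(g) for g in grid))
    if len(grid) == 0:
        raise ValueError("lambda grid is empty")
    X = np.asarray(X, dtype=float)
    errors: dict[float, np.ndarray] = {}
    for lt in grid:
        errs = []
        for rep in range(n_rep_per_value):
            res = mvnmf(
                X, r, lambda_tilde=lt, seed=derive_seed(seed, "lambda", lt, rep),
                tol=tol, max_iter=max_iter,
            )
            errs.append(res.sample_errors)
        errors[lt] = np.concatenate(errs)
    warning = None
    if len(grid) == 1:
        return LambdaSelection(grid, errors, {grid[0]: (1.0, 1.0)}, grid[0],
                               "single-value grid: no reference to compare against")
    reference = errors[grid[0]]
    pvalues: dict[float, tuple[float, float]] = {grid[0]: (1.0, 1.0)}
    chosen = grid[0]
    for lt in grid[1:]:
        worse, p_mwu, p_tail = significantly_worse(errors[lt], reference, alpha)
        pvalues[lt] = (p_mwu, p_tail)
        if not worse:
            chosen = max(chosen, lt)
    return LambdaSelection(grid, errors, pvalues, chosen, warning)


def filter_solutions(results: list[FactorizationResult]) -> list[FactorizationResult]:
    """Drop replicates whose reconstruction error exceeds the median by more
    than five median absolute deviations (occasional failed convergence)."""
    if not results:
        raise ValueError("no results to filter")
    errors = np.array([res.reconstruction_error for res in results])
    med = np.median(errors)
    mad = np.median(np.abs(errors - med))
    keep = errors <= med + 5.0 * mad
    return [res for res, k in zip(results, keep) if k]


def cluster_signatures(
    spectra: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hierarchical (average-linkage, cosine-distance) clustering of pooled
    signature spectra.

    Parameters
    ----------
    spectra : (p, m) array, one spectrum per column.
    k : number of clusters.

    Returns
    -------
    means : (p, k) cluster means, re-L1-normalized, one per cluster.
    labels : (m,) cluster labels in 0..k-1, ordered by first occurrence.
    silhouettes : (m,) per-spectrum silhouette scores on cosine distance
        (all ones when k == 1, where the score is undefined).
    """
    spectra = np.asarray(spectra, dtype=float)
    m = spectra.shape[1]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > m:
        raise ValueError(f"k={k} exceeds the number of spectra ({m})")
    points = spectra.T
    if k == 1:
        labels = np.zeros(m, dtype=int)
        sil = np.ones(m)
    else:
        Z = linkage(points, method="average", metric="cosine")
        raw = fcluster(Z, t=k, criterion="maxclust")
        # relabel by first occurrence for determinism
        order: dict[int, int] = {}
        labels = np.array([order.setdefault(c, len(order)) for c in raw])
        if len(np.unique(labels)) < 2 or m == k:
            sil = np.zeros(m)
        else:
            sil = silhouette_samples(points, labels, metric="cosine")
    means = np.column_stack(
        [spectra[:, labels == c].mean(axis=1) for c in range(labels.max() + 1)]
    )
    return l1_normalize_columns(means), labels, sil


def _cluster_labels(points: np.ndarray, k: int, metric: str) -> np.ndarray:
    if k == 1:
        return np.zeros(points.shape[0], dtype=int)
    Z = linkage(points, method="average", metric=metric)
    return fcluster(Z, t=k, criterion="maxclust")


def _kmeans_dispersions(
    points: np.ndarray, k_max: int, seed: int, floor_ratio: float
) -> np.ndarray:
    """log W_k for k = 1..k_max via k-means inertia, floored relative to W_1.

    The floor treats clusters more than ~sqrt(floor_ratio) tighter than the
    overall spread as already perfect: replicate factorization runs routinely
    reproduce signatures to near machine precision, and without the floor the
    log dispersion of such degenerate clusters keeps dropping under further
    splits, defeating the standard-error rule.
    """
    w1 = float(np.sum((points - points.mean(axis=0)) ** 2))
    floor = max(w1 * floor_ratio, 1e-300)
    log_wk = np.empty(k_max)
    log_wk[0] = np.log(max(w1, 1e-300))
    with warnings.catch_warnings():
        # duplicate points legitimately yield fewer distinct clusters than k
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        for k in range(2, k_max + 1):
            km = KMeans(n_clusters=k, n_init=10, random_state=seed % (2**31)).fit(points)
            log_wk[k - 1] = np.log(max(float(km.inertia_), floor))
    return log_wk


def gap_statistic_k(
    points: np.ndarray,
    k_max: int,
    n_reference: int = 50,
    seed: int = 0,
    floor_ratio: float = 1e-3,
) -> int:
    """Pick the number of clusters by the gap statistic.

    Within-cluster dispersion W_k is the k-means objective (inertia), and the
    reference distribution is ``n_reference`` uniform draws inside the
    per-dimension bounding box of the points. Returns the smallest k with
    Gap(k) >= Gap(k+1) - s_{k+1}. Unlike silhouette-based criteria this is
    well defined at k = 1 and will return 1 when the points have no subset
    structure. ``floor_ratio`` bounds W_k from below relative to W_1 so that
    numerically identical replicate clusters register as perfect rather than
    endlessly improvable (see :func:`_kmeans_dispersions`).
    """
    points = np.asarray(points, dtype=float)
    m = points.shape[0]
    k_max = int(min(k_max, m))
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_max == 1:
        return 1
    # degenerate input: essentially coincident points form a single cluster
    centered = points - points.mean(axis=0)
    if np.sum(centered**2) <= floor_ratio * max(np.sum(points**2), 1e-300):
        return 1
    rng = np.random.default_rng(seed)
    lo, hi = points.min(axis=0), points.max(axis=0)
    log_wk = _kmeans_dispersions(points, k_max, seed, floor_ratio)
    ref_log = np.empty((n_reference, k_max))
    for b in range(n_reference):
        ref = rng.uniform(lo, hi, size=points.shape)
        ref_log[b] = _kmeans_dispersions(ref, k_max, seed + b + 1, floor_ratio)
    gap = ref_log.mean(axis=0) - log_wk
    s = ref_log.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / n_reference)
    for k in range(1, k_max):
        if gap[k - 1] >= gap[k] - s[k]:
            return k
    return k_max


class RankSelectionError(RuntimeError):
    """No candidate rank satisfied the selection criteria."""

    def __init__(self, message: str, report: "RankSelectionReport"):
        super().__init__(message)
        self.report = report


@dataclass
class RankCandidate:
    r: int
    lambda_tilde: float
    k: int
    mean_silhouette: float
    min_silhouette: float
    n_replicates_kept: int
    consensus_W: np.ndarray | None = None


@dataclass
class RankSelectionReport:
    candidates: list[RankCandidate]
    selected_r: int | None = None
    W: np.ndarray | None = None
    H: np.ndarray | None = None
    silhouettes: np.ndarray | None = None
    labels: np.ndarray | None = None
    field_notes: dict = field(default_factory=dict)


def nnls_exposures(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Column-wise nonnegative least squares of X on W."""
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    H = np.empty((W.shape[1], X.shape[1]))
    for j in range(X.shape[1]):
        H[:, j] = _scipy_nnls(W, X[:, j])[0]
    return H


def run_replicates(
    X: np.ndarray,
    r: int,
    lambda_tilde: float,
    n_rep: int,
    seed: int,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    bootstrap: bool = False,
) -> list[FactorizationResult]:
    """Run ``n_rep`` mvNMF replicates from different random initializations.

    With ``bootstrap=True`` each replicate sees a per-sample multinomial
    resampling of X (same per-sample totals).
    """
    X = np.asarray(X, dtype=float)
    results = []
    for rep in range(n_rep):
        rep_seed = derive_seed(seed, "replicate", r, rep)
        X_rep = X
        if bootstrap:
            rng = np.random.default_rng(derive_seed(seed, "bootstrap", r, rep))
            X_rep = np.empty_like(X)
            for j in range(X.shape[1]):
                col = X[:, j]
                total = int(round(col.sum()))
                prob = col / col.sum() if col.sum() > 0 else np.full(len(col), 1 / len(col))
                X_rep[:, j] = rng.multinomial(total, prob)
        results.append(
            mvnmf(X_rep, r, lambda_tilde=lambda_tilde, seed=rep_seed,
                  tol=tol, max_iter=max_iter)
        )
    return results


def consensus_discovery(
    X,
    r: int,
    lambda_tilde: float,
    n_rep: int = 20,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    normalize_input: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Discovery at a fixed rank and regularization weight: replicates,
    filtering, clustering into exactly r clusters, consensus = cluster means,
    exposures by NNLS. Used for validation reruns that must reproduce the
    original discovery settings.
    """
    X = np.asarray(X, dtype=float)
    X_fit = l1_normalize_columns(X) if normalize_input else X
    results = run_replicates(
        X_fit, r, lambda_tilde, n_rep, seed, tol=tol, max_iter=max_iter
    )
    kept = filter_solutions(results)
    pooled = np.column_stack([res.W for res in kept])
    W, _, _ = cluster_signatures(pooled, r)
    H = nnls_exposures(X_fit, W)
    return W, H


def select_rank(
    X,
    r_range,
    n_rep: int = 20,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    seed: int = 0,
    mean_sil_min: float = 0.7,
    min_sil_min: float = 0.2,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    bootstrap: bool = False,
    normalize_input: bool = True,
    lambda_tilde: float | None = None,
    gap_n_reference: int = 50,
) -> RankSelectionReport:
    """Automatic selection of the number of signatures.

    For each candidate r the regularization weight is tuned once, ``n_rep``
    mvNMF replicates are run and filtered, pooled signatures are clustered
    with k chosen by the gap statistic (k is allowed to differ from r), and
    silhouette scores are computed at k clusters. The largest r with k == r,
    mean silhouette >= ``mean_sil_min`` and minimum per-cluster silhouette >=
    ``min_sil_min`` is selected; the consensus signatures are the cluster
    means and the exposures are recomputed by NNLS.

    ``lambda_tilde`` may be passed to skip tuning (e.g. for validation reruns
    that must reuse the original settings).
    """
    X = np.asarray(X, dtype=float)
    X_fit = l1_normalize_columns(X) if normalize_input else X
    r_list = sorted(set(int(r) for r in r_range))
    if not r_list or r_list[0] < 1 or r_list[-1] > min(X.shape):
        raise ValueError("r_range must lie within [1, min(p, n)]")
    candidates: list[RankCandidate] = []
    details: dict[int, dict] = {}
    for r in r_list:
        if lambda_tilde is None:
            lam_sel = select_lambda_tilde(
                X_fit, r, grid=lambda_grid, seed=derive_seed(seed, "tune", r),
                tol=tol, max_iter=max_iter,
            )
            lt = lam_sel.chosen
        else:
            lt = float(lambda_tilde)
        results = run_replicates(
            X_fit, r, lt, n_rep, seed, tol=tol, max_iter=max_iter, bootstrap=bootstrap
        )
        kept = filter_solutions(results)
        pooled = np.column_stack([res.W for res in kept])
        m = pooled.shape[1]
        k_max = min(max(r + 2, 2), m)
        k = gap_statistic_k(
            pooled.T, k_max, n_reference=gap_n_reference,
            seed=derive_seed(seed, "gap", r),
        )
        means, labels, sil = cluster_signatures(pooled, k)
        per_cluster = np.array([sil[labels == c].mean() for c in range(k)])
        cand = RankCandidate(
            r=r, lambda_tilde=lt, k=k,
            mean_silhouette=float(sil.mean()),
            min_silhouette=float(per_cluster.min()),
            n_replicates_kept=len(kept),
            consensus_W=means if k == r else None,
        )
        candidates.append(cand)
        details[r] = {"labels": labels, "silhouettes": sil, "means": means}
    passing = [
        c for c in candidates
        if c.k == c.r
        and c.mean_silhouette >= mean_sil_min
        and c.min_silhouette >= min_sil_min
    ]
    report = RankSelectionReport(candidates=candidates)
    if not passing:
        raise RankSelectionError(
            "no rank in r_range satisfied k == r with adequate silhouettes; "
            "widen r_range or inspect the attached report",
            report,
        )
    best = max(passing, key=lambda c: c.r)
    W = best.consensus_W
    H = nnls_exposures(X_fit, W)
    report.selected_r = best.r
    report.W = W
    report.H = H
    report.silhouettes = details[best.r]["silhouettes"]
    report.labels = details[best.r]["labels"]
    return report
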