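"""In silico validation of signature assignments and data-driven threshold
optimization.

The idea: a good final assignment (W_s, H_s) — catalog signatures plus sparse
exposures — should, when used to re-simulate a synthetic cohort, lead de novo
discovery to the same signatures it found in the real data. Concretely,
X_simul is drawn multinomially from W_s @ H_s, discovery is rerun on X_simul
with exactly the same settings (rank r, regularization weight, replicate
count), and the discovered W_simul is compared with the original W_data via
an optimal one-to-one pairing minimizing mean cosine distance. Low mean
cosine distance means the assignment is consistent with the data;
systematic discrepancies localize to specific signatures through the
over/under-assignment profile.

The same machinery drives a grid search over the two stepwise-NNLS
thresholds (matching and refitting): the pair minimizing mean cosine distance
is the anchor candidate, pairs not significantly worse (element-wise L1
error, Mann-Whitney and tail test both p > 0.05) join the candidate set, and
the sparsest assignment (fewest signatures, then largest thresholds) wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .discovery import consensus_discovery, nnls_exposures
from .matrices import cosine_distance_matrix
from .refit import clean_matches, match_signature, refit_matrix
from .simulate import simulate_count_matrix
from .stats import mann_whitney_greater, tail_test
from .utils import derive_seed


@dataclass
class AssignmentSet:
    """Final signature assignment: catalog signatures and sparse exposures."""

    signature_ids: tuple[str, ...]
    W_s: np.ndarray  # (p, m) assigned catalog signatures
    H_s: np.ndarray  # (m, n) sparse exposures
    epsilon_match: float | None = None
    epsilon_refit: float | None = None


@dataclass
class ValidationReport:
    pairing: tuple[np.ndarray, np.ndarray]  # indices into W_data, W_simul
    pair_cosine_distances: np.ndarray
    mean_cosine_distance: float
    W_simul: np.ndarray
    H_simul: np.ndarray
    elementwise_l1: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    over_assignment: np.ndarray | None = None
    under_assignment: np.ndarray | None = None
    mismatch_warning: str | None = None


def simulate_from_assignment(W_s, H_s, seed: int = 0) -> np.ndarray:
    """Multinomial re-simulation of a cohort from an assignment (shared
    contract with :func:`sigdecon.simulate.simulate_count_matrix`)."""
    return simulate_count_matrix(W_s, H_s, seed=seed)


def pair_signatures(W_a, W_b) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """Optimal one-to-one pairing of two equal-size signature sets minimizing
    the mean cosine distance (Hungarian algorithm).

    Returns ((rows, cols), mean_distance) with rows indexing columns of W_a.
    """
    W_a = np.asarray(W_a, dtype=float)
    W_b = np.asarray(W_b, dtype=float)
    if W_a.shape[1] != W_b.shape[1]:
        raise ValueError(
            f"signature sets differ in size ({W_a.shape[1]} vs {W_b.shape[1]}); "
            "pad or truncate explicitly"
        )
    D = cosine_distance_matrix(W_a, W_b)
    rows, cols = linear_sum_assignment(D)
    return (rows, cols), float(D[rows, cols].mean())


def overassignment_profile(
    W_data, W_simul, assigned_signatures
) -> tuple[np.ndarray, np.ndarray]:
    """Localize assignment discrepancies to individual catalog signatures.

    Each paired de novo signature (data side and simulation side) is
    decomposed onto the assigned catalog signatures by plain NNLS; per catalog
    signature, positive differences (excess weight in simulation, indicating
    over-assignment) and negative differences (excess in data, indicating
    under-assignment) are summed separately over the pairs.

    ``W_data`` and ``W_simul`` must already be column-paired.
    """
    W_data = np.asarray(W_data, dtype=float)
    W_simul = np.asarray(W_simul, dtype=float)
    A = assigned_signatures.values if hasattr(assigned_signatures, "schema") else np.asarray(
        assigned_signatures, dtype=float
    )
    over = np.zeros(A.shape[1])
    under = np.zeros(A.shape[1])
    for col in range(W_data.shape[1]):
        wd = nnls_exposures(W_data[:, [col]], A)[:, 0]
        ws = nnls_exposures(W_simul[:, [col]], A)[:, 0]
        diff = ws - wd
        over += np.maximum(diff, 0.0)
        under += np.maximum(-diff, 0.0)
    return over, under


def validate_assignment(
    X_data,
    assignment: AssignmentSet,
    W_data,
    H_data,
    r: int,
    lambda_tilde: float,
    n_rep: int = 20,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    normalize_input: bool = True,
) -> ValidationReport:
    """Quantify the consistency of an assignment with the original data.

    Re-simulates X_simul from the assignment, reruns discovery with the
    original settings (same r, same regularization weight, same replicate
    count; seeds offset deterministically from ``seed``), pairs W_simul
    with W_data, and reports the mean cosine distance plus the
    over/under-assignment profile.
    """
    W_data = np.asarray(W_data, dtype=float)
    X_simul = simulate_from_assignment(
        assignment.W_s, assignment.H_s, seed=derive_seed(seed, "simulate")
    )
    W_simul, H_simul = consensus_discovery(
        X_simul, r, lambda_tilde, n_rep=n_rep,
        seed=derive_seed(seed, "rediscover"),
        tol=tol, max_iter=max_iter, normalize_input=normalize_input,
    )
    warning = None
    if W_simul.shape[1] != W_data.shape[1]:  # guard; cannot happen at fixed r
        m = min(W_simul.shape[1], W_data.shape[1])
        W_simul, W_data = W_simul[:, :m], W_data[:, :m]
        warning = "signature counts differed between data and simulation; truncated"
    (rows, cols), mean_dist = pair_signatures(W_data, W_simul)
    Wd = W_data[:, rows]
    Ws = W_simul[:, cols]
    over, under = overassignment_profile(Wd, Ws, assignment.W_s)
    return ValidationReport(
        pairing=(rows, cols),
        pair_cosine_distances=cosine_distance_matrix(Wd, Ws).diagonal().copy(),
        mean_cosine_distance=mean_dist,
        W_simul=W_simul,
        H_simul=H_simul,
        elementwise_l1=np.abs(Wd - Ws).ravel(),
        over_assignment=over,
        under_assignment=under,
        mismatch_warning=warning,
    )


def assign(
    X,
    W_data,
    catalog,
    epsilon_match: float,
    epsilon_refit: float,
    clean: bool = True,
) -> AssignmentSet:
    """Match de novo signatures to a catalog, optionally clean background
    over-fits, pool the matched set, and refit the data against it."""
    X = np.asarray(X, dtype=float)
    W_data = np.asarray(W_data, dtype=float)
    cat_vals = catalog.values if hasattr(catalog, "schema") else np.asarray(catalog, dtype=float)
    cat_ids = (
        tuple(catalog.signature_ids)
        if hasattr(catalog, "signature_ids")
        else tuple(str(j) for j in range(cat_vals.shape[1]))
    )
    matched: set[int] = set()
    for col in range(W_data.shape[1]):
        s = W_data[:, col] / W_data[:, col].sum()
        weights, _ = match_signature(s, cat_vals, epsilon_match)
        if clean:
            weights = clean_matches(weights, cat_vals, s)
        matched.update(np.flatnonzero(weights > 0).tolist())
    cols = sorted(matched)
    W_s = cat_vals[:, cols]
    # refitting always runs on raw counts: H_s must carry absolute burdens so
    # that re-simulation reproduces realistic per-sample totals
    H_s, _ = refit_matrix(X, W_s, epsilon_refit)
    return AssignmentSet(
        signature_ids=tuple(cat_ids[j] for j in cols),
        W_s=W_s,
        H_s=H_s,
        epsilon_match=epsilon_match,
        epsilon_refit=epsilon_refit,
    )


@dataclass
class ThresholdSearchResult:
    epsilon_match: float
    epsilon_refit: float
    mean_cosine_distances: dict
    n_signatures: dict
    candidates: list
    reports: dict = field(default_factory=dict)


def optimize_thresholds(
    X_data,
    W_data,
    H_data,
    catalog,
    grid_match,
    grid_refit,
    r: int,
    lambda_tilde: float,
    mode: str = "grid2d",
    n_rep: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    clean: bool = True,
    sequential_fixed_refit: float = 1e-4,
) -> ThresholdSearchResult:
    """Grid-search the matching and refitting likelihood thresholds.

    For each pair, build the assignment, validate it in silico, and record the
    mean cosine distance between W_simul and W_data plus element-wise L1
    errors. Candidates are the minimizer plus every pair whose L1 errors are
    not significantly larger (Mann-Whitney AND tail test p > ``alpha``);
    among candidates the fewest assigned signatures wins, then the largest
    thresholds. ``mode='sequential'`` optimizes the matching threshold with
    the refitting threshold pinned at ``sequential_fixed_refit`` and then the
    refitting threshold at the chosen matching value.
    """
    grid_match = sorted(float(g) for g in grid_match)
    grid_refit = sorted(float(g) for g in grid_refit)
    if not grid_match or not grid_refit:
        raise ValueError("threshold grids must be nonempty")
    if mode == "grid2d":
        pairs = [(em, er) for em in grid_match for er in grid_refit]
        return _search_pairs(
            X_data, W_data, catalog, pairs, r, lambda_tilde, n_rep, seed,
            alpha, tol, max_iter, clean,
        )
    if mode == "sequential":
        pairs1 = [(em, sequential_fixed_refit) for em in grid_match]
        stage1 = _search_pairs(
            X_data, W_data, catalog, pairs1, r, lambda_tilde, n_rep, seed,
            alpha, tol, max_iter, clean,
        )
        pairs2 = [(stage1.epsilon_match, er) for er in grid_refit]
        stage2 = _search_pairs(
            X_data, W_data, catalog, pairs2, r, lambda_tilde, n_rep, seed,
            alpha, tol, max_iter, clean,
        )
        stage2.mean_cosine_distances.update(stage1.mean_cosine_distances)
        stage2.n_signatures.update(stage1.n_signatures)
        return stage2
    raise ValueError("mode must be 'grid2d' or 'sequential'")


def _search_pairs(
    X_data, W_data, catalog, pairs, r, lambda_tilde, n_rep, seed,
    alpha, tol, max_iter, clean,
) -> ThresholdSearchResult:
    mean_dist: dict[tuple[float, float], float] = {}
    l1_errors: dict[tuple[float, float], np.ndarray] = {}
    n_sigs: dict[tuple[float, float], int] = {}
    reports: dict[tuple[float, float], ValidationReport] = {}
    for em, er in pairs:
        assignment = assign(X_data, W_data, catalog, em, er, clean=clean)
        if assignment.W_s.shape[1] == 0 or assignment.H_s.sum() == 0:
            mean_dist[(em, er)] = np.inf
            l1_errors[(em, er)] = np.array([np.inf])
            n_sigs[(em, er)] = 0
            continue
        report = validate_assignment(
            X_data, assignment, W_data, None, r, lambda_tilde,
            n_rep=n_rep, seed=derive_seed(seed, "opt", em, er),
            tol=tol, max_iter=max_iter,
        )
        mean_dist[(em, er)] = report.mean_cosine_distance
        l1_errors[(em, er)] = report.elementwise_l1
        n_sigs[(em, er)] = assignment.W_s.shape[1]
        reports[(em, er)] = report
    anchor = min(mean_dist, key=mean_dist.get)
    candidates = [anchor]
    for pair in mean_dist:
        if pair == anchor or not np.isfinite(mean_dist[pair]):
            continue
        p_mwu = mann_whitney_greater(l1_errors[pair], l1_errors[anchor])
        p_tail = tail_test(l1_errors[pair], l1_errors[anchor])
        if p_mwu > alpha and p_tail > alpha:
            candidates.append(pair)
    best = min(candidates, key=lambda pr: (n_sigs[pr], -pr[0], -pr[1]))
    return ThresholdSearchResult(
        epsilon_match=best[0],
        epsilon_refit=best[1],
        mean_cosine_distances=mean_dist,
        n_signatures=n_sigs,
        candidates=candidates,
        reports=reports,
    )
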