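"""Exposure estimation against a fixed signature set.

The workhorse is a bidirectional stepwise sparse NNLS driven by a multinomial
likelihood. A sample spectrum x (counts over p channels) fit with exposures h
against signatures W induces a composite probability vector
w = Wh / ||Wh||_1, and the multinomial log likelihood of x under w is
sum_i x_i log w_i (the combinatorial constant dropped). Dividing by the total
count gives a per-mutation log likelihood, making the stepwise threshold
epsilon independent of mutational burden — and, because the per-mutation log
likelihood equals -KL(x_hat || w) minus the entropy of x_hat, the identical
algorithm applies to matching, where x is itself a probability vector
(a de novo signature to be decomposed over a catalog).

Starting from the unrestricted NNLS solution, backward steps drop the active
signature whose removal costs the least likelihood (if the cost is below
epsilon) and forward steps add the inactive signature whose inclusion gains
the most (if the gain exceeds epsilon), alternating until a full pass changes
nothing. Using the same epsilon in both directions prevents add/remove
cycling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

LOG_FLOOR = 1e-100


def nnls(x, W, support_mask=None) -> np.ndarray:
    """Nonnegative least squares min_{h>=0} ||x - Wh||_2^2 (Lawson-Hanson).

    ``support_mask`` — optional iterable of column indices allowed to be
    nonzero; all other exposures are forced to zero.
    """
    x = np.asarray(x, dtype=float).ravel()
    W = np.asarray(W, dtype=float)
    r = W.shape[1]
    h = np.zeros(r)
    if support_mask is None:
        idx = np.arange(r)
    else:
        idx = np.asarray(sorted(set(int(i) for i in support_mask)), dtype=int)
        if idx.size == 0:
            return h
    h[idx] = _scipy_nnls(W[:, idx], x)[0]
    return h


def per_mutation_loglik(x, W, h) -> float:
    """Per-mutation multinomial log likelihood of counts x under exposures h.

    (sum_i x_i log w_i) / sum_i x_i with w = Wh / ||Wh||_1. Channels with
    x_i = 0 contribute nothing; a channel with x_i > 0 where w_i = 0 drives
    the value toward -infinity (floored at log(1e-100)). Invariant under
    positive rescaling of h.
    """
    x = np.asarray(x, dtype=float).ravel()
    h = np.asarray(h, dtype=float).ravel()
    Wh = np.asarray(W, dtype=float) @ h
    total_wh = Wh.sum()
    total_x = x.sum()
    if total_wh <= 0:
        raise ValueError("Wh is all zero; likelihood undefined")
    if total_x <= 0:
        raise ValueError("x has no mutations; likelihood undefined")
    w = Wh / total_wh
    return float(np.sum(x * np.log(np.maximum(w, LOG_FLOOR))) / total_x)


@dataclass
class RefitResult:
    """Sparse exposure fit for one sample."""

    h: np.ndarray
    support: tuple[int, ...]
    loglik: float  # per-mutation, at the final support
    step_log: list[tuple[str, int, float]] = field(default_factory=list)
    epsilon: float = 0.0
    n_passes: int = 0


def _loglik_on_support(x, W, support) -> tuple[float, np.ndarray]:
    h = nnls(x, W, support_mask=support)
    if h.sum() == 0:
        return -np.inf, h
    return per_mutation_loglik(x, W, h), h


def sparse_nnls(x, W, epsilon: float) -> RefitResult:
    """Multinomial likelihood-based bidirectional stepwise sparse NNLS.

    ``epsilon`` (> 0) is the per-mutation log-likelihood threshold used both
    for backward removal (drop if the best removal costs < epsilon) and
    forward addition (add if the best addition gains > epsilon). Ties are
    broken toward the lowest signature index.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    x = np.asarray(x, dtype=float).ravel()
    W = np.asarray(W, dtype=float)
    r = W.shape[1]
    h = nnls(x, W)
    if x.sum() == 0:
        return RefitResult(h=h, support=(), loglik=0.0, epsilon=epsilon)
    support = set(np.flatnonzero(h > 0).tolist())
    loglik = per_mutation_loglik(x, W, h) if support else -np.inf
    step_log: list[tuple[str, int, float]] = []
    max_passes = 10 * r
    n_passes = 0
    for n_passes in range(1, max_passes + 1):
        changed = False
        # backward: cheapest removal
        if len(support) > 1:
            best_j, best_drop = None, np.inf
            for j in sorted(support):
                ll_minus, _ = _loglik_on_support(x, W, support - {j})
                drop = loglik - ll_minus
                if drop < best_drop:
                    best_j, best_drop = j, drop
            if best_j is not None and best_drop < epsilon:
                support.discard(best_j)
                loglik, h = _loglik_on_support(x, W, support)
                step_log.append(("remove", best_j, -best_drop))
                changed = True
        # forward: best addition
        inactive = sorted(set(range(r)) - support)
        if inactive:
            best_j, best_gain = None, -np.inf
            for j in inactive:
                ll_plus, _ = _loglik_on_support(x, W, support | {j})
                gain = ll_plus - loglik
                if gain > best_gain:
                    best_j, best_gain = j, gain
            if best_j is not None and best_gain > epsilon:
                support.add(best_j)
                loglik, h = _loglik_on_support(x, W, support)
                step_log.append(("add", best_j, best_gain))
                changed = True
        if not changed:
            break
    else:
        raise RuntimeError(
            f"sparse NNLS did not stabilize within {max_passes} passes"
        )
    h = nnls(x, W, support_mask=support)
    support = tuple(sorted(np.flatnonzero(h > 0).tolist()))
    return RefitResult(
        h=h,
        support=support,
        loglik=per_mutation_loglik(x, W, h) if support else -np.inf,
        step_log=step_log,
        epsilon=epsilon,
        n_passes=n_passes,
    )


def thresholded_nnls(x, W, frac: float) -> np.ndarray:
    """NNLS followed by zeroing signatures contributing less than ``frac`` of
    the total exposure, then re-fitting on the surviving support."""
    if not 0 <= frac < 1:
        raise ValueError("frac must be in [0, 1)")
    x = np.asarray(x, dtype=float).ravel()
    W = np.asarray(W, dtype=float)
    h = nnls(x, W)
    total = h.sum()
    if total == 0 or frac == 0:
        return h
    keep = np.flatnonzero(h / total >= frac)
    return nnls(x, W, support_mask=keep)


def match_signature(s, catalog, epsilon: float) -> tuple[np.ndarray, RefitResult]:
    """Decompose a (L1-normalized) spectrum as a sparse nonnegative mixture of
    catalog signatures.

    Because the stepwise algorithm works on per-mutation log likelihoods, a
    probability vector is a valid input; the returned weights are
    L1-normalized over the support.
    """
    s = np.asarray(s, dtype=float).ravel()
    if s.sum() <= 0:
        raise ValueError("spectrum must have positive mass")
    if abs(s.sum() - 1.0) > 1e-6:
        raise ValueError("spectrum must be L1-normalized for matching")
    W = catalog.values if hasattr(catalog, "values") and hasattr(catalog, "schema") else np.asarray(catalog, dtype=float)
    result = sparse_nnls(s, W, epsilon)
    weights = result.h.copy()
    if weights.sum() > 0:
        weights = weights / weights.sum()
    return weights, result


def clean_matches(
    weights,
    catalog,
    de_novo,
    min_channel_frac: float = 0.01,
    min_mass: float = 0.15,
    peak_ratio: float = 5.0,
    contribution: str = "reconstruction",
) -> np.ndarray:
    """Remove matched signatures that merely fit background of a de novo
    spectrum.

    A matched signature is deemed a background over-fit and removed iff
    (1) the sum of its own spectrum's probabilities over the channels where
    its weighted contribution is at least ``min_channel_frac`` (in absolute
    probability units of the unit-mass reconstruction; with
    ``contribution='own'`` the channels where its own spectrum exceeds
    ``min_channel_frac``) is below ``min_mass``, and
    (2) its maximum weighted contribution to any channel is smaller than the
    de novo spectrum's peak probability divided by ``peak_ratio``.
    Surviving weights are re-fit by NNLS and re-normalized.

    A flat signature matched at small weight under a peaked de novo spectrum
    contributes less than 1% everywhere, so its active-channel mass is 0 and
    its peak contribution is tiny: both conditions fire and it is dropped.
    A genuinely flat de novo spectrum is protected by condition (2), since
    its own peak probability is low.
    """
    weights = np.asarray(weights, dtype=float).ravel()
    W = catalog.values if hasattr(catalog, "values") and hasattr(catalog, "schema") else np.asarray(catalog, dtype=float)
    s = np.asarray(de_novo, dtype=float).ravel()
    if weights.sum() > 0:
        weights = weights / weights.sum()  # reconstruction carries unit mass
    peak = s.max()
    keep = []
    for j in np.flatnonzero(weights > 0):
        contrib = weights[j] * W[:, j]
        if contribution == "reconstruction":
            active = contrib >= min_channel_frac
        elif contribution == "own":
            active = W[:, j] >= min_channel_frac
        else:
            raise ValueError("contribution must be 'reconstruction' or 'own'")
        overfit = (W[active, j].sum() < min_mass) and (contrib.max() < peak / peak_ratio)
        if not overfit:
            keep.append(j)
    cleaned = nnls(s, W, support_mask=keep)
    if cleaned.sum() > 0:
        cleaned = cleaned / cleaned.sum()
    return cleaned


def refit_matrix(X, W, epsilon: float) -> tuple[np.ndarray, list[RefitResult]]:
    """Sparse-NNLS refit of every sample (column) of a count matrix."""
    X = np.asarray(X, dtype=float)
    W_arr = W.values if hasattr(W, "values") and hasattr(W, "schema") else np.asarray(W, dtype=float)
    H = np.zeros((W_arr.shape[1], X.shape[1]))
    results = []
    for j in range(X.shape[1]):
        res = sparse_nnls(X[:, j], W_arr, epsilon)
        H[:, j] = res.h
        results.append(res)
    return H, results
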