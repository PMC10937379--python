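"""Nonnegative matrix factorization with KL divergence, with and without a
minimum-volume penalty.

Standard NMF factorizes a nonnegative channel-by-sample matrix X as W @ H by
minimizing the generalized Kullback-Leibler divergence D(X | WH). NMF
solutions are not unique: any invertible Q with WQ >= 0 and Q^{-1}H >= 0
yields an equivalent factorization. Minimum-volume NMF (mvNMF) removes this
ambiguity by penalizing the volume of the cone spanned by the signature
columns:

    min_{W>=0, H>=0}  D(X | WH) + lambda * log det(W^T W + delta * I)

with W column-stochastic. Under mild identifiability conditions the volume
penalty makes the solution essentially unique. The W update is a
majorization-minimization multiplicative step (the log-det term is split into
convex and concave parts via the sign decomposition of (W^T W + delta I)^{-1}),
followed by column L1 normalization enforced through a backtracking line
search that guarantees a monotone objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPS = 1e-16  # zero protection inside divisions and logarithms


def kl_divergence(X: np.ndarray, Y: np.ndarray) -> float:
    """Generalized KL divergence D(X | Y) = sum x log(x/y) - x + y."""
    return float(np.sum(kl_divergence_per_sample(X, Y)))


def kl_divergence_per_sample(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Column-wise generalized KL divergence."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    term = np.where(X > 0, X * np.log((X + EPS) / (Y + EPS)), 0.0)
    return np.sum(term - X + Y, axis=0)


@dataclass
class FactorizationResult:
    """Outcome of a single NMF or mvNMF run.

    ``W`` is column-stochastic (p x r); ``H`` (r x n) absorbs the scale.
    ``reconstruction_error`` is D(X | WH); for mvNMF the ``objective_trace``
    additionally contains the volume penalty.
    """

    W: np.ndarray
    H: np.ndarray
    objective_trace: list[float]
    reconstruction_error: float
    lambda_tilde: float = 0.0
    lambda_: float = 0.0
    converged: bool = True
    seed: int | None = None
    n_iter: int = 0
    line_search_warnings: int = 0
    sample_errors: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def _init_wh(
    X: np.ndarray, r: int, init, seed
) -> tuple[np.ndarray, np.ndarray, int | None]:
    if init is not None:
        W0, H0 = init
        return np.array(W0, dtype=float), np.array(H0, dtype=float), seed
    rng = np.random.default_rng(seed)
    p, n = X.shape
    scale = np.sqrt(X.mean() / r)
    W0 = rng.uniform(EPS, 1.0, size=(p, r)) * scale
    H0 = rng.uniform(EPS, 1.0, size=(r, n)) * scale
    return W0, H0, seed


def _normalize_pair(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = W.sum(axis=0)
    s = np.maximum(s, EPS)
    return W / s, H * s[:, None]


def _check_input(X: np.ndarray, r: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if r < 1:
        raise ValueError("rank r must be >= 1")
    if X.ndim != 2:
        raise ValueError("X must be a 2-D array")
    if np.any(X < 0):
        raise ValueError("X must be nonnegative")
    if not np.any(X > 0):
        raise ValueError("X is all zero")
    if r > min(X.shape):
        raise ValueError(f"r={r} exceeds min(p, n)={min(X.shape)}")
    return X


def _update_h(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> np.ndarray:
    WH = W @ H + EPS
    numer = W.T @ (X / WH)
    denom = W.sum(axis=0)[:, None] + EPS
    return H * numer / denom


def nmf_kl(
    X,
    r: int,
    init=None,
    seed: int | None = 0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> FactorizationResult:
    """Standard KL-NMF via multiplicative updates.

    Stops when the relative objective change falls below ``tol`` or after
    ``max_iter`` iterations. The returned W is column-stochastic with the
    scale moved into H (a reparametrization that leaves WH unchanged).
    """
    X = _check_input(np.asarray(X, dtype=float), r)
    W, H, seed = _init_wh(X, r, init, seed)
    trace = [kl_divergence(X, W @ H)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        H = _update_h(X, W, H)
        WH = W @ H + EPS
        W = W * ((X / WH) @ H.T) / (H.sum(axis=1)[None, :] + EPS)
        obj = kl_divergence(X, W @ H)
        trace.append(obj)
        if abs(trace[-2] - obj) <= tol * max(abs(trace[-2]), EPS):
            converged = True
            break
    W, H = _normalize_pair(W, H)
    return FactorizationResult(
        W=W,
        H=H,
        objective_trace=trace,
        reconstruction_error=trace[-1],
        converged=converged,
        seed=seed,
        n_iter=it,
        sample_errors=kl_divergence_per_sample(X, W @ H),
    )


def compute_lambda(
    lambda_tilde: float, X, W_ini: np.ndarray, H_ini: np.ndarray, delta: float = 1.0
) -> float:
    """Scale the dimensionless penalty weight to the data.

    lambda = lambda_tilde * D(X | W_ini H_ini) / log det(W_ini^T W_ini + delta I),
    which makes the effective regularization roughly independent of cohort
    size and mutation burden. ``W_ini`` must be column-stochastic.
    """
    X = np.asarray(X, dtype=float)
    W_ini = np.asarray(W_ini, dtype=float)
    H_ini = np.asarray(H_ini, dtype=float)
    denom = float(
        np.linalg.slogdet(W_ini.T @ W_ini + delta * np.eye(W_ini.shape[1]))[1]
    )
    if denom <= 0:
        raise ValueError(
            "log det(W_ini^T W_ini + delta I) must be positive "
            "(is W_ini column-stochastic with delta >= 1?)"
        )
    return float(lambda_tilde) * kl_divergence(X, W_ini @ H_ini) / denom


def _mv_objective(X, W, H, lam: float, delta: float) -> float:
    logdet = np.linalg.slogdet(W.T @ W + delta * np.eye(W.shape[1]))[1]
    return kl_divergence(X, W @ H) + lam * float(logdet)


def _update_w_mv(
    X: np.ndarray, W: np.ndarray, H: np.ndarray, lam: float, delta: float
) -> np.ndarray:
    """MM multiplicative update for W under the volume penalty (H fixed).

    Solving the per-entry quadratic a*t^2 + b*t - c = 0 obtained from the
    majorizer; a -> 0 reduces to the plain KL multiplicative update.
    """
    r = W.shape[1]
    Y = np.linalg.inv(W.T @ W + delta * np.eye(r))
    Yp = np.maximum(Y, 0.0)
    Ym = np.maximum(-Y, 0.0)
    WH = W @ H + EPS
    C = ((X / WH) @ H.T) * W  # c_ik * W0_ik, elementwise
    a = 2.0 * lam * (W @ Yp) / np.maximum(W, EPS)
    b = H.sum(axis=1)[None, :] - 2.0 * lam * (W @ Ym)
    # robust root: when a is negligible (and b > 0) use the linear solution c/b
    small = (a * np.maximum(C, EPS) < 1e-14 * np.maximum(b * b, EPS)) & (b > 0)
    disc = np.sqrt(b * b + 4.0 * a * C)
    with np.errstate(divide="ignore", invalid="ignore"):
        quad = (-b + disc) / (2.0 * a)
        lin = C / np.maximum(b, EPS)
    W_new = np.where(small, lin, quad)
    return np.maximum(W_new, EPS)


def mvnmf(
    X,
    r: int,
    lambda_tilde: float = 0.1,
    delta: float = 1.0,
    init=None,
    seed: int | None = 0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    max_backtracks: int = 20,
) -> FactorizationResult:
    """Minimum-volume NMF with KL divergence.

    Alternates the standard multiplicative KL update for H with an MM
    multiplicative update for W; after every W update the columns are exactly
    L1-normalized (scale absorbed by H) and a backtracking line search halves
    the step until the objective does not increase. ``lambda_tilde`` is the
    dimensionless penalty weight, converted to the absolute weight via
    :func:`compute_lambda` at the initialization.
    """
    X = _check_input(np.asarray(X, dtype=float), r)
    if lambda_tilde < 0:
        raise ValueError("lambda_tilde must be >= 0")
    W, H, seed = _init_wh(X, r, init, seed)
    W, H = _normalize_pair(W, H)
    lam = compute_lambda(lambda_tilde, X, W, H, delta)
    obj = _mv_objective(X, W, H, lam, delta)
    trace = [obj]
    converged = False
    warnings = 0
    it = 0
    for it in range(1, max_iter + 1):
        H = _update_h(X, W, H)
        obj_h = _mv_objective(X, W, H, lam, delta)
        W_mu = _update_w_mv(X, W, H, lam, delta)
        gamma = 1.0
        W_new, H_new, obj_new = W, H, obj_h
        accepted = False
        for _ in range(max_backtracks + 1):
            W_try = (1.0 - gamma) * W + gamma * W_mu
            W_cand, H_cand = _normalize_pair(W_try, H)
            obj_cand = _mv_objective(X, W_cand, H_cand, lam, delta)
            if obj_cand <= obj_h + 1e-12 * max(abs(obj_h), 1.0):
                W_new, H_new, obj_new = W_cand, H_cand, obj_cand
                accepted = True
                break
            gamma *= 0.5
        if not accepted:
            warnings += 1  # keep the H update, skip the W step this round
        W, H, obj = W_new, H_new, obj_new
        trace.append(obj)
        if abs(trace[-2] - obj) <= tol * max(abs(trace[-2]), EPS):
            converged = True
            break
    return FactorizationResult(
        W=W,
        H=H,
        objective_trace=trace,
        reconstruction_error=kl_divergence(X, W @ H),
        lambda_tilde=lambda_tilde,
        lambda_=lam,
        converged=converged,
        seed=seed,
        n_iter=it,
        line_search_warnings=warnings,
        sample_errors=kl_divergence_per_sample(X, W @ H),
    )
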