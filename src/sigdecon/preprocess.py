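"""Cohort preprocessing before de novo discovery.

Two complementary operations improve discovery sensitivity:

* **Gini-based outlier removal** — a handful of samples carrying a signature
  absent elsewhere (e.g. a single hypermutator) can hijack the factorization.
  Signatures whose per-sample exposure distribution has a Gini coefficient
  above a baseline are flagged; for each flagged signature, samples are
  inspected in descending relative exposure and removed while each removal
  drops the Gini coefficient by more than a threshold.

* **Automatic stratification** — hierarchical clustering of samples (on the
  count matrix or, preferably, on the exposures from an initial discovery)
  with the number of clusters picked by the gap statistic, which gracefully
  returns k = 1 when the cohort has no subset structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .discovery import gap_statistic_k, _cluster_labels
from .matrices import l1_normalize_columns


def gini(v) -> float:
    """Gini coefficient of a nonnegative vector: sum_ij |v_i - v_j| / (2 n^2 mean).

    0 for perfect equality (including constant and single-element vectors);
    approaches 1 when all mass sits on one element of a long vector.
    """
    v = np.asarray(v, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty vector")
    if np.any(v < 0):
        raise ValueError("Gini coefficient requires nonnegative entries")
    total = v.sum()
    if total == 0:
        return 0.0
    # O(n log n) equivalent of the double sum, via the sorted (Lorenz) form
    s = np.sort(v)
    n = s.size
    ranks = np.arange(1, n + 1)
    return float(np.sum((2 * ranks - n - 1) * s) / (n * total))


@dataclass
class OutlierReport:
    flagged_signatures: list[int]
    removed: dict[int, list[tuple[str, float]]]  # signature -> [(sample, gini drop)]
    retained_sample_ids: list[str]
    gini_baseline: float
    delta_gini: float
    gini_before: dict[int, float] = field(default_factory=dict)


def remove_outliers(
    H,
    sample_ids=None,
    gini_baseline: float = 0.65,
    delta_gini: float = 0.05,
) -> OutlierReport:
    """Flag high-Gini signatures and strip the samples that drive them.

    ``H`` is the exposure matrix (signatures x samples) from an initial
    discovery on the full cohort. Exposures are column-normalized (relative)
    before both the Gini computation and the ranking. For each flagged
    signature, samples are visited in descending relative exposure; a sample
    is removed iff its removal decreases that signature's Gini coefficient by
    more than ``delta_gini``, and the scan stops at the first failure.
    Flagged signatures are processed sequentially in index order, each seeing
    the removals of its predecessors.
    """
    H_arr = H.values if hasattr(H, "signature_ids") else np.asarray(H, dtype=float)
    if sample_ids is None:
        sample_ids = (
            list(H.sample_ids)
            if hasattr(H, "sample_ids")
            else [f"S{j}" for j in range(H_arr.shape[1])]
        )
    sample_ids = list(sample_ids)
    rel = l1_normalize_columns(np.maximum(H_arr, 0) + 1e-300)
    active = list(range(len(sample_ids)))
    flagged = [
        i for i in range(rel.shape[0]) if gini(rel[i, :]) > gini_baseline
    ]
    removed: dict[int, list[tuple[str, float]]] = {}
    gini_before = {i: gini(rel[i, :]) for i in flagged}
    for sig in flagged:
        removed[sig] = []
        order = sorted(active, key=lambda j: -rel[sig, j])
        for j in order:
            remaining = [a for a in active if a != j]
            g_now = gini(rel[sig, active])
            g_without = gini(rel[sig, remaining])
            if g_now - g_without > delta_gini:
                removed[sig].append((sample_ids[j], g_now - g_without))
                active = remaining
            else:
                break
    return OutlierReport(
        flagged_signatures=flagged,
        removed=removed,
        retained_sample_ids=[sample_ids[j] for j in active],
        gini_baseline=gini_baseline,
        delta_gini=delta_gini,
        gini_before=gini_before,
    )


@dataclass
class StratificationResult:
    labels: np.ndarray  # per-sample stratum label in 0..k-1
    k: int
    basis: str  # 'counts' or 'exposures'
    sample_ids: list[str]


def stratify(
    M,
    k_max: int = 10,
    seed: int = 0,
    basis: str | None = None,
    gap_n_reference: int = 50,
) -> StratificationResult:
    """Cluster samples into strata with distinct signature compositions.

    Samples (columns of a count or exposure matrix) are L1-normalized and
    clustered hierarchically on cosine distance; k is chosen by the gap
    statistic, including k = 1 when the cohort is homogeneous. Clustering the
    exposures from an initial discovery is recommended over clustering raw
    counts, as it captures subset structure more directly.
    """
    if hasattr(M, "schema"):
        arr, ids, inferred = M.values, list(M.sample_ids), "counts"
    elif hasattr(M, "signature_ids"):
        arr, ids, inferred = M.values, list(M.sample_ids), "exposures"
    else:
        arr = np.asarray(M, dtype=float)
        ids = [f"S{j}" for j in range(arr.shape[1])]
        inferred = basis or "counts"
    basis = basis or inferred
    points = l1_normalize_columns(arr + 1e-300).T
    k = gap_statistic_k(
        points, min(k_max, points.shape[0]), n_reference=gap_n_reference, seed=seed
    )
    raw = _cluster_labels(points, k, "cosine")
    order: dict[int, int] = {}
    labels = np.array([order.setdefault(c, len(order)) for c in raw])
    return StratificationResult(labels=labels, k=k, basis=basis, sample_ids=ids)
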