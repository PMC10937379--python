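"""Two-sample comparisons used to decide whether one set of reconstruction
errors is worse than another.

Two tests are combined throughout the package: the Mann-Whitney U test on the
full samples, and a tail test sensitive to a small number of exceptionally
large errors that barely move the rank statistic.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def mann_whitney_greater(sample: np.ndarray, reference: np.ndarray) -> float:
    """P value for ``sample`` being stochastically greater than ``reference``."""
    sample = np.asarray(sample, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if np.all(sample == sample[0]) and np.all(reference == sample[0]):
        return 1.0  # identical constant samples carry no evidence
    return float(
        sps.mannwhitneyu(sample, reference, alternative="greater").pvalue
    )


def tail_test(sample: np.ndarray, reference: np.ndarray, quantile: float = 0.9) -> float:
    """P value for ``sample`` having a heavier upper tail than ``reference``.

    The two samples are pooled, the pooled ``quantile`` (default 90th
    percentile) is taken as a cut point, and the exceedance counts above the
    cut are compared with a one-sided Fisher exact test. This is this
    package's own tail-difference test: it targets the situation where a few
    samples receive exceptionally large errors while bulk ranks are unmoved.
    """
    sample = np.asarray(sample, dtype=float)
    reference = np.asarray(reference, dtype=float)
    pooled = np.concatenate([sample, reference])
    cut = np.quantile(pooled, quantile)
    a_exc = int(np.sum(sample > cut))
    b_exc = int(np.sum(reference > cut))
    table = [
        [a_exc, sample.size - a_exc],
        [b_exc, reference.size - b_exc],
    ]
    return float(sps.fisher_exact(table, alternative="greater")[1])


def significantly_worse(
    sample: np.ndarray, reference: np.ndarray, alpha: float = 0.05
) -> tuple[bool, float, float]:
    """Is ``sample`` significantly worse (larger) than ``reference``?

    Returns (flag, Mann-Whitney p, tail-test p); worse if either p < alpha.
    """
    p_mwu = mann_whitney_greater(sample, reference)
    p_tail = tail_test(sample, reference)
    return (p_mwu < alpha or p_tail < alpha), p_mwu, p_tail
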