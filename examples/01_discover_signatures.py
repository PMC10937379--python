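"""De novo signature discovery with automatic rank selection.

Simulates a 20-channel cohort from 3 planted signatures (Dirichlet exposures,
Poisson burdens, multinomial counts), then recovers both the number of
signatures and their spectra.
"""

import numpy as np

from sigdecon import select_rank
from sigdecon.simulate import SimulationSpec, random_separated_signatures, simulate_lda
from sigdecon.validate import pair_signatures

W_true = random_separated_signatures(p=20, r=3, seed=8, sparsity=2.0)
spec = SimulationSpec(W_true, n_samples=120, alpha=0.1, mean_burden=2000, seed=4)
X, H_true = simulate_lda(spec)
print(f"cohort: {X.shape[1]} samples, {X.sum(axis=0).mean():.0f} mutations/sample")

report = select_rank(
    X, r_range=range(2, 5), n_rep=6, lambda_grid=[1e-10, 1e-2, 0.1],
    seed=0, tol=1e-7, max_iter=2000, gap_n_reference=20,
)
print(f"selected number of signatures: r = {report.selected_r}")
for c in report.candidates:
    print(f"  r={c.r}: clusters k={c.k}, mean silhouette {c.mean_silhouette:.2f}, "
          f"min {c.min_silhouette:.2f}, lambda_tilde {c.lambda_tilde:g}")

_, dist = pair_signatures(W_true, report.W)
print(f"mean cosine distance of consensus signatures to the planted truth: {dist:.4f}")
# r = 3 is chosen because only there do replicate runs keep rediscovering the
# same r spectra (k == r with tight clusters); the distance near 0 shows the
# planted spectra themselves are recovered.
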