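"""Likelihood-based sparse refitting vs exposure thresholding.

Uses the constructed decoy-flat sample: 7 active signatures (one carrying
only ~2% of the burden) in a 20-signature catalog where plain NNLS hands a
decoy flat more exposure than the smallest true signature.
"""

import numpy as np

from sigdecon.refit import nnls, sparse_nnls, thresholded_nnls
from sigdecon.simulate import flat_decoy_instance

x, W, true_support = flat_decoy_instance()
print(f"sample: {int(x.sum())} mutations; true signatures {true_support}")

h0 = nnls(x, W)
rel = h0 / h0.sum()
print(f"plain NNLS assigns {np.sum(h0 > 0)} signatures; "
      f"largest spurious exposure {max(rel[j] for j in np.flatnonzero(h0>0) if j not in true_support):.3f} "
      f"vs smallest true exposure {min(rel[list(true_support)]):.3f}")

res = sparse_nnls(x, W, epsilon=0.0005)
print(f"sparse NNLS (epsilon=0.0005) support: {res.support} "
      f"-> exact recovery: {res.support == true_support}")

hits = [f for f in np.linspace(0, 0.2, 401)
        if tuple(np.flatnonzero(thresholded_nnls(x, W, float(f)) > 0)) == true_support]
print(f"exposure cutoffs recovering the exact support: {len(hits)} of 401 tried")
# No cutoff works: any threshold high enough to kill the decoy also kills the
# 2% true signature. The likelihood criterion separates them because dropping
# a genuinely active peaked signature costs far more log likelihood.
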