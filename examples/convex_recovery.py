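"""Exact low-rank + sparse recovery in the convex regime.

The solver's uniform-nuclear baseline is classical robust PCA: nuclear
norm on L, elementwise L1 on E.  On an incoherent rank-2 stack with 5%
random +-0.5 corruption it recovers the clean component almost exactly —
the standard sanity check that the ADMM machinery is correct.
"""

from dataclasses import replace

import numpy as np

from rpcalign import default_parameters, make_fixture, solve

bundle = make_fixture("rpca_convex", seed=0)
stack = bundle.degraded_stack
print(f"stack: {stack.m}x{stack.n}, true rank 2, "
      f"{np.count_nonzero(bundle.true_sparse)} corrupted entries")

config = replace(default_parameters(stack), baseline_mode="uniform_nuclear")
result = solve(stack, config)

L_true = bundle.clean_stack.data
rel = np.linalg.norm(result.L - L_true) / np.linalg.norm(L_true)
support = bundle.true_sparse != 0
coverage = np.count_nonzero(result.E[support]) / support.sum()
print(f"relative recovery error ||L_hat - L*||_F / ||L*||_F = {rel:.2e}")
print(f"sparse-support coverage: {100 * coverage:.1f}% of corrupted entries "
      "appear in E_hat")
print("errors near 1e-3 or below mean the corruption was cleanly separated "
      "from the shared low-rank structure.")
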