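"""MK-MMD as a two-sample statistic: zero under equality, growing with shift.

The multi-kernel maximum mean discrepancy d_k²(p, q) is the RKHS distance
between mean embeddings of two distributions under a convex combination
of Gaussian kernels.  It is zero iff p = q, which is what makes it usable
as a training signal for aligning source- and target-subject features.
"""

import numpy as np

from eegtransfer import make_kernel_family, mk_mmd2

rng = np.random.default_rng(0)
base = rng.normal(size=(256, 2))
family = make_kernel_family(base, m=5, spacing=2.0)
print("bandwidth ladder:", np.round(family.bandwidths, 3),
      " β =", family.beta)

print(f"\n{'mean shift':>10} {'biased MMD²':>12} {'unbiased MMD²':>14}")
for mu in [0.0, 0.5, 1.0, 2.0]:
    shifted = rng.normal(loc=mu, size=(256, 2))
    b = mk_mmd2(base, shifted, family, "biased")
    u = mk_mmd2(base, shifted, family, "unbiased")
    print(f"{mu:>10.1f} {b:>12.4f} {u:>14.4f}")

print("\nThe statistic rises monotonically with the shift; at shift 0 the")
print("unbiased estimate fluctuates around zero, the biased one stays ≥ 0.")
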