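"""Heritability and genetic correlation via LD-score regression.

Simulates two polygenic traits sharing causal variants with genetic
correlation -0.20 (the neck-width / neck-BMD relationship) and recovers
h² and rg from their summary statistics alone.
"""

import numpy as np
import pandas as pd

from fnwpipe import ldsc, synth
from fnwpipe.ldsc import LDScoreSet


def ar(rho, k):
    return rho ** np.abs(np.subtract.outer(np.arange(k), np.arange(k)))


blocks = [np.eye(1), ar(0.3, 5), ar(0.6, 10), ar(0.9, 20)]
m = 5000
ss1, ss2 = synth.simulate_sumstats_polygenic(blocks, h2=0.5, rg=-0.20,
                                             n=20_000, m=m, seed=4)

# LD scores implied by the simulation's block correlations
l2, tot, i = [], 0, 0
while tot < m:
    b = blocks[i % len(blocks)]
    k = min(b.shape[0], m - tot)
    l2.append((b[:k, :k] ** 2).sum(1))
    tot += k
    i += 1
ld = LDScoreSet(
    scores=pd.DataFrame({"id": [f"rs{j + 1}" for j in range(m)], "chr": 1,
                         "pos": np.arange(1, m + 1) * 1000,
                         "L2": np.concatenate(l2)}),
    window_kb=1000.0, n_ref=10**9,
)

h2 = ldsc.ldsc_h2(ss1, ld, n_blocks=100)
rg = ldsc.ldsc_rg(ss1, ss2, ld, n_blocks=100)
print(f"trait 1 h² = {h2['h2']:.3f} ± {h2['se_h2']:.3f} (truth 0.5), "
      f"intercept = {h2['intercept']:.2f} (1.0 expected without confounding)")
print(f"cross-trait rg = {rg.rg:.3f} ± {rg.se_rg:.3f} (truth -0.20), "
      f"p = {rg.p_rg:.2g}")
print("The regression of chi² (and z1·z2) on per-variant LD scores separates "
      "polygenic signal, which grows with LD, from confounding, which does not.")
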