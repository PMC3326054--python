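"""Compare replicate community profiles: UniFrac, MWU, PERMANOVA, PCoA.

Simulates two groups of replicate mock-community samples -- one faithful to
the specification and one with a systematic composition shift (as a proxy
for a methodological effect, e.g. a DNA extraction protocol that
under-recovers the dominant organism) -- and quantifies whether the shift
exceeds replicate noise.
"""

from itertools import combinations

import numpy as np
import pandas as pd

from amplimit import (
    exact_mann_whitney_u,
    mock_community,
    pcoa,
    permanova,
    shannon_index,
    unifrac_distance_matrix,
    weighted_unifrac,
)
from amplimit.io import genus_tree

spec = mock_community()
tree = genus_tree(spec)
rng = np.random.default_rng(8)

faithful = dict(spec.abundances)
shifted = dict(faithful)
shifted["P_aeruginosa"] -= 0.15
shifted["S_aureus"] += 0.15

ids = list(faithful)
samples = {}
for i in range(3):
    samples[f"methodA_{i + 1}"] = dict(
        zip(ids, rng.multinomial(2000, [faithful[t] for t in ids])))
    samples[f"methodB_{i + 1}"] = dict(
        zip(ids, rng.multinomial(2000, [shifted[t] for t in ids])))

counts = pd.DataFrame(samples)
dm = unifrac_distance_matrix(tree, counts)

within = [weighted_unifrac(tree, samples[a], samples[b])
          for a, b in combinations([s for s in samples if "A" in s], 2)]
between = [weighted_unifrac(tree, samples[a], samples[b])
           for a in samples if "A" in a for b in samples if "B" in b]
u, p_mwu = exact_mann_whitney_u(within, between, alternative="less")

groups = ["A" if "A" in s else "B" for s in dm.ids]
f_stat, p_perm = permanova(dm, groups, n_perm=1000, seed=9)

coords, explained, _ = pcoa(dm, n_axes=2)

print(f"mean within-method UniFrac:  {np.mean(within):.4f}")
print(f"mean between-method UniFrac: {np.mean(between):.4f}")
print(f"exact Mann-Whitney U (within < between): U={u:.1f}, p={p_mwu:.4f}")
print(f"PERMANOVA: pseudo-F={f_stat:.2f}, p={p_perm:.4f}")
print(f"Shannon (methodA_1): {shannon_index(samples['methodA_1']):.3f}")
print(f"PCoA axis 1 explains {100 * explained[0]:.1f}% of positive inertia")
print()
print("Between-method distances are an order of magnitude above replicate")
print("noise and the exact MWU flags the shift. Note the PERMANOVA p-value:")
print("with only three samples per group, permutations preserving the")
print("partition occur 10% of the time (2*(3!)^2/6!), so p cannot drop")
print("below ~0.1 regardless of effect size -- exactly why an exact")
print("rank test on the distances is preferred at this sample size.")
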