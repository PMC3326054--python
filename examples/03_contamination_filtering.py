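"""Screen spurious taxa with a depth-derived abundance cutoff.

Builds replicate mock-community samples with spiked-in contaminant genera at
low abundance, rarefies to 900 reads, filters at the minimum detectable
abundance for that depth, and classifies what survives against the known
community composition.
"""

import numpy as np

from amplimit import (
    OTUTable,
    apply_abundance_cutoff,
    classify_contaminants,
    min_detectable_abundance,
    mock_community,
    normalize_to_depth,
)
import pandas as pd

spec = mock_community()
rng = np.random.default_rng(5)

spikes = {"Escherichia": 2e-3, "Dechloromonas": 3e-4, "Stenotrophomonas": 8e-3}
scale = 1.0 - sum(spikes.values())
taxa = list(spec.abundances) + list(spikes)
probs = [a * scale for a in spec.abundances.values()] + list(spikes.values())
genus = {t.taxon_id: t.genus for t in spec.taxa} | {g: g for g in spikes}

counts = {f"rep{i + 1}": dict(zip(taxa, rng.multinomial(5000, probs)))
          for i in range(3)}
table = OTUTable(counts=pd.DataFrame(counts), genus=genus)

depth = 900
cutoff = min_detectable_abundance(depth)
norm = normalize_to_depth(table, depth, seed=6)
filtered = apply_abundance_cutoff(norm, cutoff)

before = classify_contaminants(norm, spec.genera)
after = classify_contaminants(filtered, spec.genera)

print(f"cutoff at depth {depth}: {100 * cutoff:.2f}% of reads")
for s in norm.sample_ids:
    print(f"{s}: contaminant fraction {before.contaminant_fraction[s]:.3%} "
          f"-> {after.contaminant_fraction[s]:.3%} after filtering "
          f"({before.n_contaminant_genera[s]} -> "
          f"{after.n_contaminant_genera[s]} contaminant genera)")

print()
print("Contaminants spiked below the cutoff are removed; Stenotrophomonas,")
print("spiked at 0.8% (above the 0.33% cutoff), rightly survives -- an")
print("abundance cutoff can only screen contaminants below the detection")
print("limit, and also costs any true community members sitting below it.")
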