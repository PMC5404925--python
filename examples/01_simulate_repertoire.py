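"""Simulate an OSN repertoire study and inspect its ground truth.

Each mature OSN expresses one OR allele, so OR counts in whole olfactory
mucosa (WOM) RNA-seq measure OSN-subtype proportions.  The generator draws
heavy-tailed choice probabilities, applies cis effects to the CAST strain,
and emits parental and F1 count tables with known truth.
"""

import numpy as np

from osncistrans import simulate_cistrans_dataset

data = simulate_cistrans_dataset(mode="cis", seed=1)
model = data["model"]

p = np.sort(model.p_b6)[::-1]
top = np.searchsorted(np.cumsum(p), 0.25) + 1
print(f"OR genes: {model.n_genes}; genes with cis effects: {len(model.cis_effects)}")
print(f"top {top} subtypes ({100 * top / model.n_genes:.1f}%) hold 25% of the repertoire")
print(f"B6 matrix: {data['b6'].counts.shape[0]} genes x {data['b6'].counts.shape[1]} samples")
print(f"F1 allelic rows: {len(data['f1_allelic'].table)}")
# A small top fraction holding a quarter of the repertoire reproduces the
# skewed subtype-abundance distribution seen in real WOM.
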