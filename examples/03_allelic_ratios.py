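"""Allelic ratios and allele-specific expression in an F1 hybrid.

SNP-informative read counts split each gene's F1 expression between the
B6 and CAST alleles.  Genes with informative counts in the lowest quartile
are dropped before ratios are trusted.
"""

from osncistrans import (allelic_ratio, deconvolve_alleles,
                         informative_gene_filter, simulate_cistrans_dataset,
                         two_stage_normalize)

data = simulate_cistrans_dataset(mode="cis", seed=2)
normed, s, f, _gate = two_stage_normalize(data["f1_total"])

filt = informative_gene_filter(data["f1_allelic"], s, f)
print(f"informative filter: kept {len(filt.kept)}/{filt.n_total} genes "
      f"({100 * filt.fraction_kept:.1f}%), Q1 = {filt.quartile:.1f}")

ratios, skipped = allelic_ratio(data["f1_allelic"])
kept = ratios[ratios["gene"].isin(set(filt.kept))]
totals = normed.counts.loc[:, list(data["f1_total"].samples)].mean(axis=1)
expr = deconvolve_alleles(totals, kept)
print(expr.head(5).to_string(index=False, float_format=lambda v: f"{v:.2f}"))
# allele1_value + allele2_value always equals total_value: deconvolution
# redistributes expression between alleles without creating or losing any.
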