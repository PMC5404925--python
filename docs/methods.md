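# Methods

This note records the models, conventions and numerical choices behind
`osncistrans`, in the order the pipeline applies them.

## Biological model and assumptions

Each mature OSN expresses one allele of one OR gene, chosen in a
competition over a fixed neuronal pool.  OR transcript abundance in WOM
RNA-seq is therefore treated as proportional to (OSN subtype count) ×
(OSN fraction of the tissue) × (sequencing depth).  The package assumes
per-OSN OR mRNA levels are comparable across subtypes, inputs are
gene-level fragment counts (alignment, counting and read-level SNP
filtering are upstream), and marker genes (*Omp*, *Adcy3*, *Ano2*,
*Cnga2*, *Gnal*) are expressed in mature OSNs only and stably per OSN —
the premise of the content normalization.

## Synthetic data generator

The generator produces studies with known ground truth; its defaults are
the package's reference conditions.

* **Choice probabilities**: normalized `exp(N(0, σ²))` weights over genes,
  σ = 2 by default.  The law is a modeling choice, not an inference from
  data; σ = 2 reproduces the observed skew in which a few percent of
  subtypes hold a quarter of the neuronal content.
* **Cis effects**: 30% of genes by default receive a log2 effect
  `~ N(0, 1.5²)` multiplying the CAST choice probability, renormalized
  (choice is a competition, so boosting some subtypes depresses all
  others).  Trans-driven strain differences are drawn the same way but
  marked so their F1 alleles equalize; the cis and trans gene sets are
  disjoint.
* **Per-sample conditions**: OSN fraction ~ Uniform(0.3, 0.9); expected
  OR-assigned depth 2×10⁶ fragments; 3 replicates per group.
* **Noise**: overdispersion is modeled as a shared per-sample
  Gamma(1/α, α) library factor (α = 0.05 default), so each gene's count is
  marginally NegBin(mean, α) while the overdispersed component is common
  within a sample — the component that size-factor normalization is
  designed to remove.  Per-gene-independent overdispersion is not
  simulated by this generator; the DE module's own tests add it directly.
  Consequently, passing tests show that the pipeline removes sample-level
  technical variation, not that it is robust to strong gene-level
  biological dispersion.
* **F1 alleles**: the per-sample gene total is drawn first and split
  between alleles binomially at the allele-choice odds; allele competition
  happens inside one tissue and library, so sample-level noise cancels in
  the allelic ratio, as in real hybrids.  SNP-informative counts are
  binomial thinnings of the allele counts with per-gene fraction
  π_g ~ Uniform(0.2, 0.8).
* **Matrix composition**: OR and marker means scale with the sample's OSN
  fraction; a background block of 2000 non-OSN genes (log-normal profile,
  ~1.5× the OR depth) does not, anchoring the depth normalization the way
  the non-neuronal transcriptome does in real WOM.
* **Reproducibility**: one root seed; every stage derives its generator
  from a distinct `SeedSequence` spawn key, so identical (config, seed)
  gives byte-identical serialized output.

## Normalization

Median-of-ratios depth factors use the geometric-mean reference over genes
nonzero in all samples; the median over an even number of ratios is the
midpoint of the two central ones, and factors are rescaled to unit
geometric mean (this fixes the overall scale and makes the estimator
idempotent).  "Strong correlation" for the marker gate is unquantified in
the source procedure; the default is rank correlation ≥ 0.7 (Pearson by
flag), explicit and configurable.  A constant marker is excluded with a
warning; an empty kept set is a hard error.  Zero marker values abort with
the sample named, because markers are by definition abundant — a
pseudocount option exists for robustness.

## Allelic analysis

Ratios default to pooling informative counts over F1 replicates on the
normalized scale (per-sample mode available; which the original analysis
used is not stated).  "Multiplying by the inverse of the ratio" for the
second allele is implemented as the complement (1 − r): only the
complement conserves allele1 + allele2 = total, which deconvolution
requires.  The informative filter uses the linear-interpolation first
quartile and keeps genes strictly above it; both normalization factors are
applied to SNP counts by default (whether content factors were applied to
SNP counts in the original is ambiguous; toggleable via
`apply_osn_to_allelic`).

## In-silico F1 calibration

Parental samples are binomially thinned (count-level equivalent of read
subsampling) to half the median F1 library depth and summed pairwise into
hybrids whose true allelic fold change equals the parental one.  Two
choices matter:

* **Content balancing**: within a pair, thinning fractions are
  proportional to each parent's combined normalization multiplier f_j/s_j
  (capped at the target and the sample's own total).  Equal-depth thinning
  would give the parent with the higher OSN fraction a larger share of
  every gene's fragments, shifting all in-silico allelic ratios by a
  common offset that a real F1 — where both alleles share one tissue —
  cannot have; subtracting such an offset would corrupt C_b.
* **Informative-count realism**: in-silico allelic counts are further
  thinned by the per-gene empirical informative fraction of the real F1
  table, so the calibration experiences the same SNP-informative sparsity
  as the data it corrects.

The deviation d_g is the mean over in-silico replicate sets of
(allelic − parental) log2 fold change; 32 replicate sets (rotated pairings
× independent thinning seeds) are averaged by default so that d_g is
dominated by its systematic component (pseudocount shrinkage at low
informative counts) rather than thinning noise.  Correction is performed
on the log2 scale by subtraction and never changes gene membership.

## Statistics

Lin's ccc uses population (1/n) moments, making the decomposition
ccc = r·C_b exact, with C_b = 2/(v + 1/v + u²), v = s_x/s_y,
u = (x̄ − ȳ)/√(s_x s_y).  Hypergeometric upper tails are summed in log
space (observed tails reach 10⁻¹⁹).  BH adjustment delegates to
statsmodels; rank and linear correlations to scipy.  The abundance-bias
enrichment test dichotomizes the universe at the median by default (the
construction behind the original test is not stated; all parameters are
exposed).  Log2 fold changes use a +1 pseudocount on doubly-normalized
values by default.

## Differential expression

The NB Wald test is a declared approximation of shrinkage-based DE
frameworks: per-gene method-of-moments dispersion pooled across groups
(truncated at zero, no shrinkage — a documented limitation), delta-method
NB variance of the log2 fold change, and a t reference with
n_A + n_B − 2 degrees of freedom for small-sample calibration.  Genes
all-zero in both groups are excluded and listed.  On the reference null
conditions (1000 genes, 6 vs 6, depth 10⁶, α = 0.05) the empirical
rejection rate at p < 0.05 is ≈ 0.050.

## Problem sizes and degenerate inputs

The reference study uses 1000 OR genes, 2000 background genes, 3 + 3 + 3
samples; the full cis/trans analysis with 32 calibration sets runs in
about one second, and the DE calibration (100 null runs × 1000 genes) in a
few seconds.  Degenerate inputs fail loudly and early: no gene nonzero in
all samples, empty marker gate, zero marker values, empty allelic tables,
inconsistent hypergeometric parameters, out-of-range probabilities or
ratios.  Ties throughout use average ranks; quartiles use linear
interpolation; fold-change orientation is fixed CAST vs B6 (allele 2 vs
allele 1) and configurable.

## Known limitations

Reference/mapping bias between strains is out of scope (handled upstream
by pseudo-genome alignment in real analyses).  The generator does not
simulate read-level artifacts, positional SNP placement, per-gene
biological dispersion or batch structure, so pipeline performance on data
with those features is not demonstrated by this test suite.  C_b is
reported at full precision and never hard-coded.
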