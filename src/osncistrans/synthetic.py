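"""Synthetic OSN-repertoire count data with known ground truth.

Each mature olfactory sensory neuron (OSN) expresses one allele of one OR
gene, so whole-olfactory-mucosa (WOM) RNA-seq counts of OR genes measure
OSN-subtype proportions.  The generator emulates the statistical structure
that the downstream analysis assumes:

* a heavy-tailed OR-choice probability distribution (log-normal weights;
  a handful of subtypes dominates the neuronal content),
* per-strain cis effects that multiply a gene's choice probability in one
  strain and are preserved allele-by-allele in an F1 hybrid,
* trans-driven strain differences whose F1 alleles are instead equalized,
* per-sample OSN content (fraction of tissue RNA contributed by OSNs)
  tracked by marker genes, with a background block of non-OSN genes,
* sequencing depth / library overdispersion as a shared per-sample
  Gamma factor, so each gene's count is marginally NegBin(mean, alpha),
* SNP-informative allelic counts as binomial thinnings of allele counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import AllelicCountTable, CountMatrix, infer_gene_classes
from .errors import InvalidArgumentError

#: Marker expression per unit OSN content, relative to total OR-assigned depth.
#: Omp is by far the most abundant OSN marker; the rest are pathway components.
DEFAULT_MARKER_BASELINE = {
    "Omp": 0.40,
    "Adcy3": 0.15,
    "Ano2": 0.08,
    "Cnga2": 0.05,
    "Gnal": 0.12,
}

_STRAIN_KEY = {"B6": 11, "CAST": 13}
_F1_KEY = 17
_MODEL_KEY = 19
_DOWNSAMPLE_KEY = 23


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic per-stage generator derived from one root seed."""
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(key)))


def draw_choice_probabilities(n_genes: int, sigma: float, seed: int) -> np.ndarray:
    """Normalized exp(Normal(0, sigma^2)) weights over OR genes.

    With sigma around 2 the resulting repertoire reproduces the observed
    skew in which a few percent of OSN subtypes hold a quarter of the
    neuronal content.
    """
    if n_genes < 2:
        raise InvalidArgumentError("n_genes must be >= 2")
    if sigma < 0:
        raise InvalidArgumentError("sigma must be >= 0")
    rng = _child_rng(seed, _MODEL_KEY, 1)
    w = np.exp(sigma * rng.standard_normal(n_genes))
    return w / w.sum()


@dataclass
class RepertoireModel:
    """Ground truth for a simulated repertoire.

    ``p_b6`` and ``p_cast`` are per-gene OR-choice probabilities (each sums
    to 1).  Genes in ``cis_effects`` carry a cis-acting log2 factor that is
    preserved between alleles in an F1; ``trans_genes`` differ between the
    parents but have equalized F1 alleles.  ``informative_fraction`` is the
    per-gene probability pi_g that a fragment spans a strain-discriminating
    SNP.
    """

    or_genes: list[str]
    p_b6: np.ndarray
    p_cast: np.ndarray
    cis_effects: dict[str, float]
    trans_genes: frozenset[str]
    informative_fraction: np.ndarray
    marker_baseline: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MARKER_BASELINE))
    background_genes: list[str] = field(default_factory=list)
    background_weights: np.ndarray = field(default_factory=lambda: np.array([]))
    background_relative: float = 1.5

    def __post_init__(self):
        n = len(self.or_genes)
        for name, p in (("p_b6", self.p_b6), ("p_cast", self.p_cast)):
            p = np.asarray(p, dtype=float)
            if p.shape != (n,) or (p < 0).any():
                raise InvalidArgumentError(f"{name} must be a non-negative vector over genes")
            if abs(p.sum() - 1.0) > 1e-12:
                raise InvalidArgumentError(f"{name} must sum to 1 within 1e-12")
        pi = np.asarray(self.informative_fraction, dtype=float)
        if pi.shape != (n,) or (pi < 0).any() or (pi > 1).any():
            raise InvalidArgumentError("informative_fraction must lie in [0, 1] per gene")
        overlap = set(self.cis_effects) & set(self.trans_genes)
        if overlap:
            raise InvalidArgumentError(f"cis and trans gene sets overlap: {sorted(overlap)[:5]}")

    @property
    def n_genes(self) -> int:
        return len(self.or_genes)

    def strain_probabilities(self, strain: str) -> np.ndarray:
        if strain == "B6":
            return self.p_b6
        if strain == "CAST":
            return self.p_cast
        raise InvalidArgumentError(f"unknown strain {strain!r}; expected 'B6' or 'CAST'")

    def true_log2fc(self) -> pd.Series:
        """True CAST-vs-B6 log2 fold change of choice probabilities per OR gene."""
        return pd.Series(np.log2(self.p_cast) - np.log2(self.p_b6),
                         index=pd.Index(self.or_genes, name="gene"))

    def to_json(self, path) -> None:
        payload = {
            "or_genes": list(self.or_genes),
            "p_b6": self.p_b6.tolist(),
            "p_cast": self.p_cast.tolist(),
            "cis_effects": dict(self.cis_effects),
            "trans_genes": sorted(self.trans_genes),
            "informative_fraction": np.asarray(self.informative_fraction).tolist(),
            "marker_baseline": dict(self.marker_baseline),
            "background_genes": list(self.background_genes),
            "background_weights": np.asarray(self.background_weights).tolist(),
            "background_relative": self.background_relative,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, path) -> "RepertoireModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            or_genes=d["or_genes"],
            p_b6=np.array(d["p_b6"], dtype=float),
            p_cast=np.array(d["p_cast"], dtype=float),
            cis_effects={k: float(v) for k, v in d["cis_effects"].items()},
            trans_genes=frozenset(d["trans_genes"]),
            informative_fraction=np.array(d["informative_fraction"], dtype=float),
            marker_baseline=d["marker_baseline"],
            background_genes=d["background_genes"],
            background_weights=np.array(d["background_weights"], dtype=float),
            background_relative=float(d["background_relative"]),
        )


@dataclass
class SimulationConfig:
    """Sampling conditions for one simulated experiment.

    ``depth`` is the expected number of OR-assigned fragments per sample at
    full OSN content; ``dispersion`` the negative-binomial overdispersion
    alpha (var = m + alpha*m^2 marginally per gene); ``osn_fraction_range``
    the interval from which each sample's OSN content is drawn.
    """

    n_replicates: int = 3
    depth: float = 2e6
    dispersion: float = 0.05
    osn_fraction_range: tuple[float, float] = (0.3, 0.9)
    lognormal_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise InvalidArgumentError("depth must be > 0")
        if self.dispersion < 0:
            raise InvalidArgumentError("dispersion must be >= 0")
        lo, hi = self.osn_fraction_range
        if not (0 < lo <= hi <= 1):
            raise InvalidArgumentError("osn_fraction_range must lie in (0, 1]")
        if self.n_replicates < 1:
            raise InvalidArgumentError("n_replicates must be >= 1")


def build_repertoire_model(
    n_genes: int = 1000,
    sigma: float = 2.0,
    cis_fraction: float = 0.3,
    cis_sd: float = 1.5,
    trans_fraction: float = 0.0,
    trans_sd: float = 1.5,
    informative_range: tuple[float, float] = (0.2, 0.8),
    n_background: int = 2000,
    background_sigma: float = 1.0,
    background_relative: float = 1.5,
    marker_baseline: dict[str, float] | None = None,
    seed: int = 0,
) -> RepertoireModel:
    """Draw a ground-truth repertoire.

    ``cis_fraction`` of genes receive a cis log2 effect ~ Normal(0, cis_sd^2)
    on their CAST choice probability; a disjoint ``trans_fraction`` receive
    a strain difference of the same form whose F1 alleles will be equalized.
    """
    rng = _child_rng(seed, _MODEL_KEY)
    p_b6 = draw_choice_probabilities(n_genes, sigma, seed)
    or_genes = [f"Olfr{i + 1:04d}" for i in range(n_genes)]

    n_cis = int(round(cis_fraction * n_genes))
    n_trans = int(round(trans_fraction * n_genes))
    if n_cis + n_trans > n_genes:
        raise InvalidArgumentError("cis_fraction + trans_fraction exceeds 1")
    perm = rng.permutation(n_genes)
    cis_idx = perm[:n_cis]
    trans_idx = perm[n_cis:n_cis + n_trans]

    log2_effect = np.zeros(n_genes)
    log2_effect[cis_idx] = rng.normal(0.0, cis_sd, n_cis)
    log2_effect[trans_idx] = rng.normal(0.0, trans_sd, n_trans)
    p_cast = p_b6 * np.exp2(log2_effect)
    p_cast = p_cast / p_cast.sum()

    lo, hi = informative_range
    pi = rng.uniform(lo, hi, n_genes)

    bg_genes = [f"Gene{i + 1:05d}" for i in range(n_background)]
    bg_w = np.exp(background_sigma * rng.standard_normal(n_background))
    bg_w = bg_w / bg_w.sum() if n_background else bg_w

    return RepertoireModel(
        or_genes=or_genes,
        p_b6=p_b6,
        p_cast=p_cast,
        cis_effects={or_genes[i]: float(log2_effect[i]) for i in cis_idx},
        trans_genes=frozenset(or_genes[i] for i in trans_idx),
        informative_fraction=pi,
        marker_baseline=dict(marker_baseline or DEFAULT_MARKER_BASELINE),
        background_genes=bg_genes,
        background_weights=bg_w,
        background_relative=background_relative,
    )


def _sample_conditions(rng: np.random.Generator, config: SimulationConfig):
    """Per-replicate OSN fraction and shared library factor."""
    lo, hi = config.osn_fraction_range
    osn = rng.uniform(lo, hi, config.n_replicates)
    if config.dispersion > 0:
        lib = rng.gamma(1.0 / config.dispersion, config.dispersion, config.n_replicates)
    else:
        lib = np.ones(config.n_replicates)
    return osn, lib


def _assemble_matrix(model, or_counts, marker_counts, bg_counts, sample_ids, meta):
    genes = list(model.or_genes) + list(model.marker_baseline) + list(model.background_genes)
    counts = np.vstack([or_counts, marker_counts, bg_counts])
    df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                      columns=pd.Index(sample_ids, name="sample"))
    classes = infer_gene_classes(genes, markers=model.marker_baseline)
    return CountMatrix(df, classes, meta)


def simulate_parental_counts(
    model: RepertoireModel, strain: str, config: SimulationConfig
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate WOM count replicates for one parental strain.

    Returns the matrix and a ground-truth table with each replicate's OSN
    fraction and library factor.  OR and marker means scale with the
    sample's OSN fraction; background genes do not.
    """
    p = model.strain_probabilities(strain)
    rng = _child_rng(config.seed, _STRAIN_KEY[strain])
    osn, lib = _sample_conditions(rng, config)
    depth = config.depth * lib

    or_mean = np.outer(p, depth * osn)
    marker_vals = np.array([model.marker_baseline[m] for m in model.marker_baseline])
    marker_mean = np.outer(marker_vals, depth * osn)
    bg_mean = np.outer(model.background_weights,
                       depth * model.background_relative)

    or_counts = rng.poisson(or_mean)
    marker_counts = rng.poisson(marker_mean)
    bg_counts = rng.poisson(bg_mean) if bg_mean.size else np.zeros((0, config.n_replicates), dtype=int)

    ids = [f"{strain}_{j + 1}" for j in range(config.n_replicates)]
    meta = pd.DataFrame({"strain": strain, "sex": "M", "condition": "control"},
                        index=pd.Index(ids, name="sample"))
    truth = pd.DataFrame({"osn_fraction": osn, "library_factor": lib, "depth": depth},
                         index=pd.Index(ids, name="sample"))
    return _assemble_matrix(model, or_counts, marker_counts, bg_counts, ids, meta), truth


def _f1_allele_probabilities(model: RepertoireModel, mode: str):
    """Per-gene (B6 allele, CAST allele) choice probabilities; sums to 1 overall."""
    if mode not in ("cis", "trans", "mixed"):
        raise InvalidArgumentError(f"unknown F1 mode {mode!r}")
    q1 = model.p_b6 / 2.0
    q2 = model.p_cast / 2.0
    if mode == "trans":
        equalize = np.ones(model.n_genes, dtype=bool)
    elif mode == "mixed":
        equalize = np.array([g in model.trans_genes for g in model.or_genes])
    else:
        equalize = np.zeros(model.n_genes, dtype=bool)
    avg = (q1 + q2) / 2.0
    q1 = np.where(equalize, avg, q1)
    q2 = np.where(equalize, avg, q2)
    total = q1.sum() + q2.sum()
    return q1 / total, q2 / total


def simulate_f1(
    model: RepertoireModel, config: SimulationConfig, mode: str = "cis"
) -> tuple[CountMatrix, AllelicCountTable, pd.DataFrame]:
    """Simulate F1-hybrid total counts and SNP-informative allelic counts.

    Under cis regulation each allele keeps its parental choice probability
    (halved: half the OSN pool carries each allele); under trans both
    alleles share the parental average.  The per-sample gene total is drawn
    first and split between alleles binomially — allele competition happens
    inside the same tissue and library, so sample-level noise cancels in
    the allelic ratio.
    """
    q1, q2 = _f1_allele_probabilities(model, mode)
    rng = _child_rng(config.seed, _F1_KEY)
    osn, lib = _sample_conditions(rng, config)
    depth = config.depth * lib

    gene_p = q1 + q2
    ratio = np.divide(q1, gene_p, out=np.full_like(q1, 0.5), where=gene_p > 0)
    pi = model.informative_fraction

    n = config.n_replicates
    ids = [f"F1_{j + 1}" for j in range(n)]
    total = np.empty((model.n_genes, n), dtype=np.int64)
    rows = []
    for j in range(n):
        tot_j = rng.poisson(np.outer(gene_p, depth[j] * osn[j]).ravel())
        a1_j = rng.binomial(tot_j, ratio)
        a2_j = tot_j - a1_j
        inf1 = rng.binomial(a1_j, pi)
        inf2 = rng.binomial(a2_j, pi)
        total[:, j] = tot_j
        rows.append(pd.DataFrame({
            "gene": model.or_genes,
            "sample": ids[j],
            "allele1_count": inf1,
            "allele2_count": inf2,
        }))

    marker_vals = np.array([model.marker_baseline[m] for m in model.marker_baseline])
    marker_counts = rng.poisson(np.outer(marker_vals, depth * osn))
    bg_mean = np.outer(model.background_weights, depth * model.background_relative)
    bg_counts = rng.poisson(bg_mean) if bg_mean.size else np.zeros((0, n), dtype=int)

    meta = pd.DataFrame({"strain": "B6xCAST", "sex": "M", "condition": "control"},
                        index=pd.Index(ids, name="sample"))
    matrix = _assemble_matrix(model, total, marker_counts, bg_counts, ids, meta)
    allelic = AllelicCountTable(pd.concat(rows, ignore_index=True))
    truth = pd.DataFrame({"osn_fraction": osn, "library_factor": lib, "depth": depth},
                         index=pd.Index(ids, name="sample"))
    return matrix, allelic, truth


def downsample_counts(
    matrix: CountMatrix,
    fraction: float | None = None,
    target_total: float | None = None,
    seed: int = 0,
) -> CountMatrix:
    """Binomially thin each count — the count-level equivalent of read subsampling.

    Either a common ``fraction`` in [0, 1] or a per-sample ``target_total``
    (must not exceed the current column total) fixes the thinning rate.
    """
    if (fraction is None) == (target_total is None):
        raise InvalidArgumentError("give exactly one of fraction or target_total")
    counts = matrix.counts.to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise InvalidArgumentError("downsampling requires integer counts")
        counts = counts.astype(np.int64)
    col_tot = counts.sum(axis=0)
    if fraction is not None:
        if not (0.0 <= fraction <= 1.0):
            raise InvalidArgumentError("fraction must lie in [0, 1]")
        q = np.full(counts.shape[1], float(fraction))
    else:
        if target_total < 0:
            raise InvalidArgumentError("target_total must be >= 0")
        over = col_tot < target_total
        if over.any():
            bad = matrix.samples[over].tolist()
            raise InvalidArgumentError(
                f"target_total {target_total} exceeds column total for samples {bad[:5]}")
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(col_tot > 0, target_total / np.maximum(col_tot, 1), 0.0)
    rng = _child_rng(seed, _DOWNSAMPLE_KEY)
    thinned = rng.binomial(counts, q[np.newaxis, :])
    out = pd.DataFrame(thinned, index=matrix.counts.index, columns=matrix.counts.columns)
    meta = matrix.sample_meta.copy() if matrix.sample_meta is not None else None
    return CountMatrix(out, matrix.gene_class.copy(), meta)


def simulate_cistrans_dataset(
    mode: str = "cis",
    seed: int = 1,
    n_genes: int = 1000,
    cis_fraction: float = 0.3,
    cis_sd: float = 1.5,
    informative_range: tuple[float, float] = (0.2, 0.8),
    n_background: int = 2000,
    config: SimulationConfig | None = None,
) -> dict:
    """One full study: B6 and CAST parental replicates, an F1 trio, ground truth.

    Defaults are the package's reference study conditions: 1000 OR genes,
    3 + 3 parental and 3 F1 replicates at 2e6 OR fragments per sample,
    dispersion 0.05, informative fractions uniform on (0.2, 0.8), and 30%
    of genes carrying cis log2 effects ~ Normal(0, 1.5^2).
    """
    if config is None:
        config = SimulationConfig(seed=seed)
    model = build_repertoire_model(
        n_genes=n_genes,
        sigma=config.lognormal_sigma,
        cis_fraction=cis_fraction,
        cis_sd=cis_sd,
        informative_range=informative_range,
        n_background=n_background,
        seed=seed,
    )
    b6, b6_truth = simulate_parental_counts(model, "B6", config)
    cast, cast_truth = simulate_parental_counts(model, "CAST", config)
    f1_total, f1_allelic, f1_truth = simulate_f1(model, config, mode=mode)
    return {
        "model": model,
        "config": config,
        "b6": b6,
        "cast": cast,
        "f1_total": f1_total,
        "f1_allelic": f1_allelic,
        "truth": {"B6": b6_truth, "CAST": cast_truth, "F1": f1_truth},
    }
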