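"""Generator sanity: normalization of probabilities, sampling moments, determinism."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osncistrans import (RepertoireModel, SimulationConfig,
                         build_repertoire_model, downsample_counts,
                         draw_choice_probabilities, simulate_f1,
                         simulate_parental_counts)
from osncistrans.errors import InvalidArgumentError

from conftest import make_matrix


class TestChoiceProbabilities:
    def test_zero_sigma_is_uniform(self):
        assert np.allclose(draw_choice_probabilities(4, 0.0, seed=0), 0.25)

    @given(n=st.integers(2, 500), sigma=st.floats(0, 4), seed=st.integers(0, 2**20))
    @settings(max_examples=50, deadline=None)
    def test_is_probability_vector(self, n, sigma, seed):
        p = draw_choice_probabilities(n, sigma, seed)
        assert p.shape == (n,)
        assert (p >= 0).all()
        assert abs(p.sum() - 1.0) < 1e-12

    def test_heavy_tail_few_subtypes_dominate(self):
        # at sigma=2 the top <=5% of genes carry >=25% of the repertoire
        hits = 0
        for seed in range(100):
            p = np.sort(draw_choice_probabilities(1000, 2.0, seed))[::-1]
            k = np.searchsorted(np.cumsum(p), 0.25) + 1
            hits += k <= 50
        assert hits >= 95

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            draw_choice_probabilities(1, 1.0, seed=0)
        with pytest.raises(InvalidArgumentError):
            draw_choice_probabilities(10, -0.5, seed=0)


class TestRepertoireModel:
    def test_cis_effect_applied_multiplicatively(self):
        model = build_repertoire_model(n_genes=500, cis_fraction=0.2, seed=3)
        fc = model.true_log2fc()
        # before renormalization the CAST/B6 ratio equals the drawn effect;
        # renormalization shifts all genes by one common constant
        effects = pd.Series(model.cis_effects)
        neutral = fc.drop(effects.index)
        shift = neutral.mean()
        assert neutral.std() < 1e-12
        assert np.allclose(fc[effects.index] - shift, effects, atol=1e-9)

    def test_invariants_enforced(self):
        with pytest.raises(InvalidArgumentError):
            RepertoireModel(or_genes=["a", "b"], p_b6=np.array([0.6, 0.5]),
                            p_cast=np.array([0.5, 0.5]), cis_effects={},
                            trans_genes=frozenset(),
                            informative_fraction=np.array([0.5, 0.5]))
        with pytest.raises(InvalidArgumentError):
            RepertoireModel(or_genes=["a", "b"], p_b6=np.array([0.5, 0.5]),
                            p_cast=np.array([0.5, 0.5]),
                            cis_effects={"a": 1.0}, trans_genes=frozenset(["a"]),
                            informative_fraction=np.array([0.5, 0.5]))

    def test_json_round_trip(self, tmp_path):
        model = build_repertoire_model(n_genes=50, n_background=10, seed=5)
        path = tmp_path / "truth.json"
        model.to_json(path)
        back = RepertoireModel.from_json(path)
        assert np.allclose(back.p_b6, model.p_b6)
        assert back.cis_effects == pytest.approx(model.cis_effects)


class TestParentalCounts:
    def test_poisson_limit_relative_counts(self):
        cfg = SimulationConfig(n_replicates=4, depth=1e7, dispersion=0.0,
                               osn_fraction_range=(1.0, 1.0), seed=0)
        model = build_repertoire_model(n_genes=100, sigma=0.0, cis_fraction=0.0,
                                       n_background=0, seed=0)
        mat, _ = simulate_parental_counts(model, "B6", cfg)
        p = 1.0 / 100
        rel = mat.counts.loc[model.or_genes].mean(axis=1) / 1e7
        tol = 3 * np.sqrt(p / 1e7 / 4)
        assert (np.abs(rel - p) < tol).mean() > 0.98

    def test_unknown_strain_rejected(self):
        model = build_repertoire_model(n_genes=10, seed=0)
        with pytest.raises(InvalidArgumentError):
            simulate_parental_counts(model, "129", SimulationConfig(seed=0))

    def test_column_sums_track_depth(self):
        # 50 replicates at alpha=0.05: mean OR-assigned column total within
        # 3 SE of the expected depth
        cfg = SimulationConfig(n_replicates=50, depth=1e6, dispersion=0.05,
                               osn_fraction_range=(1.0, 1.0), seed=11)
        model = build_repertoire_model(n_genes=300, sigma=1.0, cis_fraction=0.0,
                                       n_background=0, seed=11)
        mat, _ = simulate_parental_counts(model, "B6", cfg)
        or_sums = mat.counts.loc[model.or_genes].sum(axis=0).to_numpy(dtype=float)
        se = or_sums.std(ddof=1) / np.sqrt(50)
        assert abs(or_sums.mean() - 1e6) < 3 * se

    def test_ground_truth_reported(self):
        cfg = SimulationConfig(seed=2)
        model = build_repertoire_model(n_genes=20, n_background=5, seed=2)
        mat, truth = simulate_parental_counts(model, "CAST", cfg)
        assert list(truth.index) == list(mat.samples)
        assert ((truth["osn_fraction"] >= 0.3) & (truth["osn_fraction"] <= 0.9)).all()


def _two_gene_model(p_b6, p_cast, pi=1.0):
    p_b6 = np.asarray(p_b6, float)
    p_cast = np.asarray(p_cast, float)
    n = p_b6.size
    return RepertoireModel(
        or_genes=[f"Olfr{i + 1:04d}" for i in range(n)],
        p_b6=p_b6 / p_b6.sum(), p_cast=p_cast / p_cast.sum(),
        cis_effects={}, trans_genes=frozenset(),
        informative_fraction=np.full(n, pi), background_genes=[],
        background_weights=np.array([]))


class TestSimulateF1:
    def test_cis_mode_analytic_ratio(self):
        # p_b6 = 2 * p_cast for gene 1 -> allelic ratio 2/3
        model = _two_gene_model([2.0, 1.0], [1.0, 2.0])
        cfg = SimulationConfig(n_replicates=3, depth=3e6, dispersion=0.0,
                               osn_fraction_range=(1.0, 1.0), seed=4)
        _, allelic, _ = simulate_f1(model, cfg, mode="cis")
        pooled = allelic.table.groupby("gene")[["allele1_count", "allele2_count"]].sum()
        r = pooled["allele1_count"] / pooled.sum(axis=1)
        n = pooled.sum(axis=1)
        se = np.sqrt(r * (1 - r) / n)
        assert abs(r.iloc[0] - 2.0 / 3.0) < 4 * se.iloc[0]
        assert abs(r.iloc[1] - 1.0 / 3.0) < 4 * se.iloc[1]

    def test_trans_mode_equalizes_alleles(self):
        model = _two_gene_model([3.0, 1.0], [1.0, 3.0])
        cfg = SimulationConfig(n_replicates=3, depth=3e6, dispersion=0.0,
                               osn_fraction_range=(1.0, 1.0), seed=4)
        _, allelic, _ = simulate_f1(model, cfg, mode="trans")
        pooled = allelic.table.groupby("gene")[["allele1_count", "allele2_count"]].sum()
        r = pooled["allele1_count"] / pooled.sum(axis=1)
        se = np.sqrt(0.25 / pooled.sum(axis=1))
        assert (np.abs(r - 0.5) < 4 * se).all()

    def test_full_informative_fraction_conserves_counts(self):
        model = _two_gene_model([1.0, 1.0], [1.0, 1.0], pi=1.0)
        cfg = SimulationConfig(n_replicates=2, depth=1e4, dispersion=0.1, seed=9)
        total, allelic, _ = simulate_f1(model, cfg, mode="cis")
        merged = allelic.table.set_index(["gene", "sample"])
        for (gene, sample), row in merged.iterrows():
            assert row["allele1_count"] + row["allele2_count"] == \
                total.counts.loc[gene, sample]

    def test_mixed_mode_uses_model_assignment(self):
        n = 2
        model = RepertoireModel(
            or_genes=["Olfr0001", "Olfr0002"],
            p_b6=np.array([0.8, 0.2]), p_cast=np.array([0.2, 0.8]),
            cis_effects={}, trans_genes=frozenset(["Olfr0002"]),
            informative_fraction=np.ones(n), background_genes=[],
            background_weights=np.array([]))
        cfg = SimulationConfig(n_replicates=3, depth=2e6, dispersion=0.0,
                               osn_fraction_range=(1.0, 1.0), seed=6)
        _, allelic, _ = simulate_f1(model, cfg, mode="mixed")
        pooled = allelic.table.groupby("gene")[["allele1_count", "allele2_count"]].sum()
        r = pooled["allele1_count"] / pooled.sum(axis=1)
        assert r["Olfr0001"] > 0.7   # cis gene keeps the parental skew
        assert abs(r["Olfr0002"] - 0.5) < 0.05  # trans gene equalized

    def test_invalid_mode_rejected(self):
        model = _two_gene_model([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(InvalidArgumentError):
            simulate_f1(model, SimulationConfig(seed=0), mode="dominance")


class TestDownsample:
    def test_identity_and_zero_fractions(self):
        mat = make_matrix([[10, 5], [3, 7]])
        same = downsample_counts(mat, fraction=1.0, seed=0)
        assert same.counts.equals(mat.counts)
        zero = downsample_counts(mat, fraction=0.0, seed=0)
        assert (zero.counts.to_numpy() == 0).all()

    def test_binomial_moments_at_half(self):
        mat = make_matrix(np.full((20, 1), 50))
        T = 1000
        totals = [downsample_counts(mat, fraction=0.5, seed=s).counts.sum().sum()
                  for s in range(200)]
        mean = np.mean(totals)
        assert abs(mean - T / 2) < 3 * np.sqrt(0.25 * T / 200)

    def test_target_total_above_column_total_rejected(self):
        mat = make_matrix([[10], [5]])
        with pytest.raises(InvalidArgumentError):
            downsample_counts(mat, target_total=100, seed=0)

    def test_reproducible_under_seed(self):
        mat = make_matrix(np.arange(1, 13).reshape(4, 3))
        a = downsample_counts(mat, fraction=0.3, seed=42)
        b = downsample_counts(mat, fraction=0.3, seed=42)
        assert a.counts.equals(b.counts)

    def test_exactly_one_rate_argument(self):
        mat = make_matrix([[1]])
        with pytest.raises(InvalidArgumentError):
            downsample_counts(mat, fraction=0.5, target_total=1, seed=0)


class TestDeterminism:
    def test_identical_config_gives_identical_serialization(self, tmp_path):
        from osncistrans import simulate_cistrans_dataset
        from osncistrans.io import write_allelic_table, write_count_matrix

        outputs = []
        for run in range(2):
            data = simulate_cistrans_dataset(mode="cis", seed=123, n_genes=50)
            p1 = tmp_path / f"counts_{run}.tsv"
            p2 = tmp_path / f"allelic_{run}.tsv"
            write_count_matrix(data["f1_total"], p1)
            write_allelic_table(data["f1_allelic"], p2)
            outputs.append((p1.read_bytes(), p2.read_bytes()))
        assert outputs[0] == outputs[1]
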