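"""In-silico F1 construction and the deviation correction."""

import numpy as np
import pandas as pd
import pytest

from osncistrans import (build_insilico_f1, compute_deviation,
                         correct_allelic_fc)
from osncistrans.allelic import allelic_ratio
from osncistrans.errors import InvalidArgumentError
from osncistrans.stats import log2_fold_change

from conftest import make_matrix


def _parents(counts_b6, counts_cast):
    b6 = make_matrix(counts_b6, samples=[f"B6_{j}" for j in range(np.asarray(counts_b6).shape[1])])
    cast = make_matrix(counts_cast, samples=[f"CAST_{j}" for j in range(np.asarray(counts_cast).shape[1])])
    return b6, cast


class TestBuildInsilicoF1:
    def test_identical_parents_give_balanced_ratio(self):
        counts = np.full((30, 3), 2000)
        b6, cast = _parents(counts, counts)
        total, allelic = build_insilico_f1(b6, cast, f1_depths=[60000] * 3, seed=0)
        ratios, _ = allelic_ratio(allelic)
        n = ratios["informative_total"].to_numpy()
        se = np.sqrt(0.25 / n)
        assert (np.abs(ratios["r"] - 0.5) < 4 * se).all()

    def test_gene_absent_from_both_parents_stays_zero(self):
        counts = np.full((5, 2), 1000)
        counts[2, :] = 0
        b6, cast = _parents(counts, counts)
        total, allelic = build_insilico_f1(b6, cast, f1_depths=[4000] * 2, seed=1)
        gene = total.genes[2]
        assert (total.counts.loc[gene] == 0).all()
        sub = allelic.table[allelic.table["gene"] == gene]
        assert (sub[["allele1_count", "allele2_count"]].to_numpy() == 0).all()

    def test_thinning_fraction_matches_binomial_moments(self):
        # q = D/(2T): mean thinned parental contribution over 200 seeds
        counts = np.full((10, 1), 1000)  # T = 10000 per parent
        b6, cast = _parents(counts, counts)
        D = 8000.0
        contribs = []
        for seed in range(200):
            _, allelic = build_insilico_f1(b6, cast, f1_depths=[D], seed=seed)
            contribs.append(allelic.table["allele1_count"].sum())
        T = 10000
        q = D / (2 * T)
        expect = q * T
        se = np.sqrt(T * q * (1 - q) / 200)
        assert abs(np.mean(contribs) - expect) < 3 * se

    def test_unknown_pairing_sample_rejected(self):
        b6, cast = _parents(np.full((3, 1), 10), np.full((3, 1), 10))
        with pytest.raises(InvalidArgumentError):
            build_insilico_f1(b6, cast, f1_depths=[10],
                              pairing=[("nope", "CAST_0")], seed=0)

    def test_informative_fraction_thins_allelic_counts(self):
        counts = np.full((4, 1), 10000)
        b6, cast = _parents(counts, counts)
        pi = pd.Series(0.1, index=b6.or_genes)
        _, full = build_insilico_f1(b6, cast, f1_depths=[10000], seed=3)
        _, thin = build_insilico_f1(b6, cast, f1_depths=[10000], seed=3,
                                    informative_fraction=pi)
        assert thin.table["allele1_count"].sum() < 0.2 * full.table["allele1_count"].sum()


class TestComputeDeviation:
    def test_equal_fold_changes_give_zero(self):
        fc = pd.Series({"g1": 0.3, "g2": -1.2})
        dev = compute_deviation(fc, fc)
        assert np.allclose(dev.table["d"], 0.0)

    def test_simple_arithmetic(self):
        dev = compute_deviation(pd.Series({"g1": 1.5}), pd.Series({"g1": 1.0}))
        assert dev.table.loc[0, "d"] == pytest.approx(0.5)

    def test_replicates_averaged_and_counted(self):
        reps = [pd.Series({"g1": 1.0}), pd.Series({"g1": 2.0}), pd.Series({"g1": 3.0})]
        dev = compute_deviation(reps, pd.Series({"g1": 1.0}))
        assert dev.table.loc[0, "d"] == pytest.approx(1.0)
        assert dev.table.loc[0, "n"] == 3

    def test_nonoverlapping_genes_rejected(self):
        with pytest.raises(InvalidArgumentError):
            compute_deviation(pd.Series({"g1": 1.0}), pd.Series({"g2": 1.0}))

    def test_one_sided_genes_listed(self):
        dev = compute_deviation(pd.Series({"g1": 1.0, "g2": 2.0}),
                                pd.Series({"g1": 1.0, "g3": 0.0}))
        assert set(dev.omitted) == {"g2", "g3"}


class TestCorrection:
    def test_zero_deviation_is_identity(self):
        raw = pd.Series({"g1": 0.8, "g2": -0.4})
        dev = compute_deviation(raw, raw)  # d = 0
        out = correct_allelic_fc(raw, dev)
        assert np.allclose(out["allelic_log2fc_corrected"], raw.to_numpy())

    def test_subtraction(self):
        raw = pd.Series({"g1": 2.0})
        dev = compute_deviation(pd.Series({"g1": 1.5}), pd.Series({"g1": 1.0}))
        out = correct_allelic_fc(raw, dev)
        assert out.loc[0, "allelic_log2fc_corrected"] == pytest.approx(1.5)

    def test_membership_never_changes(self):
        raw = pd.Series({"g1": 1.0, "g2": 2.0, "g3": 3.0})
        dev = compute_deviation(pd.Series({"g1": 1.2}), pd.Series({"g1": 1.0}))
        out = correct_allelic_fc(raw, dev)
        assert out["gene"].tolist() == ["g1", "g2", "g3"]
        assert out["corrected_flag"].tolist() == [True, False, False]
        assert out.loc[1, "allelic_log2fc_corrected"] == pytest.approx(2.0)

    def test_correction_exact_on_the_insilico_set_itself(self):
        rng = np.random.default_rng(5)
        parental = pd.Series(rng.normal(size=10), index=[f"g{i}" for i in range(10)])
        reps = [parental + rng.normal(scale=0.3, size=10) for _ in range(6)]
        dev = compute_deviation(reps, parental)
        mean_insilico = pd.concat(reps, axis=1).mean(axis=1)
        out = correct_allelic_fc(mean_insilico, dev).set_index("gene")
        assert np.allclose(out["allelic_log2fc_corrected"],
                           parental.reindex(out.index), atol=1e-12)


class TestDeviationNull:
    def _expected_insilico_fc(self, b6_col, cast_col, q_b6, q_cast):
        """Analytic expectation of the in-silico allelic fold change."""
        a1 = q_b6 * b6_col
        a2 = q_cast * cast_col
        r = a1 / (a1 + a2)
        return np.log2(1 - r) - np.log2(r)

    def test_analytic_expectations_give_exact_zero(self):
        # at the infinite-depth limit thinning is exact scaling, so the
        # in-silico allelic fold change equals the parental one identically
        b6_col = np.array([4000.0, 1000.0, 500.0])
        cast_col = np.array([2000.0, 3000.0, 500.0])
        fc_parental = pd.Series(np.log2(cast_col) - np.log2(b6_col),
                                index=["g1", "g2", "g3"])
        fc_insilico = pd.Series(
            self._expected_insilico_fc(b6_col, cast_col, 0.5, 0.5),
            index=["g1", "g2", "g3"])
        dev = compute_deviation(fc_insilico, fc_parental)
        assert np.allclose(dev.table["d"], 0.0, atol=1e-12)

    def test_finite_depth_mean_deviation_is_unbiased(self):
        # 100 thinning seeds on fixed parental counts: per-gene mean
        # deviation within 3 SE of zero (pi = 1, no pseudocount)
        counts_b6 = np.tile([[8000], [3000], [1500], [6000]], (1, 3))
        counts_cast = np.tile([[4000], [6000], [1500], [2000]], (1, 3))
        b6, cast = _parents(counts_b6, counts_cast)
        parental = pd.Series(
            np.log2(counts_cast[:, 0]) - np.log2(counts_b6[:, 0]),
            index=b6.or_genes)
        devs = []
        for seed in range(100):
            _, allelic = build_insilico_f1(b6, cast, f1_depths=[30000] * 3,
                                           seed=seed)
            ratios, _ = allelic_ratio(allelic)
            fc = pd.Series(
                log2_fold_change(
                    (1 - ratios["r"]).to_numpy(), ratios["r"].to_numpy()),
                index=ratios["gene"].to_numpy())
            devs.append(compute_deviation(fc, parental).as_series())
        D = pd.concat(devs, axis=1)
        mean = D.mean(axis=1)
        se = D.std(axis=1, ddof=1) / np.sqrt(D.shape[1])
        assert (np.abs(mean) < 3 * se + 1e-4).all()
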