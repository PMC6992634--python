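"""TPM math, pre-filters, size factors, fold changes, the NB Wald test, DEG
calls, and ΔΔCt validation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import small_count_matrix
from transdiff.expression import (
    CountMatrix,
    call_degs,
    compute_tpm,
    ddct,
    expression_table,
    logfc,
    nb_test,
    prefilter,
    rnaseq_agreement,
    size_factors,
)

FOUR = ["stage1", "stage1", "stage2", "stage2"]


class TestTpm:
    def test_single_gene_is_one_million(self):
        cm = small_count_matrix({"g": [7, 3, 5, 9]}, FOUR)
        tpm, _ = compute_tpm(cm)
        assert np.allclose(tpm.loc["g"], 1e6)

    def test_length_normalization_closed_form(self):
        cm = small_count_matrix(
            {"short": [10, 10, 10, 10], "long": [10, 10, 10, 10]},
            FOUR,
            eff_length={"short": 500.0, "long": 1000.0},
        )
        tpm, _ = compute_tpm(cm)
        assert np.allclose(tpm.loc["short"], 2e6 / 3)
        assert np.allclose(tpm.loc["long"], 1e6 / 3)

    def test_scale_invariance_and_unit_sum(self):
        rng = np.random.default_rng(0)
        counts = {f"g{i}": list(rng.integers(1, 100, 4)) for i in range(30)}
        cm = small_count_matrix(counts, FOUR)
        doubled = small_count_matrix({g: [2 * c for c in v] for g, v in counts.items()}, FOUR)
        tpm, _ = compute_tpm(cm)
        tpm2, _ = compute_tpm(doubled)
        assert np.allclose(tpm, tpm2)
        assert np.allclose(tpm.sum(axis=0), 1e6)

    def test_all_zero_sample_rejected(self):
        cm = small_count_matrix({"g1": [0, 1, 1, 1], "g2": [0, 2, 2, 2]}, FOUR)
        with pytest.raises(ValueError, match="all-zero"):
            compute_tpm(cm)


class TestPrefilter:
    def test_total_reads_strictly_above_50(self):
        cm = small_count_matrix({"low": [10, 10, 10, 10], "edge": [13, 13, 12, 12]}, FOUR)
        survivors = prefilter(cm)
        assert "low" not in survivors  # total 40
        assert "edge" not in survivors  # total 50, not strictly above

    def test_coverage_rule(self):
        # 60 reads x 100 nt / 300 nt = 20x > 10: passes; same reads on a
        # 10,000 nt gene give 0.6x: fails
        cm = small_count_matrix(
            {"short": [15, 15, 15, 15], "long": [15, 15, 15, 15]},
            FOUR,
            eff_length={"short": 300.0, "long": 10000.0},
        )
        survivors = prefilter(cm)
        assert survivors == {"short"}

    def test_zero_condition_excludes_gene(self):
        cm = small_count_matrix({"g": [300, 300, 0, 0], "ok": [150, 150, 150, 150]}, FOUR)
        assert prefilter(cm) == {"ok"}
        assert prefilter(cm, zero_rule="off") == {"g", "ok"}

    def test_per_sample_zero_rule_is_stricter(self):
        cm = small_count_matrix({"g": [300, 0, 300, 300]}, FOUR)
        assert "g" in prefilter(cm, zero_rule="condition")
        assert "g" not in prefilter(cm, zero_rule="sample")

    def test_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(1)
        counts = {f"g{i}": list(rng.integers(0, 60, 4)) for i in range(50)}
        cm = small_count_matrix(counts, FOUR, eff_length=400.0)
        base = prefilter(cm)
        assert prefilter(cm, min_total=80) <= base
        assert prefilter(cm, min_cov=20) <= base


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = small_count_matrix({f"g{i}": [i + 1] * 4 for i in range(10)}, FOUR)
        assert np.allclose(size_factors(cm.counts), 1.0)

    def test_doubled_sample_gets_factor_two(self):
        counts = pd.DataFrame(
            {"a": [10, 20, 30], "b": [10, 20, 30], "c": [20, 40, 60]},
            index=["g1", "g2", "g3"],
        )
        sf = size_factors(counts)
        assert sf["c"] == pytest.approx(2.0 * sf["a"])
        assert sf["a"] == pytest.approx(sf["b"])

    def test_single_sample_factor_one(self):
        counts = pd.DataFrame({"only": [5, 9, 2]}, index=["g1", "g2", "g3"])
        assert np.allclose(size_factors(counts), 1.0)

    def test_no_zero_free_gene_falls_back_with_warning(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]}, index=["g1", "g2"])
        with pytest.warns(UserWarning, match="library-size"):
            sf = size_factors(counts)
        assert (sf > 0).all()

    def test_agrees_with_pydeseq2_reference(self):
        """Independent cross-check of the median-of-ratios math."""
        pydeseq2_pp = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(80, 4)),
            index=[f"g{i}" for i in range(80)],
            columns=list("abcd"),
        )
        mine = size_factors(counts)
        _, theirs = pydeseq2_pp.deseq2_norm(counts.T)
        assert np.allclose(mine.values, np.asarray(theirs).ravel(), rtol=1e-10)


class TestLogfc:
    def test_equal_means_zero(self):
        cm = small_count_matrix({"g": [30, 30, 30, 30]}, FOUR)
        assert logfc(cm, ("stage2", "stage1"))["g"] == 0.0

    def test_pseudocount_closed_form(self):
        cm = small_count_matrix({"g": [40, 40, 10, 10], "ref": [100] * 4}, FOUR)
        unit = pd.Series(1.0, index=cm.counts.columns)
        lfc = logfc(cm, ("stage1", "stage2"), factors=unit)
        assert lfc["g"] == pytest.approx(np.log2(40.5 / 10.5))

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        counts = {f"g{i}": list(rng.integers(1, 200, 4)) for i in range(40)}
        cm = small_count_matrix(counts, FOUR)
        ab = logfc(cm, ("stage1", "stage2"))
        ba = logfc(cm, ("stage2", "stage1"))
        assert np.allclose(ab, -ba)


class TestNbTest:
    def test_identical_counts_give_p_one(self):
        cm = small_count_matrix({"g": [25, 25, 25, 25]}, FOUR)
        assert nb_test(cm, ("stage2", "stage1"))["g"] == 1.0

    def test_needs_two_replicates(self):
        cm = small_count_matrix({"g": [5, 5]}, ["stage1", "stage2"])
        with pytest.raises(ValueError, match="replicates"):
            nb_test(cm, ("stage2", "stage1"))

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(21)
        n = 4000
        mu = np.exp(rng.uniform(np.log(20), np.log(500), n))
        draw = rng.negative_binomial(20, 20 / (20 + mu[:, None]), size=(n, 4))
        cm = CountMatrix(
            pd.DataFrame(draw, index=[f"g{i}" for i in range(n)], columns=["a", "b", "c", "d"]),
            pd.DataFrame(
                {"condition": FOUR, "replicate": [1, 2, 1, 2]}, index=["a", "b", "c", "d"]
            ),
            pd.Series(1000.0, index=[f"g{i}" for i in range(n)]),
        )
        p = nb_test(cm, ("stage2", "stage1"), factors=pd.Series(1.0, index=list("abcd")))
        assert stats.kstest(p, "uniform").statistic < 0.05

    def test_power_on_planted_twofold_genes(self):
        """Planted logFC 2 at mean 200, dispersion 0.05: Monte-Carlo power at
        alpha 0.05 sits near 0.78 under the calibrated t reference (a normal
        reference would be more powerful but anticonservative under the null)."""
        rng = np.random.default_rng(22)
        n = 1000
        mu = np.column_stack([np.full(n, 200.0)] * 2 + [np.full(n, 800.0)] * 2)
        draw = rng.negative_binomial(20, 20 / (20 + mu))
        genes = [f"g{i}" for i in range(n)]
        cm = CountMatrix(
            pd.DataFrame(draw, index=genes, columns=["a", "b", "c", "d"]),
            pd.DataFrame(
                {"condition": FOUR, "replicate": [1, 2, 1, 2]}, index=["a", "b", "c", "d"]
            ),
            pd.Series(1000.0, index=genes),
        )
        p = nb_test(cm, ("stage2", "stage1"), factors=pd.Series(1.0, index=list("abcd")))
        assert (p < 0.05).mean() > 0.75


class TestCallDegs:
    @pytest.mark.parametrize(
        "lfc,p,in_up",
        [(1.2, 0.01, True), (1.2, 0.06, False), (0.9, 1e-9, False)],
    )
    def test_gates(self, lfc, p, in_up):
        up, down = call_degs(pd.Series({"g": lfc}), pd.Series({"g": p}))
        assert (("g" in up) is in_up) and not down

    def test_up_down_disjoint(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(200)]
        lfc = pd.Series(rng.normal(0, 2, 200), index=genes)
        p = pd.Series(rng.uniform(0, 1, 200), index=genes)
        up, down = call_degs(lfc, p)
        assert not up & down


def ct_rows(values):
    return pd.DataFrame(values, columns=["gene", "condition", "replicate", "ct"])


class TestDdct:
    def test_flat_target_has_unit_relative_expression(self):
        rows = []
        for cond in ("stage1", "stage2", "stage3"):
            for rep in (1, 2, 3):
                rows += [
                    ("Tubulin", cond, rep, 15.0),
                    ("EF1a", cond, rep, 16.0),
                    ("tgt", cond, rep, 22.0),
                ]
        rel = ddct(ct_rows(rows), ["tgt"])
        assert np.allclose(rel.loc["tgt"], 1.0)

    def test_two_cycle_drop_is_fourfold(self):
        rows = []
        for cond, ct in (("stage1", 22.0), ("stage2", 20.0), ("stage3", 22.0)):
            for rep in (1, 2, 3):
                rows += [
                    ("Tubulin", cond, rep, 15.0),
                    ("EF1a", cond, rep, 16.0),
                    ("tgt", cond, rep, ct),
                ]
        rel = ddct(ct_rows(rows), ["tgt"])
        assert rel.loc["tgt", "stage2"] == pytest.approx(4.0)
        assert rel.loc["tgt", "stage1"] == pytest.approx(1.0)

    def test_reference_shift_cancels(self):
        # both references drift by +1 cycle in stage2: targets unaffected
        rows = []
        for cond in ("stage1", "stage2"):
            shift = 1.0 if cond == "stage2" else 0.0
            for rep in (1, 2):
                rows += [
                    ("Tubulin", cond, rep, 15.0 + shift),
                    ("EF1a", cond, rep, 16.0 + shift),
                    ("tgt", cond, rep, 22.0 + shift),
                ]
        rel = ddct(ct_rows(rows), ["tgt"])
        assert rel.loc["tgt", "stage2"] == pytest.approx(1.0)

    def test_missing_reference_rejected(self):
        rows = [("EF1a", "stage1", 1, 16.0), ("tgt", "stage1", 1, 22.0)]
        with pytest.raises(ValueError, match="Tubulin"):
            ddct(ct_rows(rows), ["tgt"])


def test_rnaseq_agreement_perfect_when_vectors_coincide():
    v = np.array([1.2, -0.5, 2.0, 0.3, -1.1])
    fit = rnaseq_agreement(v, v)
    assert fit["r_squared"] == pytest.approx(1.0)
    assert fit["slope"] == pytest.approx(1.0)


def test_expression_table_shape_and_columns():
    rng = np.random.default_rng(6)
    counts = {f"g{i}": list(rng.integers(5, 300, 8)) for i in range(25)}
    cm = small_count_matrix(
        counts, ["intact", "intact", "stage1", "stage1", "stage2", "stage2", "stage3", "stage3"]
    )
    table = expression_table(cm, [("stage2", "stage1"), ("stage2", "stage3")])
    assert {"tpm_intact", "tpm_stage2", "logfc_stage2_vs_stage1", "p_stage2_vs_stage3"} <= set(
        table.columns
    )
    assert ((table.filter(like="p_") >= 0) & (table.filter(like="p_") <= 1)).all().all()
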