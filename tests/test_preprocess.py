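"""Preprocessing against brute-force oracles and hand-computed cases."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rmsrepurpose as rr
from rmsrepurpose.preprocess import CN_FLOOR


def _frame(values, columns, index=None):
    values = np.asarray(values, dtype=float)
    index = index or [f"c{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=index, columns=columns)


class TestCollapseTranscripts:
    def test_mean_of_two_transcripts(self):
        m = _frame([[2.0, 4.0]], ["t1", "t2"])
        out = rr.collapse_transcripts(m, {"t1": "G", "t2": "G"})
        assert out.loc["c0", "G"] == pytest.approx(3.0)

    def test_one_to_one_is_renaming(self):
        m = _frame([[1.0, 2.0], [3.0, 4.0]], ["t1", "t2"])
        out = rr.collapse_transcripts(m, {"t1": "A", "t2": "B"})
        assert list(out.columns) == ["A", "B"]
        np.testing.assert_allclose(out.to_numpy(), m.to_numpy())

    def test_matches_brute_force_group_mean(self, rng):
        m = _frame(rng.normal(size=(4, 5)), [f"t{i}" for i in range(5)])
        mapping = {"t0": "A", "t1": "B", "t2": "A", "t3": "C", "t4": "A"}
        out = rr.collapse_transcripts(m, mapping)
        for symbol in ("A", "B", "C"):
            members = [t for t, s in mapping.items() if s == symbol]
            expected = m[members].to_numpy().mean(axis=1)
            np.testing.assert_allclose(out[symbol].to_numpy(), expected)

    def test_unmapped_transcripts_dropped(self):
        m = _frame([[1.0, 2.0, 9.0]], ["t1", "t2", "t3"])
        out = rr.collapse_transcripts(m, {"t1": "A", "t2": "A"})
        assert list(out.columns) == ["A"]

    def test_errors(self):
        m = _frame([[1.0]], ["t1"])
        with pytest.raises(ValueError):
            rr.collapse_transcripts(m, {})
        with pytest.raises(ValueError):
            rr.collapse_transcripts(m, {"other": "G"})

    def test_one_to_one_preserves_cell_mean(self, rng):
        m = _frame(rng.normal(size=(3, 6)), [f"t{i}" for i in range(6)])
        out = rr.collapse_transcripts(m, {f"t{i}": f"G{i}" for i in range(6)})
        np.testing.assert_allclose(out.mean(axis=1), m.mean(axis=1))


class TestVarianceFilter:
    def test_keeps_top_two_of_ten(self, rng):
        m = _frame(rng.normal(size=(20, 10)) * np.arange(1, 11), list("abcdefghij"))
        out = rr.variance_filter(m, 0.2)
        assert list(out.columns) == ["i", "j"]

    def test_keep_all_is_identity(self, rng):
        m = _frame(rng.normal(size=(5, 4)), list("abcd"))
        pd.testing.assert_frame_equal(rr.variance_filter(m, 1.0), m)

    def test_tie_at_cutoff_prefers_earlier_gene(self):
        # b and c have identical variance; only one fits -> keep b
        m = _frame([[0.0, 1.0, 1.0], [10.0, 3.0, 3.0]], ["a", "b", "c"])
        out = rr.variance_filter(m, 2 / 3)
        assert list(out.columns) == ["a", "b"]

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 10))
    def test_matches_sort_oracle(self, seed, k10):
        rng = np.random.default_rng(seed)
        n_genes = 12
        m = _frame(rng.normal(size=(6, n_genes)) * rng.uniform(0.1, 3, n_genes),
                   [f"g{i}" for i in range(n_genes)])
        frac = k10 / 10
        out = rr.variance_filter(m, frac)
        k = math.ceil(frac * n_genes)
        variances = m.var(axis=0, ddof=1)
        expected = set(
            sorted(m.columns, key=lambda g: (-variances[g], list(m.columns).index(g)))[:k]
        )
        assert set(out.columns) == expected
        assert list(out.columns) == [g for g in m.columns if g in expected]

    def test_rejects_bad_fraction_and_tiny_input(self, rng):
        m = _frame(rng.normal(size=(5, 4)), list("abcd"))
        with pytest.raises(ValueError):
            rr.variance_filter(m, 0.0)
        with pytest.raises(ValueError):
            rr.variance_filter(m.iloc[:1], 0.5)


class TestBinarizeCopyNumber:
    def test_copy_neutral(self):
        rec = rr.binarize_copy_number(2, 2, 2.0)
        assert rec.log_ratio == 0.0 and rec.binary_call == 0

    def test_magnitude_tie_keeps_max_derived_ratio(self):
        rec = rr.binarize_copy_number(1, 4, 2.0)
        assert rec.log_ratio == pytest.approx(1.0)  # +1, not -1
        assert rec.binary_call == 1

    def test_zero_copies_floored(self):
        rec = rr.binarize_copy_number(0, 2, 2.0)
        assert rec.log_ratio == pytest.approx(math.log2(CN_FLOOR / 2.0))  # -3
        assert rec.binary_call == 1

    def test_scale_consistency(self):
        a = rr.binarize_copy_number(3, 5, 2.0)
        b = rr.binarize_copy_number(6, 10, 4.0)
        assert a.log_ratio == pytest.approx(b.log_ratio)

    def test_rejects_negative_and_inverted(self):
        with pytest.raises(ValueError):
            rr.binarize_copy_number(-1, 2, 2.0)
        with pytest.raises(ValueError):
            rr.binarize_copy_number(4, 2, 2.0)
        with pytest.raises(ValueError):
            rr.binarize_copy_number(2, 2, 0.0)

    def test_vectorized_matches_scalar(self, small_panel):
        panel, _, _ = small_panel
        calls = rr.CopyNumberBinarizer().transform(panel)
        for cell in panel.cell_ids[:5]:
            for gene in panel.cn_min.columns[:5]:
                rec = rr.binarize_copy_number(
                    int(panel.cn_min.loc[cell, gene]),
                    int(panel.cn_max.loc[cell, gene]),
                    float(panel.ploidy[cell]),
                )
                assert calls.loc[cell, gene] == rec.binary_call


class TestMutationMatrix:
    def test_silent_only_gives_zeros(self):
        variants = pd.DataFrame(
            {"cell_line": ["c1"], "gene": ["G"], "consequence": ["silent"]}
        )
        out = rr.build_mutation_matrix(variants, cell_ids=["c1"], gene_ids=["G"])
        assert out.to_numpy().sum() == 0

    def test_single_missense(self):
        variants = pd.DataFrame(
            {"cell_line": ["c1"], "gene": ["G"], "consequence": ["missense"]}
        )
        out = rr.build_mutation_matrix(variants, cell_ids=["c1", "c2"], gene_ids=["G", "H"])
        assert out.to_numpy().sum() == 1 and out.loc["c1", "G"] == 1

    def test_matches_per_pair_any_oracle(self):
        variants = pd.DataFrame(
            {
                "cell_line": ["c1", "c1", "c2", "c2", "c3", "c3"],
                "gene": ["G", "G", "H", "G", "H", "H"],
                "consequence": ["silent", "missense", "frameshift",
                                "silent", "nonsense", "silent"],
            }
        )
        cells, genes = ["c1", "c2", "c3"], ["G", "H"]
        out = rr.build_mutation_matrix(variants, cell_ids=cells, gene_ids=genes)
        for c in cells:
            for g in genes:
                expected = int(
                    any(
                        (row.cell_line == c and row.gene == g and row.consequence != "silent")
                        for row in variants.itertuples()
                    )
                )
                assert out.loc[c, g] == expected

    def test_unknown_consequence_strict_vs_warn(self):
        variants = pd.DataFrame(
            {"cell_line": ["c1"], "gene": ["G"], "consequence": ["splice_site"]}
        )
        with pytest.raises(ValueError):
            rr.build_mutation_matrix(variants, strict=True)
        out = rr.build_mutation_matrix(variants, cell_ids=["c1"], gene_ids=["G"])
        assert out.loc["c1", "G"] == 1  # kept as protein-affecting


class TestAlignPanels:
    def test_identical_sets_unchanged(self, small_panel):
        panel, _, _ = small_panel
        a, b = rr.align_panels(panel, panel.copy())
        assert list(a.expression.columns) == list(panel.expression.columns)
        assert list(b.expression.columns) == list(panel.expression.columns)

    def test_partial_overlap_keeps_shared_in_order(self, small_panel):
        panel, _, _ = small_panel
        genes = list(panel.expression.columns)
        other = panel.copy()
        shared = genes[1:4]
        other.expression = other.expression[shared]
        other.cn_min = other.cn_min[shared]
        other.cn_max = other.cn_max[shared]
        a, b = rr.align_panels(panel, other)
        assert list(a.expression.columns) == shared
        assert list(b.expression.columns) == shared

    def test_disjoint_sets_error(self, small_panel):
        panel, _, _ = small_panel
        other = panel.copy()
        renamed = {g: f"X_{g}" for g in other.expression.columns}
        other.expression = other.expression.rename(columns=renamed)
        other.cn_min = other.cn_min.rename(columns=renamed)
        other.cn_max = other.cn_max.rename(columns=renamed)
        with pytest.raises(ValueError):
            rr.align_panels(panel, other)
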