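"""Confusion matrices, mismatch typing, summaries, and paired tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from fueltyping.agreement_stats import (
    AgreementResult,
    categorical_agreement,
    confusion,
    frequent_mismatches,
    mismatch_type,
    paired_t_from_summary,
    paired_t_one_sided,
    per_type_mismatch,
    round_half_away,
    suitability_summary,
    vectors_from_mismatch_counts,
)
from fueltyping.errors import DegenerateInputError, PairingError, TraitError
from fueltyping.plot_model import PlotLabels, TraitTable


class TestConfusion:
    def test_identical_vectors_diagonal(self):
        v = ["C-3", "C-7", "C-3", "O-1a"]
        cm = confusion(v, v)
        assert cm.agreement == 1.0
        assert np.trace(cm.counts) == cm.n == 4

    def test_fully_disjoint(self):
        cm = confusion(["C-7"] * 10, ["O-1a"] * 10)
        assert cm.agreement == 0.0
        assert cm.counts.sum() == 10
        assert int(cm.counts[cm.labels.index("C-7"), cm.labels.index("O-1")]) == 10

    def test_collapsed_vocabulary(self):
        cm = confusion(["O-1a", "O-1b"], ["O-1b", "O-1a"])
        assert cm.labels == ("O-1",)
        assert cm.agreement == 1.0

    def test_length_mismatch(self):
        with pytest.raises(PairingError):
            confusion(["C-3"], ["C-3", "C-7"])

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(5)
        vocab = ["C-3", "C-7", "M-2", "O-1b"]
        a = [vocab[i] for i in rng.integers(0, 4, 60)]
        b = [vocab[i] for i in rng.integers(0, 4, 60)]
        ab, ba = confusion(a, b), confusion(b, a)
        assert ab.labels == ba.labels
        assert np.array_equal(ab.counts.T, ba.counts)

    def test_conservation_law(self):
        rng = np.random.default_rng(6)
        vocab = ["C-3", "C-7", "O-1a", "NF"]
        a = [vocab[i] for i in rng.integers(0, 4, 100)]
        b = [vocab[i] for i in rng.integers(0, 4, 100)]
        cm = confusion(a, b)
        mism = per_type_mismatch(cm)
        assert np.trace(cm.counts) + sum(c for c, _ in mism.values()) == cm.n


class TestPerTypeMismatch:
    @pytest.mark.parametrize(
        "row_total,diagonal,count,pct",
        [(28, 8, 20, 71), (30, 9, 21, 70), (10, 10, 0, 0)],
    )
    def test_row_arithmetic(self, row_total, diagonal, count, pct):
        pred = ["C-7"] * row_total
        ref = ["C-7"] * diagonal + ["O-1a"] * (row_total - diagonal)
        cm = confusion(pred, ref)
        assert per_type_mismatch(cm)["C-7"] == (count, pct)

    def test_absent_types_omitted(self):
        cm = confusion(["C-3"], ["C-7"])
        assert "C-7" not in per_type_mismatch(cm)  # no predicted C-7 plots


class TestFrequentMismatches:
    def test_threshold_inclusion(self):
        pred = ["C-7"] * 12 + ["C-3"] * 2
        ref = ["O-1a"] * 12 + ["C-7"] * 2
        out = frequent_mismatches(confusion(pred, ref), threshold=3)
        assert out == [("C-7", "O-1", 12)]

    def test_all_below_threshold_empty(self):
        cm = confusion(["C-3", "C-7"], ["C-7", "C-3"])
        assert frequent_mismatches(cm, threshold=3) == []

    def test_threshold_one_equals_brute_force(self):
        rng = np.random.default_rng(9)
        vocab = ["C-3", "C-7", "M-2", "O-1b", "S-1"]
        a = [vocab[i] for i in rng.integers(0, 5, 200)]
        b = [vocab[i] for i in rng.integers(0, 5, 200)]
        cm = confusion(a, b)
        listed = frequent_mismatches(cm, threshold=1)
        # brute-force enumeration oracle over the raw pairs
        from collections import Counter

        expected = Counter(
            (x if x != "O-1b" else "O-1", y if y != "O-1b" else "O-1")
            for x, y in zip(a, b) if x != y
        )
        assert {(p, r): c for p, r, c in listed} == dict(expected)
        assert sum(c for _, _, c in listed) == cm.n - np.trace(cm.counts)
        # sorted by count desc, ties lexicographic
        keys = [(-c, p, r) for p, r, c in listed]
        assert keys == sorted(keys)


class TestMismatchType:
    def test_structure_only(self, traits):
        assert mismatch_type("C-3", "C-4", traits) == "structure"

    def test_none_on_equal_codes(self, traits):
        assert mismatch_type("C-7", "C-7", traits) == "none"
        assert mismatch_type("O-1a", "O-1b", traits) == "none"  # collapse first

    def test_structure_and_composition(self, traits):
        assert mismatch_type("C-7", "O-1a", traits) == "structure_and_composition"

    def test_symmetric(self, traits):
        codes = ["C-3", "C-4", "C-7", "D-2", "M-2", "S-1", "O-1a", "NF"]
        for a in codes:
            for b in codes:
                assert mismatch_type(a, b, traits) == mismatch_type(b, a, traits)
                none = mismatch_type(a, b, traits) == "none"
                from fueltyping.plot_model import collapse_code

                assert none == (collapse_code(a) == collapse_code(b))

    def test_code_missing_from_traits(self):
        tiny = TraitTable({"C-3": ("closed-mature", "pine")})
        with pytest.raises(TraitError):
            mismatch_type("C-3", "C-7", tiny)


class TestSuitabilitySummary:
    @staticmethod
    def _labels(counts):
        flags = {
            "acceptable": (True, True),
            "composition_mismatch": (True, False),
            "structure_mismatch": (False, True),
            "structure_and_composition_mismatch": (False, False),
        }
        out = []
        i = 0
        for cat, n in counts.items():
            for _ in range(n):
                s, c = flags[cat]
                out.append(PlotLabels(f"p{i}", "C-3", "C-3", "C-3", "C-3",
                                      structure_match=s, composition_match=c))
                i += 1
        return out

    def test_study_partition(self):
        labels = self._labels({
            "acceptable": 32, "composition_mismatch": 22,
            "structure_mismatch": 2, "structure_and_composition_mismatch": 20,
        })
        out = suitability_summary(labels)
        assert out["acceptable"] == (32, 42.1)
        assert out["composition_mismatch"] == (22, 28.9)
        assert out["structure_mismatch"] == (2, 2.6)
        assert out["structure_and_composition_mismatch"] == (20, 26.3)

    def test_all_acceptable(self):
        out = suitability_summary(self._labels({"acceptable": 10}))
        assert out["acceptable"] == (10, 100.0)
        assert out["structure_mismatch"] == (0, 0.0)

    @given(st.lists(st.integers(0, 50), min_size=4, max_size=4).filter(lambda v: sum(v) > 0))
    @settings(max_examples=40, deadline=None)
    def test_rounded_percents_sum_near_100(self, counts):
        cats = ["acceptable", "composition_mismatch", "structure_mismatch",
                "structure_and_composition_mismatch"]
        out = suitability_summary(self._labels(dict(zip(cats, counts))))
        total_pct = sum(p for _, p in out.values())
        assert 99.7 <= total_pct <= 100.3  # one-decimal rounding drift only


class TestPairedT:
    def test_summary_route_study_values(self):
        r = paired_t_from_summary(9.4, 19.7, 76)
        assert r.df == 75
        assert round_half_away(r.t, 1) == 4.2
        assert r.p_one_sided < 0.0001

    def test_raw_and_summary_routes_agree(self):
        rng = np.random.default_rng(17)
        f = rng.normal(50, 10, 40)
        inv = f - rng.normal(5, 8, 40)
        raw = paired_t_one_sided(f, inv)
        summ = paired_t_from_summary(raw.mean_diff, raw.sd_diff, raw.n)
        assert raw.t == pytest.approx(summ.t, rel=1e-10)
        assert raw.p_one_sided == pytest.approx(summ.p_one_sided, rel=1e-10)

    def test_against_scipy_oracle(self):
        rng = np.random.default_rng(23)
        f = rng.normal(30, 5, 60)
        inv = f - rng.normal(2, 6, 60)
        r = paired_t_one_sided(f, inv, direction="greater")
        ref = sps.ttest_rel(f, inv, alternative="greater")
        assert r.t == pytest.approx(ref.statistic, rel=1e-12)
        assert r.p_one_sided == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_t_one_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_tiny_n_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_t_from_summary(1.0, 1.0, 1)

    def test_shift_invariance_and_sign_flip(self):
        rng = np.random.default_rng(29)
        f = rng.normal(0, 1, 30)
        inv = f - rng.normal(1, 1, 30)
        base = paired_t_one_sided(f, inv)
        shifted = paired_t_one_sided(f + 100.0, inv + 100.0)
        assert base.t == pytest.approx(shifted.t, rel=1e-9)
        flipped = paired_t_one_sided(inv, f)
        assert flipped.t == pytest.approx(-base.t, rel=1e-9)

    def test_zero_mean_diff_p_half(self):
        r = paired_t_from_summary(0.0, 5.0, 20)
        assert r.t == 0.0
        assert r.p_one_sided == pytest.approx(0.5)


class TestCategoricalAgreement:
    @pytest.mark.parametrize("agree,n,pct", [(44, 76, 58), (34, 76, 45)])
    def test_percent_rounding(self, agree, n, pct):
        a = ["x"] * n
        b = ["x"] * agree + ["y"] * (n - agree)
        out = categorical_agreement(a, b)
        assert out == AgreementResult(agree, n, agree / n, pct)

    def test_disjoint_vocabularies(self):
        assert categorical_agreement(["a"] * 5, ["b"] * 5).percent == 0

    def test_length_mismatch(self):
        with pytest.raises(PairingError):
            categorical_agreement(["a"], ["a", "b"])


class TestVectorReconstruction:
    def test_counts_realized_exactly(self):
        pred, ref = vectors_from_mismatch_counts(
            {"C-7": 28, "O-1": 30, "C-3": 3}, {"C-7": 20, "O-1": 21, "C-3": 2}
        )
        cm = confusion(pred, ref)
        mism = per_type_mismatch(cm)
        assert mism["C-7"] == (20, 71)
        assert mism["O-1"] == (21, 70)
        assert mism["C-3"] == (2, 67)

    def test_overfull_mismatch_rejected(self):
        with pytest.raises(PairingError):
            vectors_from_mismatch_counts({"C-3": 2}, {"C-3": 5})
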