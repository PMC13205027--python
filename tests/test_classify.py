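"""Threshold classification, RECIST mapping and concordance tables."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from organoidtrack.classify import (
    DEFAULT_THRESHOLDS,
    NOVEL_XRT_THRESHOLDS,
    classify_response,
    combine_modalities,
    concordance_table,
    recist_category,
    treatment_class,
)
from organoidtrack.response_stats import EffectSize


def _eff(mgd, treatment="FOLFOX", modality="diameter"):
    return EffectSize("L", treatment, modality, mgd, 100, 100)


class TestClassifyResponse:
    @pytest.mark.parametrize(
        "mgd,treatment,modality,expected",
        [
            (1.32, "FOLFOX", "diameter", "sensitive"),
            (1.25, "FOLFOX", "diameter", "sensitive"),   # inclusive boundary
            (1.24, "FOLFOX", "diameter", "intermediate"),
            (0.75, "FOLFOX", "diameter", "resistant"),   # inclusive boundary
            (0.82, "5FU+XRT", "diameter", "intermediate"),
            (1.0, "5FU+XRT", "diameter", "sensitive"),
            (0.0, "5FU+XRT", "diameter", "resistant"),
            (1.5, "FOLFIRI", "orr", "intermediate"),     # exclusive boundary
            (1.51, "FOLFIRI", "orr", "sensitive"),
            (0.0, "FOLFIRI", "orr", "intermediate"),     # exclusive boundary
            (-0.01, "FOLFIRI", "orr", "resistant"),
            (1.0, "XRT", "orr", "intermediate"),
            (1.01, "XRT", "orr", "sensitive"),
        ],
    )
    def test_threshold_table(self, mgd, treatment, modality, expected):
        assert classify_response(_eff(mgd, treatment, modality)) == expected

    def test_alternative_xrt_preset_differs_at_quarter(self):
        e = _eff(0.3, "5FU+XRT", "diameter")
        assert classify_response(e, DEFAULT_THRESHOLDS) == "intermediate"
        assert classify_response(e, NOVEL_XRT_THRESHOLDS) == "resistant"

    def test_unknown_treatment_lists_known(self):
        with pytest.raises(KeyError, match="FOLFOX"):
            classify_response(_eff(1.0, treatment="mystery-drug"))

    def test_treatment_class_mapping(self):
        assert treatment_class("SN38") == "chemo"
        assert treatment_class("5FU+XRT") == "chemoRT"

    @given(st.lists(st.floats(-3.0, 4.0), min_size=2, max_size=20))
    def test_monotone_in_effect_size(self, values):
        order = {"resistant": 0, "intermediate": 1, "sensitive": 2}
        for treatment, modality in (("FOLFOX", "diameter"), ("XRT", "orr")):
            cats = [
                order[classify_response(_eff(v, treatment, modality))]
                for v in sorted(values)
            ]
            assert cats == sorted(cats)


class TestCombineModalities:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("sensitive", "intermediate", "sensitive"),
            ("resistant", "resistant", "resistant"),
            ("intermediate", None, "intermediate"),
            (None, "sensitive", "sensitive"),
            ("resistant", "intermediate", "intermediate"),
        ],
    )
    def test_most_sensitive_wins(self, a, b, expected):
        assert combine_modalities(a, b) == expected

    @given(
        st.sampled_from(["sensitive", "intermediate", "resistant"]),
        st.sampled_from(["sensitive", "intermediate", "resistant"]),
    )
    def test_commutative_and_idempotent(self, a, b):
        assert combine_modalities(a, b) == combine_modalities(b, a)
        assert combine_modalities(a, a) == a

    def test_both_missing_rejected(self):
        with pytest.raises(ValueError):
            combine_modalities(None, None)


def _recist_oracle(pre, post):
    """Independent rule statement for the lattice check."""
    if post == 0:
        return "CR"
    pct = 100.0 * (post - pre) / pre
    is_pr = pct <= -30.0
    is_pd = pct >= 20.0 and (post - pre) >= 5.0
    if is_pr:
        return "PR"
    if is_pd:
        return "PD"
    return "SD"


class TestRecistCategory:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [
            (100.0, 69.0, "PR"),   # 31% reduction
            (100.0, 52.0, "PR"),   # 48% reduction
            (100.0, 100.0, "SD"),
            (100.0, 0.0, "CR"),
            (100.0, 125.0, "PD"),  # +25%, +25 mm
            (20.0, 24.0, "SD"),    # +20% but only +4 mm absolute
            (100.0, 70.0, "PR"),   # -30% boundary inclusive
            (100.0, 120.0, "PD"),  # +20% boundary with 20 mm absolute
        ],
    )
    def test_named_cases(self, pre, post, expected):
        assert recist_category(pre, post) == expected

    def test_exhaustive_lattice_matches_oracle(self):
        pres = np.arange(5.0, 151.0, 5.0)
        for pre in pres:
            for post in np.arange(0.0, 1.6 * pre, 1.0):
                assert recist_category(pre, post) == _recist_oracle(pre, post), (
                    pre,
                    post,
                )

    def test_invalid_slds_rejected(self):
        with pytest.raises(ValueError):
            recist_category(0.0, 10.0)
        with pytest.raises(ValueError):
            recist_category(10.0, -1.0)


class TestConcordanceTable:
    def test_all_sensitive_responders_give_full_rate(self):
        predicted = {f"s{i}": "sensitive" for i in range(7)}
        clinical = {f"s{i}": "PR" for i in range(7)}
        t = concordance_table(predicted, clinical)
        assert t.response_rate["sensitive"] == 1.0
        assert t.n_subjects == 7

    def test_four_of_seven_rate(self):
        predicted = {f"s{i}": "intermediate" for i in range(7)}
        clinical = {f"s{i}": ("PR" if i < 4 else "SD") for i in range(7)}
        t = concordance_table(predicted, clinical)
        assert t.response_rate["intermediate"] == pytest.approx(0.571, abs=5e-4)

    def test_empty_predicted_row_is_nan(self):
        t = concordance_table({"a": "sensitive"}, {"a": "CR"})
        assert np.isnan(t.response_rate["resistant"])
        assert t.counts.loc["resistant"].sum() == 0

    def test_cr_counts_as_response(self):
        t = concordance_table({"a": "sensitive"}, {"a": "CR"})
        assert t.response_rate["sensitive"] == 1.0

    def test_unmatched_subjects_rejected(self):
        with pytest.raises(ValueError, match="unmatched"):
            concordance_table({"a": "sensitive"}, {"b": "PR"})
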