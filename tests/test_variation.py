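"""Variant counting, the relative variation score, and conservation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from classf_switch.generic_numbering import GenericLabel, HelixSegment, SegmentMap
from classf_switch.variation import (
    DegenerateNormalizerError,
    VariantRecord,
    conservation,
    count_variants,
    rank_hotspots,
    relvar,
)

LN2 = math.log(2.0)


@pytest.fixture
def family_maps():
    """FZD6 and FZD5 sharing generic label 6.32 at different resSeq."""
    fzd6 = SegmentMap("FZD6", (HelixSegment(6, 408, 427, GenericLabel(6, 24)),))
    fzd5 = SegmentMap("FZD5", (HelixSegment(6, 441, 460, GenericLabel(6, 24)),))
    return {"FZD6": fzd6, "FZD5": fzd5}


class TestCountVariants:
    def test_empty_records_all_zero(self, family_maps):
        family, per_receptor, skipped = count_variants([], family_maps, "cancer")
        assert (family == 0).all()
        assert per_receptor.values.sum() == 0
        assert sum(skipped.values()) == 0

    def test_family_wide_aggregation_at_shared_label(self, family_maps):
        """3 records at FZD6 416 + 2 at FZD5 449 (both 6.32) pool to 5."""
        records = [
            VariantRecord("FZD6", 416, "R", "Q", 3, "cancer"),
            VariantRecord("FZD5", 449, "R", "A", 2, "cancer"),
        ]
        family, per_receptor, _ = count_variants(records, family_maps, "cancer")
        assert family["6.32"] == 5
        assert per_receptor.loc["6.32", "FZD6"] == 3
        assert per_receptor.loc["6.32", "FZD5"] == 2

    def test_unmapped_and_synonymous_records_go_to_skip_report(self, family_maps):
        records = [
            VariantRecord("FZD6", 50, "A", "V", 1, "cancer"),   # loop position
            VariantRecord("FZD6", 416, "R", "R", 2, "cancer"),  # not missense
            VariantRecord("FZD6", 416, "R", "*", 1, "cancer"),  # nonsense
        ]
        family, _, skipped = count_variants(records, family_maps, "cancer")
        assert skipped["unmapped_position"] == 1
        assert skipped["not_missense"] == 3
        assert family.sum() == 0

    def test_mass_conservation(self, family_maps):
        rng = np.random.default_rng(7)
        records = [
            VariantRecord(
                "FZD6",
                int(rng.integers(400, 440)),
                "R",
                "Q",
                int(rng.integers(0, 5)),
                "cancer",
            )
            for _ in range(40)
        ]
        family, _, skipped = count_variants(records, family_maps, "cancer")
        assert family.sum() + sum(skipped.values()) == sum(r.count for r in records)

    def test_unknown_receptor_errors_with_id(self, family_maps):
        with pytest.raises(KeyError, match="FZD9"):
            count_variants(
                [VariantRecord("FZD9", 1, "A", "V")], family_maps, "cancer"
            )

    def test_other_source_records_ignored(self, family_maps):
        records = [VariantRecord("FZD6", 416, "R", "Q", 3, "population")]
        family, _, skipped = count_variants(records, family_maps, "cancer")
        assert family.sum() == 0 and sum(skipped.values()) == 0


class TestRelVar:
    def test_hand_computed_two_position_table(self):
        """CV={a:10,b:5}, NV={a:0,b:20}: RelVar_a=ln2, RelVar_b=ln(1.5/2)."""
        scores = relvar({"a": 10, "b": 5}, {"a": 0, "b": 20})
        assert scores.loc["a", "relvar"] == pytest.approx(LN2, abs=1e-12)
        assert scores.loc["b", "relvar"] == pytest.approx(math.log(1.5 / 2.0), abs=1e-12)

    def test_zero_counts_both_sides_score_zero(self):
        scores = relvar({"a": 5, "b": 0}, {"a": 3, "b": 0})
        assert scores.loc["b", "relvar"] == 0.0

    def test_max_cancer_no_population_hits_upper_bound(self):
        scores = relvar({"a": 7, "b": 1}, {"a": 0, "b": 4})
        assert scores.loc["a", "relvar"] == pytest.approx(LN2)

    def test_all_zero_table_is_degenerate(self):
        with pytest.raises(DegenerateNormalizerError):
            relvar({"a": 0, "b": 0}, {"a": 1, "b": 2})
        with pytest.raises(DegenerateNormalizerError):
            relvar({"a": 1, "b": 2}, {"a": 0, "b": 0})

    def test_mismatched_label_sets_rejected(self):
        with pytest.raises(ValueError, match="label set"):
            relvar({"a": 1}, {"b": 1})

    @given(
        cv=st.lists(st.integers(0, 100), min_size=2, max_size=8),
        nv=st.lists(st.integers(0, 100), min_size=2, max_size=8),
    )
    @settings(deadline=None, max_examples=200)
    def test_bounded_and_antisymmetric(self, cv, nv):
        n = min(len(cv), len(nv))
        cv, nv = cv[:n], nv[:n]
        if max(cv) == 0 or max(nv) == 0:
            return
        labels = [f"1.{30 + i}" for i in range(n)]
        a = dict(zip(labels, cv))
        b = dict(zip(labels, nv))
        forward = relvar(a, b)["relvar"]
        backward = relvar(b, a)["relvar"]
        assert (forward.abs() <= LN2 + 1e-12).all()
        assert np.allclose(forward.values, -backward.values)

    @given(scale=st.integers(1, 50))
    @settings(deadline=None)
    def test_scale_invariance_of_cancer_counts(self, scale):
        cv = {"a": 10, "b": 5, "c": 0}
        nv = {"a": 2, "b": 8, "c": 1}
        base = relvar(cv, nv)["relvar"]
        scaled = relvar({k: v * scale for k, v in cv.items()}, nv)["relvar"]
        assert np.allclose(base.values, scaled.values)

    def test_monotone_in_cancer_count_below_max(self):
        # increasing CV_b (argmax stays at a) must not decrease RelVar_b
        lo = relvar({"a": 10, "b": 2}, {"a": 1, "b": 5}).loc["b", "relvar"]
        hi = relvar({"a": 10, "b": 6}, {"a": 1, "b": 5}).loc["b", "relvar"]
        assert hi >= lo


class TestRankHotspots:
    def test_derived_table_ranks_cancer_excess_first(self):
        scores = relvar({"a": 10, "b": 5}, {"a": 0, "b": 20})
        assert rank_hotspots(scores, 1) == ["a"]

    def test_all_equal_scores_fall_back_to_lexicographic(self):
        scores = relvar({"b": 3, "a": 3, "c": 3}, {"b": 3, "a": 3, "c": 3})
        assert rank_hotspots(scores, 3) == ["a", "b", "c"]

    def test_ties_broken_by_higher_cancer_count(self):
        # b and c tie on relvar=0 (both at CV=NV=0 relative ratios) but differ in CV
        scores = relvar({"a": 10, "b": 4, "c": 2}, {"a": 10, "b": 4, "c": 2})
        assert rank_hotspots(scores, 3) == ["a", "b", "c"]

    def test_k_larger_than_table_returns_all(self):
        scores = relvar({"a": 1, "b": 2}, {"a": 2, "b": 1})
        assert len(rank_hotspots(scores, 10)) == 2


class TestConservation:
    def test_single_residue_column_scores_one(self):
        msa = {f"s{i}": "A" for i in range(10)}
        assert conservation(msa)["score"].iloc[0] == pytest.approx(1.0)

    def test_uniform_20_residue_column_scores_zero(self):
        msa = {f"s{i}": aa for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY")}
        assert conservation(msa)["score"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_half_half_column_matches_hand_entropy(self):
        """50% R / 50% K: score = 1 - ln2/ln20 = 0.7686."""
        msa = {f"s{i}": ("R" if i % 2 else "K") for i in range(100)}
        expected = 1.0 - math.log(2.0) / math.log(20.0)
        assert conservation(msa)["score"].iloc[0] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.7686, abs=5e-5)

    def test_gaps_excluded_and_low_coverage_flagged(self):
        msa = {"a": "A-", "b": "A-", "c": "AR", "d": "A-"}
        prof = conservation(msa, min_coverage=0.5)
        assert prof.loc[0, "covered"]
        assert not prof.loc[1, "covered"]
        assert prof.loc[1, "n_sequences"] == 1
        assert prof.loc[1, "score"] == pytest.approx(1.0)

    def test_empty_msa_errors(self):
        with pytest.raises(ValueError, match="empty"):
            conservation({})
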