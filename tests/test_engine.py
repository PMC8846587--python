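"""Cut-site arithmetic, end scoring, refractory detection, degradation."""

import numpy as np
import pytest

from dcl3dice import (
    DicingMode,
    DicingParams,
    End,
    EndChoiceMode,
    FivePrimeChem,
    PreconditionError,
    compute_cut_plan,
    degrade,
    dice,
    dice_at_end,
    enumerate_dicing_outcomes,
    is_refractory,
    make_duplex,
    outcome_conserves_nucleotides,
    score_end,
)


@pytest.mark.parametrize(
    "top_len,bottom_len,left_ext,end,measured_cut,comp_len",
    [
        (37, 38, 1, End.LEFT, 24, 23),   # canonical 24 + 23 products
        (37, 39, 2, End.LEFT, 24, 24),   # 2-nt overhang: two 24-mers
        (24, 25, 1, End.LEFT, None, 23), # measured strand too short to cut
        (23, 24, 1, End.LEFT, None, 23), # bottom trimmed by only 1 nt
        (24, 24, 0, End.LEFT, None, 22), # blunt: paired strand to 22
        (26, 27, 1, End.LEFT, 24, 23),   # domain-mutant substrate, wild type
    ],
)
def test_cut_plan_arithmetic(rng, params, top_len, bottom_len, left_ext, end,
                             measured_cut, comp_len):
    d = make_duplex(rng, top_len, bottom_len, left_ext)
    plan = compute_cut_plan(d, end, params)
    assert plan.measured_cut_after == measured_cut
    assert plan.comp_product_len == comp_len
    assert plan.valid


def test_cut_plan_comp_length_identity(rng, params):
    # comp_product_len = measure_len + jitter - cut_offset + o when both cuts exist
    d = make_duplex(rng, 37, 38, 1)
    plan = compute_cut_plan(d, End.LEFT, params)
    assert plan.comp_product_len == params.measure_len - params.cut_offset + 1


def test_cut_plan_refuses_five_prime_overhangs(rng, params):
    d = make_duplex(rng, 30, 28, -2)  # top 5' protrudes at left
    plan = compute_cut_plan(d, End.LEFT, params)
    assert not plan.valid and plan.reason == "five_prime_overhang"


def test_jitter_only_admissible_on_blunt_ends(rng, params):
    d = make_duplex(rng, 37, 38, 1)
    with pytest.raises(PreconditionError):
        compute_cut_plan(d, End.LEFT, params, jitter=1)


def test_cut_plan_oracle_coordinate_scan(rng, params):
    """The closed-form complementary product length must agree with an
    explicit scan over drawing coordinates: the complementary product is
    every bottom nucleotide lying at most measure_len - cut_offset
    positions right of the measured 5' terminus."""
    for top_len in range(22, 46):
        for o in (0, 1, 2):
            bottom_len = top_len + o  # blunt right end
            d = make_duplex(rng, top_len, bottom_len, o)
            plan = compute_cut_plan(d, End.LEFT, params)
            L = params.measure_len
            # drawing coordinate of bottom position j (top 5' terminus = 1)
            count = sum(
                1
                for j in range(1, bottom_len + 1)
                if (top_len - d.right_ext - j + 1) <= L - params.cut_offset
            )
            expected = count if 0 < count < bottom_len else None
            assert plan.comp_product_len == expected


class TestRefractory:
    def test_product_mimics_are_refractory(self, rng, params):
        assert is_refractory(make_duplex(rng, 24, 23, 1), params)
        assert is_refractory(make_duplex(rng, 24, 24, 2), params)

    def test_dicable_substrate_is_not(self, rng, params):
        assert not is_refractory(make_duplex(rng, 37, 38, 1), params)

    def test_short_duplexes_are_not_refractory(self, rng, params):
        # sub-product-size duplexes are degraded, not refractory
        assert not is_refractory(make_duplex(rng, 20, 18, 1), params)


class TestScoreEnd:
    def test_unit_weights_multiply(self, rng, params):
        d = make_duplex(rng, 37, 38, 1, top_first_nt="A")
        assert score_end(d, End.LEFT, params) == pytest.approx(1.0)

    def test_five_prime_nt_ordering(self, rng, params):
        scores = {}
        for nt in "AUCG":
            d = make_duplex(rng, 37, 38, 1, top_first_nt=nt)
            scores[nt] = score_end(d, End.LEFT, params)
        assert scores["A"] == scores["U"] > scores["C"] == scores["G"]

    def test_overhang_nucleotide_identity_is_neutral(self, rng, params):
        scores = set()
        for nt in "AUCG":
            d = make_duplex(rng, 37, 38, 1, top_first_nt="A", overhang_nt=nt)
            scores.add(score_end(d, End.LEFT, params))
        assert len(scores) == 1

    def test_chemistry_ordering(self, rng, params):
        by_chem = {}
        for chem in FivePrimeChem:
            d = make_duplex(rng, 37, 38, 1, top_first_nt="A", top_chem=chem)
            by_chem[chem] = score_end(d, End.LEFT, params)
        assert by_chem[FivePrimeChem.OH] < by_chem[FivePrimeChem.TRI_P]
        assert by_chem[FivePrimeChem.TRI_P] <= by_chem[FivePrimeChem.MONO_P]
        assert by_chem[FivePrimeChem.OH] * 10 < by_chem[FivePrimeChem.MONO_P]

    def test_overhang_class_ordering(self, rng, params):
        s_blunt = score_end(make_duplex(rng, 37, 37, 0, top_first_nt="A"),
                            End.LEFT, params)
        s1 = score_end(make_duplex(rng, 37, 38, 1, top_first_nt="A"), End.LEFT, params)
        s2 = score_end(make_duplex(rng, 37, 39, 2, top_first_nt="A"), End.LEFT, params)
        assert s1 == s2 > s_blunt > 0

    def test_zero_when_no_cut_available(self, rng, params):
        d = make_duplex(rng, 24, 23, 1)  # refractory geometry
        assert score_end(d, End.LEFT, params) == 0.0
        assert score_end(d, End.RIGHT, params) == 0.0


class TestDice:
    def test_one_nt_overhang_yields_24_and_23(self, rng, params):
        oc = dice(make_duplex(rng, 37, 38, 1), params)
        assert oc.mode is DicingMode.DICED
        assert (len(oc.product.top), len(oc.product.bottom)) == (24, 23)
        assert sorted(len(f) for f in oc.fragments) == [13, 15]

    def test_two_nt_overhang_yields_two_24mers(self, rng, params):
        oc = dice(make_duplex(rng, 37, 39, 2), params)
        assert (len(oc.product.top), len(oc.product.bottom)) == (24, 24)

    def test_product_carries_two_nt_overhang_at_new_end(self, rng, params):
        oc = dice(make_duplex(rng, 37, 38, 1), params)
        assert oc.product.right_ext == params.cut_offset

    def test_domain_a_mutant_cuts_only_measured_strand(self, rng):
        params = DicingParams(domain_a_active=False)
        oc = dice(make_duplex(rng, 26, 27, 1), params)
        assert len(oc.product.top) == 24
        assert len(oc.product.bottom) == 27  # complementary strand untouched

    def test_domain_b_mutant_cuts_only_complementary_strand(self, rng):
        params = DicingParams(domain_b_active=False)
        oc = dice(make_duplex(rng, 26, 27, 1), params)
        assert len(oc.product.top) == 26  # measured strand untouched
        assert len(oc.product.bottom) == 23

    def test_double_mutant_abolishes_dicing(self, rng):
        params = DicingParams(domain_a_active=False, domain_b_active=False)
        oc = dice(make_duplex(rng, 26, 27, 1), params)
        assert oc.mode is DicingMode.NO_CUT
        assert oc.product == oc.substrate

    def test_refractory_duplex_returned_intact(self, rng, params):
        oc = dice(make_duplex(rng, 24, 23, 1), params)
        assert oc.mode is DicingMode.REFRACTORY
        assert oc.product == oc.substrate and not oc.fragments

    def test_product_of_dicing_is_a_fixed_point(self, rng, params):
        oc = dice(make_duplex(rng, 37, 38, 1), params)
        again = dice(oc.product, params)
        assert again.mode is DicingMode.REFRACTORY

    def test_overhang_end_preferred_over_blunt(self, rng, params):
        oc = dice(make_duplex(rng, 24, 25, 1), params)  # right end is blunt
        assert oc.chosen_end is End.LEFT
        assert len(oc.product.top) == 24 and len(oc.product.bottom) == 23

    def test_stochastic_mode_requires_rng(self, rng):
        params = DicingParams(end_choice_mode=EndChoiceMode.STOCHASTIC)
        with pytest.raises(PreconditionError):
            dice(make_duplex(rng, 37, 38, 1), params)

    def test_stochastic_end_choice_follows_scores(self, rng):
        params = DicingParams(end_choice_mode=EndChoiceMode.STOCHASTIC)
        # a 37/37 duplex with 1-nt overhangs at both ends: both ends are
        # cuttable and the empirical left fraction must track the scores
        d = make_duplex(rng, 37, 37, 1, top_first_nt="G")
        stream = np.random.default_rng(0)
        ends = [dice(d, params, rng=stream).chosen_end for _ in range(400)]
        frac_left = sum(e is End.LEFT for e in ends) / len(ends)
        s_left = score_end(d, End.LEFT, params)
        s_right = score_end(d, End.RIGHT, params)
        assert abs(frac_left - s_left / (s_left + s_right)) < 0.1


class TestBluntJitter:
    def test_deterministic_blunt_dicing_uses_register_zero(self, rng, params):
        oc = dice(make_duplex(rng, 37, 37, 0), params)
        assert oc.cut_plan.jitter == 0
        measured, comp = (
            (oc.product.top, oc.product.bottom)
            if oc.chosen_end is End.LEFT
            else (oc.product.bottom, oc.product.top)
        )
        assert len(measured) == 24 and len(comp) == 22

    def test_enumeration_covers_diverse_sizes(self, rng, params):
        outs = enumerate_dicing_outcomes(make_duplex(rng, 37, 37, 0), params)
        lengths = set()
        for oc in outs:
            lengths.add(len(oc.product.top))
            lengths.add(len(oc.product.bottom))
        assert {21, 22, 23, 24, 25} <= lengths
        assert max(lengths) == 25

    def test_enumeration_empty_for_refractory(self, rng, params):
        assert enumerate_dicing_outcomes(make_duplex(rng, 24, 23, 1), params) == []


class TestDegrade:
    def test_retained_lengths_within_support(self, rng, params):
        d = make_duplex(rng, 23, 23, 0)
        stream = np.random.default_rng(3)
        seen = set()
        for _ in range(2000):
            oc = degrade(d, params, stream)
            assert oc.mode is DicingMode.DEGRADED
            seen.update(k for k in oc.notes["retained_lengths"] if k is not None)
        assert seen == set(range(17, 23))

    def test_support_of_mixed_lengths(self, rng, params):
        d = make_duplex(rng, 22, 23, 1)
        stream = np.random.default_rng(4)
        seen = set()
        for _ in range(10_000):
            oc = degrade(d, params, stream)
            seen.update(k for k in oc.notes["retained_lengths"] if k is not None)
        assert min(seen) == 17
        assert seen == set(range(17, 23))

    def test_minimum_length_duplex_is_degenerate(self, rng, params):
        d = make_duplex(rng, 17, 17, 0)
        oc = degrade(d, params, np.random.default_rng(5))
        assert oc.notes["degenerate"]
        assert oc.product == oc.substrate

    def test_precondition_on_long_strands(self, rng, params):
        with pytest.raises(PreconditionError):
            degrade(make_duplex(rng, 24, 23, 1), params, np.random.default_rng(0))

    def test_dice_delegates_short_duplexes_to_degradation(self, rng, params):
        oc = dice(make_duplex(rng, 22, 22, 0), params, rng=np.random.default_rng(6))
        assert oc.mode is DicingMode.DEGRADED

    def test_degradation_conserves_nucleotides(self, rng, params):
        d = make_duplex(rng, 23, 23, 0)
        oc = degrade(d, params, np.random.default_rng(7))
        assert outcome_conserves_nucleotides(oc)


def test_forced_end_dicing_matches_plan(rng, params):
    d = make_duplex(rng, 24, 24, 0)
    oc = dice_at_end(d, End.RIGHT, params)
    # measured strand (bottom) uncut, complementary (top) trimmed to 22
    assert len(oc.product.bottom) == 24
    assert len(oc.product.top) == 22


def test_params_validation():
    with pytest.raises(PreconditionError):
        DicingParams(measure_len=2, cut_offset=2)
    with pytest.raises(PreconditionError):
        DicingParams(degradation_min_len=30)
    with pytest.raises(PreconditionError):
        DicingParams(w_nt={"A": -1.0, "U": 1.0, "C": 1.0, "G": 1.0})
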