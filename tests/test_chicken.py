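"""The encoded chicken network: rules, genotypes, priorities, phenotypes."""

import itertools

import pytest

from zwlogic import (
    NEITHER,
    OVARY,
    TESTIS,
    Transition,
    build_chicken_model,
    build_stg,
    classify_phenotype,
    enabled_transitions,
    filter_by_priority,
    genotype_inputs,
    initial_state,
    priority_scheme,
    stable_states,
    validate_model,
)
from zwlogic.chicken import bundled_model_path
from zwlogic.model_io import dumps_model

from .conftest import OVARY_VECTOR, TESTIS_VECTOR, full_state


class TestModelStructure:
    def test_validates_cleanly(self, chicken):
        assert validate_model(chicken) == []

    def test_component_roster(self, chicken):
        assert chicken.component("DMRT1").max_level == 2
        assert chicken.inputs == ("Z1", "Z2", "W")
        booleans = set(chicken.component_names) - {"DMRT1"}
        assert all(chicken.component(n).max_level == 1 for n in booleans)

    def test_fifteen_regulatory_edges(self, chicken):
        assert len(chicken.edges) == 15
        assert set(chicken.regulators_of("DMRT1")) == \
            {"Z1", "Z2", "W", "HEMGN", "SOX9", "FOXL2"}

    @pytest.mark.parametrize("genotype,vector,inputs_ok", [
        ("ZZ", TESTIS_VECTOR, True),
        ("ZW", OVARY_VECTOR, True),
    ])
    def test_fate_vectors_are_fixed_points(self, chicken, genotype, vector, inputs_ok):
        state = full_state(genotype_inputs(genotype), vector)
        assert enabled_transitions(chicken, state) == frozenset()

    def test_bundled_file_is_bit_identical(self, chicken):
        assert bundled_model_path().read_text(encoding="utf-8") == dumps_model(chicken)


class TestGenotypes:
    @pytest.mark.parametrize("label,expected", [
        ("ZZ", {"Z1": 1, "Z2": 1, "W": 0}),
        ("ZW", {"Z1": 1, "Z2": 0, "W": 1}),
        ("Z0", {"Z1": 1, "Z2": 0, "W": 0}),
        ("ZZW", {"Z1": 1, "Z2": 1, "W": 1}),
    ])
    def test_input_levels(self, label, expected):
        assert genotype_inputs(label) == expected

    def test_unknown_genotype_rejected(self):
        with pytest.raises(ValueError, match="genotype"):
            genotype_inputs("XY")


class TestInitialState:
    def test_zz_default(self):
        assert initial_state("ZZ") == {
            "Z1": 1, "Z2": 1, "W": 0, "DMRT1": 1, "HEMGN": 0, "SOX9": 0,
            "FOXL2": 0, "AROMATASE": 0, "OESTROGEN": 0}

    def test_zw_with_dmrt1_at_zero(self):
        s = initial_state("ZW", 0)
        assert s["DMRT1"] == 0 and s["Z1"] == 1 and s["W"] == 1
        assert all(s[c] == 0 for c in ("Z2", "HEMGN", "SOX9", "FOXL2",
                                       "AROMATASE", "OESTROGEN"))

    def test_zzw(self):
        s = initial_state("ZZW", 1)
        assert (s["Z1"], s["Z2"], s["W"], s["DMRT1"]) == (1, 1, 1, 1)

    def test_invalid_dmrt1_level(self):
        with pytest.raises(ValueError):
            initial_state("ZZ", 3)


class TestPrioritySchemes:
    def test_pc1_defers_foxl2_at_zz_initial(self, chicken, zz_initial):
        enabled = enabled_transitions(chicken, zz_initial)
        assert enabled == {Transition("HEMGN", +1), Transition("FOXL2", +1)}
        assert filter_by_priority(enabled, priority_scheme("PC1")) == \
            {Transition("HEMGN", +1)}

    def test_none_is_identity(self, chicken, zw_initial):
        enabled = enabled_transitions(chicken, zw_initial)
        assert filter_by_priority(enabled, priority_scheme("none")) == enabled

    def test_pc3_overcomes_w_effect_in_foxl2_lof(self, chicken):
        pert = {"FOXL2": 0}
        root = initial_state("ZW", 1, pert)
        enabled = enabled_transitions(chicken, root, pert)
        assert enabled == {Transition("HEMGN", +1), Transition("DMRT1", -1)}
        assert filter_by_priority(enabled, priority_scheme("PC3")) == \
            {Transition("HEMGN", +1)}

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="priority"):
            priority_scheme("PC9")

    def test_two_class_shapes(self):
        pc2 = priority_scheme("PC2")
        assert pc2.rank_of(Transition("DMRT1", -1)) == 1
        assert pc2.rank_of(Transition("HEMGN", +1)) == 2
        pc4 = priority_scheme("PC4")
        assert pc4.rank_of(Transition("FOXL2", +1)) == 1
        assert pc4.rank_of(Transition("DMRT1", +1)) == 2


class TestClassifyPhenotype:
    def test_testis_fixed_point(self, zz_inputs):
        assert classify_phenotype(full_state(zz_inputs, TESTIS_VECTOR)) == TESTIS

    def test_ovary_fixed_point(self, zw_inputs):
        assert classify_phenotype(full_state(zw_inputs, OVARY_VECTOR)) == OVARY

    def test_sox9_lof_terminal_state_is_neither(self, zz_inputs):
        state = full_state(zz_inputs, {"DMRT1": 2, "HEMGN": 1, "SOX9": 0,
                                       "FOXL2": 0, "AROMATASE": 0, "OESTROGEN": 0})
        assert classify_phenotype(state, {"SOX9": 0}) == NEITHER

    def test_partial_dmrt1_gof_still_ovary(self, zw_inputs):
        # DMRT1/HEMGN presence does not disqualify the ovarian programme
        state = full_state(zw_inputs, {"DMRT1": 1, "HEMGN": 1, "SOX9": 0,
                                       "FOXL2": 1, "AROMATASE": 1, "OESTROGEN": 1})
        assert classify_phenotype(state, {"DMRT1": 1}) == OVARY

    def test_calls_are_mutually_exclusive_over_the_whole_space(self, chicken):
        axes = [range(c.max_level + 1) for c in chicken.components]
        calls = {classify_phenotype(chicken.state_dict(combo))
                 for combo in itertools.product(*axes)}
        assert calls == {TESTIS, OVARY, NEITHER}


class TestModelInvariants:
    @pytest.mark.parametrize("genotype", ["ZZ", "ZW", "Z0", "ZZW"])
    def test_hormonal_cascade_slaved_to_foxl2_at_equilibrium(self, chicken, genotype):
        for s in stable_states(chicken, inputs=genotype_inputs(genotype)):
            assert s["OESTROGEN"] == s["AROMATASE"] == s["FOXL2"]

    @pytest.mark.parametrize("genotype,n_fixed", [
        ("ZZ", 2), ("ZW", 2), ("Z0", 2), ("ZZW", 2),
    ])
    def test_two_fixed_points_per_genotype(self, chicken, genotype, n_fixed):
        assert len(stable_states(chicken, inputs=genotype_inputs(genotype))) == n_fixed

    def test_clamping_removes_a_fate(self, chicken, zz_inputs):
        # SOX9 loss removes the testis fixed point, FOXL2 loss the ovary one
        no_testis = stable_states(chicken, {"SOX9": 0}, inputs=zz_inputs)
        assert all(classify_phenotype(s, {"SOX9": 0}) != TESTIS for s in no_testis)
        no_ovary = stable_states(chicken, {"FOXL2": 0}, inputs=zz_inputs)
        assert all(classify_phenotype(s, {"FOXL2": 0}) != OVARY for s in no_ovary)

    def test_zz_initial_male_race_lost_only_to_foxl2(self, chicken, zz_initial):
        from zwlogic import target_level

        assert target_level(chicken, zz_initial, "HEMGN") == 1
        assert target_level(chicken, zz_initial, "DMRT1") == 1  # no decrease
        assert enabled_transitions(chicken, zz_initial) == {
            Transition("HEMGN", +1), Transition("FOXL2", +1)}


class TestNarratedTrajectories:
    """Regression of the narrated wild-type developmental paths."""

    def test_zz_male_path(self, chicken, zz_initial, zz_inputs):
        """HEMGN rises, boosts DMRT1 to level 2, SOX9 switches on and locks
        the male programme while repressing HEMGN."""
        state = dict(zz_initial)
        for tr in [Transition("HEMGN", +1), Transition("DMRT1", +1),
                   Transition("SOX9", +1), Transition("HEMGN", -1)]:
            assert tr in enabled_transitions(chicken, state)
            state[tr.component] += tr.direction
        assert state == full_state(zz_inputs, TESTIS_VECTOR)

    def test_zw_female_path(self, chicken, zw_initial, zw_inputs):
        """DMRT1 decays first (the W-linked effect), then the FOXL2 cascade
        establishes and maintains the ovarian programme."""
        state = dict(zw_initial)
        for tr in [Transition("DMRT1", -1), Transition("FOXL2", +1),
                   Transition("AROMATASE", +1), Transition("OESTROGEN", +1)]:
            assert tr in enabled_transitions(chicken, state)
            state[tr.component] += tr.direction
        assert state == full_state(zw_inputs, OVARY_VECTOR)
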