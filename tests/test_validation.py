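"""The seven-rule validator."""

import pytest

from adamatrix import (GeneratorParams, Header, MutationInapplicable,
                       PermissionEntry, TermEntry, UnknownRule, explain_rule,
                       generate_profile, mutate_invalid, validate)
from adamatrix.validation import RULE_IDS

from .conftest import body, build_profile


def test_minimal_profile_is_valid(minimal_profile, registry):
    report = validate(minimal_profile, registry)
    assert report.valid and not report.findings


def test_missing_required_header_item_is_r1(minimal_profile):
    p = minimal_profile.model_copy(update={"header": Header(values={
        "profile_id": "x", "profile_version": "  "})})
    assert validate(p).rules_violated() == {"R1"}


def test_body_without_any_main_value_is_r2():
    p = build_profile([body()])
    assert validate(p).rules_violated() == {"R2"}


def test_missing_mode_of_sharing_is_r3(minimal_profile):
    b = minimal_profile.bodies[0].model_copy(update={"meta": ()})
    p = minimal_profile.model_copy(update={"bodies": (b,)})
    assert validate(p).rules_violated() == {"R3"}


def test_two_obligations_without_interpretation_rule_is_r4():
    p = build_profile([body(permissions=[
        PermissionEntry(concept_id="use_for_diseases", value="Limited",
                        free_text="A[Obligatory], B[Obligatory]")])])
    assert validate(p).rules_violated() == {"R4"}
    fixed = build_profile([body(rule="MEET_ANY", permissions=[
        PermissionEntry(concept_id="use_for_diseases", value="Limited",
                        free_text="A[Obligatory], B[Obligatory]")])])
    assert validate(fixed).valid


def test_recontact_must_occur_slot_counts_toward_r4():
    p = build_profile([body(
        permissions=[PermissionEntry(concept_id="research_use",
                                     value="Unrestricted[Obligatory]")],
        terms=[TermEntry(concept_id="no_recontact_possibility", value="Untrue",
                         free_text_2="Must recontact on findings.")])])
    assert validate(p).rules_violated() == {"R4"}


def test_forbidden_on_restricted_concept_is_r5_only():
    p = build_profile([body(permissions=[
        PermissionEntry(concept_id="use_by_organizations", value="Forbidden")])])
    assert validate(p).rules_violated() == {"R5"}


def test_free_text_without_main_value_is_r6():
    p = build_profile([body(permissions=[
        PermissionEntry(concept_id="research_use", value="Unrestricted"),
        PermissionEntry(concept_id="use_for_diseases",
                        free_text="Cancer studies only.")])])
    assert validate(p).rules_violated() == {"R6"}


def test_out_of_domain_value_is_r7():
    p = build_profile([body(permissions=[
        PermissionEntry(concept_id="research_use", value="Allowed")])])
    assert validate(p).rules_violated() == {"R7"}


def test_all_violations_reported_without_short_circuit():
    p = build_profile([
        body(permissions=[
            PermissionEntry(concept_id="use_by_organizations", value="Forbidden"),
            PermissionEntry(concept_id="use_for_diseases", free_text="prose here")]),
        body(),
    ])
    p = p.model_copy(update={"header": Header(values={})})
    assert validate(p).rules_violated() == {"R1", "R2", "R5", "R6"}


def test_validate_is_pure(minimal_profile):
    assert validate(minimal_profile) == validate(minimal_profile)


class TestExplainRule:
    def test_seven_distinct_texts(self):
        texts = {explain_rule(r) for r in RULE_IDS}
        assert len(texts) == 7

    def test_r3_names_mode_of_sharing(self):
        assert "Mode of sharing" in explain_rule("R3")

    @pytest.mark.parametrize("bad", ["R0", "R8", "r1", ""])
    def test_unknown_rule(self, bad):
        with pytest.raises(UnknownRule):
            explain_rule(bad)


@pytest.mark.parametrize("seed", range(25))
def test_generated_profiles_all_validate(seed):
    p = generate_profile(GeneratorParams(seed=seed))
    assert validate(p).valid


def test_mutations_flag_exactly_their_rule():
    hits = {r: 0 for r in RULE_IDS}
    for seed in range(40):
        p = generate_profile(GeneratorParams(seed=seed))
        for rule in RULE_IDS:
            try:
                mutant = mutate_invalid(p, rule, seed=seed)
            except MutationInapplicable:
                continue
            assert validate(mutant).rules_violated() == {rule}
            hits[rule] += 1
    assert all(hits[r] > 0 for r in RULE_IDS), hits
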