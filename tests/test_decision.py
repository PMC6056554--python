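"""Decision engine: concept truth tables, body combination, screening."""

import itertools

import pytest

from adamatrix import (AccessMode, AccessRequest, InterpretationRule,
                       InvalidProfile, MainBody, MetaEntry, Overall,
                       PermissionEntry, TermEntry, Verdict, adjudicate,
                       evaluate_permission, evaluate_terms, screen_profiles)

from .conftest import body, build_profile, mini_profile, oracle_adjudicate


def _limited_abc():
    return PermissionEntry(concept_id="use_for_diseases", value="Limited",
                          free_text="Use permitted for research on diseases "
                                    "A, B[Obligatory], and C")


class TestEvaluatePermission:
    def test_obligatory_item_declared_passes(self):
        v = evaluate_permission(_limited_abc(), {"B"})
        assert v.verdict is Verdict.PASS

    def test_obligation_omitted_fails(self):
        v = evaluate_permission(_limited_abc(), {"A", "C"})
        assert v.verdict is Verdict.FAIL
        assert "obligation" in v.rationale

    def test_label_matching_normalizes_case_and_space(self):
        assert evaluate_permission(_limited_abc(), {"  b "}).verdict is Verdict.PASS

    def test_forbidden_vacuously_passes(self):
        entry = PermissionEntry(concept_id="commercial_use", value="Forbidden")
        assert evaluate_permission(entry, set()).verdict is Verdict.PASS
        assert evaluate_permission(entry, {"anything"}).verdict is Verdict.FAIL

    def test_out_of_list_use_fails(self):
        assert evaluate_permission(_limited_abc(), {"B", "Z"}).verdict is Verdict.FAIL

    def test_prose_free_text_refers(self):
        entry = PermissionEntry(concept_id="use_for_diseases", value="Limited",
                                free_text="Resulting data must be made public.")
        assert evaluate_permission(entry, set()).verdict is Verdict.REFER

    def test_limited_without_elaboration(self):
        entry = PermissionEntry(concept_id="use_for_diseases", value="Limited")
        assert evaluate_permission(entry, set()).verdict is Verdict.PASS
        assert evaluate_permission(entry, {"A"}).verdict is Verdict.REFER

    def test_meet_any_defers_obligations_to_body_level(self):
        v = evaluate_permission(_limited_abc(), {"A"},
                                rule=InterpretationRule.MEET_ANY)
        assert v.verdict is Verdict.PASS


class TestEvaluateTerms:
    def test_true_means_no_condition(self):
        entry = TermEntry(concept_id="no_collaboration_requirements", value="True")
        assert evaluate_terms(entry, set(), AccessMode.ACCESS).verdict is Verdict.PASS

    def test_untrue_unaccepted_fails_for_access(self):
        entry = TermEntry(concept_id="no_collaboration_requirements", value="Untrue")
        assert evaluate_terms(entry, set(), AccessMode.ACCESS).verdict is Verdict.FAIL
        accepted = {"no_collaboration_requirements"}
        assert evaluate_terms(entry, accepted, AccessMode.ACCESS).verdict is Verdict.PASS

    def test_untrue_is_informational_for_discovery(self):
        entry = TermEntry(concept_id="no_collaboration_requirements", value="Untrue")
        v = evaluate_terms(entry, set(), AccessMode.DISCOVERY)
        assert v.verdict is Verdict.PASS
        assert "discovery" in v.rationale

    def test_recontact_must_occur_slot_refers_for_access(self):
        entry = TermEntry(concept_id="no_recontact_possibility", value="Untrue",
                          free_text_2="Recontact must occur yearly.")
        accepted = {"no_recontact_possibility"}
        assert evaluate_terms(entry, accepted, AccessMode.ACCESS).verdict \
            is Verdict.REFER


class TestAdjudicate:
    def test_all_unrestricted_permits_any_matching_request(self, minimal_profile):
        req = AccessRequest(mode=AccessMode.ACCESS,
                            declared_uses={"research_use": ("anything",)})
        d = adjudicate(minimal_profile, req)
        assert d.overall is Overall.PERMIT
        assert d.selected_body == 0

    def test_cancer_limited_profile(self):
        profile = build_profile([body(permissions=[PermissionEntry(
            concept_id="use_for_diseases", value="Limited",
            free_text="cancer")])])
        permit = AccessRequest(mode=AccessMode.DISCOVERY,
                               declared_uses={"use_for_diseases": ("cancer",)})
        deny = AccessRequest(mode=AccessMode.DISCOVERY,
                             declared_uses={"use_for_diseases": ("diabetes",)})
        assert adjudicate(profile, permit).overall is Overall.PERMIT
        assert adjudicate(profile, deny).overall is Overall.DENY

    def test_prose_free_text_refers(self):
        profile = build_profile([body(permissions=[PermissionEntry(
            concept_id="use_for_diseases", value="Limited",
            free_text="Only uses approved by our ethics board.")])])
        req = AccessRequest(mode=AccessMode.ACCESS,
                            declared_uses={"use_for_diseases": ("cancer",)})
        assert adjudicate(profile, req).overall is Overall.REFER

    def test_mode_ineligible_profile_denies(self):
        profile = build_profile([body(mode="ACCESS", permissions=[
            PermissionEntry(concept_id="research_use", value="Unrestricted")])])
        req = AccessRequest(mode=AccessMode.DISCOVERY)
        assert adjudicate(profile, req).overall is Overall.DENY

    def test_any_passing_body_permits(self):
        profile = build_profile([
            body(permissions=[PermissionEntry(concept_id="commercial_use",
                                              value="Forbidden")]),
            body(permissions=[PermissionEntry(concept_id="commercial_use",
                                              value="Unrestricted")]),
        ])
        req = AccessRequest(mode=AccessMode.ACCESS,
                            declared_uses={"commercial_use": ("profit",)})
        d = adjudicate(profile, req)
        assert d.overall is Overall.PERMIT
        assert d.selected_body == 1

    def test_meet_any_needs_only_one_obligation(self):
        b = body(rule="MEET_ANY", permissions=[
            PermissionEntry(concept_id="use_for_diseases", value="Limited",
                            free_text="A[Obligatory], B[Obligatory]")])
        profile = build_profile([b])
        one = AccessRequest(mode=AccessMode.ACCESS,
                            declared_uses={"use_for_diseases": ("A",)})
        neither = AccessRequest(mode=AccessMode.ACCESS,
                                declared_uses={"use_for_diseases": ()})
        assert adjudicate(profile, one).overall is Overall.PERMIT
        assert adjudicate(profile, neither).overall is Overall.DENY

    def test_meet_all_needs_every_obligation(self):
        b = body(rule="MEET_ALL", permissions=[
            PermissionEntry(concept_id="use_for_diseases", value="Limited",
                            free_text="A[Obligatory], B[Obligatory]")])
        profile = build_profile([b])
        one = AccessRequest(mode=AccessMode.ACCESS,
                            declared_uses={"use_for_diseases": ("A",)})
        both = AccessRequest(mode=AccessMode.ACCESS,
                             declared_uses={"use_for_diseases": ("A", "B")})
        assert adjudicate(profile, one).overall is Overall.DENY
        assert adjudicate(profile, both).overall is Overall.PERMIT

    def test_invalid_profile_rejected(self, minimal_profile):
        broken = minimal_profile.model_copy(
            update={"header": minimal_profile.header.model_copy(
                update={"values": {}})})
        with pytest.raises(InvalidProfile):
            adjudicate(broken, AccessRequest(mode=AccessMode.ACCESS))

    def test_pure_and_deterministic(self, minimal_profile):
        req = AccessRequest(mode=AccessMode.ACCESS)
        assert adjudicate(minimal_profile, req) == adjudicate(minimal_profile, req)


class TestScreenProfiles:
    def test_keeps_permit_and_refer_only(self, minimal_profile):
        forbidding = build_profile([body(permissions=[PermissionEntry(
            concept_id="use_for_diseases", value="Limited", free_text="X")])])
        prose = build_profile([body(permissions=[PermissionEntry(
            concept_id="use_for_diseases", value="Limited",
            free_text="Ask the steward first.")])])
        req = AccessRequest(mode=AccessMode.DISCOVERY,
                            declared_uses={"use_for_diseases": ("cancer",)})
        kept = screen_profiles([minimal_profile, forbidding, prose], req)
        assert len(kept) == 2
        outcomes = {d.overall for _, d in kept}
        assert outcomes == {Overall.PERMIT, Overall.REFER}

    def test_empty_collection(self):
        req = AccessRequest(mode=AccessMode.DISCOVERY)
        assert screen_profiles([], req) == []

    def test_access_only_profiles_filtered_out(self):
        profiles = [build_profile([body(mode="ACCESS", permissions=[
            PermissionEntry(concept_id="research_use", value="Unrestricted")])])
            for _ in range(3)]
        req = AccessRequest(mode=AccessMode.DISCOVERY)
        assert screen_profiles(profiles, req) == []

    def test_rejects_access_mode(self, minimal_profile):
        with pytest.raises(ValueError):
            screen_profiles([minimal_profile],
                            AccessRequest(mode=AccessMode.ACCESS))


def test_adding_a_body_never_flips_permit_to_deny(mini_registry):
    base_bodies = [
        MainBody(permissions=(PermissionEntry(concept_id="p1",
                                              value="Unrestricted"),),
                 meta=(MetaEntry(concept_id="mode_of_sharing",
                                 value="DISCOVERY_AND_ACCESS"),)),
    ]
    extra = MainBody(permissions=(PermissionEntry(concept_id="p1",
                                                  value="Forbidden"),),
                     meta=(MetaEntry(concept_id="mode_of_sharing",
                                     value="DISCOVERY_AND_ACCESS"),))
    req = AccessRequest(mode=AccessMode.ACCESS,
                        declared_uses={"p1": ("a",)})
    before = adjudicate(mini_profile(base_bodies), req, mini_registry)
    after = adjudicate(mini_profile(base_bodies + [extra]), req, mini_registry)
    assert before.overall is Overall.PERMIT
    assert after.overall is Overall.PERMIT


def test_agrees_with_bruteforce_oracle_on_handpicked_profiles(mini_registry):
    """Spot equivalence on a few tricky profiles (exhaustive run lives in
    the acceptance suite)."""
    bodies = [
        MainBody(permissions=(
            PermissionEntry(concept_id="p1", value="Limited",
                            free_text="a, b[Obligatory]"),
            PermissionEntry(concept_id="p2", value="Forbidden"),),
            terms=(TermEntry(concept_id="no_collab", value="Untrue"),),
            meta=(MetaEntry(concept_id="mode_of_sharing", value="ACCESS"),
                  MetaEntry(concept_id="interpretation_rule", value="MEET_ANY"))),
    ]
    profile = mini_profile(bodies)
    for uses1, uses2, accepted, mode in itertools.product(
            [(), ("a",), ("b",), ("a", "c")], [(), ("x",)],
            [(), ("no_collab",)], list(AccessMode)):
        req = AccessRequest(mode=mode,
                            declared_uses={"p1": uses1, "p2": uses2},
                            accepted_terms=accepted)
        got = adjudicate(profile, req, mini_registry).overall.value
        assert got == oracle_adjudicate(profile, req), req
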