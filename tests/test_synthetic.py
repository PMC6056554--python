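"""Synthetic generator: determinism, coverage, intent contract, mutations."""

import pytest

from adamatrix import (GeneratorParams, IntentUnsatisfiable, Overall,
                       PermissionEntry, adjudicate, count_obligatory,
                       generate_profile, generate_request, mutate_invalid,
                       to_json, validate)

from .conftest import body, build_profile


class TestGenerateProfile:
    def test_identical_seed_identical_serialization(self):
        a = generate_profile(GeneratorParams(seed=42))
        b = generate_profile(GeneratorParams(seed=42))
        assert to_json(a).payload == to_json(b).payload

    def test_different_seeds_differ(self):
        assert generate_profile(GeneratorParams(seed=1)) != \
            generate_profile(GeneratorParams(seed=2))

    def test_zero_obligatory_probability_forces_zero_count(self):
        for seed in range(30):
            p = generate_profile(GeneratorParams(seed=seed, p_obligatory=0.0))
            assert all(count_obligatory(b) == 0 for b in p.bodies)

    def test_corpus_census_covers_all_values(self, corpus):
        perm_values, term_values = set(), set()
        for p in corpus:
            for b in p.bodies:
                perm_values.update(e.value for e in b.permissions)
                term_values.update(e.value for e in b.terms)
        assert perm_values >= {"Unrestricted", "Limited", "Forbidden",
                               "Unrestricted[Obligatory]", "Limited[Obligatory]"}
        assert term_values >= {"True", "Untrue"}

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            GeneratorParams(p_limited=1.5)
        with pytest.raises(ValueError):
            GeneratorParams(vocab=())
        with pytest.raises(ValueError):
            GeneratorParams(n_bodies=(0, 2))


class TestGenerateRequest:
    def test_all_unrestricted_profile_admits_no_denial(self):
        p = build_profile([body(mode=mode, permissions=[PermissionEntry(
            concept_id="research_use", value="Unrestricted")])
            for mode in ("DISCOVERY_AND_ACCESS",)])
        # both modes are covered and nothing can fail
        with pytest.raises(IntentUnsatisfiable):
            generate_request(p, "INCOMPATIBLE", seed=1)

    def test_obligatory_item_is_declared(self):
        p = build_profile([body(permissions=[PermissionEntry(
            concept_id="use_for_diseases", value="Limited",
            free_text="A, B[Obligatory], and C")])])
        req = generate_request(p, "COMPATIBLE", seed=3)
        assert "b" in {u.casefold() for u in req.declared_uses["use_for_diseases"]}
        assert adjudicate(p, req).overall is Overall.PERMIT

    @pytest.mark.parametrize("intent,outcome", [
        ("COMPATIBLE", Overall.PERMIT), ("INCOMPATIBLE", Overall.DENY)])
    def test_intent_contract_sample(self, intent, outcome):
        produced = 0
        for seed in range(60):
            p = generate_profile(GeneratorParams(seed=seed))
            try:
                req = generate_request(p, intent, seed=seed)
            except IntentUnsatisfiable:
                continue
            assert adjudicate(p, req).overall is outcome
            produced += 1
        assert produced >= 40

    def test_random_intent_is_reproducible(self):
        p = generate_profile(GeneratorParams(seed=7))
        assert generate_request(p, "RANDOM", seed=5) == \
            generate_request(p, "RANDOM", seed=5)


class TestMutateInvalid:
    def test_r6_adds_free_text_to_unset_concept(self):
        p = generate_profile(GeneratorParams(seed=11))
        mutant = mutate_invalid(p, "R6", seed=0)
        report = validate(mutant)
        assert report.rules_violated() == {"R6"}

    def test_r3_removes_mode_of_sharing(self):
        p = generate_profile(GeneratorParams(seed=11))
        mutant = mutate_invalid(p, "R3", seed=0)
        assert any(b.mode_of_sharing() is None for b in mutant.bodies)
        assert validate(mutant).rules_violated() == {"R3"}

    def test_r4_inapplicable_without_two_obligations(self):
        p = build_profile([body(permissions=[PermissionEntry(
            concept_id="research_use", value="Unrestricted")])])
        with pytest.raises(Exception) as exc_info:
            mutate_invalid(p, "R4", seed=0)
        assert "Obligatory" in str(exc_info.value)

    def test_mutations_are_seeded(self):
        p = generate_profile(GeneratorParams(seed=13))
        assert mutate_invalid(p, "R5", seed=9) == mutate_invalid(p, "R5", seed=9)
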