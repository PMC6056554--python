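"""Shared fixtures: registries, profile builders, and an independent
brute-force adjudication oracle used to cross-check the decision engine."""

from __future__ import annotations

import pytest

from adamatrix import (AccessRequest, ConceptDef, GeneratorParams, Header,
                       MainBody, MetaEntry, PermissionEntry, Profile,
                       Registry, TermEntry, default_registry,
                       generate_profile)


@pytest.fixture(scope="session")
def registry() -> Registry:
    return default_registry()


def build_profile(bodies, header_extra=None) -> Profile:
    """A profile with the three required header items plus given bodies."""
    values = {
        "profile_id": "prof-0001",
        "profile_version": "2016-12-15/v1.0",
        "resource_reference": "resource-0001",
    }
    if header_extra:
        values.update(header_extra)
    return Profile(header=Header(values=values), bodies=tuple(bodies))


def body(permissions=(), terms=(), meta_extra=(), mode="DISCOVERY_AND_ACCESS",
         rule=None) -> MainBody:
    meta = [MetaEntry(concept_id="mode_of_sharing", value=mode)]
    if rule:
        meta.append(MetaEntry(concept_id="interpretation_rule", value=rule))
    meta.extend(meta_extra)
    return MainBody(permissions=tuple(permissions), terms=tuple(terms),
                    meta=tuple(meta))


@pytest.fixture
def minimal_profile() -> Profile:
    return build_profile([body(
        permissions=[PermissionEntry(concept_id="research_use",
                                     value="Unrestricted")])])


@pytest.fixture(scope="session")
def corpus() -> list[Profile]:
    """A 500-profile seeded synthetic corpus (one per seed)."""
    return [generate_profile(GeneratorParams(seed=s)) for s in range(500)]


# ---------------------------------------------------------------------------
# tiny registry for exhaustive decision checks
# ---------------------------------------------------------------------------

def _c(cid, section, **kw):
    return ConceptDef(concept_id=cid, section=section, label=cid, **kw)


EXTENDED = ("Unrestricted", "Limited", "Unrestricted[Obligatory]",
            "Limited[Obligatory]", "Forbidden")


@pytest.fixture(scope="session")
def mini_registry() -> Registry:
    """Four Permissions concepts, one Terms concept, the two Meta concepts."""
    return Registry(version_tag="mini-test", concepts=(
        _c("profile_id", "HEADER", requirement="REQUIRED"),
        _c("p1", "PERMISSIONS", value_domain=EXTENDED,
           supports_forbidden_obligatory=True, free_text_slots=1),
        _c("p2", "PERMISSIONS", value_domain=EXTENDED,
           supports_forbidden_obligatory=True, free_text_slots=1),
        _c("p3", "PERMISSIONS", value_domain=EXTENDED,
           supports_forbidden_obligatory=True, free_text_slots=1),
        _c("geo", "PERMISSIONS", value_domain=("Unrestricted", "Limited"),
           free_text_slots=1),
        _c("no_collab", "TERMS", value_domain=("True", "Untrue"),
           free_text_slots=1),
        _c("no_recontact", "TERMS", value_domain=("True", "Untrue"),
           free_text_slots=2),
        _c("mode_of_sharing", "META",
           value_domain=("DISCOVERY", "ACCESS", "DISCOVERY_AND_ACCESS"),
           requirement="REQUIRED"),
        _c("interpretation_rule", "META",
           value_domain=("MEET_ALL", "MEET_ANY"), requirement="CONDITIONAL"),
    ))


def mini_profile(bodies) -> Profile:
    return Profile(header=Header(values={"profile_id": "mini"}),
                   bodies=tuple(bodies))


# ---------------------------------------------------------------------------
# brute-force oracle: a from-first-principles re-statement of the
# adjudication truth table, sharing no code with adamatrix.decision
# ---------------------------------------------------------------------------

def _oracle_list(text):
    """Very small re-parse of token lists: returns (labels, obligatory) or None."""
    s = text.strip().rstrip(".")
    if "\n" in s or ". " in s:
        return None
    chunks = [c.strip() for c in s.split(",")]
    if any(not c for c in chunks):
        return None
    if len(chunks) > 1 and chunks[-1].lower().startswith("and "):
        chunks[-1] = chunks[-1][4:].strip()
    labels, oblig = [], []
    for i, c in enumerate(chunks):
        flag = c.lower().endswith("[obligatory]")
        if flag:
            c = c[: c.lower().rindex("[obligatory]")].strip()
        if i == 0 and len(chunks) > 1 and " " in c:
            c = c.rsplit(" ", 1)[1]
        if not c or " " in c:
            return None
        labels.append(c.casefold())
        if flag:
            oblig.append(c.casefold())
    return labels, oblig


def oracle_adjudicate(profile: Profile, request: AccessRequest) -> str:
    """PERMIT / DENY / REFER by direct enumeration of the semantics."""
    mode = request.mode.value
    outcomes = []
    for b in profile.bodies:
        sharing = next(e.value for e in b.meta
                       if e.concept_id == "mode_of_sharing")
        if sharing != mode and sharing != "DISCOVERY_AND_ACCESS":
            continue
        rule = next((e.value for e in b.meta
                     if e.concept_id == "interpretation_rule"), None) or "MEET_ALL"
        fails = refers = 0
        obligations = []  # True / False / None (unknowable)
        for e in b.permissions:
            req = {x.strip().casefold()
                   for x in request.declared_uses.get(e.concept_id, ())}
            v = e.value
            if v == "Forbidden":
                if req:
                    fails += 1
                continue
            parsed = _oracle_list(e.free_text) if e.free_text else None
            if e.free_text and parsed is None:
                refers += 1
                continue
            if v in ("Unrestricted[Obligatory]", "Limited[Obligatory]"):
                obligations.append(len(req) > 0)
            if parsed:
                labels, oblig = parsed
                for lab in oblig:
                    obligations.append(lab in req)
                if v in ("Limited", "Limited[Obligatory]") and \
                        not set(req) <= set(labels):
                    fails += 1
            elif v in ("Limited", "Limited[Obligatory]") and req:
                refers += 1
        for e in b.terms:
            if e.free_text_2 and e.free_text_2.strip():
                obligations.append(None)
            if e.value == "Untrue" and mode == "ACCESS" and \
                    e.concept_id not in request.accepted_terms:
                fails += 1
        if rule == "MEET_ALL":
            if any(o is False for o in obligations):
                fails += 1
            elif any(o is None for o in obligations):
                refers += 1
        else:  # MEET_ANY
            if obligations and not any(o is True for o in obligations):
                if any(o is None for o in obligations):
                    refers += 1
                else:
                    fails += 1
        outcomes.append("FAIL" if fails else ("REFER" if refers else "PASS"))
    if "PASS" in outcomes:
        return "PERMIT"
    if not outcomes or all(o == "FAIL" for o in outcomes):
        return "DENY"
    return "REFER"
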