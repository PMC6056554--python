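"""Seeded generator of Profiles and AccessRequests.

No external corpus of data-use profiles exists to test against, so
this module fabricates them: validator-passing Profiles drawn from the
full combinatorial space of the model (all five Permissions values,
both Terms values, multi-body alternatives, Obligatory markers with
their interpretation rule), requests of a demanded intent
(compatible / incompatible / random), and minimal single-rule
mutations for exercising the validator.  A single integer seed drives
one reproducible stream; no global random state is touched.

The valid-profile generator emits only formulaically evaluable
content: free text is always list-shaped and the recontact
"must occur" slot is left empty, so a COMPATIBLE request provably
exists for every generated profile.  Prose free text and recontact
obligations — the REFER-grade inputs — are exercised by constructing
profiles explicitly.
"""

from __future__ import annotations

import random
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .conditions import ConditionItem, render_condition_list
from .decision import AccessMode, AccessRequest, Overall, adjudicate
from .errors import IntentUnsatisfiable, MutationInapplicable
from .profile import (Header, InterpretationRule, MainBody, MetaEntry,
                      ModeOfSharing, PermissionEntry, Profile, TermEntry,
                      count_obligatory)
from .registry import Registry, Section, default_registry
from .serialization import canonicalize
from .validation import RULE_IDS, validate

DEFAULT_VOCAB = ("A", "B", "C", "D", "E", "F")

_PREAMBLE = "Use permitted for research on diseases"


class GeneratorParams(BaseModel):
    """Knobs of the profile generator.

    Defaults describe a realistically mixed registry population: most
    asserted permissions are open, a substantial minority are Limited
    with an explicit permitted list, a small fraction Forbidden, and
    obligations appear often enough that multi-obligation bodies (and
    hence the interpretation rule) occur routinely.  The label pool
    echoes short disease tokens.
    """

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_bodies: tuple[int, int] = (1, 2)
    p_limited: float = 0.4
    p_forbidden: float = 0.15
    p_obligatory: float = 0.2
    vocab: tuple[str, ...] = DEFAULT_VOCAB
    strictness: bool = True

    @model_validator(mode="after")
    def _check(self):
        for name in ("p_limited", "p_forbidden", "p_obligatory"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be within [0, 1]")
        if not self.vocab:
            raise ValueError("vocab must be non-empty")
        lo, hi = self.n_bodies
        if not 1 <= lo <= hi:
            raise ValueError("n_bodies must be a range with 1 <= lo <= hi")
        return self


def _make_permission(rng: random.Random, concept, params: GeneratorParams
                     ) -> PermissionEntry:
    restricted = not concept.supports_forbidden_obligatory
    if not restricted and rng.random() < params.p_forbidden:
        return PermissionEntry(concept_id=concept.concept_id, value="Forbidden")
    limited = rng.random() < params.p_limited
    obligatory = not restricted and rng.random() < params.p_obligatory
    value = ("Limited" if limited else "Unrestricted") + \
            ("[Obligatory]" if obligatory else "")
    free_text = None
    if limited:
        n_items = rng.randint(1, min(4, len(params.vocab)))
        labels = rng.sample(params.vocab, n_items)
        items = [ConditionItem(
            label=lab,
            obligatory=(not restricted and rng.random() < params.p_obligatory))
            for lab in labels]
        preamble = _PREAMBLE if len(items) >= 2 and rng.random() < 0.5 else ""
        free_text = render_condition_list(items, preamble)
    return PermissionEntry(concept_id=concept.concept_id, value=value,
                           free_text=free_text)


def generate_profile(params: GeneratorParams,
                     registry: Optional[Registry] = None) -> Profile:
    """One validator-passing Profile, identical for identical seeds."""
    registry = registry or default_registry()
    rng = random.Random(params.seed)
    required = registry.required_ids(Section.HEADER)
    header_values = {cid: f"{cid}:{rng.randrange(10**8):08d}" for cid in required}
    perm_concepts = [registry[cid] for cid in registry.section_ids(Section.PERMISSIONS)]
    term_ids = registry.section_ids(Section.TERMS)

    bodies = []
    for _ in range(rng.randint(*params.n_bodies)):
        permissions = []
        for concept in rng.sample(perm_concepts, rng.randint(1, 5)):
            permissions.append(_make_permission(rng, concept, params))
        terms = []
        for cid in rng.sample(term_ids, rng.randint(0, 3)):
            value = "Untrue" if rng.random() < 0.4 else "True"
            free_text = None
            if value == "Untrue" and rng.random() < 0.5:
                free_text = "condition-ref-%04d" % rng.randrange(10**4)
            terms.append(TermEntry(concept_id=cid, value=value, free_text=free_text))
        meta = [MetaEntry(concept_id="mode_of_sharing",
                          value=rng.choice(list(ModeOfSharing)).value)]
        body = MainBody(permissions=tuple(permissions), terms=tuple(terms),
                        meta=tuple(meta))
        if count_obligatory(body) >= 2 or rng.random() < 0.2:
            rule = rng.choice(list(InterpretationRule)).value
            meta.append(MetaEntry(concept_id="interpretation_rule", value=rule))
            body = body.model_copy(update={"meta": tuple(meta)})
        bodies.append(body)

    profile = canonicalize(
        Profile(header=Header(values=header_values), bodies=tuple(bodies)),
        registry)
    if params.strictness:
        report = validate(profile, registry)
        assert report.valid, f"generator produced invalid profile: {report}"
    return profile


# ---------------------------------------------------------------------------
# requests of a demanded intent
# ---------------------------------------------------------------------------

def _compatible_for_body(rng: random.Random, body: MainBody,
                         vocab: tuple[str, ...]) -> Optional[AccessRequest]:
    """A request that makes every concept of this body PASS, or None."""
    mode_value = body.mode_of_sharing()
    mode = (rng.choice([AccessMode.DISCOVERY, AccessMode.ACCESS])
            if mode_value == ModeOfSharing.DISCOVERY_AND_ACCESS.value
            else AccessMode(mode_value))
    declared: dict[str, tuple[str, ...]] = {}
    for entry in body.permissions:
        if entry.value is None or entry.value == "Forbidden":
            continue
        if entry.free_text and entry.condition_items is None:
            return None  # prose => REFER is unavoidable for this body
        items = entry.condition_items or []
        labels = [it.label for it in items if it.obligatory]
        needs_any = entry.value.endswith("[Obligatory]")
        if needs_any and not labels:
            if items:
                labels = [rng.choice(items).label]
            elif entry.value.startswith("Unrestricted"):
                labels = [rng.choice(vocab)]
            else:
                return None  # Limited[Obligatory] with no stated list
        if entry.value.startswith("Limited") and not entry.free_text and labels:
            return None
        if labels:
            declared[entry.concept_id] = tuple(dict.fromkeys(labels))
    if any(e.free_text_2 and e.free_text_2.strip() for e in body.terms):
        return None  # recontact obligation is REFER-grade
    accepted = tuple(e.concept_id for e in body.terms if e.value == "Untrue")
    return AccessRequest(mode=mode, declared_uses=declared, accepted_terms=accepted)


def _failure_for_body(body: MainBody, mode: AccessMode
                      ) -> Optional[tuple[Optional[tuple[str, str]], bool]]:
    """A monotone-safe failure mechanism: (declaration, via_terms)."""
    for entry in body.permissions:
        if entry.value == "Forbidden":
            return (entry.concept_id, "zz-unrelated-use"), False
        if entry.value and entry.value.startswith("Limited") and \
                entry.condition_items:
            return (entry.concept_id, "zz-unrelated-use"), False
    if mode is AccessMode.ACCESS and \
            any(e.value == "Untrue" for e in body.terms):
        return None, True  # fails by simply not accepting the term
    return None


def generate_request(profile: Profile,
                     intent: str = "RANDOM",
                     seed: int = 0,
                     registry: Optional[Registry] = None) -> AccessRequest:
    """A request whose adjudication outcome matches ``intent``.

    ``COMPATIBLE`` requests adjudicate to PERMIT and ``INCOMPATIBLE``
    to DENY; ``RANDOM`` is unconstrained.  When the profile admits no
    request of the demanded intent (an all-Unrestricted profile cannot
    be denied under a mode it offers), :class:`IntentUnsatisfiable` is
    raised rather than silently returning the wrong kind of request.
    """
    registry = registry or default_registry()
    rng = random.Random(seed)
    vocab = DEFAULT_VOCAB

    if intent == "RANDOM":
        perm_ids = registry.section_ids(Section.PERMISSIONS)
        term_ids = registry.section_ids(Section.TERMS)
        declared = {cid: tuple(rng.sample(vocab, rng.randint(1, 3)))
                    for cid in rng.sample(perm_ids, rng.randint(0, 4))}
        return AccessRequest(
            mode=rng.choice(list(AccessMode)),
            declared_uses=declared,
            accepted_terms=tuple(rng.sample(term_ids, rng.randint(0, 3))))

    if intent == "COMPATIBLE":
        order = list(profile.bodies)
        rng.shuffle(order)
        for body in order:
            request = _compatible_for_body(rng, body, vocab)
            if request is None:
                continue
            if adjudicate(profile, request, registry).overall is Overall.PERMIT:
                return request
        raise IntentUnsatisfiable(
            "no body of this profile admits a PERMIT-guaranteeing request")

    if intent == "INCOMPATIBLE":
        modes = list(AccessMode)
        rng.shuffle(modes)
        covered = {m for b in profile.bodies
                   for m in AccessMode
                   if ModeOfSharing(b.mode_of_sharing()).covers(
                       ModeOfSharing(m.value))}
        for mode in modes:
            if mode not in covered:
                # profile offers no body for this mode: any request is denied
                return AccessRequest(mode=mode)
            eligible = [b for b in profile.bodies
                        if ModeOfSharing(b.mode_of_sharing()).covers(
                            ModeOfSharing(mode.value))]
            declared: dict[str, tuple[str, ...]] = {}
            feasible = True
            for body in eligible:
                mechanism = _failure_for_body(body, mode)
                if mechanism is None:
                    feasible = False
                    break
                declaration, _ = mechanism
                if declaration is not None:
                    cid, label = declaration
                    declared[cid] = tuple(dict.fromkeys(
                        declared.get(cid, ()) + (label,)))
            if not feasible:
                continue
            request = AccessRequest(mode=mode, declared_uses=declared)
            if adjudicate(profile, request, registry).overall is Overall.DENY:
                return request
        raise IntentUnsatisfiable(
            "profile admits no DENY: every eligible body is unfailable")

    raise ValueError(f"unknown intent {intent!r}")


def relax_profile(profile: Profile, seed: int = 0) -> Profile:
    """Apply one random permission relaxation (or none if nothing applies).

    A relaxation moves a value one step along Forbidden -> Limited ->
    Unrestricted, or widens a parsed permitted list with a fresh
    non-obligatory item.  Relaxations can only ever widen what a
    request may do, so they never turn a PERMIT into a DENY.
    """
    rng = random.Random(seed)
    k = rng.randrange(len(profile.bodies))
    body = profile.bodies[k]
    candidates = [i for i, e in enumerate(body.permissions)
                  if e.value in ("Forbidden", "Limited")
                  or (e.value and e.value.startswith("Limited")
                      and e.condition_items)]
    if not candidates:
        return profile
    i = rng.choice(candidates)
    entry = body.permissions[i]
    if entry.value == "Forbidden":
        new = entry.model_copy(update={"value": "Limited", "free_text": None})
    elif entry.condition_items and rng.random() < 0.5:
        new = entry.model_copy(update={
            "free_text": entry.free_text.rstrip(".") + ", Zextra"})
    else:
        new = entry.model_copy(update={
            "value": entry.value.replace("Limited", "Unrestricted")})
    permissions = list(body.permissions)
    permissions[i] = new
    return _replace_body(profile, k,
                         body.model_copy(update={"permissions": tuple(permissions)}))


# ---------------------------------------------------------------------------
# single-rule mutations
# ---------------------------------------------------------------------------

def _replace_body(profile: Profile, k: int, body: MainBody) -> Profile:
    bodies = list(profile.bodies)
    bodies[k] = body
    return profile.model_copy(update={"bodies": tuple(bodies)})


def mutate_invalid(profile: Profile, rule_id: str, seed: int = 0,
                   registry: Optional[Registry] = None) -> Profile:
    """Minimally mutate a valid profile so it violates exactly ``rule_id``.

    Raises :class:`MutationInapplicable` when the profile offers no
    cheap violation (e.g. R4 on a profile with fewer than two
    Obligatory assertions in every body).
    """
    registry = registry or default_registry()
    if rule_id not in RULE_IDS:
        raise ValueError(f"unknown rule {rule_id!r}")
    rng = random.Random(seed)
    k = rng.randrange(len(profile.bodies))
    body = profile.bodies[k]

    if rule_id == "R1":
        required = registry.required_ids(Section.HEADER)
        cid = rng.choice(required)
        values = dict(profile.header.values)
        values[cid] = ""
        return profile.model_copy(update={"header": Header(values=values)})

    if rule_id == "R2":
        return _replace_body(profile, k, body.model_copy(
            update={"permissions": (), "terms": ()}))

    if rule_id == "R3":
        meta = tuple(e for e in body.meta if e.concept_id != "mode_of_sharing")
        return _replace_body(profile, k, body.model_copy(update={"meta": meta}))

    if rule_id == "R4":
        candidates = [i for i, b in enumerate(profile.bodies)
                      if count_obligatory(b) >= 2]
        if not candidates:
            raise MutationInapplicable(
                "no body carries two or more Obligatory assertions")
        k = rng.choice(candidates)
        body = profile.bodies[k]
        meta = tuple(e for e in body.meta if e.concept_id != "interpretation_rule")
        return _replace_body(profile, k, body.model_copy(update={"meta": meta}))

    if rule_id == "R5":
        restricted = [c.concept_id for c in registry.concepts
                      if c.section is Section.PERMISSIONS
                      and not c.supports_forbidden_obligatory]
        cid = rng.choice(restricted)
        entry = PermissionEntry(concept_id=cid, value="Forbidden")
        permissions = tuple(e for e in body.permissions if e.concept_id != cid)
        return _replace_body(profile, k, body.model_copy(
            update={"permissions": permissions + (entry,)}))

    if rule_id == "R6":
        present = {e.concept_id for e in body.permissions}
        unset = [cid for cid in registry.section_ids(Section.PERMISSIONS)
                 if cid not in present]
        cid = rng.choice(unset)
        entry = PermissionEntry(concept_id=cid, value=None,
                                free_text="See the accompanying governance "
                                          "documentation for details.")
        return _replace_body(profile, k, body.model_copy(
            update={"permissions": body.permissions + (entry,)}))

    # R7: out-of-domain token on an extended (non-restricted) concept
    extended = [c.concept_id for c in registry.concepts
                if c.section is Section.PERMISSIONS
                and c.supports_forbidden_obligatory]
    cid = rng.choice(extended)
    entry = PermissionEntry(concept_id=cid, value="Maybe")
    permissions = tuple(e for e in body.permissions if e.concept_id != cid)
    return _replace_body(profile, k, body.model_copy(
        update={"permissions": permissions + (entry,)}))
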