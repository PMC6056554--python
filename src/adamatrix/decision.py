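"""Formulaic adjudication of discovery/access requests against Profiles.

A custodian holding a validated Profile can screen requests without a
human in the loop whenever the decision reduces to evaluating
straightforward Permissions and Terms values.  The engine walks every
mode-eligible Main Body, renders a per-concept verdict (PASS / FAIL /
REFER), applies the body's interpretation rule to the collected
Obligatory assertions, and combines bodies as *alternatives*: a single
body whose concepts all pass permits the request.

REFER is the deliberate boundary of automation: it is produced only by
non-formulaic inputs — prose free text that the list grammar cannot
parse (which may hide conditionalities), a Limited value whose
limitation is never spelled out, or the recontact "must occur" slot —
and routes the request to a human (the DAC).  Obligations that a
request provably omits are FAILs, not REFERs: an obligated use must
occur, so omitting it is formulaically incompatible.

Terms are enforced only when access is actually sought; in a discovery
context an applicable condition is merely useful to know about.
"""

from __future__ import annotations

import enum
import json
from typing import Iterable, Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict, Field

from .errors import InvalidProfile, MalformedDocument, UnknownConcept
from .profile import (InterpretationRule, ModeOfSharing, PermissionEntry,
                      PermissionValue, Profile, TermEntry, TermValue)
from .registry import Registry, Section, default_registry
from .validation import validate


class AccessMode(str, enum.Enum):
    DISCOVERY = "DISCOVERY"
    ACCESS = "ACCESS"


class Verdict(str, enum.Enum):
    PASS = "PASS"
    FAIL = "FAIL"
    REFER = "REFER"


class Overall(str, enum.Enum):
    PERMIT = "PERMIT"
    DENY = "DENY"
    REFER = "REFER"


def normalize_label(label: str) -> str:
    return label.strip().casefold()


class AccessRequest(BaseModel):
    """A requester's declared uses and accepted conditions.

    ``declared_uses`` maps a Permissions concept to the labels the
    requester asserts for it (diseases studied, requester category,
    country, ...); ``accepted_terms`` names the Terms concepts whose
    conditions the requester agrees to comply with.  Matching is exact
    after trimming and case-folding — no synonym or ontology expansion.
    """

    model_config = ConfigDict(frozen=True)

    mode: AccessMode
    declared_uses: dict[str, tuple[str, ...]] = Field(default_factory=dict)
    accepted_terms: tuple[str, ...] = ()

    def uses_for(self, concept_id: str) -> frozenset[str]:
        return frozenset(normalize_label(x)
                         for x in self.declared_uses.get(concept_id, ()))

    def accepts(self, concept_id: str) -> bool:
        return concept_id in self.accepted_terms


class ConceptVerdict(BaseModel):
    model_config = ConfigDict(frozen=True)

    concept_id: str
    verdict: Verdict
    rationale: str


class Obligation(BaseModel):
    """One Obligatory assertion and whether the request satisfies it.

    ``satisfied`` is ``None`` for obligations outside formulaic reach
    (the prose recontact "must occur" slot)."""

    model_config = ConfigDict(frozen=True)

    concept_id: str
    description: str
    satisfied: Optional[bool]


class BodyDecision(BaseModel):
    model_config = ConfigDict(frozen=True)

    body_index: int
    eligible: bool
    verdicts: tuple[ConceptVerdict, ...] = ()
    outcome: Optional[Verdict] = None


class Decision(BaseModel):
    model_config = ConfigDict(frozen=True)

    overall: Overall
    per_body: tuple[BodyDecision, ...] = ()
    selected_body: Optional[int] = None


# ---------------------------------------------------------------------------
# concept-level evaluation
# ---------------------------------------------------------------------------

def _eval_permission(entry: PermissionEntry, requested: frozenset[str]
                     ) -> tuple[ConceptVerdict, list[Obligation]]:
    """Base verdict plus the obligations this entry contributes."""
    cid = entry.concept_id
    value = entry.value
    if value is None:
        return ConceptVerdict(concept_id=cid, verdict=Verdict.PASS,
                              rationale="no main value: imposes no constraint"), []
    if value == PermissionValue.FORBIDDEN.value:
        if requested:
            return ConceptVerdict(
                concept_id=cid, verdict=Verdict.FAIL,
                rationale="use is Forbidden but the request declares it"), []
        return ConceptVerdict(concept_id=cid, verdict=Verdict.PASS,
                              rationale="Forbidden, and no such use declared"), []

    items = entry.condition_items
    if entry.free_text and items is None:
        return ConceptVerdict(
            concept_id=cid, verdict=Verdict.REFER,
            rationale="free text is not list-shaped; it may state "
                      "conditionalities a human must read"), []

    obligations: list[Obligation] = []
    if value in (PermissionValue.UNRESTRICTED_OBLIGATORY.value,
                 PermissionValue.LIMITED_OBLIGATORY.value):
        obligations.append(Obligation(
            concept_id=cid,
            description=f"use under {cid!r} must occur",
            satisfied=bool(requested)))
    if items:
        for it in items:
            if it.obligatory:
                obligations.append(Obligation(
                    concept_id=cid,
                    description=f"use must relate to {it.label!r}",
                    satisfied=normalize_label(it.label) in requested))

    if value in (PermissionValue.UNRESTRICTED.value,
                 PermissionValue.UNRESTRICTED_OBLIGATORY.value):
        return ConceptVerdict(concept_id=cid, verdict=Verdict.PASS,
                              rationale="use is Unrestricted"), obligations

    # Limited / Limited[Obligatory]
    if items is None:  # Limited with no elaboration at all
        if requested:
            return ConceptVerdict(
                concept_id=cid, verdict=Verdict.REFER,
                rationale="Limited, but the limitation is not spelled out"), obligations
        return ConceptVerdict(concept_id=cid, verdict=Verdict.PASS,
                              rationale="Limited, and no such use declared"), obligations
    permitted = {normalize_label(it.label) for it in items}
    extra = requested - permitted
    if extra:
        return ConceptVerdict(
            concept_id=cid, verdict=Verdict.FAIL,
            rationale=f"declared use(s) {sorted(extra)} outside the "
                      "permitted list"), obligations
    return ConceptVerdict(concept_id=cid, verdict=Verdict.PASS,
                          rationale="declared uses all among permitted items"), obligations


def _eval_term(entry: TermEntry, accepted: bool, mode: AccessMode
               ) -> tuple[ConceptVerdict, list[Obligation]]:
    cid = entry.concept_id
    obligations: list[Obligation] = []
    if entry.free_text_2 and entry.free_text_2.strip():
        obligations.append(Obligation(
            concept_id=cid,
            description="stated recontact of data subjects must occur",
            satisfied=None))
    if entry.value == TermValue.TRUE.value or entry.value is None:
        return ConceptVerdict(concept_id=cid, verdict=Verdict.PASS,
                              rationale="no such condition applies"), obligations
    if mode is AccessMode.DISCOVERY:
        return ConceptVerdict(
            concept_id=cid, verdict=Verdict.PASS,
            rationale="condition applies; may be useful to know about "
                      "in a discovery context"), obligations
    if accepted:
        return ConceptVerdict(concept_id=cid, verdict=Verdict.PASS,
                              rationale="condition applies and was accepted"), obligations
    return ConceptVerdict(
        concept_id=cid, verdict=Verdict.FAIL,
        rationale="condition applies and was not accepted"), obligations


def _fold(base: ConceptVerdict, obligations: Iterable[Obligation]) -> ConceptVerdict:
    """Fold per-entry obligations into the verdict (MEET_ALL semantics)."""
    if base.verdict is not Verdict.PASS:
        return base
    unmet = [o for o in obligations if o.satisfied is False]
    if unmet:
        return base.model_copy(update={
            "verdict": Verdict.FAIL,
            "rationale": f"obligation unmet: {unmet[0].description}"})
    unknown = [o for o in obligations if o.satisfied is None]
    if unknown:
        return base.model_copy(update={
            "verdict": Verdict.REFER,
            "rationale": f"obligation outside formulaic evaluation: "
                         f"{unknown[0].description}"})
    return base


def evaluate_permission(entry: PermissionEntry, requested: Iterable[str],
                        rule: Optional[InterpretationRule] = None) -> ConceptVerdict:
    """Verdict for one Permissions entry against the declared uses.

    Under ``MEET_ANY`` the entry's obligations are left to the
    body-level pooling and only the base constraint is judged here;
    otherwise (``MEET_ALL`` or no rule) every obligation this entry
    raises must be met by the request.
    """
    req = frozenset(normalize_label(x) for x in requested)
    base, obligations = _eval_permission(entry, req)
    if rule is InterpretationRule.MEET_ANY:
        return base
    return _fold(base, obligations)


def evaluate_terms(entry: TermEntry, accepted: Iterable[str],
                   mode: AccessMode) -> ConceptVerdict:
    """Verdict for one Terms entry given the accepted term concepts."""
    base, obligations = _eval_term(entry, entry.concept_id in set(accepted), mode)
    return _fold(base, obligations)


# ---------------------------------------------------------------------------
# body- and profile-level adjudication
# ---------------------------------------------------------------------------

def _adjudicate_body(body, body_index: int, request: AccessRequest) -> BodyDecision:
    mode_value = body.mode_of_sharing()
    eligible = (mode_value is not None
                and ModeOfSharing(mode_value).covers(ModeOfSharing(request.mode.value)))
    if not eligible:
        return BodyDecision(body_index=body_index, eligible=False)

    rule_value = body.interpretation_rule()
    rule = InterpretationRule(rule_value) if rule_value else None
    meet_any = rule is InterpretationRule.MEET_ANY

    verdicts: list[ConceptVerdict] = []
    pooled: list[Obligation] = []
    for entry in body.permissions:
        base, obligations = _eval_permission(entry, request.uses_for(entry.concept_id))
        pooled.extend(obligations)
        verdicts.append(base if meet_any else _fold(base, obligations))
    for entry in body.terms:
        base, obligations = _eval_term(
            entry, request.accepts(entry.concept_id), request.mode)
        pooled.extend(obligations)
        verdicts.append(base if meet_any else _fold(base, obligations))

    if meet_any and pooled:
        if not any(o.satisfied for o in pooled):
            unknown = any(o.satisfied is None for o in pooled)
            verdicts.append(ConceptVerdict(
                concept_id="interpretation_rule",
                verdict=Verdict.REFER if unknown else Verdict.FAIL,
                rationale="MEET_ANY: no Obligatory assertion is "
                          + ("provably satisfied" if unknown else "satisfied")))

    if any(v.verdict is Verdict.FAIL for v in verdicts):
        outcome = Verdict.FAIL
    elif any(v.verdict is Verdict.REFER for v in verdicts):
        outcome = Verdict.REFER
    else:
        outcome = Verdict.PASS
    return BodyDecision(body_index=body_index, eligible=True,
                        verdicts=tuple(verdicts), outcome=outcome)


def adjudicate(profile: Profile, request: AccessRequest,
               registry: Optional[Registry] = None) -> Decision:
    """Decide one request against one Profile.

    The profile must pass validation (:class:`InvalidProfile`
    otherwise).  Bodies whose Mode of sharing does not cover the
    request's mode are ineligible; among eligible bodies, any body with
    all concepts passing permits the request, all bodies failing denies
    it, and anything else is referred to a human.  A profile offering
    no body for the requested mode denies it.
    """
    registry = registry or default_registry()
    report = validate(profile, registry)
    if not report.valid:
        raise InvalidProfile(report)
    for cid in request.declared_uses:
        concept = registry.get(cid)
        if concept is None or concept.section is not Section.PERMISSIONS:
            raise UnknownConcept(f"declared_uses names no PERMISSIONS concept {cid!r}")
    for cid in request.accepted_terms:
        concept = registry.get(cid)
        if concept is None or concept.section is not Section.TERMS:
            raise UnknownConcept(f"accepted_terms names no TERMS concept {cid!r}")

    per_body = tuple(_adjudicate_body(body, k, request)
                     for k, body in enumerate(profile.bodies))
    eligible = [b for b in per_body if b.eligible]
    passing = [b for b in eligible if b.outcome is Verdict.PASS]
    if passing:
        return Decision(overall=Overall.PERMIT, per_body=per_body,
                        selected_body=passing[0].body_index)
    if not eligible or all(b.outcome is Verdict.FAIL for b in eligible):
        return Decision(overall=Overall.DENY, per_body=per_body)
    return Decision(overall=Overall.REFER, per_body=per_body)


def screen_profiles(profiles: Sequence[Profile], request: AccessRequest,
                    registry: Optional[Registry] = None
                    ) -> list[tuple[Profile, Decision]]:
    """Discovery prescreening: keep profiles that permit or refer.

    Filters a collection down to the resources a researcher could
    plausibly use, so ineligible requests never reach the DAC.
    """
    if request.mode is not AccessMode.DISCOVERY:
        raise ValueError("screen_profiles is defined for DISCOVERY requests")
    registry = registry or default_registry()
    out = []
    for profile in profiles:
        decision = adjudicate(profile, request, registry)
        if decision.overall in (Overall.PERMIT, Overall.REFER):
            out.append((profile, decision))
    return out


# ---------------------------------------------------------------------------
# request document dialect
# ---------------------------------------------------------------------------

def request_from_json(payload: str, registry: Optional[Registry] = None,
                      *, strict: bool = True) -> AccessRequest:
    """Decode the AccessRequest JSON dialect.

    ``{"mode": "ACCESS", "declared_uses": {"<concept>": ["label", ...]},
    "accepted_terms": ["<concept>", ...]}``
    """
    registry = registry or default_registry()
    try:
        doc = json.loads(payload)
    except json.JSONDecodeError as exc:
        raise MalformedDocument(f"not valid JSON: {exc.msg}", f"line {exc.lineno}")
    if not isinstance(doc, dict) or "mode" not in doc:
        raise MalformedDocument("request must be an object with a 'mode'", "$")
    try:
        request = AccessRequest(
            mode=AccessMode(doc["mode"]),
            declared_uses={k: tuple(v) for k, v in doc.get("declared_uses", {}).items()},
            accepted_terms=tuple(doc.get("accepted_terms", ())),
        )
    except (ValueError, TypeError) as exc:
        raise MalformedDocument(f"bad request document: {exc}", "$")
    if strict:
        for cid in (*request.declared_uses, *request.accepted_terms):
            if cid not in registry:
                raise UnknownConcept(f"unknown concept id {cid!r}")
    return request


def request_to_json(request: AccessRequest) -> str:
    doc = {"mode": request.mode.value}
    if request.declared_uses:
        doc["declared_uses"] = {k: list(request.declared_uses[k])
                                for k in sorted(request.declared_uses)}
    if request.accepted_terms:
        doc["accepted_terms"] = sorted(request.accepted_terms)
    return json.dumps(doc, indent=1, ensure_ascii=False) + "\n"
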