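"""The seven-rule Profile validator.

As a Profile grows, so does the chance of internal inconsistencies or
anomalous entries (say, free text under a concept that carries no main
value).  Validation evaluates seven rules against a structurally
decoded Profile and reports *every* violation as a machine-readable
finding — no short-circuiting, no exceptions.  The rule set is
table-driven (:data:`RULES`) so alternative wordings can replace it
without touching the API.

R1  all required HEADER items are present and non-empty;
R2  every Main Body asserts at least one Permissions or Terms value;
R3  every Main Body sets Mode of sharing;
R4  the interpretation rule is set wherever a body carries two or more
    Obligatory assertions;
R5  the three restricted use-location/organization/person concepts
    carry only Unrestricted or Limited;
R6  no free text under a concept with no main value;
R7  every value belongs to its concept's value domain (entries already
    flagged by R5 are not re-flagged, so the rules partition the
    violations).
"""

from __future__ import annotations

from typing import Callable, Optional

from pydantic import BaseModel, ConfigDict

from .errors import UnknownRule
from .profile import MainBody, Profile, count_obligatory
from .registry import Registry, Section, default_registry

RULE_IDS = ("R1", "R2", "R3", "R4", "R5", "R6", "R7")


class Finding(BaseModel):
    model_config = ConfigDict(frozen=True)

    rule_id: str
    location: str
    message: str


class ValidationReport(BaseModel):
    model_config = ConfigDict(frozen=True)

    findings: tuple[Finding, ...] = ()

    @property
    def valid(self) -> bool:
        return not self.findings

    def rules_violated(self) -> set[str]:
        return {f.rule_id for f in self.findings}


def _body_entries(body: MainBody):
    for attr in ("permissions", "terms", "meta"):
        for entry in getattr(body, attr):
            yield attr, entry


def _restricted_violation(entry, concept) -> bool:
    return (concept is not None
            and concept.section is Section.PERMISSIONS
            and not concept.supports_forbidden_obligatory
            and entry.value is not None
            and entry.value not in concept.value_domain)


def _r1(profile: Profile, registry: Registry):
    for cid in registry.required_ids(Section.HEADER):
        value = profile.header.values.get(cid)
        if value is None or not value.strip():
            yield f"header.{cid}", f"required Header item {cid!r} is missing or empty"


def _r2(profile: Profile, registry: Registry):
    for k, body in enumerate(profile.bodies):
        has_main = any(e.value is not None
                       for e in (*body.permissions, *body.terms))
        if not has_main:
            yield (f"body.{k}",
                   "body asserts no Permissions or Terms main value")


def _r3(profile: Profile, registry: Registry):
    for k, body in enumerate(profile.bodies):
        if not body.mode_of_sharing():
            yield f"body.{k}.meta.mode_of_sharing", "Mode of sharing is not set"


def _r4(profile: Profile, registry: Registry):
    for k, body in enumerate(profile.bodies):
        n = count_obligatory(body)
        if n >= 2 and not body.interpretation_rule():
            yield (f"body.{k}.meta.interpretation_rule",
                   f"{n} Obligatory assertions but no interpretation rule")


def _r5(profile: Profile, registry: Registry):
    for k, body in enumerate(profile.bodies):
        for entry in body.permissions:
            concept = registry.get(entry.concept_id)
            if _restricted_violation(entry, concept):
                yield (f"body.{k}.permissions.{entry.concept_id}",
                       f"restricted concept cannot take value {entry.value!r}")


def _r6(profile: Profile, registry: Registry):
    for k, body in enumerate(profile.bodies):
        for attr, entry in _body_entries(body):
            has_text = bool(entry.free_text) or \
                bool(getattr(entry, "free_text_2", None))
            if has_text and entry.value is None:
                yield (f"body.{k}.{attr}.{entry.concept_id}",
                       "free text under a concept with no main value")


def _r7(profile: Profile, registry: Registry):
    for k, body in enumerate(profile.bodies):
        for attr, entry in _body_entries(body):
            concept = registry.get(entry.concept_id)
            if concept is None or entry.value is None:
                continue
            if _restricted_violation(entry, concept):
                continue  # R5's finding, not R7's
            if entry.value not in concept.value_domain:
                yield (f"body.{k}.{attr}.{entry.concept_id}",
                       f"value {entry.value!r} not in domain "
                       f"{{{', '.join(concept.value_domain)}}}")


RuleCheck = Callable[[Profile, Registry], object]

RULES: dict[str, tuple[str, RuleCheck]] = {
    "R1": ("All required Header items must be present with non-empty values "
           "(3 of the 13 Header items are required).", _r1),
    "R2": ("Each Main Body must give a main value to at least one Permissions "
           "or Terms concept, so the Profile asserts at least one condition "
           "of use.", _r2),
    "R3": ("Each Main Body must set the required Meta-Conditions concept "
           "'Mode of sharing' (Discovery and/or Access).", _r3),
    "R4": ("When two or more entries across the Permissions and Terms "
           "sections of a body are stated to be [Obligatory], the "
           "'Interpretation rule if multiple Obligatory permissions are "
           "specified' must be filled in.", _r4),
    "R5": ("Use within countries/locations, use by organizations, and use by "
           "categories of person must unavoidably occur in some manner, so "
           "they cannot logically be 'Forbidden' or made 'Obligatory'.", _r5),
    "R6": ("A completed free-text field under a concept for which no main "
           "value has been entered is an anomalous entry.", _r6),
    "R7": ("Every entered value must come from its concept's own list of "
           "permitted values.", _r7),
}


def validate(profile: Profile, registry: Optional[Registry] = None) -> ValidationReport:
    """Evaluate all seven rules and report every violation."""
    registry = registry or default_registry()
    findings = []
    for rule_id in RULE_IDS:
        _, check = RULES[rule_id]
        for location, message in check(profile, registry):
            findings.append(Finding(rule_id=rule_id, location=location,
                                    message=message))
    return ValidationReport(findings=tuple(findings))


def explain_rule(rule_id: str) -> str:
    """Human-readable statement of one rule."""
    if rule_id not in RULES:
        raise UnknownRule(f"unknown rule {rule_id!r}; valid ids: {', '.join(RULE_IDS)}")
    return RULES[rule_id][0]
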