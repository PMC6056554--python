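"""The in-memory Profile data model.

A Profile is one Header (completed exactly once) plus one or more Main
Bodies, each holding Permissions, Terms and Meta-Conditions entries.
Multiple bodies state alternative combinations of data-use criteria —
for instance different rules for discovery versus access — entered
sequentially under the single Header.

Values are stored as the canonical serialized tokens (``Unrestricted``,
``Limited``, ``Unrestricted[Obligatory]``, ``Limited[Obligatory]``,
``Forbidden`` for Permissions; ``True``/``Untrue`` for Terms, which are
negative statements so ``True`` means *no* condition applies).  Value
fields are plain strings rather than closed enums on purpose: whether a
token belongs to a concept's domain is a validation finding, and the
validator must be able to inspect out-of-domain documents.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field

from .conditions import ConditionItem, parse_condition_list
from .errors import IndexOutOfRange, UnknownConcept, ValueNotInDomain
from .registry import Registry, Section


class PermissionValue(str, enum.Enum):
    """Canonical Permissions value tokens."""

    UNRESTRICTED = "Unrestricted"
    LIMITED = "Limited"
    UNRESTRICTED_OBLIGATORY = "Unrestricted[Obligatory]"
    LIMITED_OBLIGATORY = "Limited[Obligatory]"
    FORBIDDEN = "Forbidden"


class TermValue(str, enum.Enum):
    """Canonical Terms value tokens (negation semantics)."""

    TRUE = "True"
    UNTRUE = "Untrue"


class ModeOfSharing(str, enum.Enum):
    DISCOVERY = "DISCOVERY"
    ACCESS = "ACCESS"
    DISCOVERY_AND_ACCESS = "DISCOVERY_AND_ACCESS"

    def covers(self, mode: "ModeOfSharing") -> bool:
        return self is mode or self is ModeOfSharing.DISCOVERY_AND_ACCESS


class InterpretationRule(str, enum.Enum):
    """How multiple Obligatory entries combine: all must be met, or any."""

    MEET_ALL = "MEET_ALL"
    MEET_ANY = "MEET_ANY"


OBLIGATORY_VALUES = frozenset({
    PermissionValue.UNRESTRICTED_OBLIGATORY.value,
    PermissionValue.LIMITED_OBLIGATORY.value,
})


class Header(BaseModel):
    """Contextual information about the Profile and its resource."""

    model_config = ConfigDict(frozen=True)

    values: dict[str, str] = Field(default_factory=dict)


class PermissionEntry(BaseModel):
    """One Permissions concept with its main value and optional free text.

    ``value`` may be ``None`` only in structurally-decoded but invalid
    documents (the validator flags free text without a main value).
    ``condition_items`` is derived from the free text on access, never
    stored: when the text parses under the list grammar it yields the
    permitted items, otherwise it is prose for human readers.
    """

    model_config = ConfigDict(frozen=True)

    concept_id: str
    value: Optional[str] = None
    free_text: Optional[str] = None

    @property
    def condition_items(self) -> Optional[list[ConditionItem]]:
        if not self.free_text:
            return None
        return parse_condition_list(self.free_text)


class TermEntry(BaseModel):
    """One Terms concept: ``True`` = no such condition, ``Untrue`` = the
    condition applies (typically detailed in the free text).

    ``free_text_2`` exists only on the recontact concept, whose two
    slots capture recontacts that *may* and that *must* occur.
    """

    model_config = ConfigDict(frozen=True)

    concept_id: str
    value: Optional[str] = None
    free_text: Optional[str] = None
    free_text_2: Optional[str] = None


class MetaEntry(BaseModel):
    """One Meta-Conditions concept with a value from its own domain."""

    model_config = ConfigDict(frozen=True)

    concept_id: str
    value: Optional[str] = None
    free_text: Optional[str] = None


class MainBody(BaseModel):
    """One combination of data-use criteria (at most one entry per concept)."""

    model_config = ConfigDict(frozen=True)

    permissions: tuple[PermissionEntry, ...] = ()
    terms: tuple[TermEntry, ...] = ()
    meta: tuple[MetaEntry, ...] = ()

    def find(self, concept_id: str):
        for entry in (*self.permissions, *self.terms, *self.meta):
            if entry.concept_id == concept_id:
                return entry
        return None

    def mode_of_sharing(self) -> Optional[str]:
        entry = self.find("mode_of_sharing")
        return entry.value if entry else None

    def interpretation_rule(self) -> Optional[str]:
        entry = self.find("interpretation_rule")
        return entry.value if entry else None


class Profile(BaseModel):
    """One Header plus an ordered, non-empty list of Main Bodies."""

    model_config = ConfigDict(frozen=True)

    header: Header = Field(default_factory=Header)
    bodies: tuple[MainBody, ...] = Field(min_length=1)


def count_obligatory(body: MainBody) -> int:
    """Number of obligatory assertions in one body.

    Counts (a) Permissions entries whose main value carries the
    ``[Obligatory]`` suffix, (b) individual list items flagged
    ``[Obligatory]`` in parsed free text, and (c) a non-empty "recontact
    must occur" slot on the Terms recontact concept.  When the total
    reaches two, the interpretation-rule Meta concept becomes mandatory.
    """
    n = 0
    for entry in body.permissions:
        if entry.value in OBLIGATORY_VALUES:
            n += 1
        items = entry.condition_items
        if items:
            n += sum(1 for it in items if it.obligatory)
    for entry in body.terms:
        if entry.free_text_2 and entry.free_text_2.strip():
            n += 1
    return n


def _upsert(entries: tuple, new) -> tuple:
    out, replaced = [], False
    for e in entries:
        if e.concept_id == new.concept_id:
            out.append(new)
            replaced = True
        else:
            out.append(e)
    if not replaced:
        out.append(new)
    return tuple(out)


def set_entry(
    profile: Profile,
    body_index: int,
    concept_id: str,
    value: Optional[str],
    free_text: Optional[str] = None,
    free_text_2: Optional[str] = None,
    *,
    registry: Registry,
) -> Profile:
    """Return a copy of ``profile`` with one entry upserted (fail-fast).

    The value must belong to the concept's domain — in particular,
    ``Forbidden`` and the ``[Obligatory]`` variants are rejected here
    for the three restricted use-location/organization/person concepts,
    independently of the validator.  HEADER concepts are set on the
    Header (``body_index`` is ignored for them).
    """
    concept = registry.get(concept_id)
    if concept is None:
        raise UnknownConcept(f"unknown concept {concept_id!r}")
    if concept.section is Section.HEADER:
        values = dict(profile.header.values)
        values[concept_id] = value if value is not None else ""
        return profile.model_copy(update={"header": Header(values=values)})
    if not 0 <= body_index < len(profile.bodies):
        raise IndexOutOfRange(
            f"body index {body_index} out of range for {len(profile.bodies)} bodies")
    if value is not None and value not in concept.value_domain:
        raise ValueNotInDomain(
            f"{value!r} is not a permitted value of {concept_id!r} "
            f"(domain: {', '.join(concept.value_domain)})")
    if free_text is not None and concept.free_text_slots < 1:
        raise ValueNotInDomain(f"{concept_id!r} has no free-text field")
    if free_text_2 is not None and concept.free_text_slots < 2:
        raise ValueNotInDomain(f"{concept_id!r} has no second free-text field")

    body = profile.bodies[body_index]
    if concept.section is Section.PERMISSIONS:
        entry = PermissionEntry(concept_id=concept_id, value=value, free_text=free_text)
        body = body.model_copy(update={"permissions": _upsert(body.permissions, entry)})
    elif concept.section is Section.TERMS:
        entry = TermEntry(concept_id=concept_id, value=value,
                          free_text=free_text, free_text_2=free_text_2)
        body = body.model_copy(update={"terms": _upsert(body.terms, entry)})
    else:
        entry = MetaEntry(concept_id=concept_id, value=value, free_text=free_text)
        body = body.model_copy(update={"meta": _upsert(body.meta, entry)})
    bodies = list(profile.bodies)
    bodies[body_index] = body
    return profile.model_copy(update={"bodies": tuple(bodies)})
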