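"""Concept registry: the taxonomy every Profile is interpreted against.

An ADA-M v1.0 Profile is a document whose entries all refer to concepts
drawn from a fixed taxonomy: 13 HEADER items (3 required) plus a MAIN
BODY of 42 concepts split into Permissions (26, hierarchically
arranged), Terms (11, flat) and Meta-Conditions (5).  The registry is
shipped as a versioned JSON data file so an adopter can substitute an
alternative concept catalogue without touching code; the structural
invariants below are what the rest of the package relies on.

Three Permissions concepts describe dimensions of use that must
unavoidably occur in some form (where, by which organization, by which
category of person), so they can never be Forbidden nor made
Obligatory; their value domain is just ``Unrestricted``/``Limited``.
"""

from __future__ import annotations

import enum
import json
from functools import lru_cache
from importlib import resources
from typing import Mapping, Optional

from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import MalformedRegistry, RegistryInvariantViolation

DEFAULT_VERSION_TAG = "adam-registry-1.0"


class Section(str, enum.Enum):
    HEADER = "HEADER"
    PERMISSIONS = "PERMISSIONS"
    TERMS = "TERMS"
    META = "META"


class Requirement(str, enum.Enum):
    REQUIRED = "REQUIRED"
    OPTIONAL = "OPTIONAL"
    CONDITIONAL = "CONDITIONAL"


class ConceptDef(BaseModel):
    """One concept of the taxonomy and its value domain.

    ``value_domain`` is the ordered set of tokens a main value may take;
    an empty domain means the concept holds free text directly (HEADER
    items).  ``free_text_slots`` is 0, 1 or 2 — two only for the Terms
    recontact concept, whose slots separately capture recontacts that
    *may* and that *must* occur.
    """

    model_config = ConfigDict(frozen=True)

    concept_id: str
    section: Section
    label: str
    parent_id: Optional[str] = None
    value_domain: tuple[str, ...] = ()
    supports_forbidden_obligatory: bool = False
    free_text_slots: int = 0
    requirement: Requirement = Requirement.OPTIONAL


class Registry(BaseModel):
    """An ordered collection of :class:`ConceptDef` plus a version tag.

    Construction checks only the *structural* invariants (unique ids,
    parents exist inside PERMISSIONS, hierarchy is a forest, slot
    counts).  The shipped-default cardinalities (13/26/11/5 …) are
    enforced by :func:`load_registry` whenever the document claims the
    default version tag.
    """

    model_config = ConfigDict(frozen=True)

    version_tag: str
    concepts: tuple[ConceptDef, ...]

    def model_post_init(self, __context) -> None:
        seen: set[str] = set()
        for c in self.concepts:
            if c.concept_id in seen:
                raise RegistryInvariantViolation(
                    f"duplicate concept_id {c.concept_id!r}")
            seen.add(c.concept_id)
        by_id = {c.concept_id: c for c in self.concepts}
        for c in self.concepts:
            if c.parent_id is not None:
                parent = by_id.get(c.parent_id)
                if parent is None or parent.section is not Section.PERMISSIONS:
                    raise RegistryInvariantViolation(
                        f"{c.concept_id!r}: parent_id {c.parent_id!r} does not "
                        "name an existing PERMISSIONS concept")
                if c.section is not Section.PERMISSIONS:
                    raise RegistryInvariantViolation(
                        f"{c.concept_id!r}: only PERMISSIONS concepts may "
                        "have a parent")
            if c.free_text_slots not in (0, 1, 2):
                raise RegistryInvariantViolation(
                    f"{c.concept_id!r}: free_text_slots must be 0, 1 or 2")
        # hierarchy must be a forest: walk each parent chain
        for c in self.concepts:
            trail = {c.concept_id}
            cur = c
            while cur.parent_id is not None:
                if cur.parent_id in trail:
                    raise RegistryInvariantViolation(
                        f"cycle in hierarchy at {cur.parent_id!r}")
                trail.add(cur.parent_id)
                cur = by_id[cur.parent_id]
        two_slot = [c.concept_id for c in self.concepts if c.free_text_slots == 2]
        if len(two_slot) > 1:
            raise RegistryInvariantViolation(
                f"more than one two-slot concept: {two_slot}")

    # -- lookups --------------------------------------------------------
    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._by_id

    def __getitem__(self, concept_id: str) -> ConceptDef:
        return self._by_id[concept_id]

    def get(self, concept_id: str) -> Optional[ConceptDef]:
        return self._by_id.get(concept_id)

    @property
    def _by_id(self) -> dict[str, ConceptDef]:
        d = self.__dict__.get("_by_id_cache")
        if d is None:
            d = {c.concept_id: c for c in self.concepts}
            object.__setattr__(self, "_by_id_cache", d)
        return d

    def section_ids(self, section: Section) -> list[str]:
        """Concept ids of one section, in canonical registry order."""
        return [c.concept_id for c in self.concepts if c.section is section]

    def required_ids(self, section: Section) -> list[str]:
        return [c.concept_id for c in self.concepts
                if c.section is section and c.requirement is Requirement.REQUIRED]


def section_counts(registry: Registry) -> Mapping[Section, int]:
    """Exact number of concepts per section.

    For the shipped default this is ``{HEADER: 13, PERMISSIONS: 26,
    TERMS: 11, META: 5}`` — the three Main-Body sections summing to 42.
    """
    counts = {s: 0 for s in Section}
    for c in registry.concepts:
        counts[c.section] += 1
    return counts


def _check_default_cardinalities(reg: Registry) -> None:
    """Invariants that the shipped v1.0 taxonomy must satisfy."""

    def fail(msg: str):
        raise RegistryInvariantViolation(f"default registry: {msg}")

    counts = section_counts(reg)
    expected = {Section.HEADER: 13, Section.PERMISSIONS: 26,
                Section.TERMS: 11, Section.META: 5}
    for sec, n in expected.items():
        if counts[sec] != n:
            fail(f"{sec.value} must have {n} concepts, found {counts[sec]}")
    if len(reg.required_ids(Section.HEADER)) != 3:
        fail("exactly 3 HEADER items must be REQUIRED")
    body_required = [c for c in reg.concepts
                     if c.section is not Section.HEADER
                     and c.requirement is Requirement.REQUIRED]
    if [c.concept_id for c in body_required] != ["mode_of_sharing"]:
        fail("exactly one Main-Body concept (mode_of_sharing) is REQUIRED")
    conditional = [c.concept_id for c in reg.concepts
                   if c.requirement is Requirement.CONDITIONAL]
    if conditional != ["interpretation_rule"]:
        fail("exactly one concept (interpretation_rule) is CONDITIONAL")
    perms = [c for c in reg.concepts if c.section is Section.PERMISSIONS]
    extended = [c for c in perms if len(c.value_domain) == 5]
    restricted = [c for c in perms if len(c.value_domain) == 2]
    if len(extended) != 23 or len(restricted) != 3:
        fail("PERMISSIONS must split 23 extended / 3 restricted value domains")
    if any(c.supports_forbidden_obligatory for c in restricted) or \
            not all(c.supports_forbidden_obligatory for c in extended):
        fail("supports_forbidden_obligatory must match the value-domain split")
    two_slot = [c.concept_id for c in reg.concepts if c.free_text_slots == 2]
    if two_slot != ["no_recontact_possibility"]:
        fail("exactly the Terms recontact concept has two free-text slots")


def load_registry(document: str | dict) -> Registry:
    """Parse a registry config document (JSON text or a decoded mapping).

    Raises :class:`MalformedRegistry` on syntax problems and
    :class:`RegistryInvariantViolation` when the document parses but
    breaks an invariant.  A document bearing the default version tag is
    additionally held to the shipped-default cardinalities.
    """
    if isinstance(document, str):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise MalformedRegistry(f"registry document is not valid JSON: {exc}")
    if not isinstance(document, dict):
        raise MalformedRegistry("registry document must be a JSON object")
    try:
        reg = Registry(
            version_tag=document.get("version_tag", ""),
            concepts=tuple(ConceptDef(**c) for c in document.get("concepts", [])),
        )
    except ValidationError as exc:
        raise MalformedRegistry(f"registry document has malformed fields: {exc}")
    except TypeError as exc:
        raise MalformedRegistry(f"registry document has malformed records: {exc}")
    if reg.version_tag == DEFAULT_VERSION_TAG:
        _check_default_cardinalities(reg)
    return reg


@lru_cache(maxsize=1)
def default_registry() -> Registry:
    """The shipped ADA-M v1.0 taxonomy (deterministic, cached)."""
    text = resources.files("adamatrix.data").joinpath("registry_v1.json").read_text()
    return load_registry(text)


def dump_registry(registry: Registry) -> str:
    """Serialize a registry back to its JSON config dialect."""
    doc = {
        "version_tag": registry.version_tag,
        "concepts": [
            {
                "concept_id": c.concept_id,
                "section": c.section.value,
                "label": c.label,
                "parent_id": c.parent_id,
                "value_domain": list(c.value_domain),
                "supports_forbidden_obligatory": c.supports_forbidden_obligatory,
                "free_text_slots": c.free_text_slots,
                "requirement": c.requirement.value,
            }
            for c in registry.concepts
        ],
    }
    return json.dumps(doc, indent=1) + "\n"
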