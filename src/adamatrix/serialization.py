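"""Readers/writers for the two standard Profile document formats.

Profiles travel between systems either as a JSON document or as a flat
key-value text document; both dialects carry exactly the same
information and round-trip bit-stably through the in-memory model.

JSON dialect (``.adam.json``): object with ``header`` (mapping of
HEADER concept ids to text) and ``bodies`` (array of objects with
``permissions`` / ``terms`` / ``meta`` entry arrays; entry fields
``concept_id``, ``value``, ``free_text``, ``free_text_2``).  Unset
fields are omitted entirely.

Key-value dialect (``.adam.kv``): UTF-8, one pair per line,
``\\n`` line ends, dotted paths::

    header.<concept_id>=<text>
    body.<k>.<section>.<concept_id>.value=<token>
    body.<k>.<section>.<concept_id>.freeText=<text>
    body.<k>.<section>.<concept_id>.freeText2=<text>

with a zero-based body index ``<k>``, ``<section>`` one of
``permissions``/``terms``/``meta``, and backslash escapes (``\\\\``,
``\\n``, ``\\r``) for newlines inside values.

Both writers impose canonical registry order on entries, so
serialization is stable under reordering of the semantically unordered
entry collections, and the two formats agree:
``from_keyvalue(to_keyvalue(p)) == from_json(to_json(p)) == p``.
"""

from __future__ import annotations

import enum
import json
from typing import Optional, Union

from pydantic import BaseModel, ConfigDict

from .errors import DuplicateKey, MalformedDocument, UnknownConcept
from .profile import Header, MainBody, MetaEntry, PermissionEntry, Profile, TermEntry
from .registry import Registry, default_registry

_SECTION_ATTRS = ("permissions", "terms", "meta")
_ENTRY_TYPES = {"permissions": PermissionEntry, "terms": TermEntry, "meta": MetaEntry}


class DocumentFormat(str, enum.Enum):
    JSON_DIALECT = "JSON_DIALECT"
    KEYVALUE_DIALECT = "KEYVALUE_DIALECT"


class ProfileDocument(BaseModel):
    model_config = ConfigDict(frozen=True)

    format: DocumentFormat
    payload: str


def _order_key(registry: Registry):
    index = {c.concept_id: i for i, c in enumerate(registry.concepts)}
    big = len(index)

    def key(concept_id: str):
        return (index.get(concept_id, big), concept_id)

    return key


def canonicalize(profile: Profile, registry: Registry) -> Profile:
    """Re-sort entries (and header keys) into canonical registry order."""
    key = _order_key(registry)
    header = Header(values={k: profile.header.values[k]
                            for k in sorted(profile.header.values, key=key)})
    bodies = []
    for body in profile.bodies:
        bodies.append(MainBody(
            permissions=tuple(sorted(body.permissions, key=lambda e: key(e.concept_id))),
            terms=tuple(sorted(body.terms, key=lambda e: key(e.concept_id))),
            meta=tuple(sorted(body.meta, key=lambda e: key(e.concept_id))),
        ))
    return Profile(header=header, bodies=tuple(bodies))


def _check_known(profile: Profile, registry: Registry, strict: bool) -> None:
    if not strict:
        return
    ids = list(profile.header.values)
    for body in profile.bodies:
        for attr in _SECTION_ATTRS:
            ids.extend(e.concept_id for e in getattr(body, attr))
    for cid in ids:
        if cid not in registry:
            raise UnknownConcept(f"unknown concept id {cid!r}")


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def to_json(profile: Profile, registry: Optional[Registry] = None) -> ProfileDocument:
    """Serialize to the JSON dialect (deterministic, empties omitted)."""
    registry = registry or default_registry()
    profile = canonicalize(profile, registry)
    doc: dict = {}
    if profile.header.values:
        doc["header"] = dict(profile.header.values)
    bodies = []
    for body in profile.bodies:
        body_doc: dict = {}
        for attr in _SECTION_ATTRS:
            entries = []
            for e in getattr(body, attr):
                entry_doc = {"concept_id": e.concept_id}
                if e.value is not None:
                    entry_doc["value"] = e.value
                if e.free_text is not None:
                    entry_doc["free_text"] = e.free_text
                if getattr(e, "free_text_2", None) is not None:
                    entry_doc["free_text_2"] = e.free_text_2
                entries.append(entry_doc)
            if entries:
                body_doc[attr] = entries
        bodies.append(body_doc)
    doc["bodies"] = bodies
    payload = json.dumps(doc, indent=1, ensure_ascii=False) + "\n"
    return ProfileDocument(format=DocumentFormat.JSON_DIALECT, payload=payload)


def from_json(
    document: Union[ProfileDocument, str],
    registry: Optional[Registry] = None,
    *,
    strict: bool = True,
) -> Profile:
    """Decode the JSON dialect.

    ``strict`` rejects concept ids absent from the registry; with
    ``strict=False`` unknown entries are preserved untouched.
    """
    registry = registry or default_registry()
    payload = document.payload if isinstance(document, ProfileDocument) else document
    try:
        doc = json.loads(payload)
    except json.JSONDecodeError as exc:
        raise MalformedDocument(f"not valid JSON: {exc.msg}", f"line {exc.lineno}")
    if not isinstance(doc, dict):
        raise MalformedDocument("top level must be a JSON object", "$")
    header_doc = doc.get("header", {})
    if not isinstance(header_doc, dict) or \
            not all(isinstance(v, str) for v in header_doc.values()):
        raise MalformedDocument("header must map concept ids to text", "$.header")
    bodies_doc = doc.get("bodies")
    if not isinstance(bodies_doc, list) or not bodies_doc:
        raise MalformedDocument("bodies must be a non-empty array", "$.bodies")
    bodies = []
    for k, body_doc in enumerate(bodies_doc):
        if not isinstance(body_doc, dict):
            raise MalformedDocument("body must be an object", f"$.bodies[{k}]")
        sections: dict[str, tuple] = {}
        for attr in _SECTION_ATTRS:
            entry_type = _ENTRY_TYPES[attr]
            entries = []
            for i, entry_doc in enumerate(body_doc.get(attr, [])):
                loc = f"$.bodies[{k}].{attr}[{i}]"
                if not isinstance(entry_doc, dict) or "concept_id" not in entry_doc:
                    raise MalformedDocument("entry must be an object with concept_id", loc)
                allowed = set(entry_type.model_fields)
                extra = set(entry_doc) - allowed
                if extra:
                    raise MalformedDocument(
                        f"unexpected entry fields {sorted(extra)}", loc)
                try:
                    entries.append(entry_type(**entry_doc))
                except Exception as exc:
                    raise MalformedDocument(f"bad entry: {exc}", loc)
            sections[attr] = tuple(entries)
        bodies.append(MainBody(**sections))
    profile = Profile(header=Header(values=dict(header_doc)), bodies=tuple(bodies))
    _check_known(profile, registry, strict)
    return canonicalize(profile, registry)


# ---------------------------------------------------------------------------
# key-value dialect
# ---------------------------------------------------------------------------

def _escape(value: str) -> str:
    return value.replace("\\", "\\\\").replace("\n", "\\n").replace("\r", "\\r")


def _unescape(value: str, lineno: int) -> str:
    out, i = [], 0
    while i < len(value):
        ch = value[i]
        if ch == "\\":
            if i + 1 >= len(value):
                raise MalformedDocument("dangling backslash escape", f"line {lineno}")
            nxt = value[i + 1]
            mapped = {"\\": "\\", "n": "\n", "r": "\r"}.get(nxt)
            if mapped is None:
                raise MalformedDocument(f"unknown escape \\{nxt}", f"line {lineno}")
            out.append(mapped)
            i += 2
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def to_keyvalue(profile: Profile, registry: Optional[Registry] = None) -> ProfileDocument:
    """Serialize to the flat key-value dialect (deterministic)."""
    registry = registry or default_registry()
    profile = canonicalize(profile, registry)
    lines = []
    for cid, text in profile.header.values.items():
        lines.append(f"header.{cid}={_escape(text)}")
    for k, body in enumerate(profile.bodies):
        for attr in _SECTION_ATTRS:
            for e in getattr(body, attr):
                prefix = f"body.{k}.{attr}.{e.concept_id}"
                if e.value is not None:
                    lines.append(f"{prefix}.value={_escape(e.value)}")
                if e.free_text is not None:
                    lines.append(f"{prefix}.freeText={_escape(e.free_text)}")
                if getattr(e, "free_text_2", None) is not None:
                    lines.append(f"{prefix}.freeText2={_escape(e.free_text_2)}")
    payload = "\n".join(lines) + "\n" if lines else ""
    return ProfileDocument(format=DocumentFormat.KEYVALUE_DIALECT, payload=payload)


_FIELD_NAMES = {"value": "value", "freeText": "free_text", "freeText2": "free_text_2"}


def from_keyvalue(
    document: Union[ProfileDocument, str],
    registry: Optional[Registry] = None,
    *,
    strict: bool = True,
) -> Profile:
    """Decode the key-value dialect, with line-numbered errors."""
    registry = registry or default_registry()
    payload = document.payload if isinstance(document, ProfileDocument) else document
    header_values: dict[str, str] = {}
    # body index -> section -> concept_id -> field -> text
    bodies: dict[int, dict[str, dict[str, dict[str, str]]]] = {}
    seen: dict[str, int] = {}
    for lineno, raw in enumerate(payload.split("\n"), start=1):
        line = raw.rstrip("\r")
        if not line.strip():
            continue
        if "=" not in line:
            raise MalformedDocument("missing '=' separator", f"line {lineno}")
        key, _, raw_value = line.partition("=")
        key = key.strip()
        if key in seen:
            raise DuplicateKey(
                f"key {key!r} already seen on line {seen[key]}", f"line {lineno}")
        seen[key] = lineno
        value = _unescape(raw_value, lineno)
        parts = key.split(".")
        if parts[0] == "header" and len(parts) == 2:
            header_values[parts[1]] = value
        elif parts[0] == "body" and len(parts) == 5:
            _, idx_s, section, concept_id, field = parts
            if not idx_s.isdigit():
                raise MalformedDocument(f"bad body index {idx_s!r}", f"line {lineno}")
            if section not in _SECTION_ATTRS:
                raise MalformedDocument(f"unknown section {section!r}", f"line {lineno}")
            if field not in _FIELD_NAMES:
                raise MalformedDocument(f"unknown field {field!r}", f"line {lineno}")
            bodies.setdefault(int(idx_s), {}).setdefault(section, {}) \
                  .setdefault(concept_id, {})[_FIELD_NAMES[field]] = value
        else:
            raise MalformedDocument(f"unrecognized key {key!r}", f"line {lineno}")
    if not bodies:
        raise MalformedDocument("document contains no body entries")
    indices = sorted(bodies)
    if indices != list(range(len(indices))):
        raise MalformedDocument(
            f"body indices must be contiguous from 0, found {indices}")
    built = []
    for k in indices:
        sections: dict[str, tuple] = {}
        for attr in _SECTION_ATTRS:
            entry_type = _ENTRY_TYPES[attr]
            entries = []
            for cid, fields in bodies[k].get(attr, {}).items():
                if "free_text_2" in fields and attr != "terms":
                    raise MalformedDocument(
                        f"freeText2 is only defined for terms entries ({cid!r})")
                entries.append(entry_type(concept_id=cid, **fields))
            sections[attr] = tuple(entries)
        built.append(MainBody(**sections))
    profile = Profile(header=Header(values=header_values), bodies=tuple(built))
    _check_known(profile, registry, strict)
    return canonicalize(profile, registry)


# ---------------------------------------------------------------------------
# format-generic helpers (used by the CLI)
# ---------------------------------------------------------------------------

def loads(payload: str, registry: Optional[Registry] = None, *,
          strict: bool = True) -> Profile:
    """Decode a profile document, sniffing the dialect."""
    stripped = payload.lstrip()
    if stripped.startswith("{"):
        return from_json(payload, registry, strict=strict)
    return from_keyvalue(payload, registry, strict=strict)


def dumps(profile: Profile, fmt: DocumentFormat,
          registry: Optional[Registry] = None) -> str:
    if fmt is DocumentFormat.JSON_DIALECT:
        return to_json(profile, registry).payload
    return to_keyvalue(profile, registry).payload
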