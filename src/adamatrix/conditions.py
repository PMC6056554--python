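"""The ``[Obligatory]`` condition-list micro-grammar.

Limited permissions are normally elaborated in free text as a list of
permitted (or prohibited) options, e.g. ``"Use permitted for research
on diseases A, B[Obligatory], and C"``: the list items are short
tokens, an item suffixed ``[Obligatory]`` names a use that *must*
occur, and anything before the first item is a human-readable
preamble.  This module parses such text into structured items and
renders items back to canonical text; the two are mutual inverses on
canonical lists.

Text that is not list-shaped (multiple sentences, multi-word items) is
prose meant for human readers: :func:`parse_condition_list` then
returns ``None`` rather than raising, and callers keep the text
verbatim.  Downstream, such entries are outside formulaic evaluation.
"""

from __future__ import annotations

import re
from typing import Optional

from pydantic import BaseModel, ConfigDict

from .errors import EmptyList

OBLIGATORY_SUFFIX = "[Obligatory]"
_OBLIG_RE = re.compile(r"\[\s*obligatory\s*\]\s*$", re.IGNORECASE)


class ConditionItem(BaseModel):
    """One item of a permitted/prohibited list."""

    model_config = ConfigDict(frozen=True)

    label: str
    obligatory: bool = False


def _strip_obligatory(token: str) -> tuple[str, bool]:
    m = _OBLIG_RE.search(token)
    if m:
        return token[: m.start()].rstrip(), True
    return token, False


def parse_condition_list(text: str) -> Optional[list[ConditionItem]]:
    """Parse free text into condition items, or ``None`` if it is prose.

    Grammar: one sentence; items separated by commas, the last item
    optionally introduced by ``and``; each item a single whitespace-free
    token optionally suffixed ``[Obligatory]`` (matched
    case-insensitively); the first item may be preceded by a preamble.
    A comma-free text parses only when it is a bare token, so ordinary
    prose never masquerades as a one-item list.
    """
    s = text.strip()
    if not s:
        return None
    if s.endswith("."):
        s = s[:-1].rstrip()
    # multiple sentences or line breaks => prose
    if "\n" in s or ". " in s:
        return None
    parts = [p.strip() for p in s.split(",")]
    if any(not p for p in parts):
        return None
    if len(parts) > 1 and re.match(r"and\s+", parts[-1], re.IGNORECASE):
        parts[-1] = re.split(r"\s+", parts[-1], maxsplit=1)[1]
    items: list[ConditionItem] = []
    for i, part in enumerate(parts):
        token, oblig = _strip_obligatory(part)
        if i == 0 and len(parts) > 1:
            # first part may carry the preamble; the item is its last word
            token = token.split()[-1] if token else ""
        if not token or re.search(r"\s", token):
            return None
        items.append(ConditionItem(label=token, obligatory=oblig))
    return items


def render_condition_list(items: list[ConditionItem], preamble: str = "") -> str:
    """Canonical text for a list of items (inverse of parse).

    Items are joined by ``", "`` with the canonical ``[Obligatory]``
    suffix where flagged; a non-empty preamble is prepended followed by
    a space.  ``parse_condition_list(render_condition_list(items))``
    returns ``items`` for any items with token labels — except the
    degenerate case of a preamble before a single item, which the
    grammar deliberately reads as prose.
    """
    if not items:
        raise EmptyList("cannot render an empty condition list")
    rendered = ", ".join(
        it.label + (OBLIGATORY_SUFFIX if it.obligatory else "") for it in items
    )
    preamble = preamble.strip()
    return f"{preamble} {rendered}" if preamble else rendered
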