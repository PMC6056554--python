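# Methods

This note records how the package models ADA-M v1.0, the semantics it
fixes where the standard leaves latitude, and what its synthetic tests
do and do not demonstrate.

## The concept registry

The taxonomy is shipped as data
(`src/adamatrix/data/registry_v1.json`), not code, so an adopter can
substitute an alternative catalogue (for instance one aligned with an
official appendix or with DUO term bindings) without touching the
library. The shipped default satisfies the structural constants of
the standard: 13 Header items of which 3 are required, 26 Permissions
(23 with the five-value extended domain, 3 restricted to
`Unrestricted`/`Limited`), 11 Terms, 5 Meta-Conditions; exactly one
Main-Body concept required (`mode_of_sharing`) and one conditional
(`interpretation_rule`); only the Terms recontact concept carries two
free-text slots.

The standard fixes these counts and names only a handful of concepts.
Concept ids and labels here use every published name verbatim (the
three restricted use-scope concepts, the recontact and collaboration
Terms, `Mode of sharing`, the interpretation rule, the
"no other restrictions" Meta concept); the remainder are placeholder
concepts grounded in the documented category descriptions (laws;
data/sample access policies; material/data transfer and data access
agreements; consents; disease-, method-, and purpose-scoped uses).
Which three Header items are required is likewise not published; this
package requires the minimum that makes a Profile citable and
resolvable — its identifier, its creation date/version, and the
reference to the governed resource. The Permissions hierarchy is a
one-level forest: a flat list with optional parent grouping; deeper
nesting is rejected as registry data for simplicity.

Two vocabularies are this package's own, because the standard names
the fields but never prints their permitted values: Mode of sharing
uses `DISCOVERY` / `ACCESS` / `DISCOVERY_AND_ACCESS`, and the
interpretation rule `MEET_ALL` / `MEET_ANY`. All tokens the standard
does print are serialized exactly as printed (`Unrestricted`,
`Limited`, `Unrestricted[Obligatory]`, `Limited[Obligatory]`,
`Forbidden`, `True`, `Untrue`).

## The condition-list micro-grammar

`Limited` permissions are elaborated in free text, ideally as an
option list. The grammar implemented is deliberately narrow: one
sentence; comma-separated items with an optional final "and"; each
item a single whitespace-free token, optionally suffixed
`[Obligatory]` (matched case-insensitively, rendered canonically); an
optional preamble before the first item, recognized only when the
list has at least two parts. A comma-free text parses only when it is
a bare token. The narrowness is the point: ordinary prose — including
conditionality statements such as "resulting data must be made
public" — must *not* masquerade as a machine-readable list, because
prose is exactly what the decision engine refers to a human.
`parse_condition_list` therefore signals "not a list" by returning
`None` rather than raising, and the original text is always kept
verbatim; parsed items are a derived view recomputed on access, never
stored or serialized, so the free text remains the single source of
truth and round-trips are exact.

`parse` and `render` are mutual inverses on canonical token lists
(property-tested), with one documented exception: a preamble before a
single item renders to a one-part text with spaces, which the grammar
reads back as prose.

## Serialization

Both dialects canonicalize before writing: entries are sorted into
registry order (unknown ids after, alphabetically), unset fields are
omitted, and output is byte-deterministic. Decoders re-canonicalize,
so equality is stable under reordering of the semantically unordered
entry collections and the two formats always agree. The key-value
dialect is UTF-8, one dotted-path pair per line with a zero-based
body index, and backslash escapes (`\\`, `\n`, `\r`) inside values;
errors carry line numbers, JSON errors carry JSON paths. A strictness
flag decides whether unknown concept ids are rejected or preserved.

Entry values are plain string tokens rather than closed enums: the
validator must be able to represent and inspect out-of-domain
documents, so domain membership is a finding (R7), not a type error.

## The seven validation rules

The rules are reconstructed from the standard's stated hard
constraints and kept table-driven so alternative official wordings
can replace them without API change: required Header items non-empty
(R1); each body asserts at least one Permissions-or-Terms value (R2);
each body sets Mode of sharing (R3); the interpretation rule is
present when a body carries ≥ 2 Obligatory assertions (R4, counting
`[Obligatory]` values, `[Obligatory]` list items, and a non-empty
recontact "must occur" slot, across Permissions *and* Terms); the
three restricted concepts carry only `Unrestricted`/`Limited` (R5);
no free text under a concept with no main value (R6); every value in
its concept's domain (R7). R5 and R7 would overlap on a `Forbidden`
value for a restricted concept; R7 skips entries R5 already flags, so
the rules partition violations and single-rule mutations are flagged
by exactly one rule. Validation reports every violation, never
short-circuits, and is pure.

## Decision semantics

Per concept, against the normalized (trimmed, case-folded) declared
uses — matching is exact, with no synonym or ontology expansion:

- `Unrestricted` passes. `Forbidden` fails iff a use is declared for
  that concept, and passes vacuously otherwise.
- `Limited` with a parsed list passes iff the declared uses are a
  subset of the permitted items.
- Obligations — `[Obligatory]` values (some use of the concept must
  occur) and `[Obligatory]` list items (that item must be declared) —
  are collected per body and combined under the body's interpretation
  rule (`MEET_ALL` when absent, which is also the only possibility
  when at most one obligation exists). A provably unmet obligation is
  a FAIL, not a REFER: an obligated use must occur, so omitting it is
  formulaically incompatible.
- Terms: `True` passes; `Untrue` in ACCESS mode passes iff the
  requester accepted that term concept; in DISCOVERY mode an
  applicable condition is informational only, never a failure.
- REFER marks the boundary of automation and arises only from
  non-formulaic inputs: free text that does not parse as an option
  list on any non-`Forbidden` permission (prose may hide
  conditionalities, so this REFERs regardless of what is declared), a
  `Limited` value with no elaboration when a use *is* declared, and
  the recontact "must occur" slot (an obligation whose satisfaction
  no request field can prove; under `MEET_ANY` it counts as
  unprovable rather than unmet). The optional Meta concepts beyond
  Mode of sharing and the interpretation rule carry no decision
  semantics.

Bodies are alternatives: a request is permitted the moment one
mode-eligible body has all concepts passing, denied when every
eligible body has at least one failure (including the case of no
eligible body at all — the profile does not offer the requested
mode), and referred otherwise. This makes adding a body monotone
(never flips PERMIT to DENY), as are enlarging accepted terms,
widening a permitted list, and relaxing a value along
`Forbidden → Limited → Unrestricted` — properties the test suite
checks over seeded corpora, alongside exhaustive agreement with an
independent brute-force truth-table evaluator on small registries
(4 Permissions concepts, 3-label vocabulary, every declared-use
subset, both modes).

## The synthetic generator

The generator emulates a mixed population of real-world profiles: one
or two bodies; one to five asserted Permissions per body, of which
40% are `Limited` (with an explicit permitted list of 1–4 tokens
drawn from a six-token disease vocabulary `A`–`F`), 15% `Forbidden`,
and 20% of eligible values or list items `[Obligatory]`; zero to
three Terms per body, `Untrue` with probability 0.4; the
interpretation rule whenever obligations require it and occasionally
otherwise. These rates are fixed conditions, chosen once so that all
five Permissions values, both Terms values, multi-obligation bodies
and both interpretation rules occur routinely in a 500-profile
corpus; they are checked by census, not tuned.

Two things the valid-profile generator deliberately does *not*
produce: prose free text and the recontact "must occur" slot. Both
are REFER-grade inputs, and excluding them guarantees that every
generated profile admits a PERMIT-achieving request, which is what
makes the intent contract (`COMPATIBLE` ⇒ PERMIT, `INCOMPATIBLE` ⇒
DENY, else `IntentUnsatisfiable`) decidable by construction.
REFER-grade inputs are exercised by explicitly constructed profiles
in the tests and examples. `INCOMPATIBLE` requests induce failures
only through mechanisms monotone under extra declarations (a use on a
`Forbidden` concept, an out-of-list label on a `Limited` concept, an
unaccepted `Untrue` term in ACCESS mode), so the union of per-body
failing declarations fails every eligible body at once.

Consequently, passing synthetic suites demonstrate internal
consistency of model, formats, validator and engine — they do not
demonstrate that real consent language maps cleanly onto the model.
That mapping (interpreting consent forms and policies into concepts)
is a human judgement the standard itself places outside scope, and is
exactly what the REFER verdict exists to protect.

## Problem sizes and numerical choices

The shipped property suites use a 500-profile corpus for validation
and round-trip identity, 120 profiles × 7 rules for mutation
detection, 5,760 exhaustively enumerated request/profile combinations
for oracle equivalence, 1,000 relaxation pairs for monotonicity, and
200 + 200 intent-controlled pairs — sizes at which every census the
suite relies on is saturated while the whole suite runs in seconds.
All randomness flows from explicit integer seeds through local
`random.Random` instances; nothing touches global random state.
Degenerate inputs are defined rather than special-cased: an empty
declared-use set passes `Forbidden` and listed `Limited` entries
vacuously; a body with no entries is a validation finding (R2), not a
crash; an empty condition list cannot be rendered (`EmptyList`).
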