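# adamatrix

Machine-actionable data-use conditions for biomedical resources: an
implementation of the **ADA-M v1.0** (Automatable Discovery and Access
Matrix) information model as a Python library with a thin `adam`
command-line tool.

Sharing rules for datasets and biospecimens — consents, laws,
institutional policies, contractual terms — are usually prose, which
makes them invisible to the software that mediates discovery and
access, and leaves Data Access Committees (DACs), Research Ethics
Committees and biobanks re-interpreting the same documents for every
request. ADA-M structures those conditions as a metadata **Profile**
so they can be recorded, versioned, communicated, queried and — where
the rules are formulaic — acted on automatically.

## The model

A Profile is one **Header** (13 items, 3 required: profile id,
creation date/version, and a reference to the governed resource) plus
one or more **Main Bodies**, each an alternative combination of use
criteria. A Main Body draws on 42 concepts in three sections:

- **Permissions** (26, hierarchically arranged — laws, policies,
  consents, disease/method/purpose-scoped uses). Each takes one value
  from `Unrestricted`, `Limited`, `Unrestricted[Obligatory]`,
  `Limited[Obligatory]`, `Forbidden`; the last three are unavailable
  for the three concepts of use that must unavoidably occur (use
  within countries/locations, use by organizations, use by categories
  of person). A `Limited` value is elaborated in free text, ideally as
  an option list — `"Use permitted for research on diseases A,
  B[Obligatory], and C"` means the use *must* relate to B and may also
  relate to A and/or C.
- **Terms** (11, flat) are negative statements (e.g. *"There are no
  requirements regarding collaboration"*): `True` means no such
  condition applies, `Untrue` that one does, detailed in free text.
- **Meta-Conditions** (5), notably the required **Mode of sharing**
  (Discovery and/or Access) and the interpretation rule (`MEET_ALL` /
  `MEET_ANY`) that becomes mandatory once a body carries two or more
  `[Obligatory]` assertions.

On top of the model the package provides:

- two deterministic, round-trip-exact document dialects (JSON and a
  flat key-value text format);
- a **seven-rule validator** (R1–R7) producing machine-readable,
  rule-indexed findings;
- a **decision engine** that adjudicates an access request
  (declared uses per concept + accepted terms) against a Profile:
  `PERMIT` / `DENY` where evaluation is formulaic, `REFER` (route to a
  human) where it is not — unparsed prose, unspecified limitations,
  recontact obligations;
- a **seeded synthetic generator** of valid profiles,
  intent-controlled requests, and minimal single-rule mutations, so
  everything is testable without any external data.

## Worked example

```python
from adamatrix import (AccessMode, AccessRequest, Header, MainBody,
                       MetaEntry, PermissionEntry, Profile, adjudicate)

profile = Profile(
    header=Header(values={"profile_id": "cancer-resource",
                          "profile_version": "v1",
                          "resource_reference": "example:cancer"}),
    bodies=(MainBody(
        permissions=(PermissionEntry(
            concept_id="use_for_diseases", value="Limited",
            free_text="Use permitted for research on diseases A, "
                      "B[Obligatory], and C"),),
        meta=(MetaEntry(concept_id="mode_of_sharing",
                        value="DISCOVERY_AND_ACCESS"),)),))

request = AccessRequest(mode=AccessMode.ACCESS,
                        declared_uses={"use_for_diseases": ("B",)})
print(adjudicate(profile, request).overall.value)
```

Running `python examples/03_adjudicate_request.py` prints:

```
declares B                   -> PERMIT
    use_for_diseases: PASS (declared uses all among permitted items)
declares A and C only        -> DENY
    use_for_diseases: FAIL (obligation unmet: use must relate to 'B')
declares unrelated disease X -> DENY
    use_for_diseases: FAIL (declared use(s) ['x'] outside the permitted list)
```

Declaring B satisfies the obligatory list item, so the request is
permitted; omitting B leaves the obligation unmet, and declaring a
disease outside the permitted list violates the `Limited` value —
both are denied, each with a per-concept rationale.

The other scripts in `examples/` walk the remaining capabilities:
building and validating profiles, the two serialization formats,
discovery screening, and the synthetic corpus.

## Command line

```sh
adam validate profile.adam.json            # exit 0 valid / 1 findings / 2 malformed
adam convert --to kv profile.adam.json     # JSON <-> key-value
adam decide --profile p.adam.json --request r.req.json   # exit 0 PERMIT / 1 DENY / 3 REFER
adam query --profiles DIR --request r.req.json           # discovery screening
adam generate --n 10 --seed 1 --out DIR    # synthetic profiles
```

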