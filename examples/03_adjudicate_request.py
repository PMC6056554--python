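"""Adjudicate access requests against a cancer-restricted Profile.

The profile permits research limited to diseases A, B and C, with B
obligatory: an eligible request must declare B.  Free text that is not
a parseable option list would instead route the request to a human
(REFER).
"""

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

for name, uses in [("declares B", ("B",)),
                   ("declares A and C only", ("A", "C")),
                   ("declares unrelated disease X", ("X",))]:
    request = AccessRequest(mode=AccessMode.ACCESS,
                            declared_uses={"use_for_diseases": uses})
    decision = adjudicate(profile, request)
    print(f"{name:28s} -> {decision.overall.value}")
    for body in decision.per_body:
        for v in body.verdicts:
            print(f"    {v.concept_id}: {v.verdict.value} ({v.rationale})")

# Declaring B satisfies the obligation -> PERMIT; omitting B leaves an
# obligation unmet -> DENY; an out-of-list disease also fails the
# Limited permission -> DENY.
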