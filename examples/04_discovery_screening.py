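"""Prescreen a collection of Profiles for a discovery query.

Discovery screening keeps only the resources a researcher could
plausibly use (PERMIT, or REFER where a human must read free text),
cutting ineligible requests before they ever reach a Data Access
Committee.
"""

from adamatrix import (AccessMode, AccessRequest, Header, MainBody,
                       MetaEntry, PermissionEntry, Profile, screen_profiles)


def profile(pid, value, free_text=None, mode="DISCOVERY_AND_ACCESS"):
    return Profile(
        header=Header(values={"profile_id": pid, "profile_version": "v1",
                              "resource_reference": f"example:{pid}"}),
        bodies=(MainBody(
            permissions=(PermissionEntry(concept_id="use_for_diseases",
                                         value=value, free_text=free_text),),
            meta=(MetaEntry(concept_id="mode_of_sharing", value=mode),)),))


profiles = {
    "open-cohort": profile("open-cohort", "Unrestricted"),
    "cancer-only": profile("cancer-only", "Limited", "cancer"),
    "needs-review": profile("needs-review", "Limited",
                            "Contact the data steward to discuss your study."),
    "access-only": profile("access-only", "Unrestricted", mode="ACCESS"),
}

request = AccessRequest(mode=AccessMode.DISCOVERY,
                        declared_uses={"use_for_diseases": ("diabetes",)})
kept = screen_profiles(list(profiles.values()), request)
names = {id(p): n for n, p in profiles.items()}
for prof, decision in kept:
    print(f"{names[id(prof)]:14s} -> {decision.overall.value}")
print(f"kept {len(kept)} of {len(profiles)} profiles")

# The open cohort permits; the prose profile needs a human (REFER);
# the cancer-only profile denies a diabetes query and the access-only
# profile offers no discovery mode, so both are filtered out.
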