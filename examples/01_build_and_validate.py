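"""Build a data-use Profile concept by concept and validate it.

A Profile states the conditions of use of one resource: a Header
identifying the Profile and resource, plus at least one Main Body of
Permissions / Terms / Meta-Conditions entries.
"""

from adamatrix import (Header, MainBody, Profile, default_registry,
                       explain_rule, set_entry, validate)

registry = default_registry()

# start from an empty body; fill it in with the fail-fast builder
profile = Profile(header=Header(values={}), bodies=(MainBody(),))
profile = set_entry(profile, 0, "profile_id", "examples/cohort-42", registry=registry)
profile = set_entry(profile, 0, "profile_version", "2026-01-01/v1", registry=registry)
profile = set_entry(profile, 0, "resource_reference", "doi:10.9999/cohort-42",
                    registry=registry)
profile = set_entry(profile, 0, "mode_of_sharing", "DISCOVERY_AND_ACCESS",
                    registry=registry)
profile = set_entry(profile, 0, "use_for_diseases", "Limited",
                    free_text="Use permitted for research on diseases A, "
                              "B[Obligatory], and C",
                    registry=registry)

report = validate(profile, registry)
print("valid:", report.valid)

# remove the mode of sharing and watch rule R3 fire
broken = profile.model_copy(update={"bodies": (
    profile.bodies[0].model_copy(update={"meta": ()}),)})
for f in validate(broken, registry).findings:
    print(f"{f.rule_id} at {f.location}: {f.message}")
    print("  rule text:", explain_rule(f.rule_id))

# The valid profile passes all seven rules; dropping the required
# "Mode of sharing" Meta concept produces exactly one finding (R3).
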