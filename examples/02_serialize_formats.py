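"""Write one Profile in both interchange formats and read it back.

The JSON dialect suits APIs and document stores; the key-value dialect
is a flat, line-oriented form that diffs and greps well.  Both are
deterministic and round-trip to the identical in-memory Profile.
"""

from adamatrix import (GeneratorParams, from_json, from_keyvalue,
                       generate_profile, to_json, to_keyvalue)

profile = generate_profile(GeneratorParams(seed=11))

json_doc = to_json(profile)
kv_doc = to_keyvalue(profile)
print("--- key-value dialect ---")
print(kv_doc.payload, end="")
print("--- round trips ---")
print("json  ->", from_json(json_doc) == profile)
print("kv    ->", from_keyvalue(kv_doc) == profile)
print("cross ->", from_json(json_doc) == from_keyvalue(kv_doc))

# Both decoders recover the same Profile object, so a system may store
# either format and interoperate with systems using the other.
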