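"""The full signal-injection experiment in one call.

Generates the phantom, decomposes it, matches both components, seeds FC
maps at the overlap voxel and at the two component peaks, and scores every
thresholded map against the artificial-injection truth.
"""

from icaseed import experiment1

res = experiment1(rng_seed=1)
print(
    f"artificial component -> IC {res.ic_index_artificial + 1} "
    f"(|r| = {res.ic_match_r_artificial:.3f}); "
    f"natural -> IC {res.ic_index_natural + 1} "
    f"(|r| = {res.ic_match_r_natural:.3f})"
)
print()
print(res.summary().to_string(index=False))
print()
print("The artificial-peak seed isolates the injected component (100/100),")
print("while the overlap-voxel seed mixes both components into one map --")
print("the ambiguity hybrid ICA-seeding is designed to resolve.")
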