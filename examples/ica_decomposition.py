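"""Spatial ICA on a phantom run: recover the two injected components.

PCA reduces the demeaned run to 6 temporal dimensions; the fixed-point
ICA then separates maps by spatial non-Gaussianity.  Matching the z maps
against the known truth masks identifies which component is which.
"""

import numpy as np

from icaseed import (
    experiment1_config,
    fastica_spatial,
    make_phantom,
    match_component,
    normalize_run,
    pca_reduce,
)

run, truth = make_phantom(experiment1_config(), rng_seed=7)
demeaned = normalize_run(run, demean=True)
white = pca_reduce(demeaned, 6)
comps = fastica_spatial(white, rng_seed=7)

print(f"retained variance: {1 - white.residual_variance_fraction:.3f}")
print(f"converged: {comps.converged} after {comps.n_iter} iterations")
for name in ("natural", "artificial"):
    idx, r, comps = match_component(comps, truth.truth_map(name))
    peak = np.max(comps.zmaps[idx])
    print(
        f"  {name:<10} -> component {idx + 1} "
        f"(|r| with truth = {r:.3f}, peak z = {peak:.1f}, "
        f"variance share {comps.variance_fraction[idx]:.3%})"
    )
print()
print("Correlations near 1 mean the blind decomposition isolated each")
print("injected source on its own spatial map.")
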