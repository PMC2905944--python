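"""Generate the default signal-injection phantom and inspect its ground truth.

The phantom carries two known components on a 24x24x8 grid (TR 2 s, 190
volumes): a 'natural' blob responding to a block paradigm and an
'artificial' square-wave component over three triangles plus one voxel
shared with the blob, at 0.5% amplitude in 0.25% Gaussian noise.
"""

import numpy as np

from icaseed import experiment1_config, make_phantom

config = experiment1_config()
run, truth = make_phantom(config, rng_seed=7)

print(f"run: {run.t} volumes x {run.v} voxels, TR {run.geometry.tr} s")
total_var = run.data.var(axis=0).sum()
for name, mask in truth.component_masks.items():
    amp = truth.amplitudes_pct[name]
    wave_var = truth.waveforms[name].values.var()
    # injected signal variance: (amp% of the 1000-unit baseline)^2 * waveform var
    sig_var = mask.n_included * (amp / 100 * 1000.0) ** 2 * wave_var
    print(
        f"  {name:<10} {mask.n_included:>3} voxels, amplitude {amp}% "
        f"-> {100 * sig_var / total_var:.2f}% of total variance"
    )
print(f"overlap voxel(s) shared by both components: {truth.overlap_voxels.tolist()}")
print()
print("The variance shares show each injected component is a small but")
print("non-negligible fraction of the data, as in a real injection study.")
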