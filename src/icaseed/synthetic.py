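"""Synthetic BOLD phantom generator with full ground truth.

The phantom emulates the signal-injection design used to validate hybrid
ICA-seed FC methods: spatially compact components (boxes, spheres,
rasterized triangles, plus explicit extra voxels — e.g. one voxel shared
with another component) carrying square-wave or block-design-convolved
time courses, with amplitudes expressed as a percentage of the per-voxel
baseline mean, additive white Gaussian noise (optionally AR(1)-correlated
in time), and multi-subject groups with controlled amplitude variability
and spatial jitter.

Voxelwise signal model::

    data[t, j] = baseline[j] * (1 + sum_k amp_k/100 * w_k(t) * mask_k[j])
                 + noise_sd_pct/100 * baseline[j] * eps[t, j]

with each waveform ``w_k`` zero-mean and unit-peak, so an amplitude of
0.5% produces peak deviations of +/-0.5% of the voxel's baseline mean.
All randomness is driven by a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_model import BinaryMap, BrainMask, FMRIRun, Geometry, StatMap, TimeCourse

__all__ = [
    "ComponentSpec",
    "SimulationTruth",
    "PhantomConfig",
    "square_wave",
    "block_hrf_wave",
    "triangle_voxels",
    "sphere_voxels",
    "box_voxels",
    "make_phantom",
    "inject_signal",
    "make_group",
    "experiment1_config",
]


# ---------------------------------------------------------------------------
# Region helpers (0-based index space)


def box_voxels(lo, hi) -> np.ndarray:
    """Voxels of the closed box lo..hi (inclusive), as an (n, 3) array."""
    ranges = [np.arange(a, b + 1) for a, b in zip(lo, hi)]
    grid = np.meshgrid(*ranges, indexing="ij")
    return np.column_stack([g.ravel() for g in grid])


def sphere_voxels(center, radius: float) -> np.ndarray:
    c = np.asarray(center, dtype=float)
    r = int(np.ceil(radius))
    cand = box_voxels(np.floor(c - r).astype(int), np.ceil(c + r).astype(int))
    keep = np.sum((cand - c) ** 2, axis=1) <= radius**2
    return cand[keep]

def triangle_voxels(v0, v1, v2, slice_k: int) -> np.ndarray:
    """Rasterize a filled triangle (half-plane intersection) in one slice.

    Vertices are (i, j) pairs; a voxel center belongs to the triangle when
    it lies on the interior side of (or on) all three edges.
    """
    verts = [np.asarray(v, dtype=float) for v in (v0, v1, v2)]
    lo = np.floor(np.min(verts, axis=0)).astype(int)
    hi = np.ceil(np.max(verts, axis=0)).astype(int)
    ii, jj = np.meshgrid(np.arange(lo[0], hi[0] + 1), np.arange(lo[1], hi[1] + 1), indexing="ij")
    pts = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)

    def edge_sign(p, a, b):
        return (b[0] - a[0]) * (p[:, 1] - a[1]) - (b[1] - a[1]) * (p[:, 0] - a[0])

    d0 = edge_sign(pts, verts[0], verts[1])
    d1 = edge_sign(pts, verts[1], verts[2])
    d2 = edge_sign(pts, verts[2], verts[0])
    eps = 1e-9
    inside = ((d0 >= -eps) & (d1 >= -eps) & (d2 >= -eps)) | (
        (d0 <= eps) & (d1 <= eps) & (d2 <= eps)
    )
    ij = pts[inside].astype(int)
    return np.column_stack([ij, np.full(len(ij), slice_k, dtype=int)])


# ---------------------------------------------------------------------------
# Waveforms


def square_wave(t: int, tr: float, period_s: float, phase_s: float = 0.0) -> TimeCourse:
    """Zero-mean, unit-peak square wave (+1 first half-period)."""
    times = np.arange(t) * tr + phase_s
    values = np.where((times % period_s) < period_s / 2, 1.0, -1.0)
    values = values - values.mean()
    values = values / np.max(np.abs(values))
    return TimeCourse(values, label=f"square wave period {period_s}s")


def block_hrf_wave(t: int, tr: float, onsets, durations, peak_lag: float = 5.0,
                   hrf_sigma: float = 2.8) -> TimeCourse:
    """Block design convolved with the Gaussian response, zero-mean unit-peak."""
    from .glm import build_task_regressor

    reg = build_task_regressor(onsets, durations, t, tr, peak_lag, hrf_sigma)
    values = reg.values - reg.values.mean()
    values = values / np.max(np.abs(values))
    return TimeCourse(values, label="block-design response")


# ---------------------------------------------------------------------------
# Specs


@dataclass
class ComponentSpec:
    """One ground-truth component: a voxel set plus a waveform."""

    name: str
    voxels: np.ndarray  # (n, 3) int indices
    waveform: dict  # {"kind": "square_wave"|"block_hrf"|"custom", ...}
    amplitude_pct: float
    per_subject_amplitude_sd: float = 0.0  # percent of amplitude
    spatial_jitter_voxels: int = 0

    def __post_init__(self) -> None:
        self.voxels = np.unique(np.asarray(self.voxels, dtype=int), axis=0)
        if self.amplitude_pct < 0:
            raise ValueError("amplitude_pct must be >= 0")
        if len(self.voxels) == 0:
            raise ValueError(f"component {self.name!r} has an empty voxel set")

    def build_waveform(self, t: int, tr: float) -> TimeCourse:
        kind = self.waveform["kind"]
        if kind == "square_wave":
            return square_wave(
                t, tr, self.waveform["period_s"], self.waveform.get("phase_s", 0.0)
            )
        if kind == "block_hrf":
            return block_hrf_wave(
                t, tr, self.waveform["onsets"], self.waveform["durations"]
            )
        if kind == "custom":
            values = np.asarray(self.waveform["values"], dtype=float)
            values = values - values.mean()
            peak = np.max(np.abs(values))
            return TimeCourse(values / peak if peak > 0 else values, label=self.name)
        raise ValueError(f"unknown waveform kind {kind!r}")


@dataclass
class SimulationTruth:
    """Ground truth of one generated phantom."""

    component_masks: dict[str, BinaryMap]
    waveforms: dict[str, TimeCourse]
    amplitudes_pct: dict[str, float]
    overlap_voxels: np.ndarray  # (n, 3) voxels shared by >= 2 components
    rng_seed: int

    def truth_map(self, name: str) -> StatMap:
        """The component's indicator mask as a raw-valued StatMap."""
        bm = self.component_masks[name]
        return StatMap(bm.include.astype(float), "raw", bm.mask, f"truth: {name}")


@dataclass
class PhantomConfig:
    """Full recipe for one phantom (or a group template)."""

    geometry: Geometry
    t: int
    baseline_mean: float
    components: list[ComponentSpec]
    noise_sd_pct: float
    ar1_coefficient: float = 0.0
    baseline_gradient_pct: float = 0.0  # optional smooth spatial gradient

    def with_overrides(self, **kw) -> "PhantomConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Generation


def _component_column_mask(spec_voxels: np.ndarray, mask: BrainMask) -> np.ndarray:
    shape = mask.geometry.shape
    if np.any(spec_voxels < 0) or np.any(spec_voxels >= np.array(shape)):
        raise ValueError("component mask extends outside the grid")
    lin = np.ravel_multi_index(spec_voxels.T, shape, order="F")
    lookup = np.full(int(np.prod(shape)), -1, dtype=int)
    lookup[mask.linear_indices] = np.arange(mask.v)
    cols = lookup[lin]
    if np.any(cols < 0):
        raise ValueError("component mask extends outside the brain mask")
    include = np.zeros(mask.v, dtype=bool)
    include[cols] = True
    return include


def _baseline_image(config: PhantomConfig, mask: BrainMask) -> np.ndarray:
    base = np.full(mask.v, float(config.baseline_mean))
    if config.baseline_gradient_pct:
        # smooth linear gradient along the first axis, +/- gradient_pct/2
        coords = mask.coordinates()[:, 0].astype(float)
        extent = max(coords.max() - coords.min(), 1.0)
        ramp = (coords - coords.min()) / extent - 0.5
        base *= 1.0 + config.baseline_gradient_pct / 100.0 * ramp
    return base


def make_phantom(
    config: PhantomConfig, rng_seed: int = 0
) -> tuple[FMRIRun, SimulationTruth]:
    """Generate one phantom run plus its ground truth (seed-deterministic)."""
    geom = config.geometry
    if config.t < 2:
        raise ValueError("need at least 2 volumes")
    mask = BrainMask.full(geom)
    baseline = _baseline_image(config, mask)
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed) & 0x7FFFFFFF, 0xF0]))

    signal = np.zeros((config.t, mask.v))
    masks: dict[str, BinaryMap] = {}
    waves: dict[str, TimeCourse] = {}
    amps: dict[str, float] = {}
    col_sets = []
    for spec in config.components:
        cols = _component_column_mask(spec.voxels, mask)
        wave = spec.build_waveform(config.t, geom.tr)
        signal += (
            spec.amplitude_pct / 100.0
        ) * np.outer(wave.values, cols.astype(float))
        masks[spec.name] = BinaryMap(cols, mask)
        waves[spec.name] = wave
        amps[spec.name] = spec.amplitude_pct
        col_sets.append(cols)

    overlap_cols = np.zeros(mask.v, dtype=bool)
    for i in range(len(col_sets)):
        for j in range(i + 1, len(col_sets)):
            overlap_cols |= col_sets[i] & col_sets[j]
    overlap_voxels = mask.coordinates()[np.flatnonzero(overlap_cols)]

    data = baseline[None, :] * (1.0 + signal)
    if config.noise_sd_pct > 0:
        eps = rng.standard_normal((config.t, mask.v))
        if config.ar1_coefficient:
            phi = float(config.ar1_coefficient)
            for i in range(1, config.t):
                eps[i] = phi * eps[i - 1] + np.sqrt(1 - phi**2) * eps[i]
        data = data + (config.noise_sd_pct / 100.0) * baseline[None, :] * eps

    run = FMRIRun(
        data,
        mask,
        geom,
        [f"phantom: {len(config.components)} components, noise {config.noise_sd_pct}%, seed {rng_seed}"],
    )
    truth = SimulationTruth(
        component_masks=masks,
        waveforms=waves,
        amplitudes_pct=amps,
        overlap_voxels=overlap_voxels,
        rng_seed=int(rng_seed),
    )
    return run, truth


def inject_signal(
    run: FMRIRun, mask: BinaryMap, waveform: TimeCourse, amplitude_pct: float
) -> FMRIRun:
    """Add a scaled waveform to masked voxels of an existing run.

    The added signal is ``amplitude_pct/100 * per-voxel temporal mean *
    waveform``; with a zero-mean waveform the per-voxel mean is unchanged.
    """
    if len(waveform) != run.t:
        raise ValueError("waveform length does not match the run")
    if not mask.mask.same_grid(run.mask):
        raise ValueError("injection mask is not on the run's grid")
    cols = np.flatnonzero(mask.include)
    data = run.data.copy()
    voxel_means = data[:, cols].mean(axis=0)
    data[:, cols] += (amplitude_pct / 100.0) * np.outer(waveform.values, voxel_means)
    return run.with_data(
        data, f"inject_signal: {len(cols)} voxels at {amplitude_pct}% amplitude"
    )


def _jitter_voxels(
    voxels: np.ndarray, jitter: int, shape, rng: np.random.Generator
) -> np.ndarray:
    """Rigid integer shift of a voxel set, clipped to stay inside the grid."""
    if jitter <= 0:
        return voxels
    shift = rng.integers(-jitter, jitter + 1, size=3)
    lo = voxels.min(axis=0)
    hi = voxels.max(axis=0)
    shift = np.clip(shift, -lo, np.array(shape) - 1 - hi)
    return voxels + shift


def make_group(
    template: PhantomConfig, n_subjects: int, rng_seed: int = 0
) -> list[tuple[FMRIRun, SimulationTruth]]:
    """Generate a subject group from one template config.

    Per subject: component amplitudes are scaled by ``1 + N(0, sd/100)``
    (floored at 0) using each component's ``per_subject_amplitude_sd``, and
    component voxel sets are rigidly shifted by up to
    ``spatial_jitter_voxels`` in each axis.  Subject seeds derive
    deterministically from ``rng_seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    out = []
    for s in range(n_subjects):
        srng = np.random.default_rng(
            np.random.SeedSequence([int(rng_seed) & 0x7FFFFFFF, 0xA5, s])
        )
        comps = []
        for spec in template.components:
            amp = spec.amplitude_pct
            if spec.per_subject_amplitude_sd > 0:
                amp = max(
                    0.0,
                    amp * (1.0 + srng.normal(0.0, spec.per_subject_amplitude_sd / 100.0)),
                )
            voxels = _jitter_voxels(
                spec.voxels, spec.spatial_jitter_voxels, template.geometry.shape, srng
            )
            comps.append(
                ComponentSpec(
                    name=spec.name,
                    voxels=voxels,
                    waveform=spec.waveform,
                    amplitude_pct=amp,
                )
            )
        subj_cfg = template.with_overrides(components=comps)
        # subject phantom seed derived from the group seed, below 2^31
        subj_seed = int(
            np.random.SeedSequence([int(rng_seed) & 0x7FFFFFFF, 0x5E, s]).generate_state(1)[0]
            & 0x7FFFFFFF
        )
        out.append(make_phantom(subj_cfg, subj_seed))
    return out


# ---------------------------------------------------------------------------
# The named signal-injection fixture


def experiment1_config(
    shape=(24, 24, 8),
    tr: float = 2.0,
    t: int = 190,
    baseline_mean: float = 1000.0,
    artificial_amplitude_pct: float = 0.5,
    natural_amplitude_pct: float = 1.0,
    noise_sd_pct: float = 0.25,
    per_subject_amplitude_sd: float = 0.0,
    spatial_jitter_voxels: int = 0,
) -> PhantomConfig:
    """The default signal-injection phantom.

    Two ground-truth components on a 24 x 24 x 8 grid (TR 2 s, 190
    volumes, 380 s):

    * a "natural" component — a compact spherical blob responding to a
      10-block visual-style paradigm (19 s on / 19 s off) through the
      Gaussian haemodynamic response; and
    * an "artificial" component — a +/-0.5%-amplitude square wave with a
      60 s period (30 volumes) over three triangular regions in one axial
      slice, plus one voxel inside the natural blob (the overlap voxel).

    The triangles cover about 1% of the grid, so with the default noise
    level the artificial component carries a few percent of the total
    variance — the regime the injection experiment operates in.
    """
    geom = Geometry.isotropic(shape, voxel_mm=3.0, tr=tr)
    slice_k = shape[2] // 2

    natural_center = (6, 6, slice_k)
    natural_voxels = sphere_voxels(natural_center, 2.0)

    tri = np.vstack(
        [
            triangle_voxels((14, 2), (19, 2), (14, 7), slice_k),
            triangle_voxels((2, 14), (7, 14), (2, 19), slice_k),
            triangle_voxels((16, 16), (21, 16), (21, 21), slice_k),
        ]
    )
    overlap_voxel = np.array([natural_center])  # one voxel inside the blob
    artificial_voxels = np.vstack([tri, overlap_voxel])

    block_period = 38.0  # 10 blocks over 380 s
    onsets = [i * block_period for i in range(int(t * tr // block_period))]
    natural = ComponentSpec(
        name="natural",
        voxels=natural_voxels,
        waveform={"kind": "block_hrf", "onsets": onsets, "durations": [19.0]},
        amplitude_pct=natural_amplitude_pct,
        per_subject_amplitude_sd=per_subject_amplitude_sd,
        spatial_jitter_voxels=spatial_jitter_voxels,
    )
    artificial = ComponentSpec(
        name="artificial",
        voxels=artificial_voxels,
        waveform={"kind": "square_wave", "period_s": 60.0},
        amplitude_pct=artificial_amplitude_pct,
        per_subject_amplitude_sd=per_subject_amplitude_sd,
        spatial_jitter_voxels=spatial_jitter_voxels,
    )
    return PhantomConfig(
        geometry=geom,
        t=t,
        baseline_mean=baseline_mean,
        components=[natural, artificial],
        noise_sd_pct=noise_sd_pct,
    )
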