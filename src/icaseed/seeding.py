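"""Seed construction from IC spatial maps and seed time-course derivation.

Five hybrid seed flavours are supported:

* ``SV`` — single voxel: the voxel with the highest z-score in the map.
* ``FV`` — few voxels: all voxels whose z exceeds (max - 1.0).
* ``MV`` — many voxels: an integer z threshold chosen so the suprathreshold
  count is closest to a target count (ties toward the lower threshold,
  i.e. more voxels).
* ``DRS`` — dual regression against a single IC spatial map.
* ``DRA`` — dual regression against a full IC map set, one map of interest.

SV/FV/MV yield ROI time courses (unweighted voxel average); DRS/DRA yield
regression-based time courses (stage 1 of dual regression), which weight
voxels by map value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import BinaryMap, FMRIRun, StatMap, TimeCourse
from .decomposition import ComponentSet

__all__ = [
    "SeedSpec",
    "peak_voxel",
    "few_voxel_seed",
    "many_voxel_seed",
    "roi_timecourse",
    "dual_regression_stage1",
]

ROI_METHODS = ("SV", "FV", "MV")
DUAL_METHODS = ("DRS", "DRA")


@dataclass
class SeedSpec:
    """A seed definition for one of the five hybrid methods."""

    method: str
    source_map: StatMap | None = None
    source_set: ComponentSet | None = None
    interest_index: int | None = None
    voxel_mask: BinaryMap | None = None
    target_count: int | None = None

    def __post_init__(self) -> None:
        if self.method not in ROI_METHODS + DUAL_METHODS:
            raise ValueError(f"unknown seed method {self.method!r}")
        if self.method in ROI_METHODS:
            if self.voxel_mask is None or self.voxel_mask.n_included == 0:
                raise ValueError(f"{self.method} seed requires a nonempty voxel mask")
        if self.method == "DRS" and self.source_map is None:
            raise ValueError("DRS seed requires a source map")
        if self.method == "DRA":
            if self.source_set is None or self.interest_index is None:
                raise ValueError("DRA seed requires a source set and interest index")
            if not (0 <= self.interest_index < self.source_set.n_components):
                raise ValueError("interest_index out of range")

    def describe(self) -> dict:
        """JSON-serialisable summary (indices, world-mm coordinates)."""
        out: dict = {"method": self.method}
        if self.voxel_mask is not None:
            m = self.voxel_mask.mask
            in_mask = np.flatnonzero(self.voxel_mask.include)
            coords = m.coordinates()[in_mask]
            out["n_voxels"] = int(len(in_mask))
            out["voxel_indices"] = in_mask.tolist()
            out["voxel_ijk"] = coords.tolist()
            out["voxel_world_mm"] = np.atleast_2d(
                m.geometry.voxel_to_world(coords)
            ).tolist()
            out["threshold_used"] = self.voxel_mask.threshold_used
        if self.method == "DRA":
            out["interest_index"] = int(self.interest_index)
            out["n_maps"] = int(self.source_set.n_components)
        return out


def _check_nonconstant(map_: StatMap) -> None:
    if np.ptp(map_.values) == 0:
        raise ValueError("seed source map is constant")


def peak_voxel(map_: StatMap) -> SeedSpec:
    """SV seed: single-voxel mask at the map maximum (ties -> lowest index)."""
    _check_nonconstant(map_)
    idx = int(np.argmax(map_.values))  # argmax returns the first (lowest) index
    include = np.zeros(map_.mask.v, dtype=bool)
    include[idx] = True
    return SeedSpec(
        method="SV",
        source_map=map_,
        voxel_mask=BinaryMap(include, map_.mask, threshold_used=None),
    )


def few_voxel_seed(map_: StatMap) -> SeedSpec:
    """FV seed: voxels whose value exceeds (max - 1.0); always holds the peak."""
    _check_nonconstant(map_)
    cutoff = float(map_.values.max()) - 1.0
    include = map_.values > cutoff
    return SeedSpec(
        method="FV",
        source_map=map_,
        voxel_mask=BinaryMap(include, map_.mask, threshold_used=cutoff),
    )


def many_voxel_seed(map_: StatMap, target_count: int) -> SeedSpec:
    """MV seed: whole-z threshold with suprathreshold count closest to target.

    Candidate thresholds are the integers 1 .. ceil(max)-1 (strict '>');
    the threshold minimising |count - target| wins, ties going to the
    lower threshold (more voxels).
    """
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    _check_nonconstant(map_)
    zmax = float(map_.values.max())
    candidates = [
        (int(np.sum(map_.values > thr)), thr)
        for thr in range(1, int(np.ceil(zmax)) + 1)
    ]
    candidates = [(n, thr) for n, thr in candidates if n > 0]
    if not candidates:
        raise ValueError("no integer threshold yields a nonempty mask")
    # minimal |count-target|; among ties the lower threshold (scan order is
    # ascending threshold, so the first optimum encountered wins)
    best_n, best_thr = min(candidates, key=lambda c: (abs(c[0] - target_count), c[1]))
    include = map_.values > best_thr
    return SeedSpec(
        method="MV",
        source_map=map_,
        voxel_mask=BinaryMap(include, map_.mask, threshold_used=float(best_thr)),
        target_count=target_count,
    )


def _normalize_course(values: np.ndarray) -> tuple[np.ndarray, bool]:
    values = values - values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        return np.zeros_like(values), True
    return values / sd, False


def roi_timecourse(run: FMRIRun, seed: SeedSpec) -> TimeCourse:
    """Unweighted mean series over the seed voxels, normalized to z-units.

    A seed whose voxel series cancel exactly yields an all-zero course with
    ``degenerate=True``.
    """
    if seed.method not in ROI_METHODS:
        raise ValueError(f"roi_timecourse needs an SV/FV/MV seed, got {seed.method}")
    if not seed.voxel_mask.mask.same_grid(run.mask):
        raise ValueError("seed mask is not on the run's voxel grid")
    cols = np.flatnonzero(seed.voxel_mask.include)
    if len(cols) == 0:
        raise ValueError("empty seed/run intersection")
    mean_series = run.data[:, cols].mean(axis=1)
    values, degenerate = _normalize_course(mean_series)
    return TimeCourse(
        values, label=f"{seed.method} seed course", role="interest", degenerate=degenerate
    )


def dual_regression_stage1(
    run: FMRIRun,
    maps: StatMap | list[StatMap],
    interest_index: int | None = None,
    cond_tol: float = 1e8,
) -> list[TimeCourse]:
    """Stage 1 of dual regression: regress each volume on the map set.

    Each spatial map is demeaned over the mask and the joint spatial
    regression (with an intercept per time point) is solved for all time
    points at once; the resulting per-map series are normalized to zero
    mean and unit variance.  With ``interest_index`` set (DRA), the course
    at that index is labelled interest and the rest nuisance.
    """
    if isinstance(maps, StatMap):
        maps = [maps]
    if not maps:
        raise ValueError("need at least one seed map")
    for m in maps:
        if not m.mask.same_grid(run.mask):
            raise ValueError("seed map is not on the run's voxel grid")
    A = np.column_stack([m.values - m.values.mean() for m in maps])
    design = np.column_stack([A, np.ones(run.v)])
    cond = np.linalg.cond(design)
    if cond > cond_tol:
        raise ValueError(
            f"seed maps are collinear (design condition number {cond:.3g})"
        )
    coefs, *_ = np.linalg.lstsq(design, run.data.T, rcond=None)  # (m+1, t)
    courses = []
    for i, m in enumerate(maps):
        values, degenerate = _normalize_course(coefs[i])
        role = "interest"
        if interest_index is not None:
            role = "interest" if i == interest_index else "nuisance"
        courses.append(
            TimeCourse(
                values,
                label=m.label or f"map{i + 1} course",
                role=role,
                degenerate=degenerate,
            )
        )
    return courses
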