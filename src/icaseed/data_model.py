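"""Core data containers and I/O for masked 4D fMRI time series.

The central container is :class:`FMRIRun`, which stores one run as a
``t x v`` matrix (time points by in-mask voxels), following the usual
convention for voxelwise linear modelling: each row is a volume, each
column a voxel time course.  Voxel columns are ordered by ascending
linear voxel index with the fastest-varying (first) axis first, i.e.
Fortran ravel order of the spatial grid; the ordering is part of the
public contract so that seed voxel indices are reproducible.

NIfTI reading/writing goes through nibabel.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "Geometry",
    "BrainMask",
    "FMRIRun",
    "TimeCourse",
    "StatMap",
    "BinaryMap",
    "load_run",
    "save_map",
    "normalize_run",
    "highpass",
    "concat_group",
    "load_timecourses_tsv",
    "save_timecourses_tsv",
]


@dataclass(frozen=True)
class Geometry:
    """Spatial grid plus repetition time.

    Parameters
    ----------
    shape : tuple of int
        Three spatial extents in voxels.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    affine : ndarray, shape (4, 4)
        Voxel-index -> world-mm transform (NIfTI convention).
    tr : float
        Repetition time in seconds.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        vs = tuple(float(s) for s in self.voxel_size)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vs)
        affine = np.asarray(self.affine, dtype=float)
        object.__setattr__(self, "affine", affine)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be 3 extents >= 1, got {shape}")
        if any(s <= 0 for s in vs):
            raise ValueError(f"voxel sizes must be > 0, got {vs}")
        if self.tr <= 0:
            raise ValueError(f"tr must be > 0 seconds, got {self.tr}")
        if affine.shape != (4, 4) or abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @classmethod
    def isotropic(cls, shape, voxel_mm: float = 3.0, tr: float = 2.0) -> "Geometry":
        """Convenience constructor with a diagonal affine."""
        affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        return cls(tuple(shape), (voxel_mm,) * 3, affine, tr)

    def voxel_to_world(self, ijk) -> np.ndarray:
        """Map 0-based voxel indices to world mm via the affine."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        hom = np.c_[ijk, np.ones(len(ijk))]
        return (self.affine @ hom.T).T[:, :3].squeeze()


@dataclass(frozen=True)
class BrainMask:
    """Boolean inclusion mask over a spatial grid."""

    geometry: Geometry
    include: np.ndarray  # 3D boolean

    def __post_init__(self) -> None:
        inc = np.asarray(self.include, dtype=bool)
        object.__setattr__(self, "include", inc)
        if inc.shape != self.geometry.shape:
            raise ValueError(
                f"mask shape {inc.shape} != geometry shape {self.geometry.shape}"
            )
        if self.v < 1:
            raise ValueError("mask must include at least one voxel")

    @property
    def v(self) -> int:
        return int(self.include.sum())

    @property
    def linear_indices(self) -> np.ndarray:
        """Fortran-order linear indices of included voxels, ascending."""
        return np.flatnonzero(self.include.ravel(order="F"))

    def coordinates(self) -> np.ndarray:
        """0-based (i, j, k) coordinates of included voxels, column order."""
        idx = self.linear_indices
        return np.column_stack(np.unravel_index(idx, self.geometry.shape, order="F"))

    def same_grid(self, other: "BrainMask") -> bool:
        return (
            self.geometry.shape == other.geometry.shape
            and np.array_equal(self.include, other.include)
        )

    @classmethod
    def full(cls, geometry: Geometry) -> "BrainMask":
        return cls(geometry, np.ones(geometry.shape, dtype=bool))


@dataclass
class FMRIRun:
    """One subject/session's masked 4D data as a t x v matrix."""

    data: np.ndarray  # (t, v)
    mask: BrainMask
    geometry: Geometry
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D time-by-voxel matrix")
        if self.data.shape[1] != self.mask.v:
            raise ValueError(
                f"data has {self.data.shape[1]} columns but mask includes "
                f"{self.mask.v} voxels"
            )
        if self.t < 2:
            raise ValueError("a run needs at least 2 volumes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("run contains non-finite values")

    @property
    def t(self) -> int:
        return self.data.shape[0]

    @property
    def v(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray, note: str) -> "FMRIRun":
        return FMRIRun(data, self.mask, self.geometry, self.provenance + [note])


@dataclass
class TimeCourse:
    """A length-t regressor with an interest/nuisance role."""

    values: np.ndarray
    label: str = ""
    role: str = "interest"  # "interest" | "nuisance"
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"time course {self.label!r} has non-finite values")
        if self.role not in ("interest", "nuisance"):
            raise ValueError(f"unknown role {self.role!r}")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class StatMap:
    """A voxelwise statistical image over a mask's included voxels."""

    values: np.ndarray
    statistic: str  # "beta" | "t" | "z" | "raw"
    mask: BrainMask
    label: str = ""

    _STATS = ("beta", "t", "z", "raw")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != self.mask.v:
            raise ValueError(
                f"map has {len(self.values)} values for a {self.mask.v}-voxel mask"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("stat map contains non-finite values")
        if self.statistic not in self._STATS:
            raise ValueError(f"unknown statistic {self.statistic!r}")


@dataclass
class BinaryMap:
    """A thresholded (boolean) map over a mask's included voxels."""

    include: np.ndarray
    mask: BrainMask
    threshold_used: float | None = None

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool).ravel()
        if len(self.include) != self.mask.v:
            raise ValueError(
                f"binary map has {len(self.include)} entries for a "
                f"{self.mask.v}-voxel mask"
            )

    @property
    def n_included(self) -> int:
        return int(self.include.sum())


# ---------------------------------------------------------------------------
# I/O


def _geometry_from_header(img: nib.Nifti1Image, default_tr: float = 2.0) -> Geometry:
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else default_tr
    return Geometry(
        shape=tuple(int(s) for s in img.shape[:3]),
        voxel_size=tuple(float(z) for z in zooms[:3]),
        affine=np.asarray(img.affine, dtype=float),
        tr=tr,
    )


def load_run(image_path, mask_path=None) -> FMRIRun:
    """Load a 4D NIfTI image (and optional 3D mask) as an :class:`FMRIRun`.

    Without an explicit mask, voxels whose temporal standard deviation is
    zero (e.g. all-zero background) are excluded automatically.
    """
    img = nib.load(str(image_path))
    if img.ndim != 4:
        raise ValueError(f"{image_path}: expected a 4D image, got {img.ndim}D")
    geometry = _geometry_from_header(img)
    vol = np.asarray(img.get_fdata(), dtype=float)
    if not np.all(np.isfinite(vol)):
        raise ValueError(f"{image_path}: image contains non-finite values")
    t = vol.shape[3]
    if t < 2:
        raise ValueError(f"{image_path}: fewer than 2 volumes")
    # (x, y, z, t) -> (t, all voxels) with Fortran spatial ordering
    flat = vol.reshape(-1, t, order="F").T

    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        if tuple(mimg.shape[:3]) != geometry.shape:
            raise ValueError(
                f"mask grid {tuple(mimg.shape[:3])} does not match image grid "
                f"{geometry.shape}"
            )
        include = np.asarray(mimg.get_fdata()) > 0
        note = f"loaded with explicit mask ({int(include.sum())} voxels)"
    else:
        include = (flat.std(axis=0) > 0).reshape(geometry.shape, order="F")
        note = f"loaded with automatic nonzero-variance mask ({int(include.sum())} voxels)"
    mask = BrainMask(geometry, include)
    data = flat[:, mask.linear_indices]
    return FMRIRun(data, mask, geometry, [note])


def save_map(stat_or_binary, path) -> None:
    """Write a StatMap/BinaryMap to a 3D NIfTI; masked-out voxels become 0."""
    m = stat_or_binary.mask
    vol = np.zeros(np.prod(m.geometry.shape), dtype=np.float64)
    if isinstance(stat_or_binary, BinaryMap):
        vol[m.linear_indices] = stat_or_binary.include.astype(float)
    else:
        vol[m.linear_indices] = stat_or_binary.values
    img = nib.Nifti1Image(vol.reshape(m.geometry.shape, order="F"), m.geometry.affine)
    img.header.set_zooms(m.geometry.voxel_size)
    nib.save(img, str(path))


def load_map(path, mask: BrainMask, statistic: str = "raw", label: str = "") -> StatMap:
    """Load a 3D NIfTI as a StatMap over `mask` (inverse of :func:`save_map`)."""
    img = nib.load(str(path))
    if tuple(img.shape[:3]) != mask.geometry.shape:
        raise ValueError("image grid does not match mask geometry")
    flat = np.asarray(img.get_fdata(), dtype=float).ravel(order="F")
    return StatMap(flat[mask.linear_indices], statistic, mask, label)


def save_timecourses_tsv(courses: list[TimeCourse], path) -> None:
    """One column per time course, header row of labels (TSV)."""
    import pandas as pd

    cols = {c.label or f"tc{i}": c.values for i, c in enumerate(courses)}
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def load_timecourses_tsv(path, roles=None) -> list[TimeCourse]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    roles = roles or {}
    return [
        TimeCourse(df[c].to_numpy(), label=str(c), role=roles.get(c, "interest"))
        for c in df.columns
    ]


def save_provenance(run: FMRIRun, path) -> None:
    with open(path, "w") as fh:
        json.dump({"provenance": run.provenance, "t": run.t, "v": run.v}, fh, indent=2)


# ---------------------------------------------------------------------------
# Normalisation and filtering


def normalize_run(run: FMRIRun, demean: bool = True, variance_normalize: bool = False) -> FMRIRun:
    """Remove per-voxel temporal mean and/or scale temporal variance to 1.

    Zero-variance voxels map to all-zero columns rather than erroring, so
    degenerate phantom voxels stay usable.  The operation is idempotent.
    """
    data = run.data.copy()
    notes = []
    if demean:
        data -= data.mean(axis=0, keepdims=True)
        notes.append("demeaned")
    if variance_normalize:
        sd = data.std(axis=0, ddof=1, keepdims=True)
        nz = sd > 0
        data = np.where(nz, data / np.where(nz, sd, 1.0), 0.0)
        notes.append("variance-normalized")
    return run.with_data(data, "normalize_run: " + ", ".join(notes) if notes else "normalize_run: no-op")


def _gaussian_running_line_fit(data: np.ndarray, sigma_samples: float) -> np.ndarray:
    """Fitted values of a Gaussian-weighted local straight-line fit.

    For each time point i the series is fit by weighted least squares with
    weights exp(-(k-i)^2 / (2 sigma^2)); the fitted value at i is returned.
    Computed via convolution of the kernel moments.
    """
    t = data.shape[0]
    half = max(1, int(np.ceil(4 * sigma_samples)))
    k = np.arange(-half, half + 1, dtype=float)
    w = np.exp(-(k**2) / (2 * sigma_samples**2))

    # Weighted moments of the local regression, handling edges by
    # convolving the indicator alongside (weights renormalise implicitly).
    def conv(series2d: np.ndarray, kernel: np.ndarray) -> np.ndarray:
        from scipy.ndimage import convolve1d

        return convolve1d(series2d, kernel, axis=0, mode="constant", cval=0.0)

    ones = np.ones((t, 1))
    s0 = conv(ones, w)  # sum w
    s1 = conv(ones, w * k)  # sum w (k-i); kernel offset sign handled below
    s2 = conv(ones, w * k**2)
    t0 = conv(data, w)
    t1 = conv(data, w * k)
    # convolve1d flips the kernel, so w*k convolution yields sum_j w(j-i)*(i-j)*y_j;
    # flip sign to get moments in (j - i).
    s1 = -s1
    t1 = -t1
    denom = s0 * s2 - s1**2
    denom = np.where(np.abs(denom) < 1e-300, 1.0, denom)
    intercept = (s2 * t0 - s1 * t1) / denom
    return intercept


def highpass(run: FMRIRun, sigma_seconds: float) -> FMRIRun:
    """Highpass filter: residual of a Gaussian-weighted running-line fit.

    `sigma_seconds` is the kernel sigma in seconds; it is converted to
    samples via the run's TR.  The output is demeaned per voxel.
    """
    if sigma_seconds <= 0:
        raise ValueError("sigma_seconds must be > 0")
    tr = run.geometry.tr
    if sigma_seconds < tr:
        warnings.warn(
            f"highpass sigma ({sigma_seconds}s) is below the TR ({tr}s); "
            "the filter will remove nearly everything",
            stacklevel=2,
        )
    sigma_samples = sigma_seconds / tr
    fitted = _gaussian_running_line_fit(run.data, sigma_samples)
    resid = run.data - fitted
    resid -= resid.mean(axis=0, keepdims=True)
    return run.with_data(resid, f"highpass: gaussian running-line sigma={sigma_seconds}s")


def concat_group(runs: list[FMRIRun]) -> FMRIRun:
    """Temporally concatenate runs sharing one mask (group 'run')."""
    if not runs:
        raise ValueError("concat_group needs at least one run")
    first = runs[0]
    for i, r in enumerate(runs[1:], start=2):
        if not first.mask.same_grid(r.mask):
            raise ValueError(f"run {i} mask does not match run 1 mask")
    data = np.vstack([r.data for r in runs])
    ranges = []
    start = 0
    for r in runs:
        ranges.append((start, start + r.t))
        start += r.t
    prov = [f"concat_group: {len(runs)} runs, row ranges {ranges}"]
    return FMRIRun(data, first.mask, first.geometry, prov)


def subject_row_ranges(runs: list[FMRIRun]) -> list[tuple[int, int]]:
    ranges = []
    start = 0
    for r in runs:
        ranges.append((start, start + r.t))
        start += r.t
    return ranges
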