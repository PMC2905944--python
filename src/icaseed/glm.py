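"""Voxelwise GLM fitting, Gaussianised z maps and map thresholding.

The model is ``X = G beta + eps`` with ``X`` the t x v run matrix and
``G`` the t x s design of time-course regressors.  Ordinary least squares
is fit per voxel; t statistics (beta / SE) are mapped through the t
cumulative distribution and the standard-normal quantile function to
produce Gaussianised z maps, capped at |z| = 38 so that noise-free
fixtures stay finite.

Thresholding is one-tailed throughout (only positive z counts as
activation): a fixed z cutoff, Bonferroni familywise correction, or
Benjamini–Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import BinaryMap, FMRIRun, StatMap, TimeCourse
from .seeding import ROI_METHODS, SeedSpec, dual_regression_stage1, roi_timecourse

__all__ = [
    "DesignMatrix",
    "GLMResult",
    "build_task_regressor",
    "glm_fit",
    "threshold_map",
    "seed_fc",
    "Z_CAP",
]

Z_CAP = 38.0


@dataclass
class DesignMatrix:
    """Time-course regressors with per-column interest flags."""

    columns: list[TimeCourse]

    def __post_init__(self) -> None:
        if not self.columns:
            raise ValueError("design matrix needs at least one column")
        t = len(self.columns[0])
        if any(len(c) != t for c in self.columns):
            raise ValueError("design columns have unequal lengths")
        if not any(c.role == "interest" for c in self.columns):
            raise ValueError("design matrix needs at least one interest column")

    @property
    def t(self) -> int:
        return len(self.columns[0])

    @property
    def s(self) -> int:
        return len(self.columns)

    @property
    def matrix(self) -> np.ndarray:
        return np.column_stack([c.values for c in self.columns])

    @property
    def interest_flags(self) -> list[bool]:
        return [c.role == "interest" for c in self.columns]


@dataclass
class GLMResult:
    """Per-column beta and z maps plus residual variance."""

    betas: list[StatMap]
    zmaps: list[StatMap]
    residual_variance: StatMap
    dof: int
    design: DesignMatrix

    def interest_zmap(self) -> StatMap:
        """z map of the first interest column."""
        for z, flag in zip(self.zmaps, self.design.interest_flags):
            if flag:
                return z
        raise ValueError("no interest column")  # unreachable by construction


def build_task_regressor(
    block_onsets,
    block_durations,
    t: int,
    tr: float,
    peak_lag: float = 5.0,
    hrf_sigma: float = 2.8,
) -> TimeCourse:
    """Block-design regressor: boxcar convolved with a Gaussian response.

    The haemodynamic response kernel is a unit-area Gaussian centred at
    ``peak_lag`` seconds with width ``hrf_sigma``, truncated at +/- 4 sigma;
    the result is normalized to zero mean and unit variance.
    """
    onsets = np.atleast_1d(np.asarray(block_onsets, dtype=float))
    durations = np.atleast_1d(np.asarray(block_durations, dtype=float))
    if len(onsets) == 0:
        raise ValueError("block list is empty")
    if len(durations) == 1:
        durations = np.full(len(onsets), durations[0])
    if len(durations) != len(onsets):
        raise ValueError("onsets and durations differ in length")
    if np.any(durations <= 0):
        raise ValueError("durations must be > 0")
    run_len = t * tr
    if np.any(onsets < 0) or np.any(onsets >= run_len):
        raise ValueError("onsets must lie within the run")

    times = np.arange(t) * tr
    boxcar = np.zeros(t)
    for onset, dur in zip(onsets, durations):
        boxcar[(times >= onset) & (times < onset + dur)] = 1.0
    if not boxcar.any():
        raise ValueError("boxcar is all zero at this sampling; check onsets/durations")

    # kernel sampled on the acquisition grid (multiples of tr) so that an
    # impulse response peaks at the sample nearest peak_lag
    half = int(np.ceil((peak_lag + 4 * hrf_sigma) / tr))
    tau = np.arange(-half, half + 1) * tr
    tau = tau[np.abs(tau - peak_lag) <= 4 * hrf_sigma]
    kernel = np.exp(-((tau - peak_lag) ** 2) / (2 * hrf_sigma**2))
    kernel /= kernel.sum()
    n_neg = int(np.sum(tau < 0))  # acausal part of the truncated kernel
    conv = np.convolve(boxcar, kernel, mode="full")
    values = conv[n_neg : n_neg + t]

    values = values - values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("regressor is constant after convolution")
    return TimeCourse(values / sd, label="task regressor", role="interest")


def _t_to_z(tvals: np.ndarray, dof: int) -> np.ndarray:
    """Map t statistics to standard-normal quantiles, sign-symmetrically."""
    z = np.empty_like(tvals)
    pos = tvals >= 0
    # work in the survival tail for numerical precision at large |t|
    z[pos] = stats.norm.isf(stats.t.sf(tvals[pos], dof))
    z[~pos] = -stats.norm.isf(stats.t.sf(-tvals[~pos], dof))
    return np.clip(np.nan_to_num(z, nan=0.0, posinf=Z_CAP, neginf=-Z_CAP), -Z_CAP, Z_CAP)


def glm_fit(run: FMRIRun, design: DesignMatrix, prewhiten: bool = False) -> GLMResult:
    """Ordinary least squares per voxel with Gaussianised z maps.

    With ``prewhiten=True``, a single Cochrane–Orcutt step is applied: the
    pooled lag-1 autocorrelation of the OLS residuals is estimated and the
    model is refit on AR(1)-differenced data (one effective dof is spent on
    the AR coefficient).  The default OLS is exact for white noise.
    """
    if design.t != run.t:
        raise ValueError(f"design has {design.t} rows but run has {run.t} volumes")
    if design.s >= run.t:
        raise ValueError("design has as many columns as time points")
    G = design.matrix
    if np.linalg.matrix_rank(G) < design.s:
        raise ValueError("design matrix is rank deficient")

    X = run.data
    dof = run.t - design.s
    if prewhiten:
        beta0, *_ = np.linalg.lstsq(G, X, rcond=None)
        resid0 = X - G @ beta0
        num = np.sum(resid0[1:] * resid0[:-1])
        den = np.sum(resid0[:-1] ** 2)
        rho = float(np.clip(num / den if den > 0 else 0.0, -0.99, 0.99))
        X = X[1:] - rho * X[:-1]
        G = G[1:] - rho * G[:-1]
        dof = X.shape[0] - design.s - 1

    gtg_inv = np.linalg.inv(G.T @ G)
    beta = gtg_inv @ G.T @ X  # (s, v)
    resid = X - G @ beta
    sigma2 = np.sum(resid**2, axis=0) / dof
    se = np.sqrt(np.outer(np.diag(gtg_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.sign(beta) * np.inf)

    betas, zmaps = [], []
    for i, col in enumerate(design.columns):
        betas.append(StatMap(beta[i], "beta", run.mask, f"beta: {col.label}"))
        zmaps.append(StatMap(_t_to_z(tvals[i], dof), "z", run.mask, f"z: {col.label}"))
    return GLMResult(
        betas=betas,
        zmaps=zmaps,
        residual_variance=StatMap(sigma2, "raw", run.mask, "residual variance"),
        dof=dof,
        design=design,
    )


def threshold_map(map_: StatMap, method: str = "fixed_z", alpha_or_z: float = 3.1) -> BinaryMap:
    """One-tailed thresholding of a z map.

    ``fixed_z`` keeps values > alpha_or_z; ``bonferroni`` keeps values above
    the normal quantile of 1 - alpha/v; ``fdr`` applies the Benjamini–
    Hochberg step-up procedure to the one-tailed p values.
    """
    if map_.statistic != "z":
        raise ValueError("threshold_map expects a z-scale map")
    v = map_.mask.v
    if method == "fixed_z":
        cut = float(alpha_or_z)
        include = map_.values > cut
    elif method == "bonferroni":
        alpha = float(alpha_or_z)
        if not (0 < alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        cut = float(stats.norm.isf(alpha / v))
        include = map_.values > cut
    elif method == "fdr":
        alpha = float(alpha_or_z)
        if not (0 < alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        from statsmodels.stats.multitest import multipletests

        pvals = stats.norm.sf(map_.values)
        include, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        kept = map_.values[include]
        cut = float(kept.min()) if kept.size else float("inf")
    else:
        raise ValueError(f"unknown thresholding method {method!r}")
    return BinaryMap(include, map_.mask, threshold_used=cut)


def seed_fc(
    run: FMRIRun,
    seed: SeedSpec,
    nuisance: list[TimeCourse] | None = None,
    prewhiten: bool = False,
) -> StatMap:
    """Seed-based FC z map: derive the seed course(s), then regress the run.

    SV/FV/MV average the seed voxels' series; DRS regresses the run on the
    single seed map; DRA regresses on the full map set and returns the z map
    of the interest course (the rest enter the design as nuisance).
    """
    nuisance = list(nuisance or [])
    if seed.method in ROI_METHODS:
        course = roi_timecourse(run, seed)
        if course.degenerate:
            raise ValueError("seed time course is degenerate (series cancel)")
        columns = [course] + [
            TimeCourse(n.values, n.label, role="nuisance") for n in nuisance
        ]
    elif seed.method == "DRS":
        columns = dual_regression_stage1(run, seed.source_map) + [
            TimeCourse(n.values, n.label, role="nuisance") for n in nuisance
        ]
    elif seed.method == "DRA":
        maps = [
            StatMap(seed.source_set.zmaps[k], "z", seed.source_set.mask, f"IC{k + 1}")
            for k in range(seed.source_set.n_components)
        ]
        columns = dual_regression_stage1(
            run, maps, interest_index=seed.interest_index
        ) + [TimeCourse(n.values, n.label, role="nuisance") for n in nuisance]
    else:  # pragma: no cover - SeedSpec validates the method
        raise ValueError(f"unknown seed method {seed.method!r}")
    result = glm_fit(run, DesignMatrix(columns), prewhiten=prewhiten)
    return result.interest_zmap()
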