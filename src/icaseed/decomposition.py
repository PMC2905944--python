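"""Spatial PCA/ICA decomposition of fMRI runs.

The linear model here is ``X = M C + E``: the ``t x v`` data matrix is
split by PCA into a rank-N part (structured signal) and a residual ``E``
of predominately Gaussian noise, and the rank-N part is decomposed into
``N`` time courses (columns of ``M``) paired with spatially independent
maps (rows of ``C``) by a symmetric fixed-point ICA iteration optimising
spatial non-Gaussianity (logcosh contrast).

Group decomposition concatenates normalized runs in time, and per-subject
component sets are recovered by back-reconstruction: the subject's block
of the group mixing matrix provides the time courses, and a least-squares
fit of the subject's data on those time courses provides the maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import BrainMask, FMRIRun, StatMap, concat_group, subject_row_ranges

__all__ = [
    "WhitenedData",
    "ComponentSet",
    "GroupModel",
    "pca_reduce",
    "estimate_dim",
    "fastica_spatial",
    "rank_by_variance",
    "group_ica",
    "back_reconstruct",
    "match_component",
]


@dataclass
class WhitenedData:
    """PCA-whitened spatial scores with the projection matrices.

    ``scores`` is N x v with identity row covariance (over voxels);
    ``dewhitening @ scores`` reproduces the rank-N approximation of the
    (demeaned) data.  ``residual_variance_fraction`` is the discarded
    eigenvalue share — the aggregate size of the noise term E.
    """

    scores: np.ndarray  # (N, v)
    whitening: np.ndarray  # (N, t)
    dewhitening: np.ndarray  # (t, N)
    explained_variance: np.ndarray  # per-component eigenvalue share
    residual_variance_fraction: float
    mask: BrainMask

    @property
    def n_components(self) -> int:
        return self.scores.shape[0]


@dataclass
class ComponentSet:
    """Paired time courses (t x N) and spatial maps (N x v) from ICA."""

    timecourses: np.ndarray  # M, (t, N)
    maps: np.ndarray  # C, (N, v)
    zmaps: np.ndarray  # (N, v), each row mean 0 / variance 1
    variance_fraction: np.ndarray  # per-component share of data variance
    mask: BrainMask
    seed_used: int = 0
    converged: bool = True
    n_iter: int = 0

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    def zmap(self, k: int, label: str = "") -> StatMap:
        return StatMap(self.zmaps[k], "z", self.mask, label or f"IC{k + 1} z-map")


@dataclass
class GroupModel:
    """Group component set over temporally concatenated subjects."""

    group_components: ComponentSet
    subject_ranges: list[tuple[int, int]]
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = self.group_components.timecourses.shape[0]
        covered = sorted(self.subject_ranges)
        if covered[0][0] != 0 or covered[-1][1] != t or any(
            covered[i][1] != covered[i + 1][0] for i in range(len(covered) - 1)
        ):
            raise ValueError("subject_ranges must partition the concatenated time axis")
        if not self.subject_ids:
            self.subject_ids = [f"subject{i + 1}" for i in range(len(self.subject_ranges))]


# ---------------------------------------------------------------------------
# PCA


def pca_reduce(run: FMRIRun, n_components: int) -> WhitenedData:
    """Whiten and project the run into an N-dimensional temporal subspace.

    Eigen-decomposition of the t x t temporal covariance (over voxels);
    deterministic up to component sign (signs fixed so each dewhitening
    column's largest-magnitude entry is positive).
    """
    t, v = run.data.shape
    if not (1 <= n_components <= min(t - 1, v)):
        raise ValueError(
            f"n_components must be in [1, {min(t - 1, v)}], got {n_components}"
        )
    X = run.data - run.data.mean(axis=0, keepdims=True)
    cov = (X @ X.T) / v
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    total = evals.sum()
    if total <= 0:
        raise ValueError("data has zero variance")
    if evals[n_components - 1] <= 1e-12 * evals[0]:
        raise ValueError(
            f"data rank is below n_components={n_components}; reduce the order"
        )
    lam = evals[:n_components]
    U = evecs[:, :n_components]
    # sign convention for determinism
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    U = U * flip
    whitening = (U / np.sqrt(lam)).T  # (N, t)
    dewhitening = U * np.sqrt(lam)  # (t, N)
    scores = whitening @ X
    return WhitenedData(
        scores=scores,
        whitening=whitening,
        dewhitening=dewhitening,
        explained_variance=lam / total,
        residual_variance_fraction=float(evals[n_components:].sum() / total),
        mask=run.mask,
    )


# ---------------------------------------------------------------------------
# Model-order selection


def _order_loglik(evals: np.ndarray, k: int, n: int) -> float:
    """Wax–Kailath log-likelihood term for order k (sphericity of the tail)."""
    tail = evals[k:]
    p_minus_k = len(tail)
    g = np.exp(np.mean(np.log(np.maximum(tail, 1e-300))))
    a = np.mean(tail)
    return float(n * p_minus_k * np.log(g / a))


def estimate_dim(run: FMRIRun, method: str = "BIC") -> int:
    """Estimate ICA model order from the eigen-spectrum.

    Information criteria over candidate orders k = 1..t-1, computed from the
    eigenvalues of the temporal covariance of the (voxelwise-normalized)
    data, with v voxels as the observations.  AIC and MDL use the classic
    signal-array parameter count k(2t-k)+1; BIC uses the probabilistic-PCA
    parameter count with a full ln(n) penalty, so BIC <= MDL-selected orders
    on noisy data.  Ties break toward the smaller order.
    """
    method = method.upper()
    if method not in ("AIC", "BIC", "MDL"):
        raise ValueError(f"unknown method {method!r}; expected AIC, BIC or MDL")
    t, v = run.data.shape
    if t < 3:
        raise ValueError("need at least 3 volumes to estimate dimensionality")
    X = run.data - run.data.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, ddof=1, keepdims=True)
    X = np.where(sd > 0, X / np.where(sd > 0, sd, 1.0), 0.0)
    evals = np.linalg.eigvalsh((X @ X.T) / v)[::-1]
    # temporal demeaning removes one degree of freedom; the resulting
    # ~zero eigenvalue would swamp the tail geometric mean, so drop it
    evals = np.maximum(evals[: t - 1], 1e-300)
    n = v
    p = t - 1
    best_k, best_score = 1, np.inf
    for k in range(1, p):
        ll = _order_loglik(evals, k, n)
        if method == "AIC":
            m = k * (2 * p - k) + 1
            score = -2.0 * ll + 2.0 * m
        elif method == "MDL":
            m = k * (2 * p - k) + 1
            score = -ll + 0.5 * m * np.log(n)
        else:  # BIC, PPCA parameter count
            m = p * k - k * (k - 1) / 2.0 + k + 1
            score = -2.0 * ll + m * np.log(n)
        if score < best_score - 1e-9:
            best_score, best_k = score, k
    return best_k


# ---------------------------------------------------------------------------
# FastICA (symmetric fixed point, logcosh contrast)


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    s, u = np.linalg.eigh(W @ W.T)
    s = np.maximum(s, 1e-15)
    return (u / np.sqrt(s)) @ u.T @ W


def _fastica_once(
    Z: np.ndarray, epsilon: float, max_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool, int, float]:
    n, v = Z.shape
    W = _sym_decorrelate(rng.standard_normal((n, n)))
    delta = np.inf
    for it in range(1, max_iter + 1):
        U = W @ Z
        G = np.tanh(U)
        Gp = 1.0 - G**2
        W_new = (G @ Z.T) / v - (Gp.mean(axis=1)[:, None]) * W
        W_new = _sym_decorrelate(W_new)
        # convergence: rows aligned with previous iterate up to sign
        delta = float(np.max(np.abs(np.abs(np.sum(W_new * W, axis=1)) - 1.0)))
        W = W_new
        if delta < epsilon:
            return W, True, it, delta
    return W, False, max_iter, delta


def fastica_spatial(
    white: WhitenedData,
    epsilon: float = 1e-8,
    max_iter: int = 500,
    rng_seed: int = 0,
    n_restarts: int = 3,
) -> ComponentSet:
    """Fixed-point spatial ICA on whitened scores (symmetric estimation).

    All N components are estimated simultaneously with symmetric
    decorrelation and a logcosh contrast.  On non-convergence within
    ``max_iter`` iterations the estimation restarts (up to ``n_restarts``
    times) with seeds derived from ``rng_seed``; if no restart converges
    the tightest iterate is returned with ``converged=False``.
    Identical seed -> bit-identical output.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    Z = white.scores
    best = None
    for attempt in range(n_restarts + 1):
        rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), attempt]))
        W, ok, n_iter, delta = _fastica_once(Z, epsilon, max_iter, rng)
        if ok:
            best = (W, True, n_iter, delta)
            break
        if best is None or delta < best[3]:  # keep the tightest iterate
            best = (W, False, n_iter, delta)
    W, converged, n_iter, _ = best
    S = W @ Z  # (N, v) spatial sources, unit variance rows
    M = white.dewhitening @ W.T  # (t, N) time courses

    # deterministic sign: nonnegative skewness of each spatial map
    skew = np.mean((S - S.mean(axis=1, keepdims=True)) ** 3, axis=1)
    flip = np.where(skew < 0, -1.0, 1.0)
    S = S * flip[:, None]
    M = M * flip[None, :]

    cs = ComponentSet(
        timecourses=M,
        maps=S,
        zmaps=_zscore_rows(S),
        variance_fraction=_component_variance_fractions(M, S, white),
        mask=white.mask,
        seed_used=int(rng_seed),
        converged=converged,
        n_iter=n_iter,
    )
    return _sort_by_variance(cs)


def _zscore_rows(maps: np.ndarray) -> np.ndarray:
    mu = maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (maps - mu) / sd


def _component_variance_fractions(
    M: np.ndarray, S: np.ndarray, white: WhitenedData
) -> np.ndarray:
    # component k contributes M[:,k] outer S[k]; with decorrelated rows of S
    # its share of the retained variance is ||M_k||^2 var(S_k) / sum.
    contrib = np.sum(M**2, axis=0) * S.var(axis=1)
    retained = 1.0 - white.residual_variance_fraction
    total = contrib.sum()
    if total <= 0:
        return np.zeros(len(contrib))
    return contrib / total * retained


def _sort_by_variance(cs: ComponentSet) -> ComponentSet:
    order = np.argsort(-cs.variance_fraction, kind="stable")
    return ComponentSet(
        timecourses=cs.timecourses[:, order],
        maps=cs.maps[order],
        zmaps=cs.zmaps[order],
        variance_fraction=cs.variance_fraction[order],
        mask=cs.mask,
        seed_used=cs.seed_used,
        converged=cs.converged,
        n_iter=cs.n_iter,
    )


def rank_by_variance(components: ComponentSet, run: FMRIRun | None = None) -> ComponentSet:
    """Reorder components so explained-variance fractions are nonincreasing.

    Ties keep the original order (stable sort).  ``run`` is accepted for
    interface symmetry; fractions are carried by the component set.
    """
    return _sort_by_variance(components)


# ---------------------------------------------------------------------------
# Group ICA and back-reconstruction


def group_ica(
    runs: list[FMRIRun],
    n_components: int,
    rng_seed: int = 0,
    epsilon: float = 1e-8,
    max_iter: int = 500,
) -> GroupModel:
    """Temporal-concatenation group ICA: concat -> PCA -> fixed-point ICA."""
    grp = concat_group(runs)
    white = pca_reduce(grp, n_components)
    comps = fastica_spatial(white, epsilon=epsilon, max_iter=max_iter, rng_seed=rng_seed)
    return GroupModel(
        group_components=comps,
        subject_ranges=subject_row_ranges(runs),
    )


def back_reconstruct(model: GroupModel, runs: list[FMRIRun], subject) -> ComponentSet:
    """Per-subject component set from a group model.

    The subject's time courses are their row-block of the group mixing
    matrix; the subject's maps are the least-squares fit of the subject's
    data against those time courses (single-stage simplification of the
    two-stage-PCA 'regular' method — identical on noise-free data).
    """
    if isinstance(subject, str):
        if subject not in model.subject_ids:
            raise KeyError(f"unknown subject {subject!r}")
        idx = model.subject_ids.index(subject)
    else:
        idx = int(subject)
        if not (0 <= idx < len(model.subject_ranges)):
            raise KeyError(f"subject index {idx} out of range")
    lo, hi = model.subject_ranges[idx]
    M_s = model.group_components.timecourses[lo:hi]  # (t_s, N)
    run = runs[idx]
    if run.t != hi - lo:
        raise ValueError("run length does not match the model's subject range")
    X_s = run.data - run.data.mean(axis=0, keepdims=True)
    C_s, *_ = np.linalg.lstsq(M_s, X_s, rcond=None)
    total = np.sum(X_s**2)
    contrib = np.sum(M_s**2, axis=0) * np.sum(C_s**2, axis=1) / max(total, 1e-300)
    return ComponentSet(
        timecourses=M_s,
        maps=C_s,
        zmaps=_zscore_rows(C_s),
        variance_fraction=contrib,
        mask=run.mask,
        seed_used=model.group_components.seed_used,
        converged=model.group_components.converged,
    )


# ---------------------------------------------------------------------------
# Component matching


def match_component(
    components: ComponentSet, reference: StatMap, weak_threshold: float = 0.2
) -> tuple[int, float, ComponentSet]:
    """Pick the component whose z-map best matches a reference map.

    Returns ``(index, r, components)`` where ``r`` is the Pearson
    correlation after sign alignment: if the best match is negative the
    component's map and time course are sign-flipped in the returned set.
    A best |r| below ``weak_threshold`` is flagged via a warning.
    """
    ref = reference.values
    if ref.std() == 0:
        raise ValueError("reference map is constant")
    refc = (ref - ref.mean()) / ref.std()
    Z = components.zmaps
    rs = (Z @ refc) / (Z.shape[1] * np.where(Z.std(axis=1) > 0, Z.std(axis=1), 1.0))
    best = int(np.argmax(np.abs(rs)))
    r = float(rs[best])
    out = components
    if r < 0:
        maps = components.maps.copy()
        zmaps = components.zmaps.copy()
        tcs = components.timecourses.copy()
        maps[best] *= -1
        zmaps[best] *= -1
        tcs[:, best] *= -1
        out = ComponentSet(
            timecourses=tcs,
            maps=maps,
            zmaps=zmaps,
            variance_fraction=components.variance_fraction,
            mask=components.mask,
            seed_used=components.seed_used,
            converged=components.converged,
            n_iter=components.n_iter,
        )
        r = -r
    if abs(r) < weak_threshold:
        import warnings

        warnings.warn(
            f"best component match is weak (|r| = {abs(r):.3f} < {weak_threshold})",
            stacklevel=2,
        )
    return best, r, out
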