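"""Evaluation statistics for FC maps against reference maps.

Four criteria are provided: masked Pearson correlation with Fisher-z
transform, threshold-adjusted overlap (the test map re-thresholded so its
suprathreshold count equals the reference's, making false positives equal
false negatives), partial area under the ROC curve up to a largest
acceptable false-positive rate (LFPR), and plain sensitivity/specificity
against a ground-truth mask.  A small driver assembles the per-method,
per-subject comparison table with Fisher-z-scale summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import BinaryMap, BrainMask, StatMap

__all__ = [
    "OverlapResult",
    "ROCResult",
    "spatial_correlation",
    "threshold_adjusted_overlap",
    "roc_pauc",
    "sens_spec",
    "fisher_summary",
    "summarize_comparison",
    "run_comparison",
]

_R_CLIP = 1.0 - 1e-12


@dataclass
class OverlapResult:
    percent_covered: float
    adjusted_threshold: float
    fp: int
    fn: int


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    pauc_raw: float
    pauc_adjusted: float
    lfpr: float


def spatial_correlation(a: StatMap, b: StatMap, mask: BrainMask | None = None) -> tuple[float, float]:
    """Pearson r over masked voxels, plus its Fisher z transform.

    |r| is clipped just below 1 before atanh so perfectly matching maps
    yield a large finite z rather than infinity.
    """
    if mask is None:
        mask = a.mask
    if len(a.values) != mask.v or len(b.values) != mask.v:
        raise ValueError("maps are not on the given mask")
    x, y = a.values, b.values
    if x.std() == 0 or y.std() == 0:
        raise ValueError("cannot correlate a constant map")
    r = float(np.corrcoef(x, y)[0, 1])
    z = float(np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP)))
    return r, z


def _top_k_mask(values: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of the k highest values; ties at the boundary are taken
    in ascending linear-index order until exactly k voxels are selected."""
    # lexsort: primary key descending value, secondary ascending index
    order = np.lexsort((np.arange(len(values)), -values))
    include = np.zeros(len(values), dtype=bool)
    include[order[:k]] = True
    return include


def threshold_adjusted_overlap(fc: StatMap, reference: BinaryMap) -> OverlapResult:
    """Coverage of the reference after matching suprathreshold counts.

    The FC map's threshold is set so its suprathreshold count equals the
    reference's count k (taking the k highest FC values), which makes the
    number of false positives equal the number of false negatives; the
    result is the percentage of reference voxels covered.
    """
    if len(fc.values) != len(reference.include):
        raise ValueError("fc map and reference are on different masks")
    k = reference.n_included
    v = len(reference.include)
    if k == 0 or k == v:
        raise ValueError("reference must be nonempty and not cover the whole mask")
    include = _top_k_mask(fc.values, k)
    inter = int(np.sum(include & reference.include))
    fp = int(np.sum(include & ~reference.include))
    fn = int(np.sum(~include & reference.include))
    adjusted_threshold = float(np.min(fc.values[include]))
    return OverlapResult(
        percent_covered=100.0 * inter / k,
        adjusted_threshold=adjusted_threshold,
        fp=fp,
        fn=fn,
    )


def roc_pauc(fc: StatMap, reference: BinaryMap, lfpr: float = 0.05) -> ROCResult:
    """Partial area under the ROC on [0, lfpr], scaled to a maximum of 1.

    The ROC sweeps a threshold over the FC values (ties grouped); the
    partial area uses trapezoidal integration with linear interpolation of
    the curve at fpr = lfpr.  ``pauc_adjusted = pauc_raw / lfpr``.
    """
    if not (0 < lfpr <= 1):
        raise ValueError("lfpr must be in (0, 1]")
    truth = reference.include
    if truth.all() or not truth.any():
        raise ValueError("reference needs at least one positive and one negative voxel")
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(truth.astype(int), fc.values)
    # restrict to [0, lfpr], interpolating the curve at the right edge
    tpr_at = float(np.interp(lfpr, fpr, tpr))
    keep = fpr < lfpr
    fx = np.append(fpr[keep], lfpr)
    fy = np.append(tpr[keep], tpr_at)
    pauc_raw = float(np.trapezoid(fy, fx))
    return ROCResult(
        fpr=fpr, tpr=tpr, pauc_raw=pauc_raw, pauc_adjusted=pauc_raw / lfpr, lfpr=lfpr
    )


def sens_spec(predicted: BinaryMap, truth: BinaryMap) -> tuple[float, float]:
    """Sensitivity and specificity (percent) of a thresholded map."""
    if len(predicted.include) != len(truth.include):
        raise ValueError("maps are on different masks")
    pos = truth.include
    if not pos.any():
        raise ValueError("truth mask is empty; sensitivity undefined")
    tp = np.sum(predicted.include & pos)
    tn = np.sum(~predicted.include & ~pos)
    sens = 100.0 * tp / pos.sum()
    neg = (~pos).sum()
    spec = 100.0 * tn / neg if neg else 100.0
    return float(sens), float(spec)


def fisher_summary(rs, confidence: float = 0.95) -> dict:
    """Mean and CI of correlations computed on the Fisher-z scale and
    back-transformed to r."""
    rs = np.asarray(rs, dtype=float)
    zs = np.arctanh(np.clip(rs, -_R_CLIP, _R_CLIP))
    mz = zs.mean()
    out = {"mean_r": float(np.tanh(mz)), "n": int(len(zs))}
    if len(zs) > 1:
        se = zs.std(ddof=1) / np.sqrt(len(zs))
        tq = stats.t.ppf(0.5 + confidence / 2, len(zs) - 1)
        out["ci_low"] = float(np.tanh(mz - tq * se))
        out["ci_high"] = float(np.tanh(mz + tq * se))
    else:
        out["ci_low"] = out["ci_high"] = out["mean_r"]
    return out


def summarize_comparison(rows: list[dict]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the per-method x per-subject criteria table.

    ``rows`` carry one dict per (method, subject) with keys ``method``,
    ``subject``, ``r_task`` (correlation with the task/truth reference),
    ``r_seed`` (correlation with the seed-source map), ``overlap_pct``
    and ``pauc_adjusted``.  Returns the long table and a per-method summary
    with means and 95% CIs computed on the Fisher-z scale for correlations.
    """
    table = pd.DataFrame(rows)
    summaries = []
    for method, grp in table.groupby("method", sort=False):
        row = {"method": method, "n_subjects": len(grp)}
        for col in ("r_task", "r_seed"):
            if col in grp:
                s = fisher_summary(grp[col].to_numpy())
                row[f"{col}_mean"] = s["mean_r"]
                row[f"{col}_ci_low"] = s["ci_low"]
                row[f"{col}_ci_high"] = s["ci_high"]
        for col in ("overlap_pct", "pauc_adjusted"):
            if col in grp:
                row[f"{col}_mean"] = float(grp[col].mean())
        summaries.append(row)
    return table, pd.DataFrame(summaries)


def run_comparison(
    runs,
    references: list[StatMap],
    methods: list[str],
    seed_source,
    interest_index: int,
    group_model=None,
    reference_threshold: float = 3.1,
    lfpr: float = 0.05,
    target_count: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate seed-FC methods per subject against reference maps.

    For every requested method and every run, a per-subject FC z map is
    derived (seeded from ``seed_source``'s component of interest) and
    scored by: spatial correlation with the subject's reference map and
    with the seed-source map, threshold-adjusted overlap against the
    reference thresholded at ``reference_threshold``, and adjusted ROC
    PAUC at ``lfpr``.  Method ``BR`` requires ``group_model`` (group ICA
    back-reconstruction) and uses the reconstructed interest map directly.

    Returns the long per-(method, subject) table and the per-method
    summary with Fisher-z-scale means and 95% CIs.
    """
    from .decomposition import back_reconstruct
    from .glm import seed_fc
    from .seeding import SeedSpec, few_voxel_seed, many_voxel_seed, peak_voxel

    if len(references) != len(runs):
        raise ValueError("need one reference map per run")
    interest_map = seed_source.zmap(interest_index, "group IC of interest")
    seeds: dict[str, SeedSpec] = {}
    for method in methods:
        if method == "SV":
            seeds[method] = peak_voxel(interest_map)
        elif method == "FV":
            seeds[method] = few_voxel_seed(interest_map)
        elif method == "MV":
            seeds[method] = many_voxel_seed(interest_map, target_count)
        elif method == "DRS":
            seeds[method] = SeedSpec(method="DRS", source_map=interest_map)
        elif method == "DRA":
            seeds[method] = SeedSpec(
                method="DRA", source_set=seed_source, interest_index=interest_index
            )
        elif method == "BR":
            if group_model is None:
                raise ValueError("method BR requires a group model")
        else:
            raise ValueError(f"unknown method {method!r}")

    rows = []
    for method in methods:
        for si, (run, ref) in enumerate(zip(runs, references)):
            if method == "BR":
                subj = back_reconstruct(group_model, runs, si)
                fc = subj.zmap(interest_index, f"BR subject {si + 1}")
            else:
                fc = seed_fc(run, seeds[method])
            r_task, _ = spatial_correlation(fc, ref)
            r_seed, _ = spatial_correlation(fc, interest_map)
            ref_bin = BinaryMap(
                ref.values > reference_threshold, ref.mask, reference_threshold
            )
            row = {
                "method": method,
                "subject": si,
                "r_task": r_task,
                "r_seed": r_seed,
            }
            if 0 < ref_bin.n_included < ref.mask.v:
                row["overlap_pct"] = threshold_adjusted_overlap(fc, ref_bin).percent_covered
                row["pauc_adjusted"] = roc_pauc(fc, ref_bin, lfpr).pauc_adjusted
            rows.append(row)
    return summarize_comparison(rows)
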