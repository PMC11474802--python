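"""Spike-in-normalized label-free quantification statistics.

Site intensities are normalized by the XIC peak area of a spike-in
internal standard (the methoxyamine-conjugated aldehyde peptide leupeptin,
added after oxidation), which cancels sample-to-sample variation in
conjugation/elution efficiency and processing losses.  Testing follows the
Perseus-style convention: log2-transform the normalized values, then a
two-sample Student's t-test with Benjamini-Hochberg FDR (permutation FDR
optional), or a one-tailed Welch test for directional comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SiteQuantMatrix",
    "StatParams",
    "normalize_spikein",
    "log2_transform",
    "differential_test",
    "one_tailed_welch",
    "zscore_cluster",
]


@dataclass
class SiteQuantMatrix:
    """Sites x samples intensities with condition labels and spike-in areas.

    ``values`` is indexed by site id (any hashable row label) with one
    column per sample; missing observations are NaN.  ``samples`` carries
    one row per sample: columns ``condition``, ``replicate`` and
    ``spikein_area``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    log2: bool = False

    def __post_init__(self):
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples sheet lacks entries for {sorted(missing)}")
        for col in ("condition", "spikein_area"):
            if col not in self.samples.columns:
                raise ValueError(f"samples sheet lacks column {col!r}")

    def condition_columns(self, condition: str) -> list[str]:
        cols = [
            c
            for c in self.values.columns
            if self.samples.loc[c, "condition"] == condition
        ]
        if not cols:
            raise ValueError(f"no samples with condition {condition!r}")
        return cols


@dataclass(frozen=True)
class StatParams:
    """Thresholds and methods for the differential tests."""

    fdr_method: str = "BH"  # "BH" or "permutation"
    fdr_threshold: float = 0.05
    p_threshold: float = 0.05  # one-tailed Welch
    permutations: int = 250
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.fdr_threshold < 1 and 0 < self.p_threshold < 1):
            raise ValueError("thresholds must be in (0,1)")


def normalize_spikein(matrix: SiteQuantMatrix) -> SiteQuantMatrix:
    """Divide every sample column by that sample's spike-in peak area."""
    if matrix.log2:
        raise ValueError("normalize before log2 transformation")
    areas = matrix.samples.loc[list(matrix.values.columns), "spikein_area"]
    bad = areas[~(areas > 0)]
    if len(bad):
        raise ValueError(f"nonpositive spike-in area for sample(s) {list(bad.index)}")
    return replace(matrix, values=matrix.values.div(areas, axis=1))


def log2_transform(matrix: SiteQuantMatrix) -> SiteQuantMatrix:
    if matrix.log2:
        return matrix
    vals = matrix.values.where(matrix.values > 0)
    return replace(matrix, values=np.log2(vals), log2=True)


def _group_arrays(matrix: SiteQuantMatrix, cond_a: str, cond_b: str):
    a = matrix.values[matrix.condition_columns(cond_a)].to_numpy(float)
    b = matrix.values[matrix.condition_columns(cond_b)].to_numpy(float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each condition needs >= 2 replicates")
    return a, b


def _t_pvalues(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise equal-variance two-sample t on complete observations."""
    n = a.shape[0]
    p = np.full(n, np.nan)
    fc = np.full(n, np.nan)
    for i in range(n):
        x, y = a[i][~np.isnan(a[i])], b[i][~np.isnan(b[i])]
        if len(x) < 2 or len(y) < 2:
            continue
        fc[i] = y.mean() - x.mean()
        if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
            p[i] = 1.0  # identical constant groups: no evidence by convention
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p[i] = stats.ttest_ind(y, x, equal_var=True).pvalue
        if not np.isfinite(p[i]):
            p[i] = 1.0
    return fc, p


def differential_test(
    matrix: SiteQuantMatrix,
    condition_a: str,
    condition_b: str,
    params: StatParams = StatParams(),
) -> pd.DataFrame:
    """Per-site log2 fold change (b - a), p, q and significance flag.

    Expects log2-scale values (transforms a linear-scale matrix itself).
    Sites with fewer than two observed values in either group get NaN
    statistics and are never flagged significant.
    """
    matrix = log2_transform(matrix)
    a, b = _group_arrays(matrix, condition_a, condition_b)
    fc, p = _t_pvalues(a, b)
    ok = ~np.isnan(p)
    q = np.full(len(p), np.nan)
    if params.fdr_method == "BH":
        if ok.any():
            q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    elif params.fdr_method == "permutation":
        q[ok] = _permutation_fdr(matrix, condition_a, condition_b, p, ok, params)
    else:
        raise ValueError(f"unknown fdr_method {params.fdr_method!r}")
    out = pd.DataFrame(
        {
            "log2_fc": fc,
            "p": p,
            "q": q,
            "significant": (q <= params.fdr_threshold) & ok,
            "neg_log10_p": -np.log10(p),
        },
        index=matrix.values.index,
    )
    return out


def _permutation_fdr(matrix, cond_a, cond_b, p_obs, ok, params: StatParams):
    """FDR by condition-label shuffling: for each observed p, the average
    count of permuted p-values at or below it divided by the observed count."""
    rng = np.random.default_rng(params.seed)
    cols = matrix.condition_columns(cond_a) + matrix.condition_columns(cond_b)
    n_a = len(matrix.condition_columns(cond_a))
    vals = matrix.values[cols].to_numpy(float)
    perm_ps = []
    for _ in range(params.permutations):
        idx = rng.permutation(len(cols))
        _, pp = _t_pvalues(vals[:, idx[:n_a]], vals[:, idx[n_a:]])
        perm_ps.append(pp[~np.isnan(pp)])
    perm = np.sort(np.concatenate(perm_ps)) if perm_ps else np.array([])
    p_ok = p_obs[ok]
    obs_sorted = np.sort(p_ok)
    q_ok = np.empty(len(p_ok))
    for j, pv in enumerate(p_ok):
        n_perm_le = np.searchsorted(perm, pv, side="right")
        n_obs_le = np.searchsorted(obs_sorted, pv, side="right")
        expected_false = n_perm_le / max(params.permutations, 1)
        q_ok[j] = min(1.0, expected_false / max(n_obs_le, 1))
    # enforce monotonicity in p (cumulative minimum from the largest p down)
    order = np.argsort(p_ok)
    qq = np.minimum.accumulate(q_ok[order][::-1])[::-1]
    q_ok[order] = qq
    return q_ok


def one_tailed_welch(
    matrix: SiteQuantMatrix,
    condition_a: str,
    condition_b: str,
    direction: str = "greater",
) -> pd.DataFrame:
    """One-tailed Welch (unequal variance) t-test per site.

    ``direction='greater'`` tests condition_b > condition_a.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    matrix = log2_transform(matrix)
    a, b = _group_arrays(matrix, condition_a, condition_b)
    n = a.shape[0]
    p = np.full(n, np.nan)
    fc = np.full(n, np.nan)
    for i in range(n):
        x, y = a[i][~np.isnan(a[i])], b[i][~np.isnan(b[i])]
        if len(x) < 2 or len(y) < 2:
            continue
        fc[i] = y.mean() - x.mean()
        if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
            p[i] = 1.0
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.ttest_ind(y, x, equal_var=False, alternative=direction)
        p[i] = res.pvalue if np.isfinite(res.pvalue) else 1.0
    return pd.DataFrame(
        {"log2_fc": fc, "p": p}, index=matrix.values.index
    )


def zscore_cluster(
    values: pd.DataFrame,
) -> tuple[pd.DataFrame, np.ndarray, list]:
    """Row z-scores plus average-linkage hierarchical clustering.

    Missing values are imputed by the row minimum before clustering
    (display-only convention).  Constant rows get z-scores of zero with a
    warning.  Returns (z-scored frame in leaf order, linkage matrix,
    leaf row labels); leaf order is deterministic, ties broken by row id.
    """
    if len(values) < 2:
        raise ValueError("need >= 2 rows to cluster")
    filled = values.apply(lambda r: r.fillna(r.min()), axis=1)
    mat = filled.to_numpy(float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    const = (sd == 0).ravel()
    if const.any():
        warnings.warn(f"{const.sum()} constant row(s): z-scores set to 0",
                      stacklevel=2)
    sd[sd == 0] = 1.0
    z = (mat - mean) / sd
    link = hierarchy.linkage(pdist(z, metric="euclidean"), method="average")
    leaves = hierarchy.leaves_list(link)
    labels = [values.index[i] for i in leaves]
    zdf = pd.DataFrame(z, index=values.index, columns=values.columns).loc[labels]
    return zdf, link, labels
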