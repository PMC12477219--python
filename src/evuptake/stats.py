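"""Supporting statistics: PCA, differential abundance, overlaps, uptake.

Differential abundance follows the screening recipe used throughout the
analysis: per feature and per group, data points outside mean ± 1.5·IQR are
removed in a single pass, then a two-sided unpaired t-test (Welch by
default) is run on log10 abundances, and features with a raw-scale fold
change strictly greater than 2 (either direction) form the pathway-analysis
input list. The mean-based fence is kept literally as specified — note it is
*not* Tukey's median-based fence and can behave oddly on skewed groups (a
single extreme point inflates both the mean and the IQR, widening the fence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .containers import OmicsMatrix


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples × components
    loadings: pd.DataFrame          # features × components
    variance_fractions: np.ndarray  # sums to 1 over all components


def pca(matrix: OmicsMatrix, n_components: int | None = None) -> PCAResult:
    """SVD-based principal component analysis of an omics matrix.

    The input must be complete (no missing values — enforced by
    :class:`OmicsMatrix`); columns are centered (a no-op when the matrix is
    already mean-centered). ``variance_fractions`` covers *all* components
    and sums to 1, independent of how many score columns are returned.
    """
    arr = matrix.values.to_numpy(dtype=float)
    arr = arr - arr.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(arr, full_matrices=False)
    var = s ** 2
    fractions = var / var.sum()
    k = len(s) if n_components is None else min(n_components, len(s))
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(U[:, :k] * s[:k], index=matrix.values.index,
                          columns=comp_names)
    if matrix.design is not None:
        scores = scores.join(matrix.design[["cell_type", "oxygen"]])
    loadings = pd.DataFrame(Vt[:k].T, index=matrix.values.columns,
                            columns=comp_names)
    return PCAResult(scores=scores, loadings=loadings,
                     variance_fractions=fractions)


# ---------------------------------------------------------------------------
# outlier fence + differential abundance
# ---------------------------------------------------------------------------

def iqr_outlier_mask(values: np.ndarray) -> np.ndarray:
    """Boolean keep-mask for the mean ± 1.5·IQR fence, single pass.

    IQR uses the linear-interpolation quantile convention. Points exactly on
    a fence are kept (removal is strict). Requires at least two points.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("outlier fence requires a group of size >= 2")
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    lo = arr.mean() - 1.5 * iqr
    hi = arr.mean() + 1.5 * iqr
    return (arr >= lo) & (arr <= hi)


def iqr_outlier_removal(values: np.ndarray) -> np.ndarray:
    """Values surviving the mean ± 1.5·IQR fence (see
    :func:`iqr_outlier_mask`)."""
    arr = np.asarray(values, dtype=float)
    return arr[iqr_outlier_mask(arr)]


def differential_abundance(
    log_values: pd.DataFrame,
    group1: list,
    group2: list,
    fold_threshold: float = 2.0,
    equal_var: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Two-group differential abundance on log10 values.

    Parameters
    ----------
    log_values
        samples × features log10 abundance matrix (imputed, unscaled).
    group1, group2
        Non-overlapping sample-id lists; each needs ≥2 points left after
        per-group outlier removal or the feature is skipped with a reason.
    fold_threshold
        Raw-scale fold-change screen; ``passes_2fold`` is strict
        (> threshold or < 1/threshold).
    equal_var
        ``False`` (default) runs Welch's t-test; ``True`` the pooled-variance
        Student test.
    fdr
        Add Benjamini–Hochberg adjusted p-values in ``p_adj``.

    Returns the volcano table: one row per feature with ``log10_fc``,
    ``fold_change``, ``t``, ``p``, ``n1``, ``n2``, ``passes_2fold``, ``note``.
    """
    overlap = set(group1) & set(group2)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("each group needs at least 2 samples")
    rows = []
    for feature in log_values.columns:
        a = log_values.loc[group1, feature].to_numpy(dtype=float)
        b = log_values.loc[group2, feature].to_numpy(dtype=float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        note = ""
        try:
            a = iqr_outlier_removal(a)
            b = iqr_outlier_removal(b)
        except ValueError:
            pass
        if len(a) < 2 or len(b) < 2:
            rows.append({"feature": feature, "log10_fc": np.nan,
                         "fold_change": np.nan, "t": np.nan, "p": np.nan,
                         "n1": len(a), "n2": len(b), "passes_2fold": False,
                         "note": "degenerate group after outlier removal"})
            continue
        log_fc = a.mean() - b.mean()
        fc = 10.0 ** log_fc
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            t_stat, p_val = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
            note = "zero within-group variance"
        else:
            t_stat, p_val = sps.ttest_ind(a, b, equal_var=equal_var)
        rows.append({
            "feature": feature, "log10_fc": log_fc, "fold_change": fc,
            "t": float(t_stat), "p": float(p_val),
            "n1": len(a), "n2": len(b),
            "passes_2fold": bool(fc > fold_threshold or fc < 1.0 / fold_threshold),
            "note": note,
        })
    result = pd.DataFrame(rows).set_index("feature")
    if fdr:
        ok = result["p"].notna()
        adj = np.full(len(result), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(
                result.loc[ok, "p"], method="fdr_bh"
            )[1]
        result["p_adj"] = adj
    return result


def fold_change_gene_list(result: pd.DataFrame) -> list:
    """Features passing the fold-change screen (pathway-analysis input)."""
    return result.index[result["passes_2fold"]].tolist()


# ---------------------------------------------------------------------------
# presence overlap (Venn regions)
# ---------------------------------------------------------------------------

def presence_overlap(sets: dict) -> dict:
    """Counts for every exclusive region of the multi-set partition.

    ``sets`` maps a group name (e.g. parent cell type) to its detected
    feature set. Returns ``{(member, ...): count}`` keyed by the sorted
    tuple of groups a feature belongs to; counts sum to the union size.
    """
    names = sorted(sets)
    union = set().union(*sets.values()) if sets else set()
    regions: dict[tuple, int] = {}
    for item in union:
        members = tuple(n for n in names if item in sets[n])
        regions[members] = regions.get(members, 0) + 1
    return regions


def detected_feature_sets(values: pd.DataFrame,
                          groups: pd.Series) -> dict:
    """Detected-feature set per group (present pre-imputation in ≥1 sample).

    ``values`` is features × samples with NaN for missing; ``groups`` maps
    sample id → group label.
    """
    out = {}
    for label in groups.unique():
        cols = groups.index[groups == label]
        present = values[cols].notna().any(axis=1)
        out[label] = set(values.index[present])
    return out


# ---------------------------------------------------------------------------
# uptake normalization and correlation
# ---------------------------------------------------------------------------

def normalize_uptake(raw: pd.DataFrame, control: pd.Series) -> pd.DataFrame:
    """Divide raw fluorescence by the matched uninhibited control.

    ``control`` is indexed like the rows of ``raw``. Values above 1 are
    legitimate (uptake can exceed the uninhibited control). Non-positive
    controls are an error.
    """
    ctrl = control.loc[raw.index]
    bad = ctrl.index[~(ctrl > 0)]
    if len(bad) > 0:
        raise ValueError(
            f"non-positive uninhibited control for: {list(bad)[:5]}"
        )
    return raw.div(ctrl, axis=0)


def condition_correlation(a, b) -> float:
    """Pearson product-moment correlation between paired uptake vectors."""
    av = np.asarray(a, dtype=float).ravel()
    bv = np.asarray(b, dtype=float).ravel()
    if av.shape != bv.shape:
        raise ValueError("paired vectors must have equal length")
    if av.size < 3:
        raise ValueError("correlation requires n >= 3")
    return float(sps.pearsonr(av, bv)[0])


# ---------------------------------------------------------------------------
# hierarchical sample grouping (heatmap dendrogram cut)
# ---------------------------------------------------------------------------

def cluster_samples(matrix: OmicsMatrix, n_clusters: int = 4) -> pd.Series:
    """Ward hierarchical clustering of the scaled sample rows, cut into
    ``n_clusters`` groups; the rendering itself is out of scope."""
    Z = linkage(matrix.values.to_numpy(dtype=float), method="ward")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=matrix.values.index, name="cluster")
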