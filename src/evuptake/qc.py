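"""Lipidomics feature-level quality control.

Four stages, in acquisition-pipeline order:

1. :func:`background_filter` — drop features whose strongest biological
   signal is below ``factor`` × the mean blank signal (default 5×).
2. :func:`qc_presence_cv_filter` — keep features present in at least half of
   the pooled-QC injections with a raw-scale CV strictly below 30%.
3. :func:`drift_correct` — remove the monotone intensity drift along the
   injection sequence, estimated per feature from the pooled-QC injections.
4. :func:`resolve_duplicates_and_isomers` — collapse duplicate lipid
   annotations (Δ retention time ≤ 0.3 min: keep the lowest-QC-CV peak) and
   sum true isomer peaks (Δ > 0.3 min) into one feature per annotation.

:func:`run_lipid_qc` chains them and produces a :class:`QC report
<build_qc_report>` accounting for every input feature exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import ROLE_BLANK, ROLE_QC, FeatureTable

DROPPED_BY = ("background", "qc", "duplicate", "none")


# ---------------------------------------------------------------------------
# per-feature statistics
# ---------------------------------------------------------------------------

def blank_ratio(table: FeatureTable) -> pd.Series:
    """Max biological abundance over mean blank abundance, per feature.

    Missing blank values count as zero background. Features never observed
    in any biological sample get ratio 0; a zero blank mean with signal
    present gives ``inf``.
    """
    blanks = table.blank_ids
    if not blanks:
        raise ValueError("background filtering requires samples with role "
                         f"'{ROLE_BLANK}'; none found")
    blank_mean = table.values[blanks].fillna(0.0).mean(axis=1)
    bio_max = table.values[table.biological_ids].max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = bio_max.fillna(0.0) / blank_mean
    ratio[(blank_mean == 0) & (bio_max.fillna(0.0) > 0)] = np.inf
    ratio[(blank_mean == 0) & (bio_max.fillna(0.0) == 0)] = 0.0
    return ratio


def qc_stats(table: FeatureTable) -> pd.DataFrame:
    """Presence fraction and raw-scale CV over the pooled-QC injections.

    CV = sd/mean (n−1 convention) over the *present* QC values; features
    with fewer than two present QC values get CV ``NaN``.
    """
    qcs = table.qc_ids
    if not qcs:
        raise ValueError(f"no samples with role '{ROLE_QC}' in the table")
    qc_vals = table.values[qcs]
    presence = qc_vals.notna().mean(axis=1)
    mean = qc_vals.mean(axis=1)
    sd = qc_vals.std(axis=1, ddof=1)
    cv = sd / mean
    cv[qc_vals.notna().sum(axis=1) < 2] = np.nan
    return pd.DataFrame({"qc_presence": presence, "qc_cv": cv})


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def background_filter(table: FeatureTable, factor: float = 5.0) -> FeatureTable:
    """Drop features with max biological signal strictly below factor × blank.

    A feature survives when its maximum biological abundance is at least
    ``factor`` times the mean blank abundance (strict "lower than" removal,
    so a feature at exactly the threshold is kept).
    """
    ratio = blank_ratio(table)
    keep = table.feature_ids[~(ratio < factor)]
    return table.subset_features(keep)


def qc_presence_cv_filter(
    table: FeatureTable, min_presence: float = 0.5, max_cv: float = 0.30
) -> FeatureTable:
    """Keep features present in ≥ ``min_presence`` of QC injections with
    CV strictly below ``max_cv``."""
    if len(table.qc_ids) < 2:
        raise ValueError(
            "QC presence/CV filtering requires at least 2 pooled-QC "
            f"injections; found {len(table.qc_ids)}"
        )
    stats = qc_stats(table)
    keep_mask = (stats["qc_presence"] >= min_presence) & (
        stats["qc_cv"] < max_cv
    )
    return table.subset_features(table.feature_ids[keep_mask.fillna(False)])


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------

def _qc_trend(x_qc: np.ndarray, y_log: np.ndarray,
              x_eval: np.ndarray) -> np.ndarray:
    """Fit a trend to log10 QC abundance vs injection order.

    Locally weighted linear regression when ≥4 QC points are available,
    otherwise a robust (Theil–Sen) straight line. Evaluation outside the QC
    injection range is clamped to the nearest fitted value.
    """
    if len(x_qc) >= 4:
        # ~3-point local windows: tight enough to track curvature (a drift
        # linear on the raw scale is curved in log), wide enough to smooth
        frac = min(1.0, max(0.5, 3.0 / len(x_qc)))
        fitted = lowess(y_log, x_qc, frac=frac, it=1, return_sorted=True)
        return np.interp(x_eval, fitted[:, 0], fitted[:, 1])
    slope, intercept, _, _ = sps.theilslopes(y_log, x_qc)
    trend = intercept + slope * x_eval
    lo, hi = x_qc.min(), x_qc.max()
    trend[x_eval < lo] = intercept + slope * lo
    trend[x_eval > hi] = intercept + slope * hi
    return trend


def drift_correct(table: FeatureTable) -> FeatureTable:
    """Remove per-feature intensity drift using the pooled-QC injections.

    For each feature, a trend is fit to QC abundance vs injection order and
    every sample's abundance is divided by trend(injection)/median(QC).
    Features with fewer than two present QC values are left uncorrected and
    flagged in ``meta['drift_corrected']``. Missing values stay missing.
    """
    out = table.copy()
    qcs = table.qc_ids
    if not qcs:
        raise ValueError(f"drift correction requires samples with role "
                         f"'{ROLE_QC}'; none found")
    inj_all = table.injection_order.to_numpy(dtype=float)
    inj_qc = table.injection_order[qcs].to_numpy(dtype=float)
    corrected = np.zeros(table.n_features, dtype=bool)
    vals = out.values.to_numpy(dtype=float)
    qc_cols = [table.values.columns.get_loc(q) for q in qcs]
    for i in range(table.n_features):
        y = vals[i, qc_cols]
        present = ~np.isnan(y)
        if present.sum() < 2:
            continue
        y_log = np.log10(y[present])
        trend_log = _qc_trend(inj_qc[present], y_log, inj_all)
        ref = np.median(y[present])
        factor = (10.0 ** trend_log) / ref
        vals[i, :] = vals[i, :] / factor
        corrected[i] = True
    out.values.iloc[:, :] = vals
    out.meta["drift_corrected"] = corrected
    return out


# ---------------------------------------------------------------------------
# duplicate / isomer resolution
# ---------------------------------------------------------------------------

def resolve_duplicates_and_isomers(
    table: FeatureTable, rt_gap: float = 0.3
) -> FeatureTable:
    """Produce one feature per lipid annotation.

    Within an identical annotation, peaks are clustered by retention time
    (single linkage; consecutive peaks ≤ ``rt_gap`` apart join a cluster).
    Each cluster is an over-segmented duplicate: the peak with the lowest
    QC CV represents it. Distinct clusters (Δ > ``rt_gap``) are genuine
    isomers and are summed sample-wise (missing + value = value, all-missing
    stays missing). The surviving feature keeps the lexicographically
    smallest member id, so original ids remain stable.
    """
    if table.kind != "lipid":
        raise ValueError("duplicate/isomer resolution applies to lipid tables")
    if ("retention_time" not in table.meta.columns
            or table.meta["retention_time"].isna().all()):
        raise ValueError("lipid table has no retention times")

    if len(table.qc_ids) >= 2:
        cv = qc_stats(table)["qc_cv"]
    else:  # no QC columns left: fall back to highest mean biological signal
        cv = pd.Series(np.nan, index=table.feature_ids)
    bio_mean = table.values[table.biological_ids].mean(axis=1)

    annot = table.meta["annotation"].astype(object)
    annot = annot.where(annot.notna() & (annot != ""), table.feature_ids)

    keep_rows, merged_values, merged_meta = [], [], []
    for name, group in table.meta.groupby(annot, sort=False):
        ids = list(group.index)
        if len(ids) == 1:
            keep_rows.append(ids[0])
            continue
        order = group["retention_time"].sort_values().index
        rts = group.loc[order, "retention_time"].to_numpy()
        clusters: list[list] = [[order[0]]]
        for k in range(1, len(order)):
            if rts[k] - rts[k - 1] <= rt_gap:
                clusters[-1].append(order[k])
            else:
                clusters.append([order[k]])
        reps = []
        for cluster in clusters:
            if len(cluster) == 1:
                reps.append(cluster[0])
            else:
                ranked = sorted(
                    cluster,
                    key=lambda f: (
                        cv[f] if np.isfinite(cv[f]) else np.inf,
                        -bio_mean[f] if np.isfinite(bio_mean[f]) else 0.0,
                        f,
                    ),
                )
                reps.append(ranked[0])
        if len(reps) == 1:
            keep_rows.append(reps[0])
            continue
        # isomers at distinct retention times: sum sample-wise
        summed = table.values.loc[reps].sum(axis=0, min_count=1)
        new_id = min(str(r) for r in reps)
        merged_values.append(summed.rename(new_id))
        row = table.meta.loc[reps[0]].copy()
        row["retention_time"] = float(
            table.meta.loc[reps, "retention_time"].mean()
        )
        if "msi_level" in table.meta.columns:
            row["msi_level"] = table.meta.loc[reps, "msi_level"].min()
        merged_meta.append(row.rename(new_id))

    values = table.values.loc[keep_rows]
    meta = table.meta.loc[keep_rows]
    if merged_values:
        values = pd.concat([values, pd.DataFrame(merged_values)])
        meta = pd.concat([meta, pd.DataFrame(merged_meta)])
    values.index.name = "feature_id"
    return FeatureTable(values=values, meta=meta, samples=table.samples.copy(),
                        kind="lipid")


# ---------------------------------------------------------------------------
# orchestration + report
# ---------------------------------------------------------------------------

@dataclass
class QCResult:
    table: FeatureTable
    report: pd.DataFrame
    counts: dict


def run_lipid_qc(
    table: FeatureTable,
    factor: float = 5.0,
    min_presence: float = 0.5,
    max_cv: float = 0.30,
    rt_gap: float = 0.3,
) -> QCResult:
    """Run the full lipid QC chain and build the per-feature report.

    The report records, for every input feature, its blank ratio, QC
    presence, QC CV and which stage (if any) removed it:
    ``background`` / ``qc`` / ``duplicate`` / ``none``.
    """
    report = pd.DataFrame(index=table.feature_ids.copy())
    report["blank_ratio"] = blank_ratio(table)
    stats = qc_stats(table)
    report["qc_presence"] = stats["qc_presence"]
    report["qc_cv"] = stats["qc_cv"]
    report["dropped_by"] = "none"

    after_bg = background_filter(table, factor=factor)
    report.loc[~report.index.isin(after_bg.feature_ids), "dropped_by"] = (
        "background"
    )
    after_qc = qc_presence_cv_filter(after_bg, min_presence=min_presence,
                                     max_cv=max_cv)
    dropped_qc = set(after_bg.feature_ids) - set(after_qc.feature_ids)
    report.loc[report.index.isin(dropped_qc), "dropped_by"] = "qc"

    corrected = drift_correct(after_qc)
    resolved = resolve_duplicates_and_isomers(corrected, rt_gap=rt_gap)
    dropped_dup = set(corrected.feature_ids) - set(resolved.feature_ids)
    report.loc[report.index.isin(dropped_dup), "dropped_by"] = "duplicate"

    counts = {
        "input": int(table.n_features),
        "dropped_background": int((report["dropped_by"] == "background").sum()),
        "dropped_qc": int((report["dropped_by"] == "qc").sum()),
        "dropped_duplicate": int((report["dropped_by"] == "duplicate").sum()),
        "output": int(resolved.n_features),
    }
    return QCResult(table=resolved, report=report, counts=counts)
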