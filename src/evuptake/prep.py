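"""Matrix preparation: filters, imputation, log10 transform, autoscaling.

Fixed stage order for each omics table (biological samples only):

    (filter_psm, proteins only) → filter_missing → impute_fifth_minimum
    → log10_and_scale → combine

Missing-value imputation is left-censoring aware: each missing cell is
replaced by one fifth of the smallest observed abundance *in that sample
column*, which keeps imputed values strictly below everything observed in
the sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import FeatureTable, OmicsMatrix


def filter_missing(table: FeatureTable, max_missing: int = 12) -> FeatureTable:
    """Drop features missing in strictly more than ``max_missing`` biological
    samples (a feature missing in exactly ``max_missing`` is kept)."""
    bio = table.biological_ids
    n_missing = table.values[bio].isna().sum(axis=1)
    return table.subset_features(table.feature_ids[n_missing <= max_missing])


def filter_psm(table: FeatureTable, min_psm: int = 2) -> FeatureTable:
    """Keep proteins with at least ``min_psm`` PSM in at least one sample."""
    if table.psm is None:
        raise ValueError("PSM filtering requires a protein table with PSM "
                         "counts; none present")
    keep = table.psm.max(axis=1) >= min_psm
    return table.subset_features(table.feature_ids[keep])


def impute_fifth_minimum(table: FeatureTable, divisor: float = 5.0) -> FeatureTable:
    """Replace each missing cell by (sample-column minimum) / ``divisor``."""
    out = table.copy()
    vals = out.values
    mins = vals.min(axis=0, skipna=True)
    empty = mins.index[mins.isna()]
    if len(empty) > 0:
        raise ValueError(
            "cannot impute: sample(s) with no observed values: "
            f"{list(empty)}"
        )
    fill = mins / divisor
    out.values = vals.fillna(fill)
    return out


def log10_and_scale(
    table: FeatureTable,
    center: bool = True,
    unit_variance: bool = True,
    design: pd.DataFrame | None = None,
) -> OmicsMatrix:
    """log10-transform, then per-feature mean-center and unit-variance scale.

    Returns a samples × features :class:`OmicsMatrix`; the per-feature mean
    and standard deviation (n−1 convention) actually applied are stored so
    held-out data can be pushed through the identical transform. Disabled
    steps store zeros / ones.

    Raises on non-positive abundances and on zero-variance features (listed
    by id), so feature counts stay auditable rather than silently shrinking.
    """
    vals = table.values
    arr = vals.to_numpy(dtype=float)
    if np.isnan(arr).any():
        bad = vals.index[vals.isna().any(axis=1)][:5].tolist()
        raise ValueError(f"missing values remain (e.g. {bad}); impute first")
    if (arr <= 0).any():
        i, j = np.argwhere(arr <= 0)[0]
        raise ValueError(
            "non-positive abundance at feature "
            f"{vals.index[i]!r}, sample {vals.columns[j]!r}"
        )
    log_vals = np.log10(arr).T  # samples × features
    features = vals.index
    mean = log_vals.mean(axis=0)
    sd = log_vals.std(axis=0, ddof=1)
    if unit_variance:
        zero_var = features[sd == 0].tolist()
        if zero_var:
            raise ValueError(f"zero-variance features: {zero_var}")
    center_vec = mean if center else np.zeros_like(mean)
    scale_vec = sd if unit_variance else np.ones_like(sd)
    scaled = (log_vals - center_vec) / scale_vec
    values = pd.DataFrame(scaled, index=vals.columns.copy(), columns=features)
    return OmicsMatrix(
        values=values,
        feature_kind=pd.Series(table.kind, index=features),
        center=pd.Series(center_vec, index=features),
        scale=pd.Series(scale_vec, index=features),
        design=None if design is None else design.loc[values.index],
    )


def combine(lipids: OmicsMatrix, proteins: OmicsMatrix) -> OmicsMatrix:
    """Column-concatenate lipid and protein matrices over identical samples."""
    if list(lipids.values.index) != list(proteins.values.index):
        raise ValueError("sample sets/order differ between the matrices")
    overlap = lipids.values.columns.intersection(proteins.values.columns)
    if len(overlap) > 0:
        raise ValueError(f"feature ids appear in both matrices: "
                         f"{overlap[:5].tolist()}")
    return OmicsMatrix(
        values=pd.concat([lipids.values, proteins.values], axis=1),
        feature_kind=pd.concat([lipids.feature_kind, proteins.feature_kind]),
        center=pd.concat([lipids.center, proteins.center]),
        scale=pd.concat([lipids.scale, proteins.scale]),
        design=lipids.design if lipids.design is not None else proteins.design,
    )


def split_by_kind(matrix: OmicsMatrix) -> dict[str, OmicsMatrix]:
    """Inverse of :func:`combine`: one matrix per feature kind."""
    out = {}
    for kind in matrix.feature_kind.unique():
        cols = matrix.feature_kind.index[matrix.feature_kind == kind]
        out[kind] = OmicsMatrix(
            values=matrix.values[cols].copy(),
            feature_kind=matrix.feature_kind[cols].copy(),
            center=matrix.center[cols].copy(),
            scale=matrix.scale[cols].copy(),
            design=matrix.design,
        )
    return out
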