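"""Shared in-memory containers for the sEV omics→uptake pipeline.

The pipeline moves data through three core structures:

* :class:`FeatureTable` — an LC-MS (lipid) or label-free proteomics (protein)
  feature-by-sample abundance table with per-feature metadata and per-sample
  acquisition roles (biological / blank / pooled QC) and injection order.
* a *sample design* — a plain :class:`pandas.DataFrame` indexed by sample id
  with columns ``cell_type``, ``oxygen``, ``replicate`` (see
  :func:`validate_design`).
* :class:`OmicsMatrix` — the imputed, log10-transformed (optionally
  autoscaled) samples × features matrix handed to PCA and PLS, together with
  the centering/scaling vectors needed to transform held-out data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# Sample acquisition roles.
ROLE_BIOLOGICAL = "biological"
ROLE_BLANK = "blank"
ROLE_QC = "qc"
ROLES = frozenset({ROLE_BIOLOGICAL, ROLE_BLANK, ROLE_QC})

FEATURE_KINDS = ("lipid", "protein")

# Default study design labels: sEV parent cell types and oxygen conditioning.
CELL_TYPES = ("CPC", "MSC", "CEC", "CF")
OXYGEN_LEVELS = ("normoxic", "hypoxic")

# The six uptake outcomes, in fixed column order: three endocytosis pathways
# probed by small-molecule inhibition, crossed with two recipient cell types.
UPTAKE_COLUMNS = (
    "clathrin_CEC",
    "macropinocytosis_CEC",
    "caveolae_CEC",
    "clathrin_CF",
    "macropinocytosis_CF",
    "caveolae_CF",
)

DESIGN_COLUMNS = ("cell_type", "oxygen", "replicate")


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample design table (sample id → condition labels).

    Requires a unique index and the columns ``cell_type``, ``oxygen``,
    ``replicate``; returns the frame unchanged.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"sample design is missing columns: {missing}")
    if design.index.has_duplicates:
        dupes = design.index[design.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in design: {dupes}")
    return design


@dataclass
class FeatureTable:
    """Feature × sample abundance table with acquisition metadata.

    Parameters
    ----------
    values
        Abundances (non-negative, raw scale), features on the rows, samples
        on the columns. Missing measurements are ``NaN``.
    meta
        Per-feature metadata indexed like ``values``; for lipids carries
        ``annotation`` (lipid name), ``retention_time`` (minutes) and
        ``msi_level`` (Metabolomics Standards Initiative confidence, 1–4);
        for proteins ``annotation`` is the accession.
    samples
        Per-sample metadata indexed by the column labels of ``values`` with
        ``role`` ∈ {biological, blank, qc} and integer ``injection_order``.
    kind
        ``"lipid"`` or ``"protein"``.
    psm
        Peptide-spectrum-match counts (proteins only), same shape as
        ``values``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    samples: pd.DataFrame
    kind: str
    psm: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(
                f"kind must be one of {FEATURE_KINDS}, got {self.kind!r}"
            )
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()]
            raise ValueError(
                f"duplicate feature ids: {dupes.unique().tolist()}"
            )
        if not self.meta.index.equals(self.values.index):
            raise ValueError("meta index does not match feature ids")
        if not self.samples.index.equals(pd.Index(self.values.columns)):
            raise ValueError("samples index does not match value columns")
        bad_roles = set(self.samples["role"]) - ROLES
        if bad_roles:
            raise ValueError(f"unknown sample roles: {sorted(bad_roles)}")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() < 0).any():
                raise ValueError("abundances must be non-negative")
        if self.psm is not None and not (
            self.psm.index.equals(self.values.index)
            and list(self.psm.columns) == list(self.values.columns)
        ):
            raise ValueError("psm table is not aligned with values")

    # -- role helpers -------------------------------------------------------

    def sample_ids(self, role: str) -> list[str]:
        return list(self.samples.index[self.samples["role"] == role])

    @property
    def biological_ids(self) -> list[str]:
        return self.sample_ids(ROLE_BIOLOGICAL)

    @property
    def blank_ids(self) -> list[str]:
        return self.sample_ids(ROLE_BLANK)

    @property
    def qc_ids(self) -> list[str]:
        return self.sample_ids(ROLE_QC)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def injection_order(self) -> pd.Series:
        return self.samples["injection_order"]

    # -- subsetting ---------------------------------------------------------

    def subset_features(self, keep: Sequence) -> "FeatureTable":
        keep = pd.Index(keep)
        return FeatureTable(
            values=self.values.loc[keep].copy(),
            meta=self.meta.loc[keep].copy(),
            samples=self.samples.copy(),
            kind=self.kind,
            psm=None if self.psm is None else self.psm.loc[keep].copy(),
        )

    def subset_samples(self, keep: Iterable[str]) -> "FeatureTable":
        keep = list(keep)
        return FeatureTable(
            values=self.values[keep].copy(),
            meta=self.meta.copy(),
            samples=self.samples.loc[keep].copy(),
            kind=self.kind,
            psm=None if self.psm is None else self.psm[keep].copy(),
        )

    def drop_non_biological(self) -> "FeatureTable":
        """Return the table restricted to biological samples (QC stage exit)."""
        return self.subset_samples(self.biological_ids)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            values=self.values.copy(),
            meta=self.meta.copy(),
            samples=self.samples.copy(),
            kind=self.kind,
            psm=None if self.psm is None else self.psm.copy(),
        )


@dataclass
class OmicsMatrix:
    """Samples × features numeric matrix with its preprocessing record.

    ``values`` holds log10 abundances after imputation, optionally
    mean-centered and unit-variance scaled per feature. ``center`` and
    ``scale`` store the per-feature vectors actually applied (zeros / ones
    when a step was disabled) so the identical transform can be applied to
    held-out samples.
    """

    values: pd.DataFrame
    feature_kind: pd.Series
    center: pd.Series
    scale: pd.Series
    design: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        cols = pd.Index(self.values.columns)
        for name, vec in (("feature_kind", self.feature_kind),
                          ("center", self.center), ("scale", self.scale)):
            if not cols.equals(pd.Index(vec.index)):
                raise ValueError(f"{name} is not aligned with feature columns")
        if self.values.isna().any().any():
            raise ValueError("OmicsMatrix must not contain missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def unscale(self) -> pd.DataFrame:
        """Invert centering/scaling, returning log10 values."""
        return self.values * self.scale + self.center

    def subset_samples(self, keep: Iterable[str]) -> "OmicsMatrix":
        keep = list(keep)
        design = None if self.design is None else self.design.loc[keep]
        return OmicsMatrix(
            values=self.values.loc[keep].copy(),
            feature_kind=self.feature_kind.copy(),
            center=self.center.copy(),
            scale=self.scale.copy(),
            design=design,
        )
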