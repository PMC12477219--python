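"""Delimited-text and JSON I/O for every pipeline artifact.

Table layout contracts (all TSV, UTF-8, ``NA`` or empty cell = missing):

* feature table ``<stem>.features.tsv`` — first column ``feature_id``, then
  the metadata columns ``annotation``, ``retention_time``, ``msi_level``,
  then one numeric column per sample.
* sample table ``<stem>.samples.tsv`` — ``sample_id``, ``role``
  (biological/blank/qc), ``injection_order`` and, for biological samples,
  ``cell_type``, ``oxygen``, ``replicate``.
* PSM table ``<stem>.psm.tsv`` (proteins) — ``feature_id`` + sample columns.
* models are serialized to a versioned JSON document with explicit matrix
  dimensions, row-major values.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureTable, OmicsMatrix, ROLES, validate_design
from .pls import PLSModel, VIPResult

_META_COLUMNS = ("annotation", "retention_time", "msi_level")
_NA_VALUES = ["", "NA"]
MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, stem: str | Path) -> None:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    out = table.meta.reindex(columns=list(_META_COLUMNS)).join(table.values)
    out.index.name = "feature_id"
    out.to_csv(f"{stem}.features.tsv", sep="\t", na_rep="NA")
    samples = table.samples.copy()
    samples.index.name = "sample_id"
    samples.to_csv(f"{stem}.samples.tsv", sep="\t", na_rep="NA")
    if table.psm is not None:
        psm = table.psm.copy()
        psm.index.name = "feature_id"
        psm.to_csv(f"{stem}.psm.tsv", sep="\t", na_rep="NA")


def read_feature_table(stem: str | Path, kind: str) -> FeatureTable:
    """Read and validate a feature table written by
    :func:`write_feature_table`.

    Raises on duplicate feature ids, unknown sample roles, and non-numeric
    abundances (reported with row/column coordinates).
    """
    stem = Path(stem)
    feats = pd.read_csv(f"{stem}.features.tsv", sep="\t", dtype={0: str},
                        na_values=_NA_VALUES, keep_default_na=False)
    id_col = feats.columns[0]
    dupes = feats[id_col][feats[id_col].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate feature id(s): {dupes}")
    feats = feats.set_index(id_col)
    feats.index.name = "feature_id"

    samples = pd.read_csv(f"{stem}.samples.tsv", sep="\t", index_col=0,
                          na_values=_NA_VALUES, keep_default_na=False)
    bad_roles = set(samples["role"]) - ROLES
    if bad_roles:
        raise ValueError(f"unknown sample role(s): {sorted(bad_roles)}")

    sample_cols = [c for c in feats.columns if c not in _META_COLUMNS]
    missing = [s for s in samples.index if s not in sample_cols]
    if missing:
        raise ValueError(f"samples absent from the feature table: {missing}")
    values = pd.DataFrame(index=feats.index)
    for col in samples.index:
        parsed = pd.to_numeric(feats[col], errors="coerce")
        bad = parsed.isna() & feats[col].notna()
        if bad.any():
            row = feats.index[bad][0]
            raise ValueError(
                f"non-numeric abundance {feats.loc[row, col]!r} at feature "
                f"{row!r}, sample {col!r}"
            )
        values[col] = parsed
    values.columns = samples.index.copy()
    meta = feats.reindex(columns=list(_META_COLUMNS))
    meta["retention_time"] = pd.to_numeric(meta["retention_time"],
                                           errors="coerce")
    meta["msi_level"] = pd.to_numeric(meta["msi_level"], errors="coerce")
    samples["injection_order"] = pd.to_numeric(samples["injection_order"])

    psm = None
    psm_path = Path(f"{stem}.psm.tsv")
    if psm_path.exists():
        psm = pd.read_csv(psm_path, sep="\t", index_col=0,
                          na_values=_NA_VALUES, keep_default_na=False)
        psm = psm[[str(c) for c in values.columns]].astype(float)
        psm.columns = values.columns.copy()
        psm.index.name = "feature_id"
    return FeatureTable(values=values, meta=meta,
                        samples=samples[["role", "injection_order"]],
                        kind=kind, psm=psm)


# ---------------------------------------------------------------------------
# design / uptake / simple frames
# ---------------------------------------------------------------------------

def write_frame(frame: pd.DataFrame, path: str | Path,
                index_name: str = "sample_id") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = frame.copy()
    out.index.name = out.index.name or index_name
    out.to_csv(path, sep="\t", na_rep="NA")


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", index_col=0,
                         na_values=_NA_VALUES, keep_default_na=False)
    return validate_design(design)


def read_uptake(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.astype(float)


# ---------------------------------------------------------------------------
# omics matrix (+ scaling sidecar)
# ---------------------------------------------------------------------------

def write_omics_matrix(matrix: OmicsMatrix, stem: str | Path) -> None:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    vals = matrix.values.copy()
    vals.index.name = "sample_id"
    vals.to_csv(f"{stem}.matrix.tsv", sep="\t")
    sidecar = {
        "features": list(matrix.values.columns),
        "feature_kind": matrix.feature_kind.tolist(),
        "center": matrix.center.tolist(),
        "scale": matrix.scale.tolist(),
    }
    Path(f"{stem}.scaling.json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True)
    )


def read_omics_matrix(stem: str | Path,
                      design: pd.DataFrame | None = None) -> OmicsMatrix:
    stem = Path(stem)
    values = pd.read_csv(f"{stem}.matrix.tsv", sep="\t", index_col=0)
    sidecar = json.loads(Path(f"{stem}.scaling.json").read_text())
    features = pd.Index(sidecar["features"])
    if list(values.columns) != list(features):
        raise ValueError("matrix columns do not match the scaling sidecar")
    return OmicsMatrix(
        values=values.astype(float),
        feature_kind=pd.Series(sidecar["feature_kind"], index=features),
        center=pd.Series(sidecar["center"], index=features, dtype=float),
        scale=pd.Series(sidecar["scale"], index=features, dtype=float),
        design=None if design is None else design.loc[values.index],
    )


# ---------------------------------------------------------------------------
# PLS model JSON
# ---------------------------------------------------------------------------

def _matrix_doc(arr: np.ndarray) -> dict:
    arr = np.asarray(arr, dtype=float)
    return {"shape": list(arr.shape), "values": arr.ravel().tolist()}


def _matrix_from_doc(doc: dict) -> np.ndarray:
    return np.asarray(doc["values"], dtype=float).reshape(doc["shape"])


def model_to_json(model: PLSModel, path: str | Path) -> None:
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "n_components": model.n_components,
        "feature_names": list(model.feature_names),
        "outcome_names": list(model.outcome_names),
        "weights": _matrix_doc(model.weights),
        "x_loadings": _matrix_doc(model.x_loadings),
        "y_loadings": _matrix_doc(model.y_loadings),
        "scores": _matrix_doc(model.scores),
        "x_variance_explained": model.x_variance_explained.tolist(),
        "y_variance_explained": model.y_variance_explained.tolist(),
        "x_center": model.x_center.tolist(),
        "x_scale": model.x_scale.tolist(),
        "y_center": model.y_center.tolist(),
        "y_scale": model.y_scale.tolist(),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))


def model_from_json(path: str | Path) -> PLSModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {doc.get('format_version')!r}"
        )
    return PLSModel(
        weights=_matrix_from_doc(doc["weights"]),
        x_loadings=_matrix_from_doc(doc["x_loadings"]),
        y_loadings=_matrix_from_doc(doc["y_loadings"]),
        scores=_matrix_from_doc(doc["scores"]),
        x_variance_explained=np.asarray(doc["x_variance_explained"]),
        y_variance_explained=np.asarray(doc["y_variance_explained"]),
        x_center=np.asarray(doc["x_center"], dtype=float),
        x_scale=np.asarray(doc["x_scale"], dtype=float),
        y_center=np.asarray(doc["y_center"], dtype=float),
        y_scale=np.asarray(doc["y_scale"], dtype=float),
        feature_names=list(doc["feature_names"]),
        outcome_names=list(doc["outcome_names"]),
    )


def write_vip_table(vip: VIPResult, path: str | Path) -> None:
    """VIP table TSV sorted by descending average score."""
    out = vip.per_outcome.copy()
    out["average"] = vip.average
    out["selected"] = vip.average > vip.threshold
    out = out.sort_values("average", ascending=False)
    out.index.name = "feature_id"
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# ground truth sidecar
# ---------------------------------------------------------------------------

def write_ground_truth(truth, stem: str | Path) -> None:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    write_frame(truth.coefficient_matrix, f"{stem}.coefficients.tsv",
                index_name="feature_id")
    write_frame(truth.group_means.T, f"{stem}.group_means.tsv",
                index_name="feature_id")
    write_frame(truth.latent_scores, f"{stem}.latent_scores.tsv")
    doc = {"informative_feature_ids": list(truth.informative_feature_ids)}
    Path(f"{stem}.truth.json").write_text(
        json.dumps(doc, indent=1, sort_keys=True)
    )
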