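"""Synthetic sEV lipidomics/proteomics study generator.

Emulates the statistical structure the downstream analysis assumes: a small
multi-condition design (parent cell type × oxygen conditioning × replicates),
feature tables whose log10 abundances follow cell-type group means driven by a
low-rank latent factor model, left-censored missingness, blank and pooled-QC
injections with monotone multiplicative signal drift, lipid isomer duplicate
peaks, protein PSM counts, and a sparse linear map from the (log-scale)
feature matrix to six uptake outcomes. Every draw flows from a single seed
through independent named streams, so outputs are bit-reproducible.

The generator also returns the ground truth (informative feature set, latent
scores, coefficient matrix, group means) needed for parameter-recovery tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import (
    CELL_TYPES,
    OXYGEN_LEVELS,
    ROLE_BIOLOGICAL,
    ROLE_BLANK,
    ROLE_QC,
    UPTAKE_COLUMNS,
    FeatureTable,
    validate_design,
)

# Stream offsets: sub-seeds for the independent RNG streams.
_STREAM_LATENT = 0
_STREAM_LIPID = 1
_STREAM_PROTEIN = 2
_STREAM_UPTAKE = 3

_LIPID_CLASSES = ("PC", "LPC", "PE", "SM", "Cer", "TG", "DG", "PI", "PS")
# Approximate class elution windows (min) on a reversed-phase gradient.
_CLASS_RT = {
    "LPC": (1.5, 4.0), "PI": (3.0, 6.0), "PS": (3.5, 6.5), "PC": (5.0, 10.0),
    "PE": (5.5, 10.5), "SM": (6.0, 11.0), "Cer": (8.0, 13.0),
    "DG": (10.0, 14.0), "TG": (13.0, 18.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    The design defaults (4 parent cell types × 2 oxygen levels × 3
    replicates = 24 biological samples) and the feature-count defaults
    (chosen so that roughly 711 combined features survive the QC and
    missing-value filters) reproduce the scale of the study the pipeline is
    built for. ``noise_sd`` is the replicate-level standard deviation on the
    log10 scale; ``drift_slope`` is the relative intensity change per
    injection applied multiplicatively along the acquisition sequence.
    """

    n_cell_types: int = 4
    n_oxygen: int = 2
    n_replicates: int = 3
    n_lipids: int = 381          # distinct lipid annotations before isomers
    n_proteins: int = 483
    n_blanks: int = 2
    n_qc: int = 6
    n_informative: int = 30
    latent_rank: int = 2
    noise_sd: float = 0.1
    missing_rate: float = 0.10
    drift_slope: float = -0.004
    seed: int = 0
    # secondary structure exercised by the QC filters
    contaminant_frac: float = 0.08   # lipid features failing the 5x blank rule
    qc_absent_frac: float = 0.04     # lipid features present in <50% of QCs
    high_cv_frac: float = 0.05       # lipid features with QC CV >> 30%
    isomer_frac: float = 0.15        # annotations duplicated as isomer peaks
    low_psm_frac: float = 0.10       # proteins with max PSM < 2
    qc_cv: float = 0.08              # nominal QC relative SD (raw scale)
    uptake_noise_sd: float = 0.05    # Gaussian noise on normalized uptake
    outcome_loading_sd: float = 0.3  # SD of per-outcome uptake-factor weights
    baseline_mean: float = 5.0       # log10 abundance baseline
    baseline_sd: float = 0.7
    latent_loading_sd: float = 0.35  # shared-latent loading SD (all features)
    informative_loading: float = 1.0 # uptake-factor loading of informative ones
    background_loading_sd: float = 0.05  # weak uptake-factor loading of the
                                         # rest (graded relevance; their Y
                                         # coefficients stay exactly zero)
    uptake_jitter: float = 4.0       # within-group uptake-factor SD, in units
                                     # of noise_sd (0 when noise_sd = 0)
    missing_concentration: float = 1.5  # Beta concentration of per-feature rates

    def validate(self) -> "SimConfig":
        counts = {
            "n_cell_types": self.n_cell_types, "n_oxygen": self.n_oxygen,
            "n_replicates": self.n_replicates, "n_lipids": self.n_lipids,
            "n_proteins": self.n_proteins, "n_blanks": self.n_blanks,
            "n_qc": self.n_qc, "latent_rank": self.latent_rank,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.n_informative < 0:
            raise ValueError("n_informative must be >= 0")
        if self.n_informative > self.n_lipids + self.n_proteins:
            raise ValueError(
                "n_informative exceeds the total number of features"
            )
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        return self


@dataclass
class GroundTruth:
    """What the generator knows and the analysis tries to recover.

    ``coefficient_matrix`` rows are exactly zero outside the informative
    feature set. ``group_means`` are the exact expected log10 abundances per
    cell type, so with ``noise_sd=0`` and ``missing_rate=0`` they are
    recovered exactly from the generated table. ``x_log`` is the biological
    log10 matrix before drift and censoring are applied (the matrix the
    uptake outcomes are generated from).
    """

    informative_feature_ids: tuple
    latent_scores: pd.DataFrame        # biological samples × latent rank
    coefficient_matrix: pd.DataFrame   # features × 6 uptake outcomes
    group_means: pd.DataFrame          # cell types × features (log10)
    x_log: pd.DataFrame                # biological samples × features (log10)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def _labels(base: tuple, n: int, prefix: str) -> list[str]:
    if n <= len(base):
        return list(base[:n])
    return list(base) + [f"{prefix}{i}" for i in range(len(base) + 1, n + 1)]


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def generate_design(config: SimConfig) -> pd.DataFrame:
    """One biological sample per (cell type, oxygen, replicate) triple."""
    config.validate()
    cell_types = _labels(CELL_TYPES, config.n_cell_types, "CT")
    oxygen = _labels(OXYGEN_LEVELS, config.n_oxygen, "O")
    rows = []
    for ct, ox, rep in itertools.product(
        cell_types, oxygen, range(1, config.n_replicates + 1)
    ):
        rows.append({"sample_id": f"{ct}_{ox}_{rep}", "cell_type": ct,
                     "oxygen": ox, "replicate": rep})
    design = pd.DataFrame(rows).set_index("sample_id")
    return validate_design(design)


def _shared_structure(config: SimConfig, design: pd.DataFrame):
    """Latent state shared by the lipid and protein tables.

    Drawn from a dedicated stream in a fixed order so both
    :func:`generate_feature_table` calls see identical values:

    * ``latent`` — cell-type positions on the shared composition factors
      (drive the overall cell-type clustering; all features load on them);
    * ``u`` — the scalar *uptake propensity* of each sEV sample: a
      cell-type-level value (``u_ct``) plus replicate-level biological
      variation whose SD is ``uptake_jitter × noise_sd`` (so the
      no-replicate-noise limit is exact);
    * ``a`` — per-outcome weights mapping the uptake factor to the six
      uptake responses;
    * ``h`` — uptake-factor loadings of the ``n_informative`` features
      (signed, magnitude ≈ ``informative_loading``). Only informative
      features load on the uptake factor, which is what makes them
      recoverable by VIP ranking.
    """
    rng = _rng(config, _STREAM_LATENT)
    cell_types = list(dict.fromkeys(design["cell_type"]))
    latent = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(len(cell_types), config.latent_rank)),
        index=cell_types,
        columns=[f"latent_{k + 1}" for k in range(config.latent_rank)],
    )
    # the uptake-propensity axis is a composition axis of its own: its
    # cell-type pattern is orthogonalized against the shared factors (and
    # the intercept), so bulk-composition variation does not masquerade as
    # uptake signal
    z = rng.normal(0.0, 1.0, size=len(cell_types))
    basis = np.column_stack([np.ones(len(cell_types)), latent.to_numpy()])
    resid = z - basis @ np.linalg.lstsq(basis, z, rcond=None)[0]
    if resid.std() > 1e-8:
        u_vals = resid / resid.std()
    else:  # too few cell types to orthogonalize; centered draw
        u_vals = z - z.mean()
    u_ct = pd.Series(u_vals, index=cell_types)
    # every uptake outcome carries real signal: |a_k| is bounded away from
    # zero (uniform in [0.5, 1.5] × outcome_loading_sd, random sign)
    a = (rng.choice([-1.0, 1.0], size=len(UPTAKE_COLUMNS))
         * rng.uniform(0.5, 1.5, size=len(UPTAKE_COLUMNS))
         * config.outcome_loading_sd)
    eta = rng.normal(0.0, config.uptake_jitter * config.noise_sd,
                     size=len(design))
    u = pd.Series(u_ct.loc[design["cell_type"]].to_numpy() + eta,
                  index=design.index, name="uptake_factor")
    h = (rng.normal(1.0, 0.1, size=config.n_informative)
         * rng.choice([-1.0, 1.0], size=config.n_informative)
         * config.informative_loading)
    return cell_types, latent, u_ct, u, a, h


def _lipid_annotations(rng: np.random.Generator, n: int) -> tuple[list, list]:
    """Unique lipid-style annotations with class-dependent retention times."""
    combos = [
        f"{cls}({c}:{d})"
        for cls, c, d in itertools.product(
            _LIPID_CLASSES, range(28, 46, 2), range(0, 7)
        )
    ]
    idx = rng.choice(len(combos), size=n, replace=False)
    names = [combos[i] for i in sorted(idx)]
    rts = []
    for name in names:
        cls = name.split("(")[0]
        lo, hi = _CLASS_RT[cls]
        rts.append(float(rng.uniform(lo, hi)))
    return names, rts


def _injection_layout(design: pd.DataFrame, config: SimConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Acquisition sequence: blanks first, QCs bracketing biological blocks."""
    bio = list(design.index)
    order = rng.permutation(len(bio))
    bio = [bio[i] for i in order]
    blanks = [f"BLANK_{i + 1}" for i in range(config.n_blanks)]
    qcs = [f"QC_{i + 1}" for i in range(config.n_qc)]
    # place QC 1 before the first biological sample, QC last after the final
    # one, and the rest evenly through the run
    seq: list[tuple[str, str]] = [(b, ROLE_BLANK) for b in blanks]
    n_inner = max(config.n_qc - 2, 0)
    block = max(1, int(np.ceil(len(bio) / (n_inner + 1))))
    seq.append((qcs[0], ROLE_QC))
    qi = 1
    for start in range(0, len(bio), block):
        seq.extend((s, ROLE_BIOLOGICAL) for s in bio[start:start + block])
        if qi < config.n_qc - 1:
            seq.append((qcs[qi], ROLE_QC))
            qi += 1
    seq.extend((qcs[i], ROLE_QC) for i in range(qi, config.n_qc))
    samples = pd.DataFrame(
        {"role": [r for _, r in seq],
         "injection_order": np.arange(1, len(seq) + 1)},
        index=pd.Index([s for s, _ in seq], name="sample_id"),
    )
    return samples


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def generate_feature_table(
    config: SimConfig, design: pd.DataFrame, kind: str
) -> tuple[FeatureTable, GroundTruth]:
    """Generate one omics table (lipid or protein) plus its ground truth.

    Log10 abundances are cell-type group means (baseline + latent
    contribution) plus replicate noise; raw values are 10**log10, modulated
    by a monotone multiplicative drift along the injection sequence and
    left-censored at a per-feature threshold to produce
    missing-at-low-intensity cells. Lipid tables additionally carry blank
    and pooled-QC columns and isomer duplicate peaks; protein tables carry
    PSM counts on biological samples only.
    """
    config.validate()
    validate_design(design)
    if kind not in ("lipid", "protein"):
        raise ValueError(f"kind must be 'lipid' or 'protein', got {kind!r}")

    rng = _rng(config, _STREAM_LIPID if kind == "lipid" else _STREAM_PROTEIN)
    n_base = config.n_lipids if kind == "lipid" else config.n_proteins
    prefix = "L" if kind == "lipid" else "P"
    feature_ids = [f"{prefix}{i + 1:04d}" for i in range(n_base)]

    cell_types, latent, u_ct, u, a, h_all = _shared_structure(config, design)

    # informative split: proportional to table size, lipids get the remainder
    n_total = config.n_lipids + config.n_proteins
    n_inf_prot = int(round(config.n_informative * config.n_proteins / n_total))
    n_inf_lip = config.n_informative - n_inf_prot
    n_inf = n_inf_lip if kind == "lipid" else n_inf_prot
    h_slice = h_all[:n_inf_lip] if kind == "lipid" else h_all[n_inf_lip:]

    # artifact category per feature (lipids exercise the blank/QC filters)
    if kind == "lipid":
        probs = np.array([
            config.contaminant_frac, config.qc_absent_frac,
            config.high_cv_frac,
        ])
        probs = np.append(probs, 1.0 - probs.sum())
        category = rng.choice(
            ["contaminant", "qc_absent", "high_cv", "clean"],
            size=n_base, p=probs,
        )
    else:
        category = np.where(
            rng.random(n_base) < config.low_psm_frac, "low_psm", "clean"
        )
    clean = np.flatnonzero(category == "clean")
    if n_inf > clean.size:
        raise ValueError("n_informative too large for the clean feature pool")
    informative = np.sort(rng.choice(clean, size=n_inf, replace=False))
    is_inf = np.zeros(n_base, dtype=bool)
    is_inf[informative] = True

    # every feature loads weakly on the shared cell-type composition
    # factors; informative features additionally load on the uptake factor
    loadings = rng.normal(0.0, config.latent_loading_sd,
                          size=(config.latent_rank, n_base))
    # graded relevance: every feature co-varies weakly with the uptake
    # axis, the informative set strongly; only the informative rows of the
    # coefficient matrix are nonzero, so Y depends on them alone
    h_vec = rng.normal(0.0, config.background_loading_sd, size=n_base)
    h_vec[informative] = h_slice

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_base)
    group_means = pd.DataFrame(
        baseline[None, :] + latent.to_numpy() @ loadings
        + np.outer(u_ct.loc[cell_types].to_numpy(), h_vec),
        index=cell_types, columns=feature_ids,
    )

    # biological log10 matrix: group mean + replicate-level uptake-factor
    # deviation + independent replicate noise
    u_dev = (u - u_ct.loc[design["cell_type"]].set_axis(design.index)).to_numpy()
    x_log = pd.DataFrame(
        group_means.loc[design["cell_type"]].to_numpy()
        + np.outer(u_dev, h_vec)
        + rng.normal(0.0, config.noise_sd, size=(len(design), n_base)),
        index=design.index, columns=feature_ids,
    )
    scores = latent.loc[design["cell_type"]].set_axis(design.index, axis=0)
    scores["uptake_factor"] = u

    # feature→uptake coefficients, supported on the informative set: the
    # rank-one map C = h aᵀ / Σh² turns X·C into (uptake factor)·aᵀ plus a
    # small contamination term, so Y is exactly linear in X by construction
    coef = np.zeros((n_base, len(UPTAKE_COLUMNS)))
    h2_total = float(np.sum(h_all ** 2))
    if config.n_informative > 0 and h2_total > 0:
        coef[informative, :] = np.outer(h_slice, a) / h2_total
    coefficients = pd.DataFrame(coef, index=feature_ids,
                                columns=list(UPTAKE_COLUMNS))

    truth = GroundTruth(
        informative_feature_ids=tuple(feature_ids[j] for j in informative),
        latent_scores=scores,
        coefficient_matrix=coefficients,
        group_means=group_means,
        x_log=x_log.copy(),
    )

    if kind == "lipid":
        table = _assemble_lipid_table(
            config, design, rng, feature_ids, x_log, category, is_inf
        )
    else:
        table = _assemble_protein_table(
            config, design, rng, feature_ids, x_log, category, is_inf
        )
    return table, truth


def _censor(config: SimConfig, rng: np.random.Generator,
            raw: np.ndarray, is_inf: np.ndarray) -> np.ndarray:
    """Left-censor each feature at its own low-intensity threshold.

    Per-feature missing rates are Beta-distributed around ``missing_rate``
    so that some features exceed the downstream missing-count filter.
    Informative features are real, consistently detected membrane components,
    so their rates are capped below the filter threshold.
    """
    if config.missing_rate == 0:
        return raw
    m, k = config.missing_rate, config.missing_concentration
    rates = rng.beta(k * m, k * (1 - m), size=raw.shape[1])
    rates[is_inf] = np.minimum(rates[is_inf], 0.4)
    out = raw.copy()
    for j in range(raw.shape[1]):
        if rates[j] <= 0:
            continue
        thresh = np.quantile(raw[:, j], rates[j])
        out[raw[:, j] < thresh, j] = np.nan
    return out


def _assemble_lipid_table(config, design, rng, feature_ids, x_log, category,
                          is_inf):
    n_base = len(feature_ids)
    samples = _injection_layout(design, config, rng)
    inj = samples["injection_order"]
    drift = (1.0 + config.drift_slope) ** (inj.to_numpy() - 1.0)
    drift_by_sample = pd.Series(drift, index=samples.index)

    annotations, rts = _lipid_annotations(rng, n_base)
    msi = rng.choice([1, 2, 3, 4], size=n_base, p=[0.05, 0.55, 0.30, 0.10])

    bio_raw = 10.0 ** x_log.to_numpy()  # biological samples × features
    grand_log = x_log.to_numpy().mean(axis=0)

    # QC columns: grand mean × drift × small lognormal CV
    qc_ids = samples.index[samples["role"] == ROLE_QC]
    # noise_sd = 0 is the noise-free-instrument limit: QC replicate
    # injections then agree exactly (modulo drift)
    sigma = np.where(category == "high_cv", 0.6, config.qc_cv)
    if config.noise_sd == 0:
        sigma = np.zeros_like(sigma)
    qc_raw = (
        (10.0 ** grand_log)[None, :]
        * drift_by_sample[qc_ids].to_numpy()[:, None]
        * rng.lognormal(0.0, 1.0, size=(len(qc_ids), n_base)) ** sigma[None, :]
    )
    # features absent from most QC injections (fail the 50% presence rule)
    for j in np.flatnonzero(category == "qc_absent"):
        keep = rng.integers(0, len(qc_ids))
        mask = np.ones(len(qc_ids), dtype=bool)
        mask[keep] = False
        qc_raw[mask, j] = np.nan

    # blanks: low background, except contaminants at half the max biological
    blank_ids = samples.index[samples["role"] == ROLE_BLANK]
    blank_raw = 10.0 ** rng.normal(
        config.baseline_mean - 3.5, 0.3, size=(len(blank_ids), n_base)
    )
    contaminant = np.flatnonzero(category == "contaminant")
    max_bio = bio_raw.max(axis=0)
    blank_raw[:, contaminant] = (
        0.5 * max_bio[contaminant][None, :]
        * rng.lognormal(0.0, 0.05, size=(len(blank_ids), len(contaminant)))
    )

    # apply drift to biological columns (rows of bio_raw follow the design
    # order, so look drift up by design sample id), then censor
    bio_drifted = bio_raw * drift_by_sample[design.index].to_numpy()[:, None]
    bio_censored = _censor(config, rng, bio_drifted, is_inf)

    values = pd.DataFrame(
        np.full((n_base, len(samples)), np.nan),
        index=pd.Index(feature_ids, name="feature_id"), columns=samples.index,
    )
    values[design.index] = bio_censored.T
    values[qc_ids] = qc_raw.T
    values[blank_ids] = blank_raw.T

    meta = pd.DataFrame(
        {"annotation": annotations, "retention_time": rts, "msi_level": msi},
        index=values.index,
    )

    table = FeatureTable(values=values, meta=meta, samples=samples, kind="lipid")
    return _add_isomer_peaks(config, rng, table)


def _add_isomer_peaks(config, rng, table: FeatureTable) -> FeatureTable:
    """Duplicate a fraction of annotations as isomer peaks.

    Retention-time offsets are drawn on both sides of the 0.3-min isomer
    gap, so both resolution rules (sum when Δ > gap, keep the lowest-QC-CV
    peak when Δ ≤ gap) are exercised.
    """
    if config.isomer_frac <= 0:
        return table
    n = table.n_features
    chosen = np.flatnonzero(rng.random(n) < config.isomer_frac)
    if chosen.size == 0:
        return table
    new_vals, new_meta = [], []
    for j in chosen:
        fid = table.feature_ids[j]
        wide = rng.random() < 0.5
        delta = rng.uniform(0.35, 1.2) if wide else rng.uniform(0.05, 0.28)
        delta *= rng.choice([-1.0, 1.0])
        factor = rng.uniform(0.3, 0.9)
        vals = table.values.loc[fid] * factor
        # jitter the duplicate's QC values so the pair's CVs differ
        qc_ids = table.qc_ids
        vals[qc_ids] = vals[qc_ids] * rng.lognormal(0.0, 0.05, size=len(qc_ids))
        new_vals.append(vals.rename(f"{fid}_iso"))
        row = table.meta.loc[fid].copy()
        row["retention_time"] = max(0.1, row["retention_time"] + delta)
        new_meta.append(row.rename(f"{fid}_iso"))
    values = pd.concat([table.values, pd.DataFrame(new_vals)])
    meta = pd.concat([table.meta, pd.DataFrame(new_meta)])
    values.index.name = "feature_id"
    return FeatureTable(values=values, meta=meta, samples=table.samples,
                        kind="lipid")


def _assemble_protein_table(config, design, rng, feature_ids, x_log, category,
                            is_inf):
    n_base = len(feature_ids)
    samples = pd.DataFrame(
        {"role": ROLE_BIOLOGICAL,
         "injection_order": np.arange(1, len(design) + 1)},
        index=design.index.copy(),
    )
    raw = 10.0 ** x_log.to_numpy()
    censored = _censor(config, rng, raw, is_inf)

    values = pd.DataFrame(
        censored.T, index=pd.Index(feature_ids, name="feature_id"),
        columns=design.index,
    )
    meta = pd.DataFrame(
        {"annotation": [f"PROT{i + 1:04d}_HUMAN" for i in range(n_base)],
         "retention_time": np.nan, "msi_level": np.nan},
        index=values.index,
    )

    # PSM counts: Poisson around a per-protein rate; the low_psm fraction
    # never reaches 2 in any sample and is removed by the PSM filter
    lam = rng.uniform(3.0, 15.0, size=n_base)
    psm = rng.poisson(lam[None, :], size=(len(design), n_base)).astype(float)
    low = np.flatnonzero(category == "low_psm")
    psm[:, low] = rng.integers(0, 2, size=(len(design), low.size))
    psm[np.isnan(censored)] = 0.0
    # guarantee retained proteins truly pass the >=2-PSM-in-a-sample rule
    observed = ~np.isnan(censored)
    for j in np.flatnonzero(category == "clean"):
        if psm[:, j].max() < 2:
            rows = np.flatnonzero(observed[:, j])
            psm[rows[0], j] = 2.0
    psm_df = pd.DataFrame(psm.T, index=values.index, columns=design.index)

    return FeatureTable(values=values, meta=meta, samples=samples,
                        kind="protein", psm=psm_df)


# ---------------------------------------------------------------------------
# uptake outcomes
# ---------------------------------------------------------------------------

def generate_uptake(config: SimConfig, truth: GroundTruth,
                    x_true: pd.DataFrame) -> pd.DataFrame:
    """Normalized uptake outcomes: Y = 1 + centered(X)·C + noise.

    ``x_true`` is the biological log10 feature matrix aligned with
    ``truth.coefficient_matrix``; the uninhibited control corresponds to 1,
    and values above 1 are allowed (uptake can exceed the uninhibited
    control when a non-dominant pathway is blocked).
    """
    coef = truth.coefficient_matrix
    if list(x_true.columns) != list(coef.index):
        raise ValueError(
            "x_true columns do not match the coefficient matrix features "
            f"({x_true.shape[1]} vs {coef.shape[0]})"
        )
    rng = _rng(config, _STREAM_UPTAKE)
    centered = x_true.to_numpy() - x_true.to_numpy().mean(axis=0, keepdims=True)
    y = 1.0 + centered @ coef.to_numpy()
    if config.uptake_noise_sd > 0:
        y = y + rng.normal(0.0, config.uptake_noise_sd, size=y.shape)
    return pd.DataFrame(y, index=x_true.index, columns=list(UPTAKE_COLUMNS))


def merge_truth(lipid: GroundTruth, protein: GroundTruth) -> GroundTruth:
    """Concatenate per-table ground truths into the combined-feature truth."""
    return GroundTruth(
        informative_feature_ids=(
            lipid.informative_feature_ids + protein.informative_feature_ids
        ),
        latent_scores=lipid.latent_scores,
        coefficient_matrix=pd.concat(
            [lipid.coefficient_matrix, protein.coefficient_matrix]
        ),
        group_means=pd.concat(
            [lipid.group_means, protein.group_means], axis=1
        ),
        x_log=pd.concat([lipid.x_log, protein.x_log], axis=1),
    )


@dataclass
class SimulatedStudy:
    """Bundle of everything one simulated study comprises."""

    config: SimConfig
    design: pd.DataFrame
    lipids: FeatureTable
    proteins: FeatureTable
    uptake: pd.DataFrame
    truth: GroundTruth


def simulate(config: SimConfig | None = None, **overrides) -> SimulatedStudy:
    """Run the full generator: design, both omics tables, uptake, truth."""
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    config.validate()
    design = generate_design(config)
    lipids, lipid_truth = generate_feature_table(config, design, "lipid")
    proteins, protein_truth = generate_feature_table(config, design, "protein")
    truth = merge_truth(lipid_truth, protein_truth)
    uptake = generate_uptake(config, truth, truth.x_log)
    return SimulatedStudy(config=config, design=design, lipids=lipids,
                          proteins=proteins, uptake=uptake, truth=truth)
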