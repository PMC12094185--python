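"""Label-free proteomics enrichment statistics.

Implements the analysis stage downstream of protein quantification in a
proximity-labelling experiment (BioID/TurboID bait vs control): filtering to
non-contaminant proteins with at least two peptides quantified in at least
two replicates of one experiment, mode-of-pairwise-ratio normalization,
two left-censored imputation schemes (deterministic lowest-of-detection and
random draws from a down-shifted normal), and per-protein unpaired t-tests
with enrichment called at log2 fold change > 1 and p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from satquant.core import (
    ImputationError,
    InsufficientDataError,
    InvalidParameterError,
    NormalizationError,
)

META_COLUMNS = ["Gene", "Peptides", "Contaminant"]


@dataclass
class LfqMatrix:
    """Protein × sample log2 intensities with per-protein metadata.

    ``data``: DataFrame indexed by protein id, one column per sample, NaN
    for missing values. ``meta``: Gene / Peptides / Contaminant per protein.
    ``groups``: sample name → ``"bait"`` or ``"control"``.
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    groups: dict

    def __post_init__(self) -> None:
        if not self.data.columns.isin(self.groups).all():
            missing = [c for c in self.data.columns if c not in self.groups]
            raise InvalidParameterError(f"samples without group assignment: {missing}")
        if not self.meta.index.equals(self.data.index):
            self.meta = self.meta.reindex(self.data.index)
        if (self.meta["Peptides"] < 0).any():
            raise InvalidParameterError("peptide counts must be >= 0")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.data.columns if self.groups[s] == group]


@dataclass
class EnrichmentTable:
    """Per-protein fold change, p-value and enrichment call."""

    table: pd.DataFrame
    lfc_threshold: float
    p_threshold: float


def load_lfq(path, groups: dict) -> LfqMatrix:
    """Read the LFQ TSV dialect (ProteinID, Gene, Peptides, Contaminant,
    then one linear-intensity column per sample; 0 or blank = missing).

    Intensities are log2-transformed on load.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["ProteinID"] + META_COLUMNS
    for col in required:
        if col not in df.columns:
            raise InvalidParameterError(f"missing required column {col!r}")
    df = df.set_index("ProteinID")
    sample_cols = [c for c in df.columns if c not in META_COLUMNS]
    values = df[sample_cols].astype(float)
    values = values.where(values > 0)
    data = np.log2(values)
    meta = df[META_COLUMNS].copy()
    meta["Contaminant"] = meta["Contaminant"].astype(bool)
    return LfqMatrix(data, meta, dict(groups))


def write_enrichment_tsv(path, result: EnrichmentTable) -> None:
    out = result.table.copy()
    out["neg_log10_p"] = -np.log10(out["p_value"].clip(lower=1e-300))
    out.to_csv(path, sep="\t")


def filter_proteins(
    matrix: LfqMatrix,
    min_peptides: int = 2,
    min_quantified_reps: int = 2,
) -> LfqMatrix:
    """Keep non-contaminant proteins with enough peptides and replicates.

    A protein passes when it is not flagged as a contaminant, has at least
    ``min_peptides`` peptides, and is quantified in at least
    ``min_quantified_reps`` replicates of at least one experiment group.
    """
    quantified_ok = pd.Series(False, index=matrix.data.index)
    for group in ("bait", "control"):
        cols = matrix.samples_in(group)
        if cols:
            quantified_ok |= matrix.data[cols].notna().sum(axis=1) >= min_quantified_reps
    keep = (
        ~matrix.meta["Contaminant"]
        & (matrix.meta["Peptides"] >= min_peptides)
        & quantified_ok
    )
    return LfqMatrix(matrix.data[keep], matrix.meta[keep], matrix.groups)


def _kde_mode(values: np.ndarray, grid_points: int = 512) -> float:
    """Mode of a sample: argmax of a Silverman-bandwidth Gaussian KDE on a
    512-point grid spanning the sample range."""
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        return float(values[0])
    kde = stats.gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), grid_points)
    return float(grid[np.argmax(kde(grid))])


def normalize_mode(matrix: LfqMatrix, min_overlap: int = 10) -> tuple[LfqMatrix, pd.Series]:
    """Mode-of-pairwise-ratio normalization across samples.

    For every sample pair (i, j) the mode m_ij of the per-protein log2
    differences x_i − x_j (over proteins observed in both) is estimated by
    kernel density. Additive per-sample factors f (summing to zero) are then
    obtained by least squares so that f_i − f_j ≈ −m_ij, and the normalized
    matrix is x + f. For two samples offset by a constant c this reduces to
    factors (±c/2) that cancel the offset exactly.
    """
    samples = list(matrix.data.columns)
    n = len(samples)
    if n < 2:
        raise NormalizationError("need at least 2 samples")
    rows, rhs = [], []
    for i in range(n):
        for j in range(i + 1, n):
            diff = (matrix.data[samples[i]] - matrix.data[samples[j]]).dropna()
            if len(diff) < min_overlap:
                raise NormalizationError(
                    f"samples {samples[i]!r}/{samples[j]!r} share only "
                    f"{len(diff)} proteins")
            row = np.zeros(n)
            row[i], row[j] = 1.0, -1.0
            rows.append(row)
            rhs.append(-_kde_mode(diff.to_numpy()))
    rows.append(np.ones(n))  # zero-sum constraint
    rhs.append(0.0)
    f, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    factors = pd.Series(f, index=samples, name="factor")
    data = matrix.data.add(factors, axis=1)
    return LfqMatrix(data, matrix.meta, matrix.groups), factors


def impute_lod(matrix: LfqMatrix, per_sample: bool = False) -> LfqMatrix:
    """Deterministic lowest-of-detection imputation.

    Every missing entry is replaced by the minimum observed log2 intensity —
    of the whole matrix by default, or of its own sample column with
    ``per_sample=True``. Observed values are never changed.
    """
    data = matrix.data.copy()
    if data.notna().sum().sum() == 0:
        raise ImputationError("matrix has no observed values")
    if per_sample:
        data = data.fillna(data.min())
    else:
        data = data.fillna(data.min().min())
    return LfqMatrix(data, matrix.meta, matrix.groups)


def impute_nd(
    matrix: LfqMatrix,
    shift_sd: float = -1.8,
    width_sd: float = 0.3,
    seed: int = 0,
    per_sample: bool = False,
) -> LfqMatrix:
    """Left-censored normal imputation.

    Missing entries are drawn from Normal(μ + shift_sd·σ, (width_sd·σ)²)
    where μ and σ are the mean and SD of the observed values — of the whole
    matrix by default (per sample with ``per_sample=True``). The defaults
    (−1.8 SD shift, 0.3 SD width) are the convention for proteomics
    missing-not-at-random imputation. Observed values are never changed.
    """
    rng = np.random.default_rng(seed)
    data = matrix.data.copy()

    def fill(block: pd.DataFrame, mu: float, sigma: float) -> pd.DataFrame:
        if not np.isfinite(sigma) or sigma == 0:
            raise ImputationError("observed SD is zero or undefined")
        mask = block.isna()
        n_missing = int(mask.sum().sum())
        draws = rng.normal(mu + shift_sd * sigma, width_sd * sigma, n_missing)
        out = block.to_numpy()
        out[mask.to_numpy()] = draws
        return pd.DataFrame(out, index=block.index, columns=block.columns)

    if per_sample:
        parts = []
        for col in data.columns:
            obs = data[col].dropna()
            if len(obs) < 2:
                raise ImputationError(f"sample {col!r} has < 2 observed values")
            parts.append(fill(data[[col]], obs.mean(), obs.std(ddof=1)))
        data = pd.concat(parts, axis=1)
    else:
        obs = data.to_numpy()[data.notna().to_numpy()]
        if len(obs) < 2:
            raise ImputationError("matrix has < 2 observed values")
        data = fill(data, float(obs.mean()), float(obs.std(ddof=1)))
    return LfqMatrix(data, matrix.meta, matrix.groups)


def differential(
    matrix: LfqMatrix,
    test: str = "student",
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    bh_correction: bool = False,
) -> EnrichmentTable:
    """Per-protein unpaired t-test of bait vs control with enrichment calls.

    log2 fold change = mean(bait) − mean(control). ``test`` selects the
    classic Student t (pooled variance) or Welch's unequal-variance variant.
    Rows where both groups have zero variance are flagged degenerate and
    assigned p = 1 when the group means coincide (p = 0 otherwise).
    Enrichment requires log2FC strictly greater than ``lfc_threshold`` and
    p strictly below ``p_threshold``. Optional Benjamini–Hochberg adjustment
    replaces the raw p-values before calling (off by default: raw p values
    are thresholded).
    """
    if test not in ("student", "welch"):
        raise InvalidParameterError("test must be 'student' or 'welch'")
    bait = matrix.data[matrix.samples_in("bait")].to_numpy(float)
    ctrl = matrix.data[matrix.samples_in("control")].to_numpy(float)
    if bait.shape[1] < 2 or ctrl.shape[1] < 2:
        raise InsufficientDataError("need >= 2 samples per group")
    if np.isnan(bait).any() or np.isnan(ctrl).any():
        raise InvalidParameterError("impute missing values before testing")

    n1, n2 = bait.shape[1], ctrl.shape[1]
    m1, m2 = bait.mean(axis=1), ctrl.mean(axis=1)
    v1 = bait.var(axis=1, ddof=1)
    v2 = ctrl.var(axis=1, ddof=1)
    lfc = m1 - m2
    degenerate = (v1 == 0) & (v2 == 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        if test == "student":
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
            df = np.full(len(lfc), n1 + n2 - 2, dtype=float)
        else:
            se = np.sqrt(v1 / n1 + v2 / n2)
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        tstat = lfc / se
        p = 2 * stats.t.sf(np.abs(tstat), df)
    p = np.where(degenerate, np.where(lfc == 0, 1.0, 0.0), p)
    tstat = np.where(degenerate, 0.0, tstat)

    if bh_correction:
        from statsmodels.stats.multitest import multipletests
        p = multipletests(p, method="fdr_bh")[1]

    enriched = (lfc > lfc_threshold) & (p < p_threshold)
    table = pd.DataFrame({
        "log2_fold_change": lfc,
        "t_statistic": tstat,
        "p_value": p,
        "degenerate": degenerate,
        "passes_filters": True,
        "enriched": enriched,
    }, index=matrix.data.index)
    return EnrichmentTable(table, lfc_threshold, p_threshold)
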