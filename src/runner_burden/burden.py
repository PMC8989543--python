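"""From variant-level records to per-gene burden rows.

The variant table is a :class:`pandas.DataFrame` with one row per
(variant, gene) pair and columns::

    chrom pos ref alt gene_id consequence score
    case_ac case_an [ctrl_ac ctrl_an] af_<panel> ...

``case_ac``/``ctrl_ac`` are minor-allele counts, ``*_an`` allele numbers,
``af_*`` reference allele frequencies (one column per ancestry panel) and
``score`` a functional-prediction posterior in [0, 1] (NaN = missing).
A variant overlapping several genes appears once per gene and contributes
to each.

The preparation pipeline has a fixed order: consequence whitelist ->
rarity filter -> case-enrichment filter -> score imputation -> weighting ->
counting/predictor assembly.  Re-running it on its own output is a no-op.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError, SchemaError

DEFAULT_CONSEQUENCES = (
    "missense", "start-loss", "stop-loss", "stop-gain",
    "splicing", "frameshift", "non-frameshift",
)
LOF_CONSEQUENCES = frozenset({"stop-gain", "splicing", "frameshift", "start-loss", "stop-loss"})

ANNOTATION_COLUMNS = ("gene_id", "length_kb", "gc", "oe_mis", "mu_mis", "oe_lof", "mu_lof")
PREDICTOR_COLUMNS = ("x1", "x2", "x3", "x4", "x5", "x6", "x7", "x8")


@dataclass
class WeightConfig:
    """Weighting and variant-filter settings.

    b : score bin length in (0, 1]; the integer weight of a variant with
        score ``s`` is ``ceil(s / b)`` (floored at 1 so every retained
        allele counts).  ``b = 1`` or ``equal_weights=True`` reproduces the
        equal-weight (weight = 1) mode.
    d : case-enrichment fold (> 1); a variant is removed when its control
        allele frequency is at least ``d`` times its case frequency.
        ``None`` disables the filter (case-only studies).
    """

    b: float = 0.05
    equal_weights: bool = False
    d: float | None = 2.0
    rare_af_max: float = 0.01
    consequences: tuple = DEFAULT_CONSEQUENCES
    enrichment_mode: str = "exclude_control_enriched"  # or "require_case_enriched"

    def __post_init__(self):
        if not (0 < self.b <= 1):
            raise DomainError("score bin length b must lie in (0, 1]")
        if self.d is not None and self.d <= 1:
            raise DomainError("case-enrichment fold d must exceed 1")


def panel_columns(records: pd.DataFrame) -> list[str]:
    return [c for c in records.columns if c.startswith("af_")]


# ---------------------------------------------------------------------------
# Variant-level filters
# ---------------------------------------------------------------------------

def filter_consequence(records: pd.DataFrame, consequences=DEFAULT_CONSEQUENCES) -> pd.DataFrame:
    return records[records["consequence"].isin(set(consequences))].copy()


def filter_rare(records: pd.DataFrame, rare_af_max: float = 0.01,
                panels: list[str] | None = None) -> pd.DataFrame:
    """Keep variants rare in every enabled reference panel.

    The comparison uses the maximum AF across panels; a variant absent from
    the reference (all panel AFs missing) is treated as AF 0 and kept.
    """
    cols = panels or panel_columns(records)
    if not cols:
        return records.copy()
    max_af = records[cols].fillna(0.0).max(axis=1)
    return records[max_af <= rare_af_max].copy()


def filter_case_enriched(records: pd.DataFrame, d: float | None = 2.0,
                         mode: str = "exclude_control_enriched") -> pd.DataFrame:
    """Drop variants not enriched in cases relative to controls.

    With the default reading, a variant is removed when
    ``AF_control >= d * AF_case``.  The stricter alternative
    (``mode="require_case_enriched"``) keeps only ``AF_case > d * AF_control``.
    Without control columns the filter is the identity.
    """
    if d is None or "ctrl_ac" not in records.columns:
        return records.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        af_case = records["case_ac"] / records["case_an"]
        af_ctrl = records["ctrl_ac"] / records["ctrl_an"]
    af_case = af_case.fillna(0.0)
    af_ctrl = af_ctrl.fillna(0.0)
    if mode == "exclude_control_enriched":
        keep = af_ctrl < d * af_case
    elif mode == "require_case_enriched":
        keep = af_case > d * af_ctrl
    else:
        raise DomainError(f"unknown enrichment mode {mode!r}")
    return records[keep].copy()


def impute_missing_scores(records: pd.DataFrame) -> pd.DataFrame:
    """Replace missing functional scores by the gene mean.

    Genes with no scored variant fall back to the global mean of all scored
    variants; if nothing is scored anywhere a neutral 0.5 is used.
    """
    out = records.copy()
    s = out["score"]
    if s.notna().all():
        return out
    gene_mean = s.groupby(out["gene_id"]).transform("mean")
    global_mean = s.mean()
    if math.isnan(global_mean):
        warnings.warn("no functional scores available; imputing 0.5 everywhere")
        global_mean = 0.5
    out["score"] = s.fillna(gene_mean).fillna(global_mean)
    return out


# ---------------------------------------------------------------------------
# Weights, counts, frequency score
# ---------------------------------------------------------------------------

def score_to_weight(score, b: float, equal_weights: bool = False):
    """Integer weight ``ceil(s / b)`` of a functional score, floored at 1."""
    s = np.asarray(score, dtype=np.float64)
    if np.any((s < 0) | (s > 1)):
        raise DomainError("scores must lie in [0, 1]")
    if equal_weights:
        w = np.ones_like(s, dtype=np.int64)
    else:
        w = np.maximum(1, np.ceil(s / b)).astype(np.int64)
    return w if w.shape else int(w)


def weighted_gene_counts(records: pd.DataFrame, weights) -> pd.DataFrame:
    """Per-gene weighted burden ``y = sum n_j * w_j`` plus raw tallies.

    Returns a frame indexed by ``gene_id`` with columns ``y`` (weighted),
    ``y_raw`` (minor-allele tally), ``m`` (variant count) and the raw
    missense / LoF splits used in reports.
    """
    w = np.asarray(weights, dtype=np.int64)
    n = records["case_ac"].to_numpy(dtype=np.int64)
    is_lof = records["consequence"].isin(LOF_CONSEQUENCES).to_numpy()
    df = pd.DataFrame({
        "gene_id": records["gene_id"].to_numpy(),
        "c": n * w,
        "n": n,
        "n_mis": np.where(records["consequence"].to_numpy() == "missense", n, 0),
        "n_lof": np.where(is_lof, n, 0),
    })
    g = df.groupby("gene_id", sort=True).agg(
        y=("c", "sum"), y_raw=("n", "sum"), m=("n", "size"),
        missense_alleles=("n_mis", "sum"), lof_alleles=("n_lof", "sum"),
    )
    return g


def frequency_score(records: pd.DataFrame, weights,
                    panels: list[str] | None = None) -> pd.Series:
    """Gene frequency score: weighted sum of reference allele frequencies.

    ``x2_i = sum_j fbar_{ij} * w_{ij}`` over the gene's retained rare
    variants, where ``fbar`` averages the enabled panels (missing panel
    entries count as frequency 0).
    """
    cols = panels or panel_columns(records)
    if cols:
        fbar = records[cols].fillna(0.0).mean(axis=1).to_numpy()
    else:
        fbar = np.zeros(len(records))
    contrib = pd.Series(fbar * np.asarray(weights, dtype=np.float64),
                        index=records["gene_id"].to_numpy())
    return contrib.groupby(level=0).sum()


# ---------------------------------------------------------------------------
# Predictor assembly
# ---------------------------------------------------------------------------

def assemble_predictors(annotation: pd.DataFrame, x2: pd.Series) -> pd.DataFrame:
    """Build the eight-predictor matrix for every annotated gene.

    x1 coding length (kb), x2 frequency score, x3 = x1 * x2, x4 oe_mis,
    x5 mu_mis, x6 oe_lof, x7 mu_lof, x8 exon GC fraction.  Missing
    annotation values are imputed with the column median and the gene is
    flagged.
    """
    missing = set(ANNOTATION_COLUMNS) - set(annotation.columns)
    if missing:
        raise SchemaError(f"annotation table lacks column(s): {sorted(missing)}")
    ann = annotation.set_index("gene_id") if annotation.index.name != "gene_id" else annotation.copy()
    num_cols = ["length_kb", "gc", "oe_mis", "mu_mis", "oe_lof", "mu_lof"]
    flagged = ann[num_cols].isna().any(axis=1)
    ann[num_cols] = ann[num_cols].fillna(ann[num_cols].median())
    if (ann["length_kb"] <= 0).any():
        raise DomainError("coding-region length must be positive")

    out = pd.DataFrame(index=ann.index)
    out["x1"] = ann["length_kb"]
    out["x2"] = x2.reindex(ann.index).fillna(0.0)
    out["x3"] = out["x1"] * out["x2"]
    out["x4"] = ann["oe_mis"]
    out["x5"] = ann["mu_mis"]
    out["x6"] = ann["oe_lof"]
    out["x7"] = ann["mu_lof"]
    out["x8"] = ann["gc"]
    if ((out["x8"] < 0) | (out["x8"] > 1)).any():
        raise DomainError("GC fraction must lie in [0, 1]")
    out["annotation_imputed"] = flagged
    return out


def prepare_burden_table(records: pd.DataFrame, annotation: pd.DataFrame,
                         config: WeightConfig | None = None,
                         panels: list[str] | None = None) -> pd.DataFrame:
    """Run the full variant -> gene pipeline and emit the burden table.

    Output: one row per annotated gene with ``m, y, y_raw, missense_alleles,
    lof_alleles, x1..x8, annotation_imputed``.  Genes without retained
    variants keep ``y = 0``.
    """
    config = config or WeightConfig()
    rec = filter_consequence(records, config.consequences)
    rec = filter_rare(rec, config.rare_af_max, panels)
    rec = filter_case_enriched(rec, config.d, config.enrichment_mode)
    rec = impute_missing_scores(rec)
    w = score_to_weight(rec["score"].to_numpy(), config.b, config.equal_weights) \
        if len(rec) else np.zeros(0, dtype=np.int64)
    counts = weighted_gene_counts(rec, w)
    x2 = frequency_score(rec, w, panels)
    pred = assemble_predictors(annotation, x2)

    table = pred.join(counts, how="left")
    for c in ("y", "y_raw", "m", "missense_alleles", "lof_alleles"):
        table[c] = table[c].fillna(0).astype(np.int64)
    cols = ["m", "y", "y_raw", "missense_alleles", "lof_alleles",
            *PREDICTOR_COLUMNS, "annotation_imputed"]
    return table[cols]
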