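"""Recursive background purification, grid search and the full test.

The test statistic for a gene is its standardized deviance residual under
the truncated-NB baseline model; the background (null) gene set used to fit
that model is purified recursively: fit -> score -> exclude genes at a
loose FDR (default 0.1) -> refit, until the excluded set stabilizes.  The
score bin length ``b`` and truncation point ``t`` are chosen by a grid
search that balances p-value calibration (MLFC of background genes) against
the number of significant genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from . import burden as _burden
from .burden import PREDICTOR_COLUMNS, WeightConfig
from .exceptions import BackgroundShrinkageError, DomainError
from .trunc_nb import (
    TNBModel,
    deviance_residual,
    fit_tnb_regression,
    saturated_loglik_table,
    standardize_and_pvalue,
)

DEFAULT_B_GRID = tuple(np.round(np.arange(1, 21) * 0.05, 2))
DEFAULT_T_GRID = (0, 1, 2, 3, 4, 5)
EXOME_WIDE_P = 2.5e-6
_P_FLOOR = 1e-300  # guard against log(0) in MLFC for astronomically small p


# ---------------------------------------------------------------------------
# Calibration and FDR utilities
# ---------------------------------------------------------------------------

def mlfc(pvalues) -> float:
    """Mean |log2| fold change between sorted p-values and uniform quantiles.

    ``MLFC = (1/n) sum_i |log2(P_(i) / (i/n))|`` — zero for perfectly
    calibrated p-values; values near 0.3 indicate severe departure.
    """
    p = np.sort(np.asarray(pvalues, dtype=np.float64))
    if p.size == 0:
        raise DomainError("MLFC needs at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise DomainError("p-values must lie in (0, 1]")
    q = np.arange(1, p.size + 1) / p.size
    return float(np.mean(np.abs(np.log2(p / q))))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone-enforced)."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Recursive fitting
# ---------------------------------------------------------------------------

@dataclass
class RecursiveFitResult:
    """Converged model, background membership and final per-gene scores."""

    model: TNBModel
    scores: pd.DataFrame  # per gene: mu_hat, e, e_std, p, q, in_support, background
    iterations: list = field(default_factory=list)
    converged: bool = True

    @property
    def background_ids(self):
        return self.scores.index[self.scores["background"]]


def _design(table: pd.DataFrame) -> np.ndarray:
    return table[list(PREDICTOR_COLUMNS)].to_numpy(dtype=np.float64)


def recursive_fit(table: pd.DataFrame, t: int, *, exclusion_fdr: float = 0.1,
                  max_iter: int = 20, recursive: bool = True,
                  theta_fixed: float | None = None) -> RecursiveFitResult:
    """Fit the truncated-NB baseline with recursive background purification.

    Steps: fit on the current background (initially all in-support genes,
    ``y > t``); score every in-support gene; exclude genes at BH
    ``q <= exclusion_fdr``; repeat until the excluded set is stable.  Final
    scores for all genes come from the converged model.

    Raises
    ------
    BackgroundShrinkageError
        If more than half of the in-support genes would be excluded, or the
        background falls below 10 rows per coefficient.
    """
    X = _design(table)
    y = table["y"].to_numpy(dtype=np.int64)
    n_coef = X.shape[1] + 1
    in_support = y > t
    if in_support.sum() < 10 * n_coef:
        raise DomainError(
            f"only {in_support.sum()} genes with y > t={t}; "
            f"need at least {10 * n_coef}"
        )

    background = in_support.copy()
    prev_excluded: frozenset = frozenset()
    iterations = []
    model = None
    converged_rec = False
    e = np.full(y.size, np.nan)
    e_std = np.full(y.size, np.nan)
    p = np.ones(y.size)
    q = np.ones(y.size)

    for it in range(1, max_iter + 1):
        model = fit_tnb_regression(X[background], y[background], t,
                                   theta_fixed=theta_fixed)
        mu_hat = model.predict_mu(X)
        sat = saturated_loglik_table(y[in_support], model.theta, t)
        e = np.full(y.size, np.nan)
        e[in_support] = deviance_residual(
            y[in_support], mu_hat[in_support], model.theta, t, _sat_table=sat
        )
        e_std = np.full(y.size, np.nan)
        e_std[in_support], p_in = standardize_and_pvalue(e[background], e[in_support])
        p = np.ones(y.size)
        p[in_support] = p_in
        q = np.ones(y.size)
        q[in_support] = bh_fdr(p_in)

        excluded = in_support & (q <= exclusion_fdr)
        iterations.append({
            "iteration": it,
            "n_background": int(background.sum()),
            "n_excluded": int(excluded.sum()),
            "theta": model.theta,
            "loglik": model.loglik,
        })
        if excluded.sum() > 0.5 * in_support.sum():
            raise BackgroundShrinkageError(
                f"{excluded.sum()} of {in_support.sum()} in-support genes "
                "exceed the exclusion threshold; background is not a null set"
            )
        new_background = in_support & ~excluded
        if new_background.sum() < 10 * n_coef:
            raise BackgroundShrinkageError(
                "background shrank below 10 rows per coefficient"
            )
        if frozenset(np.where(excluded)[0]) == prev_excluded:
            converged_rec = True
            background = new_background
            break
        prev_excluded = frozenset(np.where(excluded)[0])
        background = new_background
        if not recursive:
            converged_rec = True
            break
    else:
        warnings.warn("recursive background purification hit the iteration cap")

    mu_hat = model.predict_mu(X)
    scores = pd.DataFrame({
        "y": y, "mu_hat": mu_hat, "e": e, "e_std": e_std, "p": p, "q": q,
        "in_support": in_support, "background": background,
    }, index=table.index)
    return RecursiveFitResult(model=model, scores=scores,
                              iterations=iterations, converged=converged_rec)


# ---------------------------------------------------------------------------
# Grid search over (b, t)
# ---------------------------------------------------------------------------

@dataclass
class GridPoint:
    b: float
    t: int
    mlfc: float = np.inf
    n_significant: int = -1
    failed: bool = False
    error: str = ""
    rank_mlfc: int = 0
    rank_sig: int = 0

    @property
    def rank_sum(self) -> int:
        return self.rank_mlfc + self.rank_sig


def grid_candidates(b_values=None, t_values=None) -> list[tuple[float, int]]:
    """Enumerate the (b, t) grid; defaults give the canonical 120 cells."""
    bs = tuple(b_values) if b_values is not None else DEFAULT_B_GRID
    ts = tuple(t_values) if t_values is not None else DEFAULT_T_GRID
    if any(not (0 < b <= 1) for b in bs):
        raise DomainError("b grid values must lie in (0, 1]")
    if any(t < 0 for t in ts):
        raise DomainError("t grid values must be >= 0")
    return [(float(b), int(t)) for b in bs for t in ts]


def rank_grid(points: list[GridPoint]) -> tuple[float, int]:
    """Competition-rank the grid and return the chosen (b, t).

    MLFC is ranked ascending, significant-gene count descending; ties share
    the smallest rank.  The winner minimizes the rank sum; residual ties are
    broken by smaller MLFC, then smaller b, then smaller t.  Failed cells
    rank last on both axes.
    """
    ml = np.array([np.inf if pt.failed else pt.mlfc for pt in points])
    ns = np.array([-1 if pt.failed else pt.n_significant for pt in points])
    r_ml = rankdata(ml, method="min")
    r_ns = rankdata(-ns, method="min")
    for pt, a, b_ in zip(points, r_ml, r_ns):
        pt.rank_mlfc, pt.rank_sig = int(a), int(b_)
    order = sorted(
        (pt for pt in points if not pt.failed),
        key=lambda pt: (pt.rank_sum, pt.mlfc, pt.b, pt.t),
    )
    if not order:
        raise BackgroundShrinkageError("every grid cell failed")
    best = order[0]
    return best.b, best.t


def grid_search(records: pd.DataFrame, annotation: pd.DataFrame, *,
                weight_config: WeightConfig | None = None,
                b_values=None, t_values=None,
                panels: list[str] | None = None,
                exclusion_fdr: float = 0.1, sig_fdr: float = 0.05,
                fast: bool = False) -> tuple[list[GridPoint], tuple[float, int]]:
    """Evaluate every (b, t) cell and pick the optimum by rank sum.

    Each cell rebuilds weights, counts and the frequency score for its
    ``b``, runs the recursive procedure at its ``t`` (a single
    non-recursive fit when ``fast=True`` — exploratory only), and records
    the background-gene MLFC and the count of genes with ``q <= sig_fdr``.
    Cells that fail a precondition are recorded and ranked last.
    """
    base = weight_config or WeightConfig()
    # filters and imputation do not depend on (b, t): run them once
    rec = _burden.filter_consequence(records, base.consequences)
    rec = _burden.filter_rare(rec, base.rare_af_max, panels)
    rec = _burden.filter_case_enriched(rec, base.d, base.enrichment_mode)
    rec = _burden.impute_missing_scores(rec)

    points: list[GridPoint] = []
    cells = grid_candidates(b_values, t_values)
    for b in sorted({b for b, _ in cells}):
        w = _burden.score_to_weight(rec["score"].to_numpy(), b, base.equal_weights)
        counts = _burden.weighted_gene_counts(rec, w)
        x2 = _burden.frequency_score(rec, w, panels)
        pred = _burden.assemble_predictors(annotation, x2)
        table = pred.join(counts, how="left")
        for c in ("y", "y_raw", "m"):
            table[c] = table[c].fillna(0).astype(np.int64)
        for t in sorted({t for bb, t in cells if bb == b}):
            pt = GridPoint(b=b, t=t)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = recursive_fit(table, t, exclusion_fdr=exclusion_fdr,
                                        recursive=not fast)
                sc = fit.scores
                bg_p = np.clip(sc.loc[sc["background"], "p"].to_numpy(), _P_FLOOR, 1.0)
                pt.mlfc = mlfc(bg_p)
                pt.n_significant = int((sc.loc[sc["in_support"], "q"] <= sig_fdr).sum())
            except (DomainError, BackgroundShrinkageError, ArithmeticError) as err:
                pt.failed = True
                pt.error = str(err)
            points.append(pt)
    chosen = rank_grid(points)
    return points, chosen


# ---------------------------------------------------------------------------
# End-to-end runner
# ---------------------------------------------------------------------------

RESULT_COLUMNS = (
    "gene", "minor_alleles", "missense_alleles", "lof_alleles",
    "weighted_alleles", "region_length", "mu_mis", "mu_lof",
    "oe_mis", "oe_lof", "exon_gc", "residual", "p", "q", "background_flag",
)


@dataclass
class RunnerResult:
    """Everything the full test produces for one dataset."""

    results: pd.DataFrame           # Table-1-style per-gene report
    scores: pd.DataFrame            # raw per-gene scores (recursive_fit output)
    model: TNBModel
    b: float
    t: int
    grid: list | None
    iterations: list
    manifest: dict


def _results_table(table: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame({
        "gene": table.index,
        "minor_alleles": table["y_raw"].to_numpy(),
        "missense_alleles": table.get("missense_alleles", pd.Series(0, index=table.index)).to_numpy(),
        "lof_alleles": table.get("lof_alleles", pd.Series(0, index=table.index)).to_numpy(),
        "weighted_alleles": table["y"].to_numpy(),
        "region_length": table["x1"].to_numpy(),
        "mu_mis": table["x5"].to_numpy(),
        "mu_lof": table["x7"].to_numpy(),
        "oe_mis": table["x4"].to_numpy(),
        "oe_lof": table["x6"].to_numpy(),
        "exon_gc": table["x8"].to_numpy(),
        "residual": scores["e_std"].to_numpy(),
        "p": scores["p"].to_numpy(),
        "q": scores["q"].to_numpy(),
        "background_flag": scores["background"].to_numpy(),
    })
    return out.sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)


def run_runner(records: pd.DataFrame, annotation: pd.DataFrame, *,
               weight_config: WeightConfig | None = None,
               panels: list[str] | None = None,
               b: float | None = None, t: int | None = None,
               b_values=None, t_values=None,
               exclusion_fdr: float = 0.1, fast_grid: bool = False) -> RunnerResult:
    """Full pipeline: prepare -> (grid search | fixed b,t) -> recursive fit.

    Supplying both ``b`` and ``t`` skips the grid search (the manifest
    records the override).  Deterministic for identical inputs and options.
    """
    config = weight_config or WeightConfig()
    grid_points = None
    if b is None or t is None:
        grid_points, (b, t) = grid_search(
            records, annotation, weight_config=config,
            b_values=b_values, t_values=t_values, panels=panels,
            exclusion_fdr=exclusion_fdr, fast=fast_grid,
        )
        override = False
    else:
        override = True

    cell_config = WeightConfig(
        b=b, equal_weights=config.equal_weights, d=config.d,
        rare_af_max=config.rare_af_max, consequences=config.consequences,
        enrichment_mode=config.enrichment_mode,
    )
    table = _burden.prepare_burden_table(records, annotation, cell_config, panels)
    fit = recursive_fit(table, t, exclusion_fdr=exclusion_fdr)
    fit.model.b = b
    results = _results_table(table, fit.scores)
    manifest = {
        "b": b, "t": t, "fixed_bt_override": override,
        "equal_weights": config.equal_weights,
        "exclusion_fdr": exclusion_fdr,
        "n_genes": int(len(table)),
        "n_in_support": int(fit.scores["in_support"].sum()),
        "n_background": int(fit.scores["background"].sum()),
        "model": {"beta": fit.model.beta.tolist(), "theta": fit.model.theta,
                  "converged": fit.model.converged, "loglik": fit.model.loglik},
        "iterations": fit.iterations,
    }
    return RunnerResult(results=results, scores=fit.scores, model=fit.model,
                        b=b, t=t, grid=grid_points, iterations=fit.iterations,
                        manifest=manifest)
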