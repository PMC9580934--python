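"""Scoring of association tables against ground truth, plus the
cross-dataset validation-rate curve and the directionality diagnostic.

A call counts as a true positive only when both the CpG *and* the cell type
match a truth entry: the benchmark scores cell-type-level localization, not
CpG-level detection. PPV is recorded as missing (NaN), never as zero, when a
method makes no calls at all.
"""

from __future__ import annotations

import traceback
from typing import Dict, Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import celldmc as _celldmc
from . import tca as _tca
from .exceptions import IndexMismatchError, ParameterError
from .simulate import ScenarioConfig, SyntheticCohort, simulate_cohort

__all__ = [
    "call_significant",
    "truth_table",
    "confusion_metrics",
    "validation_rate",
    "directionality_diagnosis",
    "run_methods",
    "run_benchmark",
    "summarize_benchmark",
]

_CORRECTIONS = ("bonferroni", "bh", "none")


def call_significant(table: pd.DataFrame, alpha: float = 0.05,
                     correction: str = "bonferroni") -> pd.DataFrame:
    """Return a copy of the table with a boolean ``significant`` column.

    The correction is applied jointly over all m x k tests in the table:
    ``bonferroni``, ``bh`` (Benjamini-Hochberg step-up) or ``none``.
    """
    if correction not in _CORRECTIONS:
        raise ParameterError(
            f"unknown correction {correction!r}; choose from {_CORRECTIONS}")
    p = np.asarray(table["p_value"], dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    if correction == "none":
        flags = p < alpha
    else:
        method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[correction]
        flags = multipletests(p, alpha=alpha, method=method)[0]
    out = table.copy()
    out["significant"] = flags
    return out


def truth_table(truth, cpg_ids: Sequence[str],
                celltype_ids: Sequence[str]) -> pd.DataFrame:
    """Long-format truth: columns cpg, cell_type, beta for nonzero entries."""
    beta = truth.beta if hasattr(truth, "beta") else np.asarray(truth)
    jj, hh = np.nonzero(beta)
    return pd.DataFrame({
        "cpg": [cpg_ids[j] for j in jj],
        "cell_type": [celltype_ids[h] for h in hh],
        "beta": beta[jj, hh],
    })


def _pair_index(table: pd.DataFrame) -> pd.MultiIndex:
    idx = pd.MultiIndex.from_arrays([table["cpg"], table["cell_type"]])
    if idx.has_duplicates:
        raise IndexMismatchError("duplicate (cpg, cell_type) rows in table")
    return idx


def confusion_metrics(table: pd.DataFrame, truth: pd.DataFrame) -> Dict[str, float]:
    """SE/SP/PPV of the ``significant`` calls against the truth table.

    ``truth`` holds one row per true (cpg, cell_type) pair (see
    :func:`truth_table`); every truth pair must exist in the table's
    (cpg, cell_type) universe.
    """
    if "significant" not in table:
        raise ParameterError("table has no 'significant' column; "
                             "run call_significant first")
    idx = _pair_index(table)
    truth_pairs = set(zip(truth["cpg"], truth["cell_type"]))
    universe = set(idx)
    if not truth_pairs <= universe:
        missing = sorted(truth_pairs - universe)[:3]
        raise IndexMismatchError(
            f"truth pairs absent from the association table, e.g. {missing}")
    is_true = np.array([pair in truth_pairs for pair in idx])
    called = np.asarray(table["significant"], dtype=bool)
    tp = int(np.sum(called & is_true))
    fp = int(np.sum(called & ~is_true))
    fn = int(np.sum(~called & is_true))
    tn = int(np.sum(~called & ~is_true))
    se = tp / (tp + fn) if (tp + fn) else np.nan
    sp = tn / (tn + fp) if (tn + fp) else np.nan
    ppv = tp / (tp + fp) if (tp + fp) else np.nan  # missing, not 0, on no calls
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "se": se, "sp": sp, "ppv": ppv, "n_calls": tp + fp}


def _top_pairs(table: pd.DataFrame, t: int) -> set:
    """The t smallest-p (cpg, cell_type) pairs, ties broken lexicographically."""
    ordered = table.sort_values(["p_value", "cpg", "cell_type"],
                                kind="mergesort")
    head = ordered.head(t)
    return set(zip(head["cpg"], head["cell_type"]))


def validation_rate(table_a: pd.DataFrame, table_b: pd.DataFrame,
                    t_values: Iterable[int]) -> pd.DataFrame:
    """Top-t replication curve between two association tables.

    For each t, the rate is the fraction of the t most significant
    (CpG, cell type) pairs shared by both tables; a pair replicates only if
    the same CpG is called in the same cell type in both.
    """
    idx_a, idx_b = _pair_index(table_a), _pair_index(table_b)
    if set(idx_a) != set(idx_b):
        raise IndexMismatchError(
            "tables do not share the same (cpg, cell_type) universe")
    total = len(idx_a)
    t_values = [int(t) for t in t_values]
    rows = []
    for t in t_values:
        if not 1 <= t <= total:
            raise ParameterError(f"t={t} outside [1, {total}]")
        inter = _top_pairs(table_a, t) & _top_pairs(table_b, t)
        rows.append({"t": t, "rate": len(inter) / t})
    return pd.DataFrame(rows)


def directionality_diagnosis(table_celldmc: pd.DataFrame,
                             table_tca_xgy: pd.DataFrame, t: int,
                             hi: float = 0.8, lo: float = 0.2) -> dict:
    """Method-consistency diagnostic for the true model directionality.

    High top-t overlap between the interaction regression and the latent
    model run as X|Y is evidence the X|Y assumption holds; low overlap
    (CellDMC reporting many associations the latent model does not) points
    to Y|X. Thresholds are declared heuristics, surfaced in the output.
    """
    score = float(validation_rate(table_celldmc, table_tca_xgy, [t])["rate"].iloc[0])
    if score >= hi:
        verdict = "supports_XgY"
    elif score <= lo:
        verdict = "supports_YgX"
    else:
        verdict = "inconclusive"
    return {"score": score, "verdict": verdict, "t": int(t),
            "threshold_high": hi, "threshold_low": lo}


def run_methods(cohort: SyntheticCohort,
                methods: Sequence[str] = ("celldmc", "tca_xgy", "tca_ygx"),
                ) -> Dict[str, pd.DataFrame]:
    """Fit the requested association methods on one cohort.

    The latent-model fit is shared between ``tca_xgy`` and ``tca_ygx``.
    """
    out: Dict[str, pd.DataFrame] = {}
    ids = dict(cpg_ids=cohort.cpg_ids, celltype_ids=cohort.celltype_ids)
    params = None
    if "celldmc" in methods:
        out["celldmc"] = _celldmc.fit_interaction_model(
            cohort.X, cohort.W, cohort.y, cohort.covariates, **ids)
    if "tca_xgy" in methods or "tca_ygx" in methods:
        params = _tca.fit_tca(cohort.X, cohort.W, cohort.covariates)
    if "tca_xgy" in methods:
        out["tca_xgy"] = _tca.tca_test_xgy(
            cohort.X, cohort.W, cohort.y, cohort.covariates, params=params, **ids)
    if "tca_ygx" in methods:
        tensor = _tca.estimate_tensor(cohort.X, cohort.W, params,
                                      cohort.covariates)
        out["tca_ygx"] = _tca.tca_test_ygx(
            tensor, cohort.y, cohort.covariates, **ids)
    return out


def run_benchmark(configs: Sequence[ScenarioConfig], n_reps: int,
                  master_seed: int = 0,
                  methods: Sequence[str] = ("celldmc", "tca_xgy", "tca_ygx"),
                  alpha: float = 0.05, correction: str = "bonferroni",
                  ) -> pd.DataFrame:
    """Simulate-fit-score over a grid of scenarios.

    For each scenario cell and replicate r the cohort seed is
    ``master_seed + r`` (a fixed, documented derivation); each requested
    method is fitted, thresholded jointly over its m x k tests, and scored
    against the cohort's truth. Failures are recorded (``failed=True``) and
    the run continues.

    Returns a tidy table with one row per (scenario cell, method, replicate).
    """
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    rows = []
    for config in configs:
        for r in range(n_reps):
            seed = int(master_seed) + r
            cfg = config.with_seed(seed)
            base = {
                "direction": cfg.direction, "scenario": cfg.scenario,
                "effect_size": cfg.effect_size, "replicate": r, "seed": seed,
            }
            try:
                cohort = simulate_cohort(cfg)
                tables = run_methods(cohort, methods)
                truth = truth_table(cohort.truth, cohort.cpg_ids,
                                    cohort.celltype_ids)
                for method, table in tables.items():
                    called = call_significant(table, alpha, correction)
                    metrics = confusion_metrics(called, truth)
                    rows.append({**base, "method": method, "failed": False,
                                 **metrics})
            except Exception:  # noqa: BLE001 — a replicate failure must not kill the run
                rows.append({**base, "method": None, "failed": True,
                             "error": traceback.format_exc(limit=3)})
    return pd.DataFrame(rows)


def summarize_benchmark(results: pd.DataFrame) -> pd.DataFrame:
    """Median SE/SP/PPV per (direction, scenario, effect_size, method)."""
    ok = results[~results["failed"]]
    grouped = ok.groupby(["direction", "scenario", "effect_size", "method"],
                         dropna=False)
    return grouped[["se", "sp", "ppv"]].median().reset_index()
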