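"""Covariate-adjusted group comparisons, FDR, and brain-behavior correlation.

The analysis layer that sits on top of the per-subject metric tables:

* one-way ANOVA of a metric across the three groups with age and sex as
  nuisance covariates (an ANCOVA: the group effect is the extra-sum-of-
  squares F of the group indicators against the covariate-only model);
* gatekept post-hoc pairwise contrasts from the same adjusted linear model,
  with Bonferroni or Benjamini-Hochberg correction;
* Benjamini-Hochberg FDR adjustment across region families for nodal
  metrics;
* Spearman rank correlations between network metrics and cognitive scores
  (reported uncorrected, as is conventional for exploratory brain-behavior
  tables);
* hub-set comparison across groups (shared / gained / lost nodes);
* a chi-square test of sex composition for the demographics table.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .metrics import (
    GLOBAL_METRIC_NAMES,
    SparsityGrid,
    auc,
    metric_curves,
)
from .matrix import ConnectivityMatrix

__all__ = [
    "DesignError",
    "GroupTestResult",
    "build_metric_table",
    "ancova_group_effect",
    "posthoc_pairwise",
    "fdr_adjust",
    "spearman_corr",
    "compare_hubs",
    "sex_chi2",
    "group_summary_table",
]

logger = logging.getLogger(__name__)


class DesignError(ValueError):
    """Rank-deficient or otherwise unusable design matrix."""


@dataclass(frozen=True)
class GroupTestResult:
    metric: str
    f_value: float
    p_value: float
    posthoc: pd.DataFrame | None  # None when gatekept out


# ---------------------------------------------------------------------------
# metric table


def build_metric_table(
    matrices,
    subject_ids,
    grid: SparsityGrid,
    metrics: tuple[str, ...] = GLOBAL_METRIC_NAMES,
    include_nodal: bool = False,
) -> pd.DataFrame:
    """Per-subject AUC summaries of global (and optionally nodal) metrics.

    Columns are ``auc_<metric>`` for the global measures and, when
    ``include_nodal`` is set, ``eff_<label>`` / ``bc_<label>`` per region
    (AUC across the same sparsity grid).
    """
    rows = []
    for sid, m in zip(subject_ids, matrices):
        if not isinstance(m, ConnectivityMatrix):
            m = ConnectivityMatrix(m)
        curve = metric_curves(m, grid, include_nodal=include_nodal, metrics=metrics)
        row: dict[str, float | str] = {"subject_id": sid}
        for name in metrics:
            row[f"auc_{name}"] = auc(curve.table[name].to_numpy(), grid)
        if include_nodal:
            s_values = grid.values()
            eff = np.stack([curve.nodal[float(s)].efficiency for s in s_values])
            bc = np.stack([curve.nodal[float(s)].betweenness for s in s_values])
            for k, lab in enumerate(m.labels):
                row[f"eff_{lab}"] = auc(eff[:, k], grid)
                row[f"bc_{lab}"] = auc(bc[:, k], grid)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# adjusted group tests


def _design_matrices(
    groups: np.ndarray, covariates: pd.DataFrame | None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Full (intercept + group dummies + covariates) and reduced designs.

    Zero-variance covariates are dropped with a warning so that
    informationless covariates reproduce the plain ANOVA exactly.  Sex given
    as strings is coded 0/1.
    """
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    if len(levels) < 2:
        raise DesignError("need at least 2 groups")
    dummies = np.column_stack([(groups == g).astype(float) for g in levels[1:]])
    cov_cols: list[np.ndarray] = []
    cov_names: list[str] = []
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                vals = sorted(set(col))
                if len(vals) > 2:
                    raise DesignError(
                        f"categorical covariate {name!r} has >2 levels"
                    )
                col = (col == vals[-1]).astype(float)
            col = np.asarray(col, dtype=float)
            if np.ptp(col) == 0:
                warnings.warn(
                    f"covariate {name!r} is constant and was dropped",
                    stacklevel=3,
                )
                continue
            cov_cols.append(col)
            cov_names.append(name)
    n = groups.size
    intercept = np.ones((n, 1))
    reduced = np.hstack([intercept] + [c[:, None] for c in cov_cols]) if cov_cols else intercept
    full = np.hstack([intercept, dummies] + [c[:, None] for c in cov_cols])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise DesignError("rank-deficient design (collinear covariates?)")
    return full, reduced, levels


def ancova_group_effect(
    values,
    groups,
    covariates: pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Group F-test adjusted for covariates (extra sum of squares).

    Fits ``y ~ group + covariates`` and ``y ~ covariates`` by OLS and tests
    the group indicators jointly.  With informationless covariates this is
    exactly the one-way ANOVA F.
    """
    y = np.asarray(values, dtype=float)
    full, reduced, levels = _design_matrices(np.asarray(groups), covariates)
    for g in levels:
        if (np.asarray(groups) == g).sum() < 3:
            raise DesignError(f"need >= 3 subjects per group (group {g!r})")
    fit_full = sm.OLS(y, full).fit()
    fit_red = sm.OLS(y, reduced).fit()
    df_num = len(levels) - 1
    df_den = int(fit_full.df_resid)
    if fit_full.ssr <= 0:
        raise DesignError("zero residual variance in the full model")
    f = ((fit_red.ssr - fit_full.ssr) / df_num) / (fit_full.ssr / df_den)
    p = float(sps.f.sf(f, df_num, df_den))
    return float(f), p


def posthoc_pairwise(
    values,
    groups,
    covariates: pd.DataFrame | None = None,
    correction: str = "fdr",
    gatekeep: bool = True,
    omnibus_alpha: float = 0.05,
) -> pd.DataFrame | None:
    """All pairwise contrasts from the same covariate-adjusted linear model.

    When ``gatekeep`` is set the post-hoc table is produced only if the
    omnibus test rejects at ``omnibus_alpha`` (returns None otherwise),
    mirroring the ANOVA-then-post-hoc workflow.  ``correction`` is
    ``"bonferroni"`` or ``"fdr"`` (Benjamini-Hochberg).
    """
    if correction not in ("bonferroni", "fdr"):
        raise ValueError(f"unknown correction {correction!r}")
    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if gatekeep:
        _, p_omni = ancova_group_effect(y, groups, covariates)
        if p_omni >= omnibus_alpha:
            return None
    full, _, levels = _design_matrices(groups, covariates)
    fit = sm.OLS(y, full).fit()
    # column 0 intercept; columns 1..k-1 are dummies for levels[1:]
    coef_index = {g: i for i, g in enumerate(levels[1:], start=1)}
    rows = []
    for g1, g2 in itertools.combinations(levels, 2):
        contrast = np.zeros(full.shape[1])
        if g1 in coef_index:
            contrast[coef_index[g1]] = 1.0
        if g2 in coef_index:
            contrast[coef_index[g2]] -= 1.0
        test = fit.t_test(contrast)
        est = float(np.squeeze(test.effect))
        rows.append(
            {
                "contrast": f"{g1} vs {g2}",
                "estimate": est,
                "t": float(np.squeeze(test.tvalue)),
                "p_raw": float(np.squeeze(test.pvalue)),
                "direction": f"{g1} > {g2}" if est > 0 else f"{g2} > {g1}",
            }
        )
    table = pd.DataFrame(rows)
    if correction == "bonferroni":
        table["p_corrected"] = np.minimum(table["p_raw"] * len(table), 1.0)
    else:
        table["p_corrected"] = fdr_adjust(table["p_raw"].to_numpy())
    return table


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_corr(metric_values, scores) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties; two-sided t-approx p.

    Returns ``(nan, nan)`` with a warning when either input has no variance.
    """
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must be paired")
    if x.size < 5:
        raise ValueError("need at least 5 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def compare_hubs(hub_sets: dict[str, set | tuple]) -> dict:
    """Shared hubs and, per ordered group pair, gained and lost nodes."""
    sets = {g: set(v) for g, v in hub_sets.items()}
    names = list(sets)
    shared = set.intersection(*sets.values()) if sets else set()
    pairs = {}
    for g1, g2 in itertools.permutations(names, 2):
        pairs[f"{g1}->{g2}"] = {
            "lost": sorted(sets[g1] - sets[g2]),
            "gained": sorted(sets[g2] - sets[g1]),
        }
    return {"shared": sorted(shared), "pairs": pairs}


def sex_chi2(phenotypes: pd.DataFrame) -> tuple[float, float]:
    """Chi-square test of sex composition across groups."""
    table = pd.crosstab(phenotypes["group"], phenotypes["sex"])
    chi2, p, _, _ = sps.chi2_contingency(table)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# report assembly


def group_summary_table(
    metric_table: pd.DataFrame,
    phenotypes: pd.DataFrame,
    metric_columns: list[str] | None = None,
    covariate_columns: tuple[str, ...] = ("age", "sex"),
    correction: str = "fdr",
    gatekeep: bool = True,
) -> pd.DataFrame:
    """Per-metric group means +/- SD, adjusted omnibus F/p, post-hoc flags.

    One row per metric column, shaped like the summary tables of structural
    connectome group studies.
    """
    merged = metric_table.merge(phenotypes, on="subject_id", validate="1:1")
    groups = merged["group"].to_numpy()
    cov = merged[list(covariate_columns)] if covariate_columns else None
    if metric_columns is None:
        metric_columns = [
            c for c in metric_table.columns if c != "subject_id"
        ]
    level_order = [g for g in ("HC", "NC", "MCI") if g in set(groups)] or sorted(
        set(groups)
    )
    rows = []
    for col in metric_columns:
        y = merged[col].to_numpy(dtype=float)
        try:
            f, p = ancova_group_effect(y, groups, cov)
        except DesignError:
            # degenerate metric (e.g. a region whose value is identical in
            # every subject): report as missing rather than abort the table
            logger.warning("metric %s has a degenerate design; reported NaN", col)
            f, p = float("nan"), float("nan")
        row: dict[str, object] = {"metric": col, "F": f, "p": p}
        for g in level_order:
            vals = y[groups == g]
            row[f"{g}_mean"] = vals.mean()
            row[f"{g}_sd"] = vals.std(ddof=1)
        post = (
            posthoc_pairwise(
                y, groups, cov, correction=correction, gatekeep=gatekeep
            )
            if np.isfinite(p)
            else None
        )
        if post is not None:
            sig = post[post["p_corrected"] < 0.05]
            row["posthoc"] = "; ".join(
                f"{r.direction} (p={r.p_corrected:.4g})" for r in sig.itertuples()
            )
        else:
            row["posthoc"] = ""
        rows.append(row)
    return pd.DataFrame(rows)
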