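"""Joining steady-state expression changes with stability changes.

Quiescence induction shifts both transcription and decay; comparing the
log2(CI7/P) abundance ratio with the (shrunken) decay difference asks which
expression changes are post-transcriptional.  Genes are partitioned at a
symmetric log2 threshold (default |log2fc| > 2) into strongly up/down
regulated subsets, each summarized by the fraction of transcripts
stabilized with quiescence (delta > 0), with a binomial test against 0.5.
An overall rank correlation quantifies the (absence of) global coupling
between expression and stability changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stability_metric import scale_to_expression

__all__ = [
    "join_and_label",
    "subset_summary",
    "stability_expression_correlation",
    "focus_set_report",
    "FocusReport",
]

LFC_COL = "log2fc_CI7"


def join_and_label(
    expression: pd.DataFrame,
    metric: pd.DataFrame,
    lfc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Inner-join expression ratios with the decay metric and label subsets.

    Returns one row per shared gene with the expression columns, ``delta``,
    ``shrunken_delta``, ``scaled_delta`` (shrunken values rescaled to the
    joined genes' expression bounds), a ``subset`` label in
    {"up", "down", "other"} at the +/- ``lfc_threshold`` cut, and a
    ``concordant`` flag (stabilized with quiescence and upregulated, or
    destabilized and downregulated).
    """
    if LFC_COL not in expression.columns:
        raise ValueError(f"expression table lacks required column {LFC_COL!r}")
    shared = expression.index.intersection(metric.index)
    if len(shared) == 0:
        raise ValueError(
            f"empty join: {len(expression)} expression genes, {len(metric)} metric genes, 0 shared"
        )
    joined = expression.loc[shared].join(
        metric.loc[shared, [c for c in ("delta", "shrunken_delta", "differential") if c in metric]]
    )
    joined["scaled_delta"] = scale_to_expression(
        joined["shrunken_delta"], joined[LFC_COL]
    )
    lfc = joined[LFC_COL]
    joined["subset"] = np.select(
        [lfc > lfc_threshold, lfc < -lfc_threshold], ["up", "down"], default="other"
    )
    joined["concordant"] = ((joined["delta"] > 0) & (lfc > 0)) | (
        (joined["delta"] <= 0) & (lfc <= 0)
    )
    return joined


def subset_summary(joined: pd.DataFrame) -> pd.DataFrame:
    """Per-subset counts and stabilized-with-quiescence fractions.

    ``frac_stabilized`` is the fraction of the subset with delta > 0;
    ``binom_pvalue`` tests that fraction against 0.5 (two-sided), asking
    whether e.g. the strongly upregulated genes are preferentially
    stabilized rather than split evenly.
    """
    rows = []
    for subset, grp in joined.groupby("subset"):
        n = len(grp)
        n_stab = int((grp["delta"] > 0).sum())
        p = stats.binomtest(n_stab, n, 0.5).pvalue if n else np.nan
        rows.append(
            {
                "subset": subset,
                "n": n,
                "n_stabilized": n_stab,
                "frac_stabilized": n_stab / n if n else np.nan,
                "binom_pvalue": p,
            }
        )
    return pd.DataFrame(rows).set_index("subset")


def stability_expression_correlation(
    joined: pd.DataFrame, method: str = "spearman"
) -> tuple[float, float]:
    """Correlation of log2 expression change with the shrunken decay change.

    Returns (correlation, p-value) from the standard asymptotic test;
    (nan, nan) when either vector is constant.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    sub = joined[[LFC_COL, "shrunken_delta"]].dropna()
    if len(sub) < 10:
        raise ValueError(f"need >= 10 joined genes for a correlation, have {len(sub)}")
    x = sub[LFC_COL].to_numpy()
    y = sub["shrunken_delta"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    else:
        rho, p = stats.pearsonr(x, y)
    return float(rho), float(p)


@dataclass
class FocusReport:
    """Heatmap-ready stability/expression table for a curated gene list."""

    table: pd.DataFrame
    missing: list[str]
    frac_stabilized: float


def focus_set_report(joined: pd.DataFrame, gene_list) -> FocusReport:
    """Per-gene expression and scaled stability for a focus list.

    The table keeps the expression columns and ``scaled_delta`` (rescaled
    within the focus subset so stability shares the expression color
    bounds), ordered by expression change; genes absent from the joined
    universe are reported in ``missing``.  ``frac_stabilized`` is the
    fraction of found genes with delta > 0 (stabilized with quiescence).
    """
    gene_list = list(gene_list)
    present = [g for g in gene_list if g in joined.index]
    missing = [g for g in gene_list if g not in joined.index]
    if not present:
        raise ValueError(f"none of the {len(gene_list)} focus genes are in the joined table")
    sub = joined.loc[present]
    lfc_cols = [c for c in sub.columns if c.startswith("log2fc")]
    tab = sub[lfc_cols].copy()
    tab["scaled_delta"] = scale_to_expression(
        sub["shrunken_delta"], sub[lfc_cols].to_numpy().ravel()
    )
    tab = tab.sort_values(LFC_COL, ascending=False)
    frac = float((sub["delta"] > 0).mean())
    return FocusReport(table=tab, missing=missing, frac_stabilized=frac)
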