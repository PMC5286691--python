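"""Gene-set tests for coordinated stability changes.

Three complementary tests:

* ``ranksum_set_test`` — two-sided Wilcoxon rank-sum comparing the decay
  differences (k_P - k_CI7, usually lfdr-shrunken) of genes inside a set
  against genes outside it.  Exact null distribution when the smaller group
  has <= 10 members and values are tie-free; otherwise the normal
  approximation with tie-corrected variance.
* ``chisq_direction_test`` — Pearson chi-squared (1 df) on the 2x2 table of
  set membership against the direction of the decay difference (faster
  decay in proliferation, delta > 0, vs not).
* ``hypergeom_overrep`` — upper-tail hypergeometric over-representation of a
  term inside a cluster, the stand-in for GO-term enrichment of k-means
  clusters.

``enrich_all_sets`` runs the rank-sum test across a whole collection (e.g.
TargetScan-style miRNA families read from GMT) with Benjamini-Hochberg
adjustment across sets and a direction call from the in-set vs out-of-set
median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

__all__ = [
    "EnrichmentResult",
    "ranksum_set_test",
    "enrich_all_sets",
    "chisq_direction_test",
    "hypergeom_overrep",
    "hypergeom_all_terms",
]

STABILIZED_CI7 = "stabilized_in_CI7"
STABILIZED_P = "stabilized_in_P"


@dataclass
class EnrichmentResult:
    set_name: str
    test: str  # "ranksum" | "chisq" | "hypergeom"
    n_in_universe: int
    statistic: float
    pvalue: float
    qvalue: float = float("nan")
    direction: str = ""
    extra: dict | None = None


def _direction(values: pd.Series, in_set: np.ndarray) -> str:
    med_in = float(np.median(values[in_set]))
    med_out = float(np.median(values[~in_set]))
    return STABILIZED_CI7 if med_in > med_out else STABILIZED_P


def ranksum_set_test(
    values: pd.Series,
    set_members,
    set_name: str = "set",
    exact: str | bool = "auto",
) -> EnrichmentResult:
    """Two-sided Wilcoxon rank-sum of in-set vs out-of-set decay differences.

    ``values`` is the per-gene metric over the tested universe (index = gene
    ids); ``set_members`` selects the in-set group.  With ``exact='auto'``
    the exact Mann-Whitney null distribution is used when min(n1, n2) <= 10
    and there are no ties; ``True`` forces it (tie-free input required),
    ``False`` forces the normal approximation with tie-corrected variance.
    The reported statistic is the Mann-Whitney U of the in-set group.
    """
    members = [g for g in set_members if g in values.index]
    in_set = values.index.isin(members)
    n1, n2 = int(in_set.sum()), int((~in_set).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError(
            f"set {set_name!r}: both set (n={n1}) and complement (n={n2}) must be non-empty"
        )
    x = values[in_set].to_numpy(dtype=float)
    y = values[~in_set].to_numpy(dtype=float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < (n1 + n2)
    if exact == "auto":
        use_exact = min(n1, n2) <= 10 and not has_ties
    else:
        use_exact = bool(exact)
    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return EnrichmentResult(
        set_name=set_name,
        test="ranksum",
        n_in_universe=n1,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        direction=_direction(values, in_set),
    )


def enrich_all_sets(
    metric: pd.DataFrame,
    collection: GeneSetCollection,
    min_size: int = 10,
    universe_mode: str = "all",
    value_col: str = "shrunken_delta",
    exact: str | bool = "auto",
) -> pd.DataFrame:
    """Rank-sum test of every sufficiently large set in a collection.

    ``universe_mode='all'`` tests over every gene in the metric table
    (filter-passing genes); ``'differential'`` restricts the universe to
    genes called differential.  P-values are Benjamini-Hochberg adjusted
    across the sets actually tested.  Returns a table sorted by p-value.
    """
    if universe_mode not in ("all", "differential"):
        raise ValueError("universe_mode must be 'all' or 'differential'")
    values = metric[value_col].dropna()
    if universe_mode == "differential":
        if "differential" not in metric.columns:
            raise ValueError("metric table lacks a 'differential' column")
        values = values[metric.loc[values.index, "differential"]]
    results: list[EnrichmentResult] = []
    for name, members in collection:
        n_in = sum(1 for g in members if g in values.index)
        if n_in < min_size or n_in == len(values):
            continue
        results.append(ranksum_set_test(values, members, set_name=name, exact=exact))
    if not results:
        warnings.warn("no sets met min_size on the tested universe", stacklevel=2)
        return pd.DataFrame(
            columns=["n_in_universe", "statistic", "pvalue", "qvalue", "direction", "planted"]
        )
    _, qvals, _, _ = multipletests([r.pvalue for r in results], method="fdr_bh")
    for r, q in zip(results, qvals):
        r.qvalue = float(q)
    tab = pd.DataFrame(
        {
            "n_in_universe": [r.n_in_universe for r in results],
            "statistic": [r.statistic for r in results],
            "pvalue": [r.pvalue for r in results],
            "qvalue": [r.qvalue for r in results],
            "direction": [r.direction for r in results],
            "planted": [r.set_name in collection.planted for r in results],
        },
        index=pd.Index([r.set_name for r in results], name="set"),
    )
    return tab.sort_values("pvalue")


def chisq_direction_test(
    deltas: pd.Series,
    set_members,
    set_name: str = "set",
    continuity: bool = False,
) -> EnrichmentResult:
    """Chi-squared independence test of set membership vs decay direction.

    Builds the 2x2 table (member / non-member) x (delta > 0 / delta <= 0)
    and applies Pearson's chi-squared with 1 df (no continuity correction by
    default).  A zero margin makes the test undefined and is rejected.
    """
    in_set = deltas.index.isin(list(set_members))
    pos = deltas.to_numpy(dtype=float) > 0
    table = np.array(
        [
            [int((in_set & pos).sum()), int((in_set & ~pos).sum())],
            [int((~in_set & pos).sum()), int((~in_set & ~pos).sum())],
        ]
    )
    for axis, margin in ((0, table.sum(axis=1)), (1, table.sum(axis=0))):
        if (margin == 0).any():
            which = "row (membership)" if axis == 0 else "column (direction)"
            raise ValueError(f"degenerate {which} margin in the 2x2 table: {table.tolist()}")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=continuity)
    return EnrichmentResult(
        set_name=set_name,
        test="chisq",
        n_in_universe=int(in_set.sum()),
        statistic=float(chi2),
        pvalue=float(p),
        direction=_direction(deltas, in_set),
        extra={"table": table.tolist(), "dof": int(dof)},
    )


def hypergeom_overrep(
    cluster_members,
    term_members,
    universe,
    term_name: str = "term",
) -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation of a term in a cluster.

    P(overlap >= observed) drawing |cluster| genes from a universe
    containing |term| term members.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    cluster = set(cluster_members) & uni
    term = set(term_members) & uni
    overlap = len(cluster & term)
    p = float(stats.hypergeom.sf(overlap - 1, len(uni), len(term), len(cluster)))
    return EnrichmentResult(
        set_name=term_name,
        test="hypergeom",
        n_in_universe=len(term),
        statistic=float(overlap),
        pvalue=min(p, 1.0),
        extra={"n_cluster": len(cluster), "n_universe": len(uni)},
    )


def hypergeom_all_terms(
    cluster_members,
    collection: GeneSetCollection,
    universe=None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of every term, BH across terms."""
    uni = list(universe) if universe is not None else list(collection.universe)
    results = [
        hypergeom_overrep(cluster_members, members, uni, term_name=name)
        for name, members in collection
    ]
    if not results:
        return pd.DataFrame(columns=["n_in_universe", "overlap", "pvalue", "qvalue"])
    _, qvals, _, _ = multipletests([r.pvalue for r in results], method="fdr_bh")
    tab = pd.DataFrame(
        {
            "n_in_universe": [r.n_in_universe for r in results],
            "overlap": [int(r.statistic) for r in results],
            "pvalue": [r.pvalue for r in results],
            "qvalue": qvals,
        },
        index=pd.Index([r.set_name for r in results], name="term"),
    )
    return tab.sort_values("pvalue")
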