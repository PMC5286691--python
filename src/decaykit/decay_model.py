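"""Per-gene log-linear decay fitting and differential-stability testing.

First-order decay gives A(t) = A0 * exp(-k t), so natural-log intensities
are affine in time.  Each gene is fit by ordinary least squares to

    ln I = mu + alpha_replicate + gamma_condition
           + beta_1 * t * 1[cond = c1] + beta_2 * t * 1[cond = c2] + eps

with decay constants k_c = -beta_c (per minute, natural-log scale).  Two
nested F-tests are computed per gene:

* ``fit_pvalue`` — joint time effect, full model vs the model with both
  slopes removed.  Genes whose intensities carry no resolvable time trend
  (p > alpha) are filtered as poor fits to log-linear decay.
* ``interaction_pvalue`` — condition x time interaction, full model vs a
  single shared slope.  Significance (after Benjamini-Hochberg adjustment
  over filter-passing genes) flags a differential decay rate between the
  two cell states.

Per-replicate decay constants for profile clustering come from independent
simple regressions of ln I on t within each (condition, replicate) series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import COND_COL, REP_COL, TIME_COL, TimeCourseDataset

__all__ = [
    "GeneDecayFit",
    "fit_gene",
    "fit_all",
    "test_differential",
    "halflife",
    "spikein_normalize",
    "FitSummary",
]

LN2 = np.log(2.0)


def halflife(k: float | np.ndarray) -> float | np.ndarray:
    """Half-life in minutes, ln(2)/k; NaN marks k <= 0 (no defined half-life)."""
    k = np.asarray(k, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(k > 0, LN2 / k, np.nan)
    return float(out) if out.ndim == 0 else out


@dataclass
class GeneDecayFit:
    """Decay-model fit for one gene."""

    gene: str
    k_P: float
    k_CI7: float
    halflife_P: float
    halflife_CI7: float
    replicate_k: dict[str, float]  # "<cond>_rep<r>" -> k from a simple per-series fit
    fit_pvalue: float
    interaction_pvalue: float
    n_samples_used: int
    fittable: bool = True
    interaction_qvalue: float = np.nan
    passed_filter: bool = False
    differential: bool = False


class _DesignMatrices:
    """Shared design matrices for the full and nested models.

    Column layout of the full model: intercept, replicate dummies (first
    replicate as baseline), condition dummy (second condition), t*1[cond1],
    t*1[cond2].
    """

    def __init__(self, design: pd.DataFrame, conditions: tuple[str, str]):
        self.samples = design.index
        t = design[TIME_COL].to_numpy(dtype=float)
        cond = design[COND_COL].to_numpy()
        reps = design[REP_COL].to_numpy()
        c1, c2 = conditions
        unknown = set(cond) - {c1, c2}
        if unknown:
            raise ValueError(f"design contains unknown conditions {sorted(unknown)}")

        cols = [np.ones_like(t)]
        self.base_names = ["intercept"]
        for r in sorted(pd.unique(reps))[1:]:
            cols.append((reps == r).astype(float))
            self.base_names.append(f"rep[{r}]")
        cols.append((cond == c2).astype(float))
        self.base_names.append(f"cond[{c2}]")
        base = np.column_stack(cols)

        slope1 = t * (cond == c1)
        slope2 = t * (cond == c2)
        shared = t.astype(float)

        self.full = np.column_stack([base, slope1, slope2])
        self.no_time = base
        self.shared_slope = np.column_stack([base, shared])
        self.names = self.base_names + [f"slope[{c1}]", f"slope[{c2}]"]
        self.conditions = conditions
        self.t = t
        self.cond = cond
        self.reps = reps


def _ols_rss(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Least-squares fit of every column of Y on X.

    Returns (coef p x m, rss length m, rank of X).
    """
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    rss = np.einsum("ij,ij->j", resid, resid)
    return coef, rss, rank


def _f_test(rss_red: np.ndarray, rss_full: np.ndarray, df_diff: int,
            df_resid: int) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_red - rss_full) / df_diff) / (rss_full / df_resid)
    f = np.clip(f, 0.0, None)  # guard tiny negative from round-off
    p = stats.f.sf(f, df_diff, df_resid)
    return f, p


def _fit_block(Y: np.ndarray, dm: _DesignMatrices) -> dict[str, np.ndarray]:
    """Fit the three nested models to a genes-in-columns ln-intensity block."""
    n_obs = Y.shape[0]
    coef, rss_full, rank_full = _ols_rss(dm.full, Y)
    df_resid = n_obs - rank_full
    if df_resid <= 0:
        raise ValueError("design leaves no residual degrees of freedom")
    _, rss_notime, rank_nt = _ols_rss(dm.no_time, Y)
    _, rss_shared, rank_sh = _ols_rss(dm.shared_slope, Y)
    _, fit_p = _f_test(rss_notime, rss_full, rank_full - rank_nt, df_resid)
    _, int_p = _f_test(rss_shared, rss_full, rank_full - rank_sh, df_resid)
    return {
        "k1": -coef[-2],
        "k2": -coef[-1],
        "fit_pvalue": fit_p,
        "interaction_pvalue": int_p,
        "coef": coef,
    }


def _replicate_slopes(Y: np.ndarray, dm: _DesignMatrices) -> dict[str, np.ndarray]:
    """k from an independent simple regression of ln I on t per series."""
    out: dict[str, np.ndarray] = {}
    for c in dm.conditions:
        for r in sorted(pd.unique(dm.reps)):
            mask = (dm.cond == c) & (dm.reps == r)
            if mask.sum() < 2:
                continue
            t = dm.t[mask]
            tc = t - t.mean()
            denom = float(tc @ tc)
            slopes = (tc @ Y[mask]) / denom
            out[f"k_{c}_rep{r}"] = -slopes
    return out


def fit_gene(
    y: np.ndarray | pd.Series,
    design: pd.DataFrame,
    conditions: tuple[str, str] = ("P", "CI7"),
    gene: str = "gene",
) -> GeneDecayFit:
    """Fit the decay model to one gene's natural-log intensities.

    ``y`` is aligned to ``design`` rows (a Series is reindexed to the design
    index).  Missing values are dropped; the gene is marked unfittable if the
    remaining design is rank-deficient or any (condition, replicate) series
    retains fewer than 3 time points.
    """
    if isinstance(y, pd.Series):
        y = y.reindex(design.index).to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float)
        if y.shape[0] != len(design):
            raise ValueError("y length does not match design rows")
    mask = np.isfinite(y)
    sub_design = design.loc[mask]
    counts = sub_design.groupby([COND_COL, REP_COL])[TIME_COL].nunique()
    expected_series = design.groupby([COND_COL, REP_COL]).ngroups
    if len(counts) < expected_series or (counts < 3).any():
        return _unfittable(gene, int(mask.sum()))
    dm = _DesignMatrices(sub_design, conditions)
    yv = y[mask][:, None]
    if np.linalg.matrix_rank(dm.full) < dm.full.shape[1] or (
        len(yv) - dm.full.shape[1] <= 0
    ):
        return _unfittable(gene, int(mask.sum()))
    res = _fit_block(yv, dm)
    reps = {name: float(v[0]) for name, v in _replicate_slopes(yv, dm).items()}
    k1, k2 = float(res["k1"][0]), float(res["k2"][0])
    return GeneDecayFit(
        gene=gene,
        k_P=k1,
        k_CI7=k2,
        halflife_P=halflife(k1),
        halflife_CI7=halflife(k2),
        replicate_k=reps,
        fit_pvalue=float(res["fit_pvalue"][0]),
        interaction_pvalue=float(res["interaction_pvalue"][0]),
        n_samples_used=int(mask.sum()),
    )


def _unfittable(gene: str, n_used: int) -> GeneDecayFit:
    nan = float("nan")
    return GeneDecayFit(
        gene=gene, k_P=nan, k_CI7=nan, halflife_P=nan, halflife_CI7=nan,
        replicate_k={}, fit_pvalue=nan, interaction_pvalue=nan,
        n_samples_used=n_used, fittable=False,
    )


def spikein_normalize(dataset: TimeCourseDataset) -> TimeCourseDataset:
    """Divide each sample by its spike-in median intensity.

    Spike-ins are added in equal amounts to every sample, so their median
    tracks labelling/hybridization efficiency; dividing by it removes
    per-array scale differences.  Requires at least one spike-in row.
    """
    if not dataset.spikein.any():
        raise ValueError("dataset has no spike-in rows to normalize by")
    factors = dataset.intensities.loc[dataset.spikein].median(axis=0)
    if (factors <= 0).any() or factors.isna().any():
        bad = factors.index[(factors <= 0) | factors.isna()][0]
        raise ValueError(f"non-positive spike-in median in sample {bad!r}")
    return TimeCourseDataset(
        dataset.intensities / factors, dataset.design.copy(), dataset.spikein.copy()
    )


@dataclass
class FitSummary:
    n_total: int
    n_fittable: int
    n_filtered: int
    n_retained: int


def fit_all(
    dataset: TimeCourseDataset,
    alpha_fit: float = 0.05,
    conditions: tuple[str, str] | None = None,
    normalize_spikein: bool = False,
) -> tuple[pd.DataFrame, FitSummary]:
    """Fit the decay model to every non-spike-in gene of a dataset.

    Genes with complete data are fit in one vectorized least-squares pass;
    genes with missing intensities fall back to individual fits and may be
    marked unfittable.  ``passed_filter`` is True when the time-effect F-test
    gives p <= alpha_fit; genes failing the filter are the poor log-linear
    fits excluded from differential testing.

    Returns the per-gene fits table and a count funnel
    (total -> fittable -> retained).
    """
    if dataset.intensities.shape[0] == 0:
        raise ValueError("empty dataset")
    if conditions is None:
        conds = dataset.conditions
        if len(conds) != 2:
            raise ValueError(f"expected exactly 2 conditions, found {conds}")
        conditions = (conds[0], conds[1])
    if normalize_spikein:
        dataset = spikein_normalize(dataset)

    inten = dataset.intensities.loc[~dataset.spikein]
    with np.errstate(divide="ignore"):
        ln_i = np.log(inten.to_numpy(dtype=float))
    ln_i[~np.isfinite(ln_i)] = np.nan

    design = dataset.design
    dm = _DesignMatrices(design, conditions)
    genes = inten.index
    complete = ~np.isnan(ln_i).any(axis=1)

    records: dict[str, GeneDecayFit] = {}
    if complete.any():
        Y = ln_i[complete].T  # samples x genes
        res = _fit_block(Y, dm)
        rep_k = _replicate_slopes(Y, dm)
        for i, g in enumerate(genes[complete]):
            k1, k2 = float(res["k1"][i]), float(res["k2"][i])
            records[g] = GeneDecayFit(
                gene=g, k_P=k1, k_CI7=k2,
                halflife_P=halflife(k1), halflife_CI7=halflife(k2),
                replicate_k={name: float(v[i]) for name, v in rep_k.items()},
                fit_pvalue=float(res["fit_pvalue"][i]),
                interaction_pvalue=float(res["interaction_pvalue"][i]),
                n_samples_used=Y.shape[0],
            )
    for g in genes[~complete]:
        records[g] = fit_gene(ln_i[genes.get_loc(g)], design, conditions, gene=g)

    fits = _fits_frame([records[g] for g in genes], conditions)
    fits["passed_filter"] = fits["fittable"] & (fits["fit_pvalue"] <= alpha_fit)
    summary = FitSummary(
        n_total=len(fits),
        n_fittable=int(fits["fittable"].sum()),
        n_filtered=int((fits["fittable"] & ~fits["passed_filter"]).sum()),
        n_retained=int(fits["passed_filter"].sum()),
    )
    return fits, summary


def _fits_frame(fits: list[GeneDecayFit], conditions: tuple[str, str]) -> pd.DataFrame:
    rep_cols = sorted({name for f in fits for name in f.replicate_k})
    rows = []
    for f in fits:
        row = {
            "k_P": f.k_P, "k_CI7": f.k_CI7,
            "halflife_P": f.halflife_P, "halflife_CI7": f.halflife_CI7,
            "fit_pvalue": f.fit_pvalue, "interaction_pvalue": f.interaction_pvalue,
            "n_samples_used": f.n_samples_used, "fittable": f.fittable,
        }
        for c in rep_cols:
            row[c] = f.replicate_k.get(c, np.nan)
        rows.append(row)
    frame = pd.DataFrame(rows, index=pd.Index([f.gene for f in fits], name="gene"))
    return frame


def test_differential(
    fits: pd.DataFrame, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Benjamini-Hochberg adjust interaction p-values over retained genes.

    Only filter-passing genes enter the multiple-testing family; all other
    genes get qvalue NaN and differential False.  Returns a copy of ``fits``
    with ``interaction_qvalue`` and ``differential`` columns.
    """
    out = fits.copy()
    out["interaction_qvalue"] = np.nan
    out["differential"] = False
    retained = out.index[out["passed_filter"]]
    if len(retained) == 0:
        warnings.warn("no genes passed the fit filter; nothing to test", stacklevel=2)
        return out
    pvals = out.loc[retained, "interaction_pvalue"].to_numpy()
    rejected, qvals, _, _ = multipletests(pvals, alpha=fdr_threshold, method="fdr_bh")
    out.loc[retained, "interaction_qvalue"] = qvals
    out.loc[retained, "differential"] = out.loc[retained, "interaction_qvalue"] <= fdr_threshold
    return out
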