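"""The lfdr-shrunken decay metric.

The raw decay difference delta = k_P - k_CI7 is noisy for genes whose
interaction test shows no condition effect.  To damp those, each gene's
interaction p-value is converted to a local false discovery rate (lfdr, the
posterior probability of "no stability change" given the p-value) via a
two-component beta-uniform mixture, and the difference is attenuated as

    shrunken_delta = delta * (1 - lfdr)

so that non-significant comparisons are pulled towards 0 while clearly
differential genes keep essentially their raw difference.  Positive values
mean faster decay in the proliferating state, i.e. the transcript is
stabilized with quiescence.  For display alongside log2 expression ratios,
``scale_to_expression`` linearly rescales the shrunken values to the bounds
of the expression values on the same gene subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "BetaUniformFit",
    "estimate_lfdr",
    "shrink",
    "scale_to_expression",
    "compute_metric",
]

_P_EPS = 1e-15


@dataclass
class BetaUniformFit:
    """Fitted beta-uniform mixture f(p) = pi0 + (1 - pi0) * a * p^(a-1)."""

    pi0: float
    a: float

    def density(self, p: np.ndarray) -> np.ndarray:
        p = np.clip(np.asarray(p, dtype=float), _P_EPS, 1.0)
        return self.pi0 + (1.0 - self.pi0) * self.a * p ** (self.a - 1.0)

    def lfdr(self, p: np.ndarray) -> np.ndarray:
        return np.clip(self.pi0 / self.density(p), 0.0, 1.0)


def _negloglik(theta: np.ndarray, p: np.ndarray) -> float:
    # unconstrained parametrization: pi0 = sigmoid(t0), a = sigmoid(t1)
    pi0 = 1.0 / (1.0 + np.exp(-theta[0]))
    a = 1.0 / (1.0 + np.exp(-theta[1]))
    a = np.clip(a, 1e-6, 1.0 - 1e-6)
    f = pi0 + (1.0 - pi0) * a * p ** (a - 1.0)
    return -float(np.sum(np.log(np.clip(f, 1e-300, None))))


def fit_beta_uniform(pvalues: np.ndarray) -> BetaUniformFit:
    """Maximum-likelihood fit of the beta-uniform mixture to p-values.

    The beta shape is restricted to 0 < a < 1 (density decreasing in p, the
    signal-concentrated-near-zero regime).  The fit is deterministic: a small
    fixed grid of starting points, best likelihood wins.
    """
    p = np.clip(np.asarray(pvalues, dtype=float), _P_EPS, 1.0)
    best = None
    for pi0_start in (0.5, 0.9):
        for a_start in (0.1, 0.5):
            theta0 = np.array([np.log(pi0_start / (1 - pi0_start)),
                               np.log(a_start / (1 - a_start))])
            res = minimize(_negloglik, theta0, args=(p,), method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
            if best is None or res.fun < best.fun:
                best = res
    pi0 = float(1.0 / (1.0 + np.exp(-best.x[0])))
    a = float(np.clip(1.0 / (1.0 + np.exp(-best.x[1])), 1e-6, 1.0 - 1e-6))
    return BetaUniformFit(pi0=pi0, a=a)


def estimate_lfdr(
    interaction_pvalues: np.ndarray | pd.Series,
) -> tuple[np.ndarray | pd.Series, BetaUniformFit]:
    """Per-gene local false discovery rate from interaction p-values.

    lfdr(p) = pi0 / f(p), clipped to [0, 1], with (pi0, a) the ML fit of the
    beta-uniform mixture.  Degenerate input (all p identical) yields lfdr = 1
    everywhere with a warning.  Fewer than ~50 p-values make the mixture fit
    unstable; a warning is emitted below that.
    """
    is_series = isinstance(interaction_pvalues, pd.Series)
    p = np.asarray(interaction_pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) < 50:
        warnings.warn(
            f"only {len(p)} p-values; beta-uniform mixture fit may be unstable",
            stacklevel=2,
        )
    if len(p) == 0 or np.ptp(p) == 0.0:
        warnings.warn("degenerate p-value vector; lfdr set to 1 everywhere", stacklevel=2)
        out = np.ones_like(p)
        fit = BetaUniformFit(pi0=1.0, a=0.5)
    else:
        fit = fit_beta_uniform(p)
        out = fit.lfdr(p)
    if is_series:
        out = pd.Series(out, index=interaction_pvalues.index)
    return out, fit


def shrink(delta, lfdr):
    """Attenuate the decay difference by the lfdr: delta * (1 - lfdr)."""
    return delta * (1.0 - lfdr)


def scale_to_expression(shrunken_deltas, expression_log2fcs):
    """Rescale shrunken deltas to the bounds of log2 expression values.

    Multiplies by max|log2fc| / max|shrunken| over the displayed subset so
    both quantities share a color scale; an all-zero shrunken vector maps to
    zeros.
    """
    shrunken = np.asarray(shrunken_deltas, dtype=float)
    lfc = np.asarray(expression_log2fcs, dtype=float)
    if lfc.size == 0:
        raise ValueError("empty expression vector")
    max_s = np.nanmax(np.abs(shrunken)) if shrunken.size else 0.0
    if max_s == 0 or np.isnan(max_s):
        scaled = np.zeros_like(shrunken)
    else:
        scaled = shrunken * (np.nanmax(np.abs(lfc)) / max_s)
    if isinstance(shrunken_deltas, pd.Series):
        return pd.Series(scaled, index=shrunken_deltas.index)
    return scaled


def compute_metric(
    fits: pd.DataFrame,
    use_log_ratio: bool = False,
    retained_only: bool = True,
) -> pd.DataFrame:
    """Build the per-gene decay-metric table from a fits table.

    Columns: ``delta`` (k_P - k_CI7 per minute; or ln(k_P / k_CI7) when
    ``use_log_ratio`` and both constants are positive), ``lfdr``,
    ``shrunken_delta``.  The lfdr mixture is fitted on the interaction
    p-values of the genes in the table.  ``differential`` is carried over
    when present.  By default only filter-passing genes enter.
    """
    tab = fits[fits["passed_filter"]] if (retained_only and "passed_filter" in fits) else fits
    tab = tab[tab["fittable"]] if "fittable" in tab else tab
    if len(tab) == 0:
        raise ValueError("no retained genes to compute the metric on")
    if use_log_ratio:
        kp, kc = tab["k_P"], tab["k_CI7"]
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = pd.Series(
                np.where((kp > 0) & (kc > 0), np.log(kp / kc), np.nan), index=tab.index
            )
    else:
        delta = tab["k_P"] - tab["k_CI7"]
    lfdr, fit = estimate_lfdr(tab["interaction_pvalue"])
    metric = pd.DataFrame(
        {
            "delta": delta,
            "lfdr": lfdr,
            "shrunken_delta": shrink(delta, lfdr),
        },
        index=tab.index,
    )
    for col in ("interaction_qvalue", "differential"):
        if col in tab:
            metric[col] = tab[col]
    metric.attrs["lfdr_pi0"] = fit.pi0
    metric.attrs["lfdr_a"] = fit.a
    return metric
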