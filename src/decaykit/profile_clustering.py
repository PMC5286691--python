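"""Clustering of replicate-level decay profiles.

Each selected gene contributes a row of per-replicate decay constants (P
replicates first, then CI7), mean-centered across the row and sign-flipped
so that positive entries mean slower-than-average decay for that gene.
K-means (default k=2) over these rows separates transcripts destabilized
with quiescence from those stabilized with quiescence; clusters are
relabeled canonically by the sign of their centroid on the CI7 columns so
that cluster 1 always means "faster decay in CI7" regardless of seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = ["StabilityProfileMatrix", "build_profile_matrix", "kmeans_profiles"]


@dataclass
class StabilityProfileMatrix:
    """Mean-centered, sign-flipped per-replicate decay constants.

    ``values``: genes x replicate-series columns (P reps then CI7 reps);
    positive = slower decay than the gene's mean rate.  Rows sum to 0.
    """

    values: pd.DataFrame
    conditions: tuple[str, str]
    n_dropped: int = 0

    @property
    def genes(self) -> pd.Index:
        return self.values.index


def build_profile_matrix(
    fits: pd.DataFrame,
    differential_only: bool = True,
    conditions: tuple[str, str] = ("P", "CI7"),
) -> StabilityProfileMatrix:
    """Assemble the clustering substrate from per-replicate decay constants.

    Selects differential genes by default (requires ``test_differential`` to
    have been run); genes missing any replicate slope are dropped and
    counted.  Entry (g, cond_rep) = -(k_{cond,rep} - mean over the gene's
    series), so slower-than-mean decay is positive.
    """
    c1, c2 = conditions
    rep_cols = [c for c in fits.columns if c.startswith(f"k_{c1}_rep")] + [
        c for c in fits.columns if c.startswith(f"k_{c2}_rep")
    ]
    if not rep_cols:
        raise ValueError("fits table has no per-replicate slope columns")
    tab = fits
    if differential_only:
        if "differential" not in tab.columns:
            raise ValueError(
                "differential_only=True requires a 'differential' column "
                "(run test_differential first)"
            )
        tab = tab[tab["differential"]]
    if len(tab) == 0:
        raise ValueError("no genes selected for profile clustering")
    block = tab[rep_cols]
    complete = block.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    block = block.loc[complete]
    if len(block) == 0:
        raise ValueError("all selected genes are missing replicate slopes")
    centered = -(block.sub(block.mean(axis=1), axis=0))
    return StabilityProfileMatrix(centered, conditions, n_dropped)


def kmeans_profiles(
    matrix: StabilityProfileMatrix,
    k: int = 2,
    n_restarts: int = 10,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Euclidean k-means over stability profiles, canonically labeled.

    Best of ``n_restarts`` initializations by within-cluster sum of squares;
    deterministic given ``seed``.  Clusters are renumbered 1..k by ascending
    centroid mean over the CI7 columns, so cluster 1 has the most negative
    CI7 centroid (fastest decay during quiescence, i.e. destabilized with
    quiescence) and cluster k the most positive.

    Returns (labels: Series of 1-based ints per gene, centroids: k x columns
    DataFrame indexed by canonical cluster id).
    """
    X = matrix.values.to_numpy(dtype=float)
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of profiles {n}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(X)
    centroids = km.cluster_centers_
    c2 = matrix.conditions[1]
    ci7_cols = [
        i for i, c in enumerate(matrix.values.columns) if c.startswith(f"k_{c2}_rep")
    ]
    order = np.argsort(centroids[:, ci7_cols].mean(axis=1), kind="stable")
    relabel = {int(old): rank + 1 for rank, old in enumerate(order)}
    labels = pd.Series(
        [relabel[int(l)] for l in raw], index=matrix.genes, name="cluster"
    )
    cent = pd.DataFrame(
        centroids[order],
        index=pd.Index(range(1, k + 1), name="cluster"),
        columns=matrix.values.columns,
    )
    return labels, cent
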