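"""Kinetic classification of time-course expression profiles.

Each gene's vst expression is averaged per timepoint (t0, t1.5 h, t4 h),
z-scored across the three timepoint means, and clustered with seeded
K-means.  Cluster centroids are then mapped to verbal kinetic classes:

* ``early`` — changed by 1.5 h and sustained at 4 h;
* ``early_transient`` — changed by 1.5 h but largely back at baseline by 4 h;
* ``late`` — essentially unchanged at 1.5 h, changed at 4 h.

Because up- and down-regulated genes have mirror-image z-profiles, callers
clustering a mixed set should split by direction first (see
:class:`KineticProfiler`); the class rule itself is sign-symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

KINETIC_CLASSES = ("early", "early_transient", "late", "unclassified")
#: persistence ratios making the three verbal definitions mutually exclusive
SUSTAINED_RATIO = 0.75
TRANSIENT_RATIO = 0.5


@dataclass
class KineticAssignment:
    gene_id: str
    cluster: int
    klass: str
    centroid: np.ndarray


def zscore_profiles(expr: pd.DataFrame, timepoints: pd.Series) -> tuple[pd.DataFrame, set[str]]:
    """Z-score each gene's per-timepoint mean profile.

    Returns the gene × timepoint z-matrix (population sd) and the set of
    zero-variance genes, whose rows are set to zero and flagged.
    """
    timepoints = pd.Series(timepoints).loc[expr.columns]
    means = expr.T.groupby(timepoints).mean().T  # genes × timepoints
    means = means[list(dict.fromkeys(timepoints))]
    values = means.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (values - mu) / sd
    z[flat] = 0.0
    zmat = pd.DataFrame(z, index=means.index, columns=means.columns)
    return zmat, set(means.index[flat])


def assign_kinetic_class(centroid, delta: float = 0.5) -> str:
    """Map a 3-point z-centroid (t0, t1.5, t4) to a kinetic class.

    With d1 = c(1.5) − c(0) and d2 = c(4) − c(0): early when the 1.5 h change
    (|d1| ≥ delta) persists at 4 h in the same direction (|d2| ≥ 0.75·|d1|);
    early_transient when it decays (|d2| < 0.5·|d1|); late when only the 4 h
    change clears delta; otherwise unclassified.
    """
    c = np.asarray(centroid, dtype=float)
    if c.shape != (3,):
        raise ValueError("centroid must have length 3 (t0, t1.5, t4)")
    d1 = c[1] - c[0]
    d2 = c[2] - c[0]
    if abs(d1) >= delta:
        if abs(d2) >= SUSTAINED_RATIO * abs(d1) and np.sign(d2) == np.sign(d1):
            return "early"
        if abs(d2) < TRANSIENT_RATIO * abs(d1):
            return "early_transient"
        return "unclassified"
    if abs(d2) >= delta:
        return "late"
    return "unclassified"


def kmeans_cluster(z: pd.DataFrame, k: int = 3, seed: int = 0, restarts: int = 10,
                   delta: float = 0.5) -> list[KineticAssignment]:
    """Seeded K-means (Lloyd, best of ``restarts`` inits) on z-profiles.

    Each gene inherits the kinetic class of its cluster centroid.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(z) < k:
        raise ValueError("fewer profiles than clusters")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(z.to_numpy(dtype=float))
    classes = {i: assign_kinetic_class(c, delta) for i, c in enumerate(km.cluster_centers_)}
    return [
        KineticAssignment(gene_id=g, cluster=int(lab), klass=classes[int(lab)],
                          centroid=km.cluster_centers_[int(lab)].copy())
        for g, lab in zip(z.index, labels)
    ]


class KineticProfiler(BaseEstimator):
    """Cluster time-course profiles and assign kinetic classes.

    Fits K-means with ``k`` clusters separately within up- and down-regulated
    genes (their z-profiles are mirror images, so a joint clustering would
    mix directions within clusters), then labels each cluster centroid with
    the class rule of :func:`assign_kinetic_class`.

    Parameters
    ----------
    k : clusters per direction group (default 3, one per expected class).
    delta : z-unit threshold for a "real" change at a timepoint.
    seed, restarts : K-means determinism controls.

    Attributes
    ----------
    assignments_ : DataFrame indexed by gene id with cluster, klass,
        direction and the three centroid coordinates.
    flagged_ : set of zero-variance gene ids (assigned "unclassified").
    """

    def __init__(self, k: int = 3, delta: float = 0.5, seed: int = 0, restarts: int = 10):
        self.k = k
        self.delta = delta
        self.seed = seed
        self.restarts = restarts

    def fit(self, expr: pd.DataFrame, timepoints: pd.Series, direction: pd.Series | None = None):
        """``expr`` is a vst matrix restricted to the genes of interest;
        ``direction`` (optional, per gene, +1/-1) splits the clustering."""
        z, flagged = zscore_profiles(expr, timepoints)
        z = z.drop(index=[g for g in flagged if g in z.index])
        if direction is None:
            # infer: sign of the larger deviation from t0
            d = z.to_numpy()
            d1 = d[:, 1] - d[:, 0]
            d2 = d[:, 2] - d[:, 0]
            direction = pd.Series(
                np.where(np.abs(d1) >= np.abs(d2), np.sign(d1), np.sign(d2)),
                index=z.index,
            )
        else:
            direction = pd.Series(direction).loc[z.index]

        rows = []
        offset = 0
        for sign in (1, -1):
            genes = direction.index[np.sign(direction) == sign]
            sub = z.loc[genes]
            if len(sub) == 0:
                continue
            if len(sub) < self.k:
                for g in sub.index:
                    rows.append((g, offset, assign_kinetic_class(sub.loc[g], self.delta),
                                 sign, *sub.loc[g].to_numpy()))
                offset += 1
                continue
            for a in kmeans_cluster(sub, k=self.k, seed=self.seed,
                                    restarts=self.restarts, delta=self.delta):
                rows.append((a.gene_id, a.cluster + offset, a.klass, sign, *a.centroid))
            offset += self.k
        for g in flagged:
            rows.append((g, -1, "unclassified", 0, 0.0, 0.0, 0.0))

        tp_names = list(z.columns) if len(z.columns) == 3 else ["t0", "t1.5", "t4"]
        self.assignments_ = pd.DataFrame(
            rows, columns=["gene_id", "cluster", "klass", "direction"] + [f"z_{t}" for t in tp_names]
        ).set_index("gene_id")
        self.flagged_ = flagged
        return self

    def fit_predict(self, expr, timepoints, direction=None) -> pd.Series:
        self.fit(expr, timepoints, direction)
        return self.assignments_["klass"]
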