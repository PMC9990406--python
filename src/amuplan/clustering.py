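"""Farm-similarity analysis on the fitted forest's proximities.

The proximity matrix P (fraction of trees in which two farms co-terminate)
is turned into a dissimilarity D = 1 - P, embedded with classical metric
MDS (principal coordinates), and the embedded farms are grouped with
k-means; the number of clusters is chosen by BIC under a spherical
equal-variance Gaussian reading of the k-means solution.  Farms are
labelled High/Low antimicrobial users by min-max normalising the (real and
predicted) transformed usage and cutting at 0.5, and each (cluster, class)
cell is summarised by a prototype: median for numeric fields, modal level
for binary answers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)


@dataclass
class UserLabel:
    farm_id: object
    real_label: str
    predicted_label: str


@dataclass
class ClusterModel:
    embedding: np.ndarray
    k: int
    assignments: np.ndarray
    bic_by_k: dict
    inertia_by_k: dict


@dataclass
class Prototype:
    cluster: int
    user_class: str
    values: dict | None
    n_members: int

    @property
    def applicable(self) -> bool:
        return self.n_members > 0


def _minmax(v: np.ndarray) -> np.ndarray:
    span = np.ptp(v)
    if span == 0:
        warnings.warn("constant vector: min-max normalisation degenerate; "
                      "all farms labelled Low", RuntimeWarning, stacklevel=3)
        return np.zeros_like(v)
    return (v - np.min(v)) / span


def label_users(y_real_t, y_pred_t, farm_ids=None) -> list:
    """High/Low-user labels from min-max normalised transformed usage.

    Each vector is normalised independently to [0, 1]; values > 0.5 are
    'High', else 'Low'.  Labels are therefore invariant under any
    increasing affine rescaling of either vector.
    """
    y_real_t = np.asarray(y_real_t, dtype=float)
    y_pred_t = np.asarray(y_pred_t, dtype=float)
    if y_real_t.size == 0 or y_real_t.shape != y_pred_t.shape:
        raise ValueError("need two equal-length nonempty vectors")
    if farm_ids is None:
        farm_ids = list(range(len(y_real_t)))
    real = np.where(_minmax(y_real_t) > 0.5, "High", "Low")
    pred = np.where(_minmax(y_pred_t) > 0.5, "High", "Low")
    return [UserLabel(fid, r, p)
            for fid, r, p in zip(farm_ids, real, pred)]


def embed(proximity: np.ndarray, dims: int = 3) -> np.ndarray:
    """Classical metric MDS (principal coordinates) of D = 1 - P.

    Double-centres the squared dissimilarities, eigendecomposes, and
    returns the first ``dims`` principal coordinates (non-positive
    eigenvalues contribute zero coordinates).
    """
    P = np.asarray(proximity, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("proximity must be a square matrix")
    if not np.allclose(P, P.T, atol=1e-8):
        raise ValueError("proximity matrix must be symmetric")
    D = 1.0 - P
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:dims]
    vals = np.clip(eigval[order], 0.0, None)
    coords = eigvec[:, order] * np.sqrt(vals)
    return coords


def stress(coordinates: np.ndarray, D: np.ndarray) -> float:
    """Kruskal-style raw stress of an embedding against dissimilarities."""
    diff = coordinates[:, None, :] - coordinates[None, :, :]
    d_emb = np.sqrt((diff ** 2).sum(axis=-1))
    num = np.sum((D - d_emb) ** 2)
    den = np.sum(D ** 2)
    return float(np.sqrt(num / den)) if den > 0 else 0.0


def kmeans_bic(coordinates: np.ndarray, labels: np.ndarray,
               centers: np.ndarray) -> float:
    """BIC of a k-means solution read as a spherical equal-variance
    Gaussian mixture (lower is better).

    The pooled variance uses the bias-corrected SSE / (d * (n - k)); the
    parameter count is (k - 1) mixing weights + k*d centre coordinates
    + 1 shared variance.
    """
    n, d = coordinates.shape
    k = centers.shape[0]
    if n <= k:
        return np.inf
    sse = float(((coordinates - centers[labels]) ** 2).sum())
    var = max(sse / (d * (n - k)), 1e-12)
    counts = np.bincount(labels, minlength=k).astype(float)
    counts = counts[counts > 0]
    loglik = (np.sum(counts * np.log(counts / n))
              - n * d / 2.0 * np.log(2 * np.pi * var)
              - d * (n - k) / 2.0)
    n_params = (k - 1) + k * d + 1
    return float(n_params * np.log(n) - 2.0 * loglik)


def cluster(coordinates: np.ndarray, k_min: int = 2, k_max: int = 10,
            n_restarts: int = 25, seed: int = 0) -> ClusterModel:
    """k-means over k in [k_min, k_max]; the k with the lowest spherical-
    Gaussian BIC wins.  Multiple restarts per k; deterministic under seed.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    n = coordinates.shape[0]
    if n < k_max + 1:
        raise ValueError(f"need at least k_max + 1 = {k_max + 1} farms")
    bic_by_k, inertia_by_k, fits = {}, {}, {}
    for k in range(k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(coordinates)
        bic_by_k[k] = kmeans_bic(coordinates, labels, km.cluster_centers_)
        inertia_by_k[k] = float(km.inertia_)
        fits[k] = labels
    best_k = min(bic_by_k, key=lambda k: (bic_by_k[k], k))
    logger.info("BIC selected k=%d (BIC %.2f)", best_k, bic_by_k[best_k])
    return ClusterModel(coordinates, best_k, fits[best_k], bic_by_k,
                        inertia_by_k)


def prototypes(table: pd.DataFrame, assignments, labels: list,
               numeric_fields=("broilers_per_round", "rounds_per_year",
                               "n_workers"),
               feature_fields=None) -> list:
    """Per-(cluster, predicted class) representative farms.

    Numeric fields get the class median, binary answers the modal level
    (ties broken toward 1, i.e. "measure applied", and logged).  A class
    with no members in a cluster yields a non-applicable prototype
    (``values=None``).
    """
    if feature_fields is None:
        feature_fields = [c for c in table.columns if c.startswith("q_")]
    assignments = np.asarray(assignments)
    pred = np.array([lab.predicted_label for lab in labels])
    out = []
    for cl in sorted(np.unique(assignments)):
        for klass in ("Low", "High"):
            mask = (assignments == cl) & (pred == klass)
            members = table.loc[mask]
            if len(members) == 0:
                out.append(Prototype(int(cl), klass, None, 0))
                continue
            values = {}
            for f in numeric_fields:
                values[f] = float(members[f].median())
            for f in feature_fields:
                col = members[f].dropna()
                n1 = int((col == 1).sum())
                n0 = int((col == 0).sum())
                if n1 == n0:
                    logger.info("prototype tie on %s in cluster %s/%s; "
                                "breaking toward 1", f, cl, klass)
                level = 1 if n1 >= n0 else 0
                freq = (n1 if level == 1 else n0) / max(len(col), 1)
                values[f] = (level, round(float(freq), 3))
            out.append(Prototype(int(cl), klass, values, int(len(members))))
    return out


def prototypes_frame(protos: list) -> pd.DataFrame:
    """Wide table of prototypes: one column per (cluster, class)."""
    cols = {}
    for p in protos:
        name = f"cluster{p.cluster}_{p.user_class}"
        if p.values is None:
            cols[name] = pd.Series({"n_members": 0}, dtype=object)
        else:
            flat = {k: (f"{v[0]} ({v[1]:.0%})" if isinstance(v, tuple)
                        else v) for k, v in p.values.items()}
            flat["n_members"] = p.n_members
            cols[name] = pd.Series(flat, dtype=object)
    return pd.DataFrame(cols)
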