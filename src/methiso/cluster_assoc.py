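"""Methylation-cluster / isoform-usage association.

Samples are clustered hierarchically (Ward linkage on Euclidean distance by
default) on the β values of isoform-correlated probes.  Whether the usage
patterns of the correlated isoforms are more similar within than between
clusters is quantified by

    Dw = sum_c sum_i ||x_ic - mu_c||^2        (within-cluster scatter)
    Db = sum_c n_c ||mu_c - mu||^2            (between-cluster scatter)
    T  = Db / Dw

with significance from permuting the cluster labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

logger = logging.getLogger(__name__)

DEFAULT_K = 4
DEFAULT_B = 1000


@dataclass
class ClusterAssocResult:
    labels: pd.Series
    Dw: float
    Db: float
    T: float
    p_perm: float
    B: int
    seed: int | None


def _impute_feature_means(X: np.ndarray) -> np.ndarray:
    """Replace NaN with the feature (column) mean; all-NaN columns -> 0."""
    if not np.isnan(X).any():
        return X
    mu = np.nanmean(np.where(np.isnan(X).all(axis=0), 0.0, X), axis=0)
    idx = np.where(np.isnan(X))
    X = X.copy()
    X[idx] = np.take(mu, idx[1])
    return X


def cluster_samples(beta_subset: pd.DataFrame, k: int = DEFAULT_K,
                    method: str = "ward", metric: str = "euclidean") -> pd.Series:
    """Agglomerative clustering of samples (columns) on β values.

    Deterministic given inputs.  Missing β entries are imputed with the
    probe mean.  Returns sample -> cluster label (1..k).
    """
    X = beta_subset.to_numpy(float).T  # samples x probes
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds {X.shape[0]} samples")
    X = _impute_feature_means(X)
    if np.allclose(X, X[0]):
        warnings.warn("all samples identical; cluster cut is arbitrary")
    Z = scipy_linkage(X, method=method, metric=metric)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=beta_subset.columns, name="cluster")


def t_statistic(usage: pd.DataFrame, labels: pd.Series) -> tuple[float, float, float]:
    """(Dw, Db, T) for usage vectors (transcripts x samples) under labels.

    Missing usage entries (gene unexpressed in a sample) are imputed with
    the transcript's cohort mean.  Dw = 0 with distinct cluster means gives
    T = +inf with a warning.
    """
    X = usage[labels.index].to_numpy(float).T  # samples x transcripts
    X = _impute_feature_means(X)
    lab = labels.to_numpy()
    mu = X.mean(axis=0)
    Dw = 0.0
    Db = 0.0
    for c in np.unique(lab):
        Xc = X[lab == c]
        mc = Xc.mean(axis=0)
        Dw += float(((Xc - mc) ** 2).sum())
        Db += float(len(Xc) * ((mc - mu) ** 2).sum())
    total = Dw + Db
    if total == 0.0 or Dw <= 1e-12 * total:   # numerically-zero within scatter
        if total == 0.0 or Db <= 1e-12 * total:
            warnings.warn("all samples identical; T undefined, reported as 0")
            return 0.0, 0.0, 0.0
        warnings.warn("zero within-cluster scatter; T = +inf")
        return 0.0, Db, float("inf")
    return Dw, Db, Db / Dw


def _t_from_group_sums(X: np.ndarray, lab_idx: np.ndarray, k: int,
                       total_ss: float, sum_all: np.ndarray) -> float:
    """T via the decomposition Db = sum_c ||S_c||^2/n_c - ||S||^2/n, Dw = SS - Db."""
    n, d = X.shape
    db = 0.0
    for c in range(k):
        m = lab_idx == c
        nc = int(m.sum())
        if nc == 0:
            continue
        Sc = X[m].sum(axis=0)
        db += float(Sc @ Sc) / nc
    db -= float(sum_all @ sum_all) / n
    dw = total_ss - db
    if dw <= 0:
        return float("inf") if db > 0 else 0.0
    return db / dw


def permutation_p(usage: pd.DataFrame, labels: pd.Series, B: int = DEFAULT_B,
                  seed: int | None = None, perm_list: list | None = None) -> float:
    """Add-one permutation p-value: p = (1 + #{T_perm >= T_obs}) / (B + 1).

    ``perm_list`` (explicit label orderings, e.g. the full permutation group
    at tiny n) replaces the random draws and overrides B.
    """
    if perm_list is not None:
        B = len(perm_list)
    if B < 1:
        raise ValueError("B must be >= 1")
    X = usage[labels.index].to_numpy(float).T
    X = _impute_feature_means(X)
    lab = labels.to_numpy()
    uniq = np.unique(lab)
    lab_idx = np.searchsorted(uniq, lab)
    mu = X.mean(axis=0)
    total_ss = float(((X - mu) ** 2).sum())
    sum_all = X.sum(axis=0)
    t_obs = _t_from_group_sums(X, lab_idx, len(uniq), total_ss, sum_all)
    rng = np.random.default_rng(seed)
    exceed = 0
    for b in range(B):
        perm = (lab_idx[np.asarray(perm_list[b])] if perm_list is not None
                else rng.permutation(lab_idx))
        if _t_from_group_sums(X, perm, len(uniq), total_ss, sum_all) >= t_obs:
            exceed += 1
    return (1 + exceed) / (B + 1)


def cluster_association(beta_subset: pd.DataFrame, usage_subset: pd.DataFrame,
                        k: int = DEFAULT_K, B: int = DEFAULT_B,
                        seed: int | None = None, method: str = "ward",
                        metric: str = "euclidean") -> ClusterAssocResult:
    """Cluster on β of correlated probes, test T on usage of correlated isoforms."""
    labels = cluster_samples(beta_subset, k=k, method=method, metric=metric)
    common = [s for s in labels.index if s in usage_subset.columns]
    labels = labels.loc[common]
    Dw, Db, T = t_statistic(usage_subset, labels)
    p = permutation_p(usage_subset, labels, B=B, seed=seed)
    return ClusterAssocResult(labels, Dw, Db, T, p, B, seed)


def subtype_crosstab(labels: pd.Series, subtypes: pd.Series) -> pd.DataFrame:
    """Cluster x provided-subtype concordance table."""
    common = labels.index.intersection(subtypes.index)
    return pd.crosstab(labels.loc[common], subtypes.loc[common])
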