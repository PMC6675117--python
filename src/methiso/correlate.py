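"""Pairwise β-usage correlation, permutation eFDR, and the significant-pair screen.

The screen follows a fixed recipe: compute Pearson (or Spearman)
correlations for every intragenic (isoform, probe) pair among tumor
samples; estimate an empirical FDR by permuting sample labels of the β
matrix and comparing null to observed exceedance counts over a grid of
|r| thresholds; restrict to the top-quartile most variable probes; and keep
pairs with |r| > 0.3 in cohorts whose eFDR-controlling threshold r* is at
most 0.3 (cohorts needing a larger r* to control the eFDR are ineligible).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_N = 30          # smallest cohort size intended for this screen
DEFAULT_R_MIN = 0.3
DEFAULT_EFDR_TARGET = 0.1
DEFAULT_B = 100
THRESHOLD_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)


# ---------------------------------------------------------------------------
# vectorized row-wise correlation with pairwise-complete handling
# ---------------------------------------------------------------------------

def rowwise_pearson(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r per row of two (pairs x samples) arrays with NaNs.

    Each row is correlated over its pairwise-complete samples.  Returns
    (r, n_used); r is NaN for rows with zero variance or n < 2.
    """
    mask = np.isfinite(X) & np.isfinite(Y)
    n = mask.sum(axis=1)
    Xm = np.where(mask, X, 0.0)
    Ym = np.where(mask, Y, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sx = Xm.sum(1)
        sy = Ym.sum(1)
        cov = (Xm * Ym).sum(1) - sx * sy / n
        vx = (Xm * Xm).sum(1) - sx * sx / n
        vy = (Ym * Ym).sum(1) - sy * sy / n
        # guard against numerically-zero variance (constant vectors)
        tol_x = n * (1e-7 * np.maximum(np.abs(Xm).max(axis=1), 1.0)) ** 2
        tol_y = n * (1e-7 * np.maximum(np.abs(Ym).max(axis=1), 1.0)) ** 2
        r = cov / np.sqrt(vx * vy)
    r[(n < 2) | (vx <= tol_x) | (vy <= tol_y) | ~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0, out=r), n


def _rank_rows(A: np.ndarray) -> np.ndarray:
    """Midranks within each row; NaNs stay NaN (ranked among non-missing)."""
    return pd.DataFrame(A).rank(axis=1, method="average").to_numpy()


def _paired_matrices(usage: pd.DataFrame, beta: pd.DataFrame,
                     pairs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Row-align usage and β to the pair table over the shared sample set."""
    samples = usage.columns.intersection(beta.columns)
    if len(samples) == 0:
        raise ValueError("no overlapping samples between usage and beta")
    U = usage.loc[pairs["transcript_id"], samples].to_numpy(float)
    B = beta.loc[pairs["probe_id"], samples].to_numpy(float)
    return U, B


def _as_pair_frame(pairs) -> pd.DataFrame:
    if isinstance(pairs, pd.DataFrame):
        return pairs[["gene_id", "transcript_id", "probe_id"]].drop_duplicates().reset_index(drop=True)
    return pd.DataFrame(pairs, columns=["gene_id", "transcript_id", "probe_id"]).drop_duplicates().reset_index(drop=True)


def pair_correlations(usage: pd.DataFrame, beta: pd.DataFrame, pairs,
                      method: str = "pearson", min_n: int = DEFAULT_MIN_N
                      ) -> pd.DataFrame:
    """Correlation per (isoform, probe) pair over pairwise-complete samples.

    Spearman is Pearson on midranks.  Pairs with fewer than ``min_n``
    complete samples or zero variance in either vector are omitted.
    Returns columns gene_id, transcript_id, probe_id, r, n_used, method.
    """
    pairs = _as_pair_frame(pairs)
    pairs = pairs[pairs.transcript_id.isin(usage.index) & pairs.probe_id.isin(beta.index)]
    pairs = pairs.reset_index(drop=True)
    U, B = _paired_matrices(usage, beta, pairs)
    if method == "spearman":
        # global row ranks are exact when missingness is absent; with missing
        # entries, re-rank each pair on its complete samples
        if np.isfinite(U).all() and np.isfinite(B).all():
            U, B = _rank_rows(U), _rank_rows(B)
        else:
            U, B = _pairwise_complete_ranks(U, B)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    r, n = rowwise_pearson(U, B)
    out = pairs.copy()
    out["r"] = r
    out["n_used"] = n
    out["method"] = method
    kept = out[(out.n_used >= min_n) & np.isfinite(out.r)].reset_index(drop=True)
    logger.info("pair_correlations: %d/%d pairs retained (min_n=%d)",
                len(kept), len(out), min_n)
    return kept


def _pairwise_complete_ranks(U: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Ur = np.full_like(U, np.nan)
    Br = np.full_like(B, np.nan)
    for i in range(U.shape[0]):
        m = np.isfinite(U[i]) & np.isfinite(B[i])
        if m.sum() >= 2:
            Ur[i, m] = pd.Series(U[i, m]).rank(method="average").to_numpy()
            Br[i, m] = pd.Series(B[i, m]).rank(method="average").to_numpy()
    return Ur, Br


# ---------------------------------------------------------------------------
# permutation eFDR
# ---------------------------------------------------------------------------

@dataclass
class EFDRResult:
    thresholds: np.ndarray
    efdr: np.ndarray
    r_star: float | None
    B: int
    seed: int | None
    n_obs_pairs: int
    obs_exceed: np.ndarray
    null_exceed_mean: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "efdr": self.efdr,
                             "n_obs": self.obs_exceed,
                             "null_mean": self.null_exceed_mean})


def _exceedance(abs_r: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """count of |r| >= t for each grid threshold t."""
    srt = np.sort(abs_r)
    return len(srt) - np.searchsorted(srt, grid, side="left")


def empirical_fdr(usage: pd.DataFrame, beta: pd.DataFrame, pairs,
                  B: int = DEFAULT_B, target: float = DEFAULT_EFDR_TARGET,
                  seed: int | None = None, method: str = "pearson",
                  min_n: int = DEFAULT_MIN_N, per_pair: bool = False,
                  grid: np.ndarray = THRESHOLD_GRID,
                  perm_list: list | None = None) -> EFDRResult:
    """Empirical FDR of the correlation screen by sample-label permutation.

    For each of B permutations the sample labels of the β matrix are
    shuffled relative to usage (one global permutation per iteration by
    default, preserving inter-probe correlation in the null; per-pair
    independent shuffles behind ``per_pair=True``) and all pair |r|
    recomputed.  eFDR(t) = mean null exceedance count at t divided by the
    observed exceedance count (0 where no observed pair reaches t; capped at
    1), made monotone non-increasing in t by a running minimum.  r* is the
    smallest grid threshold with eFDR < target.  ``perm_list`` replaces the
    random permutations with an explicit list (e.g. the full permutation
    group at tiny n), overriding B.
    """
    if perm_list is not None:
        B = len(perm_list)
    if B < 1:
        raise ValueError("B must be >= 1")
    pairs = _as_pair_frame(pairs)
    pairs = pairs[pairs.transcript_id.isin(usage.index) & pairs.probe_id.isin(beta.index)]
    pairs = pairs.reset_index(drop=True)
    U, Bm = _paired_matrices(usage, beta, pairs)
    rank_mode = method == "spearman"
    complete = np.isfinite(U).all() and np.isfinite(Bm).all()
    if rank_mode and complete:
        U, Bm = _rank_rows(U), _rank_rows(Bm)
        rank_mode = False  # ranks are permutation-invariant per row once global

    def corr(Umat, Bmat):
        if rank_mode:
            Umat, Bmat = _pairwise_complete_ranks(Umat, Bmat)
        return rowwise_pearson(Umat, Bmat)

    r_obs, n_obs = corr(U, Bm)
    ok = (n_obs >= min_n) & np.isfinite(r_obs)
    obs_exceed = _exceedance(np.abs(r_obs[ok]), grid)

    rng = np.random.default_rng(seed)
    S = U.shape[1]
    null_sum = np.zeros(len(grid))
    for b in range(B):
        if perm_list is not None:
            Bp = Bm[:, np.asarray(perm_list[b])]
        elif per_pair:
            idx = np.argsort(rng.random((Bm.shape[0], S)), axis=1)
            Bp = np.take_along_axis(Bm, idx, axis=1)
        else:
            Bp = Bm[:, rng.permutation(S)]
        r_null, n_null = corr(U, Bp)
        okn = (n_null >= min_n) & np.isfinite(r_null)
        null_sum += _exceedance(np.abs(r_null[okn]), grid)
    null_mean = null_sum / B

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(obs_exceed > 0, null_mean / np.maximum(obs_exceed, 1), 0.0)
    raw = np.minimum(raw, 1.0)
    efdr = np.minimum.accumulate(raw)  # non-increasing in threshold
    passing = np.nonzero(efdr < target)[0]
    r_star = float(grid[passing[0]]) if len(passing) else None
    return EFDRResult(grid.copy(), efdr, r_star, B, seed, int(ok.sum()),
                      obs_exceed, null_mean)


# ---------------------------------------------------------------------------
# variable-probe selection and the significant-pair set
# ---------------------------------------------------------------------------

def select_variable_probes(beta: pd.DataFrame, q: float = 0.25) -> set[str]:
    """Top ceil(q*P) probes by sample standard deviation (descending).

    Ties at the cutoff break by probe_id lexicographic order.
    """
    if len(beta) < 4:
        raise ValueError("need >= 4 probes to rank variability")
    sd = beta.std(axis=1, ddof=1, skipna=True)
    order = sorted(zip(-sd.to_numpy(), sd.index.astype(str)))
    k = math.ceil(q * len(beta))
    return {pid for _, pid in order[:k]}


def significant_pairs(records: pd.DataFrame, efdr_result: EFDRResult,
                      variable_set: set[str], r_min: float = DEFAULT_R_MIN
                      ) -> tuple[pd.DataFrame, str, dict]:
    """Apply the |r| > r_min screen within the variable-probe set.

    The cohort is ELIGIBLE only when the eFDR-controlling threshold r* is
    <= r_min, i.e. every retained pair is individually significant at the
    target eFDR.  Returns (retained records, verdict, summary counts).
    """
    eligible = efdr_result.r_star is not None and efdr_result.r_star <= r_min
    if not eligible:
        return records.iloc[0:0], "INELIGIBLE", {"n_gene": 0, "n_trans": 0, "n_pair": 0}
    keep = records[records.probe_id.isin(variable_set) & (records.r.abs() > r_min)]
    keep = keep.reset_index(drop=True)
    summary = {"n_gene": int(keep.gene_id.nunique()),
               "n_trans": int(keep.transcript_id.nunique()),
               "n_pair": int(len(keep))}
    return keep, "ELIGIBLE", summary
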