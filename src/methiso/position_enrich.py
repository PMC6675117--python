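"""Sign counting and enrichment by position around isoform landmarks.

Significant (isoform, probe) pairs are binned by their position relative to
an anchor exon class (first exon; middle exons at a given ordinal; terminal
exons, optionally pooled over ordinals): two fixed inside bins — near
(< 1 kb from the closest exon boundary) and far (>= 1 kb) — and, outside the
exon, 500-bp windows sliding 100 bp at a time out to 2 kb on either side,
truncated at the boundary of the neighbouring exon of the same transcript.
Enrichment of a correlation sign in a bin is an odds ratio against the
pooled remaining bins of the same analysis, with a one-sided (upper-tail)
hypergeometric p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

WINDOW_BP = 500
STEP_BP = 100
MAX_FLANK_BP = 2000
FLANK_OFFSETS = tuple(range(0, MAX_FLANK_BP - WINDOW_BP + STEP_BP, STEP_BP))  # 0..1500


@dataclass(frozen=True)
class WindowSpec:
    """One bin of an anchor analysis.

    anchor: 'first' | 'middle' | 'terminal' | 'terminal_pooled'
    ordinal: exact exon ordinal required (middle analyses), or None;
    ordinal_min: minimum ordinal (e.g. 4 for 'fourth or later'), or None.
    side: 'upstream' | 'downstream' for flank windows (then ``offset`` is the
    window start in bp from the exon boundary), or 'inside_near'/'inside_far'.
    """

    anchor: str
    side: str
    offset: int = 0
    ordinal: int | None = None
    ordinal_min: int | None = None

    def label(self) -> str:
        k = f"k={self.ordinal}" if self.ordinal else (f"k>={self.ordinal_min}" if self.ordinal_min else "any")
        if self.side in ("inside_near", "inside_far"):
            return f"{self.anchor}[{k}]:{self.side}"
        return f"{self.anchor}[{k}]:{self.side}+{self.offset}"


@dataclass
class EnrichmentResult:
    label: str
    n_pos: int
    n_neg: int
    n_gene: int
    odds_ratio: float
    p: float
    undefined: bool = False


def _anchor_mask(assign: pd.DataFrame, spec: WindowSpec) -> pd.Series:
    if spec.anchor == "terminal_pooled":
        m = assign.anchor == "terminal"
    else:
        m = assign.anchor == spec.anchor
    if spec.ordinal is not None:
        m &= assign.anchor_ordinal == spec.ordinal
    if spec.ordinal_min is not None:
        m &= assign.anchor_ordinal >= spec.ordinal_min
    return m


def window_members(assign: pd.DataFrame, spec: WindowSpec) -> pd.DataFrame:
    """Assignment rows falling in one bin/window.

    Flank membership: |signed_offset| in [offset, offset+500) on the given
    side, and the window must fit before the neighbouring exon
    (offset + 500 <= flank_limit) — windows extending past a flanking exon
    boundary are not counted for that pair.
    """
    m = _anchor_mask(assign, spec)
    if spec.side in ("inside_near", "inside_far"):
        m &= assign.location == spec.side
    else:
        d = assign.signed_offset.abs()
        m &= ((assign.location == "flank") & (assign.flank_side == spec.side)
              & (d >= spec.offset) & (d < spec.offset + WINDOW_BP)
              & (spec.offset + WINDOW_BP <= assign.flank_limit))
    return assign[m]


def count_signs(sig_pairs: pd.DataFrame, assignments: pd.DataFrame,
                spec: WindowSpec) -> tuple[int, int, int]:
    """(n_pos, n_neg, n_gene) for one bin.

    ``sig_pairs`` carries (gene_id, transcript_id, probe_id, r); a pair
    contributes once per matching assignment row.  n_gene counts distinct
    genes supporting the dominant sign.
    """
    hits = window_members(assignments, spec)
    merged = hits.drop(columns=["gene_id"], errors="ignore").merge(
        sig_pairs[["gene_id", "transcript_id", "probe_id", "r"]],
        on=["transcript_id", "probe_id"], how="inner")
    n_pos = int((merged.r > 0).sum())
    n_neg = int((merged.r < 0).sum())
    dom = merged[merged.r > 0] if n_pos >= n_neg else merged[merged.r < 0]
    n_gene = int(dom.gene_id.nunique())
    return n_pos, n_neg, n_gene


def anchor_window_specs(anchor: str, ordinal: int | None = None,
                        ordinal_min: int | None = None) -> list[WindowSpec]:
    """The full bin set of one anchor analysis: inside near/far plus sliding
    flank windows on both sides."""
    specs = [WindowSpec(anchor, "inside_near", 0, ordinal, ordinal_min),
             WindowSpec(anchor, "inside_far", 0, ordinal, ordinal_min)]
    for side in ("upstream", "downstream"):
        for off in FLANK_OFFSETS:
            specs.append(WindowSpec(anchor, side, off, ordinal, ordinal_min))
    return specs


def anchor_profile(sig_pairs: pd.DataFrame, assignments: pd.DataFrame,
                   anchor: str, ordinal: int | None = None,
                   ordinal_min: int | None = None) -> pd.DataFrame:
    """Counts for every bin of one anchor analysis, long format."""
    rows = []
    for spec in anchor_window_specs(anchor, ordinal, ordinal_min):
        n_pos, n_neg, n_gene = count_signs(sig_pairs, assignments, spec)
        rows.append((anchor, spec.side, spec.offset, spec.ordinal, spec.ordinal_min,
                     spec.label(), n_pos, n_neg, n_gene))
    return pd.DataFrame(rows, columns=["anchor", "side", "offset", "ordinal",
                                       "ordinal_min", "label", "n_pos", "n_neg",
                                       "n_gene"])


# ---------------------------------------------------------------------------
# odds ratios and hypergeometric tails
# ---------------------------------------------------------------------------

def _odds_ratio(a: float, b: float, c: float, d: float) -> float:
    """(a/b) / (c/d) with Haldane-Anscombe +0.5 on all cells when any is 0."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a / b) / (c / d)


def _hypergeom_upper(k: int, M: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M, K, n)."""
    return float(hypergeom.sf(k - 1, M, K, n))


def promoter_body_odds(sig_pairs_with_region: pd.DataFrame,
                       sign: str = "negative") -> EnrichmentResult:
    """Odds ratio of the tested sign in isoform promoters versus bodies.

    OR = (sign_prom / other_prom) / (sign_body / other_body), one-sided
    hypergeometric p for overrepresentation of the sign among promoter pairs.
    Rows need columns region and r; each row is one pair.
    """
    df = sig_pairs_with_region
    is_sign = (df.r < 0) if sign == "negative" else (df.r > 0)
    prom = df.region == "promoter"
    a = int((is_sign & prom).sum())
    b = int((~is_sign & prom).sum())
    c = int((is_sign & ~prom).sum())
    d = int((~is_sign & ~prom).sum())
    undefined = (a + b == 0) or (c + d == 0)
    orat = np.nan if undefined else _odds_ratio(a, b, c, d)
    p = np.nan if undefined else _hypergeom_upper(a, a + b + c + d, a + c, a + b)
    dom = df[is_sign & prom]
    return EnrichmentResult("promoter_vs_body", int((df.r > 0).sum()),
                            int((df.r < 0).sum()), int(dom.gene_id.nunique()),
                            orat, p, undefined)


def window_enrichment(profile: pd.DataFrame, sign: str = "negative") -> pd.DataFrame:
    """Per-window enrichment of one sign against the pooled other windows.

    ``profile`` is an anchor_profile table.  Windows with zero pairs are
    skipped.  The hypergeometric tail conditions on pairs: population = all
    pair-window memberships of the analysis, successes = memberships with
    the tested sign, draws = memberships in the window.
    """
    sgn = "n_neg" if sign == "negative" else "n_pos"
    oth = "n_pos" if sign == "negative" else "n_neg"
    tot_sign = int(profile[sgn].sum())
    tot_oth = int(profile[oth].sum())
    M = tot_sign + tot_oth
    rows = []
    for row in profile.itertuples(index=False):
        a, b = int(getattr(row, sgn)), int(getattr(row, oth))
        if a + b == 0:
            continue
        orat = _odds_ratio(a, b, tot_sign - a, tot_oth - b)
        p = _hypergeom_upper(a, M, tot_sign, a + b)
        rows.append((row.label, row.side, row.offset, a, b, row.n_gene, orat, p))
    return pd.DataFrame(rows, columns=["label", "side", "offset", "n_sign",
                                       "n_other", "n_gene", "odds_ratio", "p"])


def sign_contrast(n_sign_focal: int, n_other_focal: int,
                  n_sign_rest: int, n_other_rest: int,
                  label: str = "contrast") -> EnrichmentResult:
    """Two-stratum sign enrichment: odds of the tested sign in a focal
    positional class against a reference class, with a one-sided
    hypergeometric tail for overrepresentation in the focal class."""
    undefined = (n_sign_focal + n_other_focal == 0) or (n_sign_rest + n_other_rest == 0)
    if undefined:
        return EnrichmentResult(label, 0, 0, 0, np.nan, np.nan, True)
    orat = _odds_ratio(n_sign_focal, n_other_focal, n_sign_rest, n_other_rest)
    M = n_sign_focal + n_other_focal + n_sign_rest + n_other_rest
    K = n_sign_focal + n_sign_rest
    n = n_sign_focal + n_other_focal
    p = _hypergeom_upper(n_sign_focal, M, K, n)
    return EnrichmentResult(label, n_sign_focal, n_other_focal, 0, orat, p)


def context_enrichment(pairs_in_bin: pd.DataFrame, focal_context: str,
                       sign: str = "negative") -> EnrichmentResult:
    """Sign odds in one CpG context versus the union of the others, within a bin.

    Rows need columns context and r.  E.g. negative correlations near the
    first exon contrasted between open-sea probes and CGI/shore-shelf probes.
    """
    df = pairs_in_bin
    is_sign = (df.r < 0) if sign == "negative" else (df.r > 0)
    focal = df.context == focal_context
    if not focal.any():
        return EnrichmentResult(f"context:{focal_context}", 0, 0, 0, np.nan, np.nan, True)
    a = int((is_sign & focal).sum())
    b = int((~is_sign & focal).sum())
    c = int((is_sign & ~focal).sum())
    d = int((~is_sign & ~focal).sum())
    undefined = (c + d == 0)
    orat = np.nan if undefined else _odds_ratio(a, b, c, d)
    p = np.nan if undefined else _hypergeom_upper(a, a + b + c + d, a + c, a + b)
    n_gene = int(df.loc[is_sign & focal, "gene_id"].nunique()) if "gene_id" in df else 0
    return EnrichmentResult(f"context:{focal_context}",
                            int((df.r > 0).sum()), int((df.r < 0).sum()),
                            n_gene, orat, p, undefined)


def cohort_median_profile(per_cohort: dict[str, pd.DataFrame],
                          sign: str = "negative", alpha: float = 0.05
                          ) -> pd.DataFrame:
    """Median window counts across cohorts plus an all-cohorts significance flag.

    ``per_cohort`` maps cohort name -> anchor_profile table (identical bin
    layout).  A window is flagged significant-across-cohorts when its
    per-cohort window_enrichment p is < alpha in every cohort.
    """
    if not per_cohort:
        raise ValueError("need >= 1 cohort")
    names = sorted(per_cohort)
    base = per_cohort[names[0]][["label", "side", "offset"]].copy()
    pos = np.median([per_cohort[c].n_pos.to_numpy() for c in names], axis=0)
    neg = np.median([per_cohort[c].n_neg.to_numpy() for c in names], axis=0)
    sig_all = np.ones(len(base), dtype=bool)
    for c in names:
        enr = window_enrichment(per_cohort[c], sign=sign)
        pmap = dict(zip(enr.label, enr.p))
        pvals = base.label.map(pmap)
        sig_all &= (pvals < alpha).fillna(False).to_numpy()
    out = base
    out["median_n_pos"] = pos
    out["median_n_neg"] = neg
    out["significant_all_cohorts"] = sig_all
    return out
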