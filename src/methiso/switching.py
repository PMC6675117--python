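"""Single-probe isoform-switch cases and distal-TTS consistency.

A switch case is a (gene, probe) where methylation at one CpG is positively
correlated with the usage of one isoform and negatively with another
isoform of the same gene.  Cases driven by alternative first exons
(candidate alternative-TSS regulation) are set aside.  For the remainder,
when the probe lies at least 1 kb beyond the 3' boundary of the *preceding*
terminal exon (the one of the two isoforms ending further upstream in
transcription direction), the case is "distal"; it is distal-consistent
when the negatively correlated isoform is the preceding-TTS isoform and the
positively correlated isoform uses the more downstream TTS — the pattern in
which downstream methylation marks use of the distal termination site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .genome_model import FLANK_BP, GeneModel, ProbeRecord, TranscriptModel

logger = logging.getLogger(__name__)

DISTAL_BP = 1000

LABEL_DISTAL_CONSISTENT = "distal_consistent"
LABEL_DISTAL_INCONSISTENT = "distal_inconsistent"
LABEL_PROXIMAL = "proximal"
LABEL_TSS_EXCLUDED = "tss_excluded"


@dataclass
class SwitchCase:
    gene_id: str
    probe_id: str
    iso_pos: str
    iso_neg: str
    r_pos: float
    r_neg: float
    preceding_tts_transcript: str | None = None
    dist_beyond_preceding: int | None = None
    label: str | None = None


def _in_promoter(t: TranscriptModel, pos: int) -> bool:
    """Upstream of the TSS within 2 kb, or inside the first exon."""
    s, e = t.exons[0]
    if s <= pos < e:
        return True
    d = (s - pos) if t.strand == "+" else (pos - (e - 1))
    return 0 < d <= FLANK_BP


def _alt_tss_excluded(a: TranscriptModel, b: TranscriptModel, pos: int) -> bool:
    """Distinct first exons and probe in either isoform's promoter region."""
    if a.exons[0] == b.exons[0]:
        return False
    return _in_promoter(a, pos) or _in_promoter(b, pos)


def find_switch_cases(sig_pairs: pd.DataFrame, genes: Sequence[GeneModel],
                      probes: Sequence[ProbeRecord], r_min: float = 0.3,
                      best_pair: bool = False) -> list[SwitchCase]:
    """All (iso_pos, iso_neg) switch combinations per (gene, probe).

    ``sig_pairs`` needs columns gene_id, transcript_id, probe_id, r.  With
    ``best_pair`` only the max-|r| isoform on each side is kept per probe.
    Cases where the two isoforms have distinct first exons and the probe
    sits in either promoter are labeled tss_excluded (candidate
    alternative-TSS, not TTS, regulation).
    """
    tr = {t.transcript_id: t for g in genes for t in g.transcripts}
    probe_pos = {p.probe_id: p.pos for p in probes}
    cases: list[SwitchCase] = []
    for (gid, pid), sub in sig_pairs.groupby(["gene_id", "probe_id"], sort=True):
        pos_iso = sub[sub.r > r_min].sort_values(["r", "transcript_id"], ascending=[False, True])
        neg_iso = sub[sub.r < -r_min].sort_values(["r", "transcript_id"], ascending=[True, True])
        if pos_iso.empty or neg_iso.empty:
            continue
        if best_pair:
            pos_iso, neg_iso = pos_iso.iloc[:1], neg_iso.iloc[:1]
        for prow in pos_iso.itertuples(index=False):
            for nrow in neg_iso.itertuples(index=False):
                case = SwitchCase(gid, pid, prow.transcript_id, nrow.transcript_id,
                                  float(prow.r), float(nrow.r))
                ta, tb = tr[case.iso_pos], tr[case.iso_neg]
                if _alt_tss_excluded(ta, tb, probe_pos[pid]):
                    case.label = LABEL_TSS_EXCLUDED
                cases.append(case)
    return cases


def classify_tts(case: SwitchCase, models: Mapping[str, TranscriptModel],
                 probe_pos: int) -> str | None:
    """Label one (non-tss_excluded) case by the 1-kb distal rule.

    Returns None (case not classifiable) when either isoform lacks a
    terminal exon distinct from its first exon, or the two terminal exons
    are identical / end at the same base.
    """
    if case.label == LABEL_TSS_EXCLUDED:
        return LABEL_TSS_EXCLUDED
    tp, tn = models[case.iso_pos], models[case.iso_neg]
    if tp.n_exons < 2 or tn.n_exons < 2:
        logger.debug("case %s/%s: single-exon isoform, skipped", case.gene_id, case.probe_id)
        return None
    if tp.exons[-1] == tn.exons[-1]:
        logger.debug("case %s/%s: identical terminal exons, skipped", case.gene_id, case.probe_id)
        return None
    strand = tp.strand
    end_p, end_n = tp.tts, tn.tts
    if end_p == end_n:
        return None
    # preceding = the terminal exon whose 3' boundary is upstream of the other's
    if strand == "+":
        preceding = tp if end_p < end_n else tn
        d = probe_pos - preceding.tts
    else:
        preceding = tp if end_p > end_n else tn
        d = preceding.tts - probe_pos
    case.preceding_tts_transcript = preceding.transcript_id
    case.dist_beyond_preceding = max(int(d), 0)
    if d < DISTAL_BP:
        case.label = LABEL_PROXIMAL
    elif preceding.transcript_id == case.iso_neg:
        case.label = LABEL_DISTAL_CONSISTENT
    else:
        case.label = LABEL_DISTAL_INCONSISTENT
    return case.label


def classify_all(cases: Sequence[SwitchCase], genes: Sequence[GeneModel],
                 probes: Sequence[ProbeRecord]) -> list[SwitchCase]:
    """classify_tts over a case list; unclassifiable cases are dropped."""
    models = {t.transcript_id: t for g in genes for t in g.transcripts}
    probe_pos = {p.probe_id: p.pos for p in probes}
    out = []
    for c in cases:
        label = classify_tts(c, models, probe_pos[c.probe_id])
        if label is not None:
            out.append(c)
    return out


def distal_fraction(cases: Sequence[SwitchCase]) -> tuple[int, int, float | None]:
    """(n_distal, n_consistent, n_consistent / n_distal); None when no distal case."""
    n_cons = sum(1 for c in cases if c.label == LABEL_DISTAL_CONSISTENT)
    n_distal = n_cons + sum(1 for c in cases if c.label == LABEL_DISTAL_INCONSISTENT)
    frac = (n_cons / n_distal) if n_distal else None
    return n_distal, n_cons, frac


def cases_table(cases: Sequence[SwitchCase]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.gene_id, c.probe_id, c.iso_pos, c.iso_neg, c.r_pos, c.r_neg,
          c.preceding_tts_transcript, c.dist_beyond_preceding, c.label)
         for c in cases],
        columns=["gene_id", "probe_id", "iso_pos", "iso_neg", "r_pos", "r_neg",
                 "preceding_tts", "dist_beyond_preceding", "label"])
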