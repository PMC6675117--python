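"""Probe/transcript/gene filters and isoform-usage computation.

Matrices are pandas DataFrames: rows = features (probes or transcripts),
columns = samples, NaN = missing.  β values live in [0, 1] (array-normalized
upstream; only a range check is applied here); expression is TPM >= 0.
Isoform usage is one transcript's TPM divided by the summed TPM of all
retained transcripts of its gene in that sample, undefined (NaN) where the
gene total is zero.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import GeneModel, ProbeRecord, SEX_CHROMS

logger = logging.getLogger(__name__)

MAX_MISSING_RATE = 0.90


def read_matrix(path) -> pd.DataFrame:
    """TSV matrix: header row = sample ids, first column = feature id."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    df.index = df.index.astype(str)
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, na_rep="NA")


def validate_beta(beta: pd.DataFrame) -> None:
    vals = beta.to_numpy(float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValueError("beta values outside [0, 1]")


def filter_probes(beta: pd.DataFrame, probe_records: Sequence[ProbeRecord],
                  max_missing: float = MAX_MISSING_RATE) -> pd.DataFrame:
    """Drop flagged probes (sex-chromosome, cross-reactive, SNP-proximal)
    and probes missing in >= ``max_missing`` of samples.

    Flags are consumed from the manifest, not derived here.  Raises if no
    probe survives.
    """
    flagged = {p.probe_id for p in probe_records if p.flags}
    sexchrom = {p.probe_id for p in probe_records if p.chrom in SEX_CHROMS}
    drop_flag = beta.index.isin(flagged | sexchrom)
    missing_rate = beta.isna().mean(axis=1).to_numpy()
    drop_missing = missing_rate >= max_missing
    kept = beta.loc[~(drop_flag | drop_missing)]
    logger.info("filter_probes: %d flagged/sex, %d high-missing, %d kept",
                int(drop_flag.sum()), int((drop_missing & ~drop_flag).sum()), len(kept))
    if kept.empty:
        raise ValueError("no probes survive filters")
    return kept


def filter_transcripts(tpm: pd.DataFrame, genes: Sequence[GeneModel],
                       tumor_sample_ids: Sequence[str],
                       intragenic_probes: Mapping[str, Iterable[str]],
                       ) -> tuple[pd.DataFrame, list[GeneModel]]:
    """Expression filter, then gene-level filters.

    1. transcripts with median TPM (over tumor samples) <= 0 are dropped;
    2. genes are dropped when fewer than 2 isoforms survive, when on a sex
       chromosome, or when no surviving intragenic probe remains
       (``intragenic_probes`` maps gene_id -> surviving probe ids).

    Returns the filtered TPM matrix and the retained GeneModels with their
    transcript lists pruned to surviving isoforms.
    """
    tumor_cols = [s for s in tumor_sample_ids if s in tpm.columns]
    if not tumor_cols:
        raise ValueError("no tumor samples present in TPM matrix")
    med = tpm[tumor_cols].median(axis=1)
    expressed = set(tpm.index[med > 0])
    logger.info("filter_transcripts: %d/%d transcripts pass median TPM > 0",
                len(expressed), len(tpm))

    kept_genes: list[GeneModel] = []
    kept_tids: list[str] = []
    for g in genes:
        surv = tuple(t for t in g.transcripts if t.transcript_id in expressed)
        if len(surv) < 2:
            continue
        if g.chrom in SEX_CHROMS:
            continue
        if not set(intragenic_probes.get(g.gene_id, ())):
            continue
        kept_genes.append(GeneModel(gene_id=g.gene_id, transcripts=surv))
        kept_tids.extend(t.transcript_id for t in surv)
    if not kept_genes:
        logger.warning("filter_transcripts: no genes retained")
    return tpm.loc[tpm.index.intersection(kept_tids)], kept_genes


def gene_of_transcript(genes: Sequence[GeneModel]) -> pd.Series:
    """transcript_id -> gene_id mapping as a Series."""
    return pd.Series({t.transcript_id: g.gene_id for g in genes for t in g.transcripts})


def compute_usage(tpm: pd.DataFrame, genes: Sequence[GeneModel]) -> pd.DataFrame:
    """usage(t, s) = TPM(t, s) / sum of TPM over gene(t)'s isoforms in s.

    NaN where the gene's total is zero in a sample.  Transcripts absent from
    ``genes`` are dropped.
    """
    if (tpm.to_numpy(float) < 0).any():
        raise ValueError("negative TPM")
    t2g = gene_of_transcript(genes)
    common = tpm.index.intersection(t2g.index)
    sub = tpm.loc[common]
    gids = t2g.loc[common]
    totals = sub.groupby(gids.to_numpy()).transform("sum")
    with np.errstate(divide="ignore", invalid="ignore"):
        usage = sub / totals.where(totals > 0)
    return usage


def variable_probe_quantile(beta: pd.DataFrame, q: float = 0.25) -> pd.Series:
    """Per-probe standard deviation across samples (missing excluded)."""
    return beta.std(axis=1, ddof=1, skipna=True)
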