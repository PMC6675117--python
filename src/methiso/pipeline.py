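"""End-to-end cohort analysis: files in, result tables out.

Order of operations mirrors the analysis recipe: load annotation, CpG
islands and probes; filter probes and transcripts; compute isoform usage;
correlate every intragenic (isoform, probe) pair among tumor samples;
estimate the permutation eFDR threshold; keep |r| > r_min pairs among
top-quartile-variability probes; then run the positional sign-enrichment,
distal-TTS switch, and cluster-association analyses on the retained set.

All outputs are plain TSV/JSON and byte-deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cluster_assoc, correlate, position_enrich, switching
from .genome_model import CgiIndex, annotate_probe_contexts, assign_all_pairs, \
    intragenic_pairs, load_annotation, load_probe_manifest
from .preprocess import compute_usage, filter_probes, filter_transcripts, \
    read_matrix, validate_beta

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    method: str = "pearson"
    efdr_target: float = 0.1
    permutations: int = 100
    r_min: float = 0.3
    top_var: float = 0.25
    min_n: int = 30
    k_clusters: int = 4
    cluster_permutations: int = 1000
    seed: int = 0


@dataclass
class PipelineResult:
    verdict: str
    summary: dict
    records: pd.DataFrame
    sig_pairs: pd.DataFrame
    efdr: correlate.EFDRResult
    assignments: pd.DataFrame
    promoter_body: position_enrich.EnrichmentResult | None
    profiles: pd.DataFrame
    enrichments: pd.DataFrame
    context_first_1kb: position_enrich.EnrichmentResult | None
    switch_cases: pd.DataFrame
    switch_counts: tuple[int, int, float | None]
    cluster: cluster_assoc.ClusterAssocResult | None
    outputs: dict = field(default_factory=dict)


def first_exon_1kb_mask(assign: pd.DataFrame) -> pd.Series:
    """Pairs within 1 kb around the first-exon boundaries (inside-near or
    flank with |offset| <= 1 kb)."""
    return (assign.anchor == "first") & (
        (assign.location == "inside_near")
        | ((assign.location == "flank") & (assign.signed_offset.abs() <= 1000)))


def run_pipeline(gtf, cgi_bed, probes_tsv, beta_tsv, tpm_tsv, samples_tsv,
                 outdir=None, config: PipelineConfig | None = None) -> PipelineResult:
    cfg = config or PipelineConfig()
    genes = load_annotation(gtf)
    cgi = CgiIndex.from_bed(cgi_bed)
    probes = annotate_probe_contexts(load_probe_manifest(probes_tsv), cgi)
    beta = read_matrix(beta_tsv)
    validate_beta(beta)
    tpm = read_matrix(tpm_tsv)
    meta = pd.read_csv(samples_tsv, sep="\t", index_col=0)
    tumor_ids = [s for s in meta.index[meta.group == "tumor"] if s in beta.columns]

    beta_f = filter_probes(beta, probes)
    probes_f = [p for p in probes if p.probe_id in beta_f.index]
    pair_index = intragenic_pairs(genes, probes_f)
    probes_by_gene: dict[str, set[str]] = {}
    for gid, _, pid in pair_index:
        probes_by_gene.setdefault(gid, set()).add(pid)

    tpm_f, genes_f = filter_transcripts(tpm, genes, tumor_ids, probes_by_gene)
    usage = compute_usage(tpm_f, genes_f)
    kept_tids = set(usage.index)
    pairs = pd.DataFrame([t for t in pair_index if t[1] in kept_tids],
                         columns=["gene_id", "transcript_id", "probe_id"])

    beta_t = beta_f[tumor_ids]
    usage_t = usage[tumor_ids]
    records = correlate.pair_correlations(usage_t, beta_t, pairs,
                                          method=cfg.method, min_n=cfg.min_n)
    efdr = correlate.empirical_fdr(usage_t, beta_t, pairs, B=cfg.permutations,
                                   target=cfg.efdr_target, seed=cfg.seed,
                                   method=cfg.method, min_n=cfg.min_n)
    variable = correlate.select_variable_probes(beta_t, q=cfg.top_var)
    sig, verdict, summary = correlate.significant_pairs(records, efdr, variable,
                                                        r_min=cfg.r_min)
    summary["r_star"] = efdr.r_star
    summary["verdict"] = verdict
    assignments = assign_all_pairs(genes_f, probes_f)

    promoter_body = None
    profiles = pd.DataFrame()
    enrichments = pd.DataFrame()
    ctx_first = None
    cases_df = pd.DataFrame(columns=["gene_id", "probe_id", "iso_pos", "iso_neg",
                                     "r_pos", "r_neg", "preceding_tts",
                                     "dist_beyond_preceding", "label"])
    switch_counts: tuple[int, int, float | None] = (0, 0, None)
    cluster_res = None
    if len(sig):
        # region labels: one region per (transcript, probe) pair
        region = (assignments.drop_duplicates(["transcript_id", "probe_id"])
                  [["transcript_id", "probe_id", "region"]])
        sig_region = sig.merge(region, on=["transcript_id", "probe_id"], how="left")
        promoter_body = position_enrich.promoter_body_odds(sig_region.dropna(subset=["region"]))

        prof_parts = []
        enr_parts = []
        analyses = [("first", None, None), ("middle", 2, None),
                    ("middle", None, 4), ("terminal", None, 4),
                    ("terminal_pooled", None, None)]
        for anchor, k, kmin in analyses:
            prof = position_enrich.anchor_profile(sig, assignments, anchor, k, kmin)
            name = prof.label.str.split(":").str[0].iloc[0] if len(prof) else anchor
            prof.insert(0, "analysis", name)
            prof_parts.append(prof)
            for sign in ("negative", "positive"):
                enr = position_enrich.window_enrichment(prof, sign=sign)
                enr.insert(0, "analysis", name)
                enr.insert(1, "sign", sign)
                enr_parts.append(enr)
        profiles = pd.concat(prof_parts, ignore_index=True)
        enrichments = pd.concat(enr_parts, ignore_index=True)

        first_bin = assignments[first_exon_1kb_mask(assignments)]
        bin_pairs = sig.merge(
            first_bin[["transcript_id", "probe_id", "context"]].drop_duplicates(),
            on=["transcript_id", "probe_id"], how="inner")
        if len(bin_pairs):
            ctx_first = position_enrich.context_enrichment(bin_pairs, "open_sea",
                                                           sign="negative")

        cases = switching.find_switch_cases(sig, genes_f, probes_f, r_min=cfg.r_min)
        cases = switching.classify_all(cases, genes_f, probes_f)
        cases_df = switching.cases_table(cases)
        switch_counts = switching.distal_fraction(cases)

        sig_probes = sorted(sig.probe_id.unique())
        sig_tids = sorted(sig.transcript_id.unique())
        all_samples = [s for s in meta.index if s in beta_f.columns]
        if len(all_samples) >= cfg.k_clusters and len(sig_probes) >= 1:
            cluster_res = cluster_assoc.cluster_association(
                beta_f.loc[sig_probes, all_samples], usage.loc[sig_tids],
                k=cfg.k_clusters, B=cfg.cluster_permutations, seed=cfg.seed + 1)

    result = PipelineResult(verdict, summary, records, sig, efdr, assignments,
                            promoter_body, profiles, enrichments, ctx_first,
                            cases_df, switch_counts, cluster_res)
    if outdir is not None:
        result.outputs = write_outputs(result, outdir)
    return result


def write_outputs(res: PipelineResult, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def tsv(name, df, **kw):
        p = outdir / name
        df.to_csv(p, sep="\t", index=False, na_rep="NA", **kw)
        paths[name] = p

    tsv("correlations.tsv", res.records)
    tsv("efdr.tsv", res.efdr.as_frame())
    tsv("sig_pairs.tsv", res.sig_pairs)
    tsv("assignments.tsv", res.assignments)
    tsv("profiles.tsv", res.profiles)
    tsv("enrichments.tsv", res.enrichments)
    tsv("switch_cases.tsv", res.switch_cases)
    n_distal, n_cons, frac = res.switch_counts
    summary = dict(res.summary)
    summary.update({"n_distal": n_distal, "n_distal_consistent": n_cons,
                    "distal_fraction": frac})
    if res.promoter_body is not None and not res.promoter_body.undefined:
        summary["promoter_body_or"] = res.promoter_body.odds_ratio
        summary["promoter_body_p"] = res.promoter_body.p
    if res.context_first_1kb is not None and not res.context_first_1kb.undefined:
        summary["osr_first1kb_or"] = res.context_first_1kb.odds_ratio
        summary["osr_first1kb_p"] = res.context_first_1kb.p
    if res.cluster is not None:
        summary.update({"cluster_T": res.cluster.T, "cluster_p": res.cluster.p_perm,
                        "cluster_Dw": res.cluster.Dw, "cluster_Db": res.cluster.Db})
        labels = res.cluster.labels.rename("cluster").to_frame()
        labels.insert(0, "sample_id", labels.index)
        tsv("clusters.tsv", labels.reset_index(drop=True))
    p = outdir / "summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n")
    paths["summary.json"] = p
    return paths
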