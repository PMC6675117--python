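"""Synthetic annotations and coupled methylation/expression cohorts.

Every pipeline stage is testable without downloads: this module emits a toy
genome annotation (GTF), CpG-island track (BED), probe manifest and
β/TPM sample matrices in which (isoform, probe) couplings are *planted* at
known positions with known signs and known population correlation strength.

Planted gene archetypes (each gene carries one driver probe coupled to the
usage of its "A" isoform; the second isoform mirrors with opposite sign):

====================  =====================================================
first_neg             negative driver 500 bp upstream of the first exon,
                      open-sea context (promoter methylation repressing a
                      transcription start site)
cgi_pos               positive driver 300 bp upstream of the first exon,
                      inside a CpG island (activating promoter methylation)
first_pos             positive driver 1.2 kb downstream of the first-exon
                      end (gene-body methylation, still in the first-exon
                      flank analysis)
middle2_neg           negative driver 500 bp upstream of the second exon
                      (start-site repression bleeding into exon 2)
middle_pos            positive driver 300 bp upstream of a middle exon of
                      ordinal 5 (elongation-linked gene-body methylation)
tts_near / tts_far    positive driver inside a long (3 kb) alternative
                      terminal exon of ordinal 5, <1 kb / >1 kb from its
                      boundaries; the short isoform terminates >=1 kb
                      upstream of the probe, so the gene is a planted
                      distal-TTS switch (probe positively correlated with
                      the downstream-TTS isoform, negatively with the
                      preceding-TTS isoform)
====================  =====================================================

β values are logit-normal per probe (heteroscedastic by construction, with
mean-dependent variance); driver probes are high-variance so they fall in
the top variability quartile, and carry cluster-specific mean shifts that
induce the tumor-subtype structure.  Usage is coupled to β through a
softmax/sigmoid so per-gene usages always sum to one; the coupling slope is
fixed in the quasi-linear zone of the sigmoid and the usage noise scale is
solved by Gauss-Hermite quadrature so that the population correlation of
each planted pair hits its target (raising ValueError when the target is
unattainable).  Normal (non-tumor) samples come from a shifted baseline
with no planted couplings.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .genome_model import (CgiIndex, GeneModel, ProbeRecord, TranscriptModel,
                           annotate_probe_contexts)

ARCHETYPES = ("first_neg", "cgi_pos", "first_pos", "middle2_neg",
              "middle_pos", "tts_near", "tts_far")
ARCHETYPE_SIGN = {"first_neg": -1, "cgi_pos": +1, "first_pos": +1,
                  "middle2_neg": -1, "middle_pos": +1, "tts_near": +1,
                  "tts_far": +1}

GENE_STRIDE = 60_000          # bp allotted per gene on the toy chromosome
GENE_WINDOW = 52_000          # reflection window for minus-strand genes
EXON_PITCH = 8_000
EXON_LEN = 300
TERMINAL_LEN = 500
LONG_TERMINAL_LEN = 3_000


@dataclass(frozen=True)
class PlantedEffect:
    """One planted coupling class: archetype, sign, target |r|, gene fraction."""
    klass: str
    sign: int
    target_r: float
    fraction: float


def default_effects(target_r: float = 0.5, planted_fraction: float = 0.5
                    ) -> tuple[PlantedEffect, ...]:
    frac = planted_fraction / len(ARCHETYPES)
    return tuple(PlantedEffect(k, ARCHETYPE_SIGN[k], target_r, frac)
                 for k in ARCHETYPES)


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 56
    n_tumor: int = 150
    n_normal: int = 8
    n_clusters: int = 4
    cluster_effect: float = 0.8          # spread of cluster logit shifts at drivers
    effects: tuple[PlantedEffect, ...] = field(default_factory=default_effects)
    n_null_probes_per_gene: int = 6
    cgi_density: float = 0.15            # fraction of null-gene probes put in islands
    probe_sigma_planted: float = 1.0     # latent logit SD of driver probes
    probe_sigma_null: tuple[float, float] = (0.10, 0.35)
    usage_noise_sd: float = 0.5          # isoform logit noise, uncoupled genes
    zero_noise: bool = False             # deterministic couplings (no usage noise)
    slope_logits: float = 1.2            # coupling slope x SD(beta), sigmoid logits
    gene_expr_log_mean: float = math.log(50.0)
    gene_expr_log_sd: float = 0.4
    include_decoys: bool = False         # chrX gene, flagged and high-missing probes
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_tumor < 2 or self.n_clusters < 1:
            raise ValueError("counts must be positive")
        for e in self.effects:
            if not 0 < e.target_r < 1:
                raise ValueError("planted |r| must be in (0, 1)")
            if e.klass not in ARCHETYPES:
                raise ValueError(f"unknown archetype {e.klass!r}")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _std_exons(n: int = 6) -> list[tuple[int, int]]:
    """n exons at 8-kb pitch, 300 bp each, 500-bp terminal exon."""
    ex = [(k * EXON_PITCH, k * EXON_PITCH + EXON_LEN) for k in range(n - 1)]
    ex.append(((n - 1) * EXON_PITCH, (n - 1) * EXON_PITCH + TERMINAL_LEN))
    return ex


def _archetype_geometry(klass: str) -> tuple[list[tuple[int, int]], list[tuple[int, int]], int, tuple[int, int] | None]:
    """(exons_A, exons_B, driver_pos, cgi_interval) in gene-local + coords."""
    if klass in ("tts_near", "tts_far"):
        ex_a = _std_exons(5)
        ex_a[-1] = (4 * EXON_PITCH, 4 * EXON_PITCH + LONG_TERMINAL_LEN)  # 3-kb terminal
        ex_b = _std_exons(5)[:3]
        ex_b[-1] = (2 * EXON_PITCH, 2 * EXON_PITCH + EXON_LEN)
        driver = 4 * EXON_PITCH + (400 if klass == "tts_near" else 1500)
        cgi = (driver - 150, driver + 150) if klass == "tts_far" else None
        return ex_a, ex_b, driver, cgi
    ex_a = _std_exons(6)
    if klass in ("first_neg", "cgi_pos", "first_pos"):
        # distinct alternative first exon >2.5 kb from every driver position
        ex_b = [(4000, 4300)] + ex_a[1:]
    elif klass == "middle2_neg":
        ex_b = [ex_a[0], ex_a[4], ex_a[5]]
    elif klass == "middle_pos":
        ex_b = [ex_a[0], ex_a[1], ex_a[5]]
    else:
        raise ValueError(klass)
    driver = {"first_neg": -500, "cgi_pos": -300,
              "first_pos": EXON_LEN + 1199,          # d = 1.2 kb past exon-1 end
              "middle2_neg": EXON_PITCH - 500,       # 500 bp upstream of exon 2
              "middle_pos": 4 * EXON_PITCH - 300,    # 300 bp upstream of exon 5
              }[klass]
    cgi = (driver - 150, driver + 150) if klass == "cgi_pos" else None
    return ex_a, ex_b, driver, cgi


def _null_geometry() -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    ex_a = _std_exons(6)
    ex_b = [ex_a[0]] + ex_a[2:]
    return ex_a, ex_b


def _reflect(x: int, base: int) -> int:
    return base + (GENE_WINDOW - 1) - (x - base)


def _reflect_ival(iv: tuple[int, int], base: int) -> tuple[int, int]:
    s, e = iv
    return _reflect(e - 1, base), _reflect(s, base) + 1


# ---------------------------------------------------------------------------
# annotation assembly
# ---------------------------------------------------------------------------

@dataclass
class GenePlan:
    gene_id: str
    klass: str                    # archetype or 'null'
    strand: str
    chrom: str
    exons_a: list[tuple[int, int]]
    exons_b: list[tuple[int, int]]
    driver_probe: str | None
    sign: int
    target_r: float
    probe_ids: list[str]


@dataclass
class Annotation:
    genes: list[GeneModel]
    probes: list[ProbeRecord]
    cgi: CgiIndex
    plans: list[GenePlan]
    gtf_text: str
    bed_text: str
    manifest: pd.DataFrame


def make_annotation(config: SyntheticConfig, seed: int | None = None) -> Annotation:
    """Deterministic toy annotation with planted-probe placement.

    Gene strand alternates; minus-strand genes are coordinate reflections of
    the plus-strand template, so every positional class is exercised on both
    strands.  Raises on infeasible geometry (driver offset outside its
    exon/flank) — guarded by construction but revalidated here.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_planted = {e.klass: int(round(e.fraction * config.n_genes)) for e in config.effects}
    effect_by_class = {e.klass: e for e in config.effects}
    klasses: list[str] = []
    for k in ARCHETYPES:
        klasses += [k] * n_planted.get(k, 0)
    if len(klasses) > config.n_genes:
        raise ValueError("planted fractions exceed the gene count")
    klasses += ["null"] * (config.n_genes - len(klasses))

    plans: list[GenePlan] = []
    probes: list[ProbeRecord] = []
    islands: list[tuple[int, int]] = []
    probe_rows = []
    for gi, klass in enumerate(klasses):
        base = 10_000 + gi * GENE_STRIDE
        strand = "+" if gi % 2 == 0 else "-"
        gid = f"G{gi:04d}"
        if klass == "null":
            ex_a, ex_b = _null_geometry()
            driver_local, cgi_local, sign, target = None, None, 0, 0.0
        else:
            ex_a, ex_b, driver_local, cgi_local = _archetype_geometry(klass)
            eff = effect_by_class[klass]
            sign, target = eff.sign, eff.target_r
        span_lo = min(s for s, _ in ex_a + ex_b)
        span_hi = max(e for _, e in ex_a + ex_b)
        if driver_local is not None and not (span_lo - 2000 <= driver_local < span_hi + 2000):
            raise ValueError(f"infeasible geometry: driver outside reach for {klass}")

        # genomic coordinates (+ reflection for minus strand)
        def g(iv):
            iv = (iv[0] + base, iv[1] + base)
            return _reflect_ival(iv, base) if strand == "-" else iv

        def gp(x):
            x = x + base
            return _reflect(x, base) if strand == "-" else x

        exons_a = sorted(g(iv) for iv in ex_a)
        exons_b = sorted(g(iv) for iv in ex_b)
        pids = []
        driver_pid = None
        if driver_local is not None:
            driver_pid = f"cg{gi:04d}_drv"
            probes.append(ProbeRecord(driver_pid, config.chrom, gp(driver_local)))
            pids.append(driver_pid)
            if cgi_local is not None:
                islands.append(g(cgi_local))
        # null probes scattered through the intragenic span
        lo, hi = span_lo - 1800, span_hi + 1800
        for j in range(config.n_null_probes_per_gene):
            pos = int(rng.integers(lo, hi))
            pid = f"cg{gi:04d}_n{j}"
            probes.append(ProbeRecord(pid, config.chrom, gp(pos)))
            pids.append(pid)
            if klass == "null" and rng.random() < config.cgi_density:
                islands.append(g((pos - 100, pos + 100)))
        plans.append(GenePlan(gid, klass, strand, config.chrom,
                              exons_a, exons_b, driver_pid, sign, target, pids))

    if config.include_decoys:
        base = 10_000
        ex_a, ex_b = _null_geometry()
        plans.append(GenePlan("GX000", "decoy_chrX", "+", "chrX",
                              [(s + base, e + base) for s, e in ex_a],
                              [(s + base, e + base) for s, e in ex_b],
                              None, 0, 0.0, ["cgX_0"]))
        probes.append(ProbeRecord("cgX_0", "chrX", base + 100))
        probes.append(ProbeRecord("cg_flagged_xr", config.chrom, 10_100,
                                  flags=frozenset({"cross_reactive"})))
        probes.append(ProbeRecord("cg_missing", config.chrom, 10_200))
        plans[0].probe_ids.extend(["cg_flagged_xr", "cg_missing"])

    genes = []
    for p in plans:
        ta = TranscriptModel(p.gene_id + ".A", p.gene_id, p.chrom, p.strand,
                             tuple(p.exons_a if p.strand == "+" else p.exons_a[::-1]))
        tb = TranscriptModel(p.gene_id + ".B", p.gene_id, p.chrom, p.strand,
                             tuple(p.exons_b if p.strand == "+" else p.exons_b[::-1]))
        genes.append(GeneModel(p.gene_id, (ta, tb)))

    cgi = CgiIndex({config.chrom: islands} if islands else {})
    probes = annotate_probe_contexts(probes, cgi)
    gtf_text = _emit_gtf(genes)
    bed_text = "".join(f"{config.chrom}\t{s}\t{e}\tCGI_{i}\n"
                       for i, (s, e) in enumerate(sorted(islands)))
    manifest = pd.DataFrame(
        [(p.probe_id, p.chrom, p.pos, ",".join(sorted(p.flags))) for p in probes],
        columns=["probe_id", "chrom", "pos", "flags"])
    return Annotation(genes, probes, cgi, plans, gtf_text, bed_text, manifest)


def _emit_gtf(genes: list[GeneModel]) -> str:
    out = io.StringIO()
    for g in genes:
        gs = min(t.span[0] for t in g.transcripts)
        ge = max(t.span[1] for t in g.transcripts)
        attrs = f'gene_id "{g.gene_id}";'
        out.write(f"{g.chrom}\tsynthetic\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\t{attrs}\n")
        for t in g.transcripts:
            ts, te = t.span
            at = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
            out.write(f"{g.chrom}\tsynthetic\ttranscript\t{ts + 1}\t{te}\t.\t{t.strand}\t.\t{at}\n")
            for s, e in sorted(t.exons):
                out.write(f"{g.chrom}\tsynthetic\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{at}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# coupling calibration: solve the usage-noise scale for a target correlation
# ---------------------------------------------------------------------------

_GH_NODES = 48


def _planted_corr(slope: float, eps_sd: float, mu_shifts: np.ndarray,
                  sigma_z: float) -> float:
    """Population corr(usage, β) for usage = sigmoid(slope*(β - Eβ) + ε).

    β = sigmoid(z), z an equal-weight normal mixture over cluster mean
    shifts with SD sigma_z; ε ~ N(0, eps_sd).  Evaluated by Gauss-Hermite
    quadrature over (z, ε).
    """
    x, wx = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    wx = wx / wx.sum()
    z = (mu_shifts[:, None] + sigma_z * x[None, :]).ravel()          # components x nodes
    wz = np.repeat(wx[None, :], len(mu_shifts), axis=0).ravel() / len(mu_shifts)
    beta = expit(z)
    m = float(beta @ wz)
    eta = slope * (beta - m)
    if eps_sd == 0:
        u = expit(eta)
        Eu, Eb = u @ wz, m
        Eub = (u * beta) @ wz
        Vu = (u * u) @ wz - Eu ** 2
        Vb = (beta * beta) @ wz - Eb ** 2
        return float((Eub - Eu * Eb) / math.sqrt(Vu * Vb))
    e, we = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    we = we / we.sum()
    U = expit(eta[:, None] + eps_sd * e[None, :])  # z x eps
    u_mean = U @ we
    u2_mean = (U * U) @ we
    Eu = float(u_mean @ wz)
    Eb = m
    Eub = float((u_mean * beta) @ wz)
    Vu = float(u2_mean @ wz) - Eu ** 2
    Vb = float((beta * beta) @ wz - Eb ** 2)
    return float((Eub - Eu * Eb) / math.sqrt(Vu * Vb))


def _mixture_beta_moments(mu_shifts: np.ndarray, sigma_z: float
                          ) -> tuple[float, float]:
    """(mean, SD) of β = sigmoid(z), z an equal-weight normal mixture."""
    x, wx = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    wx = wx / wx.sum()
    z = (mu_shifts[:, None] + sigma_z * x[None, :]).ravel()
    wz = np.repeat(wx[None, :], len(mu_shifts), axis=0).ravel() / len(mu_shifts)
    beta = expit(z)
    m = float(beta @ wz)
    sd = math.sqrt(float((beta * beta) @ wz) - m * m)
    return m, sd


def solve_noise_for_target(target_r: float, mu_shifts: np.ndarray,
                           sigma_z: float, slope_logits: float
                           ) -> tuple[float, float]:
    """(slope, eps_sd) giving population corr == target_r.

    The slope is fixed so that slope x SD(β) = ``slope_logits`` (quasi-linear
    sigmoid zone); the usage noise SD is solved by bisection.  Raises when
    the target exceeds the zero-noise correlation.
    """
    _, sd_beta = _mixture_beta_moments(mu_shifts, sigma_z)
    slope = slope_logits / sd_beta
    r_max = _planted_corr(slope, 0.0, mu_shifts, sigma_z)
    if target_r >= r_max:
        raise ValueError(f"target |r|={target_r} unattainable: zero-noise "
                         f"correlation is {r_max:.4f} at this slope/β spread")
    f = lambda s: _planted_corr(slope, s, mu_shifts, sigma_z) - target_r
    eps_sd = brentq(f, 1e-9, 60.0, xtol=1e-6)
    return slope, float(eps_sd)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    planted_pairs: pd.DataFrame     # gene, transcript, anti_transcript, probe, klass, sign, target_r
    clusters: pd.Series             # tumor sample -> cluster label
    switch_genes: list[str]         # genes planted with the distal-TTS rule

    def as_frame(self) -> pd.DataFrame:
        return self.planted_pairs


def simulate_cohort(config: SyntheticConfig, annotation: Annotation,
                    seed: int | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """(beta, tpm, sample metadata, ground truth) for one cohort.

    Tumor samples carry the planted couplings and cluster structure; normal
    samples are drawn from a shifted baseline with no couplings.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tumors = [f"T{i:03d}" for i in range(config.n_tumor)]
    normals = [f"N{i:02d}" for i in range(config.n_normal)]
    samples = tumors + normals
    n_t, n_n = len(tumors), len(normals)

    k = config.n_clusters
    clusters = np.repeat(np.arange(1, k + 1), math.ceil(n_t / k))[:n_t]
    clusters = clusters[rng.permutation(n_t)]
    shifts = (np.linspace(-1.0, 1.0, k) * config.cluster_effect if k > 1
              else np.zeros(1))

    probes = annotation.probes
    probe_ids = [p.probe_id for p in probes]
    driver_set = {p.driver_probe for p in annotation.plans if p.driver_probe}
    mu = rng.uniform(-1.0, 1.0, size=len(probes))
    sig = rng.uniform(*config.probe_sigma_null, size=len(probes))
    for i, pid in enumerate(probe_ids):
        if pid in driver_set:
            mu[i] = 0.0
            sig[i] = config.probe_sigma_planted

    Z = np.empty((len(probes), n_t + n_n))
    eps = rng.standard_normal((len(probes), n_t + n_n))
    for i, pid in enumerate(probe_ids):
        row = mu[i] + sig[i] * eps[i]
        if pid in driver_set:
            row[:n_t] += shifts[clusters - 1]
        else:
            row[n_t:] -= 0.5          # normals: shifted baseline
        Z[i] = row
    beta = pd.DataFrame(expit(Z), index=probe_ids, columns=samples)

    if config.include_decoys and "cg_missing" in beta.index:
        n_missing = int(math.ceil(0.95 * len(samples)))
        cols = rng.choice(len(samples), size=n_missing, replace=False)
        beta.loc["cg_missing", beta.columns[cols]] = np.nan

    # usage and TPM
    solve_cache: dict[float, tuple[float, float]] = {}
    tpm_rows = {}
    truth_rows = []
    switch_genes = []
    for plan in annotation.plans:
        tid_a, tid_b = plan.gene_id + ".A", plan.gene_id + ".B"
        expr = np.exp(config.gene_expr_log_mean
                      + config.gene_expr_log_sd * rng.standard_normal(n_t + n_n))
        if plan.driver_probe is not None:
            key = plan.target_r
            if key not in solve_cache:
                if config.zero_noise:
                    _, sd_b = _mixture_beta_moments(shifts, config.probe_sigma_planted)
                    solve_cache[key] = (config.slope_logits / sd_b, 0.0)
                else:
                    solve_cache[key] = solve_noise_for_target(
                        key, shifts, config.probe_sigma_planted, config.slope_logits)
            slope, eps_sd = solve_cache[key]
            b_row = beta.loc[plan.driver_probe].to_numpy()
            m, _ = _mixture_beta_moments(shifts, config.probe_sigma_planted)
            eta = plan.sign * slope * (b_row - m)
            eta[:n_t] += eps_sd * rng.standard_normal(n_t)
            # normals: no coupling, baseline usage noise
            eta[n_t:] = config.usage_noise_sd * rng.standard_normal(n_n)
            usage_a = expit(eta)
            truth_rows.append((plan.gene_id, tid_a, tid_b, plan.driver_probe,
                               plan.klass, plan.sign, plan.target_r))
            if plan.klass in ("tts_near", "tts_far"):
                switch_genes.append(plan.gene_id)
        else:
            logits = config.usage_noise_sd * rng.standard_normal((2, n_t + n_n))
            usage_a = expit(logits[0] - logits[1])
        tpm_rows[tid_a] = expr * usage_a
        tpm_rows[tid_b] = expr * (1.0 - usage_a)

    tpm = pd.DataFrame(tpm_rows, index=samples).T
    meta = pd.DataFrame({
        "sample_id": samples,
        "group": ["tumor"] * n_t + ["normal"] * n_n,
        "cluster": list(clusters) + [0] * n_n,
        "subtype": [f"C{c}" for c in clusters] + ["normal"] * n_n,
    }).set_index("sample_id")
    truth = GroundTruth(
        pd.DataFrame(truth_rows, columns=["gene_id", "transcript_id",
                                          "anti_transcript_id", "probe_id",
                                          "klass", "sign", "target_r"]),
        pd.Series(clusters, index=tumors, name="cluster"),
        switch_genes)
    return beta, tpm, meta, truth


# ---------------------------------------------------------------------------
# cluster-shift usage generator (for the T-statistic calibration studies)
# ---------------------------------------------------------------------------

def simulate_usage_clusters(n_samples: int = 120, n_isoforms: int = 40,
                            k: int = 4, shift: float = 0.15,
                            frac_shifted: float = 0.2, noise_sd: float = 0.15,
                            seed: int | None = None
                            ) -> tuple[pd.DataFrame, pd.Series]:
    """Usage matrix with cluster-linked mean shifts planted at a fraction of
    isoforms (shift = 0 gives an exchangeable null)."""
    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    labels = np.repeat(np.arange(1, k + 1), math.ceil(n_samples / k))[:n_samples]
    labels = labels[rng.permutation(n_samples)]
    base = rng.uniform(0.3, 0.7, size=n_isoforms)
    X = base[:, None] + noise_sd * rng.standard_normal((n_isoforms, n_samples))
    n_shifted = int(round(frac_shifted * n_isoforms))
    up_cluster = rng.integers(1, k + 1, size=n_shifted)
    for j in range(n_shifted):
        X[j, labels == up_cluster[j]] += shift
    X = np.clip(X, 0.0, 1.0)
    usage = pd.DataFrame(X, index=[f"iso{j:03d}" for j in range(n_isoforms)],
                         columns=samples)
    return usage, pd.Series(labels, index=samples, name="cluster")


# ---------------------------------------------------------------------------
# dataset writing
# ---------------------------------------------------------------------------

def write_dataset(config: SyntheticConfig, outdir, seed: int | None = None) -> dict[str, Path]:
    """Generate and write the full file set the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    ann = make_annotation(config, seed)
    beta, tpm, meta, truth = simulate_cohort(config, ann, seed + 1)
    paths = {
        "gtf": outdir / "annotation.gtf",
        "bed": outdir / "cgi.bed",
        "probes": outdir / "probes.tsv",
        "beta": outdir / "beta.tsv",
        "tpm": outdir / "tpm.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
    }
    paths["gtf"].write_text(ann.gtf_text)
    paths["bed"].write_text(ann.bed_text)
    ann.manifest.to_csv(paths["probes"], sep="\t", index=False)
    beta.to_csv(paths["beta"], sep="\t", index_label="probe_id", na_rep="NA")
    tpm.to_csv(paths["tpm"], sep="\t", index_label="transcript_id", na_rep="NA")
    meta.to_csv(paths["samples"], sep="\t")
    truth.planted_pairs.to_csv(paths["truth"], sep="\t", index=False)
    return paths
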