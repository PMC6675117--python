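# Methods

## Analysis model

The unit of analysis is the (isoform, probe) pair. A 450K-style CpG probe is
*intragenic* for a gene when it lies within the union of the gene's
transcript spans extended 2 kb on both sides; each intragenic probe is
paired with every isoform of that gene, and the same probe is positioned
independently within each isoform's exon–intron structure (it can be
first-exonic for one isoform and deep-intronic for another). All
orientation-dependent quantities — upstream/downstream, exon ordinals,
signed offsets — are taken in transcription direction, so minus-strand
genes are exact coordinate reflections of plus-strand ones (a tested
invariant). Internally all coordinates are 0-based half-open; GTF input is
converted once on load, BED is used as-is.

Isoform usage is the proportion usage(t,s) = TPM(t,s) / Σ TPM over the
gene's retained isoforms, undefined where the gene total is zero. It is
scale-invariant in the gene's expression level, which is what lets a
methylation–usage correlation be read as isoform *switching* rather than
expression change.

### Filters

Probes are dropped when flagged (sex chromosome, cross-reactive,
SNP-proximal — flags are consumed from the manifest, not derived) or
missing in ≥ 90 % of samples. Transcripts with median TPM ≤ 0 over tumor
samples are dropped first; genes are then dropped when fewer than two
isoforms survive, when on chrX/Y, or when no surviving intragenic probe
remains. Ordering matters only in degenerate cases; the expression-first
order is the stricter one and is fixed. The median-TPM filter uses tumor
samples only, because all downstream correlations are computed among
tumors; normals pass through for clustering displays.

### Correlation screen and empirical FDR

Pearson r per pair over pairwise-complete samples (Spearman = Pearson on
midranks; with missing data each pair is re-ranked on its complete
samples). Pairs with fewer than `min_n = 30` complete samples (the size of
the smallest cohort this screen is meant for) or numerically zero variance
are omitted.

The null distribution is generated by permuting the sample labels of the β
matrix relative to usage — one global permutation per iteration, which
preserves the correlation structure among probes and among isoforms in the
null; an independent per-pair mode exists behind a flag. With B = 100
permutations (the number is a package default, exposed in configuration)
and a threshold grid of 0.01 steps in [0, 1]:

    eFDR(t) = mean over permutations of #{null |r| ≥ t} / #{observed |r| ≥ t}

capped at 1, defined as 0 where no observed pair reaches t, and made
monotone non-increasing in t by a running minimum (the raw ratio is not
monotone; the monotonized curve has the same r\*). r\* is the smallest grid
threshold with eFDR < 0.1. A cohort is eligible for the downstream
analyses only when r\* ≤ 0.3, so that every pair retained by the |r| > 0.3
screen (strict inequality, probes restricted to the top quartile of
standard deviation, ties at the cutoff broken by probe id) is individually
significant at the target eFDR. On all-null cohorts of 150 samples and
2,000 pairs the realized false-discovery proportion of this race averages
≈ 0.1: the top null pair beats ten times its own permutation rate about
once in ten cohorts. This is intrinsic to an empirical-FDR threshold chosen
at target 0.1 and is verified by simulation in the test suite.

### Positional assignment and window counting

For each pair the anchor exon is the exon whose body or ≤ 2-kb flank
contains the probe. Inside probes are *near* (< 1 kb from the closest
boundary) or *far* (≥ 1 kb). Outside probes contribute to 500-bp windows
starting every 100 bp from the exon boundary out to 2 kb, on each side; a
window is only counted when it fits before the neighbouring exon of the
same transcript (truncation), and a probe inside a flanking exon is never a
flank probe of the anchor. A probe in an intron within 2 kb of two exon
boundaries is assigned to **both** anchors — each anchor analysis counts
pairs independently, so counts are per-analysis, not a global partition.
Probes inside a transcript but beyond every anchor's reach carry only the
promoter/body region label (promoter = upstream of the TSS within 2 kb or
inside the first exon; body = strictly downstream of the first-exon end).

Enrichment of a correlation sign in a bin is the odds ratio against the
pooled remaining bins of the same analysis, with a one-sided upper-tail
hypergeometric p conditioned on pair(-window) counts; no multiple-testing
correction is applied across windows. Zero cells get Haldane–Anscombe +0.5
on all four cells. CpG context (island / 4-kb shore-shelf / open sea, with
island membership taking precedence over a neighbour's flank) supports the
context contrasts within a positional bin.

### Distal-TTS switching

A (gene, probe) with one isoform above +0.3 and another below −0.3 is a
switch case (every sign combination is emitted; `--best-pair` keeps the
strongest). Cases where the two isoforms have distinct first exons *and*
the probe lies in either promoter are set aside as candidate
alternative-TSS regulation; the exclusion rule is one predicate
(`_alt_tss_excluded`) so alternative readings can be swapped in. For the
rest, the *preceding* terminal exon is the one whose 3′ boundary is
upstream in transcription direction; a probe ≥ 1 kb beyond it makes the
case distal, and distal-consistent when the preceding-TTS isoform is the
negatively correlated one. Isoform pairs sharing an identical terminal exon
are unclassifiable and skipped with a log message.

### Cluster association

Samples are clustered on the β values of probes appearing in significant
pairs (Ward linkage on Euclidean distance — unspecified in the underlying
analysis recipe; Ward is the standard choice for 450K subtype work — cut at
k = 4). The association statistic on the usage vectors of the correlated
isoforms is

    Dw = Σ_c Σ_i ‖x_ic − μ_c‖²,  Db = Σ_c n_c ‖μ_c − μ‖²,  T = Db / Dw,

with p from permuting cluster labels (B = 1,000 by default) using the
add-one estimator p = (1 + #{T_perm ≥ T_obs}) / (B + 1), so p ≥ 1/(B+1).
Missing usage entries are imputed with the transcript's cohort mean before
distance computation. Numerically-zero Dw yields T = +∞ with a warning
(all-identical data yields T = 0). The permutation loop uses the
decomposition Db = Σ_c ‖S_c‖²/n_c − ‖S‖²/n with Dw = SS_total − Db, which
depends on labels only through group sums.

### Gene-set enrichment

Genes correlated in ≥ n cohorts are pooled and tested by exact
hypergeometric upper tail against user-supplied sets (GMT), with BH
q-values across sets. The background defaults to the genes analyzable in
≥ n cohorts rather than the whole genome — a deliberate, configurable
choice that makes the test conditional on what the screen could have seen.

## Synthetic-data generator

The generator emulates: β in [0, 1] as logit-normal per probe
(heteroscedastic by construction — variance shrinks toward the 0/1
boundaries), driver probes with high latent SD so they land in the top
variability quartile, cluster-specific mean shifts at driver probes
(k = 4 equal-size clusters, logit shifts spread over ±0.8), lognormal gene
expression, and per-gene usage through a softmax so usages sum to one.
Normal samples come from a shifted baseline with no couplings. Seven gene
archetypes plant one driver coupling each (see the module docstring):
negative at the first exon in open sea, positive at a CGI promoter,
positive in the first-exon far flank, negative upstream of exon 2, positive
upstream of a middle exon of ordinal 5, and positive inside a long (3-kb)
alternative terminal exon at near/far depths — the last also being a
planted distal-TTS switch with alternative termination sites ≥ 1 kb apart.
Geometries are chosen so that the driver probe is positionally assignable
to exactly one isoform (the partner isoform sees it as unreachable or
deep-intronic), keeping each planted sign in exactly one positional class.

The coupling slope is fixed at 1.2 logits per SD(β) — inside the
quasi-linear zone of the sigmoid, so the zero-noise Pearson correlation
stays > 0.99 — and the usage-noise SD is solved by Gauss–Hermite quadrature
(48 nodes per dimension, over the cluster-mixture β distribution) so the
population correlation of each planted pair equals its target; an
unattainable target raises an error. Empirical check: at n = 500, planted
r = 0.5 and r = 0.9 reproduce within ±0.05.

Default study conditions: 56 genes (half planted, 4 per archetype, strand
alternating), 6 null probes per gene, 150 tumor + 8 normal samples,
planted |r| = 0.5 — sample counts in the range of the cohorts this analysis
is designed for, and enough planted pairs that the positional sign patterns
are individually testable. Null cohorts for eFDR calibration use 125
all-null genes × 8 probes (2,000 pairs). The generator is bit-reproducible
for a fixed seed.

**What passing tests do and do not show.** The generator plants one driver
probe per gene with independent β across probes; real 450K data has
spatially correlated probes, cell-type mixture, batch structure, and
gene-level expression confounding, none of which are emulated. Calibration
and recovery results therefore validate the implementation of the
statistics, not their behaviour under real-data confounding (batch removal
and purity correction are explicitly out of scope).

## Numerical choices and degenerate inputs

- Correlation variance guard: a vector whose variance is below
  (10⁻⁷ × scale)² per sample is treated as constant and the pair omitted.
- eFDR with zero observed exceedance is 0 (no discoveries are claimed).
- Identical samples in clustering warn and proceed; k > n raises.
- Usage with gene total 0 is missing, never 0/0.
- Probe exactly at a 2-kb intragenic boundary is included; CGI flank
  boundaries are half-open ([end, end + 4000) is shore-shelf).
- All output tables are written with fixed column order and default float
  formatting, making end-to-end runs byte-identical for a fixed seed.

## Known limitations

- No liftover, no unannotated-isoform inference, no covariate adjustment,
  no batch-effect removal, no functional-consequence prediction for
  switches; pathway testing is against user-supplied GMT files only.
- The alternative-TSS exclusion rule in the switch analysis (distinct first
  exons + promoter overlap) is one reasonable reading of an underspecified
  step and is isolated behind a single predicate.
- Whether a probe equidistant between two exon anchors should be counted
  once or twice is unspecified in the field's practice; this implementation
  double-counts per anchor analysis and documents it.
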