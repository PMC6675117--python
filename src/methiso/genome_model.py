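"""Gene/transcript models and probe-to-isoform positional assignment.

The unit of analysis downstream is the (isoform, probe) pair: a single CpG
probe is assigned a position separately within the exon-intron structure of
every isoform it overlaps, so the same probe can be, e.g., first-exonic for
one isoform and deep-intronic for another.  All orientation-dependent
quantities (upstream/downstream, exon ordinals, signed offsets) are expressed
in transcription direction.

Coordinate conventions: everything internal is 0-based half-open.  GTF input
(1-based closed) is converted on load; BED input is used as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

logger = logging.getLogger(__name__)

#: upstream/downstream reach of the intragenic region and of exon flank
#: windows, in bp
FLANK_BP = 2000
#: inside-exon near/far cut: probes < NEAR_BP from the closest exon boundary
#: are "near", >= NEAR_BP are "far"
NEAR_BP = 1000
#: width of the CpG-island shore+shelf band on each side of an island
SHORE_SHELF_BP = 4000

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptModel:
    """One isoform: exons ordered in transcription direction.

    ``exons[k]`` is the (k+1)-th transcribed exon as a genomic
    ``[start, end)`` interval; for minus-strand transcripts the list is
    therefore in decreasing genomic order.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript with zero exons")
        starts = [s for s, _ in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered:
            raise ValueError(f"{self.transcript_id}: exons not in transcription order")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic [start, end) covered by the transcript."""
        starts, ends = zip(*self.exons)
        return min(starts), max(ends)

    @property
    def tss(self) -> int:
        """Genomic position of the first transcribed base."""
        s, e = self.exons[0]
        return s if self.strand == "+" else e - 1

    @property
    def tts(self) -> int:
        """Genomic position of the last transcribed base."""
        s, e = self.exons[-1]
        return e - 1 if self.strand == "+" else s

    def terminal_exon_3p_boundary(self) -> int:
        """Transcription-direction coordinate of the last transcribed base."""
        return self.tts


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) != 1:
            raise ValueError(f"{self.gene_id}: transcripts on multiple chromosomes")
        if len(strands) != 1:
            raise ValueError(f"{self.gene_id}: inconsistent strand within gene")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def intragenic_span(self) -> tuple[int, int]:
        """Union of transcript spans extended FLANK_BP on both sides."""
        starts, ends = zip(*(t.span for t in self.transcripts))
        return max(0, min(starts) - FLANK_BP), max(ends) + FLANK_BP


@dataclass(frozen=True)
class ProbeRecord:
    probe_id: str
    chrom: str
    pos: int
    context: str = "open_sea"
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("probe position must be >= 0")
        if self.context not in ("CGI", "shore_shelf", "open_sea"):
            raise ValueError(f"bad context {self.context!r}")


@dataclass(frozen=True)
class PairAssignment:
    """Positional class of one probe within one isoform.

    ``signed_offset`` is measured from the nearest boundary of the anchor
    exon in transcription direction: negative for probes upstream of the
    exon, positive downstream, and the inside min-boundary distance for
    probes within the exon.  ``flank_limit`` is the number of usable flank
    bases on the probe's side before the neighbouring exon of the same
    transcript begins (capped at FLANK_BP); window counting truncates there.
    """

    transcript_id: str
    probe_id: str
    region: str                      # promoter | body
    anchor: str                      # first | middle | terminal | none
    anchor_ordinal: int              # 1-based in transcription order; 0 if none
    location: str | None             # inside_near | inside_far | flank | None
    flank_side: str | None           # upstream | downstream | None
    signed_offset: int
    dist_to_boundaries: tuple[int, int]
    flank_limit: int = FLANK_BP


# ---------------------------------------------------------------------------
# annotation loading
# ---------------------------------------------------------------------------

def load_annotation(gtf_path) -> list[GeneModel]:
    """Parse a GTF into GeneModels with transcription-ordered exons.

    Transcripts are reconstructed from ``exon`` features; a ``transcript``
    feature without exon rows is rejected with a warning.  Genes whose
    transcripts disagree on strand raise ``ValueError``.
    """
    gr = pr.read_gtf(str(gtf_path))
    df = gr.df
    exons = df[df.Feature == "exon"]
    declared = set()
    if "transcript" in set(df.Feature):
        declared = set(df.loc[df.Feature == "transcript", "transcript_id"])
    transcripts: dict[str, TranscriptModel] = {}
    for (tid, gid), sub in exons.groupby(["transcript_id", "gene_id"], sort=False, observed=True):
        strand = sub.Strand.iloc[0]
        ivals = sorted(zip(sub.Start.astype(int), sub.End.astype(int)))
        if strand == "-":
            ivals = ivals[::-1]
        transcripts[tid] = TranscriptModel(
            transcript_id=tid, gene_id=gid, chrom=str(sub.Chromosome.iloc[0]),
            strand=str(strand), exons=tuple((int(s), int(e)) for s, e in ivals),
        )
    for tid in declared - set(transcripts):
        logger.warning("transcript %s has zero exons; record rejected", tid)
    genes: dict[str, list[TranscriptModel]] = {}
    for t in transcripts.values():
        genes.setdefault(t.gene_id, []).append(t)
    out = []
    for gid, ts in genes.items():
        ts.sort(key=lambda t: t.transcript_id)
        out.append(GeneModel(gene_id=gid, transcripts=tuple(ts)))
    out.sort(key=lambda g: g.gene_id)
    return out


# ---------------------------------------------------------------------------
# CpG-island context
# ---------------------------------------------------------------------------

class CgiIndex:
    """Sorted CpG-island intervals per chromosome, for context lookup."""

    def __init__(self, intervals_by_chrom: Mapping[str, Sequence[tuple[int, int]]]):
        self._idx: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivals in intervals_by_chrom.items():
            ivals = sorted(ivals)
            starts = np.array([s for s, _ in ivals], dtype=np.int64)
            ends = np.array([e for _, e in ivals], dtype=np.int64)
            self._idx[chrom] = (starts, ends)

    @classmethod
    def from_bed(cls, bed_path) -> "CgiIndex":
        df = pd.read_csv(bed_path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for row in df.itertuples(index=False):
            by_chrom.setdefault(str(row.chrom), []).append((int(row.start), int(row.end)))
        return cls(by_chrom)

    def context(self, chrom: str, pos: int) -> str:
        if chrom not in self._idx:
            return "open_sea"
        starts, ends = self._idx[chrom]
        # inside any island wins over a neighbouring island's flank
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and pos < ends[i]:
            return "CGI"
        # shore/shelf: within SHORE_SHELF_BP of an island edge, not inside
        j = np.searchsorted(starts, pos, side="left")       # next island to the right
        if j < len(starts) and starts[j] - pos <= SHORE_SHELF_BP and pos < starts[j]:
            return "shore_shelf"
        if i >= 0 and ends[i] <= pos < ends[i] + SHORE_SHELF_BP:
            return "shore_shelf"
        return "open_sea"


def classify_probe_context(probe: ProbeRecord, cgi: CgiIndex) -> str:
    """CGI if inside an island, shore_shelf within 4 kb of an edge, else open_sea."""
    return cgi.context(probe.chrom, probe.pos)


def annotate_probe_contexts(probes: Iterable[ProbeRecord], cgi: CgiIndex) -> list[ProbeRecord]:
    return [ProbeRecord(p.probe_id, p.chrom, p.pos, cgi.context(p.chrom, p.pos), p.flags)
            for p in probes]


# ---------------------------------------------------------------------------
# probe manifest IO
# ---------------------------------------------------------------------------

def load_probe_manifest(path) -> list[ProbeRecord]:
    """Read a probe manifest TSV (probe_id, chrom, pos, flags comma-separated)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    probes = []
    for row in df.itertuples(index=False):
        raw = getattr(row, "flags", "")
        flags = frozenset(f for f in str(raw).split(",") if f and f != "nan") if pd.notna(raw) else frozenset()
        probes.append(ProbeRecord(str(row.probe_id), str(row.chrom), int(row.pos), flags=flags))
    return probes


# ---------------------------------------------------------------------------
# positional assignment
# ---------------------------------------------------------------------------

def _anchor_class(ordinal: int, n: int) -> str:
    if ordinal == 1:
        return "first"
    if ordinal == n:
        return "terminal"
    return "middle"


def assign_pair_positions(transcript: TranscriptModel, probe: ProbeRecord) -> list[PairAssignment]:
    """All positional assignments of one probe within one isoform.

    Returns [] when the probe is on another chromosome or beyond +/-2 kb of
    the transcript span.  A probe inside an exon yields one assignment
    (inside_near/inside_far).  An intronic or outside probe within 2 kb of an
    exon boundary yields one flank assignment per reachable anchor exon (a
    probe between two exons, <=2 kb from both, is assigned to both anchors —
    each exon-anchor analysis counts pairs independently).  A probe within
    the span but >2 kb from every exon boundary yields a single anchor='none'
    assignment carrying only the promoter/body region label.
    """
    if probe.chrom != transcript.chrom:
        return []
    pos = probe.pos
    span_s, span_e = transcript.span
    if pos < span_s - FLANK_BP or pos >= span_e + FLANK_BP:
        return []

    strand = transcript.strand
    n = transcript.n_exons
    exons = transcript.exons  # transcription order

    def updist(boundary_exon: tuple[int, int]) -> int:
        """Distance from probe to the exon's 5' boundary when probe is 5' of it."""
        s, e = boundary_exon
        return (s - pos) if strand == "+" else (pos - (e - 1))

    def downdist(boundary_exon: tuple[int, int]) -> int:
        s, e = boundary_exon
        return (pos - (e - 1)) if strand == "+" else (s - pos)

    # region: promoter = upstream of TSS (within the 2-kb intragenic reach)
    # or inside the first exon; body = strictly downstream of first-exon end
    first = exons[0]
    in_first = first[0] <= pos < first[1]
    up_of_tss = updist(first) > 0
    region = "promoter" if (in_first or up_of_tss) else "body"

    in_any_exon = any(s <= pos < e for s, e in exons)

    def intron_gap(k: int) -> int | None:
        """Intron length between exon ordinal k and k+1 (1-based); None off ends."""
        if k < 1 or k >= n:
            return None
        a, b = exons[k - 1], exons[k]
        return (b[0] - a[1]) if strand == "+" else (a[0] - b[1])

    out: list[PairAssignment] = []
    for k, (s, e) in enumerate(exons, start=1):
        anchor = _anchor_class(k, n)
        exon_len = e - s
        if s <= pos < e:
            d5 = (pos - s) if strand == "+" else (e - 1 - pos)
            d3 = exon_len - 1 - d5
            loc = "inside_near" if min(d5, d3) < NEAR_BP else "inside_far"
            out.append(PairAssignment(
                transcript.transcript_id, probe.probe_id, region, anchor, k,
                loc, None, min(d5, d3), (d5, d3)))
            continue
        du = updist((s, e))
        dd = downdist((s, e))
        if 0 < du <= FLANK_BP and not in_any_exon:
            gap = intron_gap(k - 1)
            limit = FLANK_BP if gap is None else min(FLANK_BP, gap)
            if du <= limit:
                out.append(PairAssignment(
                    transcript.transcript_id, probe.probe_id, region, anchor, k,
                    "flank", "upstream", -du, (du, du + exon_len - 1), limit))
        elif 0 < dd <= FLANK_BP and not in_any_exon:
            gap = intron_gap(k)
            limit = FLANK_BP if gap is None else min(FLANK_BP, gap)
            if dd <= limit:
                out.append(PairAssignment(
                    transcript.transcript_id, probe.probe_id, region, anchor, k,
                    "flank", "downstream", dd, (dd + exon_len - 1, dd), limit))
    if not out:
        # deep intron (or unreachable flank): region label only
        out.append(PairAssignment(
            transcript.transcript_id, probe.probe_id, region, "none", 0,
            None, None, 0, (0, 0)))
    return out


def assign_all_pairs(genes: Sequence[GeneModel], probes: Sequence[ProbeRecord]) -> pd.DataFrame:
    """PairAssignments for every intragenic (transcript, probe) pair, as a table.

    One row per assignment; columns mirror PairAssignment plus gene_id and
    probe context.
    """
    pair_index = intragenic_pairs(genes, probes)
    probe_by_id = {p.probe_id: p for p in probes}
    tr_by_id = {t.transcript_id: t for g in genes for t in g.transcripts}
    rows = []
    for gid, tid, pid in pair_index:
        t = tr_by_id[tid]
        p = probe_by_id[pid]
        for a in assign_pair_positions(t, p):
            rows.append((gid, tid, pid, a.region, a.anchor, a.anchor_ordinal,
                         a.location, a.flank_side, a.signed_offset,
                         a.dist_to_boundaries[0], a.dist_to_boundaries[1],
                         a.flank_limit, p.context))
    return pd.DataFrame(rows, columns=[
        "gene_id", "transcript_id", "probe_id", "region", "anchor",
        "anchor_ordinal", "location", "flank_side", "signed_offset",
        "dist5", "dist3", "flank_limit", "context"])


def intragenic_pairs(genes: Sequence[GeneModel], probes: Sequence[ProbeRecord]
                     ) -> list[tuple[str, str, str]]:
    """(gene_id, transcript_id, probe_id) for every probe in a gene's
    intragenic span (gene span +/-2 kb).  A probe may appear in many pairs."""
    by_chrom: dict[str, list[ProbeRecord]] = {}
    for p in probes:
        by_chrom.setdefault(p.chrom, []).append(p)
    for ps in by_chrom.values():
        ps.sort(key=lambda p: p.pos)
    pos_arrays = {c: np.array([p.pos for p in ps]) for c, ps in by_chrom.items()}
    out = []
    for g in genes:
        if g.chrom not in by_chrom:
            continue
        a, b = g.intragenic_span
        arr = pos_arrays[g.chrom]
        lo, hi = np.searchsorted(arr, [a, b])
        hits = by_chrom[g.chrom][lo:hi]
        for t in g.transcripts:
            for p in hits:
                out.append((g.gene_id, t.transcript_id, p.probe_id))
    return out
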