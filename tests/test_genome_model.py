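"""Annotation parsing, CpG context, and positional-assignment logic."""

import numpy as np
import pandas as pd
import pytest

from methiso.genome_model import (CgiIndex, GeneModel, ProbeRecord,
                                  TranscriptModel, assign_pair_positions,
                                  intragenic_pairs, load_annotation)

from conftest import make_transcript, random_transcript


def write_gtf(path, transcripts):
    lines = []
    for t in transcripts:
        at = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
        for s, e in sorted(t.exons):
            lines.append(f"{t.chrom}\tt\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{at}")
    path.write_text("\n".join(lines) + "\n")


class TestLoadAnnotation:
    def test_two_transcript_gene(self, tmp_path):
        t1 = make_transcript("T1", "G", exons=[(100, 200), (300, 400), (500, 650)])
        t2 = make_transcript("T2", "G", exons=[(100, 200), (500, 650)])
        p = tmp_path / "toy.gtf"
        write_gtf(p, [t1, t2])
        genes = load_annotation(p)
        assert len(genes) == 1 and len(genes[0].transcripts) == 2
        by_id = {t.transcript_id: t for t in genes[0].transcripts}
        assert by_id["T1"].n_exons == 3 and by_id["T2"].n_exons == 2

    def test_minus_strand_exon_order(self, tmp_path):
        t = make_transcript("T1", "G", strand="-", exons=[(100, 200), (300, 400)])
        p = tmp_path / "m.gtf"
        write_gtf(p, [t])
        (g,) = load_annotation(p)
        assert g.transcripts[0].exons[0] == (300, 400)  # exon ordinal 1 is 3'-most in genome

    def test_exon_order_matches_sort_reverse_oracle(self, tmp_path):
        rng = np.random.default_rng(0)
        ts = [random_transcript(rng, tid=f"T{i}", gid=f"G{i}") for i in range(50)]
        p = tmp_path / "r.gtf"
        write_gtf(p, ts)
        got = {t.transcript_id: t for g in load_annotation(p) for t in g.transcripts}
        for t in ts:
            expect = sorted(t.exons)
            if t.strand == "-":
                expect = expect[::-1]
            assert list(got[t.transcript_id].exons) == [tuple(e) for e in expect]

    def test_inconsistent_strand_raises(self, tmp_path):
        t1 = make_transcript("T1", "G", strand="+")
        t2 = make_transcript("T2", "G", strand="-")
        p = tmp_path / "bad.gtf"
        write_gtf(p, [t1, t2])
        with pytest.raises(ValueError, match="strand"):
            load_annotation(p)


class TestCgiContext:
    def test_boundaries(self):
        cgi = CgiIndex({"chr1": [(1000, 2000)]})
        assert cgi.context("chr1", 1500) == "CGI"
        assert cgi.context("chr1", 999) == "shore_shelf"
        assert cgi.context("chr1", 2000) == "shore_shelf"
        assert cgi.context("chr1", 5999) == "shore_shelf"   # flank is [2000, 6000)
        assert cgi.context("chr1", 6000) == "open_sea"
        assert cgi.context("chr2", 1500) == "open_sea"

    def test_island_beats_neighbor_flank(self):
        cgi = CgiIndex({"chr1": [(1000, 2000), (3000, 4000)]})
        assert cgi.context("chr1", 3500) == "CGI"  # inside 2nd, within flank of 1st

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(1)
        starts = np.sort(rng.choice(200_000, size=20, replace=False))
        islands = [(int(s), int(s + rng.integers(200, 2000))) for s in starts]
        # drop overlapping islands for a clean oracle
        clean = []
        for s, e in islands:
            if not clean or s >= clean[-1][1]:
                clean.append((s, e))
        cgi = CgiIndex({"chr1": clean})
        for pos in rng.integers(0, 220_000, size=1000):
            pos = int(pos)
            if any(s <= pos < e for s, e in clean):
                want = "CGI"
            elif any(s - 4000 <= pos < s or e <= pos < e + 4000 for s, e in clean):
                want = "shore_shelf"
            else:
                want = "open_sea"
            assert cgi.context("chr1", pos) == want, pos


# ---------------------------------------------------------------------------
# positional assignment
# ---------------------------------------------------------------------------

def oracle_assignments(t, probe):
    """Independent re-derivation in transcription coordinates."""
    if probe.chrom != t.chrom:
        return set()
    u = probe.pos if t.strand == "+" else -probe.pos
    ex = [(s, e - 1) if t.strand == "+" else (-(e - 1), -s) for s, e in t.exons]
    lo = min(a for a, _ in ex)
    hi = max(b for _, b in ex)
    if u < lo - 2000 or u > hi + 2000:
        return set()
    n = len(ex)
    region = "promoter" if u <= ex[0][1] else "body"
    out = set()
    inside_any = any(a <= u <= b for a, b in ex)
    for k, (a, b) in enumerate(ex, start=1):
        anchor = "first" if k == 1 else ("terminal" if k == n else "middle")
        if a <= u <= b:
            d5, d3 = u - a, b - u
            loc = "inside_near" if min(d5, d3) < 1000 else "inside_far"
            out.add((k, anchor, region, loc, None, min(d5, d3)))
        elif not inside_any:
            if u < a:  # upstream of exon k
                d = a - u
                limit = 2000 if k == 1 else min(2000, a - ex[k - 2][1] - 1)
                if d <= limit:
                    out.add((k, anchor, region, "flank", "upstream", -d))
            elif u > b:  # downstream of exon k
                d = u - b
                limit = 2000 if k == n else min(2000, ex[k][0] - b - 1)
                if d <= limit:
                    out.add((k, anchor, region, "flank", "downstream", d))
    if not out:
        out.add((0, "none", region, None, None, 0))
    return out


def as_key_set(assignments):
    return {(a.anchor_ordinal, a.anchor, a.region, a.location, a.flank_side,
             a.signed_offset) for a in assignments}


class TestAssignPairPosition:
    def test_promoter_flank_example(self):
        t = make_transcript(exons=[(10_000, 10_300), (14_000, 14_300)])
        a, = assign_pair_positions(t, ProbeRecord("p", "chr1", 9_500))
        assert (a.region, a.anchor, a.location, a.flank_side, a.signed_offset) == \
            ("promoter", "first", "flank", "upstream", -500)

    def test_middle_exon_inside_far(self):
        exons = [(k * 10_000, k * 10_000 + 3_200) for k in range(6)]
        t = make_transcript(exons=exons)
        probe = ProbeRecord("p", "chr1", 30_000 + 1_500)  # exon 4, 1.5 kb from both ends
        a, = assign_pair_positions(t, probe)
        assert (a.anchor, a.anchor_ordinal, a.location) == ("middle", 4, "inside_far")
        assert a.dist_to_boundaries == (1500, 1699)

    def test_intron_probe_double_anchor(self):
        t = make_transcript(exons=[(0, 300), (1_500, 1_800), (10_000, 10_300)])
        asn = assign_pair_positions(t, ProbeRecord("p", "chr1", 800))
        sides = {(a.anchor_ordinal, a.flank_side, a.signed_offset) for a in asn}
        assert sides == {(1, "downstream", 501), (2, "upstream", -700)}

    def test_probe_beyond_reach_returns_empty(self):
        t = make_transcript(exons=[(10_000, 10_300)])
        assert assign_pair_positions(t, ProbeRecord("p", "chr1", 7_999)) == []
        assert assign_pair_positions(t, ProbeRecord("p", "chr2", 10_100)) == []

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_exhaustive_oracle(self, strand):
        rng = np.random.default_rng(7 if strand == "+" else 8)
        for i in range(30):
            t = random_transcript(rng, tid=f"T{i}", strand=strand)
            span_lo, span_hi = t.span
            for pos in rng.integers(max(0, span_lo - 2_500), span_hi + 2_500, size=60):
                p = ProbeRecord("p", "chr1", int(pos))
                assert as_key_set(assign_pair_positions(t, p)) == oracle_assignments(t, p)

    def test_strand_mirror_symmetry(self):
        rng = np.random.default_rng(9)
        M = 1_000_000
        for i in range(20):
            t = random_transcript(rng, tid=f"T{i}", strand="+")
            mirrored = [(M - e + 1, M - s + 1) for s, e in t.exons]
            tm = make_transcript("Tm", "G", strand="-", exons=mirrored)
            span_lo, span_hi = t.span
            for pos in rng.integers(max(0, span_lo - 2_200), span_hi + 2_200, size=30):
                p = ProbeRecord("p", "chr1", int(pos))
                pm = ProbeRecord("p", "chr1", M - int(pos))
                assert as_key_set(assign_pair_positions(t, p)) == \
                    as_key_set(assign_pair_positions(tm, pm))

    def test_region_partition(self):
        rng = np.random.default_rng(10)
        for i in range(20):
            t = random_transcript(rng, tid=f"T{i}")
            span_lo, span_hi = t.span
            for pos in rng.integers(span_lo, span_hi, size=30):
                asn = assign_pair_positions(t, ProbeRecord("p", "chr1", int(pos)))
                regions = {a.region for a in asn}
                assert len(regions) == 1 and regions <= {"promoter", "body"}


class TestIntragenicPairs:
    def _gene(self, gid, span_start, span_end):
        t = make_transcript(f"{gid}.T", gid, exons=[(span_start, span_start + 100),
                                                    (span_end - 100, span_end)])
        return GeneModel(gid, (t,))

    def test_2kb_boundary(self):
        g = self._gene("G", 10_000, 20_000)
        near = ProbeRecord("near", "chr1", 10_000 - 1_999)
        far = ProbeRecord("far", "chr1", 10_000 - 2_001)
        pairs = intragenic_pairs([g], [near, far])
        assert [p[2] for p in pairs] == ["near"]

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(11)
        genes = [self._gene(f"G{i}", int(s), int(s + rng.integers(5_000, 30_000)))
                 for i, s in enumerate(rng.integers(0, 300_000, size=15))]
        probes = [ProbeRecord(f"p{j}", "chr1", int(x))
                  for j, x in enumerate(rng.integers(0, 330_000, size=200))]
        got = set(intragenic_pairs(genes, probes))
        want = set()
        for g in genes:
            a, b = g.intragenic_span
            for t in g.transcripts:
                for p in probes:
                    if a <= p.pos < b:
                        want.add((g.gene_id, t.transcript_id, p.probe_id))
        assert got == want
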