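import numpy as np
import pytest

from methiso.genome_model import GeneModel, ProbeRecord, TranscriptModel
from methiso.synthetic_data import SyntheticConfig, make_annotation, simulate_cohort


def make_transcript(tid="T1", gid="G1", chrom="chr1", strand="+",
                    exons=((100, 200), (300, 400), (500, 650))):
    exons = sorted(exons)
    if strand == "-":
        exons = exons[::-1]
    return TranscriptModel(tid, gid, chrom, strand, tuple(tuple(e) for e in exons))


def random_transcript(rng, tid="T", gid="G", strand=None, n_exons=None, chrom="chr1"):
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    n = n_exons or int(rng.integers(1, 7))
    pos = int(rng.integers(0, 5000))
    exons = []
    for _ in range(n):
        length = int(rng.integers(50, 2500))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(100, 4000))
    return make_transcript(tid, gid, chrom, strand, exons)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared across tests (read-only)."""
    cfg = SyntheticConfig(n_tumor=80, n_normal=4, seed=42)
    ann = make_annotation(cfg, 42)
    beta, tpm, meta, truth = simulate_cohort(cfg, ann, 43)
    return cfg, ann, beta, tpm, meta, truth
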