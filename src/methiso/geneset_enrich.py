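"""Gene pooling across cohorts and hypergeometric gene-set overrepresentation.

Genes whose methylation-isoform correlations recur in at least ``n_min``
cohorts are pooled and tested for overrepresentation in user-supplied gene
sets (oncogene/tumor-suppressor lists, GMT pathway collections) with an
exact hypergeometric upper tail.  The default background is the set of
genes analyzable in at least ``n_min`` cohorts, not the whole genome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetEnrichResult:
    query_size: int
    set_size: int
    background_size: int
    overlap: int
    fraction: float
    p: float


def shared_genes(per_cohort_gene_sets: Sequence[Iterable[str]] | Mapping[str, Iterable[str]],
                 n_min: int) -> set[str]:
    """Genes present in at least n_min of the per-cohort sets."""
    if isinstance(per_cohort_gene_sets, Mapping):
        sets = [set(v) for v in per_cohort_gene_sets.values()]
    else:
        sets = [set(v) for v in per_cohort_gene_sets]
    counts = Counter(g for s in sets for g in s)
    return {g for g, c in counts.items() if c >= n_min}


def hypergeom_enrich(query: Iterable[str], annotated_set: Iterable[str],
                     background: Iterable[str]) -> GeneSetEnrichResult:
    """Exact upper-tail probability of the observed query/set overlap.

    Successes are the annotated genes within the background; the query must
    be a subset of the background.
    """
    query = set(query)
    background = set(background)
    if not background:
        raise ValueError("empty background")
    if not query <= background:
        raise ValueError("query genes missing from background")
    K = len(set(annotated_set) & background)
    k = len(query & set(annotated_set))
    N, n = len(background), len(query)
    p = float(hypergeom.sf(k - 1, N, K, n))
    return GeneSetEnrichResult(n, K, N, k, k / n if n else 0.0, p)


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set collection: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def enrich_collections(query: Iterable[str], collections: Mapping[str, Iterable[str]],
                       background: Iterable[str]) -> pd.DataFrame:
    """Hypergeometric test per gene set with Benjamini-Hochberg q-values."""
    query = set(query)
    background = set(background)
    rows = []
    for name, genes in sorted(collections.items()):
        res = hypergeom_enrich(query, genes, background)
        rows.append((name, res.set_size, res.overlap, res.fraction, res.p))
    df = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap",
                                     "fraction", "p"])
    if len(df):
        df["q"] = multipletests(df.p, method="fdr_bh")[1]
    else:
        df["q"] = []
    return df
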