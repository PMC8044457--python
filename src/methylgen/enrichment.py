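"""GO-term over-representation and gene-set overlap (Venn) analysis.

Enrichment is a one-sided hypergeometric upper-tail test per term — the
probability of drawing at least *k* of the term's *K* background genes in a
list of size *n* from a background of size *N* — with Benjamini-Hochberg
adjustment across the tested terms. This is a plain local replacement for
web-service enrichment tools; no GO-graph propagation or term clustering is
performed, and results are reported on the -log10(p_adj) scale used in
enrichment heatmaps.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.stats as st

from .dmr import adjust_pvalues

ENRICHMENT_COLUMNS = ["term", "term_name", "k", "K", "n", "N",
                      "p_raw", "p_adj", "neg_log10_p"]


def go_enrich(
    gene_list: Iterable[str],
    background: Iterable[str],
    gene2go: pd.DataFrame,
    term_names: Mapping[str, str] | None = None,
    min_term_size: int = 3,
) -> pd.DataFrame:
    """Hypergeometric over-representation of GO terms in a gene list.

    ``gene2go`` is a frame with columns (gene, term). Terms with fewer than
    ``min_term_size`` background genes are not tested. Results are sorted by
    (p_adj, term); an empty gene list yields an empty frame.
    """
    genes = set(gene_list)
    bg = set(background)
    if not genes:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    stray = genes - bg
    if stray:
        raise ValueError(
            f"genes not in background: {sorted(stray)[:10]}"
            + ("..." if len(stray) > 10 else ""))
    if gene2go.empty:
        raise ValueError("gene->GO map is empty")
    mapping = gene2go[gene2go["gene"].isin(bg)]
    N, n = len(bg), len(genes)
    rows = []
    for term, grp in mapping.groupby("term", sort=True):
        term_genes = set(grp["gene"])
        K = len(term_genes)
        if K < min_term_size:
            continue
        k = len(term_genes & genes)
        p = float(st.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, p))
    if not rows:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    df = pd.DataFrame(rows, columns=["term", "k", "K", "p_raw"])
    df["n"], df["N"] = n, N
    df["p_adj"] = adjust_pvalues(df["p_raw"].to_numpy())
    with np.errstate(divide="ignore"):
        df["neg_log10_p"] = -np.log10(df["p_adj"])
    names = term_names or {}
    df["term_name"] = df["term"].map(lambda t: names.get(t, ""))
    df = df.sort_values(["p_adj", "term"], kind="mergesort")
    return df.loc[:, ENRICHMENT_COLUMNS].reset_index(drop=True)


def venn_overlap(
    named_sets: Mapping[str, Iterable[str]],
) -> tuple[pd.DataFrame, dict[tuple[str, ...], int]]:
    """Exact region cardinalities and membership table for 2-4 gene sets.

    Returns (membership, region_counts): ``membership`` has one row per gene
    in the union with a boolean column per set; ``region_counts`` maps each
    nonempty subset of set names (as a sorted tuple) to the number of genes
    belonging to exactly those sets. Region counts therefore sum to the size
    of the union.
    """
    sets = {name: set(s) for name, s in named_sets.items()}
    if not (2 <= len(sets) <= 4):
        raise ValueError("venn_overlap supports 2-4 sets")
    names = list(sets)
    union = sorted(set().union(*sets.values()))
    membership = pd.DataFrame(
        {name: [g in sets[name] for g in union] for name in names},
        index=pd.Index(union, name="gene"))
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set().union(*(sets[c] for c in names
                                    if c not in combo)) if r < len(names) \
                else set()
            counts[tuple(sorted(combo))] = len(inside - outside)
    return membership, counts
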