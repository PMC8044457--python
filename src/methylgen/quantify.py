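"""Site-, region-, feature- and genome-level methylation summaries.

The central quantity is the *weighted methylation level*: total methylated
read count divided by total read count over a set of cytosines. It weights
each site by its coverage, which is the robust choice at low coverage and
reduces to the arithmetic mean of site levels when coverage is uniform.
Undefined levels (no covered site) are returned as NaN, never silently as 0.

Also houses the UPLC %5mdC arithmetic: the relative content of
5-methyl-2'-deoxycytidine as a percentage of total deoxycytidine,
100 * 5mdC / (dC + 5mdC).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .types import Feature


def site_level(mc: int, uc: int) -> float:
    """Methylation level of one cytosine: mc / (mc + uc); NaN at zero coverage."""
    total = mc + uc
    if total <= 0:
        return float("nan")
    return mc / total


def weighted_methylation_level(
    sample: pd.DataFrame,
    context: str | None = None,
    region: tuple[str, int, int] | None = None,
) -> float:
    """Coverage-weighted level: sum(mc) / sum(mc + uc) over qualifying sites.

    ``context`` restricts to one methylation context; ``region`` is a
    (chrom, start, end) half-open interval. NaN when no site has coverage.
    """
    df = sample
    if context is not None:
        df = df[df["context"] == context]
    if region is not None:
        chrom, start, end = region
        df = df[(df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] < end)]
    total = int(df["mc"].sum() + df["uc"].sum())
    if total == 0:
        return float("nan")
    return float(df["mc"].sum() / total)


def global_5mdC_percent(dC_amount: float, fivemdC_amount: float) -> float:
    """%5mdC = 100 * 5mdC / (dC + 5mdC); NaN when both amounts are zero."""
    if dC_amount < 0 or fivemdC_amount < 0:
        raise ValueError("amounts must be nonnegative")
    total = dC_amount + fivemdC_amount
    if total == 0:
        return float("nan")
    return 100.0 * fivemdC_amount / total


def relative_to_reference(
    values: pd.DataFrame, reference: str,
    condition_col: str = "condition", value_col: str = "percent_5mdC",
) -> pd.Series:
    """Per-condition means scaled to a reference condition's mean.

    Mirrors the convention of reporting global methylation relative to the
    unexposed parent control.
    """
    means = values.groupby(condition_col)[value_col].mean()
    if reference not in means.index:
        raise ValueError(f"reference condition {reference!r} not present")
    ref = means[reference]
    if ref == 0:
        raise ValueError("reference condition has zero mean")
    return means / ref


def feature_profile(
    sample: pd.DataFrame,
    genes: Iterable[Feature],
    chrom_lengths: Mapping[str, int],
    flank: int = 2000,
    context: str | None = None,
) -> dict[str, float]:
    """Weighted levels over upstream flank, gene body and downstream flank.

    Flanks are strand-aware (upstream of the 5' end for + genes lies left of
    the gene, for - genes right of it) and clipped at contig boundaries.
    Levels are pooled over all genes per compartment; empty compartments are
    NaN.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list is empty")
    df = sample if context is None else sample[sample["context"] == context]
    sums = {"upstream": [0, 0], "body": [0, 0], "downstream": [0, 0]}
    by_chrom = {c: g.sort_values("pos") for c, g in df.groupby("chrom")}
    for gene in genes:
        g = by_chrom.get(gene.chrom)
        if g is None:
            continue
        L = chrom_lengths[gene.chrom]
        left = (max(0, gene.start - flank), gene.start)
        right = (gene.end, min(L, gene.end + flank))
        if gene.strand == "-":
            compartments = {"upstream": right, "body": (gene.start, gene.end),
                            "downstream": left}
        else:
            compartments = {"upstream": left, "body": (gene.start, gene.end),
                            "downstream": right}
        pos = g["pos"].to_numpy()
        mc = g["mc"].to_numpy()
        uc = g["uc"].to_numpy()
        for name, (s, e) in compartments.items():
            lo, hi = np.searchsorted(pos, [s, e])
            sums[name][0] += int(mc[lo:hi].sum())
            sums[name][1] += int(mc[lo:hi].sum() + uc[lo:hi].sum())
    return {
        name: (m / t if t > 0 else float("nan"))
        for name, (m, t) in sums.items()
    }


def binned_track(
    sample: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    window: int = 10000,
    context: str | None = None,
) -> pd.DataFrame:
    """Per-window weighted methylation track (non-overlapping tiles from 0).

    Returns a frame (chrom, start, end, value, n_sites); the last partial
    tile is kept; tiles without covered sites have NaN value and n_sites 0.
    The default 10-kb window matches genome-overview methylation plots.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    df = sample if context is None else sample[sample["context"] == context]
    rows = []
    grouped = dict(tuple(df.groupby("chrom")))
    for chrom in chrom_lengths:
        length = chrom_lengths[chrom]
        g = grouped.get(chrom)
        n_tiles = max(1, -(-length // window)) if length > 0 else 0
        if g is not None:
            tile_idx = (g["pos"] // window).to_numpy()
            cov = (g["mc"] + g["uc"]).to_numpy()
            mc = g["mc"].to_numpy()
            covered = cov > 0
            mc_sum = np.bincount(tile_idx, weights=mc, minlength=n_tiles)
            cov_sum = np.bincount(tile_idx, weights=cov, minlength=n_tiles)
            n_cov = np.bincount(tile_idx[covered], minlength=n_tiles)
        else:
            mc_sum = cov_sum = np.zeros(n_tiles)
            n_cov = np.zeros(n_tiles, dtype=int)
        for k in range(n_tiles):
            value = mc_sum[k] / cov_sum[k] if cov_sum[k] > 0 else float("nan")
            rows.append((chrom, k * window, min((k + 1) * window, length),
                         value, int(n_cov[k])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value",
                                       "n_sites"])
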