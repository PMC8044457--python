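"""Windowed differential-methylation-region (DMR) calling.

The genome is tiled into fixed windows (default 1 kb, non-overlapping); for
each window, methylation context and sample, a weighted region level is
computed over the context's cytosines whose coverage in that sample reaches
``min_site_coverage``. Each pairwise comparison of conditions is tested with
a one-way ANOVA across the two groups of per-sample region levels, requiring
``min_samples_per_group`` defined levels on each side. Raw p-values are
Benjamini-Hochberg adjusted separately per (comparison, context) family, and
regions pass when the adjusted p is at most ``alpha`` and the absolute
methylation difference reaches ``min_difference``.

Direction convention: ``difference = level_b - level_a`` for a comparison
labelled ``A_vs_B``; a *hyper*methylated DMR has the higher level in the
second condition (B).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .types import (CONTEXTS, DOSES, GENERATIONS, INTERGENERATIONAL,
                    INTRAGENERATIONAL, ComparisonSpec, DMRParams,
                    condition_label)

logger = logging.getLogger(__name__)

TESTED_COLUMNS = ["comparison", "axis", "chrom", "start", "end", "context",
                  "level_a", "level_b", "difference", "p_raw",
                  "n_sites_tested"]
DMR_COLUMNS = TESTED_COLUMNS[:-1] + ["p_adj", "direction", "n_sites_tested"]


# ---------------------------------------------------------------------------
# Comparison design
# ---------------------------------------------------------------------------

def enumerate_comparisons(
    generations: Sequence[str], doses: Sequence[str],
) -> list[ComparisonSpec]:
    """All pairwise contrasts within each generation (across doses) and
    within each dose (across generations).

    For the full 3-generation x 3-dose design this yields 18 comparison
    sets (9 intragenerational + 9 intergenerational). Within a pair the
    lower dose / earlier generation comes first, which fixes the direction
    convention of the labels.
    """
    generations = sorted(set(generations), key=GENERATIONS.index)
    doses = sorted(set(doses), key=DOSES.index)
    if len(generations) < 2 and len(doses) < 2:
        raise ValueError("need at least 2 generations or 2 doses to compare")
    comparisons = []
    for gen in generations:
        for da, db in itertools.combinations(doses, 2):
            a, b = condition_label(gen, da), condition_label(gen, db)
            comparisons.append(ComparisonSpec(
                f"{a}_vs_{b}", a, b, INTRAGENERATIONAL))
    for dose in doses:
        for ga, gb in itertools.combinations(generations, 2):
            a, b = condition_label(ga, dose), condition_label(gb, dose)
            comparisons.append(ComparisonSpec(
                f"{a}_vs_{b}", a, b, INTERGENERATIONAL))
    return comparisons


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

def define_regions(
    chrom_lengths: Mapping[str, int], params: DMRParams,
) -> pd.DataFrame:
    """Tile every chromosome into windows of ``window_size`` advancing by
    ``window_step`` (default: non-overlapping); the last partial tile is kept.
    """
    rows = []
    size, step = params.window_size, params.step
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            continue
        start = 0
        while start < length:
            rows.append((chrom, start, min(start + size, length)))
            if start + size >= length:
                break
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# Aligned multi-sample container
# ---------------------------------------------------------------------------

@dataclass
class AlignedMethylomes:
    """All samples' counts aligned to one genome-derived site table.

    ``mc``/``cov`` are (n_samples, n_sites) arrays in site-table order;
    ``conditions`` maps sample id -> condition label ('S1g30', ...).
    """

    sites: pd.DataFrame
    sample_ids: list[str]
    conditions: dict[str, str]
    mc: np.ndarray
    cov: np.ndarray

    @classmethod
    def from_samples(
        cls, sites: pd.DataFrame,
        samples: Mapping[str, pd.DataFrame],
        conditions: Mapping[str, str],
    ) -> "AlignedMethylomes":
        """Align per-sample CX frames to the site table by (chrom, pos, strand)."""
        key = sites[["chrom", "pos", "strand"]]
        n = len(sites)
        ids = list(samples)
        mc = np.zeros((len(ids), n), dtype=np.int64)
        cov = np.zeros((len(ids), n), dtype=np.int64)
        for k, sid in enumerate(ids):
            df = samples[sid]
            merged = key.merge(
                df[["chrom", "pos", "strand", "mc", "uc"]],
                on=["chrom", "pos", "strand"], how="left")
            if len(merged) != n:
                raise ValueError(f"sample {sid}: duplicate site rows")
            mc[k] = merged["mc"].fillna(0).to_numpy(np.int64)
            cov[k] = mc[k] + merged["uc"].fillna(0).to_numpy(np.int64)
        return cls(sites=sites, sample_ids=ids,
                   conditions=dict(conditions), mc=mc, cov=cov)

    def sample_index(self, condition: str) -> np.ndarray:
        idx = [i for i, sid in enumerate(self.sample_ids)
               if self.conditions[sid] == condition]
        return np.asarray(idx, dtype=int)


# ---------------------------------------------------------------------------
# Region levels and tests
# ---------------------------------------------------------------------------

def region_level(
    sample: pd.DataFrame, region: tuple[str, int, int], context: str,
    params: DMRParams,
) -> float:
    """Weighted level over a region's context sites with coverage >=
    ``min_site_coverage`` in this sample; NaN if no site qualifies."""
    chrom, start, end = region
    df = sample[(sample["chrom"] == chrom) & (sample["pos"] >= start)
                & (sample["pos"] < end) & (sample["context"] == context)]
    cov = (df["mc"] + df["uc"]).to_numpy()
    qual = cov >= params.min_site_coverage
    if not qual.any():
        return float("nan")
    return float(df["mc"].to_numpy()[qual].sum() / cov[qual].sum())


def test_region(levels_a, levels_b) -> tuple[float, float]:
    """Two-group one-way ANOVA on per-sample region levels.

    Returns (difference, p_raw) with difference = mean(b) - mean(a). A region
    with no level variation at all is not differential: (0.0, 1.0).
    """
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 defined levels per group")
    diff = float(b.mean() - a.mean())
    flat = np.concatenate([a, b])
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # between-group variance only: F is infinite, p -> 0
        return diff, 0.0
    res = st.f_oneway(a, b)
    return diff, float(res.pvalue)


def adjust_pvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def region_level_matrix(
    am: AlignedMethylomes, regions: pd.DataFrame, params: DMRParams,
) -> dict[str, tuple[pd.DataFrame, np.ndarray, np.ndarray]]:
    """Per-context (regions, level matrix, site counts).

    The level matrix is (n_regions, n_samples); entries are NaN where no
    site of the region qualifies in that sample. Regions with fewer than
    ``min_sites_per_region`` context sites are dropped for that context.
    """
    sites = am.sites
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    ctx_arr = sites["context"].to_numpy()

    # contiguous slice per chromosome (site table is sorted)
    chrom_bounds: dict[str, tuple[int, int]] = {}
    if len(sites):
        change = np.flatnonzero(chrom_arr[1:] != chrom_arr[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(sites)]])
        for s, e in zip(starts, ends):
            chrom_bounds[chrom_arr[s]] = (int(s), int(e))

    out: dict[str, tuple[pd.DataFrame, np.ndarray, np.ndarray]] = {}
    for context in CONTEXTS:
        kept_rows, levels_rows, n_sites_rows = [], [], []
        for region in regions.itertuples():
            if region.chrom not in chrom_bounds:
                continue
            lo, hi = chrom_bounds[region.chrom]
            i0 = lo + np.searchsorted(pos_arr[lo:hi], region.start, "left")
            i1 = lo + np.searchsorted(pos_arr[lo:hi], region.end, "left")
            idx = np.arange(i0, i1)[ctx_arr[i0:i1] == context]
            if idx.size < params.min_sites_per_region:
                continue
            sub_cov = am.cov[:, idx]
            sub_mc = am.mc[:, idx]
            qual = sub_cov >= params.min_site_coverage
            denom = np.where(qual, sub_cov, 0).sum(axis=1)
            num = np.where(qual, sub_mc, 0).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                levels = np.where(denom > 0, num / np.maximum(denom, 1),
                                  np.nan)
            kept_rows.append((region.chrom, region.start, region.end))
            levels_rows.append(levels)
            n_sites_rows.append(idx.size)
        kept = pd.DataFrame(kept_rows, columns=["chrom", "start", "end"])
        levels_mat = (np.vstack(levels_rows) if levels_rows
                      else np.empty((0, len(am.sample_ids))))
        out[context] = (kept, levels_mat, np.asarray(n_sites_rows, dtype=int))
    return out


def test_all_regions(
    am: AlignedMethylomes,
    comparisons: Iterable[ComparisonSpec],
    chrom_lengths: Mapping[str, int],
    params: DMRParams,
) -> pd.DataFrame:
    """Test every (comparison, context, region) with enough defined levels.

    Returns the tested-region table (columns TESTED_COLUMNS); regions with
    fewer than ``min_samples_per_group`` defined levels in either group are
    skipped, not assigned p = 1.
    """
    regions = define_regions(chrom_lengths, params)
    per_context = region_level_matrix(am, regions, params)
    rows = []
    for comp in comparisons:
        ia = am.sample_index(comp.condition_a)
        ib = am.sample_index(comp.condition_b)
        if ia.size == 0 or ib.size == 0:
            logger.warning("comparison %s: missing condition; skipped",
                           comp.label)
            continue
        for context in CONTEXTS:
            kept, levels, n_sites = per_context[context]
            for r in range(len(kept)):
                la, lb = levels[r, ia], levels[r, ib]
                la, lb = la[~np.isnan(la)], lb[~np.isnan(lb)]
                if (la.size < params.min_samples_per_group
                        or lb.size < params.min_samples_per_group):
                    continue
                diff, p = test_region(la, lb)
                rows.append((
                    comp.label, comp.axis,
                    kept.iat[r, 0], int(kept.iat[r, 1]), int(kept.iat[r, 2]),
                    context, float(la.mean()), float(lb.mean()), diff, p,
                    int(n_sites[r])))
    return pd.DataFrame(rows, columns=TESTED_COLUMNS)


def call_dmrs(tested: pd.DataFrame, params: DMRParams) -> pd.DataFrame:
    """BH-adjust per (comparison, context) family and apply the DMR filters.

    Keeps regions with adjusted p <= alpha (raw p when
    ``params.use_adjusted_p`` is False) and |difference| >= min_difference;
    assigns direction hyper iff difference > 0. Output sorted by
    (comparison, context, chrom, start).
    """
    if tested.empty:
        return pd.DataFrame(columns=DMR_COLUMNS)
    df = tested.copy()
    df["p_adj"] = np.nan
    for _, idx in df.groupby(["comparison", "context"]).groups.items():
        df.loc[idx, "p_adj"] = adjust_pvalues(df.loc[idx, "p_raw"].to_numpy())
    p_filter = df["p_adj"] if params.use_adjusted_p else df["p_raw"]
    keep = (p_filter <= params.alpha) & \
        (df["difference"].abs() >= params.min_difference)
    out = df.loc[keep].copy()
    out["direction"] = np.where(out["difference"] > 0, "hyper", "hypo")
    out = out.sort_values(["comparison", "context", "chrom", "start"],
                          kind="mergesort")
    return out.loc[:, DMR_COLUMNS].reset_index(drop=True)


def dmr_count_matrix(
    dmrs: pd.DataFrame, comparisons: Iterable[ComparisonSpec],
) -> pd.DataFrame:
    """DMR counts by comparison x direction with CG/CHG/CHH columns.

    Rows cover the full comparison skeleton (intragenerational block first,
    then intergenerational) for both directions, so absent combinations
    appear as explicit zeros.
    """
    comparisons = list(comparisons)
    ordered = ([c for c in comparisons if c.axis == INTRAGENERATIONAL]
               + [c for c in comparisons if c.axis == INTERGENERATIONAL])
    rows = []
    for direction in ("hyper", "hypo"):
        for comp in ordered:
            row = {"comparison": comp.label, "axis": comp.axis,
                   "direction": direction}
            for context in CONTEXTS:
                if dmrs.empty:
                    row[context] = 0
                else:
                    row[context] = int(
                        ((dmrs["comparison"] == comp.label)
                         & (dmrs["direction"] == direction)
                         & (dmrs["context"] == context)).sum())
            rows.append(row)
    return pd.DataFrame(rows, columns=["comparison", "axis", "direction",
                                       *CONTEXTS])
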