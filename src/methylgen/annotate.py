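"""Nearest-feature annotation and promoter / gene-body / TE classification.

Each DMR is annotated with its nearest gene and nearest transposable
element (minimal gap distance, 0 on overlap — bedtools-closest-style), then
classified:

* ``promoter``  — 0 < gene distance <= 2000 bp and the region lies on the
  gene's 5' side (strand-aware: upstream of ``start`` for + genes, of
  ``end`` for - genes);
* ``gene_body`` — gene distance 0 (any overlap counts);
* ``te``        — TE distance 0.

Classes are non-exclusive except promoter/gene_body, which cannot co-occur
because a promoter requires a strictly positive gene distance.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import Feature

logger = logging.getLogger(__name__)

PROMOTER_MAX_DISTANCE = 2000


def interval_distance(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Gap between two half-open intervals; 0 on overlap or abutment."""
    return max(start_b - end_a, start_a - end_b, 0)


@dataclass
class NearestHit:
    feature: Feature
    distance: int
    position: str  # left | overlap | right (feature relative to the region)


class FeatureIndex:
    """Per-chromosome sorted feature lists supporting nearest-gap queries.

    Ties on distance are broken by smaller feature start, then lexicographic
    id — deterministic regardless of input order.
    """

    def __init__(self, features: Iterable[Feature]):
        self._by_chrom: dict[str, list[Feature]] = {}
        for f in features:
            self._by_chrom.setdefault(f.chrom, []).append(f)
        self._starts: dict[str, list[int]] = {}
        for chrom, feats in self._by_chrom.items():
            feats.sort(key=lambda f: (f.start, f.end, f.id))
            self._starts[chrom] = [f.start for f in feats]

    def nearest(self, chrom: str, start: int, end: int) -> NearestHit | None:
        """Nearest feature to the region [start, end); None when the
        chromosome has no features."""
        feats = self._by_chrom.get(chrom)
        if not feats:
            return None
        starts = self._starts[chrom]
        best: tuple[int, int, str] | None = None
        best_feat: Feature | None = None

        def consider(f: Feature) -> int:
            nonlocal best, best_feat
            d = interval_distance(start, end, f.start, f.end)
            key = (d, f.start, f.id)
            if best is None or key < best:
                best, best_feat = key, f
            return d

        # rightward from the first feature starting at/after region end:
        # for those, distance grows with start, so stop once it exceeds best
        i = bisect_left(starts, end)
        for j in range(i, len(feats)):
            d = consider(feats[j])
            if best is not None and feats[j].start - end > best[0]:
                break
        # leftward features: ends are unordered under a start sort, so scan all
        for j in range(i - 1, -1, -1):
            consider(feats[j])
        assert best is not None and best_feat is not None
        f = best_feat
        if f.start < end and start < f.end:
            position = "overlap"
        elif f.end <= start:
            position = "left"
        else:
            position = "right"
        return NearestHit(feature=f, distance=best[0], position=position)


def nearest_feature(
    region: tuple[str, int, int], features: Sequence[Feature],
) -> NearestHit | None:
    """Convenience wrapper: nearest feature to one region (builds an index)."""
    chrom, start, end = region
    return FeatureIndex(features).nearest(chrom, start, end)


def is_upstream(region_start: int, region_end: int, gene: Feature) -> bool:
    """Whether the region lies on the gene's strand-aware 5' side.

    For strand '.', falls back to 'left of the gene start' with a warning.
    """
    if gene.strand == "-":
        return region_start >= gene.end
    if gene.strand == ".":
        logger.warning("gene %s has no strand; upstream falls back to "
                       "'left of start'", gene.id)
    return region_end <= gene.start


def classify_dmr(
    region: tuple[str, int, int],
    gene_hit: NearestHit | None,
    te_hit: NearestHit | None,
    promoter_max_distance: int = PROMOTER_MAX_DISTANCE,
) -> set[str]:
    """Class labels for one region given its nearest gene and TE."""
    chrom, start, end = region
    classes: set[str] = set()
    if gene_hit is not None:
        if gene_hit.distance == 0:
            classes.add("gene_body")
        elif (0 < gene_hit.distance <= promoter_max_distance
              and is_upstream(start, end, gene_hit.feature)):
            classes.add("promoter")
    if te_hit is not None and te_hit.distance == 0:
        classes.add("te")
    return classes


ANNOTATION_COLUMNS = ["nearest_gene", "gene_distance", "upstream_of_gene",
                      "nearest_te", "te_distance", "classes"]


def annotate_dmrs(
    dmrs: pd.DataFrame, genes: Sequence[Feature], tes: Sequence[Feature],
    promoter_max_distance: int = PROMOTER_MAX_DISTANCE,
) -> pd.DataFrame:
    """Add nearest-gene/TE annotation and class labels to a DMR table.

    ``classes`` holds a comma-joined sorted label set ('' when none).
    Chromosomes without any gene (or TE) yield empty annotation for that
    feature kind, with a logged warning.
    """
    gene_index = FeatureIndex(genes)
    te_index = FeatureIndex(tes)
    out = dmrs.copy()
    records = []
    for row in dmrs.itertuples():
        region = (row.chrom, int(row.start), int(row.end))
        gh = gene_index.nearest(*region)
        th = te_index.nearest(*region)
        if gh is None:
            logger.warning("no gene on chromosome %s", row.chrom)
        if th is None:
            logger.warning("no TE on chromosome %s", row.chrom)
        classes = classify_dmr(region, gh, th, promoter_max_distance)
        records.append({
            "nearest_gene": gh.feature.id if gh else "",
            "gene_distance": gh.distance if gh else np.nan,
            "upstream_of_gene": (is_upstream(region[1], region[2], gh.feature)
                                 if gh else False),
            "nearest_te": th.feature.id if th else "",
            "te_distance": th.distance if th else np.nan,
            "classes": ",".join(sorted(classes)),
        })
    ann = pd.DataFrame(records, index=out.index,
                       columns=ANNOTATION_COLUMNS)
    return pd.concat([out, ann], axis=1)


def classification_count_matrix(annotated: pd.DataFrame) -> pd.DataFrame:
    """Gene/TE counts by comparison x direction x class.

    Promoter and gene-body cells count distinct *genes* (multiple DMRs in
    one gene's promoter count once); the TE cell counts distinct TEs. Rows
    appear for every (comparison, direction) present in the input.
    """
    cols = ["comparison", "axis", "direction",
            "promoter", "gene_body", "te"]
    if annotated.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    for (comp, axis, direction), grp in annotated.groupby(
            ["comparison", "axis", "direction"], sort=True):
        has = {cls: grp["classes"].str.split(",").apply(lambda c: cls in c)
               for cls in ("promoter", "gene_body", "te")}
        rows.append({
            "comparison": comp, "axis": axis, "direction": direction,
            "promoter": grp.loc[has["promoter"], "nearest_gene"].nunique(),
            "gene_body": grp.loc[has["gene_body"], "nearest_gene"].nunique(),
            "te": grp.loc[has["te"], "nearest_te"].nunique(),
        })
    return pd.DataFrame(rows, columns=cols)


def dmrs_to_bed(annotated: pd.DataFrame, path) -> None:
    """Export classified DMRs as BED6+ for genome browsers."""
    with open(path, "w") as out:
        for r in annotated.itertuples():
            name = f"{r.comparison}|{r.context}|{r.direction}|{r.classes or 'none'}"
            strand_score = 0
            out.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{strand_score}\t.\n")
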