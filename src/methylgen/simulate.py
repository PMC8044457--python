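"""Seeded synthetic multigenerational WGBS dataset generator.

Emulates the statistical structure of a three-generation (P0/S1/S2), three
dose-rate (control, 30, 110 mGy/h) bisulfite experiment with five biological
replicates per condition:

* a random toy genome at Arabidopsis-like GC content, with non-overlapping
  genes and partly gene-overlapping transposable elements;
* per-cytosine true methylation levels drawn from a bimodal (mostly-low /
  mostly-high) mixture whose weight is solved so each context's mean equals
  the configured baseline (CG 0.30, CHG 0.135, CHH 0.068 — typical leaf
  methylome control levels);
* beta-binomial replicate noise (a per-sample Beta draw around each site's
  true level, overdispersion ``rho``) on negative-binomially distributed
  coverage;
* planted DMRs: window-aligned regions whose sites take a constant true
  level — the context baseline in unaffected conditions, baseline shifted by
  the planted difference (clipped to [0, 1]) in the affected condition. A
  bimodal methylome cannot realise a large additive shift at every site
  (most CG sites sit near 0 or 1), so planted regions are homogeneous by
  construction and the realised group difference equals the planted one;
* an optional hypermethylation uplift of TE-resident sites in
  exposed-lineage (nonzero-dose) conditions;
* a synthetic UPLC %5mdC table and a synthetic gene->GO map.

All randomness flows from one root seed through named substreams, so e.g.
adding samples never perturbs the genome. Ground truth (planted regions and
per-condition true context levels) is recorded in manifests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io
from .context import extract_cytosine_contexts
from .dmr import AlignedMethylomes
from .types import (GENERATIONS, SEQUENCED_DOSES, DOSES, Feature,
                    SampleSheetEntry, UPLCMeasurement, split_condition)

MANIFEST_COLUMNS = ["chrom", "start", "end", "context", "direction",
                    "difference", "comparison", "affected_condition",
                    "base_level", "affected_level"]


@dataclass(frozen=True)
class PlannedDMR:
    """One block of planted DMRs for a single comparison and context."""

    axis: str
    comparison: str          # e.g. "S2g0_vs_S2g30"
    context: str = "CG"
    direction: str = "hyper"
    difference: float = 0.30
    count: int = 15
    width: int = 1000


def default_dmr_plan() -> tuple[PlannedDMR, ...]:
    """30 planted CG DMRs of difference 0.30 (15 hyper + 15 hypo) on the
    strongest contrast of the modelled design (S2 control vs S2 low dose)."""
    return (
        PlannedDMR("intragenerational", "S2g0_vs_S2g30", "CG", "hyper",
                   0.30, 15, 1000),
        PlannedDMR("intragenerational", "S2g0_vs_S2g30", "CG", "hypo",
                   0.30, 15, 1000),
    )


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 100_000
    gc_content: float = 0.36
    n_genes: int = 60
    n_tes: int = 40
    te_gene_overlap_fraction: float = 0.3
    coverage_mean: float = 20.0
    coverage_dispersion: float = 10.0   # negative-binomial shape k
    context_baseline: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.30, "CHG": 0.135, "CHH": 0.068})
    replicate_overdispersion: float = 0.02  # rho of the per-sample Beta draw
    te_uplift: float = 0.05   # TE-site baseline uplift in exposed conditions
    site_level_model: str = "mixture"   # "mixture" | "beta"
    n_replicates: int = 5
    generations: Sequence[str] = GENERATIONS
    doses: Sequence[str] = SEQUENCED_DOSES
    dmr_plan: tuple[PlannedDMR, ...] = field(default_factory=default_dmr_plan)
    uplc_control_means: Mapping[str, float] = field(
        default_factory=lambda: {"P0": 5.38, "S1": 4.88, "S2": 6.03})
    uplc_shifts: Mapping[str, float] = field(default_factory=dict)
    uplc_sd: float = 0.25
    uplc_doses: Sequence[str] = DOSES

    def __post_init__(self) -> None:
        for ctx, level in self.context_baseline.items():
            if not (0.0 <= level <= 1.0):
                raise ValueError(f"baseline for {ctx} outside [0, 1]")
        for plan in self.dmr_plan:
            base = self.context_baseline[plan.context]
            if plan.direction not in ("hyper", "hypo"):
                raise ValueError(f"bad planted direction {plan.direction!r}")
            if not (0.0 < plan.difference <= 1.0):
                raise ValueError("planted difference must lie in (0, 1]")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length
                for i in range(self.n_chromosomes)}


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A configuration with no planted effects of any kind."""
    return SimulationConfig(seed=seed, dmr_plan=(), te_uplift=0.0, **overrides)


def _rng(seed: int, *tags) -> np.random.Generator:
    """Named substream: deterministic, independent of sibling streams."""
    keys = [zlib.crc32(str(t).encode()) for t in tags]
    return np.random.default_rng([int(seed) % (2 ** 31), *keys])


# ---------------------------------------------------------------------------
# Genome and annotations
# ---------------------------------------------------------------------------

def generate_genome(config: SimulationConfig) -> dict[str, str]:
    """Random genome at the configured GC content (deterministic per seed)."""
    gc = config.gc_content
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"), dtype="U1")
    genome = {}
    for i in range(config.n_chromosomes):
        rng = _rng(config.seed, "genome", i)
        draw = rng.choice(4, size=config.chrom_length, p=p)
        genome[f"chr{i + 1}"] = "".join(bases[draw])
    return genome


def generate_annotations(
    config: SimulationConfig, genome: Mapping[str, str],
) -> tuple[list[Feature], list[Feature]]:
    """Non-overlapping genes plus TEs (a configurable fraction overlapping
    genes, the rest intergenic). Raises when the genes cannot be packed."""
    rng = _rng(config.seed, "annotation")
    chroms = list(genome)
    genes: list[Feature] = []
    per_chrom = np.array_split(np.arange(config.n_genes), len(chroms))
    for chrom, idx in zip(chroms, per_chrom):
        L = len(genome[chrom])
        n = len(idx)
        if n == 0:
            continue
        slot = L // n
        for j, g in enumerate(idx):
            length = int(rng.integers(500, min(2500, max(501, slot - 100))))
            if length >= slot:
                raise ValueError(
                    "cannot pack genes: too many/too long for the genome")
            offset = int(rng.integers(0, slot - length))
            start = j * slot + offset
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Feature(chrom, start, start + length, strand,
                                 f"gene{g + 1:04d}", "gene"))
    tes: list[Feature] = []
    n_overlap = int(round(config.n_tes * config.te_gene_overlap_fraction))
    for t in range(config.n_tes):
        length = int(rng.integers(200, 1200))
        if t < n_overlap and genes:
            host = genes[int(rng.integers(0, len(genes)))]
            start = max(0, host.start + int(rng.integers(
                -length // 2, max(1, host.end - host.start))))
            chrom = host.chrom
        else:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, len(genome[chrom]) - length))
        L = len(genome[chrom])
        end = min(L, start + length)
        tes.append(Feature(chrom, start, end, ".", f"TE{t + 1:04d}", "TE"))
    genes.sort(key=lambda f: (f.chrom, f.start))
    tes.sort(key=lambda f: (f.chrom, f.start))
    if config.te_gene_overlap_fraction == 0:
        gene_idx = {(g.chrom): [] for g in genes}
        for g in genes:
            gene_idx[g.chrom].append((g.start, g.end))
        tes = [te for te in tes if not any(
            te.start < ge and gs < te.end
            for gs, ge in gene_idx.get(te.chrom, []))]
    return genes, tes


# ---------------------------------------------------------------------------
# Methylomes
# ---------------------------------------------------------------------------

def _mixture_params(baseline: float) -> tuple[float, float, float]:
    """(weight of high component, low mean, high mean) solving the mean."""
    mu_lo, mu_hi = 0.02, 0.92
    if baseline <= mu_lo:
        return 0.0, baseline, mu_hi
    if baseline >= mu_hi:
        return 1.0, mu_lo, baseline
    return (baseline - mu_lo) / (mu_hi - mu_lo), mu_lo, mu_hi


def _draw_site_levels(
    config: SimulationConfig, contexts: np.ndarray, rng: np.random.Generator,
) -> np.ndarray:
    """Per-site true levels whose expectation per context is the baseline."""
    n = contexts.size
    levels = np.zeros(n)
    conc = 20.0  # Beta concentration of the mixture components
    for ctx in ("CG", "CHG", "CHH", "unknown"):
        mask = contexts == ctx
        m = int(mask.sum())
        if m == 0:
            continue
        base = config.context_baseline.get(ctx,
                                           config.context_baseline["CHH"])
        if config.site_level_model == "beta":
            a = max(base * conc, 1e-3)
            b = max((1 - base) * conc, 1e-3)
            levels[mask] = rng.beta(a, b, size=m)
            continue
        w, mu_lo, mu_hi = _mixture_params(base)
        hi = rng.random(m) < w
        lo_draw = rng.beta(mu_lo * conc, (1 - mu_lo) * conc, size=m)
        hi_draw = rng.beta(mu_hi * conc, (1 - mu_hi) * conc, size=m)
        levels[mask] = np.where(hi, hi_draw, lo_draw)
    return levels


def make_sample_sheet(config: SimulationConfig) -> list[SampleSheetEntry]:
    entries = []
    for gen in config.generations:
        for dose in config.doses:
            for rep in range(1, config.n_replicates + 1):
                entries.append(SampleSheetEntry(
                    f"{gen}{dose}_r{rep}", gen, dose, rep))
    return entries


def _in_regions(sites: pd.DataFrame, chrom: str, start: int, end: int,
                context: str) -> np.ndarray:
    return ((sites["chrom"].to_numpy() == chrom)
            & (sites["pos"].to_numpy() >= start)
            & (sites["pos"].to_numpy() < end)
            & (sites["context"].to_numpy() == context))


def _place_planted_regions(
    config: SimulationConfig, rng: np.random.Generator,
) -> pd.DataFrame:
    """Choose distinct window-aligned tiles for every planned DMR block."""
    rows = []
    taken: set[tuple[str, int]] = set()
    chroms = list(config.chrom_lengths)
    for plan in config.dmr_plan:
        cond_a, cond_b = plan.comparison.split("_vs_")
        base = config.context_baseline[plan.context]
        shift = plan.difference if plan.direction == "hyper" \
            else -plan.difference
        affected = float(np.clip(base + shift, 0.0, 1.0))
        placed = 0
        attempts = 0
        while placed < plan.count:
            attempts += 1
            if attempts > 100 * plan.count:
                raise ValueError("dmr_plan region collision: cannot place "
                                 "all planted regions without overlap")
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            L = config.chrom_lengths[chrom]
            n_tiles = L // plan.width
            tile = int(rng.integers(0, n_tiles))
            if (chrom, tile) in taken:
                continue
            taken.add((chrom, tile))
            rows.append((chrom, tile * plan.width, (tile + 1) * plan.width,
                         plan.context, plan.direction, plan.difference,
                         plan.comparison, cond_b, base, affected))
            placed += 1
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def _condition_site_levels(
    config: SimulationConfig,
    sites: pd.DataFrame,
    base_levels: np.ndarray,
    manifest: pd.DataFrame,
    tes: Sequence[Feature],
) -> dict[str, np.ndarray]:
    """True per-site level per condition: planted overrides + TE uplift."""
    contexts = sites["context"].to_numpy()
    conditions = [f"{g}{d}" for g in config.generations
                  for d in config.doses]
    te_mask = np.zeros(len(sites), dtype=bool)
    if config.te_uplift:
        chrom_arr = sites["chrom"].to_numpy()
        pos_arr = sites["pos"].to_numpy()
        for te in tes:
            te_mask |= ((chrom_arr == te.chrom) & (pos_arr >= te.start)
                        & (pos_arr < te.end))
    levels_by_condition: dict[str, np.ndarray] = {}
    for cond in conditions:
        levels = base_levels.copy()
        # planted regions are homogeneous: baseline everywhere, shifted in
        # the affected condition only
        for r in manifest.itertuples():
            mask = _in_regions(sites, r.chrom, r.start, r.end, r.context)
            levels[mask] = (r.affected_level
                            if cond == r.affected_condition else r.base_level)
        _, dose = split_condition(cond)
        if config.te_uplift and dose != "g0":
            levels[te_mask] = np.clip(levels[te_mask] + config.te_uplift,
                                      0.0, 1.0)
        levels_by_condition[cond] = levels
    return levels_by_condition


def generate_methylomes(
    config: SimulationConfig,
    genome: Mapping[str, str],
    tes: Sequence[Feature] = (),
    sites: pd.DataFrame | None = None,
) -> tuple[AlignedMethylomes, pd.DataFrame, pd.DataFrame]:
    """Simulate every sample's counts.

    Returns (aligned methylomes, planted-DMR manifest, per-condition true
    context levels). ``sites`` may be passed to reuse a precomputed site
    table for the same genome.
    """
    if sites is None:
        sites = extract_cytosine_contexts(genome)
    contexts = sites["context"].to_numpy()
    base_levels = _draw_site_levels(config, contexts,
                                    _rng(config.seed, "sites"))
    manifest = _place_planted_regions(config, _rng(config.seed, "plan"))
    levels_by_condition = _condition_site_levels(
        config, sites, base_levels, manifest, tes)

    sheet = make_sample_sheet(config)
    n_sites = len(sites)
    rho = config.replicate_overdispersion
    k = config.coverage_dispersion
    p_nb = k / (k + config.coverage_mean)
    mc = np.zeros((len(sheet), n_sites), dtype=np.int64)
    cov = np.zeros((len(sheet), n_sites), dtype=np.int64)
    for i, entry in enumerate(sheet):
        rng = _rng(config.seed, "sample", entry.sample_id)
        level = levels_by_condition[entry.condition]
        coverage = rng.negative_binomial(k, p_nb, size=n_sites)
        if rho > 0:
            interior = (level > 0) & (level < 1)
            p = level.copy()
            a = level[interior] * (1 - rho) / rho
            b = (1 - level[interior]) * (1 - rho) / rho
            p[interior] = rng.beta(a, b)
        else:
            p = level
        mc[i] = rng.binomial(coverage, p)
        cov[i] = coverage
    am = AlignedMethylomes(
        sites=sites, sample_ids=[e.sample_id for e in sheet],
        conditions={e.sample_id: e.condition for e in sheet},
        mc=mc, cov=cov)

    truth_rows = []
    for cond, levels in levels_by_condition.items():
        for ctx in ("CG", "CHG", "CHH"):
            mask = contexts == ctx
            truth_rows.append((cond, ctx, float(levels[mask].mean())))
    condition_levels = pd.DataFrame(
        truth_rows, columns=["condition", "context", "true_level"])
    return am, manifest, condition_levels


def sample_frame(am: AlignedMethylomes, sample_id: str) -> pd.DataFrame:
    """One sample's counts as a CX-style frame (chrom, pos, strand, mc, uc,
    context, tri)."""
    i = am.sample_ids.index(sample_id)
    df = am.sites.copy()
    df["mc"] = am.mc[i]
    df["uc"] = am.cov[i] - am.mc[i]
    return df.loc[:, ["chrom", "pos", "strand", "mc", "uc", "context", "tri"]]


# ---------------------------------------------------------------------------
# UPLC table and gene->GO map
# ---------------------------------------------------------------------------

def generate_uplc_table(config: SimulationConfig) -> list[UPLCMeasurement]:
    """Synthetic %5mdC measurements: normal noise around per-condition means
    (generation control means by default, plus configured shifts), clipped to
    [0, 100]; five replicates per condition."""
    rng = _rng(config.seed, "uplc")
    out = []
    for gen in config.generations:
        for dose in config.uplc_doses:
            mean = config.uplc_control_means[gen] \
                + config.uplc_shifts.get(f"{gen}{dose}", 0.0)
            values = np.clip(
                mean + rng.normal(0.0, config.uplc_sd,
                                  size=config.n_replicates), 0.0, 100.0)
            for rep, v in enumerate(values, 1):
                out.append(UPLCMeasurement(
                    f"{gen}{dose}_u{rep}", gen, dose, float(v)))
    return out


def generate_gene2go(
    config: SimulationConfig, genes: Sequence[Feature],
    n_terms: int = 25,
) -> pd.DataFrame:
    """Synthetic gene->GO map: each gene gets 1-3 of ``n_terms`` terms."""
    rng = _rng(config.seed, "gene2go")
    rows = []
    for gene in genes:
        k = int(rng.integers(1, 4))
        for t in sorted(rng.choice(n_terms, size=k, replace=False)):
            rows.append((gene.id, f"GO:{t + 1:07d}"))
    return pd.DataFrame(rows, columns=["gene", "term"])


# ---------------------------------------------------------------------------
# Dataset on disk
# ---------------------------------------------------------------------------

def write_dataset(config: SimulationConfig, outdir) -> dict[str, object]:
    """Generate and write the complete dataset; returns summary counts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(config)
    genes, tes = generate_annotations(config, genome)
    am, manifest, condition_levels = generate_methylomes(
        config, genome, tes)
    io.write_fasta(genome, outdir / "genome.fa")
    io.write_gff3_genes(genes, outdir / "genes.gff3")
    io.write_te_bed(tes, outdir / "transposons.bed")
    sheet = make_sample_sheet(config)
    io.write_sample_sheet(sheet, outdir / "samples.tsv")
    cx_dir = outdir / "cx_reports"
    cx_dir.mkdir(exist_ok=True)
    for entry in sheet:
        io.write_cx_report(sample_frame(am, entry.sample_id),
                           cx_dir / f"{entry.sample_id}.CX_report.txt")
    io.write_uplc_table(generate_uplc_table(config), outdir / "uplc.tsv")
    generate_gene2go(config, genes).to_csv(
        outdir / "gene2go.tsv", sep="\t", index=False)
    manifest.to_csv(outdir / "truth_dmrs.tsv", sep="\t", index=False)
    condition_levels.to_csv(outdir / "truth_levels.tsv", sep="\t",
                            index=False, float_format="%.6f")
    with open(outdir / "simulation.yaml", "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
    n_ctx = am.sites["context"].value_counts().to_dict()
    return {
        "n_samples": len(sheet),
        "n_sites": len(am.sites),
        "sites_per_context": {c: int(n_ctx.get(c, 0))
                              for c in ("CG", "CHG", "CHH", "unknown")},
        "n_genes": len(genes),
        "n_tes": len(tes),
        "n_planted_dmrs": len(manifest),
    }


def config_to_dict(config: SimulationConfig) -> dict:
    d = {
        k: v for k, v in vars(config).items()
        if k not in ("dmr_plan", "context_baseline", "uplc_control_means",
                     "uplc_shifts", "generations", "doses", "uplc_doses")
    }
    d["context_baseline"] = dict(config.context_baseline)
    d["uplc_control_means"] = dict(config.uplc_control_means)
    d["uplc_shifts"] = dict(config.uplc_shifts)
    d["generations"] = list(config.generations)
    d["doses"] = list(config.doses)
    d["uplc_doses"] = list(config.uplc_doses)
    d["dmr_plan"] = [vars(p).copy() for p in config.dmr_plan]
    return d


def config_from_dict(d: Mapping) -> SimulationConfig:
    d = dict(d)
    plan = tuple(PlannedDMR(**p) for p in d.pop("dmr_plan", []))
    for key in ("generations", "doses", "uplc_doses"):
        if key in d:
            d[key] = tuple(d[key])
    return SimulationConfig(dmr_plan=plan, **d)


# ---------------------------------------------------------------------------
# Truth-based evaluation
# ---------------------------------------------------------------------------

def true_region_difference(
    row: pd.Series, condition_a: str, condition_b: str,
) -> float:
    """Planted level difference (b - a) of a manifest region between two
    conditions."""
    la = row["affected_level"] if condition_a == row["affected_condition"] \
        else row["base_level"]
    lb = row["affected_level"] if condition_b == row["affected_condition"] \
        else row["base_level"]
    return float(lb - la)


def evaluate_calls(
    dmrs: pd.DataFrame, manifest: pd.DataFrame,
    min_difference: float = 0.20,
) -> dict[str, float]:
    """Sensitivity and empirical FDR of a DMR call set against the truth.

    Sensitivity: fraction of planted regions recovered in their designated
    comparison with the correct direction. FDR: fraction of all calls whose
    region does not carry a true difference >= ``min_difference`` between
    the compared conditions.
    """
    recovered = 0
    for r in manifest.itertuples():
        hit = dmrs[(dmrs["comparison"] == r.comparison)
                   & (dmrs["context"] == r.context)
                   & (dmrs["chrom"] == r.chrom)
                   & (dmrs["start"] < r.end) & (r.start < dmrs["end"])
                   & (dmrs["direction"] == r.direction)]
        if len(hit):
            recovered += 1
    sensitivity = recovered / len(manifest) if len(manifest) else float("nan")

    false_calls = 0
    for call in dmrs.itertuples():
        cond_a, cond_b = call.comparison.split("_vs_")
        overlapping = manifest[(manifest["context"] == call.context)
                               & (manifest["chrom"] == call.chrom)
                               & (manifest["start"] < call.end)
                               & (call.start < manifest["end"])]
        true_diffs = [true_region_difference(row, cond_a, cond_b)
                      for _, row in overlapping.iterrows()]
        if not any(abs(d) >= min_difference for d in true_diffs):
            false_calls += 1
    fdr = false_calls / len(dmrs) if len(dmrs) else 0.0
    return {"sensitivity": sensitivity, "fdr": fdr,
            "n_calls": int(len(dmrs)), "n_planted": int(len(manifest))}
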