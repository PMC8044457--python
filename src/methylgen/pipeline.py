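"""End-to-end pipeline orchestration: load a dataset, run each analysis
stage, and write deterministic, self-describing outputs.

Stage order mirrors the analysis design this package models: global UPLC
statistics; windowed DMR calling across all intra-/inter-generational
pairwise comparisons; nearest-gene/TE annotation and promoter / gene-body /
TE classification; GO over-representation and gene-set overlaps; binned
methylation tracks. Every output table carries its generating parameters as
'#' header lines, and a machine-readable run manifest records parameters and
input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .annotate import annotate_dmrs, classification_count_matrix, dmrs_to_bed
from .context import extract_cytosine_contexts
from .dmr import (AlignedMethylomes, call_dmrs, dmr_count_matrix,
                  enumerate_comparisons, test_all_regions)
from .enrichment import go_enrich, venn_overlap
from .global_stats import cascade_report, run_global_cascade
from .quantify import binned_track
from .types import DMRParams

logger = logging.getLogger(__name__)


class ConfigError(Exception):
    """Invalid or incomplete pipeline configuration (exit code 2)."""


class StageError(Exception):
    """A pipeline stage failed (exit code 3)."""


@dataclass
class PipelineConfig:
    genome: Path
    genes: Path
    tes: Path
    cx_dir: Path
    sample_sheet: Path
    uplc: Path | None = None
    gene2go: Path | None = None
    output_dir: Path = Path("results")
    dmr_params: DMRParams = field(default_factory=DMRParams)
    seed: int = 0
    log_level: str = "INFO"
    track_window: int = 10000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config: {exc}") from exc
        paths = raw.get("paths", {})
        required = ("genome", "genes", "tes", "cx_dir", "sample_sheet")
        missing = [k for k in required if k not in paths]
        if missing:
            raise ConfigError(f"config paths missing: {missing}")
        base = Path(path).parent
        def resolve(key):
            p = paths.get(key)
            return (base / p) if p is not None else None
        dmr_params = DMRParams(**raw.get("dmr", {}))
        cfg = cls(
            genome=resolve("genome"), genes=resolve("genes"),
            tes=resolve("tes"), cx_dir=resolve("cx_dir"),
            sample_sheet=resolve("sample_sheet"), uplc=resolve("uplc"),
            gene2go=resolve("gene2go"),
            output_dir=base / raw.get("output_dir", "results"),
            dmr_params=dmr_params, seed=int(raw.get("seed", 0)),
            log_level=raw.get("log_level", "INFO"),
            track_window=int(raw.get("track_window", 10000)))
        for name in ("genome", "genes", "tes", "cx_dir", "sample_sheet"):
            p = getattr(cfg, name)
            if not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")
        return cfg


def _pkg_version() -> str:
    try:
        return version("methylgen")
    except PackageNotFoundError:
        return "unknown"


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_header(config: PipelineConfig) -> dict:
    p = config.dmr_params
    return {
        "window_size": p.window_size, "window_step": p.step,
        "min_site_coverage": p.min_site_coverage,
        "min_samples_per_group": p.min_samples_per_group,
        "alpha": p.alpha, "min_difference": p.min_difference,
        "use_adjusted_p": p.use_adjusted_p, "seed": config.seed,
        "methylgen_version": _pkg_version(),
    }


class Pipeline:
    """Loads the dataset lazily and exposes one method per stage."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.output_dir)
        self._genome = None
        self._am = None
        self._sheet = None

    # ---------------- dataset loading ----------------

    @property
    def genome(self):
        if self._genome is None:
            self._genome = io.read_fasta(self.config.genome)
        return self._genome

    @property
    def chrom_lengths(self):
        return {c: len(s) for c, s in self.genome.items()}

    @property
    def sample_sheet(self):
        if self._sheet is None:
            self._sheet = io.read_sample_sheet(self.config.sample_sheet)
        return self._sheet

    @property
    def methylomes(self) -> AlignedMethylomes:
        if self._am is None:
            sites = extract_cytosine_contexts(self.genome)
            samples, conditions = {}, {}
            for entry in self.sample_sheet:
                path = Path(self.config.cx_dir) / \
                    f"{entry.sample_id}.CX_report.txt"
                if not path.exists():
                    raise StageError(f"missing CX report {path}")
                samples[entry.sample_id] = io.read_cx_report(path)
                conditions[entry.sample_id] = entry.condition
            self._am = AlignedMethylomes.from_samples(
                sites, samples, conditions)
        return self._am

    def comparisons(self):
        gens = sorted({e.generation for e in self.sample_sheet})
        doses = sorted({e.dose for e in self.sample_sheet})
        return enumerate_comparisons(gens, doses)

    # ---------------- stages ----------------

    def run_global_stats(self) -> Path:
        if self.config.uplc is None:
            raise ConfigError("no UPLC table configured")
        uplc = io.read_uplc_table(self.config.uplc)
        results = run_global_cascade(uplc)
        self.out.mkdir(parents=True, exist_ok=True)
        report = cascade_report(results)
        io.write_results_tsv(report, self.out / "global_stats.tsv",
                             params=_params_header(self.config))
        tukey_frames = []
        for r in results:
            if r.tukey is not None:
                t = r.tukey.copy()
                t.insert(0, "grouping", r.grouping)
                tukey_frames.append(t)
        tukey = (pd.concat(tukey_frames, ignore_index=True) if tukey_frames
                 else pd.DataFrame(columns=["grouping", "group_a", "group_b",
                                            "mean_difference", "p_adj"]))
        io.write_results_tsv(tukey, self.out / "global_stats_tukey.tsv",
                             params=_params_header(self.config))
        return self.out / "global_stats.tsv"

    def run_dmr(self) -> Path:
        params = self.config.dmr_params
        comps = self.comparisons()
        tested = test_all_regions(self.methylomes, comps,
                                  self.chrom_lengths, params)
        dmrs = call_dmrs(tested, params)
        self.out.mkdir(parents=True, exist_ok=True)
        header = _params_header(self.config)
        io.write_results_tsv(tested, self.out / "tested_regions.tsv",
                             params=header)
        io.write_results_tsv(dmrs, self.out / "dmrs.tsv", params=header)
        io.write_results_tsv(dmr_count_matrix(dmrs, comps),
                             self.out / "dmr_counts.tsv", params=header)
        return self.out / "dmrs.tsv"

    def run_annotate(self) -> Path:
        dmr_path = self.out / "dmrs.tsv"
        if not dmr_path.exists():
            raise StageError("run stage 'dmr' first: missing dmrs.tsv")
        dmrs = io.read_results_tsv(dmr_path)
        genes = io.read_gff3_genes(self.config.genes)
        tes = io.read_te_annotation(self.config.tes)
        annotated = annotate_dmrs(dmrs, genes, tes)
        header = _params_header(self.config)
        io.write_results_tsv(annotated, self.out / "dmrs_annotated.tsv",
                             params=header)
        io.write_results_tsv(classification_count_matrix(annotated),
                             self.out / "dmr_class_counts.tsv", params=header)
        dmrs_to_bed(annotated, self.out / "dmrs.bed")
        return self.out / "dmrs_annotated.tsv"

    def run_enrich(self) -> Path:
        ann_path = self.out / "dmrs_annotated.tsv"
        if not ann_path.exists():
            raise StageError("run stage 'annotate' first: missing "
                             "dmrs_annotated.tsv")
        if self.config.gene2go is None:
            raise ConfigError("no gene->GO map configured")
        annotated = io.read_results_tsv(ann_path)
        genes = io.read_gff3_genes(self.config.genes)
        background = [g.id for g in genes]
        gene2go = io.read_gene2go(self.config.gene2go)
        header = _params_header(self.config)
        frames = []
        gene_sets: dict[str, set] = {}
        if not annotated.empty:
            annotated["classes"] = annotated["classes"].fillna("")
            gene_assoc = annotated[
                annotated["classes"].str.contains("promoter|gene_body")]
            for (comp, direction), grp in gene_assoc.groupby(
                    ["comparison", "direction"], sort=True):
                gene_list = sorted(set(grp["nearest_gene"]) & set(background))
                gene_sets[f"{comp}|{direction}"] = set(gene_list)
                if not gene_list:
                    continue
                res = go_enrich(gene_list, background, gene2go)
                res.insert(0, "direction", direction)
                res.insert(0, "comparison", comp)
                frames.append(res)
        enrich = (pd.concat(frames, ignore_index=True) if frames else
                  pd.DataFrame(columns=["comparison", "direction", "term",
                                        "term_name", "k", "K", "n", "N",
                                        "p_raw", "p_adj", "neg_log10_p"]))
        io.write_results_tsv(enrich, self.out / "go_enrichment.tsv",
                             params=header)

        venn_rows = []
        nonempty = {k: v for k, v in gene_sets.items() if v}
        for direction in ("hyper", "hypo"):
            sets = {k.split("|")[0]: v for k, v in nonempty.items()
                    if k.endswith(direction)}
            if not (2 <= len(sets) <= 4):
                continue
            _, counts = venn_overlap(sets)
            for combo, count in sorted(counts.items()):
                venn_rows.append((direction, "&".join(combo), count))
        venn = pd.DataFrame(venn_rows,
                            columns=["direction", "region", "exclusive_count"])
        io.write_results_tsv(venn, self.out / "venn_overlaps.tsv",
                             params=header)
        return self.out / "go_enrichment.tsv"

    def run_tracks(self) -> Path:
        track_dir = self.out / "tracks"
        track_dir.mkdir(parents=True, exist_ok=True)
        am = self.methylomes
        for i, sid in enumerate(am.sample_ids):
            df = am.sites[["chrom", "pos"]].copy()
            df["mc"] = am.mc[i]
            df["uc"] = am.cov[i] - am.mc[i]
            track = binned_track(df, self.chrom_lengths,
                                 window=self.config.track_window)
            io.write_bedgraph(track, track_dir / f"{sid}.bedGraph", name=sid)
        return track_dir

    def run_all(self) -> Path:
        self.out.mkdir(parents=True, exist_ok=True)
        stages = [("dmr", self.run_dmr), ("annotate", self.run_annotate),
                  ("tracks", self.run_tracks)]
        if self.config.uplc is not None:
            stages.insert(0, ("global-stats", self.run_global_stats))
        if self.config.gene2go is not None:
            stages.append(("enrich", self.run_enrich))
        for name, fn in stages:
            logger.info("stage %s ...", name)
            try:
                fn()
            except (ConfigError, StageError):
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        self._write_manifest()
        return self.out

    def _write_manifest(self) -> None:
        inputs = {}
        for name in ("genome", "genes", "tes", "sample_sheet", "uplc",
                     "gene2go"):
            p = getattr(self.config, name)
            if p is not None and Path(p).is_file():
                inputs[name] = _sha256(p)
        cx_dir = Path(self.config.cx_dir)
        for entry in self.sample_sheet:
            p = cx_dir / f"{entry.sample_id}.CX_report.txt"
            if p.is_file():
                inputs[f"cx:{entry.sample_id}"] = _sha256(p)
        manifest = {
            "methylgen_version": _pkg_version(),
            "params": _params_header(self.config),
            "inputs": inputs,
        }
        with open(self.out / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
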