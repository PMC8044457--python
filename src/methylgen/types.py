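"""Shared domain types for the multigenerational methylome pipeline.

Coordinates are 0-based, half-open everywhere inside the package; the on-disk
formats keep their native conventions (GFF3 1-based closed, Bismark CX report
1-based, BED 0-based half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field

GENERATIONS = ("P0", "S1", "S2")
DOSES = ("g0", "g30", "g60", "g110", "g430")
#: dose rates sequenced by WGBS (the UPLC table covers all five)
SEQUENCED_DOSES = ("g0", "g30", "g110")
CONTEXTS = ("CG", "CHG", "CHH")

INTRAGENERATIONAL = "intragenerational"
INTERGENERATIONAL = "intergenerational"


@dataclass(frozen=True)
class SampleSheetEntry:
    """One WGBS sample: identity plus its experimental condition."""

    sample_id: str
    generation: str
    dose: str
    replicate: int

    def __post_init__(self) -> None:
        if self.generation not in GENERATIONS:
            raise ValueError(f"unknown generation {self.generation!r}")
        if self.dose not in DOSES:
            raise ValueError(f"unknown dose {self.dose!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")

    @property
    def condition(self) -> str:
        return f"{self.generation}{self.dose}"


@dataclass(frozen=True)
class UPLCMeasurement:
    """A UPLC-MS/MS global methylation measurement (%5mdC of dC + 5mdC)."""

    sample_id: str
    generation: str
    dose: str
    percent_5mdC: float

    def __post_init__(self) -> None:
        v = self.percent_5mdC
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"percent_5mdC {v} outside [0, 100]")


@dataclass(frozen=True)
class Feature:
    """A genomic feature (gene or transposable element), 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = ""
    kind: str = "gene"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"feature {self.id!r}: end ({self.end}) <= start ({self.start})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class ComparisonSpec:
    """An ordered pair of condition groups to contrast.

    The direction convention follows the label order: a hypermethylated region
    in ``A_vs_B`` has a higher level in the *second* condition (B).
    """

    label: str
    condition_a: str
    condition_b: str
    axis: str  # intragenerational | intergenerational

    def __post_init__(self) -> None:
        if self.axis not in (INTRAGENERATIONAL, INTERGENERATIONAL):
            raise ValueError(f"bad axis {self.axis!r}")
        if self.condition_a == self.condition_b:
            raise ValueError("comparison groups must differ")


@dataclass(frozen=True)
class DMRParams:
    """Parameters of region definition, filtering and DMR calling.

    ``min_site_coverage`` and ``min_samples_per_group`` default to the
    high-confidence settings used for the study design this package models
    (site coverage >= 5, >= 3 samples with a defined region level per group);
    the DMR filters default to adjusted p <= 0.05 and >= 20% methylation
    difference.
    """

    window_size: int = 1000
    window_step: int | None = None  # None -> non-overlapping tiles
    min_site_coverage: int = 5
    min_samples_per_group: int = 3
    min_sites_per_region: int = 1
    alpha: float = 0.05
    min_difference: float = 0.20
    use_adjusted_p: bool = True

    def __post_init__(self) -> None:
        step = self.step
        if min(self.window_size, step, self.min_site_coverage,
               self.min_samples_per_group, self.min_sites_per_region) < 1:
            raise ValueError("all size/count parameters must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0.0 < self.min_difference <= 1.0):
            raise ValueError("min_difference must lie in (0, 1]")

    @property
    def step(self) -> int:
        return self.window_step if self.window_step is not None else self.window_size


@dataclass(frozen=True)
class DMRRecord:
    """A region that passed the DMR filters for one comparison and context."""

    comparison: str
    chrom: str
    start: int
    end: int
    context: str
    level_a: float
    level_b: float
    difference: float  # level_b - level_a
    p_raw: float
    p_adj: float
    direction: str  # hyper | hypo
    n_sites_tested: int


def condition_label(generation: str, dose: str) -> str:
    return f"{generation}{dose}"


def split_condition(condition: str) -> tuple[str, str]:
    """Split 'S1g30' into ('S1', 'g30')."""
    for gen in GENERATIONS:
        if condition.startswith(gen):
            dose = condition[len(gen):]
            if dose in DOSES:
                return gen, dose
    raise ValueError(f"unparseable condition label {condition!r}")
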