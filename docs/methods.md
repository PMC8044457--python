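# Methods

## Scope and coordinates

The pipeline starts from per-cytosine counts (Bismark-style CX cytosine
reports: chromosome, 1-based position, strand, methylated count,
unmethylated count, context, trinucleotide); read alignment and bisulfite
chemistry are out of scope. Internally all coordinates are 0-based,
half-open; GFF3 (1-based closed) and CX reports (1-based) keep their native
conventions on disk, and read(write(x)) is the identity for counts and
coordinates. Zero-coverage cytosines are kept on read and removed only by
the coverage filters, so coverage rules live in exactly one place.

## Cytosine contexts

Every plus-strand C and every plus-strand G (a minus-strand C) is a site.
The context comes from the two bases 3′ of the cytosine on its own strand:
CG, CHG (H then G), CHH (H then H). A trinucleotide truncated by a contig
end or containing N is assigned context `unknown` — even when the readable
bases would determine the context — and is excluded from all downstream
statistics; guessing a context from partial information risks fabricating
sites. Symmetric CG pairs (plus-strand C at *i*, minus-strand C at *i*+1)
are deliberately *not* collapsed: each strand remains an independent
observation, which keeps counts interpretable and matches per-strand CX
reports. Organellar or other small contigs receive no special casing.

## Methylation levels

All summaries use the weighted methylation level
Σ mC / Σ (mC + uC) over the qualifying sites. When coverage is uniform this
equals the arithmetic mean of site levels; at low or uneven coverage it is
the more stable estimator, and it is the convention behind "global weighted
methylation level" reporting in plant methylome work. Undefined levels (no
covered site) are NaN throughout — never silently 0. Feature profiles pool
counts over all genes per compartment (2-kb strand-aware upstream flank,
gene body, 2-kb downstream), clipping flanks at contig boundaries rather
than discarding clipped genes. Binned tracks tile each chromosome from 0
with a 10-kb default window, keep the last partial tile, and pool all
contexts by default (a flag restricts to one context).

## DMR calling

Regions are fixed non-overlapping 1-kb tiles per chromosome (size and step
configurable; overlapping windows are supported). The defaults encode the
modelled study design:

| parameter | default | meaning |
|---|---|---|
| `window_size` | 1000 bp | region width |
| `min_site_coverage` | 5 | per-site coverage needed for a site to enter a sample's region level |
| `min_samples_per_group` | 3 | defined region levels required in *each* group |
| `min_sites_per_region` | 1 | context sites needed for a region to exist |
| `alpha` | 0.05 | threshold on the BH-adjusted p |
| `min_difference` | 0.20 | minimum absolute methylation difference |

Per region, context and sample the weighted level is computed over sites
passing the coverage filter; the two groups of per-sample levels are
compared with a one-way ANOVA (identical to the pooled two-sided t-test for
two groups — asserted against scipy's t-test to 1e-9 in the tests). Regions
with too few defined levels are skipped, not given p = 1. BH adjustment runs
separately per (comparison, context) family because contexts are
biologically distinct methylation pathways and are reported separately
everywhere. The significance filter applies to the *adjusted* p by default
(`use_adjusted_p=False` switches to raw p for sensitivity analysis). The
methylation difference is the difference of group means of per-sample
levels — the same unit of observation the ANOVA tests — not a pooled count
ratio. Direction: `hyper` in `A_vs_B` means B (the later generation /
higher dose, given the label ordering) has the higher level.

Degenerate regions with no level variation at all are reported as
(difference 0, p 1); a region with zero within-group but nonzero
between-group variance gets p = 0 (infinite F), which the effect-size filter
then adjudicates.

## Comparison design

All unordered dose pairs within each generation plus all unordered
generation pairs within each dose; the lower dose / earlier generation is
always the first member, which pins the direction convention. A 3-generation
× 3-dose design yields 18 comparison sets (9 + 9).

## Feature annotation

Nearest-feature distance is the minimal gap between half-open intervals,
0 on any overlap and also 0 for abutting intervals (gap = start₂ − end₁
when start₂ ≥ end₁). Ties are broken by smaller feature start, then
lexicographic id, making annotation deterministic. Promoter classification
(0 < distance ≤ 2 kb) is strand-aware: upstream means 5′ of the gene start
for + genes and of the gene end for − genes; strandless genes fall back to
"left of start" with a logged warning. Promoter and gene-body labels are
mutually exclusive by construction (a promoter needs strictly positive
distance); TE association is independent. Count matrices deduplicate at the
gene (or TE) level — two DMRs in one gene's promoter count one gene — while
the DMR-level table keeps every region row.

## Enrichment and overlaps

GO over-representation is a one-sided hypergeometric upper-tail test per
term (terms with fewer than 3 background genes are skipped), BH-adjusted
across tested terms and reported as −log10(p_adj). The background defaults
to all genes of the annotation and is overridable. No GO-graph ancestor
propagation and no term clustering are performed: the package reports the
plain per-term statistic. Venn analysis computes exact
intersection/exclusion cardinalities for 2–4 gene sets; region counts sum
to the union size.

## UPLC global-methylation cascade

%5mdC = 100 · 5mdC / (dC + 5mdC). Within each generation (across doses) and
each dose (across generations): Shapiro–Wilk per group and Bartlett across
groups are computed and *reported only* — they do not gate the ANOVA, since
no fallback test is part of the modelled procedure; the one-way ANOVA is
followed by Tukey HSD exactly when p < 0.05. Percentages are analysed
untransformed by default (a logit flag exists). Groupings with fewer than
two replicated conditions are skipped with a warning, not an error.

## Synthetic data model

The generator emulates the study design: 3 generations × 3 sequenced doses
× 5 replicates (45 methylomes), plus a 3 × 5-dose UPLC table.

* **Genome**: i.i.d. bases at GC 0.36 over 3 × 100-kb chromosomes
  (defaults), giving ≈ 19k CG, 16k CHG and 73k CHH strand-resolved sites —
  enough for sub-percentage-point Monte-Carlo error on context means while
  keeping a full pipeline run in seconds.
* **Site levels**: drawn per site from a two-component Beta mixture
  (means 0.02 and 0.92, concentration 20) whose weight is solved so each
  context's mean equals its baseline — CG 0.30, CHG 0.135, CHH 0.068,
  typical control levels for *A. thaliana* leaves. Plant methylomes are
  strongly bimodal, and the mixture preserves that while fixing the mean
  the recovery checks rely on. A flag switches to a single Beta.
* **Replicate noise**: per sample, interior site levels are redrawn from a
  Beta centred on the site level with overdispersion ρ = 0.02; counts are
  binomial given negative-binomial coverage (mean 20, shape 10). Pure
  binomial replicates would make the region ANOVA anti-conservative
  relative to real biological replicates; ρ = 0.02 yields per-sample
  region-level SDs of roughly 0.015–0.02 on 1-kb CG windows, a plausible
  replicate scale. No dispersion estimate exists to anchor this, so it is
  an artifact choice, stated here once.
* **Planted DMRs**: window-aligned tiles whose sites take a *constant* true
  level — the context baseline in unaffected conditions,
  baseline ± difference (clipped to [0, 1]) in the affected condition (the
  second condition of the planted comparison). An additive shift on the
  bimodal site mixture cannot realise a −0.30 difference on a 0.30-mean CG
  methylome (most sites are near 0), so homogeneous regions are the only
  construction under which "difference 0.30, both directions" is
  well-defined; the realised group difference then equals the planted one.
  The default plan plants 30 CG DMRs (15 hyper + 15 hypo, difference 0.30)
  on `S2g0_vs_S2g30`, the contrast with the strongest effects in the
  modelled design.
* **TE uplift**: sites inside TEs get +0.05 in nonzero-dose conditions,
  mimicking exposure-associated TE hypermethylation. It is itself a planted
  effect, so `null_config()` disables it along with the DMR plan.
* **UPLC table**: normal noise (SD 0.25) around per-generation control
  means 5.38 / 4.88 / 6.03 %5mdC, with optional per-condition shifts.
  Note the default table is *not* null across generations.
* **Seeding**: one root seed feeds named substreams (genome per chromosome,
  annotation, site levels, planted-region placement, each sample, UPLC,
  gene→GO), so changing one component never perturbs another, and identical
  configs give byte-identical datasets.

What the simulation does **not** model: read-level artifacts (mapping bias,
incomplete bisulfite conversion, sequencing error), linkage of methylation
state along a DNA molecule, realistic chromosomal methylation landscapes
(pericentromeric enrichment), gene/TE sequence composition, or dose-response
curves. Passing recovery tests therefore demonstrate the *statistical*
correctness of the calling machinery under the assumed noise model, not
performance on real methylomes.

## Validation set-up and problem sizes

Baseline recovery is checked on a 3 × 200-kb control simulation (~39k CG
sites), where the weighted level's Monte-Carlo SE is ≈ 0.2 percentage
points, comfortably inside the ±0.5-point acceptance band; planted-DMR
recovery runs the full default simulation (sensitivity and empirical FDR
measured against the truth manifest, with a call counted false only when no
overlapping region carries a true difference ≥ 20% between the compared
conditions); null calibration uses 20 seeded 40-kb simulations with no
planted effects and checks that the fraction of (comparison, context)
families containing any call stays within binomial tolerance of the BH
level. Full-run determinism is asserted by hashing every output of two
identical runs.

## Known limitations

* The region definition is a fixed tiling; methylome segmentation or
  smoothing-based DMR methods will outperform tiles when true DMR
  boundaries are not window-aligned (partially covered planted regions
  dilute the observed difference).
* Single-cytosine differential calling and >2-group omnibus tests per
  region are out of scope.
* The hypergeometric enrichment treats GO terms independently and without
  ancestor propagation; p-values for nested terms are correlated.
* With only 5 replicates per group the region ANOVA has limited power below
  ~10% differences at the default coverage; the 20% filter makes this moot
  for calling but matters for the supplementary 5%-cutoff ladder.
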