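# Methods

This note documents the models, parameter choices and numerical decisions
behind `betcore`. The package analyses synthetic data whose generating
process it also defines, so the note covers both sides: what the analysis
computes, and what the generators plant for it to recover.

## 1. Expression stage

### Preprocessing

* **Detection filtering.** A probe is dropped only when its detection
  p-value exceeds `detection_alpha = 0.01` in *every* sample; a single
  confidently detected sample keeps the probe.
* **Variance-stabilizing transform.** Implemented as
  `arsinh(x / c) / ln 2`, with `c` the per-sample 5th-percentile intensity.
  This is a stand-in with the contract that matters downstream: it is
  strictly monotone within each sample, behaves as `log2(x) + const` well
  above background (so differences read as log2 fold changes), and is linear
  near zero (so background noise is not blown up). It stabilizes
  multiplicative noise only for signal well above the anchor `c`; the test
  suite checks two expressed blocks agree in variance within 20%.
* **Quantile normalization.** Each sample's sorted values are replaced by
  the across-sample mean of sorted values. Ties within a sample receive the
  mean of the reference values at their tied ranks; as a consequence the
  "all sorted columns identical" identity is exact only for tie-free data.
  The map is idempotent.
* **Probe collapse.** Several probes per gene collapse to the probe with
  the highest mean (post-normalization) value.

### Moderated t

Per cell line, with n₁ vehicle and n₂ treated replicates (≥ 2 each,
enforced), the pooled per-gene variance s²_g on d = n₁+n₂−2 df is shrunk
toward a prior: the scaled-F model is fitted by method of moments on
z_g = log s²_g, using digamma/trigamma corrections to estimate the prior
variance s₀² and prior df d₀ (d₀ solved by Newton inversion of the trigamma
function; d₀ = ∞ when the spread of z is at or below pure sampling
variation, in which case the posterior variance is the common value and
shrinkage is the identity). The moderated statistic
t̃ = Δ / √(s̃²(1/n₁+1/n₂)) is referred to a t distribution on d₀+d df.
`prior_df=0` disables shrinkage and reproduces the ordinary pooled t
exactly. The implementation is cross-checked in the test suite against
Bioconductor limma's `lmFit`+`eBayes` on the same matrix and agrees to
machine precision in prior df, prior variance, t and p.

Significance gates: BH-adjusted q < 0.05 **and** linear fold change > 2
(i.e. |log2fc| > 1), applied on the post-VST scale. The core signature is
the exact set intersection of the per-line downregulated sets.

## 2. ChIP-seq stage

Reads are BED-style post-alignment records. Filtering keeps MAPQ strictly
greater than 10 and deduplicates on (chromosome, 5′ position, strand) — the
strand-aware reading of "identical loci". Reads are extended along their
strand to 300 bp fragments, clipped to chromosome bounds. Coverage is
binned (default 100 bp); the default fragment-count mode increments every
bin a fragment overlaps, while base mode conserves total overlap exactly
(Σ bins = Σ fragment lengths), which is the mode the brute-force tests pin.

TSS metaprofiles take the coverage in [TSS−5 kb, TSS+5 kb), reverse
minus-strand rows so upstream is always left of centre, zero-pad and flag
windows that leave the chromosome, and order heatmap rows by total signal.

The peak caller is a deliberately simple calibrated stand-in (peaks are not
on the critical result path; enhancer regions arrive as input): per-bin
Poisson upper-tail p-values against the maximum of the global rate and a
±10 kb local average, BH correction across all bins, and gap-tolerant
merging (default: one sub-threshold bin may be bridged). On pure Poisson
background the fraction of simulations yielding any peak stays within the
nominal level.

### Super-enhancers

Regions are quantified as RPM = overlapping extended fragments × 10⁶ /
retained reads, with per-condition retained-read denominators. Ranking and
calling use the vehicle condition; the treated condition is quantified for
the depletion comparison. On the curve of ranked signal vs rank with both
axes scaled to [0,1], the cutoff is the slope-1 tangent point, computed in
closed form as argmax(x − y) (for a convex curve this is exactly where the
tangent slope first exceeds 1); regions strictly above the cutoff signal are
super-enhancers. The call is invariant to positive rescaling and to region
relabeling; an all-equal signal vector yields none. Optional stitching of
nearby regions before ranking is available but off by default. Gene
assignment gives a gene to every region whose nearest edge is within 50 kb
of the gene's TSS (distance 0 inside); multi-assignment is recorded, not
collapsed.

## 3. Cohort stage

The signature is mapped onto the cohort's measured rows through a platform
map; genes with no measured row are dropped (the count of mapped genes is
reported), multiple rows per gene are averaged. Genes are z-scored before
Euclidean distances between patients — standard practice for expression
heatmaps, and configurable. Patients are clustered by complete linkage;
the partition can be cut either at a height or into a requested number of
groups (both modes provided, since published analyses rarely state which
was used). Group ids are renumbered by dendrogram leaf order so runs are
reproducible; equal-distance merge ties are resolved by the hierarchical
backend's deterministic order. Associations between groups and categorical
clinical factors use Pearson chi-square without continuity correction
(Fisher's exact test available for 2×2), with degenerate tables flagged
instead of tested and a warning when any expected count falls below 5.

## 4. Synthetic-data generators

The generators define the study conditions; their defaults are the designs
the analysis claims to recover.

**Expression** (`ExperimentConfig`): 4 cell lines × (3 vehicle + 3 treated)
replicates × 10,000 genes. Log2 intensities are Gaussian (sd
`null_sd = 0.25`) around per-probe baselines drawn uniformly on log2
[6, 12], then exponentiated. A 26-gene core block is shifted by
`core_log2fc = −2` (per-gene-per-line jitter sd 0.25) in every treated arm;
300 further genes per line are shifted in that line only, with random sign
and magnitude uniform on [1.2, 3] log2 units. Planted genes are drawn from
probes with baseline ≥ 2⁹, since the arsinh transform intentionally
compresses fold changes near background — as on real arrays, differential
calls concentrate in expressed genes. 5% of non-planted probes are
"undetected": detection p uniform on (0.011, 1) in all samples, vs
(0, 0.009) for detected probes, avoiding flakiness at the 0.01 threshold.
With these conditions the four-way intersection recovers exactly the 26
planted genes at the default seed; because the jittered effect of a single
gene-line can occasionally fall below the twofold gate, a small minority of
seeds recover 25, which is the honest stochastic behaviour of the design
(observed ~1 seed in 12).

**ChIP** (`ChipConfig`): a two-chromosome toy genome (10 Mb + 14 Mb). The
26 core genes sit on the first chromosome spaced 250 kb apart; exactly 12
of them (seeded choice) get a super-enhancer 5–40 kb from their TSS. All
remaining regions — 18 more super-enhancers and 470 typical enhancers —
live on the second chromosome in non-overlapping slots, so no other region
can fall within 50 kb of a core TSS and the planted 12 is also the expected
recovered count. Region widths are drawn identically for both classes
(12–22 kb) so that only signal distinguishes them. Typical signal weights
are exponential (scale `typical_rpm_scale = 100` nominal RPM); the super
class *adds* an excess `(super_multiplier − 1) × scale × (1 + Exp(4))`,
a shifted heavy-tailed term chosen so that (a) a unit multiplier makes the
super class exchangeable with typical regions (the null the tests require),
and (b) at the default multiplier of 20 the planted class sits cleanly above
the exponential tail, as empirical BRD4 hockey sticks do. Reads (36 bp,
2×10⁶ per condition) are multinomial over regions plus uniform genomic
background, with MAPQ drawn from {0, 10, 30, 60} at weights
(0.10, 0.15, 0.25, 0.50) so the MAPQ filter always has work. The treated
condition binomially thins super-enhancer reads to `ibet_se_depletion =
0.3` of the vehicle rate. Under the defaults, planted super-enhancer recall
is 1.0 and precision ≈ 0.93 averaged over seeds (the exponential tail puts
an occasional typical region above any slope-1 cutoff); the 12 planted
core-gene assignments were recovered exactly in all seeds examined.

**Cohort** (`CohortConfig`): 436 patients from 6 archetypes; archetype mean
vectors are i.i.d. Gaussian with sd `archetype_separation = 3` per gene over
the 18 measured signature genes, patients scatter around them with sd 1.
Expected between-archetype distance (≈ 3√(2·18) ≈ 18) is three times the
within-group spread, so complete-linkage recovery is essentially exact
(adjusted Rand index 1.0 at the defaults). The platform map covers a seeded
18-of-26 subset of the signature, emulating an array that measures only part
of the program. Clinical labels (karyotype class, NPM1c, FLT3-ITD) are drawn
per archetype from skewed categorical distributions, giving the association
tests planted signal.

What the generators do **not** model: bead-level array physics, probe
cross-hybridization and batch effects; sequencing errors, mappability and
GC bias; chromatin input/IgG controls; copy-number or mutation structure in
the cohort. Passing tests therefore demonstrate the correctness and
calibration of the analysis logic under a clean planted-truth regime, not
robustness to those real-data artefacts.

## 5. Problem sizes and determinism

All randomness flows through `numpy.random.default_rng(seed)` per
generator; identical config + seed is bit-identical, and the pipeline
manifest records SHA-256 checksums of every output so a rerun can be
verified wholesale. Monte-Carlo tests use reduced designs chosen to keep
the statistical question intact: null-calibration runs use 500–800 genes on
one cell line over 20 seeds; chance-level super-enhancer runs use 3×10⁵
reads over 10 seeds; the planted-recovery checks use the full default
designs. `scripts/acceptance.py` runs the two headline recoveries at full
default size (10,000 genes; 500 regions at 2×10⁶ reads/condition) in a few
seconds.

## 6. Known limitations

* The VST is a documented stand-in, not a re-implementation of any
  published bead-array transform; only its monotonicity/stabilization
  contract is guaranteed.
* The peak caller ignores fragment-shift modelling and control tracks.
* The slope-1 tangency cutoff assumes an overall convex ranked curve;
  heavily multimodal signal distributions could place the tangency
  unexpectedly (not exercised by the generators).
* With per-condition RPM denominators, global depletion in one condition
  slightly inflates that condition's RPM at unaffected regions; the
  depletion contrast is therefore interpreted on the planted (super vs
  typical) difference, which is invariant to that shift.
* The fold-change gate is applied on the variance-stabilized scale; genes
  whose raw fold change is exactly at the gate may differ from a raw-scale
  gating convention.
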