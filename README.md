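# betcore

Analysis pipeline for the **core BET/BRD4-responsive transcriptional program**
in acute myeloid leukemia (AML), re-implemented as a tested, reusable Python
package and exercised end to end on synthetic data with planted ground truth.

BET-bromodomain inhibitors downregulate a small set of genes — including
*BCL2*, *MYC* and *IRF8* — in AML cell lines of very different mutational
backgrounds. Identifying that program and relating it to chromatin takes
three computational stages, all implemented here:

1. **Expression** (`betcore.expression`, `betcore.signature`) — detection-p
   probe filtering, a variance-stabilizing transform, quantile normalization,
   an empirical-Bayes **moderated t** per cell line
   (t̃_g = Δ_g / (s̃_g·√(1/n₁+1/n₂)), with s̃²_g = (d₀s₀² + d s²_g)/(d₀+d) and
   d₀, s₀² fitted by method of moments on log sample variances),
   Benjamini–Hochberg FDR, gates at FDR < 5% and fold change > 2, and the
   exact intersection of the per-line downregulated sets across cell lines.
2. **Chromatin** (`betcore.chipseq`, `betcore.enhancers`) — MAPQ > 10
   filtering and (chrom, 5′, strand) deduplication of aligned reads, 300 bp
   strand-aware fragment extension, binned coverage and TSS-centred
   metaprofiles, reads-per-million quantification over enhancer regions,
   **super-enhancer calling** at the slope-1 tangent of the scaled ranked
   signal ("hockey-stick") curve, and assignment of genes with a TSS within
   50 kb of a region edge.
3. **Cohort** (`betcore.cohort`) — extraction of the signature genes
   measurable on a cohort's platform, complete-linkage hierarchical
   clustering of patients on the per-gene z-scored sub-matrix, and Pearson
   chi-square tests of group-by-clinical-factor association.

Because the study's microarray, ChIP-seq and patient data are not
redistributable, `betcore.simulate` generates all inputs with recorded
planted truth: a 26-gene core block downregulated 4-fold in the treated arm
of four cell lines, a two-condition ChIP experiment over a toy genome in
which 12 of those genes carry a super-enhancer, and a 436-patient cohort
drawn from six expression archetypes with correlated clinical labels. Every
downstream claim is tested as recovery of that truth.

## Worked example

```python
from betcore import ExperimentConfig, generate_expression_bundle
from betcore.expression import de_per_line
from betcore.signature import build_signature

bundle, truth = generate_expression_bundle(ExperimentConfig(seed=0))
de = de_per_line(bundle)                      # filter -> VST -> quantile -> moderated t
sig = build_signature(de)                     # per-line down sets + intersection
print(len(sig.gene_ids))                      # 26
print(set(sig.gene_ids) == set(truth.core_gene_ids))  # True
print(sig.gene_ids[:3])
```

prints

```
26
True
['G04533', 'G03195', 'G01438']
```

— the four-way intersection of significantly downregulated genes has exactly
the 26 planted members, ordered most-downregulated first (the named genes
BCL2/MYC/IRF8 are planted among the 26 ids). The same end-to-end run, plus
the ChIP and cohort stages with all intermediate files and a checksummed
manifest, is available from the command line:

```bash
betcore run --seed 0 --outdir runs/demo
```

## Layout

```
src/betcore/
  config.py      frozen dataclasses for all designs and thresholds
  simulate.py    synthetic-data generators + PlantedTruth
  expression.py  filtering, VST, quantile normalization, moderated t, BH
  signature.py   cross-line intersection, overlap correlation, gene clustering
  chipseq.py     read filtering/extension, coverage, TSS profiles, peak caller
  enhancers.py   RPM, hockey-stick cutoff, 50 kb gene assignment, deltas
  cohort.py      signature extraction, patient clustering, association tests
  io.py          strict BED/TSV/bedGraph readers and writers
  pipeline.py    six-stage orchestration with manifests
  cli.py         click command-line interface
docs/methods.md  model, parameters, numerical choices, limitations
```
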