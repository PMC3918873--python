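"""Synthetic-data generators with recorded planted truth.

Three generators emulate the inputs of a BET-inhibition study in AML:

* :func:`generate_expression_bundle` — replicated treated-vs-vehicle microarray
  intensities for several cell lines with a common downregulated "core" gene
  block plus per-line private effects;
* :func:`generate_chip_bundle` — two-condition ChIP-seq reads over a toy
  genome with a heavy-tailed enhancer signal distribution, a super-enhancer
  subset planted near designated core genes, and treated-condition depletion
  at super-enhancers;
* :func:`generate_cohort` — a patient expression matrix over the signature
  genes drawn from archetype mean vectors, with correlated clinical labels.

Each generator returns its :class:`PlantedTruth` so downstream recovery is
checkable without external data. Identical config + seed gives bit-identical
output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    ChipConfig,
    CohortConfig,
    ConfigError,
    ExperimentConfig,
    GenerationError,
    LABEL_LEVELS,
)
from .expression import ExpressionBundle

# Canonical members of the core program named in the field's literature;
# planted among the synthetic core ids for documentation fidelity.
NAMED_CORE_GENES = ("BCL2", "MYC", "IRF8")

# MAPQ values with fixed weights so the MAPQ>10 filter always has work to do.
MAPQ_VALUES = np.array([0, 10, 30, 60])
MAPQ_WEIGHTS = np.array([0.10, 0.15, 0.25, 0.50])

# Planted effects are restricted to probes whose log2 baseline is at least
# this high: the variance-stabilizing transform compresses fold changes near
# the detection floor, mirroring real arrays where reliable differential
# calls concentrate in well-expressed genes.
EXPRESSED_LOG2_BASELINE = 9.0
BASELINE_LOG2_RANGE = (6.0, 12.0)

# Enhancer width range (bp), identical for typical and super-enhancer regions
# so that only the planted signal weight distinguishes the super class.
ENHANCER_WIDTH_RANGE = (12_000, 22_000)

# Exponential scale of the super-enhancer weight excess (on top of the
# super_multiplier shift); sets how heavy the top of the hockey stick is.
SUPER_EXCESS_TAIL = 4.0


@dataclass
class PlantedTruth:
    """Ground truth recorded by the generators, merged as stages run."""

    core_gene_ids: list[str] | None = None
    per_line_down_ids: dict[str, list[str]] | None = None
    se_region_ids: list[str] | None = None
    se_core_gene_ids: list[str] | None = None
    patient_archetype: list[int] | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def generate_expression_bundle(config: ExperimentConfig) -> tuple[ExpressionBundle, PlantedTruth]:
    """Simulate the replicated multi-line expression experiment.

    Intensities are Gaussian on the log2 scale around per-probe baselines and
    then exponentiated. Core-block genes are shifted by ``core_log2fc`` (with
    per-gene-per-line jitter ``core_sd``) in the treated arm of every line;
    private genes are shifted in exactly one line with random sign. A
    ``undetected_fraction`` of non-planted probes gets detection p-values
    above the filtering threshold in all samples.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    lines = config.cell_lines
    reps = config.replicates_per_arm

    gene_ids = np.array([f"G{i:05d}" for i in range(n)], dtype=object)
    baseline = rng.uniform(*BASELINE_LOG2_RANGE, size=n)

    expressed = np.flatnonzero(baseline >= EXPRESSED_LOG2_BASELINE)
    n_planted = config.core_block_size + config.n_cell_lines * config.private_de_per_line
    if n_planted > expressed.size:
        raise ConfigError(
            f"cannot plant {n_planted} effect genes among {expressed.size} expressed probes; "
            "increase n_genes"
        )
    planted = rng.choice(expressed, size=n_planted, replace=False)
    core_idx = np.sort(planted[: config.core_block_size])
    for name, gi in zip(NAMED_CORE_GENES, core_idx):
        gene_ids[gi] = name
    private_idx = planted[config.core_block_size:].reshape(config.n_cell_lines,
                                                           config.private_de_per_line)

    private_sign = rng.choice([-1.0, 1.0], size=private_idx.shape)
    private_mag = rng.uniform(1.2, 3.0, size=private_idx.shape)

    # effect[gene, line] applied to the treated arm only
    effect = np.zeros((n, len(lines)))
    if config.core_log2fc != 0.0:
        effect[core_idx, :] = config.core_log2fc + rng.normal(
            0.0, config.core_sd, size=(config.core_block_size, len(lines))
        )
    else:
        # truth still records the block, but nothing is planted
        rng.normal(0.0, config.core_sd, size=(config.core_block_size, len(lines)))
    for li in range(len(lines)):
        effect[private_idx[li], li] += private_sign[li] * private_mag[li]

    sample_rows = []
    columns = []
    log2 = np.empty((n, len(lines) * 2 * reps))
    col = 0
    for li, line in enumerate(lines):
        for arm in ("vehicle", "treated"):
            for rep in range(1, reps + 1):
                name = f"{line}_{arm}_{rep}"
                columns.append(name)
                sample_rows.append({"sample": name, "cell_line": line,
                                    "treatment": arm, "replicate": rep})
                mu = baseline + (effect[:, li] if arm == "treated" else 0.0)
                log2[:, col] = mu + rng.normal(0.0, config.null_sd, size=n)
                col += 1

    probe_ids = np.array([f"p_{g}" for g in gene_ids], dtype=object)
    intensities = pd.DataFrame(np.exp2(log2), index=probe_ids, columns=columns)

    non_planted = np.setdiff1d(np.arange(n), planted)
    n_undet = int(round(config.undetected_fraction * n))
    if n_undet > non_planted.size:
        raise ConfigError("undetected_fraction too large for the number of non-planted probes")
    undetected = rng.choice(non_planted, size=n_undet, replace=False)
    det_p = rng.uniform(0.0, 0.009, size=log2.shape)
    det_p[undetected, :] = rng.uniform(0.011, 1.0, size=(n_undet, log2.shape[1]))
    detection_p = pd.DataFrame(det_p, index=probe_ids, columns=columns)

    samples = pd.DataFrame(sample_rows).set_index("sample")
    probe_to_gene = pd.Series(gene_ids, index=probe_ids, name="gene")
    bundle = ExpressionBundle(intensities=intensities, detection_p=detection_p,
                              samples=samples, probe_to_gene=probe_to_gene)

    per_line_down = {}
    core_set = [str(g) for g in gene_ids[core_idx]]
    for li, line in enumerate(lines):
        down_private = private_idx[li][private_sign[li] < 0]
        ids = sorted(set(core_set) | {str(g) for g in gene_ids[down_private]}
                     ) if config.core_log2fc < 0 else sorted(
                         {str(g) for g in gene_ids[down_private]})
        per_line_down[line] = ids
    truth = PlantedTruth(core_gene_ids=sorted(core_set), per_line_down_ids=per_line_down)
    return bundle, truth


# ---------------------------------------------------------------------------
# ChIP-seq
# ---------------------------------------------------------------------------

def _draw_reads_in_regions(rng, counts, starts, ends, read_len):
    lo = np.repeat(starts, counts)
    hi = np.repeat(ends - read_len, counts)
    pos = rng.integers(lo, np.maximum(hi, lo + 1))
    return pos


def generate_chip_bundle(
    config: ChipConfig, truth: PlantedTruth
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Simulate the two-condition ChIP-seq experiment over a toy genome.

    Layout: the core genes from ``truth`` are spaced along the first
    chromosome, and exactly ``core_genes_with_se`` of them get a planted
    super-enhancer within 40 kb of their TSS; all remaining enhancers (typical
    and super) live on the second chromosome, guaranteeing that no other
    region falls within the assignment window of a core gene. Enhancer signal
    weights are exponential; super-enhancers carry a shifted-exponential
    weight scaled by ``super_multiplier`` so the planted class sits above the
    typical tail. Reads carry MAPQ from a fixed discrete distribution and the
    treated condition is binomially thinned at super-enhancers.

    Returns ``(reads_by_condition, regions, genes, truth)`` where ``truth``
    extends the input with the planted super-enhancer ids.
    """
    config.validate()
    if not truth.core_gene_ids:
        raise ConfigError("truth must carry core_gene_ids (run the expression generator first)")
    core_ids = list(truth.core_gene_ids)
    if config.core_genes_with_se > len(core_ids):
        raise ConfigError("core_genes_with_se exceeds the planted core block size")
    if config.core_genes_with_se > config.n_super:
        raise ConfigError("core_genes_with_se exceeds n_super")
    rng = np.random.default_rng(config.seed)
    genome = config.genome_dict
    chroms = list(genome)
    if len(chroms) < 2:
        raise GenerationError("toy genome needs at least two chromosomes")
    core_chrom, enh_chrom = chroms[0], chroms[1]

    # --- core genes on the first chromosome, widely spaced --------------
    spacing = 250_000
    first_tss = 1_000_000
    needed = first_tss + len(core_ids) * spacing + 100_000
    if needed > genome[core_chrom]:
        raise GenerationError(
            f"{core_chrom} (len {genome[core_chrom]}) too short for {len(core_ids)} "
            f"core genes spaced {spacing} bp apart"
        )
    gene_rows = []
    core_tss = {}
    for i, gid in enumerate(core_ids):
        tss = first_tss + i * spacing
        length = int(rng.integers(10_000, 50_000))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            start, end = tss, tss + length
        else:
            start, end = tss + 1 - length, tss + 1
        gene_rows.append((core_chrom, start, end, gid, 0, strand))
        core_tss[gid] = tss

    # --- planted super-enhancers next to a seeded subset of core genes ---
    se_core = sorted(rng.choice(core_ids, size=config.core_genes_with_se, replace=False))
    region_rows = []  # (chrom, start, end, is_super)
    for gid in se_core:
        width = int(rng.integers(*ENHANCER_WIDTH_RANGE))
        dist = int(rng.integers(5_000, 40_000))
        if rng.random() < 0.5:
            start = core_tss[gid] + dist
        else:
            start = core_tss[gid] - dist - width
        region_rows.append((core_chrom, start, start + width, True))

    # --- remaining enhancers on the second chromosome --------------------
    n_rest = config.n_enhancers - config.core_genes_with_se
    n_rest_super = config.n_super - config.core_genes_with_se
    if n_rest > 0:
        slot = genome[enh_chrom] // n_rest
        if slot < ENHANCER_WIDTH_RANGE[1] + 1_000:
            raise GenerationError(
                f"{enh_chrom} too short to place {n_rest} non-overlapping enhancers"
            )
        is_super_rest = np.zeros(n_rest, dtype=bool)
        is_super_rest[:n_rest_super] = True
        rng.shuffle(is_super_rest)
        for j in range(n_rest):
            width = int(rng.integers(*ENHANCER_WIDTH_RANGE))
            jitter = int(rng.integers(0, slot - width))
            start = j * slot + jitter
            region_rows.append((enh_chrom, start, start + width, bool(is_super_rest[j])))

    regions = pd.DataFrame(region_rows, columns=["chrom", "start", "end", "is_super_truth"])
    regions = regions.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    regions.insert(3, "name", [f"E{i:04d}" for i in range(len(regions))])
    for _, row in regions.iterrows():
        if row.start < 0 or row.end > genome[row.chrom]:
            raise GenerationError(
                f"region {row['name']} [{row.start},{row.end}) overflows {row.chrom}"
            )

    # --- other (non-core) genes scattered on the enhancer chromosome -----
    for j in range(config.n_other_genes):
        length = int(rng.integers(5_000, 40_000))
        start = int(rng.integers(0, genome[enh_chrom] - length))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_rows.append((enh_chrom, start, start + length, f"OTH{j:04d}", 0, strand))
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "name", "score", "strand"])

    # --- signal weights (nominal RPM units) -------------------------------
    n_regions = len(regions)
    is_super = regions["is_super_truth"].to_numpy()
    # Typical regions draw exponential weights; the super class adds a
    # shifted heavy-tailed excess proportional to (super_multiplier - 1), so a
    # unit multiplier makes the planted class exchangeable with the rest.
    weights = rng.exponential(config.typical_rpm_scale, size=n_regions)
    n_se = int(is_super.sum())
    weights[is_super] += ((config.super_multiplier - 1.0) * config.typical_rpm_scale
                          * (1.0 + rng.exponential(SUPER_EXCESS_TAIL, size=n_se)))
    p_signal = weights / 1e6
    p_bg = 1.0 - p_signal.sum()
    if p_bg < config.background_fraction_min:
        raise GenerationError(
            f"enhancer signal occupies {1 - p_bg:.2%} of the library; lower typical_rpm_scale"
        )

    reads_by_condition: dict[str, pd.DataFrame] = {}
    lib = config.library_size_per_condition
    for condition in ("vehicle", "treated"):
        if lib == 0:
            reads_by_condition[condition] = _empty_readset(condition)
            continue
        counts = rng.multinomial(lib, np.append(p_signal, p_bg))
        region_counts, bg_count = counts[:-1], counts[-1]
        if condition == "treated" and config.ibet_se_depletion < 1.0:
            region_counts = region_counts.copy()
            region_counts[is_super] = rng.binomial(region_counts[is_super],
                                                   config.ibet_se_depletion)
        pos = _draw_reads_in_regions(
            rng, region_counts,
            regions["start"].to_numpy(), regions["end"].to_numpy(), config.read_len)
        chrom_sig = np.repeat(regions["chrom"].to_numpy(), region_counts)

        lengths = np.array([genome[c] for c in chroms], dtype=float)
        bg_chrom_idx = rng.choice(len(chroms), size=bg_count, p=lengths / lengths.sum())
        bg_pos = rng.integers(0, (lengths[bg_chrom_idx] - config.read_len).astype(np.int64))
        chrom_all = np.concatenate([chrom_sig, np.array(chroms, dtype=object)[bg_chrom_idx]])
        start_all = np.concatenate([pos, bg_pos]).astype(np.int64)

        n_reads = start_all.size
        strand = np.where(rng.random(n_reads) < 0.5, "+", "-")
        mapq = rng.choice(MAPQ_VALUES, size=n_reads, p=MAPQ_WEIGHTS)
        reads = pd.DataFrame({
            "chrom": pd.Categorical(chrom_all, categories=chroms),
            "start": start_all,
            "end": start_all + config.read_len,
            "mapq": mapq.astype(np.int64),
            "strand": pd.Categorical(strand, categories=["+", "-"]),
        })
        reads["condition"] = condition
        reads_by_condition[condition] = reads

    se_region_ids = sorted(regions.loc[is_super, "name"].tolist())
    new_truth = dataclasses.replace(truth, se_region_ids=se_region_ids,
                                    se_core_gene_ids=[str(g) for g in se_core])
    return reads_by_condition, regions, genes, new_truth


def _empty_readset(condition: str) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": pd.Series(dtype=object), "start": pd.Series(dtype=np.int64),
        "end": pd.Series(dtype=np.int64), "mapq": pd.Series(dtype=np.int64),
        "strand": pd.Series(dtype=object), "condition": condition,
    })


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortMatrix:
    """Signature-gene expression across patients plus clinical labels and the
    platform map (signature gene id -> measured row ids)."""

    values: pd.DataFrame          # rows: measured probes, columns: patients
    labels: pd.DataFrame          # index: patients, columns: clinical factors
    platform_map: dict[str, list[str]]


def generate_cohort(
    config: CohortConfig, signature_genes=None
) -> tuple[CohortMatrix, pd.DataFrame, PlantedTruth]:
    """Simulate the patient cohort measured on the signature genes.

    Patients are drawn from ``n_archetypes`` archetype mean vectors (i.i.d.
    Gaussian with sd ``archetype_separation`` per gene) with within-group sd
    ``within_sd``. When ``signature_genes`` is given (e.g. the planted core
    ids), a seeded subset of size ``n_signature_genes`` is "measurable on the
    platform" and the platform map covers exactly those genes — emulating a
    signature only partially covered by the cohort's array.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    k = config.n_archetypes

    if signature_genes is not None:
        signature_genes = sorted(str(g) for g in signature_genes)
        if len(signature_genes) < config.n_signature_genes:
            raise ConfigError("signature has fewer genes than n_signature_genes")
        measured = sorted(rng.choice(signature_genes, size=config.n_signature_genes,
                                     replace=False))
    else:
        measured = [f"SIG{i:02d}" for i in range(config.n_signature_genes)]
    probe_ids = [f"probe_{g}" for g in measured]
    platform_map = {g: [p] for g, p in zip(measured, probe_ids)}

    archetype_means = rng.normal(0.0, config.archetype_separation,
                                 size=(k, config.n_signature_genes))
    archetype = rng.integers(0, k, size=config.n_patients)
    values = (archetype_means[archetype]
              + rng.normal(0.0, config.within_sd,
                           size=(config.n_patients, config.n_signature_genes))).T
    patients = [f"P{i:04d}" for i in range(config.n_patients)]
    matrix = pd.DataFrame(values, index=probe_ids, columns=patients)

    schemes = config.resolved_label_schemes()
    label_cols = {}
    for factor, per_arch in schemes.items():
        levels = LABEL_LEVELS.get(factor)
        arch_keys = sorted(per_arch, key=lambda s: (len(s), s))
        probs = np.array([per_arch[a] for a in arch_keys])
        if levels is None:
            levels = tuple(f"L{i}" for i in range(probs.shape[1]))
        drawn = [levels[rng.choice(probs.shape[1], p=probs[a])] for a in archetype]
        label_cols[factor] = drawn
    labels = pd.DataFrame(label_cols, index=patients)

    truth = PlantedTruth(patient_archetype=[int(a) for a in archetype])
    cohort = CohortMatrix(values=matrix, labels=labels, platform_map=platform_map)
    return cohort, labels, truth
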