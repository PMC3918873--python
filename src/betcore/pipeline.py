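"""End-to-end orchestration: simulate -> DE -> signature -> ChIP coverage ->
super-enhancers -> cohort classification, with per-stage manifests.

Each stage writes its outputs into the run directory and appends a manifest
entry recording parameters, seed and output checksums, so a figure-style
output is reproducible from the config alone. Logging goes to stderr.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import chipseq, cohort as cohort_mod, enhancers, expression, io, signature, simulate
from .config import RunConfig

logger = logging.getLogger("betcore")

STAGES = ("simulate", "de", "signature", "chip", "superenh", "classify")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Stateful run directory; stages can be executed individually or via
    :meth:`run_all`. Raises a stage error naming the missing upstream output
    when stages are run out of order."""

    def __init__(self, config: RunConfig):
        config.validate()
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: list[dict] = []
        # in-memory state handed between stages
        self.bundle = None
        self.truth = None
        self.de_results = None
        self.core_signature = None
        self.chip_reads = None
        self.chip_fragments = None
        self.chip_library = None
        self.regions = None
        self.genes = None
        self.enhancer_table = None
        self.cohort_bundle = None
        self.classification = None

    def _record(self, stage: str, params: dict, outputs: list[Path]) -> None:
        entry = {
            "stage": stage,
            "params": params,
            "outputs": {str(p.relative_to(self.outdir)): _sha256(p) for p in outputs},
        }
        self.manifest.append(entry)
        logger.info("stage=%s params=%s outputs=%d", stage, json.dumps(params, default=str),
                    len(outputs))
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)

    def _require(self, attr: str, needed_by: str):
        value = getattr(self, attr)
        if value is None:
            raise RuntimeError(
                f"stage {needed_by!r} requires upstream output {attr!r}; run the earlier stage first"
            )
        return value

    # ------------------------------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.config
        self.bundle, self.truth = simulate.generate_expression_bundle(cfg.expression)
        self.chip_reads, self.regions, self.genes, self.truth = simulate.generate_chip_bundle(
            cfg.chip, self.truth)
        self.cohort_bundle, _, cohort_truth = simulate.generate_cohort(
            cfg.cohort, signature_genes=self.truth.core_gene_ids)
        self.truth = dataclasses.replace(self.truth,
                                         patient_archetype=cohort_truth.patient_archetype)
        out = self.outdir
        paths = io.write_expression_bundle(self.bundle, out / "expression")
        io.write_bed(self.regions.rename(columns={"name": "name"}), out / "enhancer_regions.bed",
                     columns=["chrom", "start", "end", "name"])
        io.write_bed(self.genes, out / "genes.bed")
        for cond, reads in self.chip_reads.items():
            io.write_reads_bed(reads, out / f"reads_{cond}.bed")
        io.write_matrix(self.cohort_bundle.values, out / "cohort_matrix.tsv")
        self.cohort_bundle.labels.to_csv(out / "cohort_labels.tsv", sep="\t")
        with open(out / "platform_map.json", "w") as fh:
            json.dump(self.cohort_bundle.platform_map, fh, indent=2)
        self.truth.to_json(out / "planted_truth.json")
        outputs = [Path(p) for p in paths.values()] + [
            out / "enhancer_regions.bed", out / "genes.bed", out / "cohort_matrix.tsv",
            out / "cohort_labels.tsv", out / "platform_map.json", out / "planted_truth.json",
        ] + [out / f"reads_{c}.bed" for c in self.chip_reads]
        self._record("simulate", {"seed": cfg.seed}, outputs)

    def stage_de(self) -> None:
        bundle = self._require("bundle", "de")
        pcfg = self.config.pipeline
        self.de_results = expression.de_per_line(bundle, pcfg.detection_alpha)
        outputs = []
        for line, de in self.de_results.items():
            path = self.outdir / f"de_{line}.tsv"
            de.to_csv(path, sep="\t")
            volcano = pd.DataFrame({
                "log2fc": de["log2fc"],
                "neg_log10_q": -np.log10(np.maximum(de["q"], 1e-300)),
            })
            up, down = expression.call_significant(de, pcfg.fdr_threshold, pcfg.fc_threshold)
            volcano["call"] = ["up" if g in up else "down" if g in down else "ns"
                               for g in de.index]
            vpath = self.outdir / f"volcano_{line}.tsv"
            volcano.to_csv(vpath, sep="\t")
            outputs += [path, vpath]
        self._record("de", {"detection_alpha": pcfg.detection_alpha}, outputs)

    def stage_signature(self) -> None:
        de_results = self._require("de_results", "signature")
        pcfg = self.config.pipeline
        self.core_signature = signature.build_signature(
            de_results, pcfg.fdr_threshold, pcfg.fc_threshold)
        gpath = self.outdir / "core_signature_genes.tsv"
        pd.Series(self.core_signature.gene_ids, name="gene").to_csv(
            gpath, sep="\t", index=False)
        jpath = self.outdir / "core_signature.json"
        self.core_signature.to_json(jpath)
        # complete-linkage clustering of the downregulated genes' fold-change profiles
        down_union = sorted(set().union(*self.core_signature.per_line_down.values()))
        fc_matrix = pd.DataFrame({line: de["log2fc"] for line, de in de_results.items()}
                                 ).loc[lambda d: d.index.isin(down_union)].dropna()
        outputs = [gpath, jpath]
        if len(fc_matrix) >= 2:
            labels = signature.cluster_genes(fc_matrix, pcfg.cluster_cutoff)
            cpath = self.outdir / "gene_clusters.tsv"
            labels.to_csv(cpath, sep="\t")
            outputs.append(cpath)
        self._record("signature", {"fdr": pcfg.fdr_threshold, "fc": pcfg.fc_threshold,
                                   "cluster_cutoff": pcfg.cluster_cutoff}, outputs)

    def stage_chip(self) -> None:
        reads = self._require("chip_reads", "chip")
        genes = self._require("genes", "chip")
        pcfg = self.config.pipeline
        genome = self.config.chip.genome_dict
        self.chip_fragments = {}
        self.chip_library = {}
        outputs = []
        for cond, rd in reads.items():
            kept = chipseq.filter_reads(rd, pcfg.mapq_min, dedup=True)
            frags = chipseq.extend_reads(kept, pcfg.fragment_len, genome)
            self.chip_fragments[cond] = frags
            self.chip_library[cond] = len(kept)
            track = chipseq.coverage(frags, pcfg.coverage_binsize, genome,
                                     library_size=len(kept))
            bg = self.outdir / f"coverage_{cond}.bedgraph"
            io.write_bedgraph(track, bg)
            heatmap, profile, _ = chipseq.tss_matrix(track, genes, pcfg.tss_flank)
            hpath = self.outdir / f"tss_heatmap_{cond}.tsv"
            heatmap.to_csv(hpath, sep="\t")
            ppath = self.outdir / f"tss_profile_{cond}.tsv"
            pd.Series(profile, index=heatmap.columns, name="mean_coverage").to_csv(
                ppath, sep="\t")
            peaks = chipseq.call_peaks(track)
            kpath = self.outdir / f"peaks_{cond}.bed"
            io.write_bed(peaks[["chrom", "start", "end"]].assign(
                name=[f"peak{i}" for i in range(len(peaks))]), kpath,
                columns=["chrom", "start", "end", "name"])
            outputs += [bg, hpath, ppath, kpath]
        self._record("chip", {"mapq_min": pcfg.mapq_min, "fragment_len": pcfg.fragment_len},
                     outputs)

    def stage_superenh(self) -> None:
        self._require("chip_fragments", "superenh")
        regions = self._require("regions", "superenh")
        genes = self._require("genes", "superenh")
        pcfg = self.config.pipeline
        self.enhancer_table = enhancers.build_enhancer_table(
            regions[["chrom", "start", "end", "name"]], self.chip_fragments,
            self.chip_library, genes=genes, window=pcfg.assign_window)
        tpath = self.outdir / "enhancer_table.tsv"
        self.enhancer_table.to_csv(tpath, sep="\t", index=False)
        delta = enhancers.condition_delta(self.enhancer_table)
        dpath = self.outdir / "enhancer_delta.tsv"
        delta.to_csv(dpath, sep="\t", index=False)
        plot = delta[["rank", "rpm_vehicle", "rpm_treated", "is_super"]]
        ppath = self.outdir / "hockey_stick.tsv"
        plot.to_csv(ppath, sep="\t", index=False)
        self._record("superenh", {"window": pcfg.assign_window}, [tpath, dpath, ppath])

    def stage_classify(self) -> None:
        cb = self._require("cohort_bundle", "classify")
        sig = self._require("core_signature", "classify")
        pcfg = self.config.pipeline
        sub, n_mapped = cohort_mod.extract_signature(
            cb.values, sig.gene_ids, cb.platform_map)
        self.classification = cohort_mod.classify_patients(
            sub, n_groups=pcfg.n_patient_groups)
        self.classification.associations = cohort_mod.factor_associations(
            self.classification.groups, cb.labels)
        self.n_mapped_signature = n_mapped
        cpath = self.outdir / "cohort_groups.tsv"
        self.classification.groups.to_csv(cpath, sep="\t")
        jpath = self.outdir / "cohort_associations.json"
        self.classification.to_json(jpath)
        mpath = self.outdir / "cohort_heatmap_matrix.tsv"
        order = self.classification.groups.sort_values(kind="stable").index
        sub.loc[:, order].to_csv(mpath, sep="\t")
        self._record("classify", {"n_groups": pcfg.n_patient_groups, "n_mapped": n_mapped},
                     [cpath, jpath, mpath])

    # ------------------------------------------------------------------
    def run_all(self) -> Path:
        t0 = time.time()
        self.stage_simulate()
        self.stage_de()
        self.stage_signature()
        self.stage_chip()
        self.stage_superenh()
        self.stage_classify()
        logger.info("pipeline complete in %.1fs -> %s", time.time() - t0, self.outdir)
        return self.outdir


def run_pipeline(config: RunConfig) -> Path:
    """Execute all six stages and return the run directory."""
    return PipelineRun(config).run_all()
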