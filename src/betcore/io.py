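"""Readers and writers for the pipeline's on-disk formats.

All interval formats are BED-style, 0-based half-open, tab-separated:

* regions — BED4 (chrom, start, end, name)
* genes — BED6 (chrom, start, end, name, score, strand); TSS is start for
  ``+`` genes and end-1 for ``-`` genes
* reads — extended 7-column BED (chrom, start, end, name, mapq, strand,
  condition)
* coverage — bedGraph

Matrices are rectangular TSVs with a header row and row names in the first
column. Readers validate strictly and report the offending line; they reject
rather than coerce malformed input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """Raised with a line number when an input file is malformed."""


_BED_SCHEMAS = {
    3: ["chrom", "start", "end"],
    4: ["chrom", "start", "end", "name"],
    6: ["chrom", "start", "end", "name", "score", "strand"],
    7: ["chrom", "start", "end", "name", "mapq", "strand", "condition"],
}


def read_bed(path, n_columns: int | None = None, genome: dict[str, int] | None = None) -> pd.DataFrame:
    """Read a 3/4/6/7-column BED file with strict validation.

    The 7-column flavor carries MAPQ in the score slot plus a condition
    column (the read format written by the simulator). Raises
    :class:`ParseError` naming the first offending line.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=_BED_SCHEMAS[n_columns or 3])
    ncol = df.shape[1]
    if n_columns is not None and ncol != n_columns:
        raise ParseError(f"{path}: expected {n_columns} columns, found {ncol}")
    if ncol not in _BED_SCHEMAS:
        raise ParseError(f"{path}: unsupported BED column count {ncol}")
    df.columns = _BED_SCHEMAS[ncol]
    for col in ("start", "end") + (("mapq",) if ncol == 7 else ()) + (("score",) if ncol == 6 else ()):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ParseError(f"{path}:{line}: non-integer value in column {col!r}")
        df[col] = converted.astype(np.int64)
    bad = df["start"] >= df["end"]
    if bad.any():
        line = int(bad.idxmax()) + 1
        raise ParseError(f"{path}:{line}: start >= end")
    if (df["start"] < 0).any():
        line = int((df["start"] < 0).idxmax()) + 1
        raise ParseError(f"{path}:{line}: negative start")
    if "strand" in df.columns:
        bad = ~df["strand"].isin(["+", "-"])
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ParseError(f"{path}:{line}: strand must be '+' or '-'")
    if genome is not None:
        unknown = ~df["chrom"].isin(genome)
        if unknown.any():
            line = int(unknown.idxmax()) + 1
            raise ParseError(f"{path}:{line}: unknown chromosome {df['chrom'][unknown].iloc[0]!r}")
        over = df["end"] > df["chrom"].map(genome)
        if over.any():
            line = int(over.idxmax()) + 1
            raise ParseError(f"{path}:{line}: interval beyond chromosome end")
    return df


def write_bed(df: pd.DataFrame, path, columns: list[str] | None = None) -> None:
    """Write records as BED; coordinates preserved bit-exactly (round-trip
    identity with :func:`read_bed`)."""
    if columns is None:
        for n in (7, 6, 4, 3):
            if set(_BED_SCHEMAS[n]).issubset(df.columns):
                columns = _BED_SCHEMAS[n]
                break
        else:
            raise ParseError("DataFrame does not match any supported BED schema")
    df.to_csv(path, sep="\t", header=False, index=False, columns=columns)


def write_reads_bed(reads: pd.DataFrame, path) -> None:
    """Write a read table as extended 7-column BED, generating read names."""
    out = reads.copy()
    if "name" not in out.columns:
        out["name"] = [f"r{i:07d}" for i in range(len(out))]
    write_bed(out, path, columns=_BED_SCHEMAS[7])


def read_matrix(path) -> pd.DataFrame:
    """Read a rectangular numeric TSV (header row, row names in column 1)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: ragged or malformed TSV ({exc})") from exc
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ParseError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
        df[col] = converted
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def write_bedgraph(track, path) -> None:
    """Export a :class:`~betcore.chipseq.CoverageTrack` as bedGraph, merging
    equal-valued adjacent bins."""
    with open(path, "w") as fh:
        for chrom, counts in track.bins.items():
            if counts.size == 0:
                continue
            change = np.flatnonzero(np.diff(counts) != 0) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [counts.size]))
            for s, e in zip(starts, ends):
                val = counts[s]
                if val != 0:
                    fh.write(f"{chrom}\t{s * track.binsize}\t{e * track.binsize}\t{val}\n")


def read_expression_bundle(intensities_path, detection_path, samples_path,
                           probe_map_path=None):
    """Assemble an :class:`~betcore.expression.ExpressionBundle` from TSVs."""
    from .expression import ExpressionBundle

    intensities = read_matrix(intensities_path)
    detection = read_matrix(detection_path)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    if probe_map_path is not None:
        pm = pd.read_csv(probe_map_path, sep="\t", index_col=0)
        probe_to_gene = pm.iloc[:, 0]
    else:
        probe_to_gene = pd.Series(intensities.index, index=intensities.index, name="gene")
    return ExpressionBundle(intensities, detection, samples, probe_to_gene)


def write_expression_bundle(bundle, prefix) -> dict[str, str]:
    """Write a bundle's four TSVs with a common path prefix; returns paths."""
    paths = {
        "intensities": f"{prefix}_intensities.tsv",
        "detection_p": f"{prefix}_detection_p.tsv",
        "samples": f"{prefix}_samples.tsv",
        "probe_map": f"{prefix}_probe_map.tsv",
    }
    write_matrix(bundle.intensities, paths["intensities"])
    write_matrix(bundle.detection_p, paths["detection_p"])
    bundle.samples.to_csv(paths["samples"], sep="\t")
    bundle.probe_to_gene.rename("gene").to_csv(paths["probe_map"], sep="\t")
    return paths
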