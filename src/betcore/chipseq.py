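"""ChIP-seq read filtering, fragment extension, binned coverage, TSS
metaprofiles, and a simplified local-Poisson peak caller.

Reads arrive as post-alignment BED-style records (0-based half-open, with a
MAPQ score). The pipeline retains reads with MAPQ strictly above the cutoff,
removes duplicates sharing (chrom, 5' position, strand), extends each read
along its strand to the estimated fragment size, and accumulates binned
coverage. The peak caller is a calibrated stand-in, not a reimplementation
of a full model-based caller: bins are tested against a Poisson background
whose rate is the maximum of the global and a local (sliding-window) rate,
with BH correction and gap-tolerant merging of significant bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import InputError, bh_adjust

READ_COLUMNS = ("chrom", "start", "end", "mapq", "strand")


def _check_reads(reads: pd.DataFrame) -> None:
    missing = set(READ_COLUMNS) - set(reads.columns)
    if missing:
        raise InputError(f"read table missing columns: {sorted(missing)}")


def five_prime(reads: pd.DataFrame) -> np.ndarray:
    """Strand-aware 5' position of each read (start on +, end-1 on -)."""
    plus = np.asarray(reads["strand"]) == "+"
    return np.where(plus, reads["start"].to_numpy(), reads["end"].to_numpy() - 1)


def filter_reads(reads: pd.DataFrame, mapq_min: int = 10, dedup: bool = True) -> pd.DataFrame:
    """Retain reads with MAPQ strictly greater than ``mapq_min``; optionally
    keep at most one read per (chrom, 5' position, strand)."""
    _check_reads(reads)
    kept = reads.loc[reads["mapq"].to_numpy() > mapq_min]
    if dedup and len(kept):
        key = pd.DataFrame({
            "chrom": np.asarray(kept["chrom"]),
            "pos5": five_prime(kept),
            "strand": np.asarray(kept["strand"]),
        })
        kept = kept.loc[~key.duplicated(keep="first").to_numpy()]
    return kept.reset_index(drop=True)


def extend_reads(reads: pd.DataFrame, fragment_len: int, genome: dict[str, int]) -> pd.DataFrame:
    """Extend reads along their strand to ``fragment_len``, clipping to
    chromosome bounds. Returns a chrom/start/end interval table."""
    _check_reads(reads)
    if len(reads):
        read_len = int((reads["end"] - reads["start"]).max())
        if fragment_len < read_len:
            raise InputError(f"fragment_len {fragment_len} shorter than read length {read_len}")
    starts = reads["start"].to_numpy(np.int64)
    ends = reads["end"].to_numpy(np.int64)
    plus = np.asarray(reads["strand"]) == "+"
    new_start = np.where(plus, starts, ends - fragment_len)
    new_end = np.where(plus, starts + fragment_len, ends)
    chroms = np.asarray(reads["chrom"]).astype(object)
    unknown = set(chroms) - set(genome)
    if unknown:
        raise InputError(f"reads on chromosomes absent from genome: {sorted(unknown)}")
    lengths = np.array([genome[c] for c in chroms], dtype=np.int64) if len(reads) else np.array([], dtype=np.int64)
    new_start = np.clip(new_start, 0, None)
    new_end = np.minimum(new_end, lengths) if len(reads) else new_end
    return pd.DataFrame({"chrom": chroms, "start": new_start, "end": new_end})


@dataclass
class CoverageTrack:
    """Per-chromosome binned coverage.

    In ``fragment`` mode a fragment increments every bin it overlaps; in
    ``base`` mode each bin holds the total per-base overlap, so that
    ``sum(bins) == sum(fragment lengths)`` exactly (after edge clipping).
    """

    bins: dict[str, np.ndarray]
    binsize: int
    library_size: int
    mode: str = "fragment"

    def chrom_names(self) -> list[str]:
        return list(self.bins)


def coverage(
    intervals: pd.DataFrame,
    binsize: int,
    genome: dict[str, int],
    library_size: int | None = None,
    mode: str = "fragment",
) -> CoverageTrack:
    """Accumulate binned coverage from extended-fragment intervals."""
    if binsize < 1:
        raise InputError("binsize must be >= 1")
    if mode not in ("fragment", "base"):
        raise InputError(f"unknown coverage mode: {mode!r}")
    bins: dict[str, np.ndarray] = {}
    for chrom, length in genome.items():
        n_bins = -(-length // binsize)
        bins[chrom] = np.zeros(n_bins, dtype=np.int64)
    if len(intervals):
        starts = intervals["start"].to_numpy(np.int64)
        ends = intervals["end"].to_numpy(np.int64)
        chroms = np.asarray(intervals["chrom"])
        if (starts < 0).any():
            raise InputError("interval start below 0")
        for chrom in np.unique(chroms):
            if chrom not in genome:
                raise InputError(f"interval on unknown chromosome {chrom!r}")
            mask = chroms == chrom
            s, e = starts[mask], ends[mask]
            if (e > genome[chrom]).any():
                raise InputError(f"interval beyond end of {chrom}")
            n_bins = bins[chrom].size
            if mode == "fragment":
                diff = np.zeros(n_bins + 1, dtype=np.int64)
                b0 = s // binsize
                b1 = (e - 1) // binsize
                np.add.at(diff, b0, 1)
                np.add.at(diff, b1 + 1, -1)
                bins[chrom] = np.cumsum(diff[:-1])
            else:
                base = np.zeros(n_bins * binsize + 1, dtype=np.int64)
                np.add.at(base, s, 1)
                np.add.at(base, e, -1)
                per_base = np.cumsum(base[:-1])
                bins[chrom] = per_base.reshape(n_bins, binsize).sum(axis=1)
    if library_size is None:
        library_size = int(len(intervals))
    return CoverageTrack(bins=bins, binsize=binsize, library_size=library_size, mode=mode)


def tss_positions(genes: pd.DataFrame) -> np.ndarray:
    """Strand-aware TSS: start for + genes, end-1 for - genes."""
    plus = np.asarray(genes["strand"]) == "+"
    return np.where(plus, genes["start"].to_numpy(), genes["end"].to_numpy() - 1)


def tss_matrix(
    track: CoverageTrack,
    genes: pd.DataFrame,
    flank: int = 5_000,
    order_by_signal: bool = True,
) -> tuple[pd.DataFrame, np.ndarray, pd.Series]:
    """Coverage in ``[TSS - flank, TSS + flank)`` per gene, oriented 5'->3'.

    Rows of minus-strand genes are reversed so that upstream sequence always
    sits left of center. Windows running off a chromosome are zero-padded and
    flagged. Returns ``(heatmap, mean_profile, clipped_flags)``; rows are
    ordered by total signal (descending) unless ``order_by_signal=False``.
    """
    bs = track.binsize
    if flank % bs != 0:
        raise InputError(f"flank ({flank}) must be a multiple of the track binsize ({bs})")
    half = flank // bs
    n_cols = 2 * half
    rows = np.zeros((len(genes), n_cols), dtype=float)
    clipped = np.zeros(len(genes), dtype=bool)
    tss = tss_positions(genes)
    strands = np.asarray(genes["strand"])
    chroms = np.asarray(genes["chrom"])
    for i in range(len(genes)):
        chrom = chroms[i]
        if chrom not in track.bins:
            clipped[i] = True
            continue
        vec = track.bins[chrom]
        b_tss = tss[i] // bs
        lo, hi = b_tss - half, b_tss + half
        src_lo, src_hi = max(lo, 0), min(hi, vec.size)
        if src_lo > lo or src_hi < hi:
            clipped[i] = True
        if src_hi > src_lo:
            rows[i, src_lo - lo: src_hi - lo] = vec[src_lo:src_hi]
        if strands[i] == "-":
            rows[i] = rows[i, ::-1]
    names = genes["name"].to_numpy() if "name" in genes.columns else np.arange(len(genes))
    heatmap = pd.DataFrame(rows, index=names,
                           columns=np.arange(-half, half) * bs)
    flags = pd.Series(clipped, index=names, name="clipped")
    mean_profile = rows.mean(axis=0) if len(genes) else np.zeros(n_cols)
    if order_by_signal and len(genes):
        order = heatmap.sum(axis=1).sort_values(ascending=False, kind="stable").index
        heatmap = heatmap.loc[order]
    return heatmap, mean_profile, flags


def call_peaks(
    track: CoverageTrack,
    lambda_bg: float | None = None,
    alpha: float = 0.05,
    local_window: int = 10_000,
    merge_gap_bins: int = 1,
) -> pd.DataFrame:
    """Poisson upper-tail peak calling against max(local, global) background.

    Per-bin p-values are BH-corrected genome-wide; adjacent significant bins
    within ``merge_gap_bins`` of each other merge into one peak. Returns a
    BED-like table (chrom, start, end, n_bins, min_q).
    """
    all_counts = np.concatenate([v for v in track.bins.values()]) if track.bins else np.array([])
    if all_counts.size == 0 or all_counts.sum() == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_bins", "min_q"])
    global_lambda = lambda_bg if lambda_bg is not None else float(all_counts.mean())
    if global_lambda <= 0:
        raise InputError("background rate must be positive")
    w_bins = max(1, local_window // track.binsize)
    pvals = {}
    for chrom, counts in track.bins.items():
        kernel = np.ones(2 * w_bins + 1)
        local_sum = np.convolve(counts, kernel, mode="same")
        local_n = np.convolve(np.ones_like(counts, dtype=float), kernel, mode="same")
        lam = np.maximum(local_sum / local_n, global_lambda)
        pvals[chrom] = stats.poisson.sf(counts - 1, lam)
    flat = np.concatenate([pvals[c] for c in track.bins])
    qflat = bh_adjust(flat)
    offsets = np.cumsum([0] + [track.bins[c].size for c in track.bins])
    peaks = []
    for (chrom, counts), o0, o1 in zip(track.bins.items(), offsets[:-1], offsets[1:]):
        q = qflat[o0:o1]
        sig = np.flatnonzero(q < alpha)
        if sig.size == 0:
            continue
        run_start = sig[0]
        prev = sig[0]
        for b in list(sig[1:]) + [None]:
            if b is not None and b - prev <= merge_gap_bins + 1:
                prev = b
                continue
            peaks.append({
                "chrom": chrom,
                "start": int(run_start * track.binsize),
                "end": int((prev + 1) * track.binsize),
                "n_bins": int(prev - run_start + 1),
                "min_q": float(q[run_start:prev + 1].min()),
            })
            if b is not None:
                run_start = prev = b
    return pd.DataFrame(peaks, columns=["chrom", "start", "end", "n_bins", "min_q"])
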