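"""Enhancer signal quantification, super-enhancer calling, and gene assignment.

Enhancer regions (imported, not called de novo) are quantified as reads per
million retained reads using extended fragments. Super-enhancers are the
upper tail of the ranked signal curve: with ranks and signals both scaled to
[0, 1], the cutoff sits where the tangent slope of the curve first exceeds 1,
and every region with signal strictly above the cutoff value is flagged.
Genes are assigned to regions when their TSS lies within a fixed window of
the region's nearest edge (distance 0 inside the region); multi-assignment is
permitted and recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chipseq import tss_positions
from .expression import InputError


def quantify_rpm(
    fragments: pd.DataFrame, regions: pd.DataFrame, library_size: int
) -> np.ndarray:
    """Reads-per-million overlap counts of extended fragments over regions.

    ``rpm_i = (#fragments overlapping region i) * 1e6 / library_size`` where
    ``library_size`` is the retained (post-filter) read count.
    """
    if library_size <= 0:
        raise InputError("library_size must be positive")
    regions = regions.reset_index(drop=True)
    rpm = np.zeros(len(regions), dtype=float)
    frag_chroms = np.asarray(fragments["chrom"]) if len(fragments) else np.array([])
    for chrom, sub in regions.groupby("chrom", sort=False, observed=True):
        if len(fragments):
            mask = frag_chroms == chrom
            starts = np.sort(fragments["start"].to_numpy(np.int64)[mask])
            ends = np.sort(fragments["end"].to_numpy(np.int64)[mask])
        else:
            starts = ends = np.array([], dtype=np.int64)
        # overlap iff frag.start < region.end and frag.end > region.start
        n_start_before_end = np.searchsorted(starts, sub["end"].to_numpy(np.int64), side="left")
        n_end_before_start = np.searchsorted(ends, sub["start"].to_numpy(np.int64), side="right")
        rpm[sub.index.to_numpy()] = n_start_before_end - n_end_before_start
    return rpm * 1e6 / library_size


@dataclass
class SuperEnhancerCall:
    cutoff_value: float
    is_super: np.ndarray          # bool, in input order
    crossing_rank: int | None     # ascending-rank index of the slope-1 tangency


def call_super_enhancers(rpm: np.ndarray) -> SuperEnhancerCall:
    """Flag super-enhancers from the ranked-signal ("hockey-stick") curve.

    Signals are sorted ascending and both axes scaled to [0, 1]. On this
    scaled curve the cutoff sits at the slope-1 tangency — the rank where the
    tangent slope of the (convex) curve first exceeds 1, computed in closed
    form as the point of maximum gap below the x = y diagonal,
    ``argmax(x - y)``. Regions with signal strictly above the cutoff value
    are flagged. The call is invariant under positive rescaling of the
    signals and under relabeling of the regions; all-equal signal means the
    scaled curve has no upward inflection and nothing is flagged.
    """
    rpm = np.asarray(rpm, dtype=float)
    n = rpm.size
    if n < 2:
        raise InputError("call_super_enhancers requires at least two regions")
    if not np.isfinite(rpm).all():
        raise InputError("non-finite signal values")
    y_sorted = np.sort(rpm, kind="stable")
    y0, y1 = y_sorted[0], y_sorted[-1]
    if y1 == y0:
        return SuperEnhancerCall(cutoff_value=float(y1),
                                 is_super=np.zeros(n, dtype=bool), crossing_rank=None)
    x = np.arange(n) / (n - 1)
    ys = (y_sorted - y0) / (y1 - y0)
    crossing = int(np.argmax(x - ys))
    cutoff = float(y_sorted[crossing])
    return SuperEnhancerCall(cutoff_value=cutoff, is_super=rpm > cutoff,
                             crossing_rank=crossing)


def assign_genes(
    regions: pd.DataFrame, genes: pd.DataFrame, window: int = 50_000
) -> pd.DataFrame:
    """Assign genes to regions whose nearest edge lies within ``window`` of
    the gene's TSS (distance 0 if the TSS falls inside the region).

    Returns a long table (region, gene, distance); a gene near several
    regions appears once per region. Genes on chromosomes absent from the
    region table are skipped with a warning.
    """
    if window < 0:
        raise InputError("window must be >= 0")
    regions = regions.reset_index(drop=True)
    genes = genes.reset_index(drop=True)
    tss = tss_positions(genes)
    gene_chroms = np.asarray(genes["chrom"])
    region_chroms = set(np.asarray(regions["chrom"]))
    unknown = sorted(set(gene_chroms) - region_chroms)
    if unknown:
        warnings.warn(f"genes on chromosomes without regions skipped: {unknown}")
    out = []
    gene_names = np.asarray(genes["name"]) if "name" in genes.columns else np.arange(len(genes))
    region_names = np.asarray(regions["name"]) if "name" in regions.columns else np.arange(len(regions))
    for chrom, sub in regions.groupby("chrom", sort=False, observed=True):
        gmask = gene_chroms == chrom
        if not gmask.any():
            continue
        g_tss = tss[gmask]
        g_names = gene_names[gmask]
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        r_names = region_names[sub.index.to_numpy()]
        # distance matrix genes × regions
        d_left = starts[None, :] - g_tss[:, None]          # >0 when TSS left of region
        d_right = g_tss[:, None] - (ends[None, :] - 1)     # >0 when TSS right of region
        dist = np.maximum(np.maximum(d_left, d_right), 0)
        gi, ri = np.nonzero(dist <= window)
        for a, b in zip(gi, ri):
            out.append((r_names[b], g_names[a], int(dist[a, b])))
    return pd.DataFrame(out, columns=["region", "gene", "distance"])


def build_enhancer_table(
    regions: pd.DataFrame,
    fragments_by_condition: dict[str, pd.DataFrame],
    library_sizes: dict[str, int],
    genes: pd.DataFrame | None = None,
    call_condition: str = "vehicle",
    window: int = 50_000,
    stitch_distance: int = 0,
) -> pd.DataFrame:
    """Quantify RPM per condition, rank, call super-enhancers on one
    condition, and (optionally) assign genes.

    ``stitch_distance > 0`` merges regions closer than that many bp before
    ranking (off by default). Ranks are 1..N by increasing RPM in the calling
    condition. Returns the region table with ``rpm_<condition>`` columns,
    ``rank``, ``is_super`` and semicolon-joined ``assigned_genes``.
    """
    table = regions.copy().reset_index(drop=True)
    if stitch_distance > 0:
        table = stitch_regions(table, stitch_distance)
    if call_condition not in fragments_by_condition:
        raise InputError(f"condition {call_condition!r} not quantified")
    for cond, frags in fragments_by_condition.items():
        table[f"rpm_{cond}"] = quantify_rpm(frags, table, library_sizes[cond])
    ref = table[f"rpm_{call_condition}"].to_numpy()
    order = np.argsort(ref, kind="stable")
    ranks = np.empty(len(table), dtype=int)
    ranks[order] = np.arange(1, len(table) + 1)
    table["rank"] = ranks
    call = call_super_enhancers(ref)
    table["is_super"] = call.is_super
    table.attrs["se_cutoff_rpm"] = call.cutoff_value
    if genes is not None:
        pairs = assign_genes(table, genes, window)
        joined = pairs.groupby("region")["gene"].apply(lambda g: ";".join(map(str, sorted(g))))
        table["assigned_genes"] = table["name"].map(joined).fillna("")
    return table


def stitch_regions(regions: pd.DataFrame, stitch_distance: int) -> pd.DataFrame:
    """Merge regions on the same chromosome whose gap is <= stitch_distance."""
    merged = []
    for chrom, sub in regions.sort_values(["chrom", "start"], kind="stable").groupby(
            "chrom", sort=False, observed=True):
        cur_start = cur_end = None
        names: list[str] = []
        for _, row in sub.iterrows():
            if cur_start is None:
                cur_start, cur_end, names = row["start"], row["end"], [str(row["name"])]
            elif row["start"] - cur_end <= stitch_distance:
                cur_end = max(cur_end, row["end"])
                names.append(str(row["name"]))
            else:
                merged.append((chrom, cur_start, cur_end, "|".join(names)))
                cur_start, cur_end, names = row["start"], row["end"], [str(row["name"])]
        if cur_start is not None:
            merged.append((chrom, cur_start, cur_end, "|".join(names)))
    return pd.DataFrame(merged, columns=["chrom", "start", "end", "name"])


def condition_delta(
    table: pd.DataFrame, cond_a: str = "vehicle", cond_b: str = "treated"
) -> pd.DataFrame:
    """Per-region RPM change between conditions plus hockey-stick plot data.

    Returns the table ordered by ``rank`` with ``delta_rpm = rpm_b - rpm_a``
    and ``ratio = rpm_b / rpm_a`` (NaN when the denominator is 0).
    """
    for cond in (cond_a, cond_b):
        if f"rpm_{cond}" not in table.columns:
            raise InputError(f"condition {cond!r} missing from enhancer table")
    out = table.sort_values("rank", kind="stable").copy()
    a = out[f"rpm_{cond_a}"].to_numpy(dtype=float)
    b = out[f"rpm_{cond_b}"].to_numpy(dtype=float)
    out["delta_rpm"] = b - a
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ratio"] = np.where(a > 0, b / a, np.nan)
    return out
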