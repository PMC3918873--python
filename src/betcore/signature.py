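"""Derivation of the cross-cell-line core downregulated program.

The core program is the exact intersection of the per-line significantly
downregulated gene sets; overlap/correlation descriptors and complete-linkage
clustering of the regulated genes accompany it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .expression import InputError, call_significant


@dataclass
class CoreSignature:
    """Genes downregulated in every cell line, with per-line context."""

    gene_ids: list[str]
    per_line_down: dict[str, set[str]]
    pairwise_overlap: pd.DataFrame | None = None       # shared-down counts
    pairwise_correlation: pd.DataFrame | None = None   # log2fc Pearson r

    def to_json(self, path) -> None:
        doc = {
            "gene_ids": self.gene_ids,
            "per_line_down": {k: sorted(v) for k, v in self.per_line_down.items()},
        }
        if self.pairwise_overlap is not None:
            doc["pairwise_overlap"] = self.pairwise_overlap.to_dict()
        if self.pairwise_correlation is not None:
            doc["pairwise_correlation"] = self.pairwise_correlation.to_dict()
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


def intersect_down(
    per_line_down: Mapping[str, Iterable[str]] | Sequence[Iterable[str]],
    de_results: Mapping[str, pd.DataFrame] | None = None,
) -> CoreSignature:
    """Exact intersection of the per-line downregulated gene sets.

    With ``de_results`` supplied, the intersection is ordered by mean log2
    fold change ascending (most downregulated first); otherwise
    lexicographically. Order-invariant and idempotent in its inputs.
    """
    if isinstance(per_line_down, Mapping):
        named = {str(k): set(v) for k, v in per_line_down.items()}
    else:
        named = {f"set{i}": set(v) for i, v in enumerate(per_line_down)}
    if len(named) < 2:
        raise InputError("intersect_down requires at least two gene sets")
    sets = list(named.values())
    common = set.intersection(*sets)
    if de_results is not None and common:
        mean_fc = {}
        for g in common:
            fcs = [de.loc[g, "log2fc"] for de in de_results.values() if g in de.index]
            mean_fc[g] = float(np.mean(fcs)) if fcs else 0.0
        ordered = sorted(common, key=lambda g: (mean_fc[g], g))
    else:
        ordered = sorted(common)
    return CoreSignature(gene_ids=[str(g) for g in ordered], per_line_down=named)


class OverlapResult(NamedTuple):
    r: float
    shared_down: int
    n_genes: int
    defined: bool


def overlap_correlation(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    fdr: float = 0.05,
    fc: float = 2.0,
    gene_universe: str = "union_significant",
) -> OverlapResult:
    """Pearson correlation of log2fc between two lines plus shared-down count.

    The correlation is computed over the union of either line's significant
    genes restricted to both universes (``gene_universe='all'`` uses every
    shared gene instead). Fewer than 3 usable genes -> ``defined=False`` with
    NaN r.
    """
    shared = de_a.index.intersection(de_b.index)
    if len(shared) == 0:
        raise InputError("gene universes do not overlap")
    up_a, down_a = call_significant(de_a, fdr, fc)
    up_b, down_b = call_significant(de_b, fdr, fc)
    shared_down = len(down_a & down_b)
    if gene_universe == "union_significant":
        genes = sorted((up_a | down_a | up_b | down_b) & set(shared))
    elif gene_universe == "all":
        genes = list(shared)
    else:
        raise InputError(f"unknown gene_universe: {gene_universe!r}")
    if len(genes) < 3:
        warnings.warn("overlap_correlation: fewer than 3 genes, correlation undefined")
        return OverlapResult(np.nan, shared_down, len(genes), False)
    a = de_a.loc[genes, "log2fc"].to_numpy(dtype=float)
    b = de_b.loc[genes, "log2fc"].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("overlap_correlation: zero variance, correlation undefined")
        return OverlapResult(np.nan, shared_down, len(genes), False)
    r = float(np.corrcoef(a, b)[0, 1])
    return OverlapResult(r, shared_down, len(genes), True)


def pairwise_summary(
    de_results: Mapping[str, pd.DataFrame], fdr: float = 0.05, fc: float = 2.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shared-down counts and log2fc correlations for every pair of lines."""
    lines = list(de_results)
    counts = pd.DataFrame(0, index=lines, columns=lines, dtype=int)
    corr = pd.DataFrame(np.nan, index=lines, columns=lines, dtype=float)
    for i, a in enumerate(lines):
        _, down_a = call_significant(de_results[a], fdr, fc)
        counts.loc[a, a] = len(down_a)
        corr.loc[a, a] = 1.0
        for b in lines[i + 1:]:
            res = overlap_correlation(de_results[a], de_results[b], fdr, fc)
            counts.loc[a, b] = counts.loc[b, a] = res.shared_down
            corr.loc[a, b] = corr.loc[b, a] = res.r
    return counts, corr


def build_signature(
    de_results: Mapping[str, pd.DataFrame], fdr: float = 0.05, fc: float = 2.0
) -> CoreSignature:
    """Call per-line downregulated sets and intersect them across lines."""
    per_line = {}
    for line, de in de_results.items():
        _, down = call_significant(de, fdr, fc)
        per_line[line] = down
    sig = intersect_down(per_line, de_results)
    counts, corr = pairwise_summary(de_results, fdr, fc)
    sig.pairwise_overlap = counts
    sig.pairwise_correlation = corr
    return sig


def cluster_genes(log2fc_matrix: pd.DataFrame, cutoff: float = 10.0) -> pd.Series:
    """Complete-linkage agglomerative clustering of gene log2fc profiles.

    Euclidean distances; the dendrogram is cut at height ``cutoff`` (clusters
    are the connected components of merges at or below the cutoff). Returns
    integer labels indexed by gene.
    """
    x = log2fc_matrix.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise InputError("cluster_genes requires at least two genes")
    if not np.isfinite(x).all():
        raise InputError("non-finite values in log2fc matrix")
    z = linkage(x, method="complete", metric="euclidean")
    labels = fcluster(z, t=cutoff, criterion="distance")
    return pd.Series(labels, index=log2fc_matrix.index, name="cluster")
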