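"""Signature-driven classification of a patient cohort.

The signature genes are extracted from the cohort matrix through a platform
map (signature gene -> measured probe rows, possibly partial), patients are
clustered by complete-linkage agglomeration on Euclidean distances of the
per-gene z-scored sub-matrix, and group-by-clinical-factor associations are
tested with Pearson chi-square contingency statistics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy import stats

from .expression import InputError


def extract_signature(
    cohort: pd.DataFrame,
    signature_genes: Iterable[str],
    platform_map: Mapping[str, Iterable[str]],
) -> tuple[pd.DataFrame, int]:
    """Restrict the cohort matrix to the measurable signature genes.

    Genes with at least one mapped measured row are kept; multiple rows per
    gene are averaged. Returns ``(sub_matrix indexed by gene, n_mapped)``.
    Idempotent: re-extracting the result with an identity map is a no-op.
    """
    rows = []
    mapped = []
    for gene in sorted(set(map(str, signature_genes))):
        probes = [p for p in platform_map.get(gene, []) if p in cohort.index]
        if not probes:
            continue
        rows.append(cohort.loc[probes].mean(axis=0).rename(gene))
        mapped.append(gene)
    if not mapped:
        raise InputError("no signature gene maps to a measured row")
    sub = pd.DataFrame(rows)
    sub.index.name = "gene"
    return sub, len(mapped)


@dataclass
class CohortClassification:
    """Patient partition with its dendrogram and association statistics."""

    groups: pd.Series                    # patient -> group id (1..k)
    linkage_matrix: np.ndarray
    cut_height: float | None = None
    n_groups_requested: int | None = None
    associations: dict = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return int(self.groups.nunique())

    def to_json(self, path) -> None:
        doc = {
            "groups": {str(k): int(v) for k, v in self.groups.items()},
            "n_groups": self.n_groups,
            "associations": {
                f: {k: (v if not isinstance(v, np.ndarray) else v.tolist())
                    for k, v in res.items() if k not in ("table", "expected")}
                for f, res in self.associations.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


def classify_patients(
    sub_matrix: pd.DataFrame,
    n_groups: int | None = 6,
    cut_height: float | None = None,
    zscore: bool = True,
) -> CohortClassification:
    """Complete-linkage hierarchical clustering of patients.

    Rows (genes) are z-scored before Euclidean distances between patient
    columns unless ``zscore=False``. Cut either into ``n_groups`` clusters or
    at ``cut_height`` (exactly one must be given). Group ids are renumbered
    by dendrogram leaf order (left to right) for reproducibility; the
    partition is invariant to patient input order up to that relabeling.
    """
    if (n_groups is None) == (cut_height is None):
        raise InputError("specify exactly one of n_groups or cut_height")
    x = sub_matrix.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise InputError("classify_patients requires at least two patients")
    if not np.isfinite(x).all():
        raise InputError("non-finite values in cohort sub-matrix")
    if zscore:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
    z = linkage(x.T, method="complete", metric="euclidean")
    if n_groups is not None:
        raw = fcluster(z, t=n_groups, criterion="maxclust")
    else:
        raw = fcluster(z, t=cut_height, criterion="distance")
    # renumber groups by first appearance along the dendrogram leaves
    leaf_order = leaves_list(z)
    mapping: dict[int, int] = {}
    for leaf in leaf_order:
        g = raw[leaf]
        if g not in mapping:
            mapping[g] = len(mapping) + 1
    groups = pd.Series([mapping[g] for g in raw], index=sub_matrix.columns, name="group")
    return CohortClassification(groups=groups, linkage_matrix=z,
                                cut_height=cut_height, n_groups_requested=n_groups)


def association_test(
    groups: pd.Series, factor: pd.Series, method: str = "chi2"
) -> dict:
    """Group-by-factor contingency test.

    Pearson chi-square without continuity correction by default; Fisher's
    exact test available for 2x2 tables. Degenerate inputs (a single group or
    a constant factor) are flagged rather than tested. Warns when any
    expected cell count falls below 5.
    """
    factor = factor.loc[groups.index]
    table = pd.crosstab(groups, factor)
    result: dict = {"table": table, "degenerate": False, "small_expected": False}
    if table.shape[0] < 2 or table.shape[1] < 2:
        warnings.warn("association_test: degenerate table (single group or factor level)")
        result.update({"degenerate": True, "chi2": np.nan, "df": 0, "p": np.nan})
        return result
    if method == "chi2":
        chi2, p, df, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
        result.update({"chi2": float(chi2), "df": int(df), "p": float(p),
                       "expected": expected})
        if (expected < 5).any():
            result["small_expected"] = True
            warnings.warn("association_test: expected count below 5; chi-square approximate")
    elif method == "fisher":
        if table.shape != (2, 2):
            raise InputError("fisher method requires a 2x2 table")
        odds, p = stats.fisher_exact(table.to_numpy())
        result.update({"odds_ratio": float(odds), "p": float(p), "chi2": np.nan, "df": 1})
    else:
        raise InputError(f"unknown method: {method!r}")
    return result


def factor_associations(groups: pd.Series, labels: pd.DataFrame) -> dict[str, dict]:
    """Run :func:`association_test` for every clinical factor column."""
    return {col: association_test(groups, labels[col]) for col in labels.columns}
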