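"""Expression preprocessing and per-cell-line moderated differential expression.

The stage mirrors a standard bead-array workflow: detection-p filtering
(probes with no sample confidently above negative-control background are
dropped), a variance-stabilizing transform, quantile normalization across
samples, and an empirical-Bayes moderated two-sample t-test per cell line
with Benjamini–Hochberg FDR control. Significance gates on both the adjusted
p-value and a linear-scale fold change.

The moderated t shrinks each gene's pooled variance toward a prior estimated
by method of moments on the log sample variances (the scaled-F model): with
pooled variances :math:`s_g^2` on :math:`d` degrees of freedom, the posterior
variance is :math:`\\tilde s_g^2 = (d_0 s_0^2 + d s_g^2)/(d_0 + d)` and the
moderated t is referred to a t distribution on :math:`d_0 + d` df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats


class InputError(ValueError):
    """Raised on malformed analysis inputs."""


@dataclass
class ExpressionBundle:
    """Probes × samples intensities with detection p-values and annotations."""

    intensities: pd.DataFrame
    detection_p: pd.DataFrame
    samples: pd.DataFrame            # index: sample id; columns: cell_line, treatment, replicate
    probe_to_gene: pd.Series         # index: probe id -> gene id

    def __post_init__(self):
        if self.intensities.shape != self.detection_p.shape:
            raise InputError("intensities and detection_p shapes disagree")
        if not self.intensities.columns.equals(self.detection_p.columns):
            raise InputError("intensities and detection_p columns disagree")
        missing = set(self.intensities.columns) - set(self.samples.index)
        if missing:
            raise InputError(f"samples missing annotation: {sorted(missing)}")
        bad = set(self.samples["treatment"]) - {"vehicle", "treated"}
        if bad:
            raise InputError(f"unknown treatment arms: {sorted(bad)}")

    @property
    def cell_lines(self) -> list[str]:
        return list(dict.fromkeys(self.samples["cell_line"]))

    def replace_values(self, values: np.ndarray | pd.DataFrame) -> "ExpressionBundle":
        df = pd.DataFrame(np.asarray(values), index=self.intensities.index,
                          columns=self.intensities.columns)
        return ExpressionBundle(df, self.detection_p, self.samples, self.probe_to_gene)


def filter_probes(bundle: ExpressionBundle, alpha: float = 0.01) -> ExpressionBundle:
    """Drop probes whose detection p-value exceeds ``alpha`` in *every* sample."""
    if not 0.0 < alpha < 1.0:
        raise InputError(f"alpha must lie in (0, 1), got {alpha}")
    if bundle.intensities.shape[1] == 0:
        raise InputError("bundle has no samples")
    keep = (bundle.detection_p <= alpha).any(axis=1)
    return ExpressionBundle(
        bundle.intensities.loc[keep],
        bundle.detection_p.loc[keep],
        bundle.samples,
        bundle.probe_to_gene.loc[keep.index[keep]],
    )


def vst(bundle: ExpressionBundle, low_quantile: float = 0.05) -> ExpressionBundle:
    """Variance-stabilizing transform: ``arsinh(x / c) / ln 2`` per sample.

    ``c`` is the per-sample ``low_quantile`` intensity, anchoring the linear
    region of arsinh at the background level; for ``x >> c`` the transform
    behaves as ``log2(x) + const`` so downstream differences read as log2
    fold changes. Strictly monotone within each sample.
    """
    x = bundle.intensities.to_numpy(dtype=float)
    if (x < 0).any():
        raise InputError("intensities must be non-negative for vst")
    c = np.quantile(x, low_quantile, axis=0)
    c = np.where(c > 0, c, np.maximum(x.max(axis=0), 1.0) * 1e-6)
    transformed = np.arcsinh(x / c) / np.log(2.0)
    return bundle.replace_values(transformed)


def quantile_normalize(bundle: ExpressionBundle) -> ExpressionBundle:
    """Force every sample onto the mean of the per-sample sorted value vectors.

    Ties within a sample receive the mean of the reference values at their
    tied ranks. Idempotent; preserves within-sample rank order.
    """
    x = bundle.intensities.to_numpy(dtype=float)
    n, m = x.shape
    if m < 2:
        warnings.warn("quantile_normalize: fewer than 2 samples, returning input unchanged")
        return bundle
    if n == 0:
        return bundle
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(m):
        order = np.argsort(x[:, j], kind="stable")
        xs = x[order, j]
        # tie runs on the sorted column -> mean reference value per run
        boundaries = np.flatnonzero(np.diff(xs) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n]))
        csum = np.concatenate(([0.0], np.cumsum(reference)))
        run_means = (csum[ends] - csum[starts]) / (ends - starts)
        vals = np.repeat(run_means, ends - starts)
        out[order, j] = vals
    return bundle.replace_values(out)


def collapse_probes(bundle: ExpressionBundle) -> pd.DataFrame:
    """Collapse probes to genes, keeping the probe with highest mean value.

    Returns a genes × samples DataFrame.
    """
    mean_expr = bundle.intensities.mean(axis=1)
    order = mean_expr.sort_values(ascending=False).index
    best = (
        bundle.probe_to_gene.rename("gene").loc[order]
        .reset_index()
        .drop_duplicates(subset="gene", keep="first")
        .set_index("index")
    )
    collapsed = bundle.intensities.loc[best.index]
    collapsed.index = best["gene"].to_numpy()
    return collapsed.sort_index()


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values with monotonicity.

    NaN entries propagate as NaN (with a warning) and are excluded from the
    effective number of tests.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    nan_mask = np.isnan(p)
    if nan_mask.any():
        warnings.warn("bh_adjust: NaN p-values propagated as NaN")
    vals = p[~nan_mask]
    if ((vals < 0) | (vals > 1)).any():
        raise InputError("p-values must lie in [0, 1]")
    n = vals.size
    if n == 0:
        return q
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    q[~nan_mask] = out
    return q


def trigamma_inverse(y: float) -> float:
    """Solve ``trigamma(x) = y`` for x > 0 (Newton iteration)."""
    if y <= 0:
        raise InputError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior on gene-wise variances.

    Matches the expectation/variance of ``log(s^2)`` under the model
    ``s^2 | sigma^2 ~ sigma^2 chi^2_df / df`` with ``1/sigma^2`` scaled
    chi-square on ``d0`` df. Returns ``(prior_var s0^2, prior_df d0)``;
    ``d0 = inf`` when the observed spread of log variances is at or below
    what sampling alone explains (then the common value is the prior).
    """
    s2 = np.asarray(s2, dtype=float)
    z = np.log(np.maximum(s2, 1e-300))
    if z.size < 2 or np.var(z) < 1e-15:
        # no spread: shrinkage must be the identity
        return float(np.mean(s2)), np.inf
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0 = float(np.exp(emean))
    return s0, d0


def moderated_de(
    bundle: ExpressionBundle,
    cell_line: str,
    *,
    prior_df: float | None = None,
    collapse: bool = True,
) -> pd.DataFrame:
    """Treated-vs-vehicle moderated t-test for one cell line.

    Values are assumed to be on a log2-like scale (post VST + quantile
    normalization); ``log2fc = mean(treated) - mean(vehicle)``. Set
    ``prior_df=0`` to disable shrinkage (ordinary pooled two-sample t);
    ``None`` estimates the prior from the data.

    Returns a DataFrame indexed by gene with columns ``log2fc``, ``t_mod``,
    ``p``, ``q``, ``mean_expr``; the fitted prior is exposed in ``.attrs``.
    """
    samp = bundle.samples
    in_line = samp["cell_line"] == cell_line
    if not in_line.any():
        raise InputError(f"unknown cell line: {cell_line!r}")
    treated_cols = samp.index[in_line & (samp["treatment"] == "treated")]
    vehicle_cols = samp.index[in_line & (samp["treatment"] == "vehicle")]
    n1, n2 = len(vehicle_cols), len(treated_cols)
    if n1 < 2 or n2 < 2:
        raise InputError(
            f"cell line {cell_line!r} needs >=2 replicates per arm (got {n1} vehicle, {n2} treated)"
        )
    matrix = collapse_probes(bundle) if collapse else bundle.intensities
    xv = matrix[vehicle_cols].to_numpy(dtype=float)
    xt = matrix[treated_cols].to_numpy(dtype=float)

    fc = xt.mean(axis=1) - xv.mean(axis=1)
    df_resid = n1 + n2 - 2
    s2 = ((n1 - 1) * xv.var(axis=1, ddof=1) + (n2 - 1) * xt.var(axis=1, ddof=1)) / df_resid

    if prior_df is None:
        s0, d0 = fit_variance_prior(s2, df_resid)
    elif prior_df == 0:
        s0, d0 = 0.0, 0.0
    else:
        s0_est, _ = fit_variance_prior(s2, df_resid)
        s0, d0 = s0_est, float(prior_df)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = float(df_resid)
    else:
        s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
        df_total = float(d0 + df_resid)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, fc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    result = pd.DataFrame({
        "log2fc": fc,
        "t_mod": t_mod,
        "p": p,
        "q": bh_adjust(p),
        "mean_expr": matrix.to_numpy(dtype=float).mean(axis=1),
    }, index=matrix.index)
    result.attrs["prior_var"] = s0
    result.attrs["prior_df"] = d0
    result.attrs["df_resid"] = df_resid
    return result


def call_significant(
    de: pd.DataFrame, fdr: float = 0.05, fc: float = 2.0
) -> tuple[set[str], set[str]]:
    """Gate on adjusted p and linear-scale fold change.

    down = {g : q < fdr and 2**(-log2fc) > fc}; up is symmetric. The two
    sets are disjoint by construction.
    """
    if fdr <= 0 or fc <= 0:
        raise InputError("thresholds must be positive")
    sig = de["q"] < fdr
    down = set(de.index[sig & (np.exp2(-de["log2fc"]) > fc)])
    up = set(de.index[sig & (np.exp2(de["log2fc"]) > fc)])
    return up, down


def de_per_line(
    bundle: ExpressionBundle,
    detection_alpha: float = 0.01,
    **de_kwargs,
) -> dict[str, pd.DataFrame]:
    """Full preprocessing + per-line DE: filter -> vst -> quantile -> moderated t."""
    prepped = quantile_normalize(vst(filter_probes(bundle, detection_alpha)))
    return {line: moderated_de(prepped, line, **de_kwargs) for line in prepped.cell_lines}
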