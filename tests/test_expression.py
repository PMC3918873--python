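"""Expression-stage contracts: detection filtering, variance stabilization,
quantile normalization, the moderated t (cross-checked against limma), BH
adjustment, and the significance gates."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats
from statsmodels.stats.multitest import multipletests

from betcore import (
    ExperimentConfig,
    ExpressionBundle,
    InputError,
    bh_adjust,
    call_significant,
    collapse_probes,
    filter_probes,
    generate_expression_bundle,
    moderated_de,
    quantile_normalize,
    vst,
)
from betcore.expression import de_per_line, fit_variance_prior


def _mini_bundle(values, detection=None, probes=None):
    values = pd.DataFrame(values)
    values.index = probes if probes is not None else [f"p{i}" for i in range(len(values))]
    values.columns = [f"s{i}" for i in range(values.shape[1])]
    det = pd.DataFrame(detection if detection is not None else 0.001,
                       index=values.index, columns=values.columns)
    n = values.shape[1]
    samples = pd.DataFrame({
        "cell_line": ["L"] * n,
        "treatment": ["vehicle"] * (n // 2) + ["treated"] * (n - n // 2),
        "replicate": list(range(1, n // 2 + 1)) + list(range(1, n - n // 2 + 1)),
    }, index=values.columns)
    genes = pd.Series([p.replace("p", "g") for p in values.index], index=values.index)
    return ExpressionBundle(values, det, samples, genes)


# -------------------------------------------------------------- filtering

def test_filter_removes_probe_only_when_all_samples_undetected():
    det = [[0.5, 0.2, 0.9],      # all above alpha -> removed
           [0.5, 0.005, 0.9],    # one below -> kept
           [0.001, 0.001, 0.001]]
    b = _mini_bundle(np.ones((3, 3)), detection=det)
    out = filter_probes(b, 0.01)
    assert list(out.intensities.index) == ["p1", "p2"]
    assert out.intensities.shape[1] == 3


def test_filter_handles_empty_probe_set():
    b = _mini_bundle(np.ones((0, 3)).reshape(0, 3))
    out = filter_probes(b, 0.01)
    assert out.intensities.shape == (0, 3)


def test_filter_rejects_bad_alpha_and_empty_samples():
    b = _mini_bundle(np.ones((2, 2)))
    with pytest.raises(InputError):
        filter_probes(b, 1.5)


# -------------------------------------------------------------- vst

@given(arrays(np.float64, (6, 3), elements=st.floats(0, 1e5, allow_nan=False)))
def test_vst_is_monotone_within_sample(x):
    b = _mini_bundle(x)
    out = vst(b).intensities.to_numpy()
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="stable")
        assert np.all(np.diff(out[order, j]) >= -1e-12)


def test_vst_preserves_constant_columns_and_rejects_negatives():
    b = _mini_bundle(np.full((4, 2), 7.0))
    out = vst(b).intensities.to_numpy()
    assert np.allclose(out, out[0, 0])
    with pytest.raises(InputError):
        vst(_mini_bundle(np.array([[-1.0, 2.0], [1.0, 2.0]])))


def test_vst_stabilizes_multiplicative_noise():
    """Two expressed blocks with the same multiplicative noise but 8-fold
    different intensity end up with variances within 20% of each other after
    the transform (a dim background block anchors the arsinh scale, as in the
    simulated bundles)."""
    rng = np.random.default_rng(0)
    background = 2.0 ** (6 + rng.normal(0, 0.3, (200, 4)))
    lo = 2.0 ** (9 + rng.normal(0, 0.3, (400, 4)))
    hi = 2.0 ** (12 + rng.normal(0, 0.3, (400, 4)))
    b = _mini_bundle(np.vstack([background, lo, hi]))
    out = vst(b).intensities.to_numpy()
    var_lo = out[200:600].var()
    var_hi = out[600:].var()
    assert abs(var_lo - var_hi) / var_hi < 0.2


# -------------------------------------------------------------- quantile

def test_quantile_normalization_forced_example():
    b = _mini_bundle(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
    out = quantile_normalize(b).intensities.to_numpy()
    expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
    assert np.allclose(out, expected)


def test_quantile_normalization_ties_get_mean_of_tied_ranks():
    b = _mini_bundle(np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]]))
    out = quantile_normalize(b).intensities.to_numpy()
    ref = np.sort(np.array([[1, 1, 5], [10, 20, 30]]).T, axis=0).mean(axis=1)
    assert np.allclose(out[:, 0], [(ref[0] + ref[1]) / 2, (ref[0] + ref[1]) / 2, ref[2]])
    assert np.allclose(np.sort(out[:, 1]), ref)


@given(arrays(np.float64, (20, 4), elements=st.floats(0, 100, allow_nan=False),
              unique=True))
def test_quantile_normalization_equalizes_sorted_columns_and_is_idempotent(x):
    """On tie-free data every normalized column shares the reference
    distribution exactly (ties instead receive tied-rank means, checked
    separately)."""
    b = _mini_bundle(x)
    out1 = quantile_normalize(b)
    y = out1.intensities.to_numpy()
    sorted_cols = np.sort(y, axis=0)
    assert np.allclose(sorted_cols, sorted_cols[:, [0]])
    y2 = quantile_normalize(out1).intensities.to_numpy()
    assert np.allclose(y, y2)


def test_quantile_normalization_single_sample_warns_and_noops():
    b = _mini_bundle(np.array([[1.0], [2.0]]))
    with pytest.warns(UserWarning):
        out = quantile_normalize(b)
    assert np.allclose(out.intensities, b.intensities)


# -------------------------------------------------------------- BH

def test_bh_matches_hand_stepup_example():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert np.allclose(bh_adjust([0.5]), [0.5])
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])


def test_bh_propagates_nan_with_warning():
    with pytest.warns(UserWarning):
        q = bh_adjust([0.01, np.nan, 0.04])
    assert np.isnan(q[1])
    # effective n excludes the NaN
    assert np.allclose(q[[0, 2]], multipletests([0.01, 0.04], method="fdr_bh")[1])


@given(arrays(np.float64, 12, elements=st.floats(0, 1, allow_nan=False)))
def test_bh_agrees_with_statsmodels(p):
    assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])


# -------------------------------------------------------------- moderated t

def test_zero_difference_gene_has_zero_t_and_unit_p():
    x = np.array([[5.0, 6.0, 7.0, 5.0, 6.0, 7.0],
                  [1.0, 2.0, 3.0, 3.0, 2.0, 1.0]])
    b = _mini_bundle(x)
    de = moderated_de(b, "L", collapse=False)
    assert de["log2fc"].iloc[0] == pytest.approx(0.0)
    assert de["t_mod"].iloc[0] == pytest.approx(0.0)
    assert de["p"].iloc[0] == pytest.approx(1.0)


def test_equal_variances_make_shrinkage_identity():
    rng = np.random.default_rng(3)
    base = rng.normal(0, 1, 6)
    x = np.stack([base + i for i in range(20)])  # every gene same sample variance
    b = _mini_bundle(x)
    de = moderated_de(b, "L", collapse=False)
    t_ref = stats.ttest_ind(x[:, 3:], x[:, :3], axis=1, equal_var=True).statistic
    assert np.allclose(de["t_mod"], t_ref)


def test_zero_prior_reduces_to_ordinary_two_sample_t():
    rng = np.random.default_rng(5)
    x = rng.normal(8, 1, (50, 6))
    b = _mini_bundle(x)
    de = moderated_de(b, "L", prior_df=0, collapse=False)
    ref = stats.ttest_ind(x[:, 3:], x[:, :3], axis=1, equal_var=True)
    assert np.allclose(de["t_mod"], ref.statistic)
    assert np.allclose(de["p"], ref.pvalue)


def test_moderated_de_requires_two_replicates_per_arm():
    x = np.ones((3, 3))
    values = pd.DataFrame(x, index=list("abc"), columns=["s0", "s1", "s2"])
    det = pd.DataFrame(0.001, index=values.index, columns=values.columns)
    samples = pd.DataFrame({"cell_line": ["L"] * 3,
                            "treatment": ["vehicle", "vehicle", "treated"],
                            "replicate": [1, 2, 1]}, index=values.columns)
    b = ExpressionBundle(values, det, samples,
                         pd.Series(list("abc"), index=values.index))
    with pytest.raises(InputError):
        moderated_de(b, "L")


def test_moderated_t_power_on_strong_planted_effects():
    """n=3 vs 3, planted log2fc = -2, sd = 0.1: detection power at q < 0.05
    must exceed 0.99 (Monte-Carlo over 100 planted genes x 20 repeats)."""
    rng = np.random.default_rng(7)
    hits = total = 0
    for _ in range(20):
        x = rng.normal(8.0, 0.1, (200, 6))
        x[:10, 3:] -= 2.0
        b = _mini_bundle(x)
        de = moderated_de(b, "L", collapse=False)
        hits += (de["q"].iloc[:10] < 0.05).sum()
        total += 10
    assert hits / total > 0.99


def test_moderated_t_matches_limma(tmp_path):
    """Independent oracle: limma's lmFit + eBayes on the same matrix must
    reproduce the prior df, prior variance, t and p to high precision."""
    cfg = ExperimentConfig(n_genes=300, private_de_per_line=20, seed=7)
    bundle, _ = generate_expression_bundle(cfg)
    prepped = quantile_normalize(vst(filter_probes(bundle)))
    line = prepped.cell_lines[0]
    ours = moderated_de(prepped, line)
    cols = prepped.samples.index[prepped.samples["cell_line"] == line]
    mat = collapse_probes(prepped)[cols]
    mat.to_csv(tmp_path / "mat.tsv", sep="\t")
    (prepped.samples.loc[cols, "treatment"] == "treated").astype(int).to_csv(
        tmp_path / "design.tsv", sep="\t")
    script = f"""
    suppressMessages(library(limma))
    x <- as.matrix(read.delim("{tmp_path}/mat.tsv", row.names=1, check.names=FALSE))
    des <- read.delim("{tmp_path}/design.tsv", row.names=1)
    design <- cbind(Intercept=1, treated=des[colnames(x), 1])
    fit <- eBayes(lmFit(x, design))
    out <- data.frame(gene=rownames(x), logFC=fit$coefficients[,2], t=fit$t[,2],
                      p=fit$p.value[,2], d0=fit$df.prior, s02=fit$s2.prior)
    write.table(out, "{tmp_path}/limma.tsv", sep="\\t", quote=FALSE, row.names=FALSE)
    """
    subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t", index_col=0).loc[ours.index]
    assert ours.attrs["prior_df"] == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
    assert ours.attrs["prior_var"] == pytest.approx(ref["s02"].iloc[0], rel=1e-6)
    assert np.allclose(ours["t_mod"], ref["t"], atol=1e-8)
    assert np.allclose(ours["p"], ref["p"], atol=1e-8)


def test_null_pipeline_calls_at_most_nominal_fdr():
    """No planted effects anywhere: the full pipeline's q<0.05 call rate stays
    at or below the nominal FDR (Monte-Carlo over 20 seeds)."""
    fractions = []
    for seed in range(20):
        cfg = ExperimentConfig(n_genes=600, core_log2fc=0.0, private_de_per_line=0,
                               n_cell_lines=1, seed=seed)
        bundle, _ = generate_expression_bundle(cfg)
        (result,) = de_per_line(bundle).values()
        fractions.append((result["q"] < 0.05).mean())
    assert np.mean(fractions) <= 0.05


# -------------------------------------------------------------- gates

@pytest.mark.parametrize("q,log2fc,expect_down", [
    (0.04, -1.1, True),    # fold 2.14 > 2
    (0.04, -0.9, False),   # fold 1.87
    (0.06, -3.0, False),   # not significant
])
def test_call_significant_applies_both_gates(q, log2fc, expect_down):
    de = pd.DataFrame({"log2fc": [log2fc], "t_mod": [0.0], "p": [q], "q": [q],
                       "mean_expr": [8.0]}, index=["g"])
    up, down = call_significant(de, 0.05, 2.0)
    assert (("g" in down) == expect_down) and not up


def test_collapse_keeps_highest_mean_probe():
    values = pd.DataFrame([[1.0, 1.0], [5.0, 5.0], [2.0, 2.0]],
                          index=["pA1", "pA2", "pB"], columns=["s0", "s1"])
    det = pd.DataFrame(0.001, index=values.index, columns=values.columns)
    samples = pd.DataFrame({"cell_line": ["L", "L"],
                            "treatment": ["vehicle", "treated"],
                            "replicate": [1, 1]}, index=values.columns)
    pg = pd.Series(["A", "A", "B"], index=values.index)
    collapsed = collapse_probes(ExpressionBundle(values, det, samples, pg))
    assert collapsed.loc["A", "s0"] == 5.0
    assert collapsed.shape == (2, 2)
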