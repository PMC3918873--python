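"""Read filtering, extension, coverage (vs per-base brute force), TSS
metaprofiles and the Poisson peak caller."""

import numpy as np
import pandas as pd
import pytest

from betcore import InputError, call_peaks, coverage, extend_reads, filter_reads, tss_matrix
from betcore.chipseq import CoverageTrack

GENOME = {"chr1": 10_000, "chr2": 5_000}


def reads_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mapq", "strand"])


def test_mapq_filter_is_strict_and_dedup_is_strand_aware():
    rd = reads_df([
        ("chr1", 100, 136, 5, "+"),
        ("chr1", 100, 136, 11, "+"),   # kept
        ("chr1", 100, 136, 30, "+"),   # duplicate 5' of previous -> dropped
        ("chr1", 100, 136, 30, "-"),   # same start, other strand: 5' differs
        ("chr1", 500, 536, 60, "-"),
    ])
    kept = filter_reads(rd, mapq_min=10, dedup=True)
    assert len(kept) == 3
    assert (kept["mapq"] > 10).all()
    # mapq == threshold removed
    assert len(filter_reads(reads_df([("chr1", 0, 36, 10, "+")]), 10)) == 0


def test_dedup_keys_on_five_prime_not_interval():
    # minus-strand reads with same end share a 5' position
    rd = reads_df([
        ("chr1", 100, 200, 60, "-"),
        ("chr1", 150, 200, 60, "-"),
        ("chr1", 150, 201, 60, "-"),
    ])
    assert len(filter_reads(rd, 10, dedup=True)) == 2


@pytest.mark.parametrize("start,end,strand,expected", [
    (1000, 1036, "+", (1000, 1300)),
    (1964, 2000, "-", (1700, 2000)),
    (64, 100, "-", (0, 100)),           # clipped at chromosome start
    (9900, 9936, "+", (9900, 10_000)),  # clipped at chromosome end
])
def test_extend_reads_strand_aware_with_clipping(start, end, strand, expected):
    out = extend_reads(reads_df([("chr1", start, end, 60, strand)]), 300, GENOME)
    assert (out.loc[0, "start"], out.loc[0, "end"]) == expected


def test_extend_rejects_fragment_shorter_than_read():
    with pytest.raises(InputError):
        extend_reads(reads_df([("chr1", 0, 500, 60, "+")]), 300, GENOME)


def test_coverage_single_fragment_and_empty():
    frags = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [300]})
    track = coverage(frags, 100, GENOME)
    assert track.bins["chr1"][:4].tolist() == [1, 1, 1, 0]
    empty = coverage(frags.iloc[:0], 100, GENOME)
    assert all((v == 0).all() for v in empty.bins.values())


def test_coverage_conservation_in_base_mode():
    rng = np.random.default_rng(0)
    starts = rng.integers(0, 9_000, 300)
    frags = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 300})
    track = coverage(frags, 128, GENOME, mode="base")
    assert track.bins["chr1"].sum() == (frags["end"] - frags["start"]).sum()


def test_coverage_matches_per_base_brute_force():
    rng = np.random.default_rng(1)
    starts = rng.integers(0, 4_500, 200)
    lengths = rng.integers(50, 400, 200)
    frags = pd.DataFrame({"chrom": "chr2", "start": starts,
                          "end": np.minimum(starts + lengths, GENOME["chr2"])})
    binsize = 97
    track = coverage(frags, binsize, GENOME, mode="base")
    per_base = np.zeros(GENOME["chr2"], dtype=int)
    for s, e in zip(frags["start"], frags["end"]):
        per_base[s:e] += 1
    n_bins = -(-GENOME["chr2"] // binsize)
    padded = np.zeros(n_bins * binsize, dtype=int)
    padded[:GENOME["chr2"]] = per_base
    assert np.array_equal(track.bins["chr2"], padded.reshape(n_bins, binsize).sum(axis=1))
    # fragment mode equals brute-force bin overlap counting
    track_f = coverage(frags, binsize, GENOME, mode="fragment")
    brute = np.zeros(n_bins, dtype=int)
    for s, e in zip(frags["start"], frags["end"]):
        brute[s // binsize: (e - 1) // binsize + 1] += 1
    assert np.array_equal(track_f.bins["chr2"], brute)


def test_filter_extend_coverage_invariant_to_read_order():
    rng = np.random.default_rng(2)
    starts = rng.integers(0, 9_000, 500)
    rd = reads_df([("chr1", int(s), int(s) + 36, int(m), st)
                   for s, m, st in zip(starts, rng.choice([0, 30, 60], 500),
                                       rng.choice(["+", "-"], 500))])
    shuffled = rd.sample(frac=1, random_state=0).reset_index(drop=True)
    def pipe(r):
        t = coverage(extend_reads(filter_reads(r, 10), 300, GENOME), 100, GENOME)
        return t.bins["chr1"]
    assert np.array_equal(pipe(rd), pipe(shuffled))


def test_coverage_rejects_out_of_bounds_intervals():
    frags = pd.DataFrame({"chrom": ["chr2"], "start": [4_900], "end": [5_200]})
    with pytest.raises(InputError):
        coverage(frags, 100, GENOME)


# -------------------------------------------------------------- tss_matrix

def _track_from_array(arr, binsize=100, chrom="chr1"):
    return CoverageTrack(bins={chrom: np.asarray(arr)}, binsize=binsize, library_size=1)


def test_tss_profile_peaks_at_center_for_symmetric_signal():
    vec = np.zeros(100)
    vec[48:53] = [1, 3, 9, 3, 1]  # symmetric around bin 50
    track = _track_from_array(vec)
    genes = pd.DataFrame({"chrom": ["chr1"], "start": [5_000], "end": [6_000],
                          "name": ["g"], "score": [0], "strand": ["+"]})
    heatmap, profile, flags = tss_matrix(track, genes, flank=2_000)
    assert profile.argmax() == len(profile) // 2
    assert not flags.any()
    left, right = profile[:len(profile) // 2], profile[len(profile) // 2 + 1:][::-1]
    assert np.allclose(left[-5:], right[-5:])


def test_tss_matrix_zero_when_no_reads():
    track = _track_from_array(np.zeros(100))
    genes = pd.DataFrame({"chrom": ["chr1"], "start": [5_000], "end": [6_000],
                          "name": ["g"], "score": [0], "strand": ["+"]})
    heatmap, profile, _ = tss_matrix(track, genes, flank=1_000)
    assert (heatmap.to_numpy() == 0).all() and (profile == 0).all()


def test_minus_strand_orientation_puts_5prime_signal_upstream():
    """Signal 1 kb 5' of a minus-strand TSS (i.e. at higher genome coordinate)
    must appear left of center after orientation."""
    vec = np.zeros(100)
    tss_bin = 50
    vec[tss_bin + 10] = 7.0   # 1 kb toward higher coordinates
    track = _track_from_array(vec)
    genes = pd.DataFrame({"chrom": ["chr1"], "start": [3_000], "end": [5_001],
                          "name": ["g"], "score": [0], "strand": ["-"]})
    heatmap, _, _ = tss_matrix(track, genes, flank=2_000)
    row = heatmap.iloc[0].to_numpy()
    hot = row.nonzero()[0]
    assert len(hot) == 1 and hot[0] < len(row) // 2


def test_mirrored_plus_minus_genes_have_equal_row_sums():
    rng = np.random.default_rng(3)
    vec = rng.poisson(2.0, 100).astype(float)
    track = _track_from_array(vec)
    genes = pd.DataFrame({
        "chrom": ["chr1", "chr1"], "start": [4_000, 3_000], "end": [5_000, 4_001],
        "name": ["plus", "minus"], "score": [0, 0], "strand": ["+", "-"],
    })
    heatmap, _, _ = tss_matrix(track, genes, flank=1_000, order_by_signal=False)
    # same TSS bin (4000 // 100 = 40): total captured signal identical
    assert heatmap.loc["plus"].sum() == heatmap.loc["minus"].sum()


def test_tss_window_off_chromosome_is_clipped_and_flagged():
    track = _track_from_array(np.ones(100))
    genes = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [500],
                          "name": ["edge"], "score": [0], "strand": ["+"]})
    heatmap, _, flags = tss_matrix(track, genes, flank=2_000)
    assert flags["edge"]
    assert heatmap.loc["edge"].sum() == 21  # 20 in-bounds bins of value 1 + tss bin


def test_tss_matrix_requires_flank_multiple_of_binsize():
    with pytest.raises(InputError):
        tss_matrix(_track_from_array(np.ones(10)), pd.DataFrame({
            "chrom": ["chr1"], "start": [0], "end": [10], "name": ["g"],
            "score": [0], "strand": ["+"]}), flank=150)


# -------------------------------------------------------------- peaks

def test_single_hot_bin_is_called_as_one_peak():
    vec = np.ones(500)
    vec[200] = 100
    peaks = call_peaks(_track_from_array(vec), lambda_bg=1.0)
    assert len(peaks) == 1
    assert peaks.loc[0, "start"] <= 20_000 < peaks.loc[0, "end"]


def test_nearby_significant_bins_merge_across_one_gap_bin():
    vec = np.ones(500)
    vec[[200, 202]] = 100  # one sub-threshold bin between them
    peaks = call_peaks(_track_from_array(vec), lambda_bg=1.0, merge_gap_bins=1)
    assert len(peaks) == 1
    assert peaks.loc[0, "n_bins"] == 3


def test_all_zero_track_yields_no_peaks():
    assert call_peaks(_track_from_array(np.zeros(100))).empty


def test_uniform_background_false_positive_rate_within_nominal():
    """Pure Poisson background: over 20 seeds the fraction of simulations
    producing any peak stays within the nominal BH level (plus MC slack)."""
    any_peak = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        vec = rng.poisson(5.0, 2_000).astype(float)
        peaks = call_peaks(_track_from_array(vec), alpha=0.05)
        any_peak += int(len(peaks) > 0)
    assert any_peak / 20 <= 0.05 + 0.10
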