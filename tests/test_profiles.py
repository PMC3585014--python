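"""Coverage and log-ratio tracks, anchor-centered summaries, NDR
regression."""

import math

import numpy as np
import pandas as pd
import pytest

from mnasefrag import profiles as prof
from mnasefrag.io import AnchorSite, IntervalFeature

from conftest import make_fragments


def test_single_fragment_coverage():
    fs = make_fragments([("chr1", 100, 200)], {"chr1": 300})
    t = prof.coverage_track(fs)
    assert np.all(t["chr1"][100:200] == 1)
    assert np.all(t["chr1"][:100] == 0) and np.all(t["chr1"][200:] == 0)


def test_overlapping_fragments_stack():
    fs = make_fragments([("chr1", 100, 160), ("chr1", 150, 200)], {"chr1": 300})
    t = prof.coverage_track(fs)
    assert np.all(t["chr1"][150:160] == 2)


def test_coverage_matches_membership_loop_and_conserves_length(rng):
    triples = []
    for _ in range(500):
        s = int(rng.integers(0, 1900))
        triples.append(("chr1", s, s + int(rng.integers(1, 100))))
    fs = make_fragments(triples, {"chr1": 2000})
    t = prof.coverage_track(fs)
    ref = np.zeros(2000)
    for _, s, e in triples:
        for b in range(s, e):
            ref[b] += 1
    np.testing.assert_array_equal(t["chr1"], ref)
    assert t.total() == sum(e - s for _, s, e in triples)


def test_fragment_past_chromosome_end_rejected():
    with pytest.raises(ValueError, match="exceeds chromosome length"):
        prof.coverage_track(make_fragments([("chr1", 90, 150)], {"chr1": 100}))


def track(values, semantics="counts/bp"):
    return prof.GenomicTrack({"chr1": np.asarray(values, float)}, semantics)


def test_log_ratio_identical_tracks_is_zero():
    t = track([0, 1, 2, 3, 0])
    r = prof.log_ratio_track(t, t)
    assert np.all(r["chr1"][1:4] == 0)
    assert np.isnan(r["chr1"][0]) and np.isnan(r["chr1"][4])  # both raw zero


def test_log_ratio_depth_scaling_cancels_global_factor():
    a = track([2, 4, 6, 8])
    b = track([1, 2, 3, 4])
    r = prof.log_ratio_track(a, b)
    np.testing.assert_allclose(r["chr1"], 0.0, atol=1e-12)


def test_log_ratio_hand_value():
    a = track([3, 1])
    b = track([1, 3])  # equal depths already
    r = prof.log_ratio_track(a, b, pseudocount=0.5)
    assert math.isclose(r["chr1"][0], math.log2(3.5 / 1.5), rel_tol=1e-12)


def test_log_ratio_mismatched_chromosomes_rejected():
    a = prof.GenomicTrack({"chr1": np.ones(5)})
    b = prof.GenomicTrack({"chr2": np.ones(5)})
    with pytest.raises(ValueError, match="different chromosomes"):
        prof.log_ratio_track(a, b)


def test_single_anchor_profile_equals_track_slice():
    t = track(np.arange(100.0))
    res = prof.aggregate_profile(t, [AnchorSite("chr1", 50, "+")], flank=10)
    np.testing.assert_array_equal(res.mean, np.arange(40.0, 61.0))


def test_constant_track_profile_is_constant():
    t = track(np.full(200, 3.5))
    anchors = [AnchorSite("chr1", p, "+") for p in (50, 100, 150)]
    res = prof.aggregate_profile(t, anchors, flank=20)
    np.testing.assert_array_equal(res.mean, 3.5)


def test_aggregate_profile_matches_brute_force(rng):
    values = rng.normal(size=500)
    values[rng.integers(0, 500, size=40)] = np.nan
    t = track(values)
    anchors = [
        AnchorSite("chr1", int(rng.integers(0, 500)), rng.choice(["+", "-"]))
        for _ in range(10)
    ]
    flank = 30
    res = prof.aggregate_profile(t, anchors, flank)
    for k, off in enumerate(range(-flank, flank + 1)):
        acc = []
        for a in anchors:
            pos = a.position + (-off if a.strand == "-" else off)
            if 0 <= pos < 500 and not np.isnan(values[pos]):
                acc.append(values[pos])
        if acc:
            assert math.isclose(res.mean[k], float(np.mean(acc)), rel_tol=1e-12)
            assert res.n_contributing[k] == len(acc)
        else:
            assert np.isnan(res.mean[k])


def anchors_at(positions):
    return [AnchorSite("chr1", p, "+", name=f"a{i}") for i, p in enumerate(positions)]


def test_quintile_group_sizes_and_remainder_rule():
    t = track(np.arange(4000.0))
    groups = prof.quintile_profiles(t, anchors_at(range(100, 1100, 100)), flank=10)
    assert len(groups) == 5
    # 12 anchors -> 3,3,2,2,2
    t2 = track(np.arange(4000.0))
    anchors = anchors_at(range(100, 1300, 100))
    scores = [a.position for a in anchors]
    groups = prof.quintile_profiles(t2, anchors, flank=10)
    # group means decrease; top group holds the 3 highest-signal anchors
    tops = sorted(scores, reverse=True)[:3]
    assert math.isclose(groups[0].mean[10], float(np.mean(tops)), rel_tol=1e-12)


def test_quintile_tie_break_is_input_order():
    t = track(np.full(2000, 1.0))
    anchors = anchors_at(range(100, 1100, 100))
    groups = prof.quintile_profiles(t, anchors, flank=5)
    # all-equal signal: grouping must follow the given anchor order,
    # verified via the heatmap ranked by per-anchor signal ("self")
    hm = prof.heatmap_matrix(t, anchors, 5, pd.DataFrame(), "self")
    assert hm.row_ids == [a.name for a in anchors]
    assert len(groups) == 5


def test_too_few_anchors_for_quintiles():
    with pytest.raises(ValueError, match="at least 5"):
        prof.quintile_profiles(track(np.ones(100)), anchors_at([10, 20]), flank=2)


def test_heatmap_rows_ranked_descending_by_metric():
    t = track(np.arange(300.0))
    anchors = anchors_at([50, 100, 150])
    metrics = pd.DataFrame({"expression": [5.0, 1.0, 9.0]}, index=["a0", "a1", "a2"])
    hm = prof.heatmap_matrix(t, anchors, 10, metrics, "expression")
    assert hm.row_ids == ["a2", "a0", "a1"]
    assert list(hm.metric_values) == [9.0, 5.0, 1.0]


def test_heatmap_minus_strand_row_is_reversed_slice():
    values = np.arange(300.0)
    t = track(values)
    plus = [AnchorSite("chr1", 150, "+", "g")]
    minus = [AnchorSite("chr1", 150, "-", "g")]
    metrics = pd.DataFrame({"m": [1.0]}, index=["g"])
    row_p = prof.heatmap_matrix(t, plus, 10, metrics, "m").matrix[0]
    row_m = prof.heatmap_matrix(t, minus, 10, metrics, "m").matrix[0]
    np.testing.assert_array_equal(row_m, row_p[::-1])


def test_heatmap_missing_metric_lists_ids():
    t = track(np.ones(100))
    metrics = pd.DataFrame({"m": [1.0]}, index=["a0"])
    with pytest.raises(KeyError, match="a1"):
        prof.heatmap_matrix(t, anchors_at([10, 20]), 5, metrics, "m")


def test_heatmap_column_mean_equals_aggregate_profile(rng):
    values = rng.normal(size=400)
    t = track(values)
    anchors = anchors_at([50, 120, 200, 350])
    metrics = pd.DataFrame({"m": rng.normal(size=4)}, index=[a.name for a in anchors])
    hm = prof.heatmap_matrix(t, anchors, 60, metrics, "m")
    res = prof.aggregate_profile(t, anchors, 60)
    np.testing.assert_allclose(np.nanmean(hm.matrix, axis=0), res.mean, rtol=1e-12)


def test_windowed_track_constant_and_identity():
    t = track(np.full(100, 2.0))
    np.testing.assert_array_equal(prof.windowed_track(t, 40)["chr1"], 2.0)
    t2 = track(np.arange(50.0))
    np.testing.assert_array_equal(prof.windowed_track(t2, 1)["chr1"], t2["chr1"])


def test_windowed_track_matches_block_means(rng):
    values = rng.normal(size=130)
    values[rng.integers(0, 130, size=15)] = np.nan
    t = track(values)
    out = prof.windowed_track(t, 40)["chr1"]
    for start in range(0, 130, 40):
        block = values[start : start + 40]
        if np.all(np.isnan(block)):
            assert np.all(np.isnan(out[start : start + 40]))
        else:
            np.testing.assert_allclose(
                out[start : start + block.size], np.nanmean(block), rtol=1e-12
            )


def ndrs_at(spans):
    return [
        IntervalFeature("chr1", s, e, name=f"ndr{i}", feature_class="NDR")
        for i, (s, e) in enumerate(spans)
    ]


def test_ndr_signal_proportional_to_width_gives_r2_one():
    values = np.zeros(2000)
    spans = [(100, 150), (300, 400), (600, 800), (1000, 1300)]
    for s, e in spans:
        values[s] = (e - s) * 0.01  # max signal proportional to width
    r2, _ = prof.ndr_correlation(track(values), ndrs_at(spans))
    assert math.isclose(r2, 1.0, abs_tol=1e-12)


def test_ndr_three_point_r2_matches_closed_form():
    values = np.zeros(1000)
    spans = [(100, 150), (300, 380), (600, 720)]
    maxima = [1.0, 3.0, 2.0]
    for (s, e), m in zip(spans, maxima):
        values[s] = m
    r2, table = prof.ndr_correlation(track(values), ndrs_at(spans))
    x = np.array([e - s for s, e in spans], float)
    y = np.array(maxima)
    # independent hand computation of Pearson r squared
    r = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    assert math.isclose(r2, r**2, rel_tol=1e-12)
    assert list(table["width"]) == [50, 80, 120]


def test_ndr_signal_independent_of_width(rng):
    """Designed independence: 500 NDRs of random width, each carrying one
    signal spike whose amplitude is drawn independently of the width; the
    regression should explain almost nothing."""
    n = 500
    length = 200_000
    values = np.zeros(length)
    starts = np.arange(n) * (length // n)
    widths = rng.integers(50, 250, size=n)
    values[starts] = np.abs(rng.normal(1.0, 0.3, size=n))
    spans = [(int(s), int(s + w)) for s, w in zip(starts, widths)]
    r2, _ = prof.ndr_correlation(track(values), ndrs_at(spans))
    assert r2 < 0.05


def test_all_masked_ndrs_rejected():
    values = np.full(100, np.nan)
    with pytest.raises(ValueError, match="at least 3"):
        prof.ndr_correlation(track(values), ndrs_at([(10, 20), (30, 40), (50, 60)]))
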