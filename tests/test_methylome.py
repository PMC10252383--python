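import math
from math import comb, factorial

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnaheterosis import methylome as me
from srnaheterosis.io_formats import GenomicInterval, cytosine_table, CytosineCall


def _calls(rows, sample="s"):
    """rows: (pos0, context, meth, total) on chr1, '+'."""
    return cytosine_table([CytosineCall(sample, "chr1", p, "+", ctx, m, t)
                           for p, ctx, m, t in rows])


REGION = GenomicInterval("chr1", 0, 1000, ".", "sirna_cluster", "r1")


# ---------------------------------------------------------------------------
# WML
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("rows,expected,ncyt", [
    ([(10, "CG", 3, 10), (20, "CG", 7, 10)], 0.5, 2),
    ([(10, "CG", 0, 8), (20, "CG", 0, 12)], 0.0, 2),
    # min_coverage 5 drops the 2/4 cytosine: 5/10
    ([(10, "CG", 2, 4), (20, "CG", 5, 10)], 0.5, 1),
])
def test_wml_arithmetic(rows, expected, ncyt):
    wml, n = me.compute_wml(_calls(rows), REGION, "CG")
    assert wml == pytest.approx(expected)
    assert n == ncyt


def test_wml_undefined_when_no_passing_cytosine():
    wml, n = me.compute_wml(_calls([(10, "CG", 1, 2)]), REGION, "CG")
    assert math.isnan(wml) and n == 0
    # a different context does not leak in
    wml2, _ = me.compute_wml(_calls([(10, "CHH", 5, 10)]), REGION, "CG")
    assert math.isnan(wml2)


@given(st.integers(1, 20))
@settings(max_examples=30)
def test_wml_scale_invariance(k):
    rows = [(10, "CG", 3, 10), (20, "CG", 7, 9)]
    scaled = [(p, c, m * k, t * k) for p, c, m, t in rows]
    a, _ = me.compute_wml(_calls(rows), REGION, "CG")
    b, _ = me.compute_wml(_calls(scaled), REGION, "CG")
    assert b == pytest.approx(a)


def test_make_bins_tiling():
    bins = me.make_bins({"c": 250}, width=100)
    assert [(b.start, b.end) for b in bins] == [(0, 100), (100, 200), (200, 250)]
    sizes = {"a": 1000, "b": 77}
    bins = me.make_bins(sizes, 100)
    assert sum(len(b) for b in bins) == sum(sizes.values())
    for chrom, size in sizes.items():
        assert sum(1 for b in bins if b.chrom == chrom) == math.ceil(size / 100)


# ---------------------------------------------------------------------------
# Met_d/a
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("f,m,h,met_da,pattern", [
    (0.8, 0.2, 0.9, (0.9 - 0.5) / 0.3, "TCM"),
    (0.8, 0.2, 0.5, 0.0, "NIM"),
    (0.2, 0.8, 0.05, -1.5, "TCdM"),
])
def test_met_da_formula(f, m, h, met_da, pattern):
    call = me.classify_met_da(f, m, h)
    assert call.met_da == pytest.approx(met_da)
    assert call.pattern == pattern


@pytest.mark.parametrize("value,expected", [
    (0.55, "TCM"), (-0.9, "TCdM"), (0.5, "NIM"), (-0.5, "NIM"), (0.0, "NIM"),
    (math.inf, "TCM"), (-math.inf, "TCdM"),
])
def test_met_da_value_intervals(value, expected):
    assert me.classify_met_da_value(value) == expected


def test_met_da_equal_parents_degenerate():
    assert me.classify_met_da(0.4, 0.4, 0.4).pattern == "NIM"
    up = me.classify_met_da(0.4, 0.4, 0.6)
    assert up.pattern == "TCM" and up.met_da == math.inf
    down = me.classify_met_da(0.4, 0.4, 0.1)
    assert down.pattern == "TCdM" and down.met_da == -math.inf
    with pytest.raises(ValueError):
        me.classify_met_da(0.4, math.nan, 0.5)


@given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
@settings(max_examples=300)
def test_met_da_closed_form_and_parent_swap(f, m, h):
    """max-based denominator equals 2(H-MPV)/|F-M|, and parent order is
    irrelevant."""
    call = me.classify_met_da(f, m, h)
    swapped = me.classify_met_da(m, f, h)
    assert call.pattern == swapped.pattern
    assert call.met_da == swapped.met_da or (math.isinf(call.met_da)
                                             and call.met_da == swapped.met_da)
    if f != m:
        closed = 2 * (h - (f + m) / 2) / abs(f - m)
        assert call.met_da == pytest.approx(closed, abs=1e-12)


# ---------------------------------------------------------------------------
# differential methylation
# ---------------------------------------------------------------------------

def _dm_samples(levels1, levels2, coverage=10):
    """Two groups x two replicates; per-cytosine levels as fractions."""
    calls = {}
    for gi, levels in ((1, levels1), (2, levels2)):
        for rep in (1, 2):
            rows = [(10 * (i + 1), "CG", int(round(lv * coverage)), coverage)
                    for i, lv in enumerate(levels)]
            calls[f"g{gi}r{rep}"] = _calls(rows, f"g{gi}r{rep}")
    return calls


def test_dm_identical_groups_not_significant():
    lv = [0.1, 0.5, 0.9, 0.4, 0.2]
    calls = _dm_samples(lv, lv)
    res = me.region_dm_test(calls, [REGION], "CG", ["g1r1", "g1r2"],
                            ["g2r1", "g2r2"], 0.1)
    assert res.loc["r1", "p"] == 1.0
    assert not res.loc["r1", "significant"]


def test_dm_extreme_separation_matches_exact_enumeration():
    """6 cytosines fully methylated vs fully unmethylated: the exact
    two-sided Mann-Whitney p is 2 * 6!6!/12! = 2/C(12,6)."""
    calls = _dm_samples([1.0] * 6, [0.0] * 6)
    res = me.region_dm_test(calls, [REGION], "CG", ["g1r1", "g1r2"],
                            ["g2r1", "g2r2"], 0.1)
    expected = 2 * factorial(6) * factorial(6) / factorial(12)
    assert res.loc["r1", "p"] == pytest.approx(expected, rel=1e-9)
    assert res.loc["r1", "meth_diff"] == pytest.approx(1.0)
    assert res.loc["r1", "significant"]


def test_dm_min_cytosine_rule():
    calls = _dm_samples([1.0] * 3, [0.0] * 3)
    res = me.region_dm_test(calls, [REGION], "CG", ["g1r1", "g1r2"],
                            ["g2r1", "g2r2"], 0.1)
    assert res.loc["r1", "n_cytosines"] == 3
    assert not res.loc["r1", "significant"]


def test_dm_region_without_cytosines_reported_untested():
    calls = _dm_samples([0.5] * 4, [0.5] * 4)
    empty = GenomicInterval("chr1", 5000, 6000, ".", "sirna_cluster", "r2")
    res = me.region_dm_test(calls, [REGION, empty], "CG", ["g1r1", "g1r2"],
                            ["g2r1", "g2r2"], 0.1)
    assert not res.loc["r2", "tested"]
    assert not res.loc["r2", "significant"]


def test_dm_coverage_filter_requires_both_groups():
    calls = _dm_samples([1.0] * 6, [0.0] * 6, coverage=2)
    # pooled coverage 4 < 5 in both groups -> no eligible cytosines
    res = me.region_dm_test(calls, [REGION], "CG", ["g1r1", "g1r2"],
                            ["g2r1", "g2r2"], 0.1)
    assert not res.loc["r1", "tested"]


def _dm_frame(ids, sig, diff):
    return pd.DataFrame({"n_cytosines": 5, "meth_diff": diff, "p": 0.5,
                         "tested": True, "context": "CG", "fdr": 0.5,
                         "significant": sig},
                        index=pd.Index(ids, name="region_id"))


def test_methylation_candidate_selection_mirrors_expression_rule():
    ids = ["a", "b", "c", "d"]
    dm_fm = _dm_frame(ids, [True, False, False, False], [0.2, 0, 0, 0])
    dm_hf = _dm_frame(ids, [False, True, True, True], [0, 0.2, 0.2, 0.2])
    dm_hm = _dm_frame(ids, [False, True, True, False], [0, 0.3, -0.2, 0])
    assert me.select_methylation_candidates(dm_fm, dm_hf, dm_hm) == {"a", "b"}


# ---------------------------------------------------------------------------
# genome-wide shift
# ---------------------------------------------------------------------------

def test_wml_shift_identical_vectors():
    v = np.linspace(0, 1, 50)
    direction, p = me.wml_shift_test(v, v)
    assert direction == 0 and p == 1.0


def test_wml_shift_detects_planted_offset():
    rng = np.random.default_rng(0)
    mpv = rng.uniform(0.1, 0.7, 100)
    direction, p = me.wml_shift_test(mpv + 0.2, mpv)
    assert direction == 1 and p < 1e-10
    direction, p = me.wml_shift_test(mpv - 0.2, mpv)
    assert direction == -1 and p < 1e-10


def test_wml_shift_rejects_bad_input():
    with pytest.raises(ValueError):
        me.wml_shift_test([], [])
    with pytest.raises(ValueError):
        me.wml_shift_test([0.1, 0.2], [0.1])
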