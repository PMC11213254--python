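"""Unit and property tests for the window-based DMR caller."""

import numpy as np
import pandas as pd
import pytest

from huskmeth import dmr, io
from huskmeth.io import MethylomeSample

from .oracles import (
    call_pairwise_oracle,
    call_population_oracle,
    random_methylome,
    welch_oracle,
)


def make_sample(sites, sample_id="s", group="G"):
    df = pd.DataFrame(
        sites, columns=["chrom", "pos", "strand", "context", "n_meth", "n_total"]
    )
    return MethylomeSample(sample_id, group, df)


def sample_with_window_level(level, n_sites=3, cov=10, context="CHG",
                             chrom="c1", win=0, sample_id="s", group="G"):
    """One window holding n_sites sites whose weighted level is exact."""
    sites = [
        (chrom, win * 100 + 10 * (i + 1), "+", context, int(round(level * cov)), cov)
        for i in range(n_sites)
    ]
    return make_sample(sites, sample_id, group)


# ---------------------------------------------------------------------------
# tiling and window levels


@pytest.mark.parametrize(
    "size,expected",
    [
        (250, [(0, 100), (100, 200), (200, 250)]),
        (100, [(0, 100)]),
        (99, [(0, 99)]),
    ],
)
def test_tile_windows(size, expected):
    wins = dmr.tile_windows({"chr1": size})
    assert [(w.start, w.end) for w in wins] == expected


def test_tile_windows_zero_size():
    with pytest.raises(io.ValidationError):
        dmr.tile_windows({"chr1": 0})


def test_window_level_weighted_vs_mean_of_fractions():
    s = make_sample([("c1", 5, "+", "CHG", 1, 2), ("c1", 50, "+", "CHG", 0, 10)])
    w = dmr.Window("c1", 0, 100)
    n, cov, level = dmr.window_level(s, w, "CHG")
    assert n == 2
    assert level == pytest.approx(1 / 12)  # weighted, not (0.5 + 0)/2
    _, _, mof = dmr.window_level(s, w, "CHG", level_mode="mean_of_fractions")
    assert mof == pytest.approx(0.25)


def test_window_level_coverage_filter_gives_missing():
    s = make_sample([("c1", 5, "+", "CHG", 1, 1), ("c1", 50, "+", "CHG", 1, 1)])
    n, cov, level = dmr.window_level(s, dmr.Window("c1", 0, 100), "CHG", min_site_cov=2)
    assert n == 0 and np.isnan(level)


# ---------------------------------------------------------------------------
# t-test


def test_welch_example():
    t, df, p = dmr.welch_t_test([0.1, 0.2, 0.3], [0.7, 0.8, 0.9])
    assert t == pytest.approx(-7.348469, abs=1e-5)
    assert df == pytest.approx(4.0)
    assert p == pytest.approx(0.0018263, abs=1e-6)


def test_welch_degenerate_conventions():
    t, _, p = dmr.welch_t_test([0.2, 0.3, 0.4], [0.2, 0.3, 0.4])
    assert (t, p) == (pytest.approx(0.0), pytest.approx(1.0))
    # zero variance in both groups is a tie, not a NaN or an infinite t
    t, _, p = dmr.welch_t_test([0.5, 0.5], [0.7, 0.7])
    assert (t, p) == (0.0, 1.0)


def test_welch_too_few_values():
    with pytest.raises(io.ValidationError):
        dmr.welch_t_test([0.1], [0.2, 0.3])


def test_welch_matches_formula_oracle():
    rng = np.random.default_rng(1)
    for _ in range(50):
        x = rng.uniform(size=rng.integers(2, 9)).tolist()
        y = rng.uniform(size=rng.integers(2, 9)).tolist()
        t1, df1, p1 = dmr.welch_t_test(x, y)
        t2, df2, p2 = welch_oracle(x, y)
        assert t1 == pytest.approx(t2, abs=1e-10)
        assert df1 == pytest.approx(df2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-10)


# ---------------------------------------------------------------------------
# merging


def test_merge_adjacent_runs():
    wins = [dmr.Window("c1", 0, 100), dmr.Window("c1", 100, 200), dmr.Window("c1", 300, 400)]
    merged = dmr.merge_adjacent(wins)
    assert [(w.start, w.end, n) for w, n in merged] == [(0, 200, 2), (300, 400, 1)]


def test_merge_never_crosses_chromosomes():
    wins = [dmr.Window("c1", 100, 200), dmr.Window("c2", 200, 300)]
    merged = dmr.merge_adjacent(wins)
    assert len(merged) == 2


def test_merge_rejects_overlap():
    with pytest.raises(io.ValidationError):
        dmr.merge_adjacent([dmr.Window("c1", 0, 100), dmr.Window("c1", 50, 150)])


# ---------------------------------------------------------------------------
# population mode


def population_instance(levels_a, levels_b, n_sites=3, cov=10):
    ga = [sample_with_window_level(l, n_sites, cov, sample_id=f"a{i}", group="A")
          for i, l in enumerate(levels_a)]
    gb = [sample_with_window_level(l, n_sites, cov, sample_id=f"b{i}", group="B")
          for i, l in enumerate(levels_b)]
    return {"A": ga, "B": gb}


def test_population_single_region():
    samples = population_instance([0.8, 0.9, 0.9, 0.8], [0.2, 0.3, 0.1, 0.3])
    out = dmr.call_dmrs_population(samples, "CHG", reference="A")
    assert len(out) == 1
    d = out[0]
    assert d.direction == "hypo"
    assert d.difference == pytest.approx(-0.625, abs=1e-12)  # 0.850 - 0.225
    assert d.p_value < 0.05
    # matches the straight-line oracle exactly
    oracle = call_population_oracle(samples, "CHG", dmr.DmrParamsPopulation(), "A")
    assert len(oracle) == 1
    assert oracle[0]["difference"] == pytest.approx(d.difference)
    assert oracle[0]["p_value"] == pytest.approx(d.p_value, abs=1e-10)


def test_population_identical_groups_no_dmrs():
    samples = population_instance([0.8, 0.82, 0.78, 0.8], [0.8, 0.82, 0.78, 0.8])
    assert dmr.call_dmrs_population(samples, "CHG", reference="A") == []


def test_population_site_count_filter_dominates_effect():
    samples = population_instance([0.8, 0.9, 0.9, 0.8], [0.2, 0.3, 0.1, 0.3], n_sites=2)
    assert dmr.call_dmrs_population(samples, "CHG", reference="A") == []


def test_population_requires_two_groups():
    samples = population_instance([0.8, 0.9], [0.1, 0.2])
    samples["C"] = samples["A"]
    with pytest.raises(io.ValidationError):
        dmr.call_dmrs_population(samples, "CHG")


def test_direction_flip_on_group_swap():
    samples = population_instance([0.8, 0.9, 0.85, 0.8], [0.2, 0.3, 0.25, 0.2])
    fwd = dmr.call_dmrs_population(samples, "CHG", reference="A")
    rev = dmr.call_dmrs_population(samples, "CHG", reference="B")
    assert len(fwd) == len(rev) == 1
    assert fwd[0].direction == "hypo" and rev[0].direction == "hyper"
    assert fwd[0].difference == pytest.approx(-rev[0].difference)
    assert fwd[0].p_value == pytest.approx(rev[0].p_value)


# ---------------------------------------------------------------------------
# pairwise mode


def test_pairwise_chg_threshold():
    wt = sample_with_window_level(0.90, sample_id="wt", group="WT")
    mut = sample_with_window_level(0.20, sample_id="mut", group="mut")
    out = dmr.call_dmrs_pairwise(wt, mut, "CHG")
    assert len(out) == 1
    assert out[0].direction == "hypo"
    assert out[0].difference == pytest.approx(-0.7)

    mut2 = sample_with_window_level(0.50, sample_id="mut", group="mut")
    wt2 = sample_with_window_level(0.20, sample_id="wt", group="WT")
    assert dmr.call_dmrs_pairwise(wt2, mut2, "CHG") == []  # |0.3| < 0.6


@pytest.mark.parametrize(
    "wt_level,mut_level,called",
    [
        (0.30, 0.04, True),   # 0.26 > 0.20; 0.04 < 0.05; 0.30 > 0.25
        (0.28, 0.07, False),  # min level 0.07 >= 0.05
        (0.22, 0.04, False),  # max level 0.22 <= 0.25
        (0.30, 0.12, False),  # |diff| 0.18 <= 0.20
    ],
)
def test_pairwise_chh_compound_rule(wt_level, mut_level, called):
    wt = sample_with_window_level(wt_level, n_sites=6, cov=200, context="CHH",
                                  sample_id="wt", group="WT")
    mut = sample_with_window_level(mut_level, n_sites=6, cov=200, context="CHH",
                                   sample_id="mut", group="mut")
    out = dmr.call_dmrs_pairwise(wt, mut, "CHH")
    assert bool(out) is called


def test_pairwise_coverage_filter():
    wt = sample_with_window_level(0.9, cov=1, sample_id="wt", group="WT")
    mut = sample_with_window_level(0.1, cov=10, sample_id="mut", group="mut")
    assert dmr.call_dmrs_pairwise(wt, mut, "CHG") == []  # WT mean coverage < 2


# ---------------------------------------------------------------------------
# summaries


@pytest.mark.parametrize(
    "n_hypo,n_total,expected",
    [(1321, 1843, 71.7), (639, 1318, 48.5), (5, 5, 100.0)],
)
def test_direction_summary_percentages(n_hypo, n_total, expected):
    dmrs = [
        dmr.MethRegion("c1", i * 100, i * 100 + 100, "CHG", 1, 0.5, 0.4, -0.1, "hypo")
        for i in range(n_hypo)
    ] + [
        dmr.MethRegion("c1", (n_hypo + i) * 100, (n_hypo + i) * 100 + 100, "CHG", 1,
                       0.4, 0.5, 0.1, "hyper")
        for i in range(n_total - n_hypo)
    ]
    s = dmr.dmr_direction_summary(dmrs)
    assert (s.n_total, s.n_hypo, s.pct_hypo) == (n_total, n_hypo, expected)


def test_direction_summary_empty():
    s = dmr.dmr_direction_summary([])
    assert s.n_total == 0 and s.pct_hypo is None


# ---------------------------------------------------------------------------
# properties


def random_instance(rng, context="CHG"):
    n_win = int(rng.integers(2, 21))
    n_a = int(rng.integers(2, 9))
    n_b = int(rng.integers(2, 9))
    ga = [MethylomeSample(f"a{i}", "A", random_methylome(rng, n_win, context))
          for i in range(n_a)]
    gb = [MethylomeSample(f"b{i}", "B", random_methylome(rng, n_win, context))
          for i in range(n_b)]
    return {"A": ga, "B": gb}


def assert_matches_oracle(called, oracle):
    assert len(called) == len(oracle)
    for d, o in zip(called, oracle):
        assert (d.chrom, d.start, d.end, d.n_windows, d.direction) == (
            o["chrom"], o["start"], o["end"], o["n_windows"], o["direction"]
        )
        assert d.difference == pytest.approx(o["difference"], abs=1e-9)
        if d.p_value is not None:
            assert d.p_value == pytest.approx(o["p_value"], abs=1e-9)


def test_population_oracle_equivalence_fuzz():
    rng = np.random.default_rng(42)
    params = dmr.DmrParamsPopulation()
    for _ in range(15):
        samples = random_instance(rng)
        called = dmr.call_dmrs_population(samples, "CHG", params, reference="A")
        oracle = call_population_oracle(samples, "CHG", params, "A")
        assert_matches_oracle(called, oracle)


def test_pairwise_oracle_equivalence_fuzz():
    rng = np.random.default_rng(43)
    params = dmr.DmrParamsPairwise()
    for context in ("CHG", "CHH"):
        for _ in range(8):
            wt = MethylomeSample("wt", "WT", random_methylome(rng, 15, context, max_sites=8))
            mut = MethylomeSample("mut", "M", random_methylome(rng, 15, context, max_sites=8))
            called = dmr.call_dmrs_pairwise(wt, mut, context, params)
            oracle = call_pairwise_oracle(wt, mut, context, params)
            assert_matches_oracle(called, oracle)


def test_threshold_monotonicity():
    rng = np.random.default_rng(7)
    for _ in range(5):
        samples = random_instance(rng)
        base = dmr.DmrParamsPopulation()
        loose = dmr.DmrParamsPopulation(min_diff={"CG": 0.0, "CHG": 0.0, "CHH": 0.0})
        strict_sites = dmr.DmrParamsPopulation(min_sites={"CG": 5, "CHG": 5, "CHH": 8})
        ids = lambda res: {(d.chrom, d.start, d.end) for d in res}
        called = ids(dmr.call_dmrs_population(samples, "CHG", base, reference="A"))
        assert called <= ids(dmr.call_dmrs_population(samples, "CHG", loose, reference="A"))
        # raising min_sites shrinks the retained window set, so every DMR
        # under the stricter rule covers only windows retained under both
        stricter = dmr.call_dmrs_population(samples, "CHG", strict_sites, reference="A")
        base_tested = dmr.test_regions_population(samples, "CHG", base, reference="A")
        covered = set()
        for t in base_tested:
            covered |= {(t.chrom, w) for w in range(t.start // 100, t.end // 100)}
        for d in stricter:
            assert {(d.chrom, w) for w in range(d.start // 100, d.end // 100)} <= covered


def test_output_regions_disjoint_non_adjacent(population_fixture):
    _, samples, _, _ = population_fixture
    tested = dmr.test_regions_population(samples, "CHG", reference="Indel-7080Ref")
    by_chrom = {}
    for t in tested:
        by_chrom.setdefault(t.chrom, []).append((t.start, t.end))
    for intervals in by_chrom.values():
        intervals.sort()
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert s2 > e1  # disjoint AND non-adjacent (merge was maximal)
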