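"""Tests for DMR annotation, DEG enrichment and rank-sum comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from huskmeth import assoc, simulate
from huskmeth.dmr import MethRegion
from huskmeth.io import GeneModel, ValidationError

from .oracles import mann_whitney_exact_oracle, yates_chi2_oracle


def region(chrom, start, end, direction="hypo", context="CHG"):
    diff = -0.2 if direction == "hypo" else 0.2
    return MethRegion(chrom, start, end, context, 1, 0.5, 0.5 + diff, diff, direction)


# ---------------------------------------------------------------------------
# promoters and feature assignment


@pytest.mark.parametrize(
    "strand,tx,expected",
    [
        ("+", (5000, 7000), (3000, 5000)),
        ("-", (5000, 7000), (7000, 9000)),
        ("+", (500, 1500), (0, 500)),  # truncated at the chromosome start
    ],
)
def test_promoter_intervals(strand, tx, expected):
    g = GeneModel("g", "chr1", strand, *tx)
    (_, _, start, end), = assoc.promoter_intervals([g])
    assert (start, end) == expected


def test_assign_features_boundaries():
    genes = [GeneModel("g1", "chr1", "+", 5000, 7000)]
    hits = assoc.assign_features([region("chr1", 4500, 4600)], genes)
    assert hits[0].classes == {"promoter"}
    # half-open: a DMR starting exactly at tx_end does not overlap the body
    hits = assoc.assign_features([region("chr1", 7000, 7100)], genes)
    assert hits[0].classes == {"intergenic"}
    hits = assoc.assign_features([region("chr1", 6900, 7000)], genes)
    assert hits[0].classes == {"gene_body"}


def test_assign_features_multi_class_and_te():
    genes = [GeneModel("g1", "chr1", "+", 5000, 7000)]
    tes = [GeneModel("te1", "chr1", ".", 4900, 5100, feature_class="TE")]
    hits = assoc.assign_features([region("chr1", 4950, 5050)], genes, tes)
    assert hits[0].classes == {"promoter", "gene_body", "TE"}


def test_feature_counts_invariant_to_order():
    genes = [GeneModel("g1", "chr1", "+", 5000, 7000)]
    dmrs = [region("chr1", 100, 200), region("chr1", 5500, 5600, "hyper"),
            region("chr1", 4000, 4100)]
    fwd = assoc.feature_class_counts(assoc.assign_features(dmrs, genes))
    rev = assoc.feature_class_counts(assoc.assign_features(dmrs[::-1], genes))
    assert fwd.equals(rev)


def test_dmr_associated_genes():
    genes = [
        GeneModel("g1", "chr1", "+", 5000, 7000),
        GeneModel("g2", "chr1", "+", 9000, 11000),  # promoter [7000, 9000)
    ]
    assert assoc.dmr_associated_genes([region("chr1", 5500, 5600)], genes) == {"g1"}
    # a DMR spanning g1's body end and g2's promoter start hits both
    assert assoc.dmr_associated_genes([region("chr1", 6950, 7150)], genes) == {"g1", "g2"}
    assert assoc.dmr_associated_genes([], genes) == set()


def test_dmr_associated_genes_monotone():
    genes = [GeneModel(f"g{i}", "chr1", "+", i * 3000, i * 3000 + 1000) for i in range(10)]
    dmrs = [region("chr1", 200 + i * 2500, 400 + i * 2500) for i in range(8)]
    prev = set()
    for k in range(len(dmrs) + 1):
        cur = assoc.dmr_associated_genes(dmrs[:k], genes)
        assert prev <= cur
        prev = cur


# ---------------------------------------------------------------------------
# DEG records and enrichment


@pytest.mark.parametrize(
    "log2fc,fdr,status",
    [(2.0, 0.01, "up"), (-1.5, 0.001, "down"), (0.5, 0.01, "ns"), (2.0, 0.2, "ns")],
)
def test_deg_status_rederived(log2fc, fdr, status):
    assert assoc.DegRecord("g", log2fc, fdr).status == status


def test_enrichment_example_table():
    degs = [assoc.DegRecord(f"g{i}", 2.0, 0.01) for i in range(50)] + [
        assoc.DegRecord(f"g{i}", 0.0, 0.9) for i in range(50, 500)
    ]
    expressed = {f"g{i}" for i in range(500)}
    assoc_genes = {f"g{i}" for i in range(20)} | {f"g{i}" for i in range(100, 180)}
    res = assoc.deg_enrichment(assoc_genes, degs, expressed)
    assert (res.k1, res.n1, res.k2, res.n2) == (20, 100, 50, 500)
    assert res.p1 == pytest.approx(0.20)
    assert res.p2 == pytest.approx(0.10)
    chi2, p = yates_chi2_oracle(20, 100, 50, 500)
    assert res.chi2 == pytest.approx(chi2, abs=1e-8)
    assert res.p_value == pytest.approx(p, abs=1e-8)


def test_enrichment_identical_proportions():
    _, p = assoc.two_proportion_test(10, 100, 50, 500)
    assert p == pytest.approx(1.0)


def test_enrichment_extreme_separation():
    _, p = assoc.two_proportion_test(40, 40, 0, 40)
    assert p < 1e-6


def test_enrichment_oracle_equality_random_tables():
    rng = np.random.default_rng(3)
    for _ in range(100):
        n1 = int(rng.integers(10, 400))
        n2 = int(rng.integers(10, 400))
        k1 = int(rng.integers(0, n1 + 1))
        k2 = int(rng.integers(0, n2 + 1))
        chi2, p = assoc.two_proportion_test(k1, n1, k2, n2)
        ochi2, op = yates_chi2_oracle(k1, n1, k2, n2)
        if k1 / n1 == k2 / n2:
            assert p == pytest.approx(1.0)
        else:
            assert chi2 == pytest.approx(ochi2, abs=1e-8)
            assert p == pytest.approx(op, abs=1e-8)


def test_enrichment_requires_subset_and_nonempty():
    degs = [assoc.DegRecord("g0", 2.0, 0.01)]
    with pytest.raises(ValidationError):
        assoc.deg_enrichment({"gX"}, degs, {"g0"})
    with pytest.raises(ValidationError):
        assoc.deg_enrichment(set(), degs, set())


# ---------------------------------------------------------------------------
# rank-sum test


def test_rank_sum_exact_examples():
    u, p = assoc.rank_sum_test([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.100, abs=1e-12)
    _, p = assoc.rank_sum_test([1], [2])
    assert p == pytest.approx(1.0)
    _, p = assoc.rank_sum_test([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
    assert p == pytest.approx(1.0)


def test_rank_sum_empty_group():
    with pytest.raises(ValidationError):
        assoc.rank_sum_test([], [1.0])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    x=st.lists(st.integers(0, 40), min_size=1, max_size=6),
    y=st.lists(st.integers(0, 40), min_size=1, max_size=6),
)
def test_rank_sum_exact_matches_enumeration(x, y):
    pooled = x + y
    if len(set(pooled)) < len(pooled):  # exact mode applies to tie-free data
        return
    u, p = assoc.rank_sum_test(x, y)
    ou, op = mann_whitney_exact_oracle(x, y)
    assert u == pytest.approx(ou)
    assert p == pytest.approx(op, abs=1e-10)


# ---------------------------------------------------------------------------
# group-level methylation comparison


def test_global_methylation_group_difference_recovery():
    cfg = simulate.SimConfig(seed=19, chrom_length=50_000, global_chg_shift=-0.05,
                             planted_dmrs=())
    samples, _, _ = simulate.simulate_population_methylomes(cfg)
    res = assoc.global_methylation_by_group(samples, "CHG")
    diff = res.group_means["Indel-7080Ref"] - res.group_means["Indel-7080In"]
    assert diff == pytest.approx(0.05, abs=0.02)


def test_global_methylation_identical_groups():
    cfg = simulate.SimConfig(seed=20, chrom_length=20_000, planted_dmrs=())
    samples, _, _ = simulate.simulate_population_methylomes(cfg)
    same = {"A": samples["Indel-7080Ref"], "B": samples["Indel-7080Ref"]}
    res = assoc.global_methylation_by_group(same, "CHG")
    assert res.p_value == pytest.approx(1.0)


def test_global_methylation_context_isolation():
    cfg = simulate.SimConfig(seed=21, chrom_length=20_000, planted_dmrs=())
    samples, _, _ = simulate.simulate_population_methylomes(cfg)
    s = samples["Indel-7080Ref"][0]
    chh_only = s.data[s.data["context"] == "CHH"]
    direct = chh_only["n_meth"].sum() / chh_only["n_total"].sum()
    assert s.global_weighted_level("CHH") == pytest.approx(direct)
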