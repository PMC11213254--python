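"""DMR annotation against genomic features and group-comparison tests.

Covers promoter derivation (2 kb upstream of the transcript start),
DMR-to-feature assignment (gene body / promoter / TE / intergenic),
the DEG-enrichment comparison (two-proportion chi-square with Yates
continuity correction, the behaviour of R's prop.test), the Mann-Whitney
rank-sum test used for haplotype-vs-trait comparisons, and genome-wide
group methylation comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .dmr import MethRegion
from .io import GeneModel, MethylomeSample, ValidationError

FEATURE_CLASSES = ("gene_body", "promoter", "TE", "intergenic")


@dataclass(frozen=True)
class DegRecord:
    """One gene's differential-expression call.

    Status is re-derived from the thresholds (FDR < 0.05, |log2FC| > 1) and
    never trusted from the input file.
    """

    gene_id: str
    log2fc: float
    fdr: float
    status: str = field(init=False)

    def __post_init__(self) -> None:
        if not (0 <= self.fdr <= 1):
            raise ValidationError(f"{self.gene_id}: FDR must be in [0,1]")
        if self.fdr < 0.05 and abs(self.log2fc) > 1:
            status = "up" if self.log2fc > 0 else "down"
        else:
            status = "ns"
        object.__setattr__(self, "status", status)

    @property
    def is_deg(self) -> bool:
        return self.status != "ns"


@dataclass(frozen=True)
class EnrichmentResult:
    k1: int  # DEGs among DMR-associated expressed genes
    n1: int
    k2: int  # DEGs among all expressed genes
    n2: int
    chi2: float
    p_value: float

    @property
    def p1(self) -> float:
        return self.k1 / self.n1

    @property
    def p2(self) -> float:
        return self.k2 / self.n2


@dataclass(frozen=True)
class FeatureAssignment:
    dmr: MethRegion
    classes: frozenset  # subset of FEATURE_CLASSES


def promoter_intervals(
    genes: Sequence[GeneModel],
    upstream: int = 2000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[tuple[str, str, int, int]]:
    """(gene_id, chrom, start, end) promoter intervals, 2 kb upstream of the
    transcript start on the gene's strand, truncated at chromosome bounds."""
    out = []
    for g in genes:
        if g.strand == "-":
            start, end = g.tx_end, g.tx_end + upstream
        else:
            start, end = g.tx_start - upstream, g.tx_start
        start = max(start, 0)
        if chrom_sizes is not None and g.chrom in chrom_sizes:
            end = min(end, chrom_sizes[g.chrom])
        if start < end:
            out.append((g.gene_id, g.chrom, start, end))
    return out


def _build_trees(intervals: Iterable[tuple[str, str, int, int]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for name, chrom, start, end in intervals:
        if start < end:
            trees.setdefault(chrom, IntervalTree()).addi(start, end, name)
    return trees


def assign_features(
    dmrs: Sequence[MethRegion],
    genes: Sequence[GeneModel],
    tes: Sequence[GeneModel] = (),
    upstream: int = 2000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[FeatureAssignment]:
    """Classify each DMR by the feature classes it overlaps (>= 1 bp).

    A DMR may hit several classes; a DMR hitting none is intergenic.
    """
    body_trees = _build_trees((g.gene_id, g.chrom, g.tx_start, g.tx_end) for g in genes)
    prom_trees = _build_trees(promoter_intervals(genes, upstream, chrom_sizes))
    te_trees = _build_trees((t.gene_id, t.chrom, t.tx_start, t.tx_end) for t in tes)
    out = []
    for d in dmrs:
        hit = set()
        if d.chrom in body_trees and body_trees[d.chrom].overlap(d.start, d.end):
            hit.add("gene_body")
        if d.chrom in prom_trees and prom_trees[d.chrom].overlap(d.start, d.end):
            hit.add("promoter")
        if d.chrom in te_trees and te_trees[d.chrom].overlap(d.start, d.end):
            hit.add("TE")
        if not hit:
            hit.add("intergenic")
        out.append(FeatureAssignment(d, frozenset(hit)))
    return out


def feature_class_counts(assignments: Sequence[FeatureAssignment]) -> pd.DataFrame:
    """Per-class DMR counts, split by hyper/hypo direction."""
    rows = []
    for direction in ("hypo", "hyper"):
        sub = [a for a in assignments if a.dmr.direction == direction]
        for cls in FEATURE_CLASSES:
            rows.append(
                {
                    "direction": direction,
                    "feature_class": cls,
                    "n_dmrs": sum(1 for a in sub if cls in a.classes),
                }
            )
    return pd.DataFrame(rows)


def dmr_associated_genes(
    dmrs: Sequence[MethRegion],
    genes: Sequence[GeneModel],
    upstream: int = 2000,
    extra_distance: int = 0,
    chrom_sizes: Mapping[str, int] | None = None,
) -> set[str]:
    """Genes whose body or promoter overlaps at least one DMR.

    ``extra_distance`` widens every DMR symmetrically before the overlap
    query (0 by default; 2000 reproduces a within-2-kb association).
    """
    body_trees = _build_trees((g.gene_id, g.chrom, g.tx_start, g.tx_end) for g in genes)
    prom_trees = _build_trees(promoter_intervals(genes, upstream, chrom_sizes))
    out: set[str] = set()
    for d in dmrs:
        start = max(0, d.start - extra_distance)
        end = d.end + extra_distance
        for trees in (body_trees, prom_trees):
            if d.chrom in trees:
                for iv in trees[d.chrom].overlap(start, end):
                    out.add(iv.data)
    return out


def read_deg_table(path) -> list[DegRecord]:
    """TSV with header gene_id, log2fc, fdr; status re-derived on read."""
    df = pd.read_csv(path, sep="\t")
    return [
        DegRecord(str(r.gene_id), float(r.log2fc), float(r.fdr))
        for r in df.itertuples(index=False)
    ]


def deg_enrichment(
    assoc_genes: set[str],
    deg_table: Sequence[DegRecord],
    expressed_genes: set[str],
    yates: bool = True,
) -> EnrichmentResult:
    """Compare the DEG fraction among DMR-associated expressed genes with the
    fraction among all expressed genes (two-proportion chi-square, two-sided,
    Yates continuity correction by default -- prop.test behaviour)."""
    if not assoc_genes <= expressed_genes:
        raise ValidationError("assoc_genes must be a subset of expressed_genes")
    deg_ids = {d.gene_id for d in deg_table if d.is_deg}
    n1 = len(assoc_genes)
    n2 = len(expressed_genes)
    if n1 == 0 or n2 == 0:
        raise ValidationError("empty gene universe for the enrichment test")
    k1 = len(assoc_genes & deg_ids)
    k2 = len(expressed_genes & deg_ids)
    chi2, p = two_proportion_test(k1, n1, k2, n2, yates=yates)
    return EnrichmentResult(k1, n1, k2, n2, chi2, p)


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, yates: bool = True
) -> tuple[float, float]:
    """Chi-square test on the 2x2 table [[k1, n1-k1], [k2, n2-k2]]."""
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table < 0).any():
        raise ValidationError("counts must satisfy k <= n")
    if k1 / n1 == k2 / n2:
        # identical proportions: chi2 = 0 by construction (scipy raises on
        # zero-margin tables, which this also covers)
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], exact_max_product: int = 400
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact distribution when |x|*|y| <= ``exact_max_product`` and the data are
    tie-free; normal approximation with tie and continuity correction
    otherwise. Returns (U for x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) * len(y) <= exact_max_product and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class GroupLevelComparison:
    context: str
    group_means: Mapping[str, float]
    per_sample_levels: Mapping[str, Mapping[str, float]]
    u_stat: float
    p_value: float


def global_methylation_by_group(
    samples_by_group: Mapping[str, Sequence[MethylomeSample]], context: str
) -> GroupLevelComparison:
    """Per-sample genome-wide weighted levels for one context, the group
    means, and a Mann-Whitney comparison of the two groups."""
    if len(samples_by_group) != 2:
        raise ValidationError("global comparison needs exactly 2 groups")
    per_sample: dict[str, dict[str, float]] = {}
    means: dict[str, float] = {}
    values = []
    for g, samples in samples_by_group.items():
        if len(samples) < 2:
            raise ValidationError("need >= 2 samples per group")
        lv = {s.sample_id: s.global_weighted_level(context) for s in samples}
        per_sample[g] = lv
        means[g] = float(np.nanmean(list(lv.values())))
        values.append(np.array(list(lv.values())))
    u, p = rank_sum_test(values[0], values[1])
    return GroupLevelComparison(context, means, per_sample, u, p)
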