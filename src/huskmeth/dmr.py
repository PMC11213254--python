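"""Window-based DMR identification in two modes.

Population mode (two haplotype groups of inbred lines): the genome is tiled
into non-overlapping 100-bp windows; a window is retained when, in BOTH
groups, strictly more than half the lines have at least ``min_sites``
cytosines of the context covered by at least ``min_site_cov`` reads;
retained adjacent windows are merged into regions; per-line weighted region
levels are recomputed; a t-test (Welch by default) compares the two groups
per region; a DMR is a region with p < alpha and an absolute group-mean
difference above the context threshold (10% for CG/CHG, 5% for CHH).

Pairwise mode (one wild-type vs one mutant methylome): windows are retained
when both samples have at least ``min_sites`` context cytosines and mean
coverage >= 2x; the per-window level difference is filtered (|d| >= 60% for
CG/CHG; the CHH compound rule: |d| > 20% with one sample < 5% and the other
> 25% methylated); surviving adjacent windows are merged and region levels
recomputed.

The modes deliberately order merge-vs-test differently: population merges
retained windows before testing, pairwise filters windows before merging.
Direction is always relative to the declared reference (group 1 / wild
type): "hypo" means lower methylation in the focal group (mutant or
Indel-7080In).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONTEXTS, MethylomeSample, ValidationError

logger = logging.getLogger(__name__)

WINDOW_WIDTH = 100


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 0-based half-open
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"window start >= end: {self.chrom}:{self.start}-{self.end}")


@dataclass
class MethRegion:
    """A merged run of retained windows with group levels and test results."""

    chrom: str
    start: int
    end: int
    context: str
    n_windows: int
    level_a: float  # reference group / wild type
    level_b: float  # focal group / mutant
    difference: float  # level_b - level_a
    direction: str  # hypo | hyper (relative to focal group)
    t_stat: float | None = None
    df: float | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if abs(self.difference) > 1 + 1e-9:
            raise ValidationError("|difference| must be <= 1")


@dataclass(frozen=True)
class DmrParamsPopulation:
    """Thresholds of the natural-population haplotype procedure."""

    min_site_cov: int = 2
    min_sites: Mapping[str, int] = field(
        default_factory=lambda: {"CG": 3, "CHG": 3, "CHH": 6}
    )
    min_informative_fraction: float = 0.5  # strict >, both groups
    alpha: float = 0.05
    min_diff: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.10, "CHG": 0.10, "CHH": 0.05}
    )
    t_test: str = "welch"  # welch | student
    level_mode: str = "weighted"  # weighted | mean_of_fractions
    fdr: bool = False  # optional Benjamini-Hochberg on region p-values


@dataclass(frozen=True)
class DmrParamsPairwise:
    """Thresholds of the mutant vs wild-type procedure."""

    min_avg_cov: float = 2.0
    min_sites: Mapping[str, int] = field(
        default_factory=lambda: {"CG": 3, "CHG": 3, "CHH": 6}
    )
    min_diff_cg_chg: float = 0.60
    chh_min_diff: float = 0.20  # strict >
    chh_low_max: float = 0.05  # min(level) strictly below
    chh_high_min: float = 0.25  # max(level) strictly above


# ---------------------------------------------------------------------------
# Windows


def tile_windows(chrom_sizes: Mapping[str, int], width: int = WINDOW_WIDTH) -> list[Window]:
    """Tile each chromosome with non-overlapping windows; the last window is
    truncated at the chromosome end."""
    if width <= 0:
        raise ValidationError("window width must be > 0")
    out = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValidationError(f"chromosome {chrom!r} has non-positive size {size}")
        for start in range(0, size, width):
            out.append(Window(chrom, start, min(start + width, size)))
    return out


def window_level(
    sample: MethylomeSample,
    window: Window,
    context: str,
    min_site_cov: int = 0,
    level_mode: str = "weighted",
) -> tuple[int, float, float]:
    """(n_sites, mean_coverage, level) for one sample in one window.

    Sites with fewer than ``min_site_cov`` reads are excluded. The level is
    the weighted level Σ n_meth / Σ n_total (or the mean of per-site
    fractions with ``level_mode='mean_of_fractions'``); NaN when no site
    passes the filter.
    """
    df = sample.data
    sel = df[
        (df["context"] == context)
        & (df["chrom"] == window.chrom)
        & (df["pos"] - 1 >= window.start)
        & (df["pos"] - 1 < window.end)
        & (df["n_total"] >= min_site_cov)
    ]
    n = len(sel)
    if n == 0:
        return 0, float("nan"), float("nan")
    cov = float(sel["n_total"].mean())
    level = _level_of(sel["n_meth"].to_numpy(), sel["n_total"].to_numpy(), level_mode)
    return n, cov, level


def _level_of(n_meth: np.ndarray, n_total: np.ndarray, mode: str) -> float:
    if mode == "weighted":
        tot = n_total.sum()
        return float(n_meth.sum() / tot) if tot else float("nan")
    if mode == "mean_of_fractions":
        ok = n_total > 0
        return float(np.mean(n_meth[ok] / n_total[ok])) if ok.any() else float("nan")
    raise ValidationError(f"unknown level mode {mode!r}")


def _window_stats(
    sample: MethylomeSample, context: str, min_site_cov: int, width: int
) -> pd.DataFrame:
    """Per-(chrom, window) site count, coverage and count sums for a sample."""
    df = sample.data
    sel = df[(df["context"] == context) & (df["n_total"] >= min_site_cov)]
    if sel.empty:
        return pd.DataFrame(
            columns=["chrom", "win", "n_sites", "sum_meth", "sum_total", "mean_cov"]
        )
    win = (sel["pos"] - 1) // width
    g = sel.groupby([sel["chrom"], win], sort=True)
    out = g.agg(
        n_sites=("pos", "size"),
        sum_meth=("n_meth", "sum"),
        sum_total=("n_total", "sum"),
        mean_cov=("n_total", "mean"),
    ).reset_index()
    out.columns = ["chrom", "win", "n_sites", "sum_meth", "sum_total", "mean_cov"]
    return out


# ---------------------------------------------------------------------------
# Tests


def welch_t_test(x: Sequence[float], y: Sequence[float], flavor: str = "welch"):
    """Two-sided t-test between two groups of region levels.

    Welch (unequal variances, Welch-Satterthwaite df) by default; a pooled
    Student flavor is available. NaNs are dropped first; fewer than two
    values in either group raises. Degenerate variance in both groups is a
    tie: (t=0, p=1) rather than NaN propagation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("need >= 2 non-missing values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        n1, n2 = len(x), len(y)
        dof = n1 + n2 - 2 if flavor == "student" else float(n1 + n2 - 2)
        return 0.0, float(dof), 1.0
    if flavor == "welch":
        res = stats.ttest_ind(x, y, equal_var=False)
        n1, n2 = len(x), len(y)
        dof = (vx / n1 + vy / n2) ** 2 / (
            (vx / n1) ** 2 / (n1 - 1) + (vy / n2) ** 2 / (n2 - 1)
        )
    elif flavor == "student":
        res = stats.ttest_ind(x, y, equal_var=True)
        dof = len(x) + len(y) - 2
    else:
        raise ValidationError(f"unknown t-test flavor {flavor!r}")
    return float(res.statistic), float(dof), float(res.pvalue)


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# Merging


def merge_adjacent(windows: Sequence[Window]) -> list[tuple[Window, int]]:
    """Merge maximal runs of zero-gap windows on the same chromosome.

    Returns (merged interval, n_windows) pairs. Input must be sorted by
    (chrom, start) and non-overlapping.
    """
    out: list[tuple[Window, int]] = []
    prev: Window | None = None
    for w in windows:
        if prev is not None and w.chrom == prev.chrom:
            if w.start < prev.end:
                raise ValidationError(
                    f"overlapping windows: {prev.chrom}:{prev.start}-{prev.end} and "
                    f"{w.chrom}:{w.start}-{w.end}"
                )
        if prev is not None and w.chrom == prev.chrom and w.start == prev.end:
            merged, n = out[-1]
            out[-1] = (Window(merged.chrom, merged.start, w.end), n + 1)
        else:
            out.append((w, 1))
        prev = w
    return out


def _merged_runs(stats_df: pd.DataFrame, width: int) -> list[dict]:
    """Group retained (chrom, win) rows into runs of consecutive windows."""
    regions = []
    for chrom, sub in stats_df.groupby("chrom", sort=True):
        wins = np.sort(sub["win"].to_numpy())
        if len(wins) == 0:
            continue
        breaks = np.where(np.diff(wins) != 1)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(wins) - 1]])
        for a, b in zip(starts, ends):
            regions.append(
                {
                    "chrom": chrom,
                    "start": int(wins[a]) * width,
                    "end": (int(wins[b]) + 1) * width,
                    "wins": set(range(int(wins[a]), int(wins[b]) + 1)),
                    "n_windows": int(b - a + 1),
                }
            )
    return regions


# ---------------------------------------------------------------------------
# Population mode


def test_regions_population(
    samples_by_group: Mapping[str, Sequence[MethylomeSample]],
    context: str,
    params: DmrParamsPopulation = DmrParamsPopulation(),
    reference: str | None = None,
    width: int = WINDOW_WIDTH,
) -> list[MethRegion]:
    """Run the population pipeline through the t-test, returning EVERY
    testable merged region (no significance filter).

    Use :func:`call_dmrs_population` for the final thresholded DMR list;
    this entry point exposes the full tested set for calibration work.
    """
    if context not in CONTEXTS:
        raise ValidationError(f"unknown context {context!r}")
    if len(samples_by_group) != 2:
        raise ValidationError("population mode needs exactly 2 groups")
    groups = list(samples_by_group)
    if reference is None:
        reference = groups[0]
    if reference not in samples_by_group:
        raise ValidationError(f"reference group {reference!r} not present")
    focal = next(g for g in groups if g != reference)
    ref_samples = list(samples_by_group[reference])
    foc_samples = list(samples_by_group[focal])
    if len(ref_samples) < 2 or len(foc_samples) < 2:
        raise ValidationError("population mode needs >= 2 samples per group")

    min_sites = params.min_sites[context]

    # (1)+(2) window retention: per-line site counts at min_site_cov
    def informative_counts(samples):
        counts = None
        for s in samples:
            st = _window_stats(s, context, params.min_site_cov, width)
            ok = st[st["n_sites"] >= min_sites][["chrom", "win"]]
            ok = ok.assign(k=1)
            counts = ok if counts is None else pd.concat([counts, ok])
        if counts is None or counts.empty:
            return pd.DataFrame(columns=["chrom", "win", "k"])
        return counts.groupby(["chrom", "win"], sort=True)["k"].sum().reset_index()

    ref_counts = informative_counts(ref_samples)
    foc_counts = informative_counts(foc_samples)
    merged_counts = ref_counts.merge(
        foc_counts, on=["chrom", "win"], how="outer", suffixes=("_ref", "_foc")
    )
    for col in ("k_ref", "k_foc"):
        merged_counts[col] = merged_counts[col].astype(float).fillna(0.0)
    thr = params.min_informative_fraction
    retained = merged_counts[
        (merged_counts["k_ref"] / len(ref_samples) > thr)
        & (merged_counts["k_foc"] / len(foc_samples) > thr)
    ][["chrom", "win"]]
    if retained.empty:
        return []

    # (3) merge adjacent retained windows into regions
    regions = _merged_runs(retained, width)
    region_id = {}
    for i, r in enumerate(regions):
        for w in r["wins"]:
            region_id[(r["chrom"], w)] = i

    # (4) recompute per-line region levels (weighted over min_site_cov sites)
    def region_levels(samples):
        lv = np.full((len(samples), len(regions)), np.nan)
        for si, s in enumerate(samples):
            df = s.data
            sel = df[(df["context"] == context) & (df["n_total"] >= params.min_site_cov)]
            if sel.empty:
                continue
            win = (sel["pos"] - 1) // width
            rid = [
                region_id.get((c, w), -1) for c, w in zip(sel["chrom"], win)
            ]
            sel = sel.assign(rid=rid)
            sel = sel[sel["rid"] >= 0]
            for r, grp in sel.groupby("rid"):
                lv[si, r] = _level_of(
                    grp["n_meth"].to_numpy(), grp["n_total"].to_numpy(), params.level_mode
                )
        return lv

    ref_levels = region_levels(ref_samples)
    foc_levels = region_levels(foc_samples)

    # (5) t-test per region; untestable regions skipped with a log line
    out = []
    for i, r in enumerate(regions):
        x = ref_levels[:, i]
        y = foc_levels[:, i]
        x = x[~np.isnan(x)]
        y = y[~np.isnan(y)]
        if len(x) < 2 or len(y) < 2:
            logger.info(
                "region %s:%d-%d untestable (<2 informative lines in a group); skipped",
                r["chrom"], r["start"], r["end"],
            )
            continue
        t, dof, p = welch_t_test(x, y, flavor=params.t_test)
        mean_a, mean_b = float(np.mean(x)), float(np.mean(y))
        diff = mean_b - mean_a
        out.append(
            MethRegion(
                chrom=r["chrom"],
                start=r["start"],
                end=r["end"],
                context=context,
                n_windows=r["n_windows"],
                level_a=mean_a,
                level_b=mean_b,
                difference=diff,
                direction="hypo" if diff < 0 else "hyper",
                t_stat=t,
                df=dof,
                p_value=p,
            )
        )
    return out


def call_dmrs_population(
    samples_by_group: Mapping[str, Sequence[MethylomeSample]],
    context: str,
    params: DmrParamsPopulation = DmrParamsPopulation(),
    reference: str | None = None,
    width: int = WINDOW_WIDTH,
) -> list[MethRegion]:
    """Population-mode DMRs: tested regions passing p < alpha and the
    context-specific minimum absolute difference."""
    tested = test_regions_population(samples_by_group, context, params, reference, width)
    if not tested:
        return []
    pvals = np.array([r.p_value for r in tested])
    if params.fdr:
        pvals = _bh_fdr(pvals)
    min_diff = params.min_diff[context]
    out = []
    for r, p in zip(tested, pvals):
        if p < params.alpha and abs(r.difference) > min_diff:
            out.append(replace(r, p_value=float(p)) if params.fdr else r)
    return out


# ---------------------------------------------------------------------------
# Pairwise mode


def call_dmrs_pairwise(
    sample_wt: MethylomeSample,
    sample_mut: MethylomeSample,
    context: str,
    params: DmrParamsPairwise = DmrParamsPairwise(),
    width: int = WINDOW_WIDTH,
) -> list[MethRegion]:
    """Mutant-vs-wild-type DMRs (threshold pipeline, no test statistic)."""
    if context not in CONTEXTS:
        raise ValidationError(f"unknown context {context!r}")
    min_sites = params.min_sites[context]
    wt = _window_stats(sample_wt, context, 0, width)
    mut = _window_stats(sample_mut, context, 0, width)
    m = wt.merge(mut, on=["chrom", "win"], how="inner", suffixes=("_wt", "_mut"))
    # (1) retention: site count and mean coverage in BOTH samples
    m = m[
        (m["n_sites_wt"] >= min_sites)
        & (m["n_sites_mut"] >= min_sites)
        & (m["mean_cov_wt"] >= params.min_avg_cov)
        & (m["mean_cov_mut"] >= params.min_avg_cov)
    ]
    if m.empty:
        return []
    # (2)+(3) per-window levels and the context difference rule
    lw = m["sum_meth_wt"] / m["sum_total_wt"]
    lm = m["sum_meth_mut"] / m["sum_total_mut"]
    d = lm - lw
    if context in ("CG", "CHG"):
        keep = d.abs() >= params.min_diff_cg_chg
    else:
        lo = np.minimum(lw, lm)
        hi = np.maximum(lw, lm)
        keep = (d.abs() > params.chh_min_diff) & (lo < params.chh_low_max) & (hi > params.chh_high_min)
    surviving = m[keep][["chrom", "win"]]
    if surviving.empty:
        return []
    # (4) merge adjacent surviving windows
    regions = _merged_runs(surviving, width)
    # (5) recompute merged-region levels from raw counts (all sites)
    out = []
    for r in regions:
        lvl = {}
        for tag, s in (("wt", sample_wt), ("mut", sample_mut)):
            df = s.data
            sel = df[
                (df["context"] == context)
                & (df["chrom"] == r["chrom"])
                & (df["pos"] - 1 >= r["start"])
                & (df["pos"] - 1 < r["end"])
            ]
            tot = sel["n_total"].sum()
            lvl[tag] = float(sel["n_meth"].sum() / tot) if tot else float("nan")
        diff = lvl["mut"] - lvl["wt"]
        out.append(
            MethRegion(
                chrom=r["chrom"],
                start=r["start"],
                end=r["end"],
                context=context,
                n_windows=r["n_windows"],
                level_a=lvl["wt"],
                level_b=lvl["mut"],
                difference=diff,
                direction="hypo" if diff < 0 else "hyper",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Summaries


@dataclass(frozen=True)
class DirectionSummary:
    n_total: int
    n_hypo: int
    n_hyper: int
    pct_hypo: float | None  # one decimal; None for the empty summary


def dmr_direction_summary(dmrs: Sequence[MethRegion]) -> DirectionSummary:
    """Hyper/hypo counts and the percentage hypomethylated (1 decimal)."""
    n = len(dmrs)
    if n == 0:
        return DirectionSummary(0, 0, 0, None)
    n_hypo = sum(1 for d in dmrs if d.direction == "hypo")
    return DirectionSummary(n, n_hypo, n - n_hypo, round(100.0 * n_hypo / n, 1))
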