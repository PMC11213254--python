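"""Seeded generators for every input the pipeline consumes, with truth tables.

The generators emulate the study designs the pipeline targets: two-group
population methylomes (6 inbred lines per Indel haplotype, Poisson 10x
coverage, beta-binomial site counts, a small global CHG shift and planted
locus-specific CHG DMRs of effect 0.3), a wild-type/mutant methylome pair
with genome-wide CHG/CHH depletion plus planted regions crossing the
pairwise call thresholds, DEG tables enriched near hypomethylated DMRs
(10.1%-like coupled rate over a 7.8%-like background), and maize/teosinte
alignments in which the maize sample's diversity is reduced by a
domestication bottleneck (360-bp locus, 21 teosinte haplotypes).

Every generator is a pure function of its config and seed: same config,
same bytes. Truth tables carry planted features by id so calls can be
scored without re-reading configs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import popgen
from .io import GeneModel, MethylomeSample, PopAlignment, SampleSheet, ValidationError

_CTX_LIST = ("CG", "CHG", "CHH")


@dataclass(frozen=True)
class PlantedDmr:
    dmr_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    context: str
    effect: float  # additive shift of the focal group's mean level

    @property
    def direction(self) -> str:
        return "hypo" if self.effect < 0 else "hyper"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for all generators.

    Site densities are per kb and approximate maize gene space (~6 CG/CHG
    and ~12 CHH cytosines per 100-bp window). Sequencing depth is locally
    structured as in real WGBS: each 100-bp window carries a mappability
    factor shared by every sample (a fraction of windows is repeat-like and
    effectively unsequenceable), so window retention is patchy and merged
    regions stay local. Baselines follow the maize-typical ordering (high CG
    and CHG, low CHH); counts are beta-binomial (precision 20) because real
    WGBS is overdispersed.
    """

    seed: int = 0
    n_chrom: int = 1
    chrom_length: int = 100_000
    site_density: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 60.0, "CHG": 60.0, "CHH": 120.0}
    )
    coverage_mean: float = 10.0
    frac_unmappable: float = 0.35  # windows with repeat-like coverage collapse
    low_mappability_factor: float = 0.05
    baseline: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.85, "CHG": 0.70, "CHH": 0.05}
    )
    precision: float = 20.0  # beta-binomial a+b
    global_chg_shift: float = -0.01  # focal (Indel-7080In) group
    planted_dmrs: tuple[PlantedDmr, ...] | None = None  # None -> per-mode default
    # mutant pair conditions
    mutant_chg_factor: float = 0.65  # genome-wide CHG depletion in the mutant
    mutant_chh_factor: float = 0.50
    planted_chg_depletion: float = 0.05  # mutant level factor inside planted CHG regions
    chh_island_wt: float = 0.35  # planted CHH islands: WT level
    chh_island_mut: float = 0.03
    # expression coupling
    deg_p_coupled: float = 0.101
    deg_p_background: float = 0.078
    frac_up_in_hypo: float = 0.67

    def __post_init__(self) -> None:
        for p in (self.deg_p_coupled, self.deg_p_background, self.frac_up_in_hypo):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must be in [0,1]")
        if any(d < 0 for d in self.site_density.values()):
            raise ValidationError("site densities must be >= 0")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # distinct child stream per generator so outputs are independent
    return np.random.default_rng([int(config.seed), stream])


def chrom_sizes(config: SimConfig) -> dict[str, int]:
    return {f"chr{i + 1}": config.chrom_length for i in range(config.n_chrom)}


# ---------------------------------------------------------------------------
# Reference and planted defaults


def make_reference(config: SimConfig) -> tuple[dict[str, int], pd.DataFrame]:
    """Chromosome sizes plus a cytosine catalog (chrom, pos, strand, context).

    Per context, the site count is Binomial(chrom_length, density/1000) and
    positions are uniform without replacement across contexts.
    """
    rng = _rng(config, 1)
    sizes = chrom_sizes(config)
    rows = []
    for chrom, size in sizes.items():
        n_by_ctx = {
            ctx: int(rng.binomial(size, min(1.0, config.site_density.get(ctx, 0.0) / 1000.0)))
        for ctx in _CTX_LIST}
        total = sum(n_by_ctx.values())
        if total > size:
            raise ValidationError("site densities exceed one site per bp")
        pos = rng.choice(size, size=total, replace=False) + 1  # 1-based
        strands = rng.choice(np.array(["+", "-"]), size=total)
        ctx_col = np.repeat(list(n_by_ctx.keys()), list(n_by_ctx.values()))
        order = np.argsort(pos, kind="stable")
        for p, st, cx in zip(pos[order], strands[order], ctx_col[order]):
            rows.append((chrom, int(p), st, cx))
    return sizes, pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context"])


def window_mappability(config: SimConfig) -> dict[tuple[str, int], float]:
    """Per-window coverage factor shared by all samples.

    A fraction of windows is repeat-like (factor ``low_mappability_factor``,
    effectively unsequenceable); the rest fluctuates mildly around 1
    (Gamma with mean 1, CV ~0.22). Deterministic under the config seed.
    """
    rng = _rng(config, 7)
    out: dict[tuple[str, int], float] = {}
    for chrom, size in chrom_sizes(config).items():
        n_win = -(-size // 100)
        low = rng.uniform(size=n_win) < config.frac_unmappable
        factors = rng.gamma(20.0, 1.0 / 20.0, size=n_win)
        factors[low] = config.low_mappability_factor
        for w in range(n_win):
            out[(chrom, w)] = float(factors[w])
    return out


def _window_site_counts(catalog: pd.DataFrame, context: str, width: int = 100) -> dict:
    sub = catalog[catalog["context"] == context]
    win = (sub["pos"] - 1) // width
    return sub.groupby([sub["chrom"], win]).size().to_dict()


def _pick_window_pairs(
    catalog: pd.DataFrame,
    sizes: Mapping[str, int],
    mappability: Mapping[tuple[str, int], float],
    context: str,
    min_sites: int,
    n_wanted: int,
    isolated: bool,
    taken: set | None = None,
    width: int = 100,
) -> list[tuple[str, int]]:
    """Deterministically choose ``n_wanted`` two-window regions in which both
    windows are retainable loci (at least ``min_sites`` cytosines of the
    context and mappable coverage) -- a planted DMR must be an observable
    locus. With ``isolated=True`` the flanking windows must be
    non-retainable, so planted loci stay discrete after merging. Candidates
    are spread evenly along the genome.
    """
    counts = _window_site_counts(catalog, context, width)
    taken = taken or set()

    def retainable(chrom: str, w: int) -> bool:
        return counts.get((chrom, w), 0) >= min_sites and mappability.get((chrom, w), 0.0) > 0.5

    candidates = []
    for chrom, size in sizes.items():
        n_win = size // width
        for w in range(1, n_win - 2):
            if (chrom, w) in taken or (chrom, w + 1) in taken:
                continue
            if not (retainable(chrom, w) and retainable(chrom, w + 1)):
                continue
            if isolated and (retainable(chrom, w - 1) or retainable(chrom, w + 2)):
                continue
            candidates.append((chrom, w))
    # enforce a >= 1 window gap between chosen regions
    chosen: list[tuple[str, int]] = []
    last: tuple[str, int] | None = None
    spaced = []
    for c in candidates:
        if last is None or c[0] != last[0] or c[1] - last[1] >= 3:
            spaced.append(c)
            last = c
    if len(spaced) < n_wanted:
        warnings.warn(
            f"only {len(spaced)} plantable {context} loci available ({n_wanted} requested)"
        )
        return spaced
    idx = np.unique(np.round(np.linspace(0, len(spaced) - 1, n_wanted)).astype(int))
    return [spaced[i] for i in idx]


def default_population_dmrs(
    config: SimConfig, catalog: pd.DataFrame | None = None, effect: float = -0.3
) -> tuple[PlantedDmr, ...]:
    """30 two-window CHG regions at observable, isolated loci."""
    if catalog is None:
        _, catalog = make_reference(config)
    picks = _pick_window_pairs(
        catalog, chrom_sizes(config), window_mappability(config), "CHG", 3, 30, isolated=True
    )
    return tuple(
        PlantedDmr(f"pop_dmr_{i:02d}", chrom, w * 100, (w + 2) * 100, "CHG", effect)
        for i, (chrom, w) in enumerate(picks)
    )


def default_pair_dmrs(
    config: SimConfig, catalog: pd.DataFrame | None = None
) -> tuple[PlantedDmr, ...]:
    """20 CHG regions plus 10 CHH islands for the mutant/wild-type pair, at
    loci with enough sites for the pairwise retention rule.

    Effects here are markers; the actual levels come from the depletion and
    island parameters in the config.
    """
    if catalog is None:
        _, catalog = make_reference(config)
    sizes = chrom_sizes(config)
    mapp = window_mappability(config)
    chg = _pick_window_pairs(catalog, sizes, mapp, "CHG", 3, 20, isolated=False)
    taken = {(c, w) for c, w in chg} | {(c, w + 1) for c, w in chg}
    chh = _pick_window_pairs(catalog, sizes, mapp, "CHH", 6, 10, isolated=False, taken=taken)
    out = [
        PlantedDmr(f"pair_chg_{i:02d}", chrom, w * 100, (w + 2) * 100, "CHG", -1.0)
        for i, (chrom, w) in enumerate(chg)
    ]
    out += [
        PlantedDmr(f"pair_chh_{j:02d}", chrom, w * 100, (w + 2) * 100, "CHH", -1.0)
        for j, (chrom, w) in enumerate(chh)
    ]
    return tuple(out)


def truth_frame(planted: Sequence[PlantedDmr]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.dmr_id, p.chrom, p.start, p.end, p.context, p.effect, p.direction)
            for p in planted
        ],
        columns=["dmr_id", "chrom", "start", "end", "context", "effect", "direction"],
    )


# ---------------------------------------------------------------------------
# Methylome synthesis


def _site_means(
    catalog: pd.DataFrame,
    baseline: Mapping[str, float],
    planted: Sequence[PlantedDmr],
    chg_shift: float = 0.0,
    chh_factor: float = 1.0,
    chg_factor: float = 1.0,
    apply_planted: bool = True,
) -> np.ndarray:
    means = np.array([baseline[c] for c in catalog["context"]], dtype=float)
    means[catalog["context"].to_numpy() == "CHG"] *= chg_factor
    means[catalog["context"].to_numpy() == "CHH"] *= chh_factor
    means[catalog["context"].to_numpy() == "CHG"] += chg_shift
    if apply_planted:
        pos0 = catalog["pos"].to_numpy() - 1
        for p in planted:
            mask = (
                (catalog["chrom"].to_numpy() == p.chrom)
                & (pos0 >= p.start)
                & (pos0 < p.end)
                & (catalog["context"].to_numpy() == p.context)
            )
            means[mask] += p.effect
    clipped = np.clip(means, 0.0, 1.0)
    if not np.allclose(clipped, means):
        warnings.warn("planted effects pushed some site means outside [0,1]; clipped")
    return clipped


def _site_coverage_means(
    catalog: pd.DataFrame,
    coverage_mean: float,
    mappability: Mapping[tuple[str, int], float],
) -> np.ndarray:
    win = (catalog["pos"].to_numpy() - 1) // 100
    chroms = catalog["chrom"].to_numpy()
    return coverage_mean * np.array(
        [mappability.get((c, int(w)), 1.0) for c, w in zip(chroms, win)]
    )


def _draw_sample(
    rng: np.random.Generator,
    catalog: pd.DataFrame,
    means: np.ndarray,
    coverage_mean: float | np.ndarray,
    precision: float,
    sample_id: str,
    group: str,
) -> MethylomeSample:
    n = len(catalog)
    cov = rng.poisson(coverage_mean, size=n)
    p = np.empty(n)
    interior = (means > 0) & (means < 1)
    p[~interior] = means[~interior]
    a = means[interior] * precision
    b = (1.0 - means[interior]) * precision
    p[interior] = rng.beta(a, b)
    meth = rng.binomial(cov, p)
    df = pd.DataFrame(
        {
            "chrom": catalog["chrom"].to_numpy(),
            "pos": catalog["pos"].to_numpy(),
            "strand": catalog["strand"].to_numpy(),
            "context": catalog["context"].to_numpy(),
            "n_meth": meth,
            "n_total": cov,
        }
    )
    return MethylomeSample(sample_id, group, df)


def simulate_population_methylomes(
    config: SimConfig,
    n_per_group: int = 6,
    groups: tuple[str, str] = ("Indel-7080Ref", "Indel-7080In"),
) -> tuple[dict[str, list[MethylomeSample]], SampleSheet, pd.DataFrame]:
    """Two-group population methylomes with the global CHG shift and planted
    DMRs applied to the focal (second) group.

    Returns (samples keyed by group, sample sheet, truth table).
    """
    if n_per_group < 2:
        raise ValidationError("need >= 2 lines per group")
    _, catalog = make_reference(config)
    planted = (
        config.planted_dmrs
        if config.planted_dmrs is not None
        else default_population_dmrs(config, catalog)
    )
    rng = _rng(config, 2)
    ref_group, focal_group = groups
    cov_means = _site_coverage_means(catalog, config.coverage_mean, window_mappability(config))
    means_ref = _site_means(catalog, config.baseline, planted, apply_planted=False)
    means_foc = _site_means(
        catalog, config.baseline, planted, chg_shift=config.global_chg_shift
    )
    samples: dict[str, list[MethylomeSample]] = {ref_group: [], focal_group: []}
    rows = []
    for g, means in ((ref_group, means_ref), (focal_group, means_foc)):
        for i in range(n_per_group):
            sid = f"{g}_L{i + 1}"
            samples[g].append(
                _draw_sample(rng, catalog, means, cov_means, config.precision, sid, g)
            )
            rows.append({"sample_id": sid, "group": g})
    sheet = SampleSheet(pd.DataFrame(rows))
    return samples, sheet, truth_frame(planted)


def simulate_pair_methylomes(
    config: SimConfig,
) -> tuple[MethylomeSample, MethylomeSample, pd.DataFrame]:
    """A wild-type/mutant methylome pair with genome-wide CHG/CHH depletion
    in the mutant plus planted regions built to cross the pairwise-call
    thresholds (CHG: deep local depletion; CHH: WT islands lost in the
    mutant). CG is untouched.
    """
    _, catalog = make_reference(config)
    planted = (
        config.planted_dmrs
        if config.planted_dmrs is not None
        else default_pair_dmrs(config, catalog)
    )
    rng = _rng(config, 3)
    chg_planted = [p for p in planted if p.context == "CHG"]
    chh_planted = [p for p in planted if p.context == "CHH"]

    means_wt = _site_means(catalog, config.baseline, (), apply_planted=False)
    means_mut = _site_means(
        catalog,
        config.baseline,
        (),
        chg_factor=config.mutant_chg_factor,
        chh_factor=config.mutant_chh_factor,
        apply_planted=False,
    )
    pos0 = catalog["pos"].to_numpy() - 1
    ctx = catalog["context"].to_numpy()
    chroms = catalog["chrom"].to_numpy()
    for p in chg_planted:
        mask = (chroms == p.chrom) & (pos0 >= p.start) & (pos0 < p.end) & (ctx == "CHG")
        means_mut[mask] = config.baseline["CHG"] * config.planted_chg_depletion
    for p in chh_planted:
        mask = (chroms == p.chrom) & (pos0 >= p.start) & (pos0 < p.end) & (ctx == "CHH")
        means_wt[mask] = config.chh_island_wt
        means_mut[mask] = config.chh_island_mut

    cov_means = _site_coverage_means(catalog, config.coverage_mean, window_mappability(config))
    wt = _draw_sample(rng, catalog, means_wt, cov_means, config.precision, "WT_1", "WT")
    mut = _draw_sample(
        rng, catalog, means_mut, cov_means, config.precision, "zmet2-1_1", "zmet2-1"
    )
    return wt, mut, truth_frame(planted)


# ---------------------------------------------------------------------------
# Genes and expression


def simulate_genes(
    config: SimConfig, n_genes: int = 120, gene_length: int = 600
) -> list[GeneModel]:
    """Evenly spaced gene models with random strand across the genome."""
    rng = _rng(config, 4)
    sizes = chrom_sizes(config)
    genes = []
    i = 0
    for chrom, size in sizes.items():
        spacing = max(size // max(n_genes // len(sizes), 1), gene_length + 1)
        start = spacing // 4
        while start + gene_length < size and i < n_genes:
            strand = "+" if rng.uniform() < 0.5 else "-"
            genes.append(GeneModel(f"gene_{i:04d}", chrom, strand, start, start + gene_length))
            i += 1
            start += spacing
    return genes


def simulate_expression(
    config: SimConfig,
    genes: Sequence[GeneModel],
    truth: pd.DataFrame,
    upstream: int = 2000,
) -> tuple[pd.DataFrame, set[str], pd.DataFrame]:
    """DEG table plus expressed-gene universe, with genes near planted
    hypomethylated DMRs up-weighted as DEGs.

    Returns (deg table: gene_id/log2fc/fdr, expressed gene ids, per-gene
    truth with the coupling flag).
    """
    from .assoc import dmr_associated_genes
    from .dmr import MethRegion

    rng = _rng(config, 5)
    hypo = truth[truth["direction"] == "hypo"]
    pseudo = [
        MethRegion(r.chrom, int(r.start), int(r.end), r.context, 1, 0.0, 0.0, -0.1, "hypo")
        for r in hypo.itertuples(index=False)
    ]
    coupled = dmr_associated_genes(pseudo, genes, upstream=upstream)
    rows = []
    truth_rows = []
    for g in genes:
        is_coupled = g.gene_id in coupled
        p_deg = config.deg_p_coupled if is_coupled else config.deg_p_background
        is_deg = rng.uniform() < p_deg
        if is_deg:
            up = rng.uniform() < (config.frac_up_in_hypo if is_coupled else 0.5)
            mag = 1.0 + rng.exponential(0.8)
            log2fc = mag if up else -mag
            fdr = rng.uniform(0.0, 0.049)
        else:
            log2fc = float(np.clip(rng.normal(0.0, 0.4), -0.99, 0.99))
            fdr = rng.uniform(0.05, 1.0)
        rows.append({"gene_id": g.gene_id, "log2fc": log2fc, "fdr": fdr})
        truth_rows.append(
            {"gene_id": g.gene_id, "coupled": is_coupled, "planted_deg": is_deg}
        )
    deg_table = pd.DataFrame(rows)
    expressed = {g.gene_id for g in genes}
    return deg_table, expressed, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Alignments


@dataclass(frozen=True)
class AlignmentTruth:
    pi_derived: float
    pi_ancestral: float
    ratio: float
    demography: popgen.DemographyModel
    theta: float


def simulate_alignments(
    config: SimConfig,
    demography: popgen.DemographyModel | None = None,
    n_derived: int = 20,
    n_ancestral: int = 21,
    length: int = 360,
    theta: float = 5.0,
    rho: float = 0.0,
) -> tuple[PopAlignment, AlignmentTruth]:
    """Maize-class + teosinte alignments for one locus.

    The teosinte sample evolves at constant size, the maize sample under the
    bottleneck; both genealogies are rendered as biallelic substitutions on
    a shared random 360-bp reference. theta is per locus, estimated in the
    real study from the teosinte data.
    """
    if demography is None:
        demography = popgen.DemographyModel()
    rng = _rng(config, 6)
    der = popgen.simulate_coalescent(n_derived, theta, rho, demography, 1, rng)[0]
    anc = popgen.simulate_coalescent(
        n_ancestral, theta, rho, popgen.DemographyModel.constant(demography.ancestral_size), 1, rng
    )[0]
    ref = rng.choice(np.array(list("ACGT")), size=length)
    ref_str = "".join(ref)
    aln_der = popgen.replicate_to_alignment(
        der, length, rng, labels="maize", id_prefix="maize_", reference=ref_str
    )
    aln_anc = popgen.replicate_to_alignment(
        anc, length, rng, labels="teosinte", id_prefix="teosinte_", reference=ref_str
    )
    combined = PopAlignment(
        aln_der.ids + aln_anc.ids, aln_der.seqs + aln_anc.seqs, aln_der.labels + aln_anc.labels
    )
    pi_d = popgen.pairwise_pi(aln_der)
    pi_a = popgen.pairwise_pi(aln_anc)
    ratio = pi_d / pi_a if pi_a > 0 else float("nan")
    return combined, AlignmentTruth(pi_d, pi_a, ratio, demography, theta)
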