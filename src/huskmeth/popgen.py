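"""Nucleotide diversity, Watterson's theta, and a coalescent selection test.

Diversity (pi) is the mean pairwise per-site difference with pairwise
deletion of gaps/Ns; the sliding profile uses a 100-bp window with a 25-bp
step and drops any trailing partial window. The retained-diversity ratio
pi_derived / pi_ancestral (pi_M / pi_T for maize vs teosinte) is compared
against its distribution under a neutral domestication bottleneck, obtained
from an ms-style coalescent simulator written here: piecewise-constant
population sizes, infinite-sites mutations placed as a Poisson process on
the ancestral material, and (optionally) crossover recombination via the
ancestral recombination graph. A ratio in the lower tail of the neutral
distribution indicates diversity loss beyond what the bottleneck explains,
i.e. selection.

Time and rate conventions: the simulator's internal clock runs in units of
2N0 generations, so k lineages in an epoch of relative size s coalesce at
rate C(k,2)/s and the expected number of segregating sites is
theta * a_{n-1} with theta = 4*N0*mu per locus. :class:`DemographyModel`
accepts epoch times in units of 4N0 generations (the ms convention) and
converts internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import PopAlignment, ValidationError

_VALID_BASES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# Diversity from alignments


def _pair_pi(a: str, b: str) -> tuple[int, int]:
    """(differences, comparable sites) for one sequence pair, pairwise
    deletion: a site is comparable iff neither sequence has N or a gap."""
    diffs = comp = 0
    for ca, cb in zip(a, b):
        if ca in _VALID_BASES and cb in _VALID_BASES:
            comp += 1
            if ca != cb:
                diffs += 1
    return diffs, comp


def pairwise_pi(alignment: PopAlignment) -> float:
    """Nucleotide diversity per site: mean over all sequence pairs of
    (differences / comparable sites)."""
    n = alignment.n_seqs
    if n < 2:
        raise ValidationError("diversity needs >= 2 sequences")
    ratios = []
    skipped = 0
    for i in range(n):
        for j in range(i + 1, n):
            d, c = _pair_pi(alignment.seqs[i], alignment.seqs[j])
            if c == 0:
                skipped += 1
                continue
            ratios.append(d / c)
    if skipped:
        warnings.warn(f"{skipped} sequence pair(s) had no comparable sites; skipped")
    if not ratios:
        raise ValidationError("no sequence pair with comparable sites")
    return float(np.mean(ratios))


@dataclass(frozen=True)
class DiversityProfile:
    windows: tuple[tuple[int, int, float], ...]  # (start, end, pi)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.windows, columns=["start", "end", "pi"])


def sliding_pi(alignment: PopAlignment, window: int = 100, step: int = 25) -> DiversityProfile:
    """Sliding-window pi profile (no trailing partial window)."""
    L = alignment.length
    if window > L:
        raise ValidationError(f"window {window} exceeds alignment length {L}")
    out = []
    for start in range(0, L - window + 1, step):
        sub = PopAlignment(
            list(alignment.ids),
            [s[start : start + window] for s in alignment.seqs],
            list(alignment.labels),
        )
        out.append((start, start + window, pairwise_pi(sub)))
    return DiversityProfile(tuple(out))


def segregating_sites(alignment: PopAlignment) -> int:
    """Number of columns with >= 2 distinct valid bases (gaps/Ns ignored)."""
    mat = alignment.matrix()
    s = 0
    for col in mat.T:
        bases = {c for c in col if c in _VALID_BASES}
        if len(bases) >= 2:
            s += 1
    return s


def watterson_theta(n: int, s: int, length: float = 1.0) -> float:
    """Watterson's estimator theta_W = S / (a_{n-1} * L)."""
    if n < 2:
        raise ValidationError("Watterson's theta needs n >= 2")
    if s < 0 or length <= 0:
        raise ValidationError("need S >= 0 and L > 0")
    a = harmonic_a(n)
    return s / (a * length)


def harmonic_a(n: int) -> float:
    """a_{n-1} = sum_{i=1..n-1} 1/i."""
    return float(sum(1.0 / i for i in range(1, n)))


def watterson_theta_from_alignment(alignment: PopAlignment, per_site: bool = True) -> float:
    L = alignment.length if per_site else 1.0
    return watterson_theta(alignment.n_seqs, segregating_sites(alignment), L)


def diversity_ratio(aln_derived: PopAlignment, aln_ancestral: PopAlignment) -> float:
    """pi(derived)/pi(ancestral); the fraction of diversity retained."""
    pi_a = pairwise_pi(aln_ancestral)
    if pi_a == 0:
        raise ValidationError("ancestral alignment is monomorphic; ratio undefined")
    return pairwise_pi(aln_derived) / pi_a


# ---------------------------------------------------------------------------
# Demography


@dataclass(frozen=True)
class DemographyModel:
    """Piecewise-constant size history with a single bottleneck.

    Sizes are relative to the present-day reference N0; epoch times are in
    units of 4*N0 generations (ms convention). The defaults encode a maize
    domestication bottleneck with ancestral N = 150,000: domestication 9,000
    generations ago (t_start = 9000/(4*150000) = 0.015), a 1,000-generation
    bottleneck (duration ~ 0.00167) at severity k = N_bottleneck/N_ancestral
    = 0.05. All three are ordinary parameters, not hidden constants.
    """

    t_start: float = 0.015
    duration: float = 0.0016667
    severity: float = 0.05
    ancestral_size: float = 1.0
    current_size: float = 1.0

    def __post_init__(self) -> None:
        if self.t_start < 0 or self.duration < 0:
            raise ValidationError("epoch times must be >= 0")
        if min(self.severity, self.ancestral_size, self.current_size) <= 0:
            raise ValidationError("population sizes must be > 0")

    @classmethod
    def constant(cls, size: float = 1.0) -> "DemographyModel":
        return cls(t_start=0.0, duration=0.0, severity=1.0, ancestral_size=size, current_size=size)

    def epochs(self) -> list[tuple[float, float]]:
        """[(epoch start time in 2N0 units, relative size), ...] backwards in
        time from the present."""
        t0 = 2.0 * self.t_start  # 4N -> 2N units
        t1 = 2.0 * (self.t_start + self.duration)
        eps = [(0.0, self.current_size)]
        if self.duration > 0 and self.severity != 1.0:
            eps.append((t0, self.severity * self.ancestral_size))
        eps.append((t1, self.ancestral_size))
        # collapse zero-length / redundant epochs
        out: list[tuple[float, float]] = []
        for t, s in eps:
            if out and t == out[-1][0]:
                out[-1] = (t, s)
            elif not out or s != out[-1][1]:
                out.append((t, s))
        return out


@dataclass
class CoalescentReplicate:
    """One simulated sample: haplotypes over segregating sites."""

    positions: np.ndarray  # in [0, 1), sorted
    matrix: np.ndarray  # (n_samples, S) of {0,1}

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def s(self) -> int:
        return self.matrix.shape[1]

    def pi(self) -> float:
        """Mean pairwise difference per locus."""
        n = self.n_samples
        if self.s == 0:
            return 0.0
        counts = self.matrix.sum(axis=0)
        return float(np.sum(2.0 * counts * (n - counts)) / (n * (n - 1)))


def _size_at(epochs: list[tuple[float, float]], t: float) -> tuple[float, float]:
    """(size at time t, time of the next epoch boundary or inf)."""
    for i in range(len(epochs) - 1, -1, -1):
        if t >= epochs[i][0]:
            nxt = epochs[i + 1][0] if i + 1 < len(epochs) else np.inf
            return epochs[i][1], nxt
    return epochs[0][1], epochs[1][0] if len(epochs) > 1 else np.inf


def _simulate_one(
    rng: np.random.Generator,
    n: int,
    theta: float,
    rho: float,
    epochs: list[tuple[float, float]],
) -> CoalescentReplicate:
    """One ms-style replicate via the ancestral recombination graph.

    Each lineage carries its ancestral material as a list of
    (start, end, sample-bitmask) segments on [0,1). Segments whose mask
    reaches all samples are at their local MRCA and are dropped. Mutations
    accrue along the way as a Poisson process of rate theta/2 per unit
    ancestral length per unit (2N0) time, each toggling the samples beneath
    the segment it lands on.
    """
    full = (1 << n) - 1
    lineages: list[list[tuple[float, float, int]]] = [
        [(0.0, 1.0, 1 << i)] for i in range(n)
    ]
    muts: list[tuple[float, int]] = []
    t = 0.0

    def material(lin) -> float:
        return sum(e - s for s, e, _ in lin)

    def span(lin) -> float:
        return lin[-1][1] - lin[0][0]

    while len(lineages) > 1:
        k = len(lineages)
        size, t_next = _size_at(epochs, t)
        lens = [material(lin) for lin in lineages]
        total_len = sum(lens)
        c_rate = k * (k - 1) / 2.0 / size
        spans = [span(lin) for lin in lineages] if rho > 0 else None
        r_rate = (rho / 2.0) * sum(spans) if rho > 0 else 0.0
        rate = c_rate + r_rate
        wait = rng.exponential(1.0 / rate)
        dt = min(wait, t_next - t)
        # mutations over (t, t + dt) with the current lineage set
        n_mut = rng.poisson(theta / 2.0 * dt * total_len)
        for _ in range(n_mut):
            u = rng.uniform(0.0, total_len)
            li = 0
            while u > lens[li]:
                u -= lens[li]
                li += 1
            for s, e, mask in lineages[li]:
                if u <= e - s:
                    muts.append((s + u, mask))
                    break
                u -= e - s
        if wait > t_next - t:
            t = t_next
            continue
        t += wait
        if rng.uniform() < c_rate / rate:
            i, j = rng.choice(k, size=2, replace=False)
            merged = _merge_segments(lineages[int(i)], lineages[int(j)], full)
            lineages = [lin for li, lin in enumerate(lineages) if li not in (int(i), int(j))]
            if merged:
                lineages.append(merged)
        else:
            u = rng.uniform(0.0, sum(spans))
            li = 0
            while u > spans[li]:
                u -= spans[li]
                li += 1
            lin = lineages[li]
            bp = lin[0][0] + u
            left = [(s, min(e, bp), m) for s, e, m in lin if s < bp]
            right = [(max(s, bp), e, m) for s, e, m in lin if e > bp]
            left = [(s, e, m) for s, e, m in left if e > s]
            right = [(s, e, m) for s, e, m in right if e > s]
            if left and right:
                lineages[li] = left
                lineages.append(right)

    muts = [(p, m) for p, m in muts if 0 < m < full]
    muts.sort(key=lambda x: x[0])
    positions = np.array([p for p, _ in muts], dtype=float)
    matrix = np.zeros((n, len(muts)), dtype=np.uint8)
    for col, (_, mask) in enumerate(muts):
        for i in range(n):
            if mask >> i & 1:
                matrix[i, col] = 1
    return CoalescentReplicate(positions, matrix)


def _merge_segments(a, b, full: int):
    """Coalesce two lineages' segment lists; overlapping material unions its
    sample masks, and segments covering every sample (local MRCA) drop out."""
    points = sorted({p for s, e, _ in a + b for p in (s, e)})
    out = []
    for lo, hi in zip(points, points[1:]):
        mask = 0
        for s, e, m in a:
            if s <= lo and hi <= e:
                mask |= m
        for s, e, m in b:
            if s <= lo and hi <= e:
                mask |= m
        if mask and mask != full:
            if out and out[-1][1] == lo and out[-1][2] == mask:
                out[-1] = (out[-1][0], hi, mask)
            else:
                out.append((lo, hi, mask))
    return out


def simulate_coalescent(
    n_samples: int,
    theta: float,
    rho: float = 0.0,
    demography: DemographyModel | None = None,
    n_reps: int = 1,
    seed: int | np.random.Generator | None = None,
) -> list[CoalescentReplicate]:
    """Simulate ``n_reps`` independent samples of ``n_samples`` haplotypes.

    theta and rho are per-locus (4*N0*mu and 4*N0*r); the demography defaults
    to constant size. Fully reproducible from the seed.
    """
    if n_samples < 1:
        raise ValidationError("need n_samples >= 1")
    if theta < 0 or rho < 0:
        raise ValidationError("theta and rho must be >= 0")
    if demography is None:
        demography = DemographyModel.constant()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    epochs = demography.epochs()
    return [_simulate_one(rng, n_samples, theta, rho, epochs) for _ in range(n_reps)]


# ---------------------------------------------------------------------------
# Selection test


@dataclass(frozen=True)
class SelectionTestResult:
    p_value: float
    obs_ratio: float
    ratios: np.ndarray  # simulated null pi_derived/pi_ancestral ratios
    n_reps: int
    n_redrawn: int  # replicates redrawn because the ancestral pi was 0


def selection_test(
    obs_ratio: float,
    n_derived: int,
    n_ancestral: int,
    theta_ancestral: float,
    rho: float = 0.0,
    demography: DemographyModel | None = None,
    n_reps: int = 1000,
    seed: int | np.random.Generator | None = None,
    statistic: str = "ratio",
) -> SelectionTestResult:
    """One-sided lower-tail test of the observed retained-diversity ratio
    against its neutral-bottleneck distribution.

    Each replicate simulates an independent derived sample under the
    bottleneck demography and an ancestral sample at constant size, both at
    theta_ancestral; the null statistic is pi_derived/pi_ancestral
    (``statistic='derived_pi'`` uses the derived pi alone). Replicates with
    a monomorphic ancestral sample are redrawn (counted). The p-value uses
    the add-one convention p = (1 + #{ratio <= obs}) / (n_reps + 1).
    """
    if obs_ratio < 0:
        raise ValidationError("observed ratio must be >= 0")
    if n_reps < 100:
        raise ValidationError("need n_reps >= 100 for a meaningful tail estimate")
    if demography is None:
        demography = DemographyModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    constant = DemographyModel.constant(demography.ancestral_size)
    ratios = np.empty(n_reps)
    n_redrawn = 0
    for i in range(n_reps):
        while True:
            der = simulate_coalescent(
                n_derived, theta_ancestral, rho, demography, 1, rng
            )[0]
            if statistic == "derived_pi":
                ratios[i] = der.pi()
                break
            anc = simulate_coalescent(
                n_ancestral, theta_ancestral, rho, constant, 1, rng
            )[0]
            pi_a = anc.pi()
            if pi_a > 0:
                ratios[i] = der.pi() / pi_a
                break
            n_redrawn += 1
    p = (1.0 + int(np.sum(ratios <= obs_ratio))) / (n_reps + 1.0)
    return SelectionTestResult(p, obs_ratio, ratios, n_reps, n_redrawn)


def replicate_to_alignment(
    rep: CoalescentReplicate,
    length: int,
    rng: np.random.Generator,
    labels: str = "pop",
    id_prefix: str = "hap",
    reference: str | None = None,
) -> PopAlignment:
    """Render a 0/1 replicate onto a nucleotide reference of ``length`` bp
    as biallelic substitutions (one column per segregating site)."""
    bases = np.array(list("ACGT"))
    if reference is None:
        ref = rng.choice(bases, size=length)
    else:
        ref = np.array(list(reference), dtype="U1")
        length = len(ref)
    if rep.s > length:
        raise ValidationError("more segregating sites than alignment columns")
    cols = np.sort(rng.choice(length, size=rep.s, replace=False))
    seqs = np.tile(ref, (rep.n_samples, 1))
    for j, col in enumerate(cols):
        alt_choices = [b for b in "ACGT" if b != ref[col]]
        alt = alt_choices[int(rng.integers(3))]
        carriers = rep.matrix[:, j] == 1
        seqs[carriers, col] = alt
    return PopAlignment(
        [f"{id_prefix}{i}" for i in range(rep.n_samples)],
        ["".join(row) for row in seqs],
        [labels] * rep.n_samples,
    )
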