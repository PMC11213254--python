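import numpy as np
import pytest

from huskmeth import dmr, simulate


@pytest.fixture(scope="session")
def population_fixture():
    """Default two-haplotype population methylomes with planted CHG DMRs."""
    cfg = simulate.SimConfig(seed=11)
    samples, sheet, truth = simulate.simulate_population_methylomes(cfg)
    return cfg, samples, sheet, truth


@pytest.fixture(scope="session")
def pair_fixture():
    """Default wild-type / mutant methylome pair with planted regions."""
    cfg = simulate.SimConfig(seed=11)
    wt, mut, truth = simulate.simulate_pair_methylomes(cfg)
    return cfg, wt, mut, truth


def overlaps_interval(region, interval) -> bool:
    chrom, start, end = interval
    return region.chrom == chrom and region.start < end and region.end > start


def recovery_rates(called, truth):
    """(sensitivity, off-target fraction) of calls against a truth table."""
    planted = [(r.chrom, int(r.start), int(r.end)) for r in truth.itertuples(index=False)]
    hits = sum(1 for p in planted if any(overlaps_interval(d, p) for d in called))
    off = sum(1 for d in called if not any(overlaps_interval(d, p) for p in planted))
    sens = hits / len(planted) if planted else float("nan")
    off_frac = off / len(called) if called else 0.0
    return sens, off_frac
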