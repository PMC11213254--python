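"""Independent straight-line re-implementations used as test oracles.

Everything here is deliberately written in plain dict/loop style,
materializing every intermediate table, so it shares no code path with the
package's vectorized implementations.
"""

from __future__ import annotations

import itertools
import math

from scipy.stats import t as t_dist


def window_site_lists(sample, context, min_cov, width=100):
    """(chrom, win) -> list of (n_meth, n_total) for sites passing min_cov."""
    out = {}
    for r in sample.data.itertuples(index=False):
        if r.context != context or r.n_total < min_cov:
            continue
        key = (r.chrom, (r.pos - 1) // width)
        out.setdefault(key, []).append((int(r.n_meth), int(r.n_total)))
    return out


def welch_oracle(x, y):
    n1, n2 = len(x), len(y)
    m1 = sum(x) / n1
    m2 = sum(y) / n2
    v1 = sum((v - m1) ** 2 for v in x) / (n1 - 1)
    v2 = sum((v - m2) ** 2 for v in y) / (n2 - 1)
    if v1 == 0 and v2 == 0:
        return 0.0, float(n1 + n2 - 2), 1.0
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return t, df, p


def merge_runs(keys):
    """Sorted (chrom, win) keys -> list of (chrom, first_win, last_win)."""
    runs = []
    for chrom, win in sorted(keys):
        if runs and runs[-1][0] == chrom and win == runs[-1][2] + 1:
            runs[-1][2] = win
        else:
            runs.append([chrom, win, win])
    return [(c, a, b) for c, a, b in runs]


def call_population_oracle(samples_by_group, context, params, reference, width=100):
    groups = list(samples_by_group)
    focal = next(g for g in groups if g != reference)
    ref_samples = list(samples_by_group[reference])
    foc_samples = list(samples_by_group[focal])

    ref_tables = [window_site_lists(s, context, params.min_site_cov, width) for s in ref_samples]
    foc_tables = [window_site_lists(s, context, params.min_site_cov, width) for s in foc_samples]

    all_windows = set()
    for t in ref_tables + foc_tables:
        all_windows |= set(t)

    min_sites = params.min_sites[context]
    thr = params.min_informative_fraction
    retained = []
    for key in sorted(all_windows):
        k_ref = sum(1 for t in ref_tables if len(t.get(key, [])) >= min_sites)
        k_foc = sum(1 for t in foc_tables if len(t.get(key, [])) >= min_sites)
        if k_ref / len(ref_samples) > thr and k_foc / len(foc_samples) > thr:
            retained.append(key)

    results = []
    for chrom, w0, w1 in merge_runs(retained):
        wins = set(range(w0, w1 + 1))

        def levels(tables):
            out = []
            for t in tables:
                meth = tot = 0
                for w in wins:
                    for m, n in t.get((chrom, w), []):
                        meth += m
                        tot += n
                if tot > 0:
                    out.append(meth / tot)
            return out

        x = levels(ref_tables)
        y = levels(foc_tables)
        if len(x) < 2 or len(y) < 2:
            continue
        t, df, p = welch_oracle(x, y)
        mean_a = sum(x) / len(x)
        mean_b = sum(y) / len(y)
        diff = mean_b - mean_a
        if p < params.alpha and abs(diff) > params.min_diff[context]:
            results.append(
                {
                    "chrom": chrom,
                    "start": w0 * width,
                    "end": (w1 + 1) * width,
                    "n_windows": w1 - w0 + 1,
                    "level_a": mean_a,
                    "level_b": mean_b,
                    "difference": diff,
                    "direction": "hypo" if diff < 0 else "hyper",
                    "p_value": p,
                }
            )
    return results


def call_pairwise_oracle(sample_wt, sample_mut, context, params, width=100):
    wt = window_site_lists(sample_wt, context, 0, width)
    mut = window_site_lists(sample_mut, context, 0, width)
    min_sites = params.min_sites[context]

    surviving = []
    for key in sorted(set(wt) & set(mut)):
        sw, sm = wt[key], mut[key]
        if len(sw) < min_sites or len(sm) < min_sites:
            continue
        if sum(n for _, n in sw) / len(sw) < params.min_avg_cov:
            continue
        if sum(n for _, n in sm) / len(sm) < params.min_avg_cov:
            continue
        lw = sum(m for m, _ in sw) / sum(n for _, n in sw)
        lm = sum(m for m, _ in sm) / sum(n for _, n in sm)
        d = lm - lw
        if context in ("CG", "CHG"):
            if abs(d) >= params.min_diff_cg_chg:
                surviving.append(key)
        else:
            if (
                abs(d) > params.chh_min_diff
                and min(lw, lm) < params.chh_low_max
                and max(lw, lm) > params.chh_high_min
            ):
                surviving.append(key)

    results = []
    for chrom, w0, w1 in merge_runs(surviving):
        wins = set(range(w0, w1 + 1))

        def region_level(table):
            meth = tot = 0
            for w in wins:
                for m, n in table.get((chrom, w), []):
                    meth += m
                    tot += n
            return meth / tot if tot else float("nan")

        la = region_level(wt)
        lb = region_level(mut)
        diff = lb - la
        results.append(
            {
                "chrom": chrom,
                "start": w0 * width,
                "end": (w1 + 1) * width,
                "n_windows": w1 - w0 + 1,
                "level_a": la,
                "level_b": lb,
                "difference": diff,
                "direction": "hypo" if diff < 0 else "hyper",
            }
        )
    return results


def yates_chi2_oracle(k1, n1, k2, n2):
    """Textbook 2x2 chi-square with continuity correction: the cell formula
    sum((|O-E| - 0.5)^2 / E) with the correction capped at |O-E|."""
    from scipy.stats import chi2 as chi2_dist

    obs = [[k1, n1 - k1], [k2, n2 - k2]]
    total = n1 + n2
    col = [k1 + k2, total - k1 - k2]
    row = [n1, n2]
    chi2 = 0.0
    for i in range(2):
        for j in range(2):
            e = row[i] * col[j] / total
            adj = max(abs(obs[i][j] - e) - 0.5, 0.0)
            chi2 += adj * adj / e
    return chi2, float(chi2_dist.sf(chi2, 1))


def mann_whitney_exact_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group labelings."""
    pooled = list(x) + list(y)
    n1 = len(x)
    m = n1 * len(y)

    def u_of(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    u_obs = u_of(x, y)
    us = [
        u_of([pooled[i] for i in comb], [pooled[i] for i in range(len(pooled)) if i not in comb])
        for comb in itertools.combinations(range(len(pooled)), n1)
    ]
    lo, hi = min(u_obs, m - u_obs), max(u_obs, m - u_obs)
    p = (sum(1 for u in us if u <= lo) + sum(1 for u in us if u >= hi)) / len(us)
    return u_obs, min(p, 1.0)


def pi_oracle(seqs):
    """Mean over pairs of per-site differences, pairwise deletion."""
    valid = set("ACGT")
    vals = []
    n = len(seqs)
    for i in range(n):
        for j in range(i + 1, n):
            d = c = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in valid and b in valid:
                    c += 1
                    if a != b:
                        d += 1
            if c:
                vals.append(d / c)
    return sum(vals) / len(vals)


def random_methylome(rng, n_win, context="CHG", width=100, max_sites=5, chrom="c1"):
    """A random small sample for oracle-equivalence fuzzing."""
    import pandas as pd

    rows = []
    for w in range(n_win):
        n_sites = int(rng.integers(0, max_sites + 1))
        if n_sites == 0:
            continue
        positions = rng.choice(width, size=n_sites, replace=False)
        for off in positions:
            cov = int(rng.poisson(3))
            meth = int(rng.binomial(cov, rng.uniform())) if cov else 0
            rows.append((chrom, w * width + int(off) + 1, "+", context, meth, cov))
    if not rows:
        rows = [(chrom, 1, "+", context, 0, 0)]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_total"])
    return df
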