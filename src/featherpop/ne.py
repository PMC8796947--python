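"""Effective population size from linkage disequilibrium, and demographic
parameter conversions from scaled coalescent outputs.

The LD method estimates Ne from the Burrows composite disequilibrium
between unlinked locus pairs: after removing the sampling expectation
E[r^2 | S], the residual r^2 reflects drift in a finite parental pool.
The monogamy mating model roughly doubles the estimate relative to random
mating, appropriate for species with lifetime pair bonds.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

Pair = Tuple[int, int]


def burrows_r2(genos1: Sequence[Optional[Pair]], genos2: Sequence[Optional[Pair]],
               p_crit: float = 0.05) -> Tuple[List[float], int]:
    """Burrows-Delta based squared correlations for one locus pair.

    Returns (r^2 per retained allele pair, S = individuals typed at both).
    Alleles with frequency below ``p_crit`` (or above 1 - p_crit) among the
    jointly typed individuals are excluded.
    """
    mask = [g1 is not None and g2 is not None for g1, g2 in zip(genos1, genos2)]
    g1 = [g for g, m in zip(genos1, mask) if m]
    g2 = [g for g, m in zip(genos2, mask) if m]
    s = len(g1)
    if s < 2:
        return [], s

    def screened_alleles(genos):
        counts = Counter(a for g in genos for a in g)
        total = sum(counts.values())
        return [a for a, c in counts.items()
                if p_crit <= c / total <= 1 - p_crit]

    out: List[float] = []
    for a in sorted(screened_alleles(g1)):
        x = np.array([(g[0] == a) + (g[1] == a) for g in g1], dtype=float)
        p = x.mean() / 2
        # homozygote-excess adjusted variance (Weir's composite denominator)
        paa = np.mean(x == 2)
        da = paa - p * p
        var_a = p * (1 - p) + da
        if var_a <= 0:
            continue
        for b in sorted(screened_alleles(g2)):
            y = np.array([(g[0] == b) + (g[1] == b) for g in g2], dtype=float)
            q = y.mean() / 2
            pbb = np.mean(y == 2)
            db = pbb - q * q
            var_b = q * (1 - q) + db
            if var_b <= 0:
                continue
            delta = (np.mean(x * y) / 2 - 2 * p * q) * s / (s - 1)
            out.append(float(delta ** 2 / (var_a * var_b)))
    return out, s


def expected_r2_sample(s: float) -> float:
    """Sampling expectation E[r^2 | S] (Waples 2006 regressions)."""
    if s >= 30:
        return 1.0 / s + 3.19 / s ** 2
    return 0.0018 + 0.907 / s + 4.44 / s ** 2


def ne_from_r2prime(r2p: float, s: float, mating: str) -> float:
    """Invert the drift relation r^2' ~ f(Ne, S) to an Ne point estimate."""
    if r2p <= 0:
        return math.inf
    if mating == "monogamy":
        if s >= 30:
            disc = 4.0 / 9.0 - 7.2 * r2p
            if disc < 0:
                return math.inf if r2p < 0 else (2.0 / 3.0) / (2 * r2p)
            return (2.0 / 3.0 + math.sqrt(disc)) / (2 * r2p)
        disc = 0.618 ** 2 - 5.24 * r2p
        return (0.618 + math.sqrt(max(disc, 0.0))) / (2 * r2p)
    if mating == "random":
        if s >= 30:
            disc = 1.0 / 9.0 - 2.76 * r2p
            if disc < 0:
                return (1.0 / 3.0) / (2 * r2p)
            return (1.0 / 3.0 + math.sqrt(disc)) / (2 * r2p)
        disc = 0.308 ** 2 - 2.08 * r2p
        return (0.308 + math.sqrt(max(disc, 0.0))) / (2 * r2p)
    raise ValueError(f"unknown mating model {mating!r}")


@dataclass
class NeEstimate:
    ne: float
    r2_mean: float
    r2_expected: float
    r2_prime: float
    s_harmonic: float
    mating: str
    p_crit: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    n_locus_pairs: int = 0


def ld_ne(genotypes: Dict[str, List[Optional[Pair]]], p_crit: float = 0.05,
          mating: str = "monogamy", jackknife: bool = True) -> NeEstimate:
    """LD effective population size (Waples & Do 2008 style).

    r^2 is averaged over all locus pairs and retained allele pairs,
    weighted by the joint sample size S; the harmonic mean S sets
    E[r^2 | S]; Ne from r^2' = r^2 - E[r^2|S] under the chosen mating
    model.  Non-positive r^2' reports Ne = inf.  CI by leave-one-locus-out
    jackknife on the weighted mean r^2.
    """
    loci = [l for l in genotypes if len({a for g in genotypes[l] if g for a in g}) >= 2]
    if len(loci) < 2:
        raise ValueError("need >= 2 polymorphic loci")
    per_pair: Dict[Tuple[str, str], Tuple[List[float], int]] = {}
    for l1, l2 in combinations(loci, 2):
        r2s, s = burrows_r2(genotypes[l1], genotypes[l2], p_crit)
        if r2s:
            per_pair[(l1, l2)] = (r2s, s)
    if not per_pair:
        raise ValueError("no informative locus pairs after allele screening")

    def summarize(pairs) -> Tuple[float, float]:
        wsum = r2sum = 0.0
        hw = hs = 0.0
        for r2s, s in pairs:
            w = len(r2s) * s
            wsum += w
            r2sum += s * sum(r2s)
            hw += len(r2s)
            hs += len(r2s) / s
        return r2sum / wsum, hw / hs

    r2_mean, s_harm = summarize(per_pair.values())
    e_r2 = expected_r2_sample(s_harm)
    r2p = r2_mean - e_r2
    ne = ne_from_r2prime(r2p, s_harm, mating)
    est = NeEstimate(ne=ne, r2_mean=r2_mean, r2_expected=e_r2, r2_prime=r2p,
                     s_harmonic=s_harm, mating=mating, p_crit=p_crit,
                     n_locus_pairs=len(per_pair))
    if jackknife and len(loci) > 2:
        jk = []
        for drop in loci:
            pairs = [v for k, v in per_pair.items() if drop not in k]
            if pairs:
                jk.append(summarize(pairs)[0])
        jk = np.array(jk)
        n_jk = len(jk)
        var = (n_jk - 1) / n_jk * float(np.sum((jk - jk.mean()) ** 2))
        half = 1.96 * math.sqrt(var)
        lo_r2 = r2_mean - half
        hi_r2 = r2_mean + half
        # Ne is monotone decreasing in r^2
        est.ci_low = ne_from_r2prime(hi_r2 - e_r2, s_harm, mating)
        est.ci_high = ne_from_r2prime(lo_r2 - e_r2, s_harm, mating)
    return est


# ---------------------------------------------------------------------------
# demographic parameter conversions

def _round_half_up(x: float) -> int:
    # round to 6 decimals first so accumulated fp error cannot flip a .5
    return int(math.floor(round(x, 6) + 0.5))


@dataclass
class DemographicParams:
    theta: float
    theta_anc: float
    scaled_time: float       # D = T / (2N)
    mu: float = 5e-4         # per locus per generation
    generation_years: Tuple[float, float] = (5.0, 7.5)


@dataclass
class DemographicEstimates:
    n_current: float
    n_ancestral: float
    t_generations: float
    years_range: Tuple[int, int]
    n_ratio: float


def demographic_convert(params: DemographicParams) -> DemographicEstimates:
    """Resolve census-scale demographic quantities from scaled coalescent
    parameters: N = theta/(2 mu), N_anc = theta_anc/(2 mu), T = D * 2N,
    years = T x generation-time endpoints (rounded half up)."""
    if params.mu <= 0 or params.theta <= 0 or params.theta_anc <= 0:
        raise ValueError("theta, theta_anc and mu must be positive")
    if params.scaled_time <= 0 or min(params.generation_years) <= 0:
        raise ValueError("scaled time and generation times must be positive")
    n = params.theta / (2 * params.mu)
    n_anc = params.theta_anc / (2 * params.mu)
    t = params.scaled_time * 2 * n
    g_lo, g_hi = sorted(params.generation_years)
    return DemographicEstimates(
        n_current=n, n_ancestral=n_anc, t_generations=t,
        years_range=(_round_half_up(t * g_lo), _round_half_up(t * g_hi)),
        n_ratio=n / n_anc,
    )


def ne_census_ratio(ne: float, census_range: Tuple[float, float]) -> Tuple[float, float]:
    """Ne/N ratio range, rounded to 2 decimals (low census gives the high
    ratio)."""
    lo, hi = sorted(census_range)
    if lo <= 0:
        raise ValueError("census sizes must be positive")
    return (round(ne / hi, 2), round(ne / lo, 2))


def extrapolate_n(ne: float, ratio_range: Tuple[float, float]) -> Tuple[int, int]:
    """Census size range implied by Ne and an assumed Ne/N ratio range."""
    lo, hi = sorted(ratio_range)
    if lo <= 0:
        raise ValueError("ratios must be positive")
    return (_round_half_up(ne / hi), _round_half_up(ne / lo))
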