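"""Locus-level quality control.

Null-allele frequencies (EM under the recessive-null model), Hardy-Weinberg
exact tests (Levene-conditional probability test), genotypic linkage
disequilibrium (permutation G-test), sequential-Bonferroni (Holm) and
Fisher combination of p-values, and the locus-filtering rules used to build
the final marker panel.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datamodel import PopulationDataset


# ---------------------------------------------------------------------------
# allele / genotype count tables

@dataclass
class LocusTable:
    """Per-locus, per-region genotype and allele counts with frequencies."""

    genotype_counts: Dict[str, Dict[str, Counter]]  # region -> locus -> Counter
    allele_counts: Dict[str, Dict[str, Counter]]
    n_typed: Dict[str, Dict[str, int]]

    def freqs(self, region: str, locus: str) -> Dict[int, float]:
        counts = self.allele_counts[region][locus]
        total = sum(counts.values())
        return {a: c / total for a, c in counts.items()} if total else {}

    def pooled_freqs(self, locus: str) -> Dict[int, float]:
        pooled: Counter = Counter()
        for region in self.allele_counts:
            pooled.update(self.allele_counts[region][locus])
        total = sum(pooled.values())
        return {a: c / total for a, c in pooled.items()} if total else {}


def build_locus_table(dataset: PopulationDataset) -> LocusTable:
    geno: Dict[str, Dict[str, Counter]] = {}
    alle: Dict[str, Dict[str, Counter]] = {}
    n_typed: Dict[str, Dict[str, int]] = {}
    for region, inds in dataset.by_region().items():
        geno[region] = {l: Counter() for l in dataset.locus_names}
        alle[region] = {l: Counter() for l in dataset.locus_names}
        n_typed[region] = {l: 0 for l in dataset.locus_names}
        for ind in inds:
            for locus in dataset.locus_names:
                pair = ind.consensus.get(locus)
                if pair is None:
                    continue
                geno[region][locus][pair] += 1
                alle[region][locus][pair[0]] += 1
                alle[region][locus][pair[1]] += 1
                n_typed[region][locus] += 1
    return LocusTable(genotype_counts=geno, allele_counts=alle, n_typed=n_typed)


# ---------------------------------------------------------------------------
# null alleles

def _null_likelihood(geno_counts: Dict[Tuple[int, int], int],
                     vis_freqs: Dict[int, float], p0: float) -> float:
    """Log-likelihood of observed genotypes under HWE with a null allele at
    frequency p0 (observed homozygote ii is true ii or i/null; the
    blank-class count is zero so its factor is 1)."""
    ll = 0.0
    for (a, b), n in geno_counts.items():
        pa = vis_freqs.get(a, 0.0)
        if a == b:
            prob = pa * pa + 2 * pa * p0
        else:
            prob = 2 * pa * vis_freqs.get(b, 0.0)
        if prob <= 0:
            return -math.inf
        ll += n * math.log(prob)
    return ll


def null_allele_em(geno_counts: Dict[Tuple[int, int], int],
                   tol: float = 1e-6, max_iter: int = 10_000) -> float:
    """ML null-allele frequency by EM under the recessive-null model.

    Each observed homozygote ii is a mixture of a true homozygote and a
    visible/null heterozygote; the E-step splits its two allele copies
    accordingly, the M-step re-estimates frequencies from expected counts.
    Converges when the null-frequency update changes by < ``tol``.
    """
    n_total = sum(geno_counts.values())
    if n_total == 0:
        raise ValueError("no typed genotypes at locus")
    alleles = sorted({a for pair in geno_counts for a in pair})
    if len(alleles) < 2 and all(a == b for a, b in geno_counts):
        # monomorphic visible data: null frequency unidentifiable
        return 0.0
    # init: uniform visible freqs, small null
    p = {a: (1.0 - 0.05) / len(alleles) for a in alleles}
    p0 = 0.05
    for _ in range(max_iter):
        counts = {a: 0.0 for a in alleles}
        c0 = 0.0
        for (a, b), n in geno_counts.items():
            if a == b:
                denom = p[a] ** 2 + 2 * p[a] * p0
                if denom <= 0:
                    w_null = 0.0
                else:
                    w_null = 2 * p[a] * p0 / denom
                counts[a] += n * (2 - w_null)
                c0 += n * w_null
            else:
                counts[a] += n
                counts[b] += n
        total = 2 * n_total
        new_p0 = c0 / total
        new_p = {a: c / total for a, c in counts.items()}
        delta = abs(new_p0 - p0)
        p, p0 = new_p, new_p0
        if delta < tol:
            break
    return p0


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test

def _levene_log_prob(table: Dict[Tuple[int, int], int]) -> float:
    """Log conditional probability of a genotype table given its allele
    counts (Levene 1949)."""
    n = sum(table.values())
    allele: Counter = Counter()
    n_het = 0
    for (a, b), cnt in table.items():
        allele[a] += cnt
        allele[b] += cnt
        if a != b:
            n_het += cnt
    lp = math.lgamma(n + 1) + n_het * math.log(2)
    for cnt in table.values():
        lp -= math.lgamma(cnt + 1)
    for c in allele.values():
        lp += math.lgamma(c + 1)
    lp -= math.lgamma(2 * n + 1)
    return lp


def _enumerate_tables(allele_counts: List[int], budget: List[int]):
    """Yield all genotype tables (dict cell -> count) with the given allele
    count margins, by recursion over cells; raises if the budget runs out."""
    k = len(allele_counts)
    cells = [(i, j) for i in range(k) for j in range(i, k)]

    def rec(idx: int, remaining: List[int], table: Dict[Tuple[int, int], int]):
        budget[0] -= 1
        if budget[0] < 0:
            raise RuntimeError("enumeration budget exceeded")
        if idx == len(cells):
            if all(r == 0 for r in remaining):
                yield dict(table)
            return
        i, j = cells[idx]
        if i == j:
            cap = remaining[i] // 2
        else:
            cap = min(remaining[i], remaining[j])
        for c in range(cap + 1):
            remaining[i] -= c * (2 if i == j else 1)
            if i != j:
                remaining[j] -= c
            if c:
                table[(i, j)] = c
            yield from rec(idx + 1, remaining, table)
            if c:
                del table[(i, j)]
            remaining[i] += c * (2 if i == j else 1)
            if i != j:
                remaining[j] += c

    yield from rec(0, list(allele_counts), {})


def hwe_exact_test(geno_counts: Dict[Tuple[int, int], int],
                   n_mc: int = 10_000, seed: int = 0,
                   enum_budget: int = 200_000) -> float:
    """Exact HWE probability test conditional on allele counts.

    p = sum of Levene probabilities of all tables as or less probable than
    the observed one; tables are completely enumerated when feasible
    (few alleles, small samples), and sampled by seeded Monte-Carlo pairing
    of the allele vector otherwise.  Monomorphic loci return p = 1.
    """
    table = {tuple(sorted(k)): v for k, v in geno_counts.items() if v > 0}
    alleles = sorted({a for pair in table for a in pair})
    if len(alleles) < 2:
        return 1.0
    index = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    itable = {(index[a], index[b]): v for (a, b), v in table.items()}
    margins = [0] * k
    for (i, j), cnt in itable.items():
        margins[i] += cnt
        margins[j] += cnt
    n = sum(itable.values())
    lp_obs = _levene_log_prob(itable)
    eps = 1e-9
    if k <= 3 or (k == 4 and n <= 20):
        try:
            total = 0.0
            for t in _enumerate_tables(margins, [enum_budget]):
                lp = _levene_log_prob(t)
                if lp <= lp_obs + eps:
                    total += math.exp(lp)
            return min(1.0, total)
        except RuntimeError:
            pass
    # vectorized Monte Carlo over random pairings of the allele vector;
    # margin-dependent factors are constant, so only the variable part of
    # the Levene log-probability is compared
    rng = np.random.default_rng(seed)
    vec = np.concatenate([np.full(margins[i], i, dtype=np.int64) for i in range(k)])
    lgam = [math.lgamma(c + 1) for c in range(n + 1)]

    def variable_part(counts: np.ndarray, n_het: np.ndarray) -> np.ndarray:
        lg = np.array(lgam)
        return n_het * math.log(2) - lg[counts].sum(axis=1)

    obs_counts = np.zeros(k * k, dtype=np.int64)
    n_het_obs = 0
    for (i, j), cnt in itable.items():
        obs_counts[i * k + j] = cnt
        if i != j:
            n_het_obs += cnt
    vp_obs = float(n_het_obs * math.log(2)
                   - sum(lgam[c] for c in obs_counts if c))
    keys = np.argsort(rng.random((n_mc, 2 * n)), axis=1)
    shuffled = vec[keys]
    a = np.minimum(shuffled[:, 0::2], shuffled[:, 1::2])
    b = np.maximum(shuffled[:, 0::2], shuffled[:, 1::2])
    cell = a * k + b
    offsets = (np.arange(n_mc)[:, None] * (k * k))
    flat = np.bincount((cell + offsets).ravel(), minlength=n_mc * k * k)
    counts = flat.reshape(n_mc, k * k)
    n_het = (a != b).sum(axis=1)
    vp = variable_part(counts, n_het)
    hits = int(np.sum(vp <= vp_obs + eps))
    return (hits + 1) / (n_mc + 1)


# ---------------------------------------------------------------------------
# linkage disequilibrium

def ld_test(geno1: Sequence[Optional[Tuple[int, int]]],
            geno2: Sequence[Optional[Tuple[int, int]]],
            n_perm: int = 10_000, seed: int = 0) -> float:
    """Genotypic LD: permutation p-value of the G statistic on the
    two-locus genotype contingency table (single-locus genotypes of one
    locus permuted among individuals)."""
    pairs = [(g1, g2) for g1, g2 in zip(geno1, geno2)
             if g1 is not None and g2 is not None]
    if len(pairs) < 2:
        raise ValueError("fewer than 2 individuals typed at both loci")
    a = [p[0] for p in pairs]
    b = [p[1] for p in pairs]

    def g_stat(x: Sequence, y: Sequence) -> float:
        n = len(x)
        cx, cy = Counter(x), Counter(y)
        joint = Counter(zip(x, y))
        g = 0.0
        for (gx, gy), o in joint.items():
            e = cx[gx] * cy[gy] / n
            g += o * math.log(o / e)
        return 2 * g

    if len(set(a)) < 2 or len(set(b)) < 2:
        return 1.0
    obs = g_stat(a, b)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        idx = rng.permutation(len(b))
        if g_stat(a, [b[j] for j in idx]) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# multiple testing

def sequential_bonferroni(pvals: Sequence[float], alpha: float = 0.05) -> List[bool]:
    """Holm step-down: sort ascending, reject while p_(i) < alpha/(k-i+1)."""
    k = len(pvals)
    order = sorted(range(k), key=lambda i: pvals[i])
    flags = [False] * k
    for rank, i in enumerate(order):
        if pvals[i] < alpha / (k - rank):
            flags[i] = True
        else:
            break
    return flags


def fishers_combine(pvals: Sequence[float]) -> Tuple[float, int, float]:
    """Fisher's method: X2 = -2 * sum(ln p), df = 2k."""
    from scipy import stats
    for p in pvals:
        if p <= 0:
            raise ValueError("p = 0 cannot be combined; bound it away from zero")
        if p > 1:
            raise ValueError("p-values must be in (0, 1]")
    x2 = -2.0 * sum(math.log(p) for p in pvals)
    df = 2 * len(pvals)
    return x2, df, float(stats.chi2.sf(x2, df))


# ---------------------------------------------------------------------------
# locus filtering

@dataclass
class LocusQCReport:
    null_per_region: Dict[str, Dict[str, float]]   # locus -> region -> null
    hwe_per_region: Dict[str, Dict[str, float]]    # locus -> region -> p
    missing_fraction: Dict[str, float]
    minor_allele_count: Dict[str, int]
    decision: Dict[str, str] = field(default_factory=dict)  # keep / drop:<reason>


def qc_report(dataset: PopulationDataset, seed: int = 0) -> LocusQCReport:
    """Compute the per-locus QC inputs: null frequency and HWE p per region,
    overall missing fraction, overall minor-allele count."""
    table = build_locus_table(dataset)
    regions = list(table.genotype_counts)
    null_pr: Dict[str, Dict[str, float]] = {}
    hwe_pr: Dict[str, Dict[str, float]] = {}
    missing: Dict[str, float] = {}
    mac: Dict[str, int] = {}
    n_ind = len(dataset.individuals)
    for li, locus in enumerate(dataset.locus_names):
        null_pr[locus] = {}
        hwe_pr[locus] = {}
        for region in regions:
            counts = dict(table.genotype_counts[region][locus])
            if counts:
                null_pr[locus][region] = null_allele_em(counts)
                hwe_pr[locus][region] = hwe_exact_test(
                    counts, seed=(seed + 7919 * li) % (2 ** 31))
        typed = sum(table.n_typed[r][locus] for r in regions)
        missing[locus] = 1.0 - typed / n_ind if n_ind else 0.0
        pooled: Counter = Counter()
        for r in regions:
            pooled.update(table.allele_counts[r][locus])
        if len(pooled) >= 2:
            mac[locus] = sorted(pooled.values())[-2] if len(pooled) == 2 else \
                sum(pooled.values()) - max(pooled.values())
            # minor allele count = copies not belonging to the major allele
            mac[locus] = sum(pooled.values()) - max(pooled.values())
        else:
            mac[locus] = 0
    return LocusQCReport(null_per_region=null_pr, hwe_per_region=hwe_pr,
                         missing_fraction=missing, minor_allele_count=mac)


def filter_loci(dataset: PopulationDataset, report: LocusQCReport,
                min_minor_allele_count: int = 2,
                max_missing: float = 0.40,
                max_null: float = 0.10,
                alpha: float = 0.05) -> List[str]:
    """Apply the locus-filtering rules and fill in per-locus decisions.

    Drop order (first triggering rule justifies the decision): low
    polymorphism, missing fraction above threshold, mean null frequency
    above threshold, HWE rejected (Holm-corrected within region) in every
    region.  Returns the retained locus list.
    """
    regions = sorted({r for by in report.hwe_per_region.values() for r in by})
    # Holm per region across loci
    hwe_reject: Dict[str, Dict[str, bool]] = {l: {} for l in dataset.locus_names}
    for region in regions:
        loci_here = [l for l in dataset.locus_names
                     if region in report.hwe_per_region.get(l, {})]
        pvals = [report.hwe_per_region[l][region] for l in loci_here]
        flags = sequential_bonferroni(pvals, alpha=alpha)
        for l, f in zip(loci_here, flags):
            hwe_reject[l][region] = f
    retained: List[str] = []
    for locus in dataset.locus_names:
        if report.minor_allele_count.get(locus, 0) < min_minor_allele_count:
            report.decision[locus] = "drop:low_polymorphism"
        elif report.missing_fraction.get(locus, 0.0) > max_missing:
            report.decision[locus] = "drop:missing"
        elif np.mean(list(report.null_per_region.get(locus, {0: 0.0}).values() or [0.0])) > max_null:
            report.decision[locus] = "drop:null_alleles"
        elif hwe_reject[locus] and all(hwe_reject[locus].get(r, False) for r in regions):
            report.decision[locus] = "drop:hwe_all_regions"
        else:
            report.decision[locus] = "keep"
            retained.append(locus)
    return retained
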