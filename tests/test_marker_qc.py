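"""Null-allele EM, HWE exact test, LD test, multiple testing and the
locus-filtering rules."""

import math
from collections import Counter

import numpy as np
import pytest
from scipy.optimize import minimize

from featherpop.datamodel import Genotype, Individual, Locus, PopulationDataset
from featherpop.marker_qc import (LocusQCReport, build_locus_table,
                                  fishers_combine, filter_loci,
                                  hwe_exact_test, ld_test, null_allele_em,
                                  qc_report, sequential_bonferroni,
                                  _levene_log_prob)


# ---------------------------------------------------------------------------
# null-allele EM

def _null_loglik(geno_counts, vis_freqs, p0):
    ll = 0.0
    for (a, b), n in geno_counts.items():
        if a == b:
            prob = vis_freqs[a] ** 2 + 2 * vis_freqs[a] * p0
        else:
            prob = 2 * vis_freqs[a] * vis_freqs[b]
        if prob <= 0:
            return -math.inf
        ll += n * math.log(prob)
    return ll


def _grid_oracle(geno_counts):
    """Independent maximization of the same likelihood via a softmax
    parametrization and a multi-start quasi-Newton search."""
    alleles = sorted({a for pair in geno_counts for a in pair})
    k = len(alleles)

    def nll(x):
        w = np.exp(x - x.max())
        w /= w.sum()
        vis = dict(zip(alleles, w[:k]))
        return -_null_loglik(geno_counts, vis, w[k])

    best = None
    for start in range(6):
        rng = np.random.default_rng(start)
        res = minimize(nll, rng.normal(size=k + 1), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10,
                                "maxiter": 20000})
        if best is None or res.fun < best.fun:
            best = res
    w = np.exp(best.x - best.x.max())
    w /= w.sum()
    return w[k]


def test_null_em_zero_for_hwe_counts():
    # p = q = 0.5, exact HWE proportions: no heterozygote deficit
    counts = {(1, 1): 25, (2, 2): 25, (1, 2): 50}
    assert null_allele_em(counts) < 0.01


def test_null_em_matches_independent_optimizer():
    counts = {(1, 1): 25, (2, 2): 25}
    em = null_allele_em(counts)
    oracle = _grid_oracle(counts)
    assert em == pytest.approx(oracle, abs=1e-4)


def test_null_em_random_tables_match_optimizer(rng):
    for _ in range(3):
        counts = {}
        for i in range(1, 4):
            for j in range(i, 4):
                c = int(rng.integers(0, 20))
                if c:
                    counts[(i, j)] = c
        if len({a for p in counts for a in p}) < 2:
            continue
        em = null_allele_em(counts)
        oracle = _grid_oracle(counts)
        assert abs(em - oracle) < 5e-3
        assert 0.0 <= em < 1.0


def test_null_em_all_missing_errors():
    with pytest.raises(ValueError):
        null_allele_em({})


def test_null_em_monomorphic_returns_zero():
    assert null_allele_em({(1, 1): 30}) == 0.0


# ---------------------------------------------------------------------------
# HWE exact test

def test_hwe_exact_toy_enumeration():
    # 2 individuals, alleles 2A/2a; observed AA + aa has probability 1/3
    p = hwe_exact_test({(1, 1): 1, (2, 2): 1})
    assert p == pytest.approx(1 / 3)


def test_hwe_monomorphic_p_one():
    assert hwe_exact_test({(1, 1): 20}) == 1.0


def _enumerate_oracle(geno_counts):
    """Independent recursive enumeration of the conditional distribution."""
    alleles = sorted({a for pair in geno_counts for a in pair})
    margins = Counter()
    for (a, b), c in geno_counts.items():
        margins[a] += c
        margins[b] += c
    n = sum(geno_counts.values())
    cells = [(a, b) for i, a in enumerate(alleles) for b in alleles[i:]]
    tables = []

    def rec(idx, left, tab):
        if idx == len(cells):
            if all(v == 0 for v in left.values()):
                tables.append(dict(tab))
            return
        a, b = cells[idx]
        cap = left[a] // 2 if a == b else min(left[a], left[b])
        for c in range(cap + 1):
            left[a] -= 2 * c if a == b else c
            if a != b:
                left[b] -= c
            tab[(a, b)] = c
            rec(idx + 1, left, tab)
            left[a] += 2 * c if a == b else c
            if a != b:
                left[b] += c
        del tab[(a, b)]

    rec(0, Counter(margins), {})
    probs = []
    for t in tables:
        t = {k: v for k, v in t.items() if v}
        probs.append(math.exp(_levene_log_prob(t)) if t or n == 0 else 0.0)
    obs = math.exp(_levene_log_prob(
        {k: v for k, v in geno_counts.items() if v}))
    return sum(p for p in probs if p <= obs * (1 + 1e-9))


def test_hwe_monte_carlo_agrees_with_enumeration():
    # 5 alleles forces the Monte-Carlo path; small table is enumerable
    counts = {(1, 2): 1, (3, 3): 1, (4, 5): 1, (1, 1): 1, (2, 4): 1}
    exact = _enumerate_oracle(counts)
    mc = hwe_exact_test(counts, n_mc=20000, seed=3)
    se = math.sqrt(exact * (1 - exact) / 20000)
    assert abs(mc - exact) < 3 * se + 1e-3


def test_hwe_p_never_exceeds_one():
    counts = {(1, 1): 8, (1, 2): 9, (2, 2): 3}
    assert 0 < hwe_exact_test(counts) <= 1.0


# ---------------------------------------------------------------------------
# LD test

def test_ld_perfect_association():
    rng = np.random.default_rng(0)
    g1 = [tuple(sorted(rng.integers(1, 5, 2))) for _ in range(40)]
    p = ld_test(g1, list(g1), n_perm=99, seed=1)
    assert p <= 1 / (99 + 1) + 1e-12


def test_ld_degenerate_identical_genotypes():
    g = [(1, 1)] * 20
    assert ld_test(g, g, n_perm=49, seed=0) == 1.0


def test_ld_independent_loci_p_roughly_uniform():
    rng = np.random.default_rng(42)
    ps = []
    for _ in range(60):
        g1 = [tuple(sorted(rng.integers(1, 4, 2))) for _ in range(30)]
        g2 = [tuple(sorted(rng.integers(1, 4, 2))) for _ in range(30)]
        ps.append(ld_test(g1, g2, n_perm=99, seed=int(rng.integers(2 ** 31))))
    from scipy.stats import kstest
    stat = kstest(ps, "uniform")
    assert stat.pvalue > 0.01


def test_ld_requires_two_individuals():
    with pytest.raises(ValueError):
        ld_test([(1, 2)], [(1, 2)], n_perm=10, seed=0)


# ---------------------------------------------------------------------------
# multiple testing

@pytest.mark.parametrize("pvals,expected", [
    ([0.01, 0.04], [True, True]),
    ([], []),
    ([0.04, 0.04], [False, False]),
    ([0.001, 0.2, 0.03], [True, False, False]),
])
def test_sequential_bonferroni_holm_rule(pvals, expected):
    assert sequential_bonferroni(pvals) == expected


def test_holm_sandwich_property(rng):
    for _ in range(20):
        pvals = list(rng.random(8))
        holm = sequential_bonferroni(pvals)
        plain = [p < 0.05 / len(pvals) for p in pvals]
        raw = [p < 0.05 for p in pvals]
        assert all(h >= b for h, b in zip(holm, plain))   # never fewer than Bonferroni
        assert all(r >= h for r, h in zip(raw, holm))     # never more than raw


def test_fishers_combine():
    x2, df, p = fishers_combine([1.0, 1.0, 1.0])
    assert x2 == 0.0 and p == pytest.approx(1.0)
    x2, df, p = fishers_combine([0.05, 0.05])
    assert x2 == pytest.approx(11.98, abs=0.01)
    assert df == 4
    _, _, p_single = fishers_combine([0.2])
    assert p_single == pytest.approx(0.2, abs=1e-9)
    with pytest.raises(ValueError):
        fishers_combine([0.0])


# ---------------------------------------------------------------------------
# locus filtering

def _dataset_with(loci_genos):
    """loci_genos: dict locus -> list of (region, pair-or-None)."""
    loci = sorted(loci_genos)
    n = len(next(iter(loci_genos.values())))
    inds = []
    for i in range(n):
        calls = {l: loci_genos[l][i][1] for l in loci}
        inds.append(Individual(f"i{i}", Genotype(calls),
                               region=loci_genos[loci[0]][i][0]))
    return PopulationDataset(loci=[Locus(l) for l in loci], individuals=inds)


def test_filter_drops_high_missing_locus(rng):
    rows = []
    for i in range(60):
        region = "r1" if i < 30 else "r2"
        good = tuple(sorted(rng.integers(1, 6, 2)))
        bad = None if rng.random() < 0.43 else good
        rows.append((region, good, bad))
    data = {"Lgood": [(r, g) for r, g, b in rows],
            "Lmiss": [(r, b) for r, g, b in rows]}
    ds = _dataset_with(data)
    report = qc_report(ds, seed=0)
    kept = filter_loci(ds, report)
    assert "Lgood" in kept
    assert report.decision["Lmiss"] == "drop:missing"


def test_filter_drops_high_null_locus(rng):
    # strong heterozygote deficit drives the EM null estimate above 0.10
    rows = []
    for i in range(80):
        region = "r1" if i < 40 else "r2"
        a = int(rng.integers(1, 5))
        good = tuple(sorted(rng.integers(1, 5, 2)))
        rows.append((region, good, (a, a)))
    data = {"Lgood": [(r, g) for r, g, h in rows],
            "Lnull": [(r, h) for r, g, h in rows]}
    ds = _dataset_with(data)
    report = qc_report(ds, seed=0)
    filter_loci(ds, report)
    assert report.decision["Lnull"].startswith("drop:")
    mean_null = np.mean(list(report.null_per_region["Lnull"].values()))
    assert mean_null > 0.10


def test_filter_drops_low_polymorphism(rng):
    rows = [("r1" if i < 20 else "r2",
             tuple(sorted(rng.integers(1, 5, 2)))) for i in range(40)]
    mono = [(r, (7, 7)) for r, _ in rows]
    ds = _dataset_with({"Lpoly": rows, "Lmono": mono})
    report = qc_report(ds, seed=0)
    kept = filter_loci(ds, report)
    assert report.decision["Lmono"] == "drop:low_polymorphism"
    assert "Lpoly" in kept


def test_locus_table_counts_consistent(small_truth):
    from featherpop.synthdata import visible_genotype
    inds = [Individual(i.individual_id,
                       Genotype({l: visible_genotype(i.genotype[l])
                                 for l in small_truth.locus_names}),
                       region=i.region)
            for i in small_truth.individuals]
    ds = PopulationDataset(loci=[Locus(l) for l in small_truth.locus_names],
                           individuals=inds)
    table = build_locus_table(ds)
    for region in table.n_typed:
        for locus in ds.locus_names:
            n = table.n_typed[region][locus]
            assert sum(table.genotype_counts[region][locus].values()) == n
            assert sum(table.allele_counts[region][locus].values()) == 2 * n
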