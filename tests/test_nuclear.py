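"""Diversity summaries, Weir-Cockerham theta (plain and ENA-corrected),
power simulation, Mantel test and spatial autocorrelation."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from featherpop.datamodel import Genotype, Individual, Locus, PopulationDataset
from featherpop.nuclear import (diversity_summary, fst_ena,
                                genotype_sq_distance_matrix,
                                homogeneity_permutation_test, mantel_test,
                                pairwise_fst, power_fst_detection,
                                rarefied_richness, spatial_autocorrelation,
                                wc_theta)


# ---------------------------------------------------------------------------
# diversity

def _hwe_dataset(rng, n=120, freqs=(0.5, 0.5)):
    inds = []
    for i in range(n):
        a, b = rng.choice(len(freqs), size=2, p=freqs) + 1
        inds.append(Individual(f"i{i}", Genotype({"L1": tuple(sorted((a, b)))}),
                               region="r1" if i < n // 2 else "r2"))
    return PopulationDataset(loci=[Locus("L1")], individuals=inds)


def test_diversity_he_fis_on_hwe_locus(rng):
    ds = _hwe_dataset(rng, n=400)
    div = diversity_summary(ds)
    for region in div.per_region.values():
        assert region["H_E"] == pytest.approx(0.5, abs=0.05)
        assert abs(region["F_IS"]) < 0.15


def test_rarefied_richness_worked_example():
    # allele counts A:3, B:1 (2N = 4), rarefied to g = 2:
    # A_R = [1 - C(1,2)/C(4,2)] + [1 - C(3,2)/C(4,2)] = 1 + (1 - 3/6) = 1.5
    assert rarefied_richness(Counter({"A": 3, "B": 1}), 2) == pytest.approx(1.5)


def test_private_alleles_counted_in_owning_region():
    inds = [
        Individual("a", Genotype({"L1": (1, 2)}), region="r1"),
        Individual("b", Genotype({"L1": (1, 1)}), region="r1"),
        Individual("c", Genotype({"L1": (1, 3)}), region="r2"),
        Individual("d", Genotype({"L1": (1, 1)}), region="r2"),
    ]
    ds = PopulationDataset(loci=[Locus("L1")], individuals=inds)
    div = diversity_summary(ds)
    assert div.per_region["r1"]["PA"] == 1  # allele 2
    assert div.per_region["r2"]["PA"] == 1  # allele 3


# ---------------------------------------------------------------------------
# Weir-Cockerham theta

def _wc_oracle_biallelic(pop_counts):
    """Independently coded textbook W&C for one biallelic locus.

    pop_counts: list of (n_AA, n_Aa, n_aa) per population.
    Returns (a, b, c) variance components summed over the two alleles.
    """
    r = len(pop_counts)
    n = [sum(t) for t in pop_counts]
    nbar = sum(n) / r
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    out = [0.0, 0.0, 0.0]
    for allele in range(2):
        p = []
        h = []
        for (naa, nab, nbb), ni in zip(pop_counts, n):
            if allele == 0:
                p.append((2 * naa + nab) / (2 * ni))
            else:
                p.append((2 * nbb + nab) / (2 * ni))
            h.append(nab / ni)
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        out[0] += a
        out[1] += b
        out[2] += c
    return out


def _pop_from_counts(naa, nab, nbb):
    return {"L1": [(1, 1)] * naa + [(1, 2)] * nab + [(2, 2)] * nbb}


def test_wc_theta_matches_textbook_oracle():
    counts = [(12, 30, 8), (25, 10, 15)]
    a, b, c = _wc_oracle_biallelic(counts)
    expected = a / (a + b + c)
    pops = [_pop_from_counts(*t) for t in counts]
    assert wc_theta(pops) == pytest.approx(expected, abs=1e-10)


def test_wc_theta_fixed_populations_near_one():
    pops = [{"L1": [(1, 1)] * 50}, {"L1": [(2, 2)] * 50}]
    assert wc_theta(pops) >= 0.98


def test_wc_theta_identical_frequency_pops_near_zero(rng):
    def draw():
        return {f"L{k}": [tuple(sorted(rng.choice([1, 2, 3], 2, p=[.5, .3, .2])))
                          for _ in range(100)] for k in range(8)}
    theta = wc_theta([draw(), draw()])
    assert abs(theta) < 0.02


def test_wc_theta_invariant_to_allele_relabeling(rng):
    pops = [
        {"L1": [tuple(sorted(rng.integers(1, 5, 2))) for _ in range(50)]}
        for _ in range(3)
    ]
    relabel = {1: 107, 2: 93, 3: 211, 4: 5}
    relabeled = [
        {"L1": [tuple(sorted((relabel[a], relabel[b]))) for a, b in p["L1"]]}
        for p in pops
    ]
    assert wc_theta(pops) == pytest.approx(wc_theta(relabeled), abs=1e-12)


def test_pairwise_fst_symmetric_roles(rng):
    pops = {
        name: {f"L{k}": [tuple(sorted(rng.integers(1, 5, 2)))
                         for _ in range(40)] for k in range(5)}
        for name in ("pa", "pb", "pc")
    }
    theta, _ = pairwise_fst(pops)
    assert set(theta) == {("pa", "pb"), ("pa", "pc"), ("pb", "pc")}


# ---------------------------------------------------------------------------
# ENA correction

def test_fst_ena_equals_plain_without_nulls(rng):
    pops = [
        {f"L{k}": [tuple(sorted(rng.integers(1, 6, 2))) for _ in range(80)]
         for k in range(6)}
        for _ in range(2)
    ]
    zero_nulls = [{f"L{k}": 0.0 for k in range(6)} for _ in range(2)]
    plain = wc_theta(pops)
    ena = fst_ena(pops, null_freqs=zero_nulls)
    assert ena == pytest.approx(plain, abs=1e-9)


def test_fst_ena_reduces_null_driven_bias():
    """With a shared null allele and true F_ST = 0, the ENA estimate is on
    average closer to zero than the uncorrected one."""
    rng = np.random.default_rng(7)
    plain_vals, ena_vals = [], []
    for _ in range(40):
        def draw_pop():
            genos = {}
            for k in range(6):
                pairs = []
                for _ in range(60):
                    alleles = rng.choice([0, 1, 2, 3], size=2,
                                         p=[0.15, 0.35, 0.3, 0.2])
                    a, b = sorted(alleles)
                    if a == 0 and b == 0:
                        pairs.append(None)
                    elif a == 0:
                        pairs.append((b, b))
                    else:
                        pairs.append((a, b))
                genos[f"L{k}"] = pairs
            return genos
        pops = [draw_pop(), draw_pop()]
        plain_vals.append(wc_theta(pops))
        ena_vals.append(fst_ena(pops))
    assert abs(np.mean(ena_vals)) <= abs(np.mean(plain_vals)) + 0.002


def test_fst_ena_hand_rescaled_frequencies():
    # one locus, both pops with a 20% EM-consistent null: visible allele
    # frequencies are rescaled by (1 - p0); with identical pops theta ~ 0
    pops = [
        {"L1": [(1, 1)] * 30 + [(1, 2)] * 20 + [(2, 2)] * 10},
        {"L1": [(1, 1)] * 30 + [(1, 2)] * 20 + [(2, 2)] * 10},
    ]
    nulls = [{"L1": 0.2}, {"L1": 0.2}]
    ena = fst_ena(pops, null_freqs=nulls)
    plain = wc_theta(pops)
    # identical populations: theta carries only the usual small-sample
    # bias, and the rescaling must not introduce spurious differentiation
    assert abs(ena) < 0.02
    assert ena == pytest.approx(plain, abs=0.02)


# ---------------------------------------------------------------------------
# power

def test_power_type_one_error_near_alpha():
    rng = np.random.default_rng(0)
    base = {f"L{k}": rng.dirichlet(np.ones(6) * 2) for k in range(10)}
    rate = power_fst_detection(base, 0.0, [50, 50], n_reps=120, seed=5)
    # binomial 99% CI around 0.05 at 120 reps
    assert abs(rate - 0.05) < 2.58 * math.sqrt(0.05 * 0.95 / 120)


def test_power_monotone_in_fst():
    rng = np.random.default_rng(1)
    base = {f"L{k}": rng.dirichlet(np.ones(6) * 2) for k in range(10)}
    rates = [power_fst_detection(base, f, [60, 60], n_reps=30, seed=9)
             for f in (0.0, 0.02, 0.1)]
    assert rates[0] <= rates[1] + 0.15
    assert rates[1] <= rates[2] + 0.1
    assert rates[2] > 0.9


# ---------------------------------------------------------------------------
# Mantel

def test_mantel_identity_r_one(rng):
    d = np.abs(rng.normal(size=(6, 6)))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    r, p = mantel_test(d, d.copy(), n_perm=99, seed=0)
    assert r == pytest.approx(1.0)


def test_mantel_enumeration_oracle():
    rng = np.random.default_rng(3)
    def sym(m):
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return m
    d1 = sym(np.abs(rng.normal(size=(4, 4))))
    d2 = sym(np.abs(rng.normal(size=(4, 4))))
    r_obs, p = mantel_test(d1, d2, n_perm=9999, seed=0)
    # independent enumeration over all 24 permutations
    iu = np.triu_indices(4, 1)
    def corr(a, b):
        return np.corrcoef(a[iu], b[iu])[0, 1]
    hits = total = 0
    for perm in itertools.permutations(range(4)):
        p_ = list(perm)
        if corr(d1[np.ix_(p_, p_)], d2) >= r_obs - 1e-12:
            hits += 1
        total += 1
    assert p == pytest.approx(hits / total)


def test_mantel_independent_matrices_r_small(rng):
    def sym(m):
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return m
    d1 = sym(np.abs(rng.normal(size=(50, 50))))
    d2 = sym(np.abs(rng.normal(size=(50, 50))))
    r, p = mantel_test(d1, d2, n_perm=199, seed=0)
    assert abs(r) < 0.12
    assert 1 / 200 <= p <= 1.0


def test_mantel_size_mismatch_errors():
    with pytest.raises(ValueError):
        mantel_test(np.zeros((3, 3)), np.zeros((4, 4)))


# ---------------------------------------------------------------------------
# spatial autocorrelation

def test_genotype_distance_follows_allele_count_metric():
    g = [{"L1": (1, 1)}, {"L1": (1, 2)}, {"L1": (2, 2)}, {"L1": (2, 3)}]
    d = genotype_sq_distance_matrix(g, ["L1"])
    assert d[0, 1] == pytest.approx(1.0)   # AA vs AB
    assert d[0, 2] == pytest.approx(4.0)   # AA vs BB
    assert d[0, 3] == pytest.approx(3.0)   # AA vs BC
    assert d[1, 3] == pytest.approx(1.0)   # AB vs BC shares one allele


def test_spatial_autocorrelation_matches_direct_formula(rng):
    genos = [{f"L{k}": tuple(sorted(rng.integers(1, 4, 2))) for k in range(5)}
             for _ in range(6)]
    coords = [(65.0 + 0.3 * i, 26.0) for i in range(6)]
    res = spatial_autocorrelation(genos, coords, [f"L{k}" for k in range(5)],
                                  class_width_km=40.0, n_perm=19, n_boot=19,
                                  seed=0)
    # direct evaluation: double-centre the squared-distance matrix by hand
    d2 = genotype_sq_distance_matrix(genos, [f"L{k}" for k in range(5)])
    n = 6
    c = np.zeros((n, n))
    row = d2.mean(axis=1)
    grand = d2.mean()
    for i in range(n):
        for j in range(n):
            c[i, j] = -0.5 * (d2[i, j] - row[i] - row[j] + grand)
    from featherpop.io import great_circle_km
    geo = np.array([[great_circle_km(*a, *b) for b in coords] for a in coords])
    for h in range(len(res.r)):
        num = den = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                if h * 40.0 <= geo[i, j] < (h + 1) * 40.0 or (
                        geo[i, j] == geo.max() and h == len(res.r) - 1
                        and geo[i, j] >= (h + 1) * 40.0):
                    num += 2 * c[i, j]
                    den += c[i, i] + c[j, j]
        if den:
            assert res.r[h] == pytest.approx(num / den, abs=1e-9)


def test_spatial_autocorrelation_degenerate_errors():
    genos = [{"L1": (1, 1)}] * 5
    coords = [(65.0 + 0.1 * i, 26.0) for i in range(5)]
    with pytest.raises(ValueError):
        spatial_autocorrelation(genos, coords, ["L1"])


def test_spatial_autocorrelation_default_class_width():
    import inspect
    sig = inspect.signature(spatial_autocorrelation)
    assert sig.parameters["class_width_km"].default == 50.0
    assert sig.parameters["n_perm"].default == 999
    assert sig.parameters["n_boot"].default == 1000
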