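"""Replicate regrouping, consensus calling, error rates, identity
statistics and molecular sexing."""

import itertools

import numpy as np
import pytest

from featherpop.datamodel import Genotype, Individual, Sex
from featherpop.identification import (assign_sex, consensus_genotype,
                                       estimate_error_rates, filter_missing,
                                       mismatch_count, pid,
                                       regroup_genotypes, regroup_stepwise,
                                       sex_ratio_test)


def _g(**calls):
    return Genotype(calls)


# ---------------------------------------------------------------------------
# mismatch counting

def test_mismatch_identical_genotypes():
    g = _g(L1=(1, 2), L2=(3, 3), L3=(4, 5))
    assert mismatch_count(g, g) == (0, 3, [])


def test_mismatch_dropout_consistent():
    g1 = _g(L1=(1, 1), L2=(3, 3))
    g2 = _g(L1=(1, 2), L2=(3, 3))
    n_mm, n_cmp, flags = mismatch_count(g1, g2)
    assert (n_mm, n_cmp, flags) == (1, 2, [True])


def test_mismatch_no_shared_allele_not_dropout():
    g1 = _g(L1=(1, 2), L2=(3, 3))
    g2 = _g(L1=(5, 6), L2=(3, 3))
    n_mm, n_cmp, flags = mismatch_count(g1, g2)
    assert (n_mm, flags) == (1, [False])


def test_mismatch_skips_missing_loci():
    g1 = _g(L1=(1, 2), L2=None, L3=(4, 4))
    g2 = _g(L1=(1, 2), L2=(3, 3), L3=None)
    assert mismatch_count(g1, g2) == (0, 1, [])


# ---------------------------------------------------------------------------
# regrouping

def _loci(pairs):
    return {f"L{i + 1}": p for i, p in enumerate(pairs)}


def test_regroup_identical_genotypes_one_cluster():
    g = Genotype(_loci([(1, 2)] * 8))
    res = regroup_genotypes({"s1": g, "s2": g})
    assert res.clusters == [["s1", "s2"]]
    assert res.excluded == []


def test_regroup_three_mismatches_same_cluster():
    base = [(1, 2)] * 8
    other = [(1, 1), (3, 4), (5, 6)] + [(1, 2)] * 5
    res = regroup_genotypes({"a": Genotype(_loci(base)),
                             "b": Genotype(_loci(other))})
    assert res.clusters == [["a", "b"]]


def test_regroup_standalone_dropout_pair_excluded():
    base = [(1, 2), (3, 4), (5, 6), (7, 8)] + [(9, 9)] * 4
    dropped = [(1, 1), (3, 3), (5, 5), (7, 7)] + [(9, 9)] * 4
    res = regroup_genotypes({"a": Genotype(_loci(base)),
                             "b": Genotype(_loci(dropped))})
    assert res.excluded == ["a", "b"]
    assert res.clusters == []


def test_regroup_four_mismatches_not_dropout_distinct():
    base = [(1, 2), (3, 4), (5, 6), (7, 8)] + [(9, 9)] * 4
    other = [(11, 12), (13, 14), (15, 16), (17, 18)] + [(9, 9)] * 4
    res = regroup_genotypes({"a": Genotype(_loci(base)),
                             "b": Genotype(_loci(other))})
    assert res.excluded == []
    assert res.clusters == [["a"], ["b"]]


def test_regroup_permutation_invariant(small_samples):
    genotypes = {s.sample_id: s.genotype for s in small_samples[:60]}
    res1 = regroup_genotypes(genotypes)
    shuffled = dict(reversed(list(genotypes.items())))
    res2 = regroup_genotypes(shuffled)
    assert res1.clusters == res2.clusters
    assert res1.excluded == res2.excluded


def test_regroup_recovers_true_individuals_error_free(clean_truth, clean_samples):
    genotypes = {s.sample_id: s.genotype for s in clean_samples}
    res = regroup_genotypes(genotypes)
    truth_partition = {}
    for s in clean_samples:
        truth_partition.setdefault(s.sample_id.rsplit("_r", 1)[0], set()).add(
            s.sample_id)
    # error-free: distinct individuals may still share a genotype by chance
    # at few loci, but with 22 loci clusters must match the true partition
    got = {frozenset(c) for c in res.clusters}
    want = {frozenset(v) for v in truth_partition.values()}
    assert got == want


def test_stepwise_equals_single_pass_on_error_free_data(clean_truth, clean_samples):
    genotypes = {s.sample_id: s.genotype for s in clean_samples}
    loci = clean_truth.locus_names
    panels = {"B": loci[:5], "A": loci[5:12], "C": loci[12:17], "D": loci[17:]}
    res_step = regroup_stepwise(genotypes, panels)
    res_one = regroup_genotypes(genotypes)
    assert sorted(res_step.clusters) == sorted(res_one.clusters)


# ---------------------------------------------------------------------------
# consensus

def test_consensus_majority():
    reps = [_g(L1=(1, 2)), _g(L1=(1, 2)), _g(L1=(1, 1))]
    assert consensus_genotype(reps)["L1"] == (1, 2)


def test_consensus_two_replicates_prefers_heterozygote():
    reps = [_g(L1=(1, 1)), _g(L1=(1, 2))]
    assert consensus_genotype(reps)["L1"] == (1, 2)


def test_consensus_unanimous_homozygote():
    reps = [_g(L1=(1, 1))] * 3
    assert consensus_genotype(reps)["L1"] == (1, 1)


def test_consensus_unresolved_tie_is_missing():
    reps = [_g(L1=(1, 1)), _g(L1=(2, 2))]
    assert consensus_genotype(reps)["L1"] is None
    reps3 = [_g(L1=(1, 2)), _g(L1=(1, 3)), _g(L1=(2, 3))]
    assert consensus_genotype(reps3)["L1"] is None


def test_consensus_ignores_missing_observations():
    reps = [_g(L1=None), _g(L1=(1, 2)), _g(L1=None)]
    assert consensus_genotype(reps)["L1"] == (1, 2)


# ---------------------------------------------------------------------------
# missing-data filter

@pytest.mark.parametrize("n_missing,retained", [(7, True), (8, False), (0, True)])
def test_filter_missing_boundary(n_missing, retained):
    calls = {f"L{i}": ((1, 1) if i >= n_missing else None) for i in range(28)}
    ind = Individual("x", Genotype(calls))
    out = filter_missing([ind], max_missing=0.25)
    assert (ind in out) == retained


# ---------------------------------------------------------------------------
# error rates

def test_error_rates_ado_by_hand():
    cons = _g(L1=(1, 2))
    reps = [_g(L1=(1, 2)), _g(L1=(1, 1)), _g(L1=(1, 2)), _g(L1=(2, 2))]
    er = estimate_error_rates([reps], [cons])
    assert er.ado_per_locus["L1"] == pytest.approx(2 / 4)


def test_error_rates_fa_and_per_allele_by_hand():
    cons = _g(L1=(1, 1))
    reps = [_g(L1=(1, 3)), _g(L1=(1, 1))]
    er = estimate_error_rates([reps], [cons])
    assert er.fa_per_locus["L1"] == pytest.approx(1 / 2)
    # observation (1,3) vs consensus (1,1): one of two alleles mismatches
    assert er.error_per_allele == pytest.approx(1 / 4)


def test_error_rates_zero_when_replicates_match():
    cons = _g(L1=(1, 2), L2=(3, 3))
    reps = [cons, cons, cons]
    er = estimate_error_rates([reps], [cons])
    assert er.mean_fa == 0.0
    assert er.error_per_allele == 0.0
    assert er.error_per_locus == 0.0


def test_error_rates_require_multi_replicate_cluster():
    cons = _g(L1=(1, 2))
    with pytest.raises(ValueError):
        estimate_error_rates([[cons]], [cons])


def test_error_rate_recovery_from_simulated_replicates():
    """Estimated ADO/FA recover the generator settings within +-0.01."""
    from featherpop.pipeline import PipelineConfig, identify_individuals
    from featherpop.synthdata import SimulationConfig, simulate_population, \
        simulate_feather_samples
    cfg = SimulationConfig(seed=13, n_pairs_per_region=5,
                           n_singles_per_region=40)
    truth = simulate_population(cfg)
    samples = simulate_feather_samples(truth)
    _, errors, _ = identify_individuals(samples, truth.locus_names,
                                        PipelineConfig())
    assert errors.n_observations >= 500
    assert abs(errors.mean_ado - cfg.ado_rate) < 0.01
    assert abs(errors.mean_fa - cfg.fa_rate) < 0.01


# ---------------------------------------------------------------------------
# probability of identity

def _pid_naive_bruteforce(p):
    """Enumerate genotype probabilities; P_ID = sum P(g)^2."""
    k = len(p)
    total = 0.0
    for i in range(k):
        for j in range(i, k):
            pg = p[i] ** 2 if i == j else 2 * p[i] * p[j]
            total += pg ** 2
    return total


def _pid_sib_bruteforce(p):
    """P(two full sibs share a genotype), enumerating parental genotypes
    and Mendelian offspring distributions."""
    k = len(p)
    genos = [(i, j) for i in range(k) for j in range(i, k)]

    def gprob(g):
        i, j = g
        return p[i] ** 2 if i == j else 2 * p[i] * p[j]

    def offspring_dist(gm, gf):
        dist = {}
        for a in gm:
            for b in gf:
                g = tuple(sorted((a, b)))
                dist[g] = dist.get(g, 0.0) + 0.25
        return dist

    total = 0.0
    for gm in genos:
        for gf in genos:
            w = gprob(gm) * gprob(gf)
            dist = offspring_dist(gm, gf)
            total += w * sum(v ** 2 for v in dist.values())
    return total


def test_pid_naive_matches_enumeration():
    p = np.array([0.5, 0.5])
    st = pid({"L1": p}, n=100, unbiased=False)
    assert st.pid_per_locus["L1"] == pytest.approx(_pid_naive_bruteforce(p))
    assert st.pid_per_locus["L1"] == pytest.approx(0.375)
    p3 = np.array([0.5, 0.3, 0.2])
    st3 = pid({"L1": p3}, n=100, unbiased=False)
    assert st3.pid_per_locus["L1"] == pytest.approx(_pid_naive_bruteforce(p3))


def test_pid_sib_matches_bruteforce():
    for p in (np.array([0.5, 0.5]), np.array([0.4, 0.35, 0.25])):
        st = pid({"L1": p}, n=100, unbiased=False)
        assert st.pidsib_per_locus["L1"] == pytest.approx(_pid_sib_bruteforce(p))
    st = pid({"L1": np.array([0.5, 0.5])}, n=100, unbiased=False)
    assert st.pidsib_per_locus["L1"] == pytest.approx(0.59375)


def test_pid_cumulative_is_product_over_loci():
    freqs = {"L1": np.array([0.5, 0.5]), "L2": np.array([0.25, 0.75])}
    st = pid(freqs, n=50, unbiased=False)
    assert st.cumulative_pid == pytest.approx(
        st.pid_per_locus["L1"] * st.pid_per_locus["L2"])
    assert st.cumulative_pidsib == pytest.approx(
        st.pidsib_per_locus["L1"] * st.pidsib_per_locus["L2"])
    assert st.cumulative_pid <= min(st.pid_per_locus.values())


def test_pid_unbiased_converges_to_naive():
    p = np.array([0.3, 0.3, 0.2, 0.2])
    naive = pid({"L1": p}, n=100000, unbiased=False).pid_per_locus["L1"]
    unb = pid({"L1": p}, n=100000).pid_per_locus["L1"]
    assert abs(unb - naive) / naive < 1e-3


def test_pid_unbiased_needs_n_at_least_4():
    with pytest.raises(ValueError):
        pid({"L1": np.array([0.5, 0.5])}, n=3)


# ---------------------------------------------------------------------------
# sexing

@pytest.mark.parametrize("bp,expected", [
    (287, Sex.FEMALE), (297, Sex.MALE), (292, Sex.UNKNOWN),
    (288, Sex.FEMALE), (296, Sex.MALE), (None, Sex.UNKNOWN),
])
def test_assign_sex(bp, expected):
    assert assign_sex(bp) == expected


def test_sex_ratio_test_values():
    chi2, p = sex_ratio_test(237, 189)
    assert chi2 == pytest.approx(5.40, abs=0.01)
    assert p == pytest.approx(0.02, abs=0.005)
    chi2, p = sex_ratio_test(10, 10)
    assert chi2 == 0.0 and p == 1.0
    chi2, _ = sex_ratio_test(20, 0)
    assert chi2 == pytest.approx(20.0)
    with pytest.raises(ValueError):
        sex_ratio_test(0, 0)
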