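"""Individual identification from replicate feather samples.

Replicate multilocus genotypes are regrouped into individuals (up to a fixed
number of per-locus mismatches tolerated, dropout-consistent borderline
pairs excluded), consensus genotypes are built by per-locus majority vote,
genotyping-error rates (allele dropout, false alleles) are estimated from
the replicate structure, and identity statistics (P_ID, P_ID_SIB) quantify
the panel's power to distinguish individuals.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .datamodel import Genotype, SampleRecord, Sex


def mismatch_count(g1: Genotype, g2: Genotype) -> Tuple[int, int, List[bool]]:
    """Count mismatching loci between two multilocus genotypes.

    Loci missing in either genotype are skipped.  Returns
    (n_mismatch, n_compared, ado_consistent) where ado_consistent has one
    flag per mismatching locus: True iff one genotype is homozygous and the
    other is a heterozygote containing that homozygote's allele — the
    signature of an allele dropout.
    """
    if set(g1.calls) != set(g2.calls):
        raise ValueError("genotypes cover different locus sets")
    n_mismatch = 0
    n_compared = 0
    flags: List[bool] = []
    for locus in g1.calls:
        p1, p2 = g1.calls[locus], g2.calls[locus]
        if p1 is None or p2 is None:
            continue
        n_compared += 1
        if p1 == p2:
            continue
        n_mismatch += 1
        hom, het = None, None
        if p1[0] == p1[1] and p2[0] != p2[1]:
            hom, het = p1, p2
        elif p2[0] == p2[1] and p1[0] != p1[1]:
            hom, het = p2, p1
        flags.append(hom is not None and hom[0] in het)
    return n_mismatch, n_compared, flags


@dataclass
class RegroupResult:
    clusters: List[List[str]]            # sample ids per individual
    excluded: List[str]                  # dropout-suspect samples removed
    genotypes: Dict[str, Genotype] = field(default_factory=dict)


def regroup_genotypes(
    genotypes: Dict[str, Genotype],
    max_same: int = 3,
    review_band: Tuple[int, int] = (4, 5),
) -> RegroupResult:
    """Cluster replicate samples into individuals.

    Samples whose genotypes mismatch at <= ``max_same`` loci are linked;
    clusters are connected components of that graph (deterministic: samples
    processed in sorted order).  Pairs mismatching inside ``review_band``
    whose mismatches are all consistent with allele dropout are
    poor-template suspects: a suspect is excluded before clustering unless
    it is confidently linked (<= ``max_same`` mismatches) to some sample
    outside the flagged pair, in which case its identity is secured by that
    link.  Pairs with >= review_band[0] mismatches not all
    dropout-consistent are simply distinct individuals.
    """
    ids = sorted(genotypes)
    lo, hi = review_band
    links: Dict[str, set] = {s: set() for s in ids}
    review_pairs: List[Tuple[str, str]] = []
    edges: List[Tuple[str, str]] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            n_mm, n_cmp, flags = mismatch_count(genotypes[a], genotypes[b])
            if n_cmp == 0:
                continue
            if n_mm <= max_same:
                edges.append((a, b))
                links[a].add(b)
                links[b].add(a)
            elif lo <= n_mm <= hi and flags and all(flags):
                review_pairs.append((a, b))
    excluded: set = set()
    for a, b in review_pairs:
        if not (links[a] - {b}):
            excluded.add(a)
        if not (links[b] - {a}):
            excluded.add(b)
    kept = [s for s in ids if s not in excluded]
    parent = {s: s for s in kept}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        if a in excluded or b in excluded:
            continue
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    groups: Dict[str, List[str]] = {}
    for s in kept:
        groups.setdefault(find(s), []).append(s)
    clusters = [sorted(groups[root]) for root in sorted(groups)]
    return RegroupResult(clusters=clusters, excluded=sorted(excluded),
                         genotypes=genotypes)


def regroup_stepwise(
    genotypes: Dict[str, Genotype],
    panels: Dict[str, Sequence[str]],
    panel_order: Sequence[str] = ("B", "A", "C", "D"),
    max_same: int = 3,
    review_band: Tuple[int, int] = (4, 5),
) -> RegroupResult:
    """Stepwise panel screening: quality-screen after each multiplex panel.

    Mirrors lab practice: a first cheap panel screens for poor-quality
    samples, later panels refine.  After each panel the accumulated loci
    are regrouped with the same rules and the poor-template suspects found
    at that stage are dropped from further rounds; cluster memberships are
    never frozen on a partial panel — the final round re-clusters all
    surviving samples over all loci, so on error-free data the result
    equals the single-pass one.
    """
    active = sorted(genotypes)
    used_loci: List[str] = []
    excluded: List[str] = []
    result = None
    rounds = [p for p in panel_order if p in panels]
    for panel in rounds:
        used_loci.extend(panels[panel])
        sub = {
            s: Genotype({l: genotypes[s].calls[l] for l in used_loci})
            for s in active
        }
        result = regroup_genotypes(sub, max_same=max_same, review_band=review_band)
        excluded.extend(result.excluded)
        active = [s for s in active if s not in result.excluded]
    clusters = sorted(sorted(c) for c in result.clusters)
    return RegroupResult(clusters=clusters, excluded=sorted(set(excluded)),
                         genotypes=genotypes)


def consensus_genotype(replicates: Sequence[Genotype]) -> Genotype:
    """Per-locus consensus over replicates.

    Strict majority genotype wins; with exactly two discordant observations
    the heterozygote is chosen when one call is heterozygous (dropouts are
    likelier than false alleles); unresolved ties are recorded missing.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    loci = replicates[0].loci
    calls: Dict[str, Optional[Tuple[int, int]]] = {}
    for locus in loci:
        obs = [g.calls[locus] for g in replicates if g.calls[locus] is not None]
        if not obs:
            calls[locus] = None
            continue
        counts = Counter(obs)
        best, best_n = counts.most_common(1)[0]
        if best_n > len(obs) / 2:
            calls[locus] = best
            continue
        if len(obs) == 2:
            hets = [p for p in obs if p[0] != p[1]]
            if len(hets) == 1:
                calls[locus] = hets[0]
                continue
        calls[locus] = None  # unresolved tie
    return Genotype(calls)


def filter_missing(individuals, max_missing: float = 0.25):
    """Retain individuals whose consensus missing fraction is <= max_missing
    (strictly more than the threshold is excluded)."""
    return [i for i in individuals if i.consensus.missing_fraction() <= max_missing]


@dataclass
class ErrorRates:
    """Per-locus and mean allele-dropout / false-allele / error rates."""

    ado_per_locus: Dict[str, float]
    fa_per_locus: Dict[str, float]
    mean_ado: float
    mean_fa: float
    error_per_allele: float
    error_per_locus: float
    null_per_locus: Dict[str, float] = field(default_factory=dict)
    n_observations: int = 0


def estimate_error_rates(
    clusters: Sequence[Sequence[Genotype]],
    consensuses: Sequence[Genotype],
) -> ErrorRates:
    """Estimate ADO and FA rates from replicates of identified individuals.

    ADO per locus: among replicate observations at loci whose consensus is
    heterozygous, the fraction showing only one consensus allele.  FA per
    locus: fraction of typed observations containing an allele absent from
    the consensus.  Error per allele / per locus: mismatching alleles /
    locus observations relative to consensus, over all comparisons.  Means
    are unweighted over loci.
    """
    if len(clusters) != len(consensuses):
        raise ValueError("clusters and consensuses must align")
    loci = consensuses[0].loci if consensuses else []
    ado_num = {l: 0 for l in loci}
    ado_den = {l: 0 for l in loci}
    fa_num = {l: 0 for l in loci}
    fa_den = {l: 0 for l in loci}
    allele_mismatch = allele_total = 0
    locus_mismatch = locus_total = 0
    n_obs = 0
    multi = False
    for replicates, cons in zip(clusters, consensuses):
        if len(replicates) < 2:
            # a lone replicate is its own consensus and carries no error signal
            continue
        multi = True
        for g in replicates:
            for locus in loci:
                obs = g.calls[locus]
                true = cons.calls[locus]
                if obs is None or true is None:
                    continue
                n_obs += 1
                cons_set = set(true)
                obs_set = set(obs)
                fa_den[locus] += 1
                if obs_set - cons_set:
                    fa_num[locus] += 1
                if true[0] != true[1]:
                    ado_den[locus] += 1
                    if obs[0] == obs[1] and obs[0] in cons_set:
                        ado_num[locus] += 1
                locus_total += 1
                if obs != true:
                    locus_mismatch += 1
                # per-allele comparison of unordered pairs
                shared = len(list((Counter(obs) & Counter(true)).elements()))
                allele_total += 2
                allele_mismatch += 2 - shared
    ado = {l: (ado_num[l] / ado_den[l]) if ado_den[l] else float("nan") for l in loci}
    fa = {l: (fa_num[l] / fa_den[l]) if fa_den[l] else float("nan") for l in loci}
    ado_vals = [v for v in ado.values() if not np.isnan(v)]
    fa_vals = [v for v in fa.values() if not np.isnan(v)]
    rates = ErrorRates(
        ado_per_locus=ado, fa_per_locus=fa,
        mean_ado=float(np.mean(ado_vals)) if ado_vals else float("nan"),
        mean_fa=float(np.mean(fa_vals)) if fa_vals else float("nan"),
        error_per_allele=allele_mismatch / allele_total if allele_total else float("nan"),
        error_per_locus=locus_mismatch / locus_total if locus_total else float("nan"),
        n_observations=n_obs,
    )
    if not multi:
        raise ValueError("no cluster has >= 2 replicates: error rates undefined")
    return rates


@dataclass
class IdentityStats:
    pid_per_locus: Dict[str, float]
    pidsib_per_locus: Dict[str, float]
    cumulative_pid: float
    cumulative_pidsib: float
    n: int


def _pid_naive(p: np.ndarray) -> float:
    a2 = float(np.sum(p ** 2))
    a4 = float(np.sum(p ** 4))
    return 2 * a2 ** 2 - a4


def _pid_unbiased(p: np.ndarray, n: int) -> float:
    # sample-size-corrected estimator of the probability of identity
    a2 = float(np.sum(p ** 2))
    a3 = float(np.sum(p ** 3))
    a4 = float(np.sum(p ** 4))
    num = n ** 3 * (2 * a2 ** 2 - a4) - 2 * n ** 2 * (a3 + 2 * a2) + n * (9 * a2 + 2) - 6
    return num / ((n - 1) * (n - 2) * (n - 3))


def _pid_sib(p: np.ndarray) -> float:
    a2 = float(np.sum(p ** 2))
    a4 = float(np.sum(p ** 4))
    return 0.25 + 0.5 * a2 + 0.5 * a2 ** 2 - 0.25 * a4


def pid(freqs: Dict[str, np.ndarray], n: int, unbiased: bool = True) -> IdentityStats:
    """Probability-of-identity statistics from per-locus allele frequencies.

    P_ID (unbiased, sample-size corrected) is the chance two random
    individuals share a multilocus genotype; P_ID_SIB the same for full
    siblings.  Cumulative values are products over independent loci.
    """
    if unbiased and n <= 3:
        raise ValueError("unbiased P_ID estimator requires n >= 4")
    pid_l: Dict[str, float] = {}
    sib_l: Dict[str, float] = {}
    for locus, p in freqs.items():
        p = np.asarray(p, dtype=float)
        if not np.isclose(p.sum(), 1.0, atol=1e-6):
            raise ValueError(f"frequencies at {locus} do not sum to 1")
        pid_l[locus] = _pid_unbiased(p, n) if unbiased else _pid_naive(p)
        sib_l[locus] = _pid_sib(p)
    return IdentityStats(
        pid_per_locus=pid_l, pidsib_per_locus=sib_l,
        cumulative_pid=float(np.prod(list(pid_l.values()))),
        cumulative_pidsib=float(np.prod(list(sib_l.values()))),
        n=n,
    )


def assign_sex(fragment_bp: Optional[int], tolerance: int = 1,
               female_bp: int = 287, male_bp: int = 297) -> Sex:
    """Molecular sexing from the Z/W gametolog fragment length:
    287 bp in females, 297 bp in males (within +-tolerance)."""
    if fragment_bp is None:
        return Sex.UNKNOWN
    if abs(fragment_bp - female_bp) <= tolerance:
        return Sex.FEMALE
    if abs(fragment_bp - male_bp) <= tolerance:
        return Sex.MALE
    return Sex.UNKNOWN


def sex_ratio_test(n_f: int, n_m: int) -> Tuple[float, float]:
    """1-df chi-squared goodness-of-fit of the sex counts against 1:1."""
    total = n_f + n_m
    if total == 0:
        raise ValueError("no sexed individuals")
    expected = total / 2
    chi2 = (n_f - expected) ** 2 / expected + (n_m - expected) ** 2 / expected
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p
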