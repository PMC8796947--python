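"""Nuclear diversity, differentiation, power and spatial pattern analyses.

Implements per-region diversity summaries (A, rarefied allelic richness,
private alleles, H_O, H_E, F_IS), the Weir-Cockerham F_ST estimator with
an ENA-style null-allele correction, a marker-power simulation, the Mantel
test for isolation by distance, and multivariate spatial autocorrelation of
codominant genotypes over distance classes.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from .datamodel import PopulationDataset
from .marker_qc import build_locus_table, fishers_combine, hwe_exact_test, null_allele_em

PairList = List[Optional[Tuple[int, int]]]
PopGenotypes = Dict[str, PairList]  # locus -> genotype per individual


def dataset_to_pops(dataset: PopulationDataset) -> Dict[str, PopGenotypes]:
    out: Dict[str, PopGenotypes] = {}
    for region, inds in dataset.by_region().items():
        out[region] = {
            locus: [ind.consensus.get(locus) for ind in inds]
            for locus in dataset.locus_names
        }
    return out


# ---------------------------------------------------------------------------
# diversity

def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_richness(allele_counts: Counter, g: int) -> float:
    """Allelic richness rarefied to g gene copies:
    A_R = sum_alleles [1 - C(2N - N_i, g) / C(2N, g)]."""
    two_n = sum(allele_counts.values())
    if g > two_n:
        raise ValueError("rarefaction size exceeds sample")
    total = 0.0
    for n_i in allele_counts.values():
        if two_n - n_i < g:
            total += 1.0
        else:
            total += 1.0 - math.exp(_log_comb(two_n - n_i, g) - _log_comb(two_n, g))
    return total


@dataclass
class DiversitySummary:
    per_region: "Dict[str, Dict[str, float]]"  # region -> stat -> value
    per_locus: "Dict[str, Dict[str, Dict[str, float]]]"  # region -> locus -> stat
    se_over_loci: "Dict[str, Dict[str, float]]" = field(default_factory=dict)


def diversity_summary(dataset: PopulationDataset, rarefaction_n: Optional[int] = None,
                      hwe_seed: int = 0, unbiased_he: bool = False) -> DiversitySummary:
    """Per-region diversity: n, A, A_R, PA, H_O, H_E, F_IS and combined HWE p.

    H_E = 1 - sum(p^2) from per-region frequencies (no small-sample
    correction by default); F_IS per locus = (H_E - H_O)/H_E averaged
    unweighted over loci; A_R rarefied to twice the smallest per-region
    typed sample at each locus; private alleles counted against all other
    regions.  Standard errors are over loci.
    """
    table = build_locus_table(dataset)
    regions = list(table.genotype_counts)
    loci = dataset.locus_names
    # presence per allele per region for private alleles
    presence: Dict[str, Dict[int, set]] = {l: {} for l in loci}
    for region in regions:
        for locus in loci:
            for a in table.allele_counts[region][locus]:
                presence[locus].setdefault(a, set()).add(region)

    per_region: Dict[str, Dict[str, float]] = {}
    per_locus: Dict[str, Dict[str, Dict[str, float]]] = {}
    se: Dict[str, Dict[str, float]] = {}
    for region in regions:
        inds = dataset.by_region()[region]
        stats_l: Dict[str, Dict[str, float]] = {}
        hwe_ps: List[float] = []
        a_total = 0
        pa_total = 0
        for li, locus in enumerate(loci):
            counts = table.allele_counts[region][locus]
            n_typed = table.n_typed[region][locus]
            if n_typed == 0:
                continue
            freqs = np.array(list(counts.values()), dtype=float)
            freqs /= freqs.sum()
            he = 1.0 - float(np.sum(freqs ** 2))
            if unbiased_he:
                he *= 2 * n_typed / (2 * n_typed - 1)
            n_het = sum(cnt for (a, b), cnt in table.genotype_counts[region][locus].items()
                        if a != b)
            ho = n_het / n_typed
            fis = (he - ho) / he if he > 0 else float("nan")
            if rarefaction_n is not None:
                g = 2 * rarefaction_n
            else:
                g = 2 * min(table.n_typed[r][locus] for r in regions
                            if table.n_typed[r][locus] > 0)
            ar = rarefied_richness(counts, min(g, sum(counts.values())))
            a_total += len(counts)
            pa_total += sum(1 for a in counts if presence[locus][a] == {region})
            stats_l[locus] = {"A": len(counts), "A_R": ar, "H_O": ho, "H_E": he,
                              "F_IS": fis}
            hwe_ps.append(max(hwe_exact_test(
                dict(table.genotype_counts[region][locus]),
                seed=(hwe_seed + 31 * li) % (2 ** 31)), 1e-300))
        fis_vals = [v["F_IS"] for v in stats_l.values() if not math.isnan(v["F_IS"])]
        ho_vals = [v["H_O"] for v in stats_l.values()]
        he_vals = [v["H_E"] for v in stats_l.values()]
        ar_vals = [v["A_R"] for v in stats_l.values()]
        _, _, hwe_comb = fishers_combine(hwe_ps) if hwe_ps else (0, 0, 1.0)
        per_region[region] = {
            "n": len(inds), "A": a_total,
            "A_R": float(np.mean(ar_vals)) if ar_vals else float("nan"),
            "PA": pa_total,
            "H_O": float(np.mean(ho_vals)) if ho_vals else float("nan"),
            "H_E": float(np.mean(he_vals)) if he_vals else float("nan"),
            "F_IS": float(np.mean(fis_vals)) if fis_vals else float("nan"),
            "P_HWE": hwe_comb,
        }
        per_locus[region] = stats_l
        se[region] = {
            k: float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else float("nan")
            for k, vals in (("H_O", ho_vals), ("H_E", he_vals), ("F_IS", fis_vals))
        }
    return DiversitySummary(per_region=per_region, per_locus=per_locus, se_over_loci=se)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta

def _to_locus_array(genos: PairList) -> np.ndarray:
    """(n, 2) int array with -1 for missing."""
    return np.array([g if g is not None else (-1, -1) for g in genos],
                    dtype=np.int64)


def _wc_components_locus(pop_arrays: Sequence[np.ndarray]) -> Tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components (a, b, c) summed over
    alleles at one locus; populations with no typed data are skipped.
    Each population is an (n, 2) array of allele labels, -1 = missing."""
    typed = []
    for arr in pop_arrays:
        t = arr[arr[:, 0] >= 0]
        if len(t):
            typed.append(t)
    r = len(typed)
    if r < 2:
        return 0.0, 0.0, 0.0
    alleles = np.unique(np.concatenate([t.ravel() for t in typed]))
    if len(alleles) < 2:
        return 0.0, 0.0, 0.0
    n = np.array([len(t) for t in typed], dtype=float)
    nbar = n.mean()
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - np.sum(n ** 2) / (r * nbar)) / (r - 1)
    # p[pop, allele], h[pop, allele] via vectorized comparisons
    p = np.empty((r, len(alleles)))
    h = np.empty((r, len(alleles)))
    for i, t in enumerate(typed):
        eq = t[:, :, None] == alleles[None, None, :]        # (n, 2, k)
        p[i] = eq.sum(axis=(0, 1)) / (2 * len(t))
        het = t[:, 0] != t[:, 1]
        h[i] = (eq.any(axis=1) & het[:, None]).sum(axis=0) / len(t)
    w = n[:, None]
    pbar = (w * p).sum(axis=0) / (r * nbar)
    s2 = (w * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (w * h).sum(axis=0) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def _pops_to_arrays(pops: Sequence[PopGenotypes]) -> List[Dict[str, np.ndarray]]:
    return [{l: _to_locus_array(p[l]) for l in p} for p in pops]


def _theta_from_arrays(pop_arrays: Sequence[Dict[str, np.ndarray]]) -> float:
    loci = list(pop_arrays[0])
    num = den = 0.0
    for locus in loci:
        a, b, c = _wc_components_locus([p[locus] for p in pop_arrays])
        num += a
        den += a + b + c
    return num / den if den != 0 else float("nan")


def wc_theta(pops: Sequence[PopGenotypes]) -> float:
    """Multi-locus Weir-Cockerham theta as a ratio of summed components."""
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    return _theta_from_arrays(_pops_to_arrays(pops))


def pairwise_fst(pops: Dict[str, PopGenotypes], n_perm: int = 0,
                 seed: int = 0) -> Tuple[Dict[Tuple[str, str], float],
                                         Dict[Tuple[str, str], float]]:
    """Pairwise Weir-Cockerham theta with optional permutation p-values
    (individuals shuffled between the two populations)."""
    names = list(pops)
    theta: Dict[Tuple[str, str], float] = {}
    pvals: Dict[Tuple[str, str], float] = {}
    rng = np.random.default_rng(seed)
    arrays = {name: {l: _to_locus_array(pops[name][l]) for l in pops[name]}
              for name in names}
    loci = list(pops[names[0]])
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            obs = _theta_from_arrays([arrays[na], arrays[nb]])
            theta[(na, nb)] = obs
            if n_perm:
                n_a = len(arrays[na][loci[0]])
                merged = {
                    locus: np.concatenate([arrays[na][locus], arrays[nb][locus]])
                    for locus in loci
                }
                total = n_a + len(arrays[nb][loci[0]])
                hits = 0
                for _ in range(n_perm):
                    idx = rng.permutation(total)
                    pa = {l: merged[l][idx[:n_a]] for l in loci}
                    pb = {l: merged[l][idx[n_a:]] for l in loci}
                    if _theta_from_arrays([pa, pb]) >= obs - 1e-15:
                        hits += 1
                pvals[(na, nb)] = (hits + 1) / (n_perm + 1)
    return theta, pvals


def fst_ena(pops: Sequence[PopGenotypes],
            null_freqs: Optional[Sequence[Dict[str, float]]] = None) -> float:
    """Weir-Cockerham theta with the ENA ("excluding null alleles")
    correction: per population and locus the null-allele frequency is
    estimated (EM) unless supplied, visible allele frequencies are taken
    from the EM fit (summing to 1 - null), and the null class is excluded
    from the allele-wise sums.

    Works from EM-adjusted allele frequencies and the observed
    heterozygosity structure; loci where any population's null estimate
    reaches 1 are excluded.
    """
    loci = list(pops[0])
    num = den = 0.0
    for locus in loci:
        per_pop = []
        skip = False
        for pi, pop in enumerate(pops):
            genos = [g for g in pop[locus] if g is not None]
            if not genos:
                continue
            counts = Counter(genos)
            if null_freqs is not None:
                p0 = null_freqs[pi].get(locus, 0.0)
            else:
                p0 = null_allele_em(dict(counts))
            if p0 >= 1.0:
                skip = True
                break
            # visible allele frequencies rescaled so they sum to 1 - p0;
            # the null is treated as an unobserved allele excluded from the
            # allele-wise sums below
            raw_counts = Counter(a for pair in genos for a in pair)
            two_n = sum(raw_counts.values())
            vis = {a: c / two_n for a, c in raw_counts.items()}
            adj = {a: v * (1 - p0) for a, v in vis.items()}
            per_pop.append((len(genos), adj, counts, p0))
        if skip or len(per_pop) < 2:
            continue
        alleles = sorted({a for _, adj, _, _ in per_pop for a in adj})
        if len(alleles) < 2:
            continue
        r = len(per_pop)
        n = np.array([t[0] for t in per_pop], dtype=float)
        nbar = n.mean()
        nc = (r * nbar - np.sum(n ** 2) / (r * nbar)) / (r - 1)
        for allele in alleles:
            p = np.array([adj.get(allele, 0.0) for _, adj, _, _ in per_pop])
            h = np.array([
                sum((g[0] != g[1]) and (allele in g) for g in counts.elements()) /
                max(1, sum(counts.values()))
                for _, _, counts, _ in per_pop
            ])
            # rescale p back to a frequency among visible + null classes
            pbar = float(np.sum(n * p) / (r * nbar))
            if pbar <= 0 or pbar >= 1:
                continue
            s2 = float(np.sum(n * (p - pbar) ** 2) / ((r - 1) * nbar))
            hbar = float(np.sum(n * h) / (r * nbar))
            if nbar <= 1:
                continue
            a_c = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
                                 / (nbar - 1))
            b_c = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                         - (2 * nbar - 1) / (4 * nbar) * hbar)
            c_c = hbar / 2
            num += a_c
            den += a_c + b_c + c_c
    return num / den if den != 0 else float("nan")


# ---------------------------------------------------------------------------
# power simulation

def _chi2_stat(counts: np.ndarray) -> float:
    """Chi-square statistic of a pops x alleles count table."""
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    total = counts.sum()
    if total == 0:
        return 0.0
    expected = row * col / total
    mask = expected > 0
    return float((((counts - expected) ** 2)[mask] / expected[mask]).sum())


def homogeneity_permutation_test(pop_genos: Sequence[Dict[str, np.ndarray]],
                                 n_perm: int = 199, seed: int = 0) -> float:
    """Exact permutation test of allele-frequency homogeneity across
    populations: statistic = chi-square summed over loci, alleles permuted
    among populations within each locus."""
    rng = np.random.default_rng(seed)
    loci = list(pop_genos[0])
    sizes = [p[loci[0]].shape[0] for p in pop_genos]
    obs = 0.0
    null = np.zeros(n_perm)
    for locus in loci:
        vecs = [p[locus].ravel() for p in pop_genos]
        pooled = np.concatenate(vecs)
        k = int(pooled.max()) + 1
        bounds = np.cumsum([0] + [2 * s for s in sizes])
        counts = np.array([
            np.bincount(v, minlength=k) for v in vecs
        ])
        obs += _chi2_stat(counts)
        for b in range(n_perm):
            perm = rng.permutation(pooled)
            c = np.array([
                np.bincount(perm[bounds[i]:bounds[i + 1]], minlength=k)
                for i in range(len(sizes))
            ])
            null[b] += _chi2_stat(c)
    hits = int(np.sum(null >= obs - 1e-12))
    return (hits + 1) / (n_perm + 1)


def power_fst_detection(base_freqs: Dict[str, np.ndarray], target_fst: float,
                        sample_sizes: Sequence[int], n_reps: int, seed: int,
                        alpha: float = 0.05, n_perm: int = 199) -> float:
    """Probability that differentiation at a given true F_ST is detected.

    Populations are drifted to the target F_ST, sampled, and tested for
    allele-frequency homogeneity; the detection rate is the rejection
    fraction at level alpha (the POWSIM design).
    """
    from .synthdata import simulate_drift_populations
    rng = np.random.default_rng(seed)
    hits = 0
    for rep in range(n_reps):
        s1 = int(rng.integers(2 ** 31))
        pops = simulate_drift_populations(
            base_freqs, target_fst, len(sample_sizes), sample_sizes, seed=s1)
        p = homogeneity_permutation_test(pops, n_perm=n_perm,
                                         seed=int(rng.integers(2 ** 31)))
        if p <= alpha:
            hits += 1
    return hits / n_reps


# ---------------------------------------------------------------------------
# Mantel test

def mantel_test(d_gen: np.ndarray, d_geo: np.ndarray, n_perm: int = 9999,
                seed: int = 0) -> Tuple[float, float]:
    """Mantel matrix correlation with a one-sided (positive) permutation p.

    Rows/columns of one matrix are permuted jointly; all n! permutations
    are enumerated when that is fewer than n_perm.
    """
    d_gen = np.asarray(d_gen, dtype=float)
    d_geo = np.asarray(d_geo, dtype=float)
    if d_gen.shape != d_geo.shape or d_gen.shape[0] != d_gen.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    n = d_gen.shape[0]
    iu = np.triu_indices(n, k=1)

    def corr(m1: np.ndarray, m2: np.ndarray) -> float:
        x, y = m1[iu], m2[iu]
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(d_gen, d_geo)
    if math.factorial(n) <= max(n_perm, 1):
        hits = total = 0
        for perm in iter_permutations(range(n)):
            p = list(perm)
            r = corr(d_gen[np.ix_(p, p)], d_geo)
            total += 1
            if r >= r_obs - 1e-12:
                hits += 1
        return r_obs, hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if corr(d_gen[np.ix_(p, p)], d_geo) >= r_obs - 1e-12:
            hits += 1
    return r_obs, (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# spatial autocorrelation (Smouse & Peakall 1999)

def genotype_sq_distance_matrix(genotypes: Sequence[Dict[str, Optional[Tuple[int, int]]]],
                                loci: Sequence[str]) -> np.ndarray:
    """Pairwise squared genetic distance for codominant loci: per locus
    d^2 = 0.5 * sum over alleles of squared allele-count differences,
    averaged over loci typed in both individuals (pairwise deletion) and
    scaled to the full locus count."""
    n = len(genotypes)
    n_loci = len(loci)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            total = 0.0
            shared = 0
            for locus in loci:
                gi, gj = genotypes[i].get(locus), genotypes[j].get(locus)
                if gi is None or gj is None:
                    continue
                shared += 1
                ci, cj = Counter(gi), Counter(gj)
                alleles = set(ci) | set(cj)
                total += 0.5 * sum((ci[a] - cj[a]) ** 2 for a in alleles)
            if shared == 0:
                d[i, j] = d[j, i] = np.nan
            else:
                d[i, j] = d[j, i] = total * n_loci / shared
    return d


@dataclass
class AutocorrResult:
    class_edges: np.ndarray          # km, contiguous
    r: np.ndarray                    # autocorrelation per class
    null_low: np.ndarray
    null_high: np.ndarray
    boot_low: np.ndarray
    boot_high: np.ndarray
    n_pairs: np.ndarray
    heterogeneity_p: float


def _class_r(c: np.ndarray, pair_idx: List[np.ndarray]) -> np.ndarray:
    out = np.full(len(pair_idx), np.nan)
    diag = np.diag(c)
    for h, pairs in enumerate(pair_idx):
        if pairs.size == 0:
            continue
        i, j = pairs[:, 0], pairs[:, 1]
        num = 2.0 * c[i, j].sum()
        den = (diag[i] + diag[j]).sum()
        if den != 0:
            out[h] = num / den
    return out


def spatial_autocorrelation(genotypes, coords, loci, class_width_km: float = 50.0,
                            n_perm: int = 999, n_boot: int = 1000,
                            seed: int = 0) -> AutocorrResult:
    """Multivariate spatial autocorrelation of genotypes by distance class.

    r per class from the double-centered squared genetic distance matrix;
    95% null band by permuting genotypes over locations; error bars by
    bootstrap over pairs within class; heterogeneity test by comparing the
    summed squared standardized class departures against its permutation
    distribution.
    """
    from .io import great_circle_km
    n = len(genotypes)
    if n < 2:
        raise ValueError("need >= 2 individuals")
    d2 = genotype_sq_distance_matrix(genotypes, loci)
    if np.allclose(np.nan_to_num(d2), 0.0):
        raise ValueError("all genetic distances are zero: r undefined")
    geo = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            geo[i, j] = geo[j, i] = great_circle_km(
                coords[i][0], coords[i][1], coords[j][0], coords[j][1])
    max_d = geo.max()
    n_classes = max(1, int(math.ceil(max_d / class_width_km)))
    edges = np.arange(n_classes + 1) * class_width_km
    iu = np.triu_indices(n, k=1)
    pair_class = np.minimum((geo[iu] / class_width_km).astype(int), n_classes - 1)
    pair_idx = []
    for h in range(n_classes):
        mask = pair_class == h
        pair_idx.append(np.column_stack([iu[0][mask], iu[1][mask]]))
    # double centering: c = -1/2 J d2 J
    d2f = np.nan_to_num(d2, nan=float(np.nanmean(d2)))
    j_mat = np.eye(n) - np.ones((n, n)) / n
    c = -0.5 * j_mat @ d2f @ j_mat

    r_obs = _class_r(c, pair_idx)
    rng = np.random.default_rng(seed)
    null = np.full((n_perm, n_classes), np.nan)
    for b in range(n_perm):
        p = rng.permutation(n)
        null[b] = _class_r(c[np.ix_(p, p)], pair_idx)
    null_low = np.nanpercentile(null, 2.5, axis=0)
    null_high = np.nanpercentile(null, 97.5, axis=0)
    boot = np.full((n_boot, n_classes), np.nan)
    diag = np.diag(c)
    for b in range(n_boot):
        for h, pairs in enumerate(pair_idx):
            if pairs.size == 0:
                continue
            pick = pairs[rng.integers(len(pairs), size=len(pairs))]
            i, j = pick[:, 0], pick[:, 1]
            den = (diag[i] + diag[j]).sum()
            if den != 0:
                boot[b, h] = 2.0 * c[i, j].sum() / den
    mu = np.nanmean(null, axis=0)
    sd = np.nanstd(null, axis=0)
    sd[sd == 0] = np.nan
    omega_obs = float(np.nansum(((r_obs - mu) / sd) ** 2))
    omega_null = np.nansum(((null - mu) / sd) ** 2, axis=1)
    het_p = float((np.sum(omega_null >= omega_obs - 1e-12) + 1) / (n_perm + 1))
    return AutocorrResult(
        class_edges=edges, r=r_obs,
        null_low=null_low, null_high=null_high,
        boot_low=np.nanpercentile(boot, 2.5, axis=0),
        boot_high=np.nanpercentile(boot, 97.5, axis=0),
        n_pairs=np.array([len(p) for p in pair_idx]),
        heterogeneity_p=het_p,
    )
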