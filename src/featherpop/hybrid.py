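"""Hybrid-class simulation and direct-likelihood assignment.

Six categories are defined by gamete-pool composition: pure parentals P1
and P2 (both gametes from the own pool), F1 (one gamete from each pool),
F2 (both gametes from the F1 gamete pool, a 50:50 mixture), and the
backcrosses BC1 = F1 x P1 and BC2 = F1 x P2.  Simulation draws alleles
independently per locus from the class's two gamete pools; assignment
computes each class's multilocus genotype likelihood and a posterior under
a uniform prior.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

HYBRID_CLASSES = ("P1", "P2", "F1", "F2", "BC1", "BC2")

Freqs = Dict[str, Dict[int, float]]  # locus -> allele -> frequency
Pair = Tuple[int, int]

# gamete-pool mixture (weight on P1 frequencies) for each class's two gametes
_GAMETE_POOLS: Dict[str, Tuple[float, float]] = {
    "P1": (1.0, 1.0),
    "P2": (0.0, 0.0),
    "F1": (1.0, 0.0),
    "F2": (0.5, 0.5),
    "BC1": (0.5, 1.0),
    "BC2": (0.5, 0.0),
}


def _check_loci(freqs_p1: Freqs, freqs_p2: Freqs) -> List[str]:
    if set(freqs_p1) != set(freqs_p2):
        missing = set(freqs_p1) ^ set(freqs_p2)
        raise ValueError(f"loci absent from one parental pool: {sorted(missing)}")
    return list(freqs_p1)


def _pool(f1: Dict[int, float], f2: Dict[int, float], w: float) -> Dict[int, float]:
    alleles = set(f1) | set(f2)
    return {a: w * f1.get(a, 0.0) + (1 - w) * f2.get(a, 0.0) for a in alleles}


def simulate_hybrids(freqs_p1: Freqs, freqs_p2: Freqs, hybrid_class: str,
                     n: int, seed: int) -> List[Dict[str, Pair]]:
    """Simulate multilocus genotypes of a hybrid class from parental
    allele frequencies (each allele drawn independently from its gamete
    pool; linkage ignored, as in HybridLab-style simulation)."""
    if hybrid_class not in HYBRID_CLASSES:
        raise ValueError(f"unknown class {hybrid_class!r}")
    loci = _check_loci(freqs_p1, freqs_p2)
    w1, w2 = _GAMETE_POOLS[hybrid_class]
    rng = np.random.default_rng(seed)
    out: List[Dict[str, Pair]] = []
    pools = {}
    for locus in loci:
        pool_a = _pool(freqs_p1[locus], freqs_p2[locus], w1)
        pool_b = _pool(freqs_p1[locus], freqs_p2[locus], w2)
        pools[locus] = (
            (list(pool_a), np.array(list(pool_a.values()))),
            (list(pool_b), np.array(list(pool_b.values()))),
        )
    for _ in range(n):
        g: Dict[str, Pair] = {}
        for locus in loci:
            (al_a, pa), (al_b, pb) = pools[locus]
            a = al_a[rng.choice(len(al_a), p=pa / pa.sum())]
            b = al_b[rng.choice(len(al_b), p=pb / pb.sum())]
            g[locus] = (a, b) if a <= b else (b, a)
        out.append(g)
    return out


def _floor_freqs(freqs: Freqs, observed_alleles: Dict[str, set],
                 floor: float) -> Freqs:
    out: Freqs = {}
    for locus, f in freqs.items():
        f = dict(f)
        for a in observed_alleles.get(locus, set()):
            if f.get(a, 0.0) <= 0.0:
                f[a] = floor
        total = sum(f.values())
        out[locus] = {a: v / total for a, v in f.items()}
    return out


def class_likelihood(genotype: Dict[str, Optional[Pair]], freqs_p1: Freqs,
                     freqs_p2: Freqs, floor: float = 1e-4) -> Dict[str, float]:
    """Posterior over the six hybrid classes for one multilocus genotype.

    Per class and locus the genotype probability follows from the class's
    two gamete pools; unseen alleles get a small frequency floor (then
    renormalized) so field noise cannot zero a likelihood.  Uniform prior.
    """
    loci = _check_loci(freqs_p1, freqs_p2)
    observed = {l: set(genotype[l]) for l in loci
                if genotype.get(l) is not None}
    if not observed:
        raise ValueError("no typed loci")
    fp1 = _floor_freqs(freqs_p1, observed, floor)
    fp2 = _floor_freqs(freqs_p2, observed, floor)
    logl = {}
    for cls in HYBRID_CLASSES:
        w1, w2 = _GAMETE_POOLS[cls]
        ll = 0.0
        for locus, alleles in observed.items():
            a, b = genotype[locus]
            pool_a = _pool(fp1[locus], fp2[locus], w1)
            pool_b = _pool(fp1[locus], fp2[locus], w2)
            if a == b:
                prob = pool_a.get(a, 0.0) * pool_b.get(a, 0.0)
            else:
                prob = (pool_a.get(a, 0.0) * pool_b.get(b, 0.0)
                        + pool_a.get(b, 0.0) * pool_b.get(a, 0.0))
            ll += np.log(max(prob, 1e-300))
        logl[cls] = ll
    m = max(logl.values())
    weights = {c: np.exp(v - m) for c, v in logl.items()}
    z = sum(weights.values())
    return {c: w / z for c, w in weights.items()}


def classify(genotype: Dict[str, Optional[Pair]], freqs_p1: Freqs,
             freqs_p2: Freqs,
             rng: Optional[np.random.Generator] = None) -> Tuple[str, float]:
    """Best class and its posterior probability; exact posterior ties
    (e.g. uninformative loci) are broken at random when an rng is given,
    otherwise by class order."""
    post = class_likelihood(genotype, freqs_p1, freqs_p2)
    top = max(post.values())
    tied = [c for c in HYBRID_CLASSES if post[c] >= top - 1e-12]
    if rng is not None and len(tied) > 1:
        best = tied[int(rng.integers(len(tied)))]
    else:
        best = tied[0]
    return best, post[best]


def hybrid_benchmark(freqs_p1: Freqs, freqs_p2: Freqs, n_per_class: int,
                     seed: int) -> Dict[str, Dict[str, float]]:
    """Simulate each class, classify, and report the confusion matrix
    (rows: true class; columns: fraction assigned to each class)."""
    rng = np.random.default_rng(seed)
    confusion: Dict[str, Dict[str, float]] = {}
    for cls in HYBRID_CLASSES:
        sims = simulate_hybrids(freqs_p1, freqs_p2, cls, n_per_class,
                                seed=int(rng.integers(2 ** 31)))
        row = {c: 0.0 for c in HYBRID_CLASSES}
        for g in sims:
            assigned, _ = classify(g, freqs_p1, freqs_p2, rng=rng)
            row[assigned] += 1.0
        confusion[cls] = {c: v / n_per_class for c, v in row.items()}
    return confusion
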