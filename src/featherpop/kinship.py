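"""Pairwise relatedness, relationship classification, parentage exclusion
and construction of the non-kin dataset.

Relatedness between a dyad is estimated by maximum likelihood over the
identity-by-descent coefficients (k0, k1, k2): the probability that the two
individuals share 0, 1 or 2 alleles IBD at a locus.  r-hat = k1/2 + k2.
Relationship classes are compared at their canonical coefficients:
unrelated U = (1,0,0), half-sib HS = (1/2,1/2,0), full-sib FS =
(1/4,1/2,1/4), parent-offspring PO = (0,1,0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

RELATIONSHIP_CLASSES: Dict[str, Tuple[float, float, float]] = {
    "U": (1.0, 0.0, 0.0),
    "HS": (0.5, 0.5, 0.0),
    "FS": (0.25, 0.5, 0.25),
    "PO": (0.0, 1.0, 0.0),
}

Pair = Tuple[int, int]


def _genotype_prob(g: Pair, freqs: Dict[int, float]) -> float:
    a, b = g
    pa, pb = freqs.get(a, 0.0), freqs.get(b, 0.0)
    return pa * pa if a == b else 2 * pa * pb


def _ibd1_prob(g1: Pair, g2: Pair, freqs: Dict[int, float]) -> float:
    """Joint probability of an unordered genotype pair given one pair of
    alleles IBD (standard transition probabilities)."""
    a, b = g1
    c, d = g2
    p = freqs
    if a == b and c == d:
        return p[a] ** 3 if a == c else 0.0
    if a == b and c != d:
        return p[a] ** 2 * (p[c] + p[d]) if a in (c, d) else 0.0
    if a != b and c == d:
        return p[c] ** 2 * (p[a] + p[b]) if c in (a, b) else 0.0
    # both heterozygous
    shared = set(g1) & set(g2)
    if not shared:
        return 0.0
    if set(g1) == set(g2):
        return p[a] * p[b] * (p[a] + p[b])
    s = shared.pop()
    others = [x for x in (a, b, c, d) if x != s]
    return p[s] * p[others[0]] * p[others[1]]


def _ibd2_prob(g1: Pair, g2: Pair, freqs: Dict[int, float]) -> float:
    return _genotype_prob(g1, freqs) if set(g1) == set(g2) and tuple(sorted(g1)) == tuple(sorted(g2)) else 0.0


def _pair_prob_null(g1_obs: Pair, g2_obs: Pair, freqs: Dict[int, float],
                    k: Tuple[float, float, float], p_null: float) -> float:
    """Dyad probability with the null modelled as an extra recessive
    allele: an observed homozygote aa may truly be aa or a/null."""
    NULL = -1
    f = dict(freqs)
    scale = 1.0 - p_null
    f = {a: v * scale for a, v in f.items()}
    f[NULL] = p_null

    def expand(g: Pair) -> List[Pair]:
        a, b = g
        if a == b:
            return [(a, a), tuple(sorted((a, NULL)))]
        return [g]

    total = 0.0
    for t1 in expand(g1_obs):
        for t2 in expand(g2_obs):
            total += (k[0] * _genotype_prob(t1, f) * _genotype_prob(t2, f)
                      + k[1] * _ibd1_prob(t1, t2, f)
                      + k[2] * _ibd2_prob(t1, t2, f))
    return total


def dyad_log_likelihood(
    g1: Dict[str, Optional[Pair]],
    g2: Dict[str, Optional[Pair]],
    freqs: Dict[str, Dict[int, float]],
    k: Tuple[float, float, float],
    null_freqs: Optional[Dict[str, float]] = None,
) -> float:
    """Log-likelihood of a dyad's multilocus genotypes given IBD
    coefficients k = (k0, k1, k2); loci are independent, loci missing in
    either individual are skipped.  With ``null_freqs`` the null allele is
    modelled as an extra recessive allele class."""
    ll = 0.0
    used = 0
    for locus, f in freqs.items():
        p1, p2 = g1.get(locus), g2.get(locus)
        if p1 is None or p2 is None:
            continue
        for a in set(p1) | set(p2):
            if a not in f:
                raise ValueError(f"allele {a} at {locus} absent from frequency table")
        if null_freqs and null_freqs.get(locus, 0.0) > 0:
            prob = _pair_prob_null(p1, p2, f, k, null_freqs[locus])
        else:
            prob = (k[0] * _genotype_prob(p1, f) * _genotype_prob(p2, f)
                    + k[1] * _ibd1_prob(p1, p2, f)
                    + k[2] * _ibd2_prob(p1, p2, f))
        ll += math.log(max(prob, 1e-300))
        used += 1
    if used == 0:
        raise ValueError("no loci typed in both individuals")
    return ll


@dataclass
class DyadRelatedness:
    id1: str
    id2: str
    r_hat: float
    k_hat: Tuple[float, float, float]
    best_class: str
    class_loglik: Dict[str, float] = field(default_factory=dict)


def ml_relatedness(
    id1: str, g1: Dict[str, Optional[Pair]],
    id2: str, g2: Dict[str, Optional[Pair]],
    freqs: Dict[str, Dict[int, float]],
    null_freqs: Optional[Dict[str, float]] = None,
    grid_step: float = 0.05,
) -> DyadRelatedness:
    """Maximum-likelihood IBD coefficients over the (k0,k1,k2) simplex.

    A coarse grid seeds a local simplex-constrained refinement; the dyad is
    classified by the best-supported canonical relationship class."""

    def nll(k01: np.ndarray) -> float:
        k0, k1 = k01
        k2 = 1.0 - k0 - k1
        if k0 < 0 or k1 < 0 or k2 < -1e-12:
            return 1e12
        return -dyad_log_likelihood(g1, g2, freqs, (k0, k1, max(k2, 0.0)),
                                    null_freqs)

    best = None
    steps = int(round(1 / grid_step))
    for i in range(steps + 1):
        for j in range(steps + 1 - i):
            k0, k1 = i * grid_step, j * grid_step
            v = nll(np.array([k0, k1]))
            if best is None or v < best[0]:
                best = (v, (k0, k1))
    res = minimize(nll, np.array(best[1]), method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-8})
    k0, k1 = res.x if res.fun < best[0] else best[1]
    k0, k1 = max(k0, 0.0), max(k1, 0.0)
    k2 = max(1.0 - k0 - k1, 0.0)
    total = k0 + k1 + k2
    k_hat = (k0 / total, k1 / total, k2 / total)
    class_ll = {
        name: dyad_log_likelihood(g1, g2, freqs, k, null_freqs)
        for name, k in RELATIONSHIP_CLASSES.items()
    }
    best_class = max(class_ll, key=class_ll.get)
    return DyadRelatedness(
        id1=id1, id2=id2,
        r_hat=k_hat[1] / 2 + k_hat[2],
        k_hat=k_hat, best_class=best_class, class_loglik=class_ll,
    )


def mendelian_mismatches(offspring: Dict[str, Optional[Pair]],
                         parent: Dict[str, Optional[Pair]],
                         parent2: Optional[Dict[str, Optional[Pair]]] = None) -> int:
    """Loci at which the offspring cannot have received an allele from the
    candidate parent (or, with two parents, any compatible allele split)."""
    mm = 0
    for locus, go in offspring.items():
        if go is None:
            continue
        gp = parent.get(locus)
        if gp is None:
            continue
        if parent2 is not None:
            gq = parent2.get(locus)
            if gq is None:
                if not (set(go) & set(gp)):
                    mm += 1
                continue
            ok = any(
                a in gp and b in gq
                for a, b in (go, (go[1], go[0]))
            )
            if not ok:
                mm += 1
        else:
            if not (set(go) & set(gp)):
                mm += 1
    return mm


@dataclass
class ParentageAssignment:
    offspring: str
    parents: Tuple[str, ...]        # one id, or a pair under monogamy
    n_mismatch: int
    log_likelihood: float


def parentage_exclusion(
    offspring: Dict[str, Dict[str, Optional[Pair]]],
    candidates: Dict[str, Dict[str, Optional[Pair]]],
    freqs: Dict[str, Dict[int, float]],
    max_mendel_mismatch: int = 1,
    monogamy: bool = True,
) -> Dict[str, List[ParentageAssignment]]:
    """Exclusion-based parentage: retain candidates (or monogamous pairs)
    whose Mendelian-incompatible loci are within tolerance, ranked by the
    parent-offspring dyad likelihood; individuals are never their own
    parent."""
    out: Dict[str, List[ParentageAssignment]] = {}
    cand_ids = sorted(candidates)
    po = RELATIONSHIP_CLASSES["PO"]
    for off_id, g_off in offspring.items():
        found: List[ParentageAssignment] = []
        if monogamy:
            for i, a in enumerate(cand_ids):
                if a == off_id:
                    continue
                for b in cand_ids[i + 1:]:
                    if b == off_id:
                        continue
                    mm = mendelian_mismatches(g_off, candidates[a], candidates[b])
                    if mm <= max_mendel_mismatch:
                        ll = (dyad_log_likelihood(g_off, candidates[a], freqs, po)
                              + dyad_log_likelihood(g_off, candidates[b], freqs, po))
                        found.append(ParentageAssignment(off_id, (a, b), mm, ll))
        else:
            for a in cand_ids:
                if a == off_id:
                    continue
                mm = mendelian_mismatches(g_off, candidates[a])
                if mm <= max_mendel_mismatch:
                    ll = dyad_log_likelihood(g_off, candidates[a], freqs, po)
                    found.append(ParentageAssignment(off_id, (a,), mm, ll))
        found.sort(key=lambda x: (-x.log_likelihood, x.parents))
        out[off_id] = found
    return out


@dataclass
class KinPruneReport:
    removed: Dict[str, str]         # id -> reason
    retained: List[str]


def prune_kin(
    individual_ids: Sequence[str],
    dyads: Sequence[DyadRelatedness],
    r_threshold: float = 0.55,
    parents: Sequence[str] = (),
    fs_support: float = 2.0,
) -> KinPruneReport:
    """Build the non-kin subset.

    Removes inferred parents; keeps exactly one member (lowest id) of each
    full-sib cluster (connected components of FS-classified dyads whose FS
    support exceeds the next-best class by ``fs_support`` log units); then
    greedily removes the fewest individuals so no remaining dyad exceeds
    ``r_threshold`` (highest-degree first, ties by id)."""
    removed: Dict[str, str] = {}
    for p in parents:
        removed[p] = "parent"
    # full-sib clusters
    import networkx as nx
    fs_graph = nx.Graph()
    alive = [i for i in individual_ids if i not in removed]
    fs_graph.add_nodes_from(alive)
    for d in dyads:
        if d.id1 in removed or d.id2 in removed:
            continue
        if d.best_class == "FS":
            second = max(v for c, v in d.class_loglik.items() if c != "FS")
            if d.class_loglik["FS"] - second >= fs_support:
                fs_graph.add_edge(d.id1, d.id2)
    for comp in nx.connected_components(fs_graph):
        if len(comp) > 1:
            keep = min(comp)
            for m in sorted(comp):
                if m != keep:
                    removed[m] = "extra-sibling"
    # greedy threshold pruning
    hot = nx.Graph()
    hot.add_nodes_from(i for i in individual_ids if i not in removed)
    for d in dyads:
        if d.id1 in removed or d.id2 in removed:
            continue
        if d.r_hat > r_threshold:
            hot.add_edge(d.id1, d.id2)
    while hot.number_of_edges() > 0:
        worst = max(hot.degree, key=lambda nd: (nd[1], nd[0]))[0]
        # ties by id: recompute max with deterministic ordering
        max_deg = max(dict(hot.degree).values())
        worst = min(n for n, deg in hot.degree if deg == max_deg)
        removed[worst] = f"r>{r_threshold}"
        hot.remove_node(worst)
    retained = [i for i in individual_ids if i not in removed]
    return KinPruneReport(removed=removed, retained=retained)
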