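"""Mitochondrial control-region analyses.

Haplotype collapsing, haplotype and nucleotide diversity, Tajima's D and
Fu's Fs neutrality tests, Jukes-Cantor distances, AMOVA-based phi_ST with
permutation tests, a minimum-spanning haplotype network, and a screen for
Numts (nuclear copies of mitochondrial DNA) by divergence from reference
haplotypes.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

AMBIGUOUS = {"N", "-"}


def _check_aligned(seqs: Sequence[str]) -> None:
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"sequences are not aligned: lengths {sorted(lengths)}")


def hamming(s1: str, s2: str, pairwise_deletion: bool = True) -> int:
    """Substitution count; gap/N positions are pairwise-deleted."""
    if len(s1) != len(s2):
        raise ValueError("unequal sequence lengths")
    return sum(
        a != b for a, b in zip(s1, s2)
        if not (pairwise_deletion and (a in AMBIGUOUS or b in AMBIGUOUS))
    )


@dataclass
class HaplotypeTable:
    """Collapsed haplotypes with representative sequences and counts."""

    sequences: Dict[str, str]                       # hap id -> representative
    members: Dict[str, List[str]]                   # hap id -> sequence ids
    region_counts: Dict[str, Counter] = field(default_factory=dict)
    ambiguous_merges: List[str] = field(default_factory=list)

    @property
    def counts(self) -> Dict[str, int]:
        return {h: len(m) for h, m in self.members.items()}

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)


def collapse_haplotypes(alignment: Sequence[Tuple[str, str]],
                        regions: Optional[Dict[str, str]] = None) -> HaplotypeTable:
    """Merge identical aligned sequences into haplotypes.

    Sequences containing ambiguous bases (N) are merged into a haplotype
    when they match it at every unambiguous position (flagged); haplotype
    ids H1, H2, ... follow first occurrence.
    """
    seqs = [s.upper() for _, s in alignment]
    if seqs:
        _check_aligned(seqs)
    table = HaplotypeTable(sequences={}, members={})
    order: List[str] = []
    for (seq_id, _), seq in zip(alignment, seqs):
        placed = None
        if not (set(seq) & AMBIGUOUS):
            for hap_id in order:
                if table.sequences[hap_id] == seq:
                    placed = hap_id
                    break
        else:
            for hap_id in order:
                rep = table.sequences[hap_id]
                ok = all(
                    a == b or a in AMBIGUOUS or b in AMBIGUOUS
                    for a, b in zip(seq, rep)
                )
                if ok:
                    placed = hap_id
                    table.ambiguous_merges.append(seq_id)
                    break
        if placed is None:
            placed = f"H{len(order) + 1}"
            order.append(placed)
            table.sequences[placed] = seq
            table.members[placed] = []
        table.members[placed].append(seq_id)
    if regions is not None:
        for hap_id, members in table.members.items():
            table.region_counts[hap_id] = Counter(
                regions[m] for m in members if m in regions
            )
    return table


def haplotype_diversity(counts: Sequence[int]) -> float:
    """h = n(1 - sum f^2)/(n - 1)."""
    n = sum(counts)
    if n < 2:
        raise ValueError("need n >= 2")
    f2 = sum((c / n) ** 2 for c in counts)
    return n * (1.0 - f2) / (n - 1)


def mean_pairwise_differences(seqs: Sequence[str]) -> float:
    if len(seqs) < 2:
        raise ValueError("need n >= 2")
    _check_aligned(seqs)
    total = 0
    n_pairs = 0
    for s1, s2 in combinations(seqs, 2):
        total += hamming(s1, s2)
        n_pairs += 1
    return total / n_pairs


def nucleotide_diversity(seqs: Sequence[str]) -> float:
    """pi: mean pairwise difference per site."""
    return mean_pairwise_differences(seqs) / len(seqs[0])


def _segregating_sites(seqs: Sequence[str]) -> int:
    s = 0
    for col in zip(*seqs):
        bases = {b for b in col if b not in AMBIGUOUS}
        if len(bases) > 1:
            s += 1
    return s


def tajimas_d(seqs: Sequence[str]) -> float:
    """Tajima's D from mean pairwise differences and segregating sites."""
    n = len(seqs)
    if n < 4:
        raise ValueError("need n >= 4")
    _check_aligned(seqs)
    s = _segregating_sites(seqs)
    if s == 0:
        raise ValueError("no segregating sites: D undefined")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    k_hat = mean_pairwise_differences(seqs)
    return (k_hat - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def _log_stirling_first_row(n: int) -> np.ndarray:
    """log |S(n, k)| for k = 0..n (unsigned Stirling numbers, first kind)."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |S(0,0)| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        # |S(m,k)| = |S(m-1,k-1)| + (m-1) |S(m-1,k)|
        shifted = np.concatenate([[-np.inf], row[:-1]])
        with np.errstate(divide="ignore"):
            scaled = row + (math.log(m - 1) if m > 1 else -np.inf)
        new = np.logaddexp(shifted, scaled)
        row = new
    return row


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """P(K = k) for k = 0..n under the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    log_s = _log_stirling_first_row(n)
    log_rising = sum(math.log(theta + i) for i in range(n))
    ks = np.arange(n + 1)
    with np.errstate(invalid="ignore"):
        logp = log_s + ks * math.log(theta) - log_rising
    p = np.exp(logp)
    p[~np.isfinite(p)] = 0.0
    return p


def fus_fs(seqs: Sequence[str], k_obs: Optional[int] = None) -> float:
    """Fu's Fs: Fs = ln(S'/(1-S')), S' = P(K >= k_obs | theta = pi-hat)
    under the Ewens sampling distribution."""
    n = len(seqs)
    if n < 2:
        raise ValueError("need n >= 2")
    theta = mean_pairwise_differences(seqs)
    if theta <= 0:
        raise ValueError("all sequences identical: Fs undefined")
    if k_obs is None:
        k_obs = len(set(seqs))
    p = ewens_k_distribution(n, theta)
    s_prime = float(p[k_obs:].sum())
    s_prime = min(max(s_prime, 1e-15), 1 - 1e-15)
    return math.log(s_prime / (1 - s_prime))


def jc_distance(s1: str, s2: str) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - (4/3) p), pairwise deletion."""
    compared = [
        (a, b) for a, b in zip(s1, s2)
        if a not in AMBIGUOUS and b not in AMBIGUOUS
    ]
    if len(s1) != len(s2):
        raise ValueError("unequal sequence lengths")
    if not compared:
        raise ValueError("no comparable sites")
    p = sum(a != b for a, b in compared) / len(compared)
    if p >= 0.75:
        raise ValueError(f"p = {p:.3f} >= 3/4: JC distance undefined")
    return -0.75 * math.log(1 - 4 * p / 3)


@dataclass
class AmovaResult:
    sigma_among: float
    sigma_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float


def _amova_components(d2: np.ndarray, labels: np.ndarray) -> Tuple[float, float]:
    """Variance components (among, within) from squared distances."""
    n = len(labels)
    groups = np.unique(labels)
    ssd_total = d2[np.triu_indices(n, k=1)].sum() / n
    ssd_within = 0.0
    sizes = []
    for g in groups:
        idx = np.where(labels == g)[0]
        sizes.append(len(idx))
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ssd_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ssd_among = ssd_total - ssd_within
    df_among = len(groups) - 1
    df_within = n - len(groups)
    sigma_w = ssd_within / df_within if df_within > 0 else float("nan")
    sizes_arr = np.array(sizes, dtype=float)
    n_eff = (n - np.sum(sizes_arr ** 2) / n) / df_among if df_among > 0 else float("nan")
    ms_among = ssd_among / df_among if df_among > 0 else float("nan")
    sigma_a = (ms_among - sigma_w) / n_eff
    return sigma_a, sigma_w


def amova_phist(seqs: Sequence[str], regions: Sequence[str], n_perm: int = 999,
                seed: int = 0, min_per_region: int = 2) -> AmovaResult:
    """AMOVA on squared Jukes-Cantor distances: variance components,
    phi_ST = sigma_a/(sigma_a + sigma_w), permutation p-value (individuals
    permuted among regions).  Regions with fewer than ``min_per_region``
    members are excluded."""
    counts = Counter(regions)
    keep = [i for i, r in enumerate(regions) if counts[r] >= min_per_region]
    seqs = [seqs[i] for i in keep]
    labels = np.array([regions[i] for i in keep])
    if len(set(labels)) < 2:
        raise ValueError("need >= 2 regions with >= 2 individuals")
    n = len(seqs)
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d2[i, j] = d2[j, i] = jc_distance(seqs[i], seqs[j]) ** 2
    sigma_a, sigma_w = _amova_components(d2, labels)
    total = sigma_a + sigma_w
    phi = sigma_a / total if total != 0 else 0.0
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = labels[rng.permutation(n)]
        sa, sw = _amova_components(d2, perm)
        t = sa + sw
        if (sa / t if t != 0 else 0.0) >= phi - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    tot = max(total, 1e-300)
    return AmovaResult(
        sigma_among=sigma_a, sigma_within=sigma_w,
        pct_among=100 * sigma_a / tot, pct_within=100 * sigma_w / tot,
        phi_st=phi, p_value=p,
    )


def pairwise_phist(seqs: Sequence[str], regions: Sequence[str], n_perm: int = 999,
                   seed: int = 0) -> Dict[Tuple[str, str], Tuple[float, float]]:
    """Pairwise phi_ST between regions with permutation p-values."""
    out: Dict[Tuple[str, str], Tuple[float, float]] = {}
    names = sorted(set(regions))
    for i, ra in enumerate(names):
        for rb in names[i + 1:]:
            idx = [k for k, r in enumerate(regions) if r in (ra, rb)]
            res = amova_phist([seqs[k] for k in idx], [regions[k] for k in idx],
                              n_perm=n_perm, seed=seed)
            out[(ra, rb)] = (res.phi_st, res.p_value)
    return out


def msn_network(table: HaplotypeTable) -> nx.Graph:
    """Minimum-spanning haplotype network on Hamming distances.

    All co-minimal edges are retained: edges are added in order of weight,
    and every edge of the current weight that joins two distinct components
    (as of the start of that weight class) is kept.  Nodes carry a ``size``
    attribute equal to the haplotype count.
    """
    g = nx.Graph()
    for hap_id, seq in table.sequences.items():
        g.add_node(hap_id, size=len(table.members[hap_id]), sequence=seq)
    ids = list(table.sequences)
    if len(ids) < 2:
        return g
    edges = []
    for a, b in combinations(ids, 2):
        edges.append((hamming(table.sequences[a], table.sequences[b]), a, b))
    edges.sort()
    uf = {h: h for h in ids}

    def find(x):
        while uf[x] != x:
            uf[x] = uf[uf[x]]
            x = uf[x]
        return x

    i = 0
    while i < len(edges):
        w = edges[i][0]
        batch = []
        while i < len(edges) and edges[i][0] == w:
            batch.append(edges[i])
            i += 1
        # component structure frozen at the start of this weight class
        comp = {h: find(h) for h in ids}
        to_join = []
        for wt, a, b in batch:
            if comp[a] != comp[b]:
                g.add_edge(a, b, weight=wt)
                to_join.append((a, b))
        for a, b in to_join:
            ra, rb = find(a), find(b)
            if ra != rb:
                uf[ra] = rb
    return g


def flag_numts(sequences: Sequence[Tuple[str, str]],
               reference_haplotypes: Sequence[str],
               max_divergence: int = 5) -> Dict[str, bool]:
    """Flag putative Numts: sequences more than ``max_divergence``
    substitutions from every reference haplotype."""
    if not reference_haplotypes:
        raise ValueError("reference haplotype set is empty")
    out: Dict[str, bool] = {}
    for seq_id, seq in sequences:
        dmin = min(hamming(seq.upper(), ref.upper()) for ref in reference_haplotypes)
        out[seq_id] = dmin > max_divergence
    return out
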