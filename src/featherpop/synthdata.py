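"""Ground-truthed synthetic feather-sampling populations.

Emulates the statistical structure of a non-invasively sampled goose
population: monogamous families with broods in four geographic regions,
maternally inherited mtDNA haplotypes with regional structure, panmictic
nuclear microsatellites, hidden null alleles, and replicate feather samples
corrupted by allele dropout (ADO), false alleles (FA) and missing data.

Null alleles are modelled as a hidden allele (label 0) segregating at each
affected locus; a genotype carrying one null appears homozygous for the
visible allele and a null homozygote appears as a missing locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datamodel import Genotype, SampleRecord, Sex

NULL = 0  # hidden null-allele label

REGION_NAMES = (
    "WesternFinland",
    "EasternFinlandKainuu",
    "NOstrobothniaSLapland",
    "Lapland",
)
# region the tilted haplotype frequencies differentiate (mirrors the study
# area's core breeding region)
DIFFERENTIATED_REGION = "NOstrobothniaSLapland"

FEMALE_FRAGMENT_BP = 287
MALE_FRAGMENT_BP = 297

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic population.

    Defaults reproduce the field study's conditions: 4 regions, 22 loci,
    mean ADO 0.041, mean FA 0.009, null-allele rate 0.034, ~4% introgressed
    mtDNA, nuclear panmixia and mtDNA regional structure around phi_ST 0.15.
    """

    seed: int = 0
    n_regions: int = 4
    n_pairs_per_region: int = 5
    n_singles_per_region: int = 70
    brood_size_mean: float = 2.5
    brood_size_max: int = 6
    n_loci: int = 22
    alleles_per_locus: int = 8
    nuclear_fst_target: float = 0.0
    mtdna_phist_target: float = 0.15
    ado_rate: float = 0.041
    fa_rate: float = 0.009
    null_rate: float = 0.034
    missing_rate: float = 0.03
    sex_marker_missing_rate: float = 0.12
    gosling_sample_fraction: float = 0.5
    replicates_min: int = 1
    replicates_max: int = 6
    introgressed_haplotype_freq: float = 0.04
    hybrid_fraction: float = 0.0
    n_haplotypes: int = 6
    seq_length: int = 210

    def __post_init__(self) -> None:
        for name in ("ado_rate", "fa_rate", "null_rate", "missing_rate",
                     "sex_marker_missing_rate", "introgressed_haplotype_freq",
                     "hybrid_fraction", "nuclear_fst_target",
                     "gosling_sample_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.mtdna_phist_target < 1.0:
            raise ValueError("mtdna_phist_target must be in [0, 1)")


@dataclass
class TrueIndividual:
    individual_id: str
    genotype: Dict[str, Tuple[int, int]]  # true alleles incl. hidden nulls (0)
    haplotype_id: str
    sex: Sex
    region: str
    site_id: str
    latitude: float
    longitude: float
    dam: Optional[str] = None
    sire: Optional[str] = None


@dataclass
class TruthSet:
    """Ground truth: individuals, pedigree, haplotype sequences, loci."""

    individuals: List[TrueIndividual]
    locus_names: List[str]
    allele_labels: Dict[str, List[int]]  # visible alleles per locus
    haplotype_seqs: Dict[str, str]
    config: SimulationConfig

    def by_id(self) -> Dict[str, TrueIndividual]:
        return {i.individual_id: i for i in self.individuals}


def _mutate(seq: np.ndarray, positions: Sequence[int], rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for pos in positions:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return out


def _make_haplotypes(config: SimulationConfig, rng: np.random.Generator) -> Dict[str, str]:
    """A star-like haplotype cloud plus one divergent introgressed lineage."""
    root = _BASES[rng.integers(4, size=config.seq_length)]
    haps = {"H1": root}
    used: set = set()
    for k in range(2, config.n_haplotypes + 1):
        n_subs = int(rng.integers(1, 4))
        positions = rng.choice(config.seq_length, size=n_subs, replace=False)
        positions = [p for p in positions if p not in used]
        used.update(positions)
        haps[f"H{k}"] = _mutate(root, positions, rng)
    far = [p for p in range(config.seq_length) if p not in used]
    positions = rng.choice(far, size=10, replace=False)
    haps["INTRO"] = _mutate(root, positions, rng)
    return {k: "".join(v) for k, v in haps.items()}


def _pairwise_hap_distance(haps: Dict[str, str]) -> Tuple[List[str], np.ndarray]:
    ids = list(haps)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = sum(a != b for a, b in zip(haps[ids[i]], haps[ids[j]]))
            d[i, j] = d[j, i] = diff
    return ids, d


def _population_phist(freqs: np.ndarray, d2: np.ndarray) -> float:
    """Analytic population-level phi_ST for given per-region haplotype
    frequencies (rows) and squared inter-haplotype distances:
    (piB - piW)/piB with piW the mean within-region and piB the mean
    between-region expected squared distance."""
    r = freqs.shape[0]
    pi_within = np.mean([f @ d2 @ f for f in freqs])
    between = [freqs[i] @ d2 @ freqs[j]
               for i in range(r) for j in range(r) if i != j]
    pi_between = float(np.mean(between))
    if pi_between <= 0:
        raise ValueError("zero molecular diversity: phi_ST target infeasible")
    return (pi_between - pi_within) / pi_between


def regional_haplotype_freqs(
    base: np.ndarray, d2: np.ndarray, target: float, n_regions: int,
    diff_region_idx: int = 2,
) -> np.ndarray:
    """Per-region haplotype frequencies hitting a population phi_ST target.

    One region's frequencies are tilted toward its locally common haplotype
    by a mixing weight found by bisection so that the analytic population
    phi_ST equals ``target``; the remaining regions share the base
    frequencies (the study's observed pattern: one differentiated region).
    """
    if target <= 0:
        return np.tile(base, (n_regions, 1))
    if np.count_nonzero(base) < 2:
        raise ValueError("phi_ST target infeasible with fewer than 2 haplotypes")
    # tilt toward the haplotype most distant from the frequency-weighted mean
    tilt_idx = int(np.argmax(d2 @ base))
    delta = np.zeros_like(base)
    delta[tilt_idx] = 1.0

    def phist_at(m: float) -> float:
        freqs = np.tile(base, (n_regions, 1))
        freqs[diff_region_idx] = (1 - m) * base + m * delta
        return _population_phist(freqs, d2)

    lo, hi = 0.0, 1.0
    if phist_at(hi) < target:
        raise ValueError(f"phi_ST target {target} unreachable (max {phist_at(hi):.3f})")
    for _ in range(60):
        mid = (lo + hi) / 2
        if phist_at(mid) < target:
            lo = mid
        else:
            hi = mid
    m = (lo + hi) / 2
    freqs = np.tile(base, (n_regions, 1))
    freqs[diff_region_idx] = (1 - m) * base + m * delta
    return freqs


# Finland-like region centres (lat, lon), ~150-400 km apart
_REGION_CENTRES = [(62.5, 22.0), (64.0, 28.5), (65.8, 26.5), (68.0, 25.5)]


def simulate_population(config: SimulationConfig) -> TruthSet:
    """Simulate monogamous founder pairs and Mendelian broods per region.

    Nuclear allele frequencies are shared across regions (drifted apart only
    if ``nuclear_fst_target`` > 0); each locus carries a hidden null allele
    at frequency ``null_rate``.  Haplotype frequencies are region-specific,
    calibrated so the population phi_ST equals ``mtdna_phist_target``; the
    introgressed lineage segregates at ``introgressed_haplotype_freq``.
    """
    rng = np.random.default_rng(config.seed)
    locus_names = [f"L{i + 1:02d}" for i in range(config.n_loci)]
    allele_labels = {
        name: [100 + 4 * a for a in range(config.alleles_per_locus)]
        for name in locus_names
    }

    # base visible-allele frequencies, rescaled to leave room for the null
    base_freqs: Dict[str, np.ndarray] = {}
    for name in locus_names:
        f = rng.dirichlet(np.full(config.alleles_per_locus, 2.0))
        base_freqs[name] = f * (1.0 - config.null_rate)

    region_names = list(REGION_NAMES[: config.n_regions]) + [
        f"Region{i + 1}" for i in range(4, config.n_regions)
    ]

    # per-region nuclear frequencies (shared when target is 0)
    region_freqs: Dict[str, Dict[str, np.ndarray]] = {}
    for ri, region in enumerate(region_names):
        region_freqs[region] = {}
        for name in locus_names:
            vis = base_freqs[name]
            if config.nuclear_fst_target > 0:
                fst = config.nuclear_fst_target
                alpha = np.maximum(vis / vis.sum() * (1 - fst) / fst, 1e-3)
                drifted = rng.dirichlet(alpha) * vis.sum()
            else:
                drifted = vis
            region_freqs[region][name] = np.append(drifted, config.null_rate)

    haps = _make_haplotypes(config, rng)
    hap_ids, hap_d = _pairwise_hap_distance(haps)
    intro_idx = hap_ids.index("INTRO")
    native = [i for i in range(len(hap_ids)) if i != intro_idx]
    base_hap = np.zeros(len(hap_ids))
    raw = rng.dirichlet(np.full(len(native), 1.5))
    # star-like skew: make one haplotype clearly dominant, as in real data
    raw = np.sort(raw)[::-1]
    base_hap[native] = raw * (1.0 - config.introgressed_haplotype_freq)
    base_hap[intro_idx] = config.introgressed_haplotype_freq
    hap_freqs = regional_haplotype_freqs(
        base_hap, hap_d ** 2, config.mtdna_phist_target, config.n_regions,
        diff_region_idx=min(2, config.n_regions - 1),
    )

    def draw_genotype(region: str) -> Dict[str, Tuple[int, int]]:
        g = {}
        for name in locus_names:
            f = region_freqs[region][name]
            labels = allele_labels[name] + [NULL]
            idx = rng.choice(len(labels), size=2, p=f / f.sum())
            a, b = labels[idx[0]], labels[idx[1]]
            g[name] = (a, b) if a <= b else (b, a)
        return g

    individuals: List[TrueIndividual] = []
    counter = 0
    for ri, region in enumerate(region_names):
        clat, clon = _REGION_CENTRES[ri % len(_REGION_CENTRES)]
        # unrelated molting/non-breeding adults: the bulk of a feather
        # collection has no sampled relatives
        for u in range(config.n_singles_per_region):
            hp = hap_freqs[ri]
            counter += 1
            individuals.append(TrueIndividual(
                individual_id=f"I{counter:04d}", genotype=draw_genotype(region),
                haplotype_id=hap_ids[rng.choice(len(hap_ids), p=hp / hp.sum())],
                sex=Sex.FEMALE if rng.random() < 0.5 else Sex.MALE,
                region=region, site_id=f"{region}_m{u + 1}",
                latitude=clat + rng.normal(0, 0.5),
                longitude=clon + rng.normal(0, 1.0),
            ))
        for p in range(config.n_pairs_per_region):
            site_lat = clat + rng.normal(0, 0.5)
            site_lon = clon + rng.normal(0, 1.0)
            site_id = f"{region}_s{p + 1}"
            hp = hap_freqs[ri]
            dam_hap = hap_ids[rng.choice(len(hap_ids), p=hp / hp.sum())]
            sire_hap = hap_ids[rng.choice(len(hap_ids), p=hp / hp.sum())]
            counter += 1
            dam = TrueIndividual(
                individual_id=f"I{counter:04d}", genotype=draw_genotype(region),
                haplotype_id=dam_hap, sex=Sex.FEMALE, region=region,
                site_id=site_id, latitude=site_lat, longitude=site_lon,
            )
            counter += 1
            sire = TrueIndividual(
                individual_id=f"I{counter:04d}", genotype=draw_genotype(region),
                haplotype_id=sire_hap, sex=Sex.MALE, region=region,
                site_id=site_id, latitude=site_lat, longitude=site_lon,
            )
            individuals.extend([dam, sire])
            n_goslings = min(int(rng.poisson(config.brood_size_mean)), config.brood_size_max)
            for _ in range(n_goslings):
                # feather collection misses most brood members; sampling only
                # a fraction keeps kin density at field-realistic levels
                if rng.random() >= config.gosling_sample_fraction:
                    continue
                g = {}
                for name in locus_names:
                    a = dam.genotype[name][rng.integers(2)]
                    b = sire.genotype[name][rng.integers(2)]
                    g[name] = (a, b) if a <= b else (b, a)
                counter += 1
                individuals.append(TrueIndividual(
                    individual_id=f"I{counter:04d}", genotype=g,
                    haplotype_id=dam.haplotype_id,
                    sex=Sex.FEMALE if rng.random() < 0.5 else Sex.MALE,
                    region=region, site_id=site_id,
                    latitude=site_lat, longitude=site_lon,
                    dam=dam.individual_id, sire=sire.individual_id,
                ))

    return TruthSet(
        individuals=individuals, locus_names=locus_names,
        allele_labels=allele_labels, haplotype_seqs=haps, config=config,
    )


def visible_genotype(true_pair: Tuple[int, int]) -> Optional[Tuple[int, int]]:
    """What a null-carrying genotype looks like on a gel: one null appears
    homozygous for the visible allele; a null homozygote fails (missing)."""
    a, b = true_pair
    if a == NULL and b == NULL:
        return None
    if a == NULL:
        return (b, b)
    if b == NULL:
        return (a, a)
    return true_pair


def simulate_feather_samples(truth: TruthSet, config: Optional[SimulationConfig] = None,
                             seed_offset: int = 1) -> List[SampleRecord]:
    """Generate noisy replicate feather samples from the true individuals.

    Per replicate and locus: the visible genotype (nulls hidden) suffers
    allele dropout with probability ``ado_rate`` if heterozygous, then a
    false allele with probability ``fa_rate`` (one allele replaced by a
    uniformly chosen different allele at that locus), and the locus goes
    missing with probability ``missing_rate``.
    """
    config = config or truth.config
    rng = np.random.default_rng((truth.config.seed + seed_offset) % (2 ** 31))
    samples: List[SampleRecord] = []
    for ind in truth.individuals:
        n_rep = int(rng.integers(config.replicates_min, config.replicates_max + 1))
        for r in range(n_rep):
            calls: Dict[str, Optional[Tuple[int, int]]] = {}
            for name in truth.locus_names:
                pair = visible_genotype(ind.genotype[name])
                if pair is not None and pair[0] != pair[1] and rng.random() < config.ado_rate:
                    keep = pair[rng.integers(2)]
                    pair = (keep, keep)
                if pair is not None and rng.random() < config.fa_rate:
                    which = int(rng.integers(2))
                    others = [a for a in truth.allele_labels[name] if a != pair[which]]
                    if others:
                        new = others[rng.integers(len(others))]
                        pair = tuple(sorted((new, pair[1 - which])))
                if pair is not None and rng.random() < config.missing_rate:
                    pair = None
                calls[name] = pair
            if rng.random() < config.sex_marker_missing_rate:
                frag = None
            else:
                frag = FEMALE_FRAGMENT_BP if ind.sex == Sex.FEMALE else MALE_FRAGMENT_BP
            samples.append(SampleRecord(
                sample_id=f"{ind.individual_id}_r{r + 1}",
                genotype=Genotype(calls),
                site_id=ind.site_id,
                latitude=ind.latitude, longitude=ind.longitude,
                sex_fragment_bp=frag,
                mtdna_seq=truth.haplotype_seqs[ind.haplotype_id],
            ))
    return samples


def simulate_drift_populations(
    base_freqs: Dict[str, np.ndarray],
    target_fst: float,
    n_pops: int,
    sample_sizes: Sequence[int],
    seed: int,
    drift_n: int = 2000,
) -> List[Dict[str, np.ndarray]]:
    """Drift populations apart to an expected F_ST, then sample genotypes.

    Each population drifts independently from the base frequencies by
    Wright-Fisher binomial resampling at size ``drift_n`` for t generations,
    with t solved from F_ST = 1 - (1 - 1/(2N))^t.  Returns, per population,
    a dict locus -> (n_i, 2) integer array of allele indices.
    """
    if not 0.0 <= target_fst < 0.5:
        raise ValueError("target_fst must be in [0, 0.5)")
    if len(sample_sizes) != n_pops:
        raise ValueError("sample_sizes must have one entry per population")
    rng = np.random.default_rng(seed)
    if target_fst == 0:
        t = 0
    else:
        t = round(math.log(1 - target_fst) / math.log(1 - 1 / (2 * drift_n)))
        if t < 1:
            t = 1
    pops = []
    for p in range(n_pops):
        freqs = {}
        for locus, f in base_freqs.items():
            f = np.asarray(f, dtype=float)
            cur = f.copy()
            if len(f) > 1:
                for _ in range(t):
                    counts = rng.multinomial(2 * drift_n, cur)
                    cur = counts / (2 * drift_n)
            freqs[locus] = cur
        genos = {}
        for locus, f in freqs.items():
            if f.sum() <= 0:
                f = np.asarray(base_freqs[locus], dtype=float)
            genos[locus] = rng.choice(len(f), size=(sample_sizes[p], 2), p=f / f.sum())
        pops.append(genos)
    return pops


def simulate_wright_fisher(
    n_ind: int,
    n_generations: int,
    n_loci: int,
    alleles_per_locus: int,
    sample_size: int,
    seed: int,
    monogamy: bool = False,
) -> Dict[str, np.ndarray]:
    """Discrete Wright-Fisher population of ``n_ind`` diploids, unlinked loci.

    Founders drawn from Dirichlet(2) frequencies; each generation, offspring
    pick parents at random (a fixed pairing when ``monogamy``).  Returns
    locus -> (sample_size, 2) array of allele indices from the final
    generation, for LD-based Ne recovery checks.
    """
    rng = np.random.default_rng(seed)
    pop = np.empty((n_ind, n_loci, 2), dtype=np.int64)
    for l in range(n_loci):
        f = rng.dirichlet(np.full(alleles_per_locus, 2.0))
        pop[:, l, :] = rng.choice(alleles_per_locus, size=(n_ind, 2), p=f)
    for _ in range(n_generations):
        if monogamy:
            perm = rng.permutation(n_ind)
            pairs = [(perm[2 * i], perm[2 * i + 1]) for i in range(n_ind // 2)]
            pair_idx = rng.integers(len(pairs), size=n_ind)
            mothers = np.array([pairs[i][0] for i in pair_idx])
            fathers = np.array([pairs[i][1] for i in pair_idx])
        else:
            mothers = rng.integers(n_ind, size=n_ind)
            fathers = rng.integers(n_ind, size=n_ind)
            clash = mothers == fathers
            while clash.any():
                fathers[clash] = rng.integers(n_ind, size=int(clash.sum()))
                clash = mothers == fathers
        nxt = np.empty_like(pop)
        gm = rng.integers(2, size=(n_ind, n_loci))
        gf = rng.integers(2, size=(n_ind, n_loci))
        rows = np.arange(n_loci)
        for i in range(n_ind):
            nxt[i, :, 0] = pop[mothers[i], rows, gm[i]]
            nxt[i, :, 1] = pop[fathers[i], rows, gf[i]]
        pop = nxt
    pick = rng.choice(n_ind, size=min(sample_size, n_ind), replace=False)
    return {f"L{l + 1:02d}": pop[pick, l, :] for l in range(n_loci)}
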