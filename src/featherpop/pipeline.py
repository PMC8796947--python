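"""End-to-end orchestration of the feather-sampling analysis workflow.

Stages run in dependency order on a synthetic (or supplied) dataset:
simulate -> identify -> marker QC -> nuclear stats -> mtDNA stats ->
kinship -> Ne -> hybrids.  Every stochastic step derives its seed from the
run seed, the config snapshot is written alongside the reports, and a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from . import identification as ident
from . import kinship as kin
from . import marker_qc as qc
from . import mtdna
from . import ne as ne_mod
from . import nuclear
from . import synthdata
from .datamodel import Genotype, Individual, PopulationDataset, Locus, Sex
from .io import write_genepop, write_fasta

log = logging.getLogger("featherpop")


@dataclass
class PipelineConfig:
    seed: int = 1
    out_dir: str = "featherpop_run"
    # identification thresholds
    max_mismatch: int = 3
    review_band: tuple = (4, 5)
    max_missing: float = 0.25
    # QC thresholds
    null_drop: float = 0.10
    missing_drop: float = 0.40
    # kinship / Ne / spatial
    r_threshold: float = 0.55
    p_crit: float = 0.05
    mating: str = "monogamy"
    class_width_km: float = 50.0
    site_merge_km: float = 16.0
    n_perm: int = 199
    # synthetic-population settings
    simulation: Dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "review_band" in raw:
            raw["review_band"] = tuple(raw["review_band"])
        return cls(**raw)


def identify_individuals(samples, loci: List[str], config: PipelineConfig):
    """Samples -> identified individuals with consensus genotypes and sex."""
    genotypes = {s.sample_id: s.genotype for s in samples}
    by_id = {s.sample_id: s for s in samples}
    result = ident.regroup_genotypes(
        genotypes, max_same=config.max_mismatch,
        review_band=tuple(config.review_band))
    individuals = []
    clusters_geno = []
    consensuses = []
    for ci, cluster in enumerate(result.clusters):
        reps = [genotypes[s] for s in cluster]
        cons = ident.consensus_genotype(reps)
        clusters_geno.append(reps)
        consensuses.append(cons)
        first = by_id[cluster[0]]
        frags = [by_id[s].sex_fragment_bp for s in cluster
                 if by_id[s].sex_fragment_bp is not None]
        sex = ident.assign_sex(frags[0]) if frags else Sex.UNKNOWN
        individuals.append(Individual(
            individual_id=f"ID{ci + 1:04d}", consensus=cons, members=cluster,
            sex=sex, region=first.site_id.rsplit("_", 1)[0],
            latitude=first.latitude, longitude=first.longitude,
            mtdna_seq=first.mtdna_seq,
        ))
    retained = ident.filter_missing(individuals, config.max_missing)
    errors = None
    if any(len(c) >= 2 for c in clusters_geno):
        errors = ident.estimate_error_rates(clusters_geno, consensuses)
    return retained, errors, result


def run_pipeline(config: PipelineConfig, sim_config=None) -> Path:
    """Run the full synthetic workflow; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    logging.basicConfig(level=logging.INFO)

    sim_config = sim_config or synthdata.SimulationConfig(
        seed=config.seed, **config.simulation)
    log.info("stage simulate: seed=%d", sim_config.seed)
    truth = synthdata.simulate_population(sim_config)
    samples = synthdata.simulate_feather_samples(truth)

    log.info("stage identify: %d samples", len(samples))
    individuals, errors, regroup = identify_individuals(
        samples, truth.locus_names, config)
    dataset = PopulationDataset(
        loci=[Locus(n) for n in truth.locus_names], individuals=individuals)
    write_genepop(dataset, out / "individuals.gen")
    with open(out / "identification.tsv", "w") as fh:
        fh.write("individual_id\tn_replicates\tsex\tregion\n")
        for ind in individuals:
            fh.write(f"{ind.individual_id}\t{len(ind.members)}\t{ind.sex.value}"
                     f"\t{ind.region}\n")
    if errors:
        with open(out / "error_rates.json", "w") as fh:
            json.dump({"mean_ado": errors.mean_ado, "mean_fa": errors.mean_fa,
                       "error_per_allele": errors.error_per_allele,
                       "error_per_locus": errors.error_per_locus}, fh, indent=1)

    log.info("stage qc: %d individuals", len(individuals))
    report = qc.qc_report(dataset, seed=config.seed)
    kept = qc.filter_loci(dataset, report, max_missing=config.missing_drop,
                          max_null=config.null_drop)
    with open(out / "qc.tsv", "w") as fh:
        fh.write("locus\tmissing\tminor_allele_count\tmean_null\tdecision\n")
        for locus in dataset.locus_names:
            nulls = list(report.null_per_region[locus].values())
            mean_null = sum(nulls) / len(nulls) if nulls else float("nan")
            fh.write(f"{locus}\t{report.missing_fraction[locus]:.3f}"
                     f"\t{report.minor_allele_count[locus]}"
                     f"\t{mean_null:.3f}\t{report.decision[locus]}\n")

    log.info("stage nuclear: %d loci kept", len(kept))
    pruned = PopulationDataset(
        loci=[Locus(n) for n in kept],
        individuals=[Individual(
            individual_id=i.individual_id,
            consensus=Genotype({l: i.consensus.get(l) for l in kept}),
            members=i.members, sex=i.sex, region=i.region,
            latitude=i.latitude, longitude=i.longitude, mtdna_seq=i.mtdna_seq)
            for i in individuals])
    div = nuclear.diversity_summary(pruned, hwe_seed=config.seed)
    with open(out / "diversity.tsv", "w") as fh:
        cols = ["n", "A", "A_R", "PA", "H_O", "H_E", "F_IS", "P_HWE"]
        fh.write("region\t" + "\t".join(cols) + "\n")
        for region, stats in div.per_region.items():
            fh.write(region + "\t" + "\t".join(
                f"{stats[c]:.4g}" for c in cols) + "\n")
    pops = nuclear.dataset_to_pops(pruned)
    theta, pvals = nuclear.pairwise_fst(pops, n_perm=config.n_perm,
                                        seed=config.seed)
    with open(out / "fst.tsv", "w") as fh:
        fh.write("region1\tregion2\tfst\tp\n")
        for (a, b), v in theta.items():
            fh.write(f"{a}\t{b}\t{v:.5f}\t{pvals.get((a, b), float('nan')):.4f}\n")

    log.info("stage mtdna")
    seqs = [(i.individual_id, i.mtdna_seq) for i in individuals if i.mtdna_seq]
    regions = {i.individual_id: i.region for i in individuals}
    table = mtdna.collapse_haplotypes(seqs, regions)
    write_fasta([(h, s) for h, s in table.sequences.items()],
                out / "haplotypes.fasta")
    seq_list = [s for _, s in seqs]
    reg_list = [regions[i] for i, _ in seqs]
    amova = mtdna.amova_phist(seq_list, reg_list, n_perm=config.n_perm,
                              seed=config.seed)
    with open(out / "mtdna.json", "w") as fh:
        json.dump({
            "n_haplotypes": table.n_haplotypes,
            "phi_st": amova.phi_st, "p": amova.p_value,
            "pct_among": amova.pct_among, "pct_within": amova.pct_within,
        }, fh, indent=1)

    log.info("stage kinship")
    pooled_freqs: Dict[str, Dict[int, float]] = {}
    for locus in kept:
        counts: Dict[int, int] = {}
        for ind in individuals:
            pair = ind.consensus.get(locus)
            if pair is None:
                continue
            for a in pair:
                counts[a] = counts.get(a, 0) + 1
        total = sum(counts.values())
        if total:
            pooled_freqs[locus] = {a: c / total for a, c in counts.items()}
    # kin live at the sampling site in this design: score within-site dyads
    sample_site = {s.sample_id: s.site_id for s in samples}
    dyads = []
    grouped: Dict[str, List] = {}
    for ind in individuals:
        site = sample_site.get(ind.members[0], "")
        grouped.setdefault(site, []).append(ind)
    for members in grouped.values():
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                ga = {l: a.consensus.get(l) for l in kept}
                gb = {l: b.consensus.get(l) for l in kept}
                try:
                    dyads.append(kin.ml_relatedness(
                        a.individual_id, ga, b.individual_id, gb,
                        pooled_freqs))
                except ValueError:
                    continue
    prune = kin.prune_kin([i.individual_id for i in individuals], dyads,
                          r_threshold=config.r_threshold)
    with open(out / "kinship.tsv", "w") as fh:
        fh.write("id1\tid2\tr_hat\tclass\n")
        for d in dyads:
            fh.write(f"{d.id1}\t{d.id2}\t{d.r_hat:.3f}\t{d.best_class}\n")
    with open(out / "nonkin.txt", "w") as fh:
        fh.write("\n".join(prune.retained) + "\n")

    log.info("stage hybrids")
    from .hybrid import hybrid_benchmark
    rng = np.random.default_rng(config.seed + 11)
    p2_pool = {}
    for locus, f in pooled_freqs.items():
        # a drifted sister pool stands in for the second parental taxon
        alleles = list(f)
        drifted = rng.dirichlet(np.maximum(np.array(list(f.values())) * 4.0,
                                           1e-3))
        p2_pool[locus] = dict(zip(alleles, drifted))
    conf = hybrid_benchmark(pooled_freqs, p2_pool, 30,
                            seed=(config.seed + 13) % (2 ** 31))
    with open(out / "hybrids.json", "w") as fh:
        json.dump(conf, fh, indent=1)

    log.info("stage ne")
    genos = {l: [i.consensus.get(l) for i in individuals] for l in kept}
    try:
        est = ne_mod.ld_ne(genos, p_crit=config.p_crit, mating=config.mating)
        ne_out = {"ne": est.ne if est.ne != float("inf") else "inf",
                  "r2_mean": est.r2_mean, "r2_prime": est.r2_prime,
                  "ci": [est.ci_low, est.ci_high]}
    except ValueError as exc:
        ne_out = {"error": str(exc)}
    with open(out / "ne.json", "w") as fh:
        json.dump(ne_out, fh, indent=1, default=str)

    log.info("pipeline complete: %s", out)
    return out
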