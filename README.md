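# featherpop

Population-genetic analysis of non-invasively collected feather samples,
built around the workflow used to assess a declining taiga bean goose
(*Anser fabalis fabalis*) breeding population: molted feathers collected by
volunteers are genotyped at 22–28 microsatellite loci in replicate, a short
hypervariable fragment of the mitochondrial control region (210 bp) is
sequenced, and the population's structure, diversity, kinship, effective
size and hybridization status are inferred from the combined data.

It is aimed at conservation geneticists working with non-invasive samples
(feathers, hair, feces), where genotypes are error-prone and replicate
samples from unknown individuals are the norm.

## What it computes

- **Individual identification** from replicate multilocus genotypes:
  samples with up to 3 per-locus mismatches are regrouped into one
  individual, 4–5-locus mismatch pairs consistent with allele dropout are
  treated as poor-template suspects, consensus genotypes are built by
  per-locus majority (two-replicate conflicts resolve to the heterozygote),
  and individuals with more than 25% missing loci are excluded.
  Genotyping-error rates — allele dropout (ADO), false alleles (FA), error
  per allele and per locus — are estimated from the replicate structure,
  and the panel's discriminatory power is summarized by the unbiased
  probability of identity P_ID and its full-sibling analogue P_ID_SIB
  (per locus: P_ID_SIB = 1/4 + (1/2)Σp² + (1/2)(Σp²)² − (1/4)Σp⁴).
- **Molecular sexing** from the Z/W gametolog fragment (287 bp females,
  297 bp males) with a χ² test against a 1:1 sex ratio.
- **Marker QC**: null-allele frequency by EM under the recessive-null
  model, Hardy–Weinberg exact tests (Levene-conditional probability test,
  enumerated or Monte-Carlo), genotypic LD permutation G-tests, sequential
  Bonferroni (Holm) correction, and the locus-filtering rules
  (polymorphism, missingness > 40%, null frequency > 10%, out of HWE in
  every region).
- **Nuclear statistics**: A, rarefied allelic richness, private alleles,
  H_O, H_E, F_IS; Weir–Cockerham θ (multi-locus ratio of summed variance
  components) with permutation tests and an ENA-style null-allele
  correction; POWSIM-style marker power simulation; Mantel tests; and
  Smouse–Peakall multivariate spatial autocorrelation with permutation
  null bands, bootstrap error bars and a heterogeneity test.
- **mtDNA statistics**: haplotype collapsing, haplotype (h) and nucleotide
  (π) diversity, Tajima's D, Fu's Fs (Ewens sampling distribution),
  Jukes–Cantor distances, AMOVA-based ɸ_ST with permutation tests, a
  minimum-spanning haplotype network, and a divergence screen for Numts.
- **Kinship**: maximum-likelihood pairwise relatedness over the IBD
  simplex (k₀, k₁, k₂) with relationship classification (U/HS/FS/PO),
  exclusion-based parentage under monogamy, and construction of a non-kin
  dataset (parents removed, one sibling kept per cluster, r̂ > 0.55 dyads
  broken).
- **Effective population size**: the linkage-disequilibrium method
  (Burrows Δ composite r², E[r²|S] bias correction, monogamy or
  random-mating inversion, jackknife CI) and demographic conversions from
  scaled coalescent parameters (θ = 2Nµ, θ_anc = 2N_anc µ, D = T/2N) with
  µ = 5×10⁻⁴ and a 5–7.5-year generation time.
- **Hybridization**: HybridLab-style simulation of P1/P2/F1/F2/backcross
  genotypes from parental allele frequencies and a direct-likelihood
  classifier over the six classes.

A fully ground-truthed synthetic feather-sampling generator
(`featherpop.synthdata`) reproduces the study conditions — four regions,
monogamous families, maternally inherited haplotypes with regional
structure (ɸ_ST ≈ 0.1–0.2) over panmictic nuclear loci (F_ST < 0.005),
ADO ≈ 0.041, FA ≈ 0.009, null alleles ≈ 0.034, and a rare (~4%)
introgressed mtDNA lineage — so the full pipeline is testable end to end.

## Worked example

```python
from featherpop import SimulationConfig, simulate_population, simulate_feather_samples
from featherpop.pipeline import PipelineConfig, identify_individuals
from featherpop import ne

truth = simulate_population(SimulationConfig(seed=5))
samples = simulate_feather_samples(truth)
individuals, errors, _ = identify_individuals(samples, truth.locus_names,
                                              PipelineConfig())
print(len(truth.individuals), len(individuals))
print(round(errors.mean_ado, 4), round(errors.mean_fa, 4))

est = ne.demographic_convert(ne.DemographicParams(
    theta=4.701, theta_anc=0.601, scaled_time=4353 / (2 * 4701)))
print(round(est.n_ratio, 1), est.years_range)
```

prints

```
344 353
0.0351 0.0066
7.8 (21765, 32648)
```

— 344 true individuals recovered as 353 identified clusters from ~1200
noisy replicate feathers; the estimated mean allele-dropout rate 0.0351
and false-allele rate 0.0066 recover the generator's configured 0.041 and
0.009; and the demographic conversion of the scaled parameters gives a
7.8-fold population expansion starting 21,765–32,648 years before present.

The full workflow (simulate → identify → QC → nuclear → mtDNA → Ne) runs
from the shell:

```
featherpop all --seed 1 --out run1
```

and writes TSV/JSON reports plus a config snapshot into `run1/`.

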