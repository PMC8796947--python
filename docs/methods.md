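# Methods

This note documents the models, estimators and numerical choices behind
featherpop, and what the synthetic study conditions do and do not
represent.

## Individual identification from replicate samples

Non-invasive genotypes carry allele dropout (ADO: one allele of a
heterozygote fails to amplify), false alleles (FA: an artifactual allele
is scored), and missing loci. A per-locus *mismatch* between two
multilocus genotypes is any disagreement at a locus typed in both; a
mismatch is *dropout-consistent* when one genotype is homozygous and the
other is a heterozygote containing that allele.

Regrouping links samples whose genotypes mismatch at ≤ 3 loci and takes
connected components as individuals. Pairs mismatching at 4–5 loci with
every mismatch dropout-consistent are poor-template suspects; a suspect is
excluded only when it has no confident (≤ 3-mismatch) link outside the
flagged pair. Blanket exclusion of both members of every such pair would
preferentially discard the error-rich replicates of well-supported
individuals and bias the ADO estimate downward by roughly 25%; the
conditional rule keeps the poor-template screen (a standalone suspect pair
is still fully excluded) without that selection effect.

The stepwise multiplex-panel mode screens for poor-quality samples after
each panel using the accumulated loci, but never freezes cluster
membership on a partial panel: the final clustering always uses all loci
for all surviving samples. On error-free data stepwise and single-pass
results are identical by construction.

Consensus calls use strict per-locus majority; with exactly two discordant
observations the heterozygote wins (dropouts are likelier than false
alleles); unresolved ties (including three-way conflicts) are conservatively
set missing. Individuals with more than 25% missing consensus loci are
dropped (7/28 missing is retained, 8/28 excluded).

Error rates are estimated only from clusters with ≥ 2 replicates (a lone
replicate is its own consensus and carries no error signal). ADO per locus
is the fraction of typed observations at heterozygous-consensus loci
showing only one consensus allele; FA per locus the fraction of typed
observations containing an allele absent from consensus; error per allele
and per locus compare observations to consensus over all loci. Per-locus
rates are averaged unweighted. These denominators follow the
replicate-comparison conventions of Broquet & Petit (2004).

P_ID uses the sample-size-corrected (unbiased) estimator; P_ID_SIB the
standard sibling formula; cumulative values are products over loci, which
assumes linkage equilibrium.

## Marker QC

Null alleles are modelled as one extra recessive allele per locus:
observed homozygotes are mixtures of true homozygotes and visible/null
heterozygotes, null homozygotes are blanks. The EM estimator maximizes the
multinomial likelihood over visible frequencies and the null frequency
jointly (E-step splits homozygote allele copies; convergence |Δp₀| <
1e-6). The blank class enters with its observed count (zero in data
without locus-specific failure records), so the estimate is conservative
when amplification failure is frequent.

The HWE test is the exact (probability-ordering) test conditional on
allele counts, with Levene's conditional distribution. Tables are fully
enumerated when the allele count is small (k ≤ 3, or k = 4 with n ≤ 20);
otherwise a seeded vectorized Monte Carlo (default 10,000 pairings of the
allele vector) is used, with p = (hits + 1)/(m + 1).

Genotypic LD is a permutation G-test on the two-locus genotype table.
Sequential Bonferroni is the Holm step-down. Locus filtering applies, in
order: minor-allele count < 2 (low polymorphism), missing fraction > 0.40,
mean null frequency > 0.10, HWE rejected (Holm within region) in every
region. The first triggering rule is recorded as the drop reason.

## Nuclear statistics

H_E = 1 − Σp² without small-sample correction and F_IS averaged as the
mean of per-locus (H_E − H_O)/H_E, matching the GenAlEx conventions (the
unbiased H_E is available as an option). Allelic richness is rarefied to
g = twice the smallest per-region typed sample at each locus. Multi-locus
Weir–Cockerham θ is the ratio of summed variance components a/(a+b+c),
never a mean of per-locus ratios. Pairwise significance comes from
permuting individuals between the two regions; the pairwise matrix is
interpreted after sequential Bonferroni, as the source analyses were.

The ENA correction estimates a per-population, per-locus null frequency
(EM, or supplied), rescales visible allele frequencies to sum to 1 − p₀,
and excludes the null class from the allele-wise sums.

Marker power follows the POWSIM design: populations are drifted from base
frequencies by Wright–Fisher binomial resampling (N = 2000; generations
solved from F_ST = 1 − (1 − 1/2N)^t), then tested for allele-frequency
homogeneity. The test itself is an exact permutation test whose statistic
is the chi-square summed over loci, with alleles permuted among
populations within each locus; with m = 199 permutations and rejection at
p ≤ α the type-I error is exactly α under the null. This replaces the
combination of per-locus Monte-Carlo Fisher p-values, which is biased
conservative by the discreteness of each component p-value.

Spatial autocorrelation uses the squared codominant genotype distance
(half the squared difference of allele-count vectors, summed over loci;
missing loci pairwise-deleted and rescaled to the panel size), double
centering, and the class-wise ratio r = Σ2c_ij / Σ(c_ii + c_jj). The null
band permutes genotypes over locations (999 by default), error bars
bootstrap pairs within class (1000), and the heterogeneity test compares
the summed squared standardized class departures to its permutation
distribution. The default distance class is 50 km; sites within 16 km are
mergeable into one location by single-linkage clustering under
great-circle distance (the most permissive reading of a "within 16 km"
rule).

## Mitochondrial statistics

Haplotypes are collapsed over identical aligned sequences; sequences with
ambiguous bases merge into a haplotype they match at every unambiguous
position and are flagged. h and π use the standard unbiased formulas;
Tajima's D the 1989 constants with complete deletion of ambiguous sites;
Fu's Fs evaluates P(K ≥ k_obs) under the Ewens sampling distribution with
θ = mean pairwise differences, using a log-space Stirling-number
recursion stable to n of several hundred. Distances are Jukes–Cantor with
pairwise deletion; AMOVA uses squared JC distances (variance components
from sums of squares, significance by permuting individuals among
regions), and φ_ST = σ²_a/(σ²_a + σ²_w). Regions with fewer than two
members are excluded.

The haplotype network is a minimum-spanning network on Hamming distances
retaining all co-minimal edges — a deliberate simplification of
median-joining (no median vectors), which is topologically equivalent for
star-like clouds of closely related haplotypes. Putative Numts are flagged
when more than 5 substitutions (over 210 bp) from every reference
haplotype; the threshold is configurable and is a stand-in for a
laboratory criterion that cannot be reconstructed from sequence alone.

## Kinship

Dyad likelihoods use the standard IBD-conditional genotype-pair
probabilities for k = (k₀, k₁, k₂); maximization is a 0.05-step grid over
the simplex refined by Nelder–Mead, and r̂ = k₁/2 + k₂. Classification
compares the canonical points U(1,0,0), HS(½,½,0), FS(¼,½,¼), PO(0,1,0).
Null alleles enter as an extra recessive allele class by summing over the
true genotypes compatible with each observed homozygote; the option is
intended for loci with estimated null frequency above 0.05.

Full-sib clusters are connected components of FS-classified dyads with
likelihood support (≥ 2 log-units over the next class) — a deliberate
approximation to full-likelihood sibship reconstruction. The non-kin set
removes inferred parents, keeps the lowest-id member of each sib cluster,
then greedily deletes highest-degree nodes until no dyad exceeds
r̂ > 0.55. ML relatedness is truncated at the simplex boundary, so
unrelated dyads have a small positive mean r̂ (≈ 0.03–0.06 depending on
marker information); this is a property of the estimator, not a defect.

## LD effective population size

For every locus pair, Burrows Δ is computed over individuals typed at
both loci for each allele pair passing the frequency screen (default
p_crit = 0.05), with the S/(S−1) correction and the homozygote-excess
denominator. r² values are weighted by S; the harmonic mean S sets
E[r²|S] (1/S + 3.19/S² for S ≥ 30), and Ne inverts the drift relation
under monogamy ((2/3 + √(4/9 − 7.2r²'))/(2r²')) or random mating
((1/3 + √(1/9 − 2.76r²'))/(2r²')); r²' ≤ 0 reports Ne = ∞ rather than an
error. The CI is a leave-one-locus-out jackknife on the weighted mean r²
mapped through the (monotone) Ne inversion.

Demographic conversions invert θ = 2Nµ, θ_anc = 2N_anc µ and T = D·2N
with µ = 5×10⁻⁴ per locus per generation and a 5–7.5-year generation
time. Years are rounded half-up after clamping accumulated floating-point
error at the sixth decimal; ratios are reported to 2 decimals and census
sizes to the nearest integer.

## Hybrid classes

Six classes are defined by gamete-pool composition: P-gametes draw from a
parental frequency pool, F1-gametes from the 50:50 mixture; F2 and
backcrosses draw each allele independently (linkage ignored). The
classifier computes each class's multilocus genotype likelihood from
fixed parental frequencies with a 1e-4 floor for unseen alleles
(renormalized) and a uniform prior; it deliberately ignores uncertainty
in the parental frequencies, trading MCMC machinery for a transparent
likelihood whose behaviour — parental classes recovered reliably, F2 and
backcrosses confusable — is the scientifically relevant structure.
Posterior ties (completely uninformative markers) are broken at random
under the benchmark's seed.

## Synthetic study conditions

The generator reproduces the survey structure the pipeline is meant for:
four regions ~150–400 km apart; per region 70 unrelated molting adults
plus 5 monogamous pairs with Poisson(2.5) broods of which each gosling is
sampled with probability 0.5 (kin density chosen to match a survey in
which ~52 full-sib pairs and ~25 parent–offspring links occur among ~490
individuals — feather collections sample most individuals without their
relatives); 22 loci with 8 possible alleles (Dirichlet(2) frequencies), a
hidden null allele at 3.4% per locus; replicates uniform on 1–6 per
individual; ADO 4.1% per heterozygous observation, FA 0.9% (uniform
substitution), 3% missing loci, 12% sex-marker failure; six native
control-region haplotypes in a star topology plus one divergent
introgressed lineage at 4%. Regional haplotype frequencies tilt one
region (the analogue of a core breeding area) toward its locally common
haplotype, with the tilt solved by bisection so the analytic
population-level φ_ST — (π_B − π_W)/π_B over the region layout — equals
the 0.15 target; realized sample AMOVA φ_ST recovers the target within
±0.05 on unrelated samples.

What the synthetic data do **not** emulate: genuine spatial continuity
within regions (sites are jittered around centres), stutter artifacts and
allele-size-dependent dropout, locus-specific error heterogeneity,
temporal structure across collection years, and real microsatellite
allele-frequency spectra (which are typically more uneven and more
allele-rich; marker power on real panels can therefore exceed the
synthetic panel's). Passing tests demonstrate the estimators and the
pipeline logic, not field performance on any particular marker set.

## Problem sizes

The default conditions produce ~345 individuals and ~1200 feather
samples. The test suite runs oracle checks on toy instances, parameter
recovery at these defaults, marker power at 200 replicates (type-I) and
30 per power point, and LD-Ne recovery over 12 Wright–Fisher replicates
per true size; the acceptance script uses 12 structure replicates, 300/100
power replicates and 25 LD-Ne replicates per size. These sizes keep every
Monte-Carlo standard error well inside the tolerance being asserted.
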