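# Methods

This note documents the models behind `resistscan`, the defaults and
why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions a user should know before
trusting the output.

## Haplodiploid Wright–Fisher model

Spider mites have haplodiploid sex determination: females are diploid,
males develop from unfertilized eggs and are haploid, and a mating pair
therefore carries c = 3 genome copies. The simulator
(`resistscan.simulate`) tracks, per site, female genotype counts and
male hemizygote counts in a population of N females and N males
(constant 1:1 census). Each generation:

1. viability selection weights female genotypes 1 : 1+hs : 1+s and
   males 1 : 1+s (male selection can be switched off; the default
   applies selection in both sexes);
2. the post-selection egg and sperm gamete pools receive one-way
   recurrent mutation toward the derived allele at rate μ per gamete
   (applied at target sites only — recurrence at the pesticide-target
   codons is the process of interest; genome-wide neutral mutation is
   not simulated);
3. N daughters are drawn by random union of an egg and a sperm, and N
   sons from unfertilized eggs.

Under this scheme the expected influx of new derived copies at a target
site is 3Nμ per generation (2N gametes into daughters plus N into
sons), which is the basis of the recurrent-mutation estimate below.
Defaults are the study conditions of the system: μ = 2.8×10⁻⁹ per bp
per generation and 20 generations per year. Dominance h of resistance
alleles is a free parameter (default 0.5) — nothing in the system pins
it, and incomplete dominance materially changes trajectories, so it is
exposed rather than assumed away. Sites are unlinked; a sampled
frequency is the copy-weighted mean over sexes (2 per female, 1 per
male), and all randomness flows through one explicitly passed numpy
Generator, so a seed fully determines every output.

With h = ½ the per-generation logit slope of a selected allele is
approximately (2/3)·s in this model (females contribute 2/3 of copies
at hs, hemizygous males 1/3 at s) — about 2/3 of the diploid textbook
s/2 + extra male term. The infinite-N recursion
(`deterministic_trajectory`) is provided as the exact reference.

## Pooled sequencing emulation

`sample_pool_reads` is two-stage binomial: pool allele counts in
2 × pool_size female chromosomes, then reads binomial in the pool
proportion at Poisson per-site depth (fixed depth available). The read
count variance is therefore D·p(1−p)·(1 + (D−1)/(2n)) at fixed depth D
and pool size n — pooling noise is not ignorable and the tests pin it.
There is no read-error or mapping-error model: passing tests say
nothing about reference bias, duplicate reads or indel artefacts in
real pool-seq data.

The genome-scan generator (`simulate_scan_dataset`) places 100 windows
of 5 kb with 8 SNPs each, ancestral frequencies drawn from a truncated
1/p density (neutral-SFS-like standing variation), and lets one focal
and two reference populations drift independently for 30 generations at
N = 500. A sweep (default s = 0.5 from p₀ = 0.05) at a selected gene
window is modelled with complete within-window linkage: sites in the
swept 5-kb window hitchhike on one haplotype background, and the
resistance SNP itself (at the sweep frequency in the focal population,
absent in the references) sits at the window centre. Windows are
otherwise free-recombining. This reproduces the local diversity trough
and focal-branch excess of a hard sweep but not intermediate linkage
decay, soft-sweep haplotype structure, or demographic confounders.

## Dose-response

Control mortality is pooled from concentration-0 rows and removed with
Abbott's correction max(0, (p − c₀)/(1 − c₀)); corrected proportions
are fitted by maximum-likelihood binomial regression with a probit link
on log₁₀ concentration (statsmodels GLM; a logit link is available).
LC50 = 10^(−α/β); the 95% CI uses the delta method on −α/β by default
with Fieller's theorem behind a flag — the two agree closely away from
shallow slopes, and the delta form is the conventional default.
Doses with 0% or 100% corrected mortality stay in the likelihood.
Tables that never leave 0% mortality are reported as censored bounds
("LC50 > top dose"), fully lethal tables as "below lowest dose", and
complete separation (no dose with intermediate mortality) as an
explicit failure — never a silent number. Mortality is assumed scored
at the final (48 h) reading. Classification uses the bimodal defaults
of 30.1 mg/L (susceptible ceiling) and 1498.6 mg/L (resistant floor)
with everything between flagged unclassified; group means over fits
with censored members carry a ">" bound flag. Fold-resistance is the
plain ratio of LC50s, rounded to integer folds only at the reporting
layer.

## Windowed diversity and FST

Reads are subsampled without replacement (multivariate hypergeometric)
to exactly b = 50 per site; shallower sites are masked, never silently
kept. After that, reads are treated as sampled sequences: per site
π = (b/(b−1))(1 − Σp²) over the four bases, a site is a SNP when its
non-major read count is ≥ min_count (default 2), per window θ_W = S/a₁,
and Tajima's D uses the classical constants at n = b. Two conventions
to be aware of:

* **min_count ascertainment.** Requiring 2 minor reads removes the
  singleton class, which deflates S relative to π and biases window D
  upward by roughly +0.8 on truly neutral input at b = 50. This is
  inherent to subsample-then-threshold pooled analysis (the pooled
  correction of the PoPoolation lineage addresses it and is out of
  scope here). The neutral-calibration test therefore runs at
  min_count = 1, where mean window D on neutral input is ≈ 0. Compare
  D values only across windows computed under one convention.
* **Denominators.** Per-site π and θ divide by covered positions (or by
  the window span under `assume_full_coverage`, for inputs that list
  only variable sites); windows below a configurable covered fraction
  are masked with explicit status.

Window FST is (π_total − π_within)/π_total with π_within the average of
the per-pool window π sums and π_total computed on the summed counts at
depth 2b. Each π carries its own depth correction, which makes the
estimator unbiased under the null (independent pools from one
population) — the property the PBE scan depends on — at the cost that
two *identical* count vectors score −1/(2(b−1)) ≈ −0.01 rather than
exactly 0. Negative estimates are clamped to 0 by the branch transform.
Note also that two finite pools of n individuals from one panmictic
population have true expected FST ≈ 1/(4n); that is biology, not bias.
Indel/N columns never enter frequencies; a BED mask handles indel
margins; triallelic sites contribute all four base frequencies to π.

## PBS/PBE scan

T = −ln(1 − FST) (FST clamped into [0, 1−10⁻⁹)),
PBS = (T_f1 + T_f2 − T_12)/2, and PBE subtracts the genome-wide
expectation: PBE_w = PBS_w − T_12,w · median over usable windows of
PBS/T_12. The median (not the mean) is used for robustness to the
sweep windows themselves; windows with a masked FST in any pair are
excluded from both the median and outlier calling, and at least 20
usable windows are required. Outliers are windows at or above the
empirical (1−q) quantile with ties all flagged; q = 0.01 is the default
with q = 0.05 exposed (both thresholds are in common use and the choice
is a reporting decision, so both are available). The per-gene "signal"
call is: any outlier window within the gene body ±25 kb — an explicit
rule standing in for figure-level judgement. π and Tajima's D contrasts
(gene-proximal vs ±1 Mb flank) accompany each call.

## Mutation catalog and annotation

The catalog ships 15 amino-acid substitutions — H146Q, S212I, H258Y,
I260T, I260V, A285S on *sdhB*; D116G, D116E, D116N, R119C, R119L,
R119G, R119P, R119H, P120L on *sdhD* — with wild/mutant codons and
first-detection years, validated on load against the standard nuclear
code (the *sdh* subunits are nuclear-encoded). D116E is stored as two
rows (wild codons GAC and GAT, both one step from GAA) sharing one
label and counting once. Annotation maps a genomic substitution through
the gene model (1-based inclusive CDS intervals, strand-aware) to codon
and residue, with reference-mismatch errors naming the CDS offset.
Residue numbering is the mite protein coordinate system.
`accessible_substitutions` enumerates all nine single-nucleotide codon
neighbours with stop codons flagged; the saturation report compares
observed catalog changes against accessible missense changes per codon
position (at *sdhD* R119, CGT: all three position-2 changes H/P/L are
catalogued; position 1 carries C and G but not S). The "mutation
present in a population" threshold is configurable (default: any
non-zero frequency) because detection limits differ between pooled and
Sanger data.

## Haplotypes

Resolution follows the ≤1-heterozygous-site rule: 0 het sites → two
copies of one haplotype; exactly 1 → both implied haplotypes (phase is
then unambiguous); ≥2 het sites or any missing panel genotype →
excluded with the reason reported. Copy counts are conserved exactly.
Caveat: exclusion is not frequency-neutral when haplotypes two or more
steps apart co-occur in individuals, so resolved frequencies are
estimates of the retained-copy pool and over-represent common
haplotypes; round-trip tests use panels where the rule excludes no one.

Networks are minimum-spanning networks: Kruskal over Hamming distances,
keeping every co-minimal edge within a distance class instead of
breaking ties arbitrarily. Ancestral haplotypes are those in the top
count quartile with degree ≥ 2 (both knobs explicit; "common and
central" is otherwise ill-defined), with a most-frequent-node fallback;
derived nodes get their nearest ancestral neighbour by weighted
shortest path. Recombinant enumeration lists every ordered parent pair
and breakpoint k with target = prefix(a)+suffix(b), parents required to
differ from the target; double-crossover explanations are off by
default (short amplicons make single crossovers the relevant
hypothesis) and available behind a flag. The co-occurrence screen
lists populations containing both parents and the recombinant. The
expected-event calculator returns ρ = 2·c·Ne·r·d per generation and
1/ρ as individuals per event; with r = 10⁻⁷/bp (10 cM/Mb), c = 3,
Ne = 10⁶ and d = 60 bp, ρ = 36 per generation. It reports its own
value from explicit inputs only.

## Selection inference

Trajectory fits are binomial GLMs with logit link: allele counts
(frequency × chromosomes sampled) against calendar year, so populations
with more sampled chromosomes weigh proportionally more. The per-allele
slope is s per year; the joint fit pools alleles with allele-specific
intercepts and one shared year slope (fixed effects; no random-effects
variant). Wald Z and two-sided p accompany each estimate, with a
per-generation conversion s/gens_per_year reported alongside. Alleles
seen in fewer than two distinct years are non-estimable; all-0/all-1
trajectories are flagged as separated. The estimand of the slope is the
logit-linear projection of the true trajectory — for recovery tests the
reference value is the same GLM applied to the deterministic (N = ∞)
recursion over the same sampling design, not s itself (see the
haplodiploid 2s/3 relation above).

The recurrent-mutation estimate is arithmetic made explicit:
Θ = k̄/(years × gens_per_year) distinct mutations per population per
generation, and Ne = Θ/(c·μ); k̄ = 2.7 over 7 years at 20
generations/year with μ = 2.8×10⁻⁹ and c = 3 gives Θ = 0.0193 and
Ne ≈ 2.3×10⁶.

Survival associations are OLS of survival at the discriminating dose on
each frequency metric (predominant-allele, any-carrier, homozygote);
univariate R² equals squared Pearson correlation, constant predictors
are flagged rather than fitted, and a multivariate fit on per-mutation
frequencies reports the coefficient table. Isolation by distance uses
Hudson-style FST on resistance-allele frequencies (1 − ΣH_w/ΣH_b,
negative estimates clamped at 0 for the distance matrix), great-circle
distances, and scikit-bio's one-sided Mantel permutation test (999
permutations by default).

## Problem sizes and test design

Simulation-backed checks run at sizes chosen to make their statistical
bands meaningful on a single CPU: 500 replicate bioassays for LC50
recovery; 50 sweep replicates (100 windows × 8 SNPs, three populations,
N = 500, 30 generations) for detection and for null calibration; 30
populations of N = 10⁵ sampled at 50 chromosomes every quarter-year for
selection-coefficient recovery and CI coverage; 1000 null replicates
for Mantel type-I error; 1000 individuals for the haplotype round trip.
All are regenerated from seeds at run time; nothing is stored.

## Known limitations

* No linkage within the Wright–Fisher core (only the scan generator's
  swept window is linked); no coalescent equilibrium — backgrounds are
  standing variation with a 1/p spectrum, so absolute diversity levels
  are stylised.
* Tajima's D under min_count = 2 carries the positive ascertainment
  bias described above; only relative window contrasts are meaningful
  there.
* The probit CI is asymptotic; with 5–8 doses of 30 animals, coverage
  is approximate.
* Haplotype-frequency estimates inherit the ≤1-het selection bias.
* The joint selection coefficient assumes one shared slope across
  alleles; allele-specific time-varying selection will be averaged.
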