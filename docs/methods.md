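# Methods

`famseg` implements a family-based strategy for finding disease variants:
instead of fitting a transmission model, it filters exome-scale variant
tables by perfect co-segregation with affection status inside one deep
pedigree, prioritizes the survivors by in-silico deleteriousness and gene
novelty, confirms haplotype sharing among the affected, and intersects the
family findings with a case-control cohort. Every input the pipeline needs
can be produced by the bundled gene-dropping simulator, which is how the
package is tested end to end.

## Co-segregation filter

A variant co-segregates when every genotyped affected member carries it
and no genotyped unaffected member does. Because complex diseases rarely
show a clean inheritance mode, no likelihood is fitted; instead the filter
runs under two carrier definitions and reports them side by side:

* **dominant carrier** — carrier ⟺ alt dosage ≥ 1;
* **recessive homozygote** — carrier ⟺ alt dosage = 2.

Individuals whose affection is `unknown` are ignored, and `excluded`
members (e.g. relatives with atopy but not the disease under study) are
kept in the pedigree structure but never counted. Missing genotypes are
governed by an explicit policy: `strict` (default) declares a variant
*ambiguous* — never segregating — when any affected member is uncalled;
`permissive` simply drops missing individuals. Strict is the default
because a variant passed on partial data cannot be distinguished from a
false positive, and the strict segregating set is provably a subset of the
permissive one (tested by exhaustive enumeration and property tests).

The filter is exactly equivalent to brute-force enumeration over carrier
patterns; the test suite checks all 2⁸ patterns for a 5-affected /
3-unaffected family and all 3⁶ dosage patterns for the recessive model.

## Prioritization

Five predictor scores are consumed as annotations (never computed):
SIFT (< 0.05), PolyPhen-2 (> 0.85), CADD phred (≥ 15), GERP (> 2.0) and
MutationTaster (= disease-causing), each at its conventional damaging
cut-off. A variant is *deleterious* when at least `min_votes` (default 2)
of its present scores vote damaging and at least `min_present` (default 2)
scores are present; missing scores shrink the denominator rather than
counting as benign, because some gene families (olfactory receptors among
them) are poorly covered by individual tools. The exact cut-offs and the
vote rule are deliberate package choices — published pipelines rarely
state theirs — and every threshold is exposed in `PriorityRules`.

Novelty means the gene symbol is absent from a user-supplied
known-disease-gene list (a plain text file; nothing is fetched at run
time). Tier 1 = deleterious **and** novel; population MAF is attached as
a label (`rare` < 0.01) but never filters by default, since a common
variant can be the reproducible hit — an optional `max_maf` cut exists and
defaults to off.

## Haplotype analysis

**Phasing.** Within a pedigree, Mendelian logic alone phases most
genotypes: homozygotes are trivially phased, and a heterozygous child with
a homozygous genotyped parent has its transmission forced. Triple-
heterozygote trios stay unresolved, and Mendelian-inconsistent (variant,
child) pairs are skipped and reported. This deliberately replaces
population-coalescent phasing: it resolves no ambiguous case by guessing,
so every resolved call is exactly checkable against simulator truth (the
suite requires 100% agreement). On the bundled template at founder allele
frequency 0.3, roughly 80% of genotypes resolve.

**Shared risk interval.** From a seed variant whose risk allele all
affected carry, the interval extends greedily in both directions while
some allele exists that every affected can still carry on one of its
tracked chromosome sides. Unresolved phases count as compatible in the
default `permissive` mode (the claim being co-segregation, not certainty);
`strict` mode only follows resolved phases. Recombination inside the
ancestral segment is handled implicitly — the interval shrinks to the
intersection across carriers. When both alleles can extend the interval,
the one preserving the larger side-sets is taken (ties prefer alt); this
greedy rule can overshoot the true ancestral segment by a variant or two
at low-information flanks, which is why recovery tests assert containment
of the causal variant, not exact boundaries.

**Two-locus EM.** Haplotype frequencies for unrelated samples are
maximum-likelihood estimates via expectation-maximization over the
double-heterozygote ambiguity, started at linkage equilibrium and iterated
to a 1e-10 sup-norm change (max 1000 iterations). No random restarts are
used: with only one latent class the two-locus likelihood is well behaved,
and tests verify the EM optimum dominates 40 000 Dirichlet draws over the
frequency simplex plus a fine slice at the observed allele frequencies.
The log-likelihood is asserted non-decreasing at every step. D = f_AB −
p_A·p_B, D′ normalizes by the admissible bound given the allele
frequencies, r² = D²/(p_A(1−p_A)p_B(1−p_B)); monomorphic loci return D = 0
flagged degenerate.

## Case-control association

The intersection with the cohort uses the *unadjusted* allelic (2n) test:
a 2×2 risk/other × case/control allele-count table, odds ratio with Woolf
95% CI exp(ln OR ± 1.96·√(Σ1/cell)), Pearson chi-square (1 df, no Yates by
default) and two-sided Fisher exact p-values. The Haldane–Anscombe +0.5
correction is applied to the OR and CI if and only if the table contains a
zero cell (`correction="auto"`); the test statistics always use raw
counts. Two-sided Fisher p-values run conservative relative to the
chi-square — differences up to ~0.1 at moderate counts are expected and
are not a defect. HWE chi-square (1 df at the sample allele frequency),
MAF folding and carrier fractions round out the cohort utilities. No
covariates and no multiple-testing correction enter this step by design.

## Phenotype statistics

Group comparisons are normality-gated: Shapiro–Wilk per group at α = 0.05
routes to ANOVA / unpaired t-test (all groups normal) or Kruskal–Wallis /
Wilcoxon rank-sum otherwise. Both routes are always computed and attached
to the result, so the gate only chooses the headline. The gate's α and
per-group application are package choices.

`anova_from_summary` computes one-way ANOVA from printed (n, mean, SD)
triples — SSB from n-weighted means, SSW = Σ(nᵢ−1)sᵢ² — and is bit-level
consistent (1e-9 on F) with the raw-data ANOVA on moment-matched samples.
This is the only honest route to published tables whose raw data are
unavailable.

Covariate adjustment of FeNO and exacerbation frequency fits one pooled
least-squares model of the value on age, sex (binary indicator) and
height, and reports the ratio actual/predicted per row; rows with missing
covariates get no ratio and constant covariates raise by name. Percent
bronchodilator responsiveness is 100·(post−pre)/pre with pre > 0 enforced.
Bonferroni uses threshold α/m and adjusted p = min(1, m·p).

## Synthetic data

The simulator emulates the study conditions, and its defaults are those
conditions, not tuning knobs:

* **Family** — a fixed four-generation, 32-member template with one
  first-cousin consanguineous mating and a 20-member genotyped subset.
  Founder haplotypes are independent Bernoulli draws at the founder
  frequency (default 0.2 for background variants); each meiosis transmits
  one recombinant gamete with per-interval recombination fraction 0.01.
  The causal variant is private to founder I-1 (two copies, carried on a
  15-variant founder risk segment), so the risk allele spreads only by
  descent. With penetrance f1 = 0.9 and phenocopy rate f0 = 0.05 this
  yields a mean affected fraction of ≈ 0.39 across seeds, matching the
  family's ~40% diagnosed rate; sensitivity tests switch to f1 = 1,
  f0 = 0 where recovery must be exact.
* **Genotyping noise** — symmetric single-allele flips at a configurable
  rate plus a missingness mask, both defaulting to 0. The error model is
  intentionally crude: it exists to exercise QC and missingness policy, not
  to model array chemistry.
* **Cohort** — 141 cases / 130 controls at one biallelic SNP; controls at
  risk-allele frequency p₀ = 0.38, cases at the odds-transform frequency
  p₁ = θp₀/(1−p₀+θp₀) for true allelic OR θ = 1.579, drawn under HWE
  within group.
* **Phenotypes** — per-genotype-group normal draws at the published
  group moments (nine phenotypes, group sizes 57/58/26), with optional
  linear covariate effects added before noise.

Everything flows from one `numpy.random.default_rng(seed)`; fixtures are
byte-identical across runs at equal seed.

What the simulator does **not** emulate: linkage disequilibrium between
background variants (draws are independent), population stratification,
relatedness among cohort samples, realistic error/missingness structure,
or per-phenotype missing data. Passing tests therefore demonstrate
correctness of the algorithms under the stated generative model — not
robustness to every artefact of real exome or array data.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale versions of the study shape: 501-
to 5001-variant exomes (the filter is linear in variants and the logic is
size-independent), 500-replicate cohort recovery, 2000-replicate ANOVA
null calibration, 40 000-point likelihood scans. Deterministic outputs are
ordered by (chrom, pos, alt); EM tolerance is 1e-10; the Kruskal–Wallis p
is the tie-corrected asymptotic chi-square (an exact permutation null
appears only as a test oracle at tiny n).

## Known limitations

* X/Y/mitochondrial inheritance is not modelled; all variants are treated
  as autosomal in Mendelian validation and phasing.
* Compound-heterozygote and X-linked segregation logic is intentionally
  absent.
* The Mendelian-violation report never auto-excludes variants; filtering
  on it is the caller's decision.
* Multi-locus (> 2) haplotype EM and haplotype association tests are out
  of scope, as are parametric linkage (LOD) and IBD estimation.
* Summary-statistics ANOVA cannot recover per-phenotype missing-data
  patterns: published p-values computed on unreported subsets will not
  reproduce from printed group sizes alone.
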