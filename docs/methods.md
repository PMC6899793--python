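# Methods

## Genetic model

The package models a diploid M2 family derived from selfing a single
heterozygous M1 plant that carries a set of induced point mutations on one
haplotype (pollen mutagenesis mutates one gamete, so every induced SNP is
heterozygous in the M1). Under selfing, each induced SNP segregates
1 hom-wt : 2 het : 1 hom-mut, independently across unlinked sites. A single
causal locus drives the phenotype through one of three inheritance modes:

* **recessive** — dosage 2 is mutant;
* **dominant** — dosage ≥ 1 is mutant;
* **semi-dominant, homozygous lethal** — dosage 1 is mutant, dosage 2
  aborts as an embryo. Viable selfed offspring of a heterozygote then
  segregate 2 het : 1 hom-wt, i.e. an expected mutant fraction of 2/3 among
  germinated plants.

## Zygosity inference from progeny counts

* Heterozygote calls use the two-sided exact binomial test
  (minimum-likelihood convention, via `scipy.stats.binomtest`) against the
  mode-specific expectation (1/4 for a recessive het selfed, 3/4 dominant,
  2/3 lethal, 1/2 for outcrosses to a wild-type tester). α defaults to 0.05
  per record without multiple-testing correction — decisions are per plant,
  and at the sample sizes involved a correction changes no call.
* The het vs hom-wt decision for parents with zero mutant offspring is
  one-sided: P(zero | het) = (1−q)ⁿ < α, with n the number of *phenotyped*
  offspring. This mirrors the genetic argument ("enough offspring that a
  carrier would have shown segregation") rather than a two-sided test.
* Progeny tables tolerate a phenotyped count below the germinated count
  (plants can die or escape scoring between germination and phenotyping);
  the validation enforces n_mutant + n_wildtype ≤ germinated ≤ planted.
* For the lethal mode, the expected selfed mutant fraction among germinated
  offspring is taken as 2/3 (lethality acts before germination). Real
  families often show ratios closer to 1:1 because germination is itself
  depressed in mutant-parent seed; the simulator therefore exposes
  germination as a free (optionally parent-phenotype-dependent) probability
  rather than fitting a mechanism.

## Inheritance-mode inference

Rule cascade over a family's records: (1) a mutant parent outcrossed to a
wild-type tester giving only wild-type offspring, or a *wild-type* parent
whose selfed offspring segregate mutants, proves recessiveness; (2) a mutant
parent whose selfed offspring segregate both phenotypes proves the mutant
parents are heterozygous, hence dominance; (3) under dominance, the lethal
call additionally requires both the absence of any statistically-significant
all-mutant selfed progeny set (no viable homozygote observed) and
significantly depressed germination of mutant-parent seed (one-sided Fisher
test on pooled germinated/failed counts). Germination depression alone is
treated as evidence, not proof. A family showing only all-mutant selfed sets
from mutant parents is ambiguous between a homozygous recessive parent and a
homozygous dominant one; the cascade resolves it as dominant only when
wild-type siblings' selfed progeny conspicuously fail to segregate, and
raises an error otherwise.

## The zygosity filter

States are encoded as mutant-allele dosages (hom-wt 0, het 1, hom-mut 2).
Each individual contributes an *allowed set*: a singleton when its progeny
test is informative, otherwise the set its phenotype permits under the
inheritance mode. A site passes when every individual's non-missing dosage
lies in its allowed set.

* **Missing calls** default to "compatible but counted": a coverage dropout
  must not eliminate the causal SNP, so the site survives and a per-site
  informativeness score (number of non-missing constrained individuals)
  preserves ranking. A `strict` mode drops such sites instead.
* Deduction assigns a state to an ambiguous individual only when all passing
  sites agree on one non-missing dosage; the upgraded pattern is a fixed
  point (re-filtering returns the identical candidate set).
* The filter operates on the target family only; the other sequenced family
  enters solely through allele polarity and the shared-high-frequency
  exclusion.

**Mutant-allele polarity.** When the family's inbred background differs from
the reference genome, the VCF ALT allele is not necessarily the induced
allele. For each family-segregating site the induced allele is taken as the
one segregating in this family while rare (frequency ≤ 0.7) among the other
sequenced individuals; ties default to ALT.

## Theory

* Unlinked-SNP match probability: product over constrained individuals of
  the 1:2:1 prior mass of the allowed set (1/4 homozygous singleton, 1/2
  {het}, 3/4 {het, hom-wt}). The prior assumes every segregating SNP was
  heterozygous in the selfed M1; germline mosaicism is out of model.
* BSA resolution: 100·(1 − α^(1/m)) cM for m meioses.
* Zygosity-mapping resolution: 100/m cM per side, unresolved block 2·100/m.
* Expected linked SNPs: n_snps · region/map_length, with uniform placement
  on the genetic map.
* All values are carried at full precision; rounding to the printed integer
  happens only in reports.

## Simulator

* **Genetic map**: ten chromosomes, 2.3 Gbp / 2200 cM total, split evenly
  (230 Mbp / 220 cM each) with linear bp↔cM interpolation. The theory above
  depends only on totals, so the even split is a neutral simplification.
* **Meiosis**: crossover count per chromosome ~ Poisson(L/100), breakpoints
  uniform in cM, starting haplotype by fair coin — no interference
  (Haldane), which keeps closed-form oracles (two sites d cM apart recombine
  with probability (1 − e^(−2d/100))/2).
* **Induced SNPs** are placed uniformly on the *genetic* map (linked-SNP
  expectations are per-cM); base exchanges are transitions (G→A / C→T) with
  probability 0.98, matching an EMS spectrum. The causal site is always
  forced into the induced set. Background variants (reference-vs-inbred
  differences) are homozygous in all family members and must be removed by
  the segregation filter, not by an EMS-spectrum filter.
* **Call model**: depth ~ Poisson(λ = 19, the study-scale coverage), per-read
  error rate 0.005; the dosage call is homozygous when the minor-read
  fraction is below 0.15, heterozygous otherwise; GQ is a phred-like
  log-odds of the best against second-best dosage hypothesis, capped at 99.
  Any monotone rule suffices here because validation scores calls against
  the simulator's truth set, not against a specific caller.
* **Defaults** follow the two study designs: 1357 induced SNPs with a 7+9
  mutant/wild-type sequencing design (recessive preset) and 3536 SNPs with
  8+8 (lethal preset); 40 M3 kernels planted per parent. The M2 pool size
  (96, lethal preset 60) is set so the design counts are sampleable with
  negligible failure probability; germination defaults per preset (0.98;
  mutant-parent 0.60 / wild-type-parent 0.97 for the lethal preset, the
  level implied by published germinated/planted ratios).
* Fixed seed ⇒ byte-identical output files (single `numpy` Generator drives
  every draw; writers emit deterministic text).

What the simulator does **not** emulate: read-level artifacts (mapping
bias, index hopping), structural variants (a causal insertion appears only
through its linked SNPs — exactly how the zygosity filter detects one),
residual heterozygosity of the inbred background, crossover interference,
and age-related penetrance. Passing tests therefore demonstrate the
statistical machinery under idealized segregation and coverage noise, not
robustness to caller-specific artifacts.

## Filter-threshold scope

The 60%-heterozygosity and 10%-missingness caps are evaluated over all
sequenced individuals jointly by default (`het_scope="joint"`), with a
per-family mode available — the defensible readings of a two-family design
where calling is done across both families at once.

## Numerical and scale choices

The simulation-based validation in `tests/test_acceptance.py` uses 300
replicates of the full 1357-SNP recessive design with error-free calls
(~10 s), 400 000 Monte-Carlo draws for the false-pass calibration, and 240
simulated parents for zygosity recovery. These sizes give Monte-Carlo
standard errors small relative to the tolerances being checked while keeping
the suite quick on one CPU.

## Known limitations

* The segregation-based polarity rule cannot rescue a site where the other
  family is entirely missing *and* the induced allele equals REF; such sites
  keep ALT polarity.
* `infer_inheritance` needs at least one informative record and refuses
  contradictory evidence rather than weighing it probabilistically.
* Half-missing VCF genotypes (one known allele) are treated as fully
  missing.
* The deduction step trusts the candidate set; with zero candidates nothing
  is deduced, and with a spurious candidate a wrong unanimous dosage would
  propagate (mitigated by the mismatch log and informativeness scores).
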