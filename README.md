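# zygomap

Mapping-by-sequencing of induced mutations in small segregating families,
using progeny-tested zygosity as the filter.

## The problem

Forward genetics in crops with long generation times (maize being the
motivating case) suffers from the cost of classical mapping: backcross
programs or the large phenotyped bulks needed for bulked segregant analysis
(BSA). `zygomap` implements an alternative that works on a *single* selfed
M2 family of an EMS-mutagenized line, with as few as 16 individually
sequenced plants — and, unlike BSA, it can map a mutation that only exists
in the heterozygous state (e.g. a semi-dominant, homozygous-lethal allele).

## The method

For a family derived from selfing a heterozygous M1, every induced SNP
segregates 1 hom-wt : 2 het : 1 hom-mut.  The workflow:

1. **Call-level confidence masking** — genotypes with DP < 10 or GQ < 10 are
   set to missing.
2. **Site filters** — retain SNPs with MAF ≥ 10%, ≤ 10% missing data and
   ≤ 60% heterozygous calls.
3. **Family segregation** — SNPs segregating *within* the family are the
   induced-mutation candidates; fixed differences against the reference
   (inbred background polymorphism) drop out. Sites with a mutant allele
   frequency > 0.7 in both phenotype groups are excluded.
4. **Zygosity inference** — each sequenced M2 plant is selfed (or crossed to
   a wild-type tester) and the M3 phenotype ratio determines its genotype at
   the causal locus: an exact binomial test against the Mendelian
   expectation (e.g. 1:3 for a recessive heterozygote) calls heterozygotes,
   and P(zero mutants | het) = (1−q)ⁿ < α calls homozygous wild-types. The
   same counts, pooled, decide the inheritance mode (recessive / dominant /
   semi-dominant homozygous-lethal).
5. **Zygosity filter** — keep only SNPs whose per-individual dosage matches
   every plant's allowed state. An unlinked SNP matches a fully determined
   pattern of n individuals with probability ∏ pᵢ where pᵢ is 1/4 for a
   homozygous-constrained plant and 1/2 for a het-constrained one — for 16
   homozygous-constrained plants, 0.25¹⁶ ≈ 2.3·10⁻¹⁰. Survivors are the
   causal SNP and its perfect-linkage block; with m meioses the unresolved
   block spans ~2·100/m cM.
6. **Deduction** — plants whose progeny test failed are assigned the state
   the surviving SNPs unanimously show.

A forward pedigree simulator (`zygomap.simulate`) generates the whole
design — genetic map, induced SNPs, meiosis without interference, selfing,
call noise, M3 counts — with known truth, so every stage is testable without
the original sequencing data. `zygomap.theory` provides the closed-form
design arithmetic (resolution, expected linked-SNP counts, coverage
comparison against BSA), and `zygomap.qpcr` the ΔΔCt copy-number analysis
used to corroborate dosage-sensitive candidates.

## Worked example

Simulate a recessive family (400 induced SNPs, 7 mutant + 9 wild-type
sequenced plants) and run the pipeline:

```sh
$ zygomap simulate --preset dwarf --seed 7 --n-snps 400 --out demo
seed: 7
causal site: 1:115000000
...

$ zygomap run --vcf demo/scenario.vcf --phenotypes demo/phenotypes.tsv \
      --progeny demo/progeny.tsv --family 1744 --out demo/out
input: 600
population_filter: 310
family_segregating: 310
shared_af_excluded: 310
zygosity_pass: 3
candidates: 1:115000000, 1:116619327, 1:116632186
```

Of 600 input sites (400 induced + 200 background), the filters keep the 310
that segregate confidently in the family, and the zygosity pattern collapses
them to 3 SNPs in one linkage block — including the true causal site at
1:115000000. `demo/out/candidates.tsv` lists each survivor with its base
exchange, per-group mutant-allele frequencies and allele counts;
`run_log.json` records the per-stage site counts and any zygosities deduced
for plants without informative progeny.

The design arithmetic for the 16-plant study:

```sh
$ zygomap theory --meioses 32
meiotic resolution: 3.125 cM (unresolved region ~6 cM)
BSA resolution at alpha=0.05: 8.94 cM (~9 cM)
expected linked SNPs (1357 SNPs / 2200 cM): 3.9 (~4)
zygosity design total coverage: 320x
BSA pool of 50: minimal 100x, recommended 200-300x
```

## Layout

| module | contents |
| --- | --- |
| `zygomap.core` | `GenotypeMatrix`, `Individual`, `VariantSite` |
| `zygomap.io` | VCF (GT:DP:GQ) and TSV readers/writers |
| `zygomap.filters` | the SNP retention cascade |
| `zygomap.segregation` | zygosity classification, inheritance inference, allelism tests |
| `zygomap.zygosity` | the zygosity-pattern filter and deduction |
| `zygomap.theory` | resolution / linked-SNP / coverage arithmetic |
| `zygomap.simulate` | forward pedigree simulator with truth sets |
| `zygomap.qpcr` | ΔΔCt relative copy number |
| `zygomap.pipeline`, `zygomap.cli` | orchestration and the `zygomap` command |

See `docs/methods.md` for the model details, parameter choices and known
limitations.
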