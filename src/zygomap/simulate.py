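"""Forward simulator of pollen-EMS M1 -> M2 -> M3 maize pedigrees.

Emulates the mapping design end to end with known truth: a fully
heterozygous M1 (one mutagenized gamete) carrying a configurable number of
induced SNPs placed uniformly on the genetic map, Poisson crossovers without
interference (Haldane), selfing into an M2 pool, phenotyping through an
inheritance model at a designated causal locus, sampling of a sequenced set,
a depth/error genotype-call model, and M3 segregation counts with
configurable germination.  A fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io as zio
from .core import MISSING, GenotypeMatrix, Individual, ValidationError, VariantSite
from .segregation import (
    InheritanceMode,
    InheritanceModel,
    MODELS,
    ProgenyRecord,
    RECESSIVE,
    SEMIDOMINANT_LETHAL,
)

_TRANSITION_PAIRS = (("G", "A"), ("C", "T"))
_TRANSVERSION_PAIRS = (
    ("G", "T"), ("G", "C"), ("C", "A"), ("C", "G"),
    ("A", "T"), ("A", "C"), ("T", "A"), ("T", "G"),
)


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    length_cm: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0 or self.length_cm < 0:
            raise ValidationError(f"invalid chromosome lengths for {self.name}")


@dataclass
class GeneticMap:
    """Physical and genetic chromosome lengths with linear bp<->cM mapping."""

    chromosomes: list[Chromosome]

    @classmethod
    def default_maize(cls) -> "GeneticMap":
        """Ten chromosomes totalling 2.3 Gbp / 2200 cM, split evenly."""
        n = 10
        return cls(
            [Chromosome(str(i + 1), 230_000_000, 220.0) for i in range(n)]
        )

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def total_cm(self) -> float:
        return sum(c.length_cm for c in self.chromosomes)

    @property
    def total_bp(self) -> int:
        return sum(c.length_bp for c in self.chromosomes)

    def cm_to_bp(self, chrom_index: int, cm: float) -> int:
        c = self.chromosomes[chrom_index]
        return max(1, int(round(cm / c.length_cm * c.length_bp))) if c.length_cm else 1

    def bp_to_cm(self, chrom_index: int, bp: int) -> float:
        c = self.chromosomes[chrom_index]
        return bp / c.length_bp * c.length_cm


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study-design parameters of one simulated M2 family."""

    n_induced_snps: int = 1357
    transition_fraction: float = 0.98
    inheritance: str = InheritanceMode.RECESSIVE.value
    causal_chrom: int = 0            # chromosome index on the map
    causal_cm: float = 110.0         # genetic position of the causal locus
    n_background_variants: int = 200
    n_mutant_sequenced: int = 7
    n_wildtype_sequenced: int = 9
    m2_pool_size: int = 96
    depth_lambda: float = 19.0
    error_rate: float = 0.005
    n_m3_planted: int = 40
    #: germination probability; either a single float or a mapping from the
    #: parent's phenotype ("mutant"/"wildtype") to a probability
    germination: float | Mapping[str, float] = 1.0
    family: str = "F1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.transition_fraction <= 1.0:
            raise ValidationError("transition_fraction must lie in [0,1]")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValidationError("error_rate must lie in [0, 0.5)")
        if self.inheritance not in MODELS:
            raise ValidationError(f"unknown inheritance mode {self.inheritance!r}")
        for g in self._germination_values():
            if not 0.0 <= g <= 1.0:
                raise ValidationError("germination probabilities must lie in [0,1]")
        if min(self.n_induced_snps, self.n_background_variants, self.n_m3_planted) < 0:
            raise ValidationError("counts must be non-negative")

    def _germination_values(self):
        if isinstance(self.germination, Mapping):
            return list(self.germination.values())
        return [self.germination]

    def germination_for(self, parent_phenotype: str) -> float:
        if isinstance(self.germination, Mapping):
            return self.germination.get(parent_phenotype, 1.0)
        return self.germination

    @property
    def model(self) -> InheritanceModel:
        return MODELS[self.inheritance]


def dwarf_preset(seed: int = 0) -> SimConfig:
    """Recessive design: 1357 induced SNPs, 7 mutants + 9 wild-types."""
    return SimConfig(
        n_induced_snps=1357,
        inheritance=InheritanceMode.RECESSIVE.value,
        n_mutant_sequenced=7,
        n_wildtype_sequenced=9,
        germination=0.98,
        family="1744",
        seed=seed,
    )


def pale_green_preset(seed: int = 0) -> SimConfig:
    """Semi-dominant homozygous-lethal design: 3536 SNPs, 8 + 8 sequenced.

    Mutant-parent seed germinates poorly, as expected when a quarter of the
    zygotes abort and maternal vigour is reduced.
    """
    return SimConfig(
        n_induced_snps=3536,
        inheritance=InheritanceMode.SEMIDOMINANT_LETHAL.value,
        n_mutant_sequenced=8,
        n_wildtype_sequenced=8,
        m2_pool_size=60,
        germination={"mutant": 0.60, "wildtype": 0.97},
        family="1754",
        causal_chrom=9,
        causal_cm=140.0,
        seed=seed,
    )


PRESETS = {"dwarf": dwarf_preset, "pale_green": pale_green_preset}


@dataclass
class M1Genome:
    """Site table plus the M1's two haplotypes (0/1 allele indicators).

    Induced SNPs sit on haplotype A only (the mutagenized gamete);
    background variants against the reference are on both haplotypes.
    """

    sites: list[VariantSite]
    chrom_index: np.ndarray      # per site
    pos_cm: np.ndarray
    induced: np.ndarray          # bool per site
    causal_index: int
    hap_a: np.ndarray            # uint8 allele per site
    hap_b: np.ndarray
    chrom_slices: list[slice]    # contiguous per-chromosome site ranges

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class TruthSet:
    """Ground truth of a generated scenario, for scoring recovery."""

    induced_positions: list[str]
    causal_position: str
    true_dosage: np.ndarray          # sites x sequenced individuals (mutant polarity)
    parental_zygosity: dict[str, str]
    phenotypes: dict[str, str]

    def to_json(self) -> dict:
        return {
            "induced_positions": self.induced_positions,
            "causal_position": self.causal_position,
            "true_dosage": self.true_dosage.tolist(),
            "parental_zygosity": self.parental_zygosity,
            "phenotypes": self.phenotypes,
        }


# ---------------------------------------------------------------------------
# M1 construction
# ---------------------------------------------------------------------------

def _draw_base_pair(rng: np.random.Generator, transition_fraction: float) -> tuple[str, str]:
    if rng.random() < transition_fraction:
        return _TRANSITION_PAIRS[rng.integers(2)]
    return _TRANSVERSION_PAIRS[rng.integers(len(_TRANSVERSION_PAIRS))]


def _place_uniform(gmap: GeneticMap, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniform positions on the genetic map -> (chrom_index, cm)."""
    bounds = np.cumsum([c.length_cm for c in gmap.chromosomes])
    u = rng.uniform(0.0, gmap.total_cm, n)
    chrom = np.minimum(np.searchsorted(bounds, u, side="right"), len(bounds) - 1)
    offset = np.concatenate([[0.0], bounds[:-1]])
    return chrom, u - offset[chrom]


def simulate_m1(config: SimConfig, gmap: GeneticMap, rng: np.random.Generator) -> M1Genome:
    """Build the heterozygous M1: induced SNPs uniform on the genetic map on
    one haplotype, the causal site forced into the set, plus homozygous
    background variants."""
    n_other = max(config.n_induced_snps - 1, 0)
    chrom_i, cm_i = _place_uniform(gmap, n_other, rng)
    chrom_i = np.append(chrom_i, config.causal_chrom)
    cm_i = np.append(cm_i, config.causal_cm)
    if config.causal_cm > gmap.chromosomes[config.causal_chrom].length_cm:
        raise ValidationError("causal locus lies beyond its chromosome")

    chrom_b, cm_b = _place_uniform(gmap, config.n_background_variants, rng)

    chrom_all = np.concatenate([chrom_i, chrom_b])
    cm_all = np.concatenate([cm_i, cm_b])
    induced = np.concatenate(
        [np.ones(chrom_i.size, dtype=bool), np.zeros(chrom_b.size, dtype=bool)]
    )
    causal_flag = np.zeros(chrom_all.size, dtype=bool)
    causal_flag[chrom_i.size - 1] = True

    pos_bp = np.array(
        [gmap.cm_to_bp(int(c), float(x)) for c, x in zip(chrom_all, cm_all)], dtype=np.int64
    )
    # resolve duplicate physical positions deterministically
    while True:
        key = chrom_all.astype(np.int64) * (gmap.total_bp + 1) + pos_bp
        _, first = np.unique(key, return_index=True)
        dup = np.setdiff1d(np.arange(key.size), first)
        if dup.size == 0:
            break
        pos_bp[dup] += rng.integers(1, 1000, dup.size)

    order = np.lexsort((pos_bp, chrom_all))
    chrom_all, cm_all, pos_bp = chrom_all[order], cm_all[order], pos_bp[order]
    induced = induced[order]
    causal_index = int(np.flatnonzero(causal_flag[order])[0])

    sites = []
    for c, bp in zip(chrom_all, pos_bp):
        ref, alt = _draw_base_pair(rng, config.transition_fraction)
        sites.append(VariantSite(chrom=gmap.chromosomes[int(c)].name, pos=int(bp), ref=ref, alt=alt))

    hap_a = np.ones(chrom_all.size, dtype=np.uint8)    # induced on A; background on both
    hap_b = np.where(induced, 0, 1).astype(np.uint8)

    chrom_slices = []
    for ci in range(gmap.n_chromosomes):
        idx = np.flatnonzero(chrom_all == ci)
        chrom_slices.append(slice(int(idx[0]), int(idx[-1]) + 1) if idx.size else slice(0, 0))

    return M1Genome(
        sites=sites,
        chrom_index=chrom_all.astype(int),
        pos_cm=cm_all,
        induced=induced,
        causal_index=causal_index,
        hap_a=hap_a,
        hap_b=hap_b,
        chrom_slices=chrom_slices,
    )


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------

def meiosis(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    genome: M1Genome,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one gamete from a diploid: per chromosome, Poisson(L/100)
    crossovers at uniform genetic positions, alternating parental segments,
    starting haplotype by fair coin (no interference)."""
    gamete = np.empty_like(hap_a)
    for ci, chrom in enumerate(gmap.chromosomes):
        sl = genome.chrom_slices[ci]
        k = rng.poisson(chrom.length_cm / 100.0)
        start = int(rng.integers(2))
        if sl.start == sl.stop:
            continue
        if k == 0:
            seg = np.full(sl.stop - sl.start, start)
        else:
            breaks = np.sort(rng.uniform(0.0, chrom.length_cm, k))
            seg = (start + np.searchsorted(breaks, genome.pos_cm[sl])) % 2
        gamete[sl] = np.where(seg == 0, hap_a[sl], hap_b[sl])
    return gamete


# ---------------------------------------------------------------------------
# M2 generation
# ---------------------------------------------------------------------------

def self_to_m2(
    genome: M1Genome,
    model: InheritanceModel,
    n_individuals: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str]]:
    """Self the M1 into an M2 pool.

    Returns (dosage matrix sites x individuals in mutant polarity,
    phenotype list).  Under the homozygous-lethal model, causal-dosage-2
    zygotes abort and are redrawn, so the viable pool segregates 1 hom_wt :
    2 het at the causal locus.
    """
    lethal = model.mode is InheritanceMode.SEMIDOMINANT_LETHAL
    dosages = np.empty((genome.n_sites, n_individuals), dtype=np.int8)
    phenotypes = []
    for j in range(n_individuals):
        while True:
            g1 = meiosis(genome.hap_a, genome.hap_b, genome, gmap, rng)
            g2 = meiosis(genome.hap_a, genome.hap_b, genome, gmap, rng)
            d = g1.astype(np.int8) + g2.astype(np.int8)
            causal_d = int(d[genome.causal_index])
            if lethal and causal_d == 2:
                continue
            break
        dosages[:, j] = d
        phenotypes.append(model.phenotype(causal_d))
    return dosages, phenotypes


def sample_sequenced_set(
    phenotypes: Sequence[str],
    n_mutant: int,
    n_wildtype: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample the sequencing design (without replacement) from the M2 pool."""
    phen = np.asarray(phenotypes)
    mut_idx = np.flatnonzero(phen == "mutant")
    wt_idx = np.flatnonzero(phen == "wildtype")
    if mut_idx.size < n_mutant or wt_idx.size < n_wildtype:
        raise ValidationError(
            f"M2 pool exhausted (have {mut_idx.size} mutant / {wt_idx.size} wild-type, "
            f"need {n_mutant}/{n_wildtype}); increase m2_pool_size"
        )
    chosen = np.concatenate(
        [
            rng.choice(mut_idx, n_mutant, replace=False),
            rng.choice(wt_idx, n_wildtype, replace=False),
        ]
    )
    return chosen


# ---------------------------------------------------------------------------
# Genotype-call noise model
# ---------------------------------------------------------------------------

def simulate_calls(
    true_dosage: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-call depth/error model -> (called dosage, depth, genotype quality).

    Depth ~ Poisson(depth_lambda); each read shows the alternate allele with
    probability d/2 perturbed by the per-read error rate.  The call is
    homozygous when the minor-read fraction is below 0.15, heterozygous
    otherwise; zero depth gives a missing call.  GQ is a phred-like log-odds
    of the best against the second-best dosage hypothesis, capped at 99.
    """
    shape = true_dosage.shape
    depth = rng.poisson(config.depth_lambda, size=shape).astype(np.int32)
    e = config.error_rate
    p_alt = np.choose(true_dosage.astype(int), [e, 0.5, 1.0 - e])
    alt_reads = rng.binomial(depth, p_alt)

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, alt_reads / np.maximum(depth, 1), np.nan)
    called = np.full(shape, MISSING, dtype=np.int8)
    has = depth > 0
    called[has & (frac < 0.15)] = 0
    called[has & (frac > 0.85)] = 2
    called[has & (frac >= 0.15) & (frac <= 0.85)] = 1

    # phred-like quality from binomial log-likelihoods of dosage 0/1/2
    e_q = max(e, 1e-4)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.stack(
            [
                alt_reads * np.log(p) + (depth - alt_reads) * np.log(1.0 - p)
                for p in (e_q, 0.5, 1.0 - e_q)
            ]
        )
    ll_sorted = np.sort(ll, axis=0)
    gq = 10.0 / np.log(10.0) * (ll_sorted[2] - ll_sorted[1])
    gq = np.clip(np.where(depth > 0, gq, 0.0), 0.0, 99.0)
    return called, depth, gq.astype(np.float32)


def matrix_from_truth(
    genome: M1Genome,
    individuals: Sequence[Individual],
    true_dosage: np.ndarray,
    depth: int = 30,
    quality: float = 99.0,
) -> GenotypeMatrix:
    """Error-free GenotypeMatrix straight from the truth (no call noise)."""
    n = true_dosage.shape[1]
    return GenotypeMatrix(
        sites=[replace(s) for s in genome.sites],
        individuals=list(individuals),
        dosage=true_dosage.astype(np.int8),
        depth=np.full_like(true_dosage, depth, dtype=np.int32),
        quality=np.full(true_dosage.shape, quality, dtype=np.float32),
    )


# ---------------------------------------------------------------------------
# M3 progeny
# ---------------------------------------------------------------------------

def simulate_m3(
    parent_id: str,
    parent_causal_dosage: int,
    model: InheritanceModel,
    config: SimConfig,
    rng: np.random.Generator,
    pollination: str = "selfed",
) -> ProgenyRecord:
    """Draw an M3 segregation record for one M2 parent.

    Zygote genotypes follow Mendel; under the lethal model dosage-2 zygotes
    abort before germination; surviving kernels germinate with the
    configured probability and are phenotyped through the model.
    """
    n_planted = config.n_m3_planted
    lethal = model.mode is InheritanceMode.SEMIDOMINANT_LETHAL
    parent_phenotype = (
        model.phenotype(parent_causal_dosage)
        if not (lethal and parent_causal_dosage == 2)
        else "inviable"
    )
    if pollination.strip().lower() == "selfed":
        probs = {
            0: (1.0, 0.0, 0.0),
            1: (0.25, 0.5, 0.25),
            2: (0.0, 0.0, 1.0),
        }[parent_causal_dosage]
    else:  # outcross to a homozygous wild-type tester
        probs = {
            0: (1.0, 0.0, 0.0),
            1: (0.5, 0.5, 0.0),
            2: (0.0, 1.0, 0.0),
        }[parent_causal_dosage]
    zygotes = rng.choice(3, size=n_planted, p=probs)
    viable = zygotes != 2 if lethal else np.ones(n_planted, dtype=bool)
    g = config.germination_for(parent_phenotype)
    germinated = viable & (rng.random(n_planted) < g)
    phen = np.array([model.phenotype(int(d)) for d in zygotes[germinated]])
    return ProgenyRecord(
        parent_id=parent_id,
        pollination=pollination,
        n_mutant=int((phen == "mutant").sum()),
        n_wildtype=int((phen == "wildtype").sum()),
        n_germinated=int(germinated.sum()),
        n_planted=n_planted,
        parent_phenotype=parent_phenotype,
    )


# ---------------------------------------------------------------------------
# End-to-end scenario
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    config: SimConfig
    gmap: GeneticMap
    genome: M1Genome
    matrix: GenotypeMatrix          # noisy calls for the sequenced set
    truth: TruthSet
    progeny: list[ProgenyRecord]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "scenario.vcf",
            "phenotypes": out / "phenotypes.tsv",
            "progeny": out / "progeny.tsv",
            "truth": out / "truth.json",
        }
        zio.write_vcf(self.matrix, paths["vcf"])
        zio.write_phenotype_table(self.matrix.individuals, paths["phenotypes"])
        zio.write_progeny_table(self.progeny, paths["progeny"])
        truth = self.truth.to_json()
        truth["seed"] = self.config.seed
        with paths["truth"].open("w", encoding="utf-8", newline="\n") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


def generate_scenario(
    config: SimConfig,
    gmap: GeneticMap | None = None,
    noisy_calls: bool = True,
) -> Scenario:
    """Simulate one family end to end; deterministic for a fixed seed."""
    gmap = gmap or GeneticMap.default_maize()
    rng = np.random.default_rng(config.seed)
    model = config.model
    genome = simulate_m1(config, gmap, rng)
    pool_dosage, pool_phen = self_to_m2(genome, model, config.m2_pool_size, gmap, rng)
    chosen = sample_sequenced_set(
        pool_phen, config.n_mutant_sequenced, config.n_wildtype_sequenced, rng
    )
    true_dosage = pool_dosage[:, chosen]
    phenotypes = [pool_phen[i] for i in chosen]

    individuals = [
        Individual(
            id=f"{config.family}_{k + 1:02d}_{'mt' if ph == 'mutant' else 'WT'}",
            family=config.family,
            generation="M2",
            phenotype=ph,
        )
        for k, ph in enumerate(phenotypes)
    ]

    if noisy_calls:
        called, depth, gq = simulate_calls(true_dosage, config, rng)
        matrix = GenotypeMatrix(
            sites=[replace(s) for s in genome.sites],
            individuals=individuals,
            dosage=called,
            depth=depth,
            quality=gq,
        )
    else:
        matrix = matrix_from_truth(genome, individuals, true_dosage)

    causal_dosages = true_dosage[genome.causal_index]
    progeny = [
        simulate_m3(ind.id, int(causal_dosages[j]), model, config, rng)
        for j, ind in enumerate(individuals)
    ]
    state_name = {0: "hom_wt", 1: "het", 2: "hom_mut"}
    truth = TruthSet(
        induced_positions=[genome.sites[i].label for i in np.flatnonzero(genome.induced)],
        causal_position=genome.sites[genome.causal_index].label,
        true_dosage=true_dosage,
        parental_zygosity={ind.id: state_name[int(causal_dosages[j])] for j, ind in enumerate(individuals)},
        phenotypes={ind.id: ind.phenotype for ind in individuals},
    )
    return Scenario(config=config, gmap=gmap, genome=genome, matrix=matrix, truth=truth, progeny=progeny)
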