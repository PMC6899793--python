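"""Core genotype containers shared by every pipeline stage.

The central object is :class:`GenotypeMatrix`, a sites x individuals grid of
diploid genotype calls.  Dosages are stored as counts of the VCF ALT allele
(0, 1, 2, or :data:`MISSING`); each site additionally records which allele
(REF or ALT) is the family's induced ("mutant") allele, so downstream code
can work in mutant-allele polarity via :meth:`GenotypeMatrix.mutant_dosage`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

#: Sentinel dosage for a missing (uncalled or masked) genotype.
MISSING: int = -1

PHENOTYPES = ("mutant", "wildtype", "unknown")
GENERATIONS = ("M1", "M2", "M3", "F1")

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = ("A", "C", "G", "T")


class ValidationError(ValueError):
    """Raised when an input table or matrix violates a model invariant."""


@dataclass(frozen=True)
class Individual:
    """A single plant with its family, generation and phenotype class."""

    id: str
    family: str
    generation: str = "M2"
    phenotype: str = "unknown"

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValidationError(
                f"unknown phenotype label {self.phenotype!r} for {self.id!r}; "
                f"expected one of {PHENOTYPES}"
            )


@dataclass
class VariantSite:
    """A biallelic SNP with 1-based VCF coordinates.

    ``mutant_allele`` designates which of REF/ALT is the family's induced
    allele.  It defaults to ALT and may be re-polarised by the segregation
    filter when the family was mapped against a divergent reference.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    mutant_allele: str = "alt"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if self.mutant_allele not in ("ref", "alt"):
            raise ValidationError(f"mutant_allele must be 'ref' or 'alt', got {self.mutant_allele!r}")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and self.ref in _BASES and self.alt in _BASES

    @property
    def is_transition(self) -> bool:
        return (self.ref, self.alt) in _TRANSITIONS

    @property
    def wt_base(self) -> str:
        return self.ref if self.mutant_allele == "alt" else self.alt

    @property
    def mutant_base(self) -> str:
        return self.alt if self.mutant_allele == "alt" else self.ref

    @property
    def base_exchange(self) -> str:
        """Wild-type/mutant base pair, e.g. ``"G/A"``."""
        return f"{self.wt_base}/{self.mutant_base}"

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass
class GenotypeMatrix:
    """Sites x individuals grid of dosage/depth/quality calls.

    ``dosage`` counts ALT alleles (-1 = missing), ``depth`` is per-call read
    depth (DP) and ``quality`` is the genotype quality (GQ).
    """

    sites: list[VariantSite]
    individuals: list[Individual]
    dosage: np.ndarray
    depth: np.ndarray
    quality: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.sites), len(self.individuals))
        self.dosage = np.asarray(self.dosage, dtype=np.int8).reshape(shape)
        self.depth = np.asarray(self.depth, dtype=np.int32).reshape(shape)
        self.quality = np.asarray(self.quality, dtype=np.float32).reshape(shape)
        bad = (self.dosage < MISSING) | (self.dosage > 2)
        if bad.any():
            raise ValidationError("dosages must be in {0,1,2} or missing (-1)")
        if (self.depth < 0).any():
            raise ValidationError("depths must be non-negative")
        if not np.isfinite(self.quality).all() or (self.quality < 0).any():
            raise ValidationError("qualities must be finite and non-negative")
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate individual ids in matrix")

    # -- shape helpers -----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    # -- polarity ----------------------------------------------------------
    @property
    def mutant_dosage(self) -> np.ndarray:
        """Dosage counted in each site's mutant-allele polarity."""
        flip = np.fromiter(
            (s.mutant_allele == "ref" for s in self.sites), dtype=bool, count=self.n_sites
        )
        md = self.dosage.copy()
        if flip.any():
            rows = md[flip]
            nonmiss = rows != MISSING
            rows[nonmiss] = 2 - rows[nonmiss]
            md[flip] = rows
        return md

    # -- subsetting --------------------------------------------------------
    def take_sites(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sites=[self.sites[i] for i in index],
            individuals=list(self.individuals),
            dosage=self.dosage[index],
            depth=self.depth[index],
            quality=self.quality[index],
        )

    def take_individuals(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sites=list(self.sites),
            individuals=[self.individuals[i] for i in index],
            dosage=self.dosage[:, index],
            depth=self.depth[:, index],
            quality=self.quality[:, index],
        )

    def family_index(self, family: str) -> np.ndarray:
        return np.array([i for i, ind in enumerate(self.individuals) if ind.family == family])

    def phenotype_index(self, phenotype: str, family: str | None = None) -> np.ndarray:
        return np.array(
            [
                i
                for i, ind in enumerate(self.individuals)
                if ind.phenotype == phenotype and (family is None or ind.family == family)
            ],
            dtype=int,
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sites=[replace(s) for s in self.sites],
            individuals=list(self.individuals),
            dosage=self.dosage.copy(),
            depth=self.depth.copy(),
            quality=self.quality.copy(),
        )

    # -- accounting --------------------------------------------------------
    def allele_counts(self) -> np.ndarray:
        """Per-site (ref, alt, missing) allele counts in ALT polarity.

        Conservation: ref + alt + 2*missing == 2 * n_individuals.
        """
        miss = self.dosage == MISSING
        alt = np.where(miss, 0, self.dosage).sum(axis=1)
        n_miss = miss.sum(axis=1)
        ref = 2 * self.n_individuals - alt - 2 * n_miss
        return np.stack([ref, alt, n_miss], axis=1)


def concat_sites(matrices: Iterable[GenotypeMatrix]) -> GenotypeMatrix:
    """Stack matrices that share the same individuals."""
    matrices = list(matrices)
    first = matrices[0]
    for m in matrices[1:]:
        if m.ids != first.ids:
            raise ValidationError("cannot concatenate matrices over different individuals")
    return GenotypeMatrix(
        sites=[s for m in matrices for s in m.sites],
        individuals=list(first.individuals),
        dosage=np.concatenate([m.dosage for m in matrices]),
        depth=np.concatenate([m.depth for m in matrices]),
        quality=np.concatenate([m.quality for m in matrices]),
    )
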