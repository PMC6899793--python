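"""SNP retention cascade for a segregating M2 family.

Fixed pipeline order, each stage only masking or removing calls:

1. per-call confidence masking (DP < 10 or GQ < 10 -> missing),
2. population-level site filters (MAF >= 10%, missing <= 10%, het <= 60%),
3. family-segregation selection (both alleles observed within the family),
4. per-phenotype-group mutant-allele frequencies,
5. exclusion of sites with mutant allele frequency > 0.7 in both groups
   (background polymorphism shared by mutants and wild-types cannot be the
   induced lesion).

Every stage is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core import MISSING, GenotypeMatrix, ValidationError


@dataclass
class FilterConfig:
    """Thresholds of the retention cascade (defaults follow standard WGS
    genotype-calling practice for ~20x coverage)."""

    min_depth: int = 10
    min_quality: float = 10.0
    min_maf: float = 0.10
    max_missing: float = 0.10
    max_het: float = 0.60
    shared_af_cutoff: float = 0.70
    #: "joint" evaluates missingness/heterozygosity over all sequenced
    #: individuals together; "per_family" restricts to the target family.
    het_scope: str = "joint"

    def __post_init__(self) -> None:
        for name in ("min_maf", "max_missing", "max_het", "shared_af_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0,1], got {v}")
        if self.min_depth < 0 or self.min_quality < 0:
            raise ValidationError("depth/quality thresholds must be non-negative")
        if self.het_scope not in ("joint", "per_family"):
            raise ValidationError(f"het_scope must be 'joint' or 'per_family', got {self.het_scope!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FilterLog:
    """Per-site removal log: which stage dropped a site and why."""

    entries: list[tuple[str, int, str, str]] = field(default_factory=list)

    def add(self, chrom: str, pos: int, stage: str, reason: str) -> None:
        self.entries.append((chrom, pos, stage, reason))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["chrom", "pos", "stage", "reason"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Stage 1: per-call confidence masking
# ---------------------------------------------------------------------------

def mask_low_confidence(matrix: GenotypeMatrix, config: FilterConfig) -> GenotypeMatrix:
    """Set calls with depth < min_depth or quality < min_quality to missing.

    Thresholds are strict ("below 10"), so DP=10/GQ=10 calls are retained.
    """
    out = matrix.copy()
    low = (out.depth < config.min_depth) | (out.quality < config.min_quality)
    out.dosage[low] = MISSING
    return out


# ---------------------------------------------------------------------------
# Stage 2: population-level site filters
# ---------------------------------------------------------------------------

def population_site_filter(
    matrix: GenotypeMatrix,
    config: FilterConfig,
    log: FilterLog | None = None,
) -> GenotypeMatrix:
    """Retain sites with MAF >= min_maf, missingness <= max_missing and
    heterozygosity <= max_het.

    MAF and heterozygosity are computed over non-missing calls; missingness
    over all calls.  Sites without any non-missing call are removed.
    """
    dos = matrix.dosage
    miss = dos == MISSING
    n_ind = matrix.n_individuals
    n_nonmiss = (~miss).sum(axis=1)
    n_het = (dos == 1).sum(axis=1)
    alt = np.where(miss, 0, dos).sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        f_alt = alt / (2.0 * n_nonmiss)
        maf = np.minimum(f_alt, 1.0 - f_alt)
        het_frac = n_het / n_nonmiss
    miss_frac = miss.sum(axis=1) / n_ind

    keep = (
        (n_nonmiss > 0)
        & (maf >= config.min_maf)
        & (miss_frac <= config.max_missing)
        & (het_frac <= config.max_het)
    )
    if log is not None:
        for i in np.flatnonzero(~keep):
            s = matrix.sites[i]
            if n_nonmiss[i] == 0:
                reason = "all_missing"
            elif miss_frac[i] > config.max_missing:
                reason = f"missing_{miss_frac[i]:.3f}"
            elif not maf[i] >= config.min_maf:
                reason = f"maf_{maf[i]:.3f}"
            else:
                reason = f"het_{het_frac[i]:.3f}"
            log.add(s.chrom, s.pos, "population_site_filter", reason)
    return matrix.take_sites(keep)


# ---------------------------------------------------------------------------
# Stage 3: family-segregation selection
# ---------------------------------------------------------------------------

def select_family_segregating(
    matrix: GenotypeMatrix,
    family: str,
    config: FilterConfig | None = None,
    log: FilterLog | None = None,
) -> GenotypeMatrix:
    """Select sites segregating within one family as induced-SNP candidates.

    A site segregates when both alleles are observed among the family's
    non-missing calls (a selfed heterozygous M1 transmits 1:2:1).  Fixed
    differences against the reference (background polymorphism of the inbred
    the family derives from) are monomorphic within the family and drop out.

    The induced allele at each retained site is the allele segregating in
    this family that is rare or absent in the other sequenced individuals;
    when the other individuals give no guidance, ALT is kept.
    """
    config = config or FilterConfig()
    fam_idx = matrix.family_index(family)
    if fam_idx.size == 0:
        raise ValidationError(f"no individuals of family {family!r} in matrix")
    other_idx = np.array([i for i in range(matrix.n_individuals) if i not in set(fam_idx.tolist())])

    dos = matrix.dosage[:, fam_idx]
    miss = dos == MISSING
    n_nonmiss = (~miss).sum(axis=1)
    alt = np.where(miss, 0, dos).sum(axis=1)
    total = 2 * n_nonmiss
    segregating = (n_nonmiss >= 2) & (alt > 0) & (alt < total)

    if log is not None:
        for i in np.flatnonzero(~segregating):
            s = matrix.sites[i]
            reason = "too_few_calls" if n_nonmiss[i] < 2 else "not_segregating"
            log.add(s.chrom, s.pos, "family_segregation", reason)

    out = matrix.take_sites(segregating)

    # polarity: the induced allele should be rare in the other family
    if other_idx.size:
        odos = out.dosage[:, other_idx]
        omiss = odos == MISSING
        o_nonmiss = (~omiss).sum(axis=1)
        o_alt = np.where(omiss, 0, odos).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            o_falt = o_alt / (2.0 * o_nonmiss)
        for i, site in enumerate(out.sites):
            if o_nonmiss[i] == 0:
                site.mutant_allele = "alt"
            elif o_falt[i] <= config.shared_af_cutoff:
                site.mutant_allele = "alt"
            elif (1.0 - o_falt[i]) <= config.shared_af_cutoff:
                site.mutant_allele = "ref"
            else:  # tie: both alleles common elsewhere
                site.mutant_allele = "alt"
    return out


# ---------------------------------------------------------------------------
# Stage 4: per-group allele frequencies
# ---------------------------------------------------------------------------

def group_allele_frequencies(matrix: GenotypeMatrix, family: str | None = None) -> pd.DataFrame:
    """Mutant-allele frequency and counts per phenotype group at every site.

    Frequencies are mutant alleles over non-missing alleles per group; a
    fully missing group yields NaN with ``undefined`` flagged.
    """
    md = matrix.mutant_dosage
    rows = {}
    for group in ("mutant", "wildtype"):
        idx = matrix.phenotype_index(group, family=family)
        if idx.size:
            dos = md[:, idx]
            miss = dos == MISSING
            n_nonmiss_alleles = 2 * (~miss).sum(axis=1)
            mut = np.where(miss, 0, dos).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                f = np.where(n_nonmiss_alleles > 0, mut / np.maximum(n_nonmiss_alleles, 1), np.nan)
            rows[group] = (f, mut, n_nonmiss_alleles, miss.sum(axis=1), 2 * idx.size)
        else:
            nan = np.full(matrix.n_sites, np.nan)
            zero = np.zeros(matrix.n_sites, dtype=int)
            rows[group] = (nan, zero, zero, zero, 0)

    fm, mm, nm, missm, totm = rows["mutant"]
    fw, mw, nw, missw, totw = rows["wildtype"]
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in matrix.sites],
            "pos": [s.pos for s in matrix.sites],
            "f_mutant_group": fm,
            "f_wildtype_group": fw,
            "mut_alleles_mutant_group": mm,
            "mut_alleles_wildtype_group": mw,
            "called_alleles_mutant_group": nm,
            "called_alleles_wildtype_group": nw,
            "missing_mutant_group": missm,
            "missing_wildtype_group": missw,
            "total_alleles_mutant_group": totm,
            "total_alleles_wildtype_group": totw,
            "undefined": np.isnan(fm) | np.isnan(fw),
        }
    )


# ---------------------------------------------------------------------------
# Stage 5: shared-high-frequency exclusion
# ---------------------------------------------------------------------------

def exclude_shared_high_af(
    matrix: GenotypeMatrix,
    frequencies: pd.DataFrame,
    config: FilterConfig,
    log: FilterLog | None = None,
) -> GenotypeMatrix:
    """Drop sites whose mutant allele frequency exceeds the cutoff in BOTH
    phenotype groups (strict inequality); an undefined frequency in either
    group keeps the site."""
    fm = frequencies["f_mutant_group"].to_numpy()
    fw = frequencies["f_wildtype_group"].to_numpy()
    remove = (fm > config.shared_af_cutoff) & (fw > config.shared_af_cutoff)
    remove = np.where(np.isnan(fm) | np.isnan(fw), False, remove)
    if log is not None:
        for i in np.flatnonzero(remove):
            s = matrix.sites[i]
            log.add(s.chrom, s.pos, "shared_high_af", f"f=({fm[i]:.3f},{fw[i]:.3f})")
    return matrix.take_sites(~remove)
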