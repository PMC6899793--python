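"""The zygosity-pattern filter.

The discriminating idea of the method: every sequenced M2 individual has a
known (or phenotype-bounded) zygosity at the causal locus, so only SNPs
whose genotype matches that state in *every* individual can be causal or in
perfect linkage.  With 16 individuals the chance that an unlinked
1:2:1-segregating SNP matches a fully determined pattern is of order
0.25^16, so the filter typically reduces thousands of induced SNPs to a
handful of markers in one linkage block.

States are encoded as mutant-allele dosages: hom_wt = 0, het = 1,
hom_mut = 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, Individual, ValidationError
from .filters import group_allele_frequencies
from .segregation import InheritanceMode, InheritanceModel, ZygosityCall

STATE_DOSAGE = {"hom_wt": 0, "het": 1, "hom_mut": 2}
DOSAGE_STATE = {v: k for k, v in STATE_DOSAGE.items()}
FULL_SET = frozenset({0, 1, 2})


class PatternConflictError(ValidationError):
    """An individual's progeny-proved state contradicts its phenotype."""


def phenotype_forced_states(model: InheritanceModel, phenotype: str) -> frozenset[int]:
    """Dosages compatible with a phenotype under an inheritance model."""
    if phenotype == "unknown":
        return FULL_SET
    allowed = frozenset(
        d for d, ph in model.phenotype_map.items() if ph == phenotype
    )
    if not allowed:
        raise PatternConflictError(
            f"phenotype {phenotype!r} impossible under {model.mode.value}"
        )
    return allowed


@dataclass
class ZygosityPattern:
    """Per-individual sets of allowed dosages, with provenance."""

    individuals: list[Individual]
    allowed: dict[str, frozenset[int]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ind in self.individuals:
            states = self.allowed.get(ind.id)
            if not states:
                raise ValidationError(f"empty or missing allowed set for {ind.id!r}")

    @property
    def ids(self) -> list[str]:
        return [i.id for i in self.individuals]

    def is_constrained(self, individual_id: str) -> bool:
        return self.allowed[individual_id] != FULL_SET

    def with_state(self, individual_id: str, state: str, provenance: str = "deduced") -> "ZygosityPattern":
        allowed = dict(self.allowed)
        allowed[individual_id] = frozenset({STATE_DOSAGE[state]})
        prov = dict(self.provenance)
        prov[individual_id] = provenance
        return ZygosityPattern(list(self.individuals), allowed, prov)


def build_pattern(
    individuals: Sequence[Individual],
    model: InheritanceModel,
    calls: Mapping[str, ZygosityCall] | None = None,
) -> ZygosityPattern:
    """Combine progeny-proved zygosities with phenotype-forced bounds.

    A known progeny-test state becomes a singleton set; individuals without
    an informative progeny test fall back to the states their phenotype
    permits under the model (for a recessive mutation: mutants must be
    homozygous mutant, wild-types are het or hom wild-type).  A proved state
    outside the phenotype-permitted set is a conflict.
    """
    calls = calls or {}
    allowed: dict[str, frozenset[int]] = {}
    provenance: dict[str, str] = {}
    for ind in individuals:
        forced = phenotype_forced_states(model, ind.phenotype)
        call = calls.get(ind.id)
        if call is not None and call.state != "unknown":
            d = STATE_DOSAGE[call.state]
            if d not in forced:
                raise PatternConflictError(
                    f"{ind.id}: progeny-proved state {call.state} incompatible with "
                    f"{ind.phenotype} phenotype under {model.mode.value}"
                )
            allowed[ind.id] = frozenset({d})
            provenance[ind.id] = "progeny_test"
        else:
            allowed[ind.id] = forced
            provenance[ind.id] = "phenotype_forced" if forced != FULL_SET else "unconstrained"
    return ZygosityPattern(list(individuals), allowed, provenance)


@dataclass
class CandidateSet:
    """Sites passing the zygosity filter, with per-site informativeness and
    a log of near-misses (which individuals each failed site violated)."""

    matrix: GenotypeMatrix
    pattern: ZygosityPattern
    informativeness: np.ndarray
    mismatch_log: pd.DataFrame

    @property
    def n_candidates(self) -> int:
        return self.matrix.n_sites

    def positions(self) -> list[str]:
        return [s.label for s in self.matrix.sites]


def _allowed_matrix(pattern: ZygosityPattern, ids: Sequence[str]) -> np.ndarray:
    """(n_individuals, 3) boolean table of allowed dosages."""
    table = np.zeros((len(ids), 3), dtype=bool)
    for j, iid in enumerate(ids):
        for d in pattern.allowed[iid]:
            table[j, d] = True
    return table


def apply_zygosity_filter(
    matrix: GenotypeMatrix,
    pattern: ZygosityPattern,
    missing_policy: str = "lenient",
) -> CandidateSet:
    """Retain sites whose dosage lies in every individual's allowed set.

    ``missing_policy='lenient'`` (default) treats a missing call as
    compatible but reports per-site informativeness (number of non-missing
    constrained individuals) so thin sites rank low; ``'strict'`` drops any
    site missing in a constrained individual.  Coverage dropouts should not
    eliminate the causal SNP, hence the lenient default.
    """
    if missing_policy not in ("lenient", "strict"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    ids = matrix.ids
    for iid in ids:
        if iid not in pattern.allowed:
            raise ValidationError(f"pattern has no entry for individual {iid!r}")
    table = _allowed_matrix(pattern, ids)
    constrained = np.array([pattern.is_constrained(i) for i in ids])

    md = matrix.mutant_dosage
    miss = md == MISSING
    cols = np.arange(len(ids))
    ok = miss | table[cols[None, :], np.where(miss, 0, md)]
    matches = ok.all(axis=1)
    if missing_policy == "strict":
        matches &= ~(miss & constrained[None, :]).any(axis=1)

    informativeness = ((~miss) & constrained[None, :]).sum(axis=1)

    log_rows = []
    for i in np.flatnonzero(~matches):
        bad = [ids[j] for j in np.flatnonzero(~ok[i])]
        missing_bad = (
            [ids[j] for j in np.flatnonzero(miss[i] & constrained)]
            if missing_policy == "strict"
            else []
        )
        s = matrix.sites[i]
        log_rows.append(
            (s.chrom, s.pos, ";".join(bad), ";".join(missing_bad), len(bad))
        )
    mismatch_log = pd.DataFrame(
        log_rows, columns=["chrom", "pos", "violating_individuals", "missing_individuals", "n_violations"]
    )
    return CandidateSet(
        matrix=matrix.take_sites(matches),
        pattern=pattern,
        informativeness=informativeness[matches],
        mismatch_log=mismatch_log,
    )


def deduce_unknown_zygosity(
    candidates: CandidateSet,
    pattern: ZygosityPattern,
) -> tuple[ZygosityPattern, dict[str, str], list[str]]:
    """Infer non-singleton individuals' states from the surviving SNPs.

    If every passing site shows the same non-missing dosage for an
    individual whose allowed set is still ambiguous, that dosage becomes the
    individual's state (provenance "deduced").  Disagreement across sites
    leaves the individual unknown with a warning.
    """
    if candidates.n_candidates == 0:
        return pattern, {}, ["no candidate sites; nothing to deduce"]
    md = candidates.matrix.mutant_dosage
    ids = candidates.matrix.ids
    deduced: dict[str, str] = {}
    warnings: list[str] = []
    new_pattern = pattern
    for j, iid in enumerate(ids):
        if len(pattern.allowed[iid]) <= 1:
            continue
        values = md[:, j]
        values = values[values != MISSING]
        uniq = np.unique(values)
        if uniq.size == 0:
            warnings.append(f"{iid}: all candidate calls missing; state remains unknown")
            continue
        if uniq.size > 1:
            warnings.append(
                f"{iid}: candidate sites disagree (dosages {sorted(int(u) for u in uniq)}); "
                "state remains unknown"
            )
            continue
        state = DOSAGE_STATE[int(uniq[0])]
        deduced[iid] = state
        new_pattern = new_pattern.with_state(iid, state)
    return new_pattern, deduced, warnings


def pattern_allele_counts(
    individuals: Sequence[Individual],
    target_family: str,
    states: Mapping[str, str],
) -> dict[str, int]:
    """Allele bookkeeping over ALL sequenced individuals from the final
    zygosity assignments of the target family.

    Individuals outside the target family do not carry the family's induced
    allele and contribute reference alleles only.  Returns total alleles,
    reference alleles and mutant alleles split by phenotype group.
    """
    total = 2 * len(individuals)
    mut_m = mut_w = 0
    for ind in individuals:
        if ind.family != target_family:
            continue
        state = states.get(ind.id)
        if state is None or state == "unknown":
            raise ValidationError(f"no final zygosity for {ind.id!r}")
        d = STATE_DOSAGE[state]
        if ind.phenotype == "mutant":
            mut_m += d
        else:
            mut_w += d
    return {
        "total_alleles": total,
        "ref_alleles": total - mut_m - mut_w,
        "mut_alleles_mutant_group": mut_m,
        "mut_alleles_wildtype_group": mut_w,
    }


def expected_group_frequency(states: Sequence[str]) -> float:
    """Expected mutant-allele frequency in a group of assigned zygosities,
    e.g. 7 het + 2 hom_wt wild-types -> 7/18."""
    if not states:
        raise ValidationError("empty group")
    return sum(STATE_DOSAGE[s] for s in states) / (2.0 * len(states))


def candidate_report(
    candidates: CandidateSet,
    family: str | None = None,
) -> pd.DataFrame:
    """Tabulate passing sites in genome order with per-group allele counts
    and transition/transversion annotation."""
    m = candidates.matrix
    freqs = group_allele_frequencies(m, family=family)
    df = pd.DataFrame(
        {
            "chrom": [s.chrom for s in m.sites],
            "pos": [s.pos for s in m.sites],
            "base_exchange": [s.base_exchange for s in m.sites],
            "is_transition": [s.is_transition for s in m.sites],
            "f_mutant_group": freqs["f_mutant_group"],
            "f_wildtype_group": freqs["f_wildtype_group"],
            "total_alleles": freqs["total_alleles_mutant_group"] + freqs["total_alleles_wildtype_group"],
            "mut_alleles_mutant_group": freqs["mut_alleles_mutant_group"],
            "mut_alleles_wildtype_group": freqs["mut_alleles_wildtype_group"],
            "n_informative": candidates.informativeness,
        }
    )
    df["ref_alleles"] = (
        df["total_alleles"] - df["mut_alleles_mutant_group"] - df["mut_alleles_wildtype_group"]
    )
    order = np.lexsort((df["pos"].to_numpy(), df["chrom"].to_numpy()))
    return df.iloc[order].reset_index(drop=True)
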