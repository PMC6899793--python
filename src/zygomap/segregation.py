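"""Progeny-based zygosity inference and inheritance-model deduction.

A sequenced M2 plant's genotype at the causal locus (homozygous mutant,
heterozygous, homozygous wild-type) is inferred from the phenotype
segregation of its selfed (or tester-outcrossed) M3 offspring.  The same
counts, pooled over a family, decide the mode of inheritance: recessive,
dominant, or semi-dominant with homozygous lethality.  Allelism
(complementation) crosses between independent mutants are evaluated against
the Mendelian expectation implied by the parents' zygosities.

Statistical convention: segregation ratios are tested with the two-sided
exact binomial test (minimum-likelihood convention); the heterozygous vs
homozygous-wild-type decision for parents with zero mutant offspring uses
the one-sided probability P(zero mutants | het) = (1 - q)^n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from scipy import stats

from .core import ValidationError

DEFAULT_ALPHA = 0.05

#: Expected mutant fraction among germinated selfed offspring of a
#: semi-dominant homozygous-lethal heterozygote: the 1:2:1 zygote ratio loses
#: its lethal dosage-2 class, leaving 2 het (mutant) : 1 hom wild-type.
LETHAL_SELFED_MUTANT_FRACTION = 2.0 / 3.0


class InheritanceMode(str, Enum):
    RECESSIVE = "recessive"
    DOMINANT = "dominant"
    SEMIDOMINANT_LETHAL = "semidominant_homozygous_lethal"


@dataclass(frozen=True)
class InheritanceModel:
    """Maps mutant-allele dosage (0/1/2) to phenotype under a mode."""

    mode: InheritanceMode

    @property
    def phenotype_map(self) -> dict[int, str]:
        if self.mode is InheritanceMode.RECESSIVE:
            return {0: "wildtype", 1: "wildtype", 2: "mutant"}
        if self.mode is InheritanceMode.DOMINANT:
            return {0: "wildtype", 1: "mutant", 2: "mutant"}
        return {0: "wildtype", 1: "mutant", 2: "inviable"}

    def phenotype(self, dosage: int) -> str:
        return self.phenotype_map[dosage]

    def selfed_mutant_fraction(self, parent_state: str) -> float:
        """Expected mutant fraction among viable selfed offspring."""
        mode = self.mode
        if parent_state == "hom_wt":
            return 0.0
        if mode is InheritanceMode.RECESSIVE:
            return {"het": 0.25, "hom_mut": 1.0}[parent_state]
        if mode is InheritanceMode.DOMINANT:
            return {"het": 0.75, "hom_mut": 1.0}[parent_state]
        if parent_state == "hom_mut":
            raise ValidationError("homozygous mutants are inviable under the lethal model")
        return LETHAL_SELFED_MUTANT_FRACTION

    def outcross_mutant_fraction(self, parent_state: str) -> float:
        """Expected mutant fraction in offspring of a cross to a wild-type tester."""
        mode = self.mode
        if parent_state == "hom_wt":
            return 0.0
        if mode is InheritanceMode.RECESSIVE:
            return 0.0  # offspring are at most heterozygous
        return {"het": 0.5, "hom_mut": 1.0}[parent_state]


RECESSIVE = InheritanceModel(InheritanceMode.RECESSIVE)
DOMINANT = InheritanceModel(InheritanceMode.DOMINANT)
SEMIDOMINANT_LETHAL = InheritanceModel(InheritanceMode.SEMIDOMINANT_LETHAL)

MODELS = {m.mode.value: m for m in (RECESSIVE, DOMINANT, SEMIDOMINANT_LETHAL)}


@dataclass(frozen=True)
class ProgenyRecord:
    """M3 phenotype segregation counts for one M2 parent."""

    parent_id: str
    pollination: str  # "selfed" or a tester/outcross label
    n_mutant: int
    n_wildtype: int
    n_germinated: int
    n_planted: int
    parent_phenotype: str = "unknown"

    def __post_init__(self) -> None:
        counts = (self.n_mutant, self.n_wildtype, self.n_germinated, self.n_planted)
        if any(c < 0 for c in counts):
            raise ValidationError(f"{self.parent_id}: negative progeny counts {counts}")
        if self.n_mutant + self.n_wildtype > self.n_germinated:
            raise ValidationError(
                f"{self.parent_id}: phenotyped offspring ({self.n_mutant}+{self.n_wildtype}) "
                f"exceed germinated count {self.n_germinated}"
            )
        if self.n_germinated > self.n_planted:
            raise ValidationError(
                f"{self.parent_id}: germinated {self.n_germinated} > planted {self.n_planted}"
            )

    @property
    def selfed(self) -> bool:
        return self.pollination.strip().lower() == "selfed"

    @property
    def n_classified(self) -> int:
        return self.n_mutant + self.n_wildtype

    @property
    def germination_rate(self) -> float:
        return self.n_germinated / self.n_planted if self.n_planted else float("nan")


@dataclass
class ZygosityCall:
    """Inferred zygosity of one M2 parent with the rule that fired."""

    parent_id: str
    state: str  # hom_mut | het | hom_wt | unknown
    rule: str
    p_value: float = float("nan")
    n_informative: int = 0
    conflict: bool = False


# ---------------------------------------------------------------------------
# Segregation test
# ---------------------------------------------------------------------------

def segregation_test(
    n_mutant: int,
    n_total: int,
    expected_mutant_fraction: float,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[float, bool | None]:
    """Two-sided exact binomial test of an observed segregation ratio.

    Returns ``(p_value, consistent)`` where ``consistent`` is True when the
    counts do not reject the expected fraction at level ``alpha``.  With zero
    classified offspring the outcome is unknowable and ``(nan, None)`` is
    returned.  Degenerate expectations (0 or 1) are handled exactly.
    """
    if not 0 <= n_mutant <= n_total:
        raise ValidationError(f"need 0 <= n_mutant <= n_total, got {n_mutant}/{n_total}")
    if not 0.0 <= expected_mutant_fraction <= 1.0:
        raise ValidationError(f"expected fraction must lie in [0,1], got {expected_mutant_fraction}")
    if n_total == 0:
        return float("nan"), None
    if expected_mutant_fraction in (0.0, 1.0):
        forced = 0 if expected_mutant_fraction == 0.0 else n_total
        p = 1.0 if n_mutant == forced else 0.0
        return p, p >= alpha
    p = stats.binomtest(n_mutant, n_total, expected_mutant_fraction).pvalue
    return p, p >= alpha


def zero_mutant_probability(n: int, expected_mutant_fraction: float) -> float:
    """P(no mutant among n offspring | the parent segregates at q)."""
    return (1.0 - expected_mutant_fraction) ** n


# ---------------------------------------------------------------------------
# Per-parent zygosity classification
# ---------------------------------------------------------------------------

def classify_parent_zygosity(
    record: ProgenyRecord,
    model: InheritanceModel,
    alpha: float = DEFAULT_ALPHA,
    lethal_selfed_fraction: float = LETHAL_SELFED_MUTANT_FRACTION,
) -> ZygosityCall:
    """Infer a parent's zygosity from its progeny counts under a model.

    Phenotype-forced states (a recessive mutant must be homozygous mutant; a
    lethal-model mutant must be heterozygous) are assigned without a test.
    Otherwise the decision is between heterozygous (segregation consistent
    with the Mendelian expectation) and homozygous wild-type (zero mutants,
    with enough offspring that a heterozygote would almost surely have shown
    some).
    """
    n = record.n_classified
    pid = record.parent_id
    mode = model.mode

    if record.parent_phenotype == "mutant":
        if mode is InheritanceMode.RECESSIVE:
            conflict = record.selfed and record.n_wildtype > 0
            return ZygosityCall(pid, "hom_mut", "phenotype_forced", n_informative=n, conflict=conflict)
        if mode is InheritanceMode.SEMIDOMINANT_LETHAL:
            # homozygotes are inviable, so a living mutant is heterozygous
            q = lethal_selfed_fraction if record.selfed else 0.5
            conflict = n > 0 and record.n_mutant == 0 and zero_mutant_probability(n, q) < alpha
            return ZygosityCall(pid, "het", "lethality_forced", n_informative=n, conflict=conflict)
        # dominant: mutant parent is het or hom_mut
        q = 0.75 if record.selfed else 0.5
        if n == 0:
            return ZygosityCall(pid, "unknown", "no_offspring")
        if record.n_wildtype > 0:
            p, ok = segregation_test(record.n_mutant, n, q, alpha)
            if ok:
                return ZygosityCall(pid, "het", f"segregation_{q:g}", p, n)
            return ZygosityCall(pid, "unknown", "segregation_inconsistent", p, n, conflict=True)
        p0 = zero_mutant_probability(n, 1.0 - q)  # P(no wild-type | het)
        if p0 < alpha:
            return ZygosityCall(pid, "hom_mut", "all_mutant_offspring", p0, n)
        return ZygosityCall(pid, "unknown", "too_few_offspring", p0, n)

    # wild-type parent ------------------------------------------------------
    if mode is InheritanceMode.DOMINANT:
        conflict = record.selfed and record.n_mutant > 0
        return ZygosityCall(pid, "hom_wt", "phenotype_forced", n_informative=n, conflict=conflict)
    if mode is InheritanceMode.SEMIDOMINANT_LETHAL:
        conflict = record.n_mutant > 0
        if record.selfed and n > 0 and record.n_mutant == 0:
            p0 = zero_mutant_probability(n, lethal_selfed_fraction)
            if p0 < alpha:
                return ZygosityCall(pid, "hom_wt", "zero_mutant_offspring", p0, n)
        return ZygosityCall(pid, "hom_wt", "phenotype_forced", n_informative=n, conflict=conflict)

    # recessive wild-type parent: het vs hom_wt
    if not record.selfed:
        # outcross to a wild-type tester yields wild-type offspring either way
        return ZygosityCall(pid, "unknown", "outcross_uninformative", n_informative=n)
    if n == 0:
        return ZygosityCall(pid, "unknown", "no_offspring")
    if record.n_mutant > 0:
        p, ok = segregation_test(record.n_mutant, n, 0.25, alpha)
        if ok:
            return ZygosityCall(pid, "het", "segregation_0.25", p, n)
        return ZygosityCall(pid, "unknown", "segregation_inconsistent", p, n, conflict=True)
    p0 = zero_mutant_probability(n, 0.25)
    if p0 < alpha:
        return ZygosityCall(pid, "hom_wt", "zero_mutant_offspring", p0, n)
    return ZygosityCall(pid, "unknown", "too_few_offspring", p0, n)


# ---------------------------------------------------------------------------
# Inheritance-model inference
# ---------------------------------------------------------------------------

class InferenceError(ValidationError):
    """Raised when progeny records are uninformative or contradictory."""


@dataclass
class InheritanceInference:
    model: InheritanceModel
    evidence: list[str] = field(default_factory=list)


def infer_inheritance(
    records: Sequence[ProgenyRecord],
    alpha: float = DEFAULT_ALPHA,
) -> InheritanceInference:
    """Decide recessive / dominant / semi-dominant-lethal from family records.

    Rule cascade:

    1. a mutant parent outcrossed to a wild-type tester producing only
       wild-type offspring, or a wild-type parent whose selfed offspring
       segregate mutants, proves recessiveness;
    2. a mutant parent whose selfed offspring segregate both phenotypes
       proves the mutant parents are heterozygous, hence dominance;
    3. under dominance, absence of any all-mutant selfed progeny set
       (no viable homozygote observed) combined with depressed germination of
       mutant-parent offspring indicates homozygous lethality.

    Contradictory evidence (1 and 2 both firing) raises
    :class:`InferenceError` listing the records involved.
    """
    if not records:
        raise InferenceError("no progeny records given")
    evidence: list[str] = []
    recessive_ids: list[str] = []
    dominant_ids: list[str] = []
    all_mutant_hom_ids: list[str] = []
    weak_dominant = False

    for r in records:
        if r.parent_phenotype == "mutant":
            if not r.selfed:
                if r.n_classified > 0 and r.n_mutant == 0 and zero_mutant_probability(r.n_classified, 0.5) < alpha:
                    recessive_ids.append(r.parent_id)
                    evidence.append(
                        f"{r.parent_id}: mutant x wild-type tester gave 0/{r.n_classified} "
                        "mutant offspring -> recessive"
                    )
            else:
                if r.n_mutant > 0 and r.n_wildtype > 0:
                    dominant_ids.append(r.parent_id)
                    evidence.append(
                        f"{r.parent_id}: selfed mutant segregated "
                        f"{r.n_mutant}:{r.n_wildtype} -> mutant parent heterozygous -> dominant"
                    )
                elif r.n_wildtype == 0 and r.n_classified > 0:
                    if zero_mutant_probability(r.n_classified, 0.25) < alpha:
                        # too many offspring for a segregating het to have shown no wild-type
                        all_mutant_hom_ids.append(r.parent_id)
        else:  # wild-type parent
            if r.selfed and r.n_mutant > 0:
                recessive_ids.append(r.parent_id)
                evidence.append(
                    f"{r.parent_id}: selfed wild-type parent segregated "
                    f"{r.n_mutant}:{r.n_wildtype} mutants -> recessive"
                )

    if recessive_ids and dominant_ids:
        raise InferenceError(
            "contradictory segregation evidence: recessive from "
            f"{recessive_ids}, dominant from {dominant_ids}"
        )

    if recessive_ids:
        evidence.append("conclusion: recessive")
        return InheritanceInference(RECESSIVE, evidence)

    if not dominant_ids and all_mutant_hom_ids:
        # all-mutant selfed progeny with no wild-type-parent segregation:
        # a homozygous viable carrier of a dominant allele
        wt_all_wt = [
            r.parent_id
            for r in records
            if r.parent_phenotype == "wildtype" and r.selfed and r.n_classified > 0 and r.n_mutant == 0
        ]
        if wt_all_wt:
            weak_dominant = True
            evidence.append(
                f"{all_mutant_hom_ids}: all-mutant selfed offspring with non-segregating "
                f"wild-type siblings {wt_all_wt} -> dominant (homozygote viable)"
            )

    if dominant_ids or weak_dominant:
        if all_mutant_hom_ids:
            evidence.append(
                f"conclusion: dominant, fully viable (all-mutant selfed sets from {all_mutant_hom_ids})"
            )
            return InheritanceInference(DOMINANT, evidence)
        if _germination_depressed(records, alpha):
            evidence.append(
                "no all-mutant selfed progeny and depressed germination of mutant-parent "
                "offspring -> semi-dominant, homozygous lethal"
            )
            return InheritanceInference(SEMIDOMINANT_LETHAL, evidence)
        evidence.append("conclusion: dominant")
        return InheritanceInference(DOMINANT, evidence)

    raise InferenceError("progeny records are uninformative about the mode of inheritance")


def _germination_depressed(records: Sequence[ProgenyRecord], alpha: float) -> bool:
    """One-sided Fisher test: mutant-parent seed germinates worse than wild-type-parent seed."""
    gm = fm = gw = fw = 0
    for r in records:
        if not r.selfed or r.n_planted == 0:
            continue
        if r.parent_phenotype == "mutant":
            gm += r.n_germinated
            fm += r.n_planted - r.n_germinated
        elif r.parent_phenotype == "wildtype":
            gw += r.n_germinated
            fw += r.n_planted - r.n_germinated
    if (gm + fm) == 0 or (gw + fw) == 0:
        return False
    _, p = stats.fisher_exact([[gm, fm], [gw, fw]], alternative="less")
    return p < alpha


# ---------------------------------------------------------------------------
# Allelism (complementation) tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossRecord:
    """One complementation cross with its offspring phenotype counts."""

    female: str
    male: str
    n_mutant: int
    n_wildtype: int

    def __post_init__(self) -> None:
        if self.n_mutant < 0 or self.n_wildtype < 0:
            raise ValidationError("cross counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_mutant + self.n_wildtype


def allelism_expected_fraction(
    female_state: str,
    male_state: str,
    hypothesis: str,
    dominant_parent_state: str | None = None,
) -> float:
    """Expected mutant fraction in an allelism cross.

    Both loci recessive: allelic hom x hom -> 1, hom x het -> 1/2,
    het x het -> 1/4, anything x hom_wt -> 0; non-allelic -> 0.  When one
    crossing partner carries a dominant allele (a dominance control cross),
    a heterozygous carrier transmits the mutant phenotype to half the
    offspring and a homozygous wild-type carrier to none, regardless of the
    other parent.
    """
    valid = {"hom_mut", "het", "hom_wt"}
    if female_state not in valid or male_state not in valid:
        raise ValidationError(f"unsupported zygosity combination ({female_state}, {male_state})")
    if dominant_parent_state is not None:
        return {"het": 0.5, "hom_mut": 1.0, "hom_wt": 0.0}[dominant_parent_state]
    if hypothesis == "non_allelic":
        return 0.0
    if hypothesis != "allelic":
        raise ValidationError(f"unknown hypothesis {hypothesis!r}")
    if "hom_wt" in (female_state, male_state):
        return 0.0
    n_hom = [female_state, male_state].count("hom_mut")
    return {2: 1.0, 1: 0.5, 0: 0.25}[n_hom]


def allelism_test(
    cross: CrossRecord,
    female_state: str,
    male_state: str,
    hypothesis: str,
    alpha: float = DEFAULT_ALPHA,
    dominant_parent_state: str | None = None,
) -> tuple[float, float, bool | None]:
    """Test a complementation cross against a hypothesis.

    Returns ``(expected_mutant_fraction, p_value, consistent)``.
    """
    q = allelism_expected_fraction(female_state, male_state, hypothesis, dominant_parent_state)
    p, ok = segregation_test(cross.n_mutant, cross.n_total, q, alpha)
    return q, p, ok
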