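"""Shared fixtures: the published study tables and small simulated scenarios."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from zygomap.core import Individual
from zygomap.segregation import CrossRecord, ProgenyRecord
from zygomap.simulate import SimConfig, dwarf_preset, generate_scenario


# M3 segregation counts of the two published maize families
# (parent_id, pollination, n_mutant, n_wildtype, n_germinated, n_planted, parent_phenotype)
PALE_GREEN_ROWS = [
    ("1754_5_pg", "selfed", 21, 11, 32, 40, "mutant"),
    ("1754_40_pg", "selfed", 3, 3, 6, 35, "mutant"),
    ("1754_46_pg", "selfed", 11, 9, 20, 40, "mutant"),
    ("1754_49_pg", "selfed", 4, 1, 5, 21, "mutant"),
    ("1754_50_pg", "selfed", 1, 0, 1, 2, "mutant"),
    ("1754_53_pg", "selfed", 2, 2, 4, 16, "mutant"),
    ("1754_63_pg", "selfed", 8, 8, 16, 31, "mutant"),
    ("1754_48_PG", "selfed", 0, 33, 33, 40, "wildtype"),
    ("1754_52_PG", "selfed", 0, 40, 40, 40, "wildtype"),
    ("1754_54_PG", "selfed", 0, 40, 40, 40, "wildtype"),
    ("1754_55_PG", "selfed", 0, 39, 39, 40, "wildtype"),
    ("1754_56_PG", "selfed", 0, 38, 38, 40, "wildtype"),
    ("1754_58_PG", "selfed", 0, 39, 39, 40, "wildtype"),
    ("1754_60_PG", "selfed", 0, 39, 39, 40, "wildtype"),
]

DWARF_ROWS = [
    ("1744_10_dw", "B73", 0, 22, 22, 22, "mutant"),
    ("1744_23_dw", "selfed", 1, 0, 1, 1, "mutant"),
    ("1744_28_dw", "B73", 0, 7, 7, 7, "mutant"),
    ("1744_5_DW", "selfed", 12, 28, 42, 42, "wildtype"),
    ("1744_11_DW", "selfed", 10, 29, 40, 40, "wildtype"),
    ("1744_13_DW", "selfed", 9, 31, 40, 40, "wildtype"),
    ("1744_16_DW", "B73", 0, 38, 40, 40, "wildtype"),
    ("1744_21_DW", "selfed", 0, 39, 40, 40, "wildtype"),
    ("1744_25_DW", "selfed", 10, 30, 40, 40, "wildtype"),
    ("1744_27_DW", "selfed", 12, 28, 42, 42, "wildtype"),
]

# allelism crosses of the dwarf mutant against public an1 and D8 stocks:
# (female, male, n_mutant, n_wildtype, female_state, male_state, hypothesis,
#  dominant_parent_state)
ALLELISM_ROWS = [
    ("dwarf", "116G_DWARF", 25, 23, "hom_mut", "het", "allelic", None),
    ("dwarf", "116G_dwarf", 41, 0, "hom_mut", "hom_mut", "allelic", None),
    ("DWARF", "116G_DWARF", 15, 33, "het", "het", "allelic", None),
    ("DWARF", "116GA_DWARF", 11, 39, "het", "het", "allelic", None),
    ("dwarf", "116GA_DWARF", 24, 26, "hom_mut", "het", "allelic", None),
    ("116GA_dwarf", "dwarf", 35, 0, "hom_mut", "hom_mut", "allelic", None),
    ("116G_dwarf", "dwarf", 48, 0, "hom_mut", "hom_mut", "allelic", None),
    ("116G_DWARF", "dwarf", 20, 24, "het", "hom_mut", "allelic", None),
    ("dwarf", "116G_DWARF", 0, 48, "hom_mut", "hom_wt", "allelic", None),
    ("DWARF", "116G_DWARF", 0, 50, "het", "hom_wt", "allelic", None),
    ("dwarf", "121C_D8_DWARF", 0, 40, "hom_mut", "hom_wt", "non_allelic", "hom_wt"),
    ("DWARF", "131E_D8_dwarf", 18, 22, "het", "het", "non_allelic", "het"),
    ("DWARF", "131E_D8_DWARF", 0, 40, "het", "hom_wt", "non_allelic", "hom_wt"),
    ("dwarf", "131E_D8_dwarf", 17, 23, "hom_mut", "het", "non_allelic", "het"),
    ("dwarf", "131F_D8_dwarf", 18, 12, "hom_mut", "het", "non_allelic", "het"),
    ("DWARF", "131F_D8_DWARF", 0, 30, "het", "hom_wt", "non_allelic", "hom_wt"),
]


@pytest.fixture(scope="session")
def pale_green_records() -> list[ProgenyRecord]:
    return [ProgenyRecord(*row) for row in PALE_GREEN_ROWS]


@pytest.fixture(scope="session")
def dwarf_records() -> list[ProgenyRecord]:
    return [ProgenyRecord(*row) for row in DWARF_ROWS]


@pytest.fixture(scope="session")
def allelism_crosses() -> list[tuple]:
    return [
        (CrossRecord(f, m, nm, nw), fs, ms, hyp, dom)
        for f, m, nm, nw, fs, ms, hyp, dom in ALLELISM_ROWS
    ]


def study_individuals() -> list[Individual]:
    """The 32-plant sequencing design: 7 dwarf, 9 DWARF, 8 pale green, 8 PALE GREEN."""
    inds = []
    for k in range(7):
        inds.append(Individual(f"1744_m{k}", "1744", "M2", "mutant"))
    for k in range(9):
        inds.append(Individual(f"1744_w{k}", "1744", "M2", "wildtype"))
    for k in range(8):
        inds.append(Individual(f"1754_m{k}", "1754", "M2", "mutant"))
    for k in range(8):
        inds.append(Individual(f"1754_w{k}", "1754", "M2", "wildtype"))
    return inds


@pytest.fixture(scope="session")
def thirty_two_plants() -> list[Individual]:
    return study_individuals()


@pytest.fixture(scope="session")
def small_scenario():
    """Down-scaled recessive family with noisy calls (fast, deterministic)."""
    cfg = dataclasses.replace(
        dwarf_preset(42), n_induced_snps=120, n_background_variants=30, m2_pool_size=60
    )
    return generate_scenario(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
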