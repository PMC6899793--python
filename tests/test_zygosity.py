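"""The zygosity-pattern filter: pattern building, matching, deduction."""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pytest

from zygomap.core import MISSING, GenotypeMatrix, Individual, VariantSite
from zygomap.segregation import RECESSIVE, SEMIDOMINANT_LETHAL, ZygosityCall
from zygomap.zygosity import (
    FULL_SET,
    PatternConflictError,
    STATE_DOSAGE,
    ZygosityPattern,
    apply_zygosity_filter,
    build_pattern,
    candidate_report,
    deduce_unknown_zygosity,
    expected_group_frequency,
    pattern_allele_counts,
)


def dwarf_family():
    """7 mutants; 5 proved het + 1 proved hom_wt + 3 unknown wild-types."""
    inds = [Individual(f"m{j}", "1744", "M2", "mutant") for j in range(7)]
    inds += [Individual(f"w{j}", "1744", "M2", "wildtype") for j in range(9)]
    calls = {f"w{j}": ZygosityCall(f"w{j}", "het", "segregation_0.25") for j in range(5)}
    calls["w5"] = ZygosityCall("w5", "hom_wt", "zero_mutant_offspring")
    return inds, calls


def matrix_for(inds, dosage_rows):
    dosage = np.asarray(dosage_rows, dtype=np.int8)
    sites = [VariantSite("1", 1000 + i, "G", "A") for i in range(dosage.shape[0])]
    return GenotypeMatrix(
        sites=sites,
        individuals=inds,
        dosage=dosage,
        depth=np.full_like(dosage, 30, dtype=np.int32),
        quality=np.full(dosage.shape, 99.0, dtype=np.float32),
    )


class TestBuildPattern:
    def test_dwarf_design_pattern(self):
        inds, calls = dwarf_family()
        pat = build_pattern(inds, RECESSIVE, calls)
        for j in range(7):
            assert pat.allowed[f"m{j}"] == frozenset({2})
        for j in range(5):
            assert pat.allowed[f"w{j}"] == frozenset({1})
            assert pat.provenance[f"w{j}"] == "progeny_test"
        assert pat.allowed["w5"] == frozenset({0})
        for j in (6, 7, 8):
            assert pat.allowed[f"w{j}"] == frozenset({0, 1})
            assert pat.provenance[f"w{j}"] == "phenotype_forced"

    def test_lethal_design_pattern_fully_determined_by_phenotype(self):
        inds = [Individual(f"m{j}", "1754", "M2", "mutant") for j in range(8)]
        inds += [Individual(f"w{j}", "1754", "M2", "wildtype") for j in range(8)]
        pat = build_pattern(inds, SEMIDOMINANT_LETHAL, {})
        assert all(pat.allowed[f"m{j}"] == frozenset({1}) for j in range(8))
        assert all(pat.allowed[f"w{j}"] == frozenset({0}) for j in range(8))

    def test_no_progeny_recessive_falls_back_to_phenotype(self):
        inds = [Individual("m0", "F", "M2", "mutant"), Individual("w0", "F", "M2", "wildtype")]
        pat = build_pattern(inds, RECESSIVE, {})
        assert pat.allowed["m0"] == frozenset({2})
        assert pat.allowed["w0"] == frozenset({0, 1})

    def test_progeny_state_contradicting_phenotype_raises(self):
        inds = [Individual("m0", "F", "M2", "mutant")]
        calls = {"m0": ZygosityCall("m0", "het", "segregation_0.25")}
        with pytest.raises(PatternConflictError):
            build_pattern(inds, RECESSIVE, calls)


class TestApplyFilter:
    def test_exact_pattern_match_and_single_violation(self):
        inds, calls = dwarf_family()
        pat = build_pattern(inds, RECESSIVE, calls)
        # columns follow the pattern: 7 hom-mut mutants, 5 proved-het +
        # 1 proved-hom-wt wild-types, then 3 unconstrained wild-types
        good = [2] * 7 + [1] * 5 + [0] + [1, 1, 0]
        bad = list(good)
        bad[0] = 1  # one mutant heterozygous: cannot carry a recessive causal SNP
        m = matrix_for(inds, [good, bad])
        cs = apply_zygosity_filter(m, pat)
        assert [s.pos for s in cs.matrix.sites] == [1000]
        assert cs.mismatch_log["violating_individuals"].tolist() == ["m0"]

    def test_matches_brute_force_over_random_sites(self, rng):
        inds, calls = dwarf_family()
        pat = build_pattern(inds, RECESSIVE, calls)
        dosage = rng.choice([MISSING, 0, 1, 2], size=(60, 16), p=[0.05, 0.3, 0.35, 0.3])
        m = matrix_for(inds, dosage)
        cs = apply_zygosity_filter(m, pat)
        expected = []
        for i in range(60):
            ok = all(
                d == MISSING or int(d) in pat.allowed[ind.id]
                for d, ind in zip(dosage[i], inds)
            )
            if ok:
                expected.append(1000 + i)
        assert [s.pos for s in cs.matrix.sites] == expected

    def test_missing_policies(self):
        inds, calls = dwarf_family()
        pat = build_pattern(inds, RECESSIVE, calls)
        row = [2] * 7 + [1] * 5 + [0] + [1, 1, 0]
        row[3] = MISSING  # dropout in a constrained mutant
        m = matrix_for(inds, [row])
        lenient = apply_zygosity_filter(m, pat, "lenient")
        assert lenient.n_candidates == 1
        assert lenient.informativeness[0] == 15
        strict = apply_zygosity_filter(m, pat, "strict")
        assert strict.n_candidates == 0

    def test_tightening_monotonicity(self, rng):
        """Shrinking any individual's allowed set never grows the passing set."""
        inds, calls = dwarf_family()
        pat = build_pattern(inds, RECESSIVE, calls)
        dosage = rng.choice([0, 1, 2], size=(200, 16), p=[0.3, 0.4, 0.3])
        m = matrix_for(inds, dosage)
        base = {s.pos for s in apply_zygosity_filter(m, pat).matrix.sites}
        for iid in ("w6", "w7", "w8"):
            for state in ("het", "hom_wt"):
                tighter = pat.with_state(iid, state)
                got = {s.pos for s in apply_zygosity_filter(m, tighter).matrix.sites}
                assert got <= base


class TestDeduction:
    def test_unanimous_dosage_assigns_state(self):
        inds, calls = dwarf_family()
        pat = build_pattern(inds, RECESSIVE, calls)
        # three passing sites all showing w6,w7 het and w8 hom-wt
        rows = [[2] * 7 + [1] * 5 + [0] + [1, 1, 0] for _ in range(3)]
        m = matrix_for(inds, rows)
        cs = apply_zygosity_filter(m, pat)
        new_pat, deduced, warn = deduce_unknown_zygosity(cs, pat)
        assert deduced == {"w6": "het", "w7": "het", "w8": "hom_wt"}
        assert not warn
        assert new_pat.allowed["w8"] == frozenset({0})

    def test_disagreement_leaves_unknown_with_warning(self):
        inds, calls = dwarf_family()
        pat = build_pattern(inds, RECESSIVE, calls)
        rows = [
            [2] * 7 + [1] * 5 + [0] + [1, 1, 0],
            [2] * 7 + [1] * 5 + [0] + [0, 1, 0],  # w6 disagrees between sites
        ]
        m = matrix_for(inds, rows)
        cs = apply_zygosity_filter(m, pat)
        _, deduced, warn = deduce_unknown_zygosity(cs, pat)
        assert "w6" not in deduced
        assert any("w6" in w for w in warn)

    def test_deduction_is_a_fixed_point(self, rng):
        inds, calls = dwarf_family()
        pat = build_pattern(inds, RECESSIVE, calls)
        dosage = rng.choice([0, 1, 2], size=(300, 16), p=[0.25, 0.5, 0.25])
        dosage[0] = [2] * 7 + [1] * 5 + [0] + [1, 1, 0]  # guarantee one passing site
        m = matrix_for(inds, dosage)
        cs = apply_zygosity_filter(m, pat)
        new_pat, deduced, _ = deduce_unknown_zygosity(cs, pat)
        again = apply_zygosity_filter(m, new_pat)
        assert [s.pos for s in again.matrix.sites] == [s.pos for s in cs.matrix.sites]


class TestAlleleAccounting:
    def test_table_style_counts_for_both_designs(self, thirty_two_plants):
        # pale-green family: 8 het mutants, 8 hom-wt wild-types
        pg_states = {f"1754_m{j}": "het" for j in range(8)}
        pg_states.update({f"1754_w{j}": "hom_wt" for j in range(8)})
        pg = pattern_allele_counts(thirty_two_plants, "1754", pg_states)
        assert pg == {
            "total_alleles": 64,
            "ref_alleles": 56,
            "mut_alleles_mutant_group": 8,
            "mut_alleles_wildtype_group": 0,
        }
        # dwarf family: 7 hom mutants, 7 het + 2 hom-wt wild-types
        dw_states = {f"1744_m{j}": "hom_mut" for j in range(7)}
        dw_states.update({f"1744_w{j}": "het" for j in range(7)})
        dw_states.update({f"1744_w{j}": "hom_wt" for j in (7, 8)})
        dw = pattern_allele_counts(thirty_two_plants, "1744", dw_states)
        assert dw == {
            "total_alleles": 64,
            "ref_alleles": 43,
            "mut_alleles_mutant_group": 14,
            "mut_alleles_wildtype_group": 7,
        }

    def test_all_hom_wt_pattern_counts_no_mutant_alleles(self):
        inds = [Individual(f"w{j}", "F", "M2", "wildtype") for j in range(4)]
        counts = pattern_allele_counts(inds, "F", {f"w{j}": "hom_wt" for j in range(4)})
        assert counts["mut_alleles_mutant_group"] == 0
        assert counts["mut_alleles_wildtype_group"] == 0
        assert counts["ref_alleles"] == counts["total_alleles"]

    def test_expected_group_frequency(self):
        assert expected_group_frequency(["het"] * 7 + ["hom_wt"] * 2) == pytest.approx(7 / 18)
        assert expected_group_frequency(["het"] * 8) == pytest.approx(0.5)
        assert expected_group_frequency(["hom_mut"] * 7) == pytest.approx(1.0)

    def test_candidate_report_sorted_and_annotated(self):
        inds, calls = dwarf_family()
        pat = build_pattern(inds, RECESSIVE, calls)
        rows = [[2] * 7 + [1] * 5 + [0] + [1, 1, 0]] * 2
        m = matrix_for(inds, rows)
        m.sites[0] = VariantSite("2", 50, "G", "A")   # transition
        m.sites[1] = VariantSite("1", 99, "C", "A")   # transversion
        cs = apply_zygosity_filter(m, pat)
        rep = candidate_report(cs)
        assert rep["chrom"].tolist() == ["1", "2"]
        assert rep["is_transition"].tolist() == [False, True]
        assert rep["base_exchange"].tolist() == ["C/A", "G/A"]
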