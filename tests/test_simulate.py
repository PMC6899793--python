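"""Forward pedigree simulator: meiosis, Mendelian ratios, call noise,
scenario determinism."""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pytest
from scipy import stats

from zygomap.core import MISSING, ValidationError
from zygomap.segregation import DOMINANT, RECESSIVE, SEMIDOMINANT_LETHAL
from zygomap.simulate import (
    Chromosome,
    GeneticMap,
    SimConfig,
    dwarf_preset,
    generate_scenario,
    matrix_from_truth,
    meiosis,
    pale_green_preset,
    sample_sequenced_set,
    self_to_m2,
    simulate_calls,
    simulate_m1,
    simulate_m3,
)


@pytest.fixture(scope="module")
def gmap():
    return GeneticMap.default_maize()


class TestGeneticMap:
    def test_default_totals(self, gmap):
        assert gmap.n_chromosomes == 10
        assert gmap.total_cm == pytest.approx(2200.0)
        assert gmap.total_bp == 2_300_000_000

    def test_position_mapping_is_monotone_linear(self, gmap):
        cms = [10.0, 50.0, 219.0]
        bps = [gmap.cm_to_bp(0, c) for c in cms]
        assert bps == sorted(bps)
        assert gmap.bp_to_cm(0, bps[1]) == pytest.approx(50.0, rel=1e-6)


class TestSimulateM1:
    def test_exact_induced_count_and_forced_causal(self, gmap, rng):
        cfg = SimConfig(n_induced_snps=137, n_background_variants=25)
        g = simulate_m1(cfg, gmap, rng)
        assert int(g.induced.sum()) == 137
        assert g.n_sites == 137 + 25
        assert bool(g.induced[g.causal_index])
        # induced on one haplotype only; background homozygous
        assert (g.hap_a[g.induced] == 1).all() and (g.hap_b[g.induced] == 0).all()
        assert (g.hap_a[~g.induced] == 1).all() and (g.hap_b[~g.induced] == 1).all()

    def test_pure_transition_spectrum(self, gmap, rng):
        cfg = SimConfig(n_induced_snps=150, n_background_variants=0, transition_fraction=1.0)
        g = simulate_m1(cfg, gmap, rng)
        assert all(s.is_transition for s in g.sites)
        assert {s.base_exchange for s in g.sites} <= {"G/A", "C/T"}

    def test_zero_requested_still_forces_causal(self, gmap, rng):
        cfg = SimConfig(n_induced_snps=0, n_background_variants=0)
        g = simulate_m1(cfg, gmap, rng)
        assert g.n_sites == 1 and g.causal_index == 0

    def test_positions_unique_and_sorted(self, gmap, rng):
        cfg = SimConfig(n_induced_snps=500, n_background_variants=100)
        g = simulate_m1(cfg, gmap, rng)
        keys = [(s.chrom, s.pos) for s in g.sites]
        assert len(set(keys)) == len(keys)
        for sl in g.chrom_slices:
            pos = [g.sites[i].pos for i in range(sl.start, sl.stop)]
            assert pos == sorted(pos)


class TestMeiosis:
    def test_poisson_crossover_rate_via_recombinant_fraction(self, rng):
        """Two sites 1 cM apart recombine at the Haldane fraction
        (1 - exp(-0.02)) / 2 ~ 0.0099."""
        gm = GeneticMap([Chromosome("1", 1_000_000, 100.0)])
        cfg = SimConfig(n_induced_snps=2, n_background_variants=0, causal_cm=50.0)
        g = simulate_m1(cfg, gm, rng)
        g.pos_cm = np.array([50.0, 51.0])
        n = 40_000
        rec = 0
        for _ in range(n):
            gam = meiosis(g.hap_a, g.hap_b, g, gm, rng)
            rec += gam[0] != gam[1]
        expected = (1 - np.exp(-0.02)) / 2
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(rec / n - expected) <= 3 * se

    def test_zero_cm_chromosome_never_recombines(self, rng):
        gm = GeneticMap([Chromosome("1", 1_000_000, 0.0)])
        cfg = SimConfig(n_induced_snps=5, n_background_variants=0, causal_cm=0.0)
        g = simulate_m1(cfg, gm, rng)
        for _ in range(200):
            gam = meiosis(g.hap_a, g.hap_b, g, gm, rng)
            assert gam[g.induced].min() == gam[g.induced].max()


class TestM2AndM3:
    @pytest.mark.parametrize(
        "model,expected_fraction",
        [(RECESSIVE, 0.25), (DOMINANT, 0.75)],
    )
    def test_m2_mutant_fraction(self, gmap, rng, model, expected_fraction):
        cfg = SimConfig(n_induced_snps=5, n_background_variants=0)
        g = simulate_m1(cfg, gmap, rng)
        _, phen = self_to_m2(g, model, 1500, gmap, rng)
        frac = np.mean([p == "mutant" for p in phen])
        se = np.sqrt(expected_fraction * (1 - expected_fraction) / 1500)
        assert abs(frac - expected_fraction) <= 3.5 * se

    def test_lethal_model_excludes_homozygotes(self, gmap, rng):
        cfg = SimConfig(n_induced_snps=5, n_background_variants=0)
        g = simulate_m1(cfg, gmap, rng)
        dos, phen = self_to_m2(g, SEMIDOMINANT_LETHAL, 900, gmap, rng)
        causal = dos[g.causal_index]
        assert (causal != 2).all()
        het = np.mean(causal == 1)
        se = np.sqrt((2 / 3) * (1 / 3) / 900)
        assert abs(het - 2 / 3) <= 3.5 * se

    def test_sampling_design_and_exhaustion(self, rng):
        phen = ["mutant"] * 10 + ["wildtype"] * 20
        idx = sample_sequenced_set(phen, 7, 9, rng)
        assert sum(phen[i] == "mutant" for i in idx) == 7
        assert len(set(idx.tolist())) == 16
        with pytest.raises(ValidationError, match="pool exhausted"):
            sample_sequenced_set(phen, 11, 9, rng)

    def test_m3_hom_wt_parent_has_no_mutant_offspring(self, rng):
        cfg = SimConfig(n_m3_planted=40, germination=1.0)
        for _ in range(20):
            rec = simulate_m3("p", 0, RECESSIVE, cfg, rng)
            assert rec.n_mutant == 0 and rec.n_germinated == 40

    def test_m3_het_recessive_segregates_one_in_four(self, rng):
        cfg = SimConfig(n_m3_planted=40, germination=1.0)
        total_mut = total = 0
        for _ in range(150):
            rec = simulate_m3("p", 1, RECESSIVE, cfg, rng)
            total_mut += rec.n_mutant
            total += rec.n_classified
        se = np.sqrt(0.25 * 0.75 / total)
        assert abs(total_mut / total - 0.25) <= 3.5 * se

    def test_m3_het_lethal_two_thirds_mutant_among_germinated(self, rng):
        cfg = SimConfig(n_m3_planted=40, germination=1.0)
        total_mut = total = 0
        for _ in range(150):
            rec = simulate_m3("p", 1, SEMIDOMINANT_LETHAL, cfg, rng)
            total_mut += rec.n_mutant
            total += rec.n_classified
            assert rec.n_germinated <= 40
        se = np.sqrt((2 / 3) * (1 / 3) / total)
        assert abs(total_mut / total - 2 / 3) <= 3.5 * se


class TestCallModel:
    def test_error_free_deep_calls_equal_truth(self, rng):
        truth = rng.choice([0, 1, 2], size=(60, 8)).astype(np.int8)
        cfg = SimConfig(depth_lambda=400.0, error_rate=0.0)
        called, depth, gq = simulate_calls(truth, cfg, rng)
        assert np.array_equal(called, truth)
        assert (gq[depth > 0] > 0).all()

    def test_low_depth_fraction_matches_poisson_cdf(self, rng):
        truth = np.ones((300, 16), dtype=np.int8)
        cfg = SimConfig(depth_lambda=19.0)
        _, depth, _ = simulate_calls(truth, cfg, rng)
        frac = (depth < 10).mean()
        expected = stats.poisson.cdf(9, 19.0)
        se = np.sqrt(expected * (1 - expected) / depth.size)
        assert abs(frac - expected) <= 3.5 * se

    def test_zero_depth_is_missing(self, rng):
        truth = np.ones((200, 4), dtype=np.int8)
        cfg = SimConfig(depth_lambda=0.5)
        called, depth, _ = simulate_calls(truth, cfg, rng)
        assert (called[depth == 0] == MISSING).all()

    def test_matrix_from_truth_is_exact(self, gmap, rng):
        cfg = SimConfig(n_induced_snps=20, n_background_variants=0)
        g = simulate_m1(cfg, gmap, rng)
        from zygomap.core import Individual

        truth = rng.choice([0, 1, 2], size=(g.n_sites, 3)).astype(np.int8)
        inds = [Individual(f"i{j}", "F", "M2", "wildtype") for j in range(3)]
        m = matrix_from_truth(g, inds, truth)
        assert np.array_equal(m.dosage, truth)
        assert (m.depth >= 10).all() and (m.quality >= 10).all()


class TestScenario:
    def test_fixed_seed_is_byte_identical(self, tmp_path):
        cfg = dataclasses.replace(
            dwarf_preset(9), n_induced_snps=60, n_background_variants=10, m2_pool_size=60
        )
        p1 = generate_scenario(cfg).write(tmp_path / "a")
        p2 = generate_scenario(cfg).write(tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_truth_file_schema(self, small_scenario, tmp_path):
        paths = small_scenario.write(tmp_path)
        truth = json.loads(paths["truth"].read_text())
        assert truth["causal_position"] in truth["induced_positions"]
        assert set(truth["parental_zygosity"]) == set(truth["phenotypes"])
        assert len(truth["true_dosage"]) == small_scenario.matrix.n_sites

    def test_pale_green_preset_structure(self):
        cfg = dataclasses.replace(
            pale_green_preset(4), n_induced_snps=80, n_background_variants=10
        )
        sc = generate_scenario(cfg, noisy_calls=False)
        zyg = sc.truth.parental_zygosity
        phen = sc.truth.phenotypes
        for iid, state in zyg.items():
            assert state == ("het" if phen[iid] == "mutant" else "hom_wt")

    def test_end_to_end_recovery_with_error_free_calls(self):
        from zygomap.pipeline import run_pipeline

        cfg = dataclasses.replace(
            dwarf_preset(21), n_induced_snps=250, n_background_variants=40
        )
        sc = generate_scenario(cfg, noisy_calls=False)
        res = run_pipeline(sc.matrix, cfg.family, progeny=sc.progeny)
        assert res.model.mode.value == "recessive"
        assert sc.truth.causal_position in res.candidates.positions()
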