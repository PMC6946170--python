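"""Meiosis simulation: crossover placement, bivalent structure, chromatid
selection under inheritance modes, the truth classifier, and zygote fate."""

import numpy as np
import pytest

from gynotype import (ChromosomeGenotype, GenomeSpec, MaternalMode,
                      PaternalFate, PaternalFateKind, ZygoteFate,
                      classify_pair_truth, count_dapi_bodies,
                      draw_crossover_position, make_bivalent,
                      select_maternal_chromatids, simulate_zygote, zygote_fate)
from gynotype.genome import ChromosomeSpec
from gynotype.meiosis import zygosity_intervals


def _spec(length=1_000_000, **kw):
    return GenomeSpec(chromosomes=[ChromosomeSpec("c", length)], **kw)


class TestCrossoverPlacement:
    def test_zero_center_probability_confines_crossovers_to_arms(self, rng):
        spec = _spec(p_center_crossover=0.0, arm_fraction=0.2)
        L, arm = 1_000_000, 200_000
        for _ in range(500):
            pos = draw_crossover_position(spec, "c", rng)
            assert pos < arm or pos >= L - arm

    def test_positions_stay_inside_open_interval(self, rng):
        spec = _spec(arm_fraction=0.5)  # arms cover everything
        draws = [draw_crossover_position(spec, "c", rng) for _ in range(2000)]
        assert min(draws) >= 1 and max(draws) <= 999_999

    def test_center_fraction_matches_configured_mixture(self, rng):
        # binomial check: empirical center fraction within 3 SE of p_center
        spec = _spec(arm_fraction=0.3, p_center_crossover=0.1)
        n = 10_000
        L, arm = 1_000_000, 300_000
        hits = sum(arm <= draw_crossover_position(spec, "c", rng) < L - arm
                   for _ in range(n))
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(hits / n - 0.1) < 3 * se

    def test_unknown_chromosome_rejected(self, rng):
        with pytest.raises(KeyError):
            draw_crossover_position(_spec(), "nope", rng)


class TestBivalent:
    def test_structure_and_reciprocity(self, rng):
        spec = _spec()
        for _ in range(20):
            biv = make_bivalent(spec, "c", rng)
            n1, j2 = biv.chromatids["N1"], biv.chromatids["J2"]
            assert n1.blocks == [(0, 1_000_000, "N")]
            assert j2.blocks == [(0, 1_000_000, "J")]
            # N2 and J1 are complementary at every block
            n2, j1 = biv.chromatids["N2"], biv.chromatids["J1"]
            for pos in (0, biv.crossover_pos - 1, biv.crossover_pos, 999_999):
                assert {n2.origin_at(pos), j1.origin_at(pos)} == {"N", "J"}

    def test_origin_conservation(self, rng):
        # total origin-N length across the four chromatids equals 2L
        spec = _spec()
        for _ in range(20):
            biv = make_bivalent(spec, "c", rng)
            total_n = sum(ct.origin_length("N") for ct in biv.chromatids.values())
            assert total_n == 2 * 1_000_000

    def test_dyad_members_identical_on_long_side(self, rng):
        spec = _spec()
        for _ in range(50):
            biv = make_bivalent(spec, "c", rng)
            c = biv.crossover_pos
            long_probe = (c + 1_000_000) // 2 if c <= 1_000_000 - c else c // 2
            for a, b in biv.dyads:
                pa = biv.chromatids[a].origin_at(long_probe)
                pb = biv.chromatids[b].origin_at(long_probe)
                assert pa == pb
                # one recombinant and one non-recombinant per dyad
                n_blocks = {len(biv.chromatids[k].blocks) for k in (a, b)}
                assert n_blocks == {1, 2}


class TestChromatidSelection:
    def test_canonical_returns_one_chromatid_and_two_polar_bodies(self, rng):
        biv = make_bivalent(_spec(), "c", rng)
        retained, pb = select_maternal_chromatids(biv, MaternalMode.CANONICAL, rng)
        assert len(retained) == 1 and pb == 2

    def test_central_fusion_never_returns_a_sister_pair(self, rng):
        spec = _spec()
        for _ in range(200):
            biv = make_bivalent(spec, "c", rng)
            retained, _ = select_maternal_chromatids(
                biv, MaternalMode.CENTRAL_FUSION, rng)
            ids = {id(ct) for ct in retained}
            for a, b in biv.dyads:
                dyad_ids = {id(biv.chromatids[a]), id(biv.chromatids[b])}
                assert ids != dyad_ids

    def test_apomixis_is_heterozygous_everywhere(self, rng):
        biv = make_bivalent(_spec(), "c", rng)
        retained, pb = select_maternal_chromatids(biv, MaternalMode.APOMIXIS, rng)
        runs = zygosity_intervals(tuple(retained))
        assert runs == [(0, 1_000_000, "HET")]
        assert pb == 0

    def test_endoreplication_returns_identical_copies(self, rng):
        biv = make_bivalent(_spec(), "c", rng)
        retained, _ = select_maternal_chromatids(
            biv, MaternalMode.ENDOREPLICATION, rng)
        assert retained[0].blocks == retained[1].blocks

    def test_random_two_uniform_over_six_pairs(self, rng):
        # 60,000 draws: each unordered pair at 1/6 within 3 SE
        spec = _spec()
        biv = make_bivalent(spec, "c", rng)
        key_of = {id(ct): k for k, ct in biv.chromatids.items()}
        counts = {}
        n = 60_000
        for _ in range(n):
            retained, _ = select_maternal_chromatids(biv, MaternalMode.RANDOM_TWO, rng)
            pair = tuple(sorted(key_of[id(ct)] for ct in retained))
            counts[pair] = counts.get(pair, 0) + 1
        assert len(counts) == 6
        se = np.sqrt((1 / 6) * (5 / 6) / n)
        for pair, cnt in counts.items():
            assert abs(cnt / n - 1 / 6) < 3 * se, pair


class TestTruthClassifier:
    def test_enumeration_of_all_six_pairs(self, rng):
        # brute force over one bivalent: {S1:1, S2:1, H1:1, H2:1, H3:2}
        spec = _spec(p_center_crossover=0.0)
        for _ in range(10):
            biv = make_bivalent(spec, "c", rng)
            classes = [classify_pair_truth(biv.pair(a, b))
                       for a, b in biv.all_pairs()]
            tally = {c: classes.count(c) for c in set(classes)}
            assert tally == {ChromosomeGenotype.SISTERS_1: 1,
                             ChromosomeGenotype.SISTERS_2: 1,
                             ChromosomeGenotype.HOMOLOGS_1: 1,
                             ChromosomeGenotype.HOMOLOGS_2: 1,
                             ChromosomeGenotype.HOMOLOGS_3: 2}

    def test_sister_pair_homozygous_center_heterozygous_arm(self, rng):
        spec = _spec(p_center_crossover=0.0)
        biv = make_bivalent(spec, "c", rng)
        for dyad in biv.dyads:
            runs = zygosity_intervals(biv.pair(*dyad))
            assert len(runs) == 2
            states = {state for _, _, state in runs}
            assert "HET" in states and any(s.startswith("HOM_") for s in states)
            # the midpoint-containing run is homozygous
            mid_state = next(s for a, b, s in runs if a <= 500_000 < b)
            assert mid_state.startswith("HOM_")

    def test_nonrecombinants_give_homologs_3(self, rng):
        biv = make_bivalent(_spec(), "c", rng)
        assert classify_pair_truth(biv.pair("N1", "J2")) is ChromosomeGenotype.HOMOLOGS_3

    def test_identical_copies_give_full_homozygosity(self, rng):
        biv = make_bivalent(_spec(), "c", rng)
        n1 = biv.chromatids["N1"]
        assert classify_pair_truth((n1, n1)) is ChromosomeGenotype.FULL_HOM_N
        j2 = biv.chromatids["J2"]
        assert classify_pair_truth((j2, j2)) is ChromosomeGenotype.FULL_HOM_J

    def test_chromosome_mismatch_rejected(self, rng):
        spec = GenomeSpec(chromosomes=[ChromosomeSpec("a", 1_000_000),
                                       ChromosomeSpec("b", 1_000_000)])
        ba = make_bivalent(spec, "a", rng)
        bb = make_bivalent(spec, "b", rng)
        with pytest.raises(ValueError):
            classify_pair_truth((ba.chromatids["N1"], bb.chromatids["N1"]))

    def test_sub_resolution_terminal_collapses_to_body(self):
        from gynotype.meiosis import recombinant_chromatid, uniform_chromatid
        n1 = uniform_chromatid("c", 1_000_000, "N")
        n2 = recombinant_chromatid("c", 1_000_000, "N", "J", 990_000)
        assert classify_pair_truth((n1, n2)) is ChromosomeGenotype.SISTERS_1
        assert classify_pair_truth((n1, n2), min_terminal_bp=50_000) \
            is ChromosomeGenotype.FULL_HOM_N


class TestZygote:
    def test_central_fusion_no_paternal_is_fertile_diploid(self, tiny_genome, rng):
        z = simulate_zygote(tiny_genome, MaternalMode.CENTRAL_FUSION,
                            PaternalFate(PaternalFateKind.NONE), rng)
        assert z.fate is ZygoteFate.FERTILE_VIABLE
        assert all(z.maternal_copies(c.id) == 2 for c in tiny_genome.chromosomes)
        assert z.paternal == []

    def test_canonical_full_fertilization_is_haploid_maternal(self, tiny_genome, rng):
        z = simulate_zygote(tiny_genome, MaternalMode.CANONICAL,
                            PaternalFate(PaternalFateKind.FULL, include_X=False), rng)
        assert all(z.maternal_copies(c) == 1 for c in tiny_genome.autosome_ids)
        assert set(z.paternal) == set(tiny_genome.autosome_ids)
        assert z.fate is ZygoteFate.DEAD  # haploid maternal complement

    def test_central_fusion_full_paternal_makes_sterile_triploid(self, tiny_genome, rng):
        z = simulate_zygote(tiny_genome, MaternalMode.CENTRAL_FUSION,
                            PaternalFate(PaternalFateKind.FULL, include_X=False), rng)
        assert all(z.maternal_copies(c) == 2 for c in tiny_genome.autosome_ids)
        assert z.fate is ZygoteFate.STERILE_VIABLE

    def test_paternal_x_is_lethal(self, tiny_genome, rng):
        z = simulate_zygote(tiny_genome, MaternalMode.CENTRAL_FUSION,
                            PaternalFate(PaternalFateKind.FULL, include_X=True), rng)
        assert z.fate is ZygoteFate.DEAD
        assert "X" in z.fate_reason

    def test_uv_destroyed_leaves_no_paternal_blocks(self, tiny_genome, rng):
        z = simulate_zygote(tiny_genome, MaternalMode.CENTRAL_FUSION,
                            PaternalFate(PaternalFateKind.UV_DESTROYED), rng)
        assert z.paternal == []

    def test_x_missegregation_produces_single_x(self, tiny_genome):
        rng = np.random.default_rng(3)
        z = simulate_zygote(tiny_genome, MaternalMode.CENTRAL_FUSION,
                            PaternalFate(PaternalFateKind.NONE), rng, p_X_loss=1.0)
        assert z.maternal_copies("cX") == 1
        assert z.fate is ZygoteFate.FERTILE_VIABLE  # XO male, autosomes diploid

    def test_mosaic_fraction_validation(self):
        with pytest.raises(ValueError):
            PaternalFate(PaternalFateKind.MOSAIC, mosaic_fraction=1.0)

    def test_seeded_runs_are_reproducible(self, tiny_genome):
        def run():
            rng = np.random.default_rng(77)
            z = simulate_zygote(tiny_genome, MaternalMode.RANDOM_TWO,
                                PaternalFate(PaternalFateKind.MOSAIC,
                                             mosaic_fraction=0.4), rng)
            return ([(c, [ct.blocks for ct in cts]) for c, cts in z.maternal.items()],
                    z.paternal, z.polar_bodies, z.fate)

        assert run() == run()


class TestCytology:
    @pytest.mark.parametrize("ploidy,expected", [(1, 6), (2, 6), (3, 12), (4, 18)])
    def test_dapi_body_counts(self, ploidy, expected):
        assert count_dapi_bodies(ploidy, 6) == expected

    def test_nonpositive_ploidy_rejected(self):
        with pytest.raises(ValueError):
            count_dapi_bodies(0, 6)

    def test_polar_body_contract(self, rng):
        spec = _spec()
        biv = make_bivalent(spec, "c", rng)
        # canonical meiosis always expels two polar bodies
        for _ in range(50):
            _, pb = select_maternal_chromatids(biv, MaternalMode.CANONICAL, rng)
            assert pb == 2
        # central fusion: one polar body with frequency p_shared_spindle
        n, p = 4000, 0.5
        ones = sum(select_maternal_chromatids(
            biv, MaternalMode.CENTRAL_FUSION, rng, p_shared_spindle=p)[1] == 1
            for _ in range(n))
        se = np.sqrt(p * (1 - p) / n)
        assert abs(ones / n - p) < 3 * se


class TestModeFrequencies:
    @pytest.mark.parametrize("mode,expected", [
        (MaternalMode.RANDOM_TWO,
         {ChromosomeGenotype.SISTERS_1: 1 / 6, ChromosomeGenotype.SISTERS_2: 1 / 6,
          ChromosomeGenotype.HOMOLOGS_1: 1 / 6, ChromosomeGenotype.HOMOLOGS_2: 1 / 6,
          ChromosomeGenotype.HOMOLOGS_3: 1 / 3}),
        (MaternalMode.CENTRAL_FUSION,
         {ChromosomeGenotype.HOMOLOGS_1: 1 / 4, ChromosomeGenotype.HOMOLOGS_2: 1 / 4,
          ChromosomeGenotype.HOMOLOGS_3: 1 / 2}),
    ])
    def test_class_frequencies_converge_to_enumeration(self, mode, expected, rng):
        spec = _spec()
        n = 10_000
        counts = {}
        for _ in range(n):
            biv = make_bivalent(spec, "c", rng)
            retained, _ = select_maternal_chromatids(biv, mode, rng)
            cls = classify_pair_truth(tuple(retained))
            counts[cls] = counts.get(cls, 0) + 1
        assert set(counts) == set(expected)
        for cls, p in expected.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts.get(cls, 0) / n - p) < 3 * se, cls

    def test_central_fusion_retains_central_heterozygosity(self, rng):
        # with arm-restricted crossovers every homolog pair is heterozygous
        # at the chromosome center
        spec = _spec(p_center_crossover=0.0)
        for _ in range(300):
            biv = make_bivalent(spec, "c", rng)
            retained, _ = select_maternal_chromatids(
                biv, MaternalMode.CENTRAL_FUSION, rng)
            assert retained[0].origin_at(500_000) != retained[1].origin_at(500_000)
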