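"""Ground-truth-linked synthetic data generation."""

import math

import pytest

from trfphas.fixtures import load_published_tables
from trfphas.synth import (
    ConfigError,
    GenerationError,
    GroundTruth,
    PlantedTRF,
    SimConfig,
    random_reference,
    simulate_phas_reads,
    simulate_trf_reads,
    simulate_trna_set,
    simulate_two_libraries,
)
from trfphas.trna import write_trna_tsv


class TestTRNASet:
    def test_single_gene_valid(self):
        (gene,) = simulate_trna_set(SimConfig(seed=7, n_trnas=1))
        assert 72 <= len(gene) <= 90
        prev = 0
        for key in ("acceptor5", "d_arm", "ac_arm", "var_loop", "t_arm", "acceptor3"):
            s, e = gene.landmarks[key]
            assert s == prev
            prev = e

    def test_byte_identical_replay(self):
        cfg = SimConfig(seed=7, n_trnas=6)
        a = write_trna_tsv(simulate_trna_set(cfg))
        b = write_trna_tsv(simulate_trna_set(cfg))
        assert a == b

    def test_dloop_precedes_anticodon_loop_everywhere(self):
        genes = simulate_trna_set(SimConfig(seed=1, n_trnas=100))
        assert all(
            g.landmarks["d_loop"][1] <= g.landmarks["ac_loop"][0] for g in genes
        )

    def test_ala_with_terminal_g_present(self):
        genes = simulate_trna_set(SimConfig(seed=2, n_trnas=4))
        alas = [g for g in genes if g.isotype == "Ala"]
        assert alas and all(g.sequence[0] == "G" for g in alas)
        # the canonical 20-nt fragment ends at a D-loop U
        assert all(g.sequence[19] == "U" for g in alas)

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="n_trnas"):
            simulate_trna_set(SimConfig(n_trnas=0))


class TestTRFReads:
    def test_degenerate_profile_yields_prefix_reads(self, trna_set):
        cfg = SimConfig(
            seed=4, trf_cleavage_profile={(0, 20): 1.0}, noise_fraction=0.0,
            depth_per_library=500,
        )
        reads, truth = simulate_trf_reads(trna_set, cfg)
        prefixes = {g.sequence[:20] for g in trna_set}
        assert all(seq in prefixes for seq, _ in reads)
        assert all(t.start == 0 and t.end == 20 for t in truth.trfs)

    def test_length_mix_matches_binomial(self, trna_set):
        cfg = SimConfig(
            seed=3, depth_per_library=1000, noise_fraction=0.0,
            trf_cleavage_profile={(0, 20): 0.9, (0, 22): 0.1},
        )
        reads, _ = simulate_trf_reads(trna_set, cfg)
        n20 = sum(c for s, c in reads if len(s) == 20)
        total = sum(c for _, c in reads)
        sd = math.sqrt(1000 * 0.9 * 0.1)
        assert abs(n20 - 0.9 * total) <= 3 * sd

    def test_all_noise_plants_nothing(self, trna_set):
        cfg = SimConfig(seed=5, noise_fraction=1.0, depth_per_library=300)
        _, truth = simulate_trf_reads(trna_set, cfg)
        assert truth.trfs == []

    def test_reads_are_exact_substrings(self, trna_set):
        cfg = SimConfig(seed=6, depth_per_library=2000)
        reads, _ = simulate_trf_reads(trna_set, cfg)
        assert all(
            any(seq in g.sequence for g in trna_set) and 18 <= len(seq) <= 30
            for seq, _ in reads
        )

    def test_oversized_interval_is_generation_error(self, trna_set):
        cfg = SimConfig(trf_cleavage_profile={(0, 500): 1.0})
        with pytest.raises(GenerationError):
            simulate_trf_reads(trna_set, cfg)

    def test_truth_linkage_noise_free(self, trna_set):
        """Every planted item maps to generated reads and vice versa."""
        cfg = SimConfig(seed=8, noise_fraction=0.0, depth_per_library=4000)
        reads, truth = simulate_trf_reads(trna_set, cfg)
        assert sum(truth.weights.values()) == sum(c for _, c in reads)
        assert len({t.item_id for t in truth.trfs}) == len(truth.trfs)


class TestPhasReads:
    def test_noise_free_ladder_in_register(self):
        cfg = SimConfig(seed=2, n_phase_cycles=10, noise_fraction=0.0, depth_per_library=800)
        ref = random_reference(cfg)
        reads, truth = simulate_phas_reads(ref, cfg)
        (locus,) = truth.phas_loci
        assert all(start % 21 == locus.register for _, start, _, _, _ in reads)

    def test_noise_fraction_recovered(self):
        cfg = SimConfig(seed=5, noise_fraction=0.5, depth_per_library=2000, n_phase_cycles=8)
        ref = random_reference(cfg)
        reads, truth = simulate_phas_reads(ref, cfg)
        (locus,) = truth.phas_loci
        planted_pos = {locus.start + k * 21 for k in range(locus.n_cycles)}
        n_planted = sum(c for _, s, _, _, c in reads if s in planted_pos)
        total = sum(c for *_, c in reads)
        sd = math.sqrt(2000 * 0.25)
        assert abs(n_planted - 0.5 * total) <= 3 * sd + 1

    def test_zero_cycles_empty(self):
        cfg = SimConfig(seed=1, n_phase_cycles=0, noise_fraction=0.0, depth_per_library=100)
        reads, truth = simulate_phas_reads(random_reference(cfg), cfg)
        assert truth.phas_loci == []

    def test_short_reference_rejected(self):
        cfg = SimConfig(seed=1, n_phase_cycles=10)
        with pytest.raises(GenerationError):
            simulate_phas_reads(("r", "ACGU" * 10), cfg)

    def test_antisense_reads_carry_two_nt_offset(self):
        cfg = SimConfig(
            seed=9, n_phase_cycles=8, noise_fraction=0.0, depth_per_library=2000,
            phas_antisense=True,
        )
        reads, truth = simulate_phas_reads(random_reference(cfg), cfg)
        (locus,) = truth.phas_loci
        minus = [(s + 2) % 21 for _, s, strand, _, _ in reads if strand == "-"]
        assert minus and all(r == locus.register for r in minus)


class TestTwoLibraries:
    @staticmethod
    def _truth(n_items=20):
        truth = GroundTruth()
        for i in range(n_items):
            truth.trfs.append(PlantedTRF(f"item{i}", f"t{i}", 0, 20, frozenset()))
            truth.weights[f"item{i}"] = 1.0
        return truth

    def test_unit_effects_conserve_depth(self):
        truth = self._truth()
        cfg = SimConfig(seed=3, depth_per_library=10000, dispersion=0.0)
        libs = simulate_two_libraries(truth, cfg)
        assert sum(libs["C1D"].values()) == 10000
        assert sum(libs["A1D"].values()) == 10000

    def test_planted_fourfold_down_recovered(self):
        truth = self._truth(10)
        cfg = SimConfig(
            seed=4, depth_per_library=100000, dispersion=0.0,
            condition_effects={"item0": 0.25},
        )
        libs = simulate_two_libraries(truth, cfg)
        lfc = math.log2(libs["A1D"]["item0"] / libs["C1D"]["item0"])
        assert abs(lfc - (-2.0)) <= 0.3

    def test_empty_truth_is_fine(self):
        libs = simulate_two_libraries(GroundTruth(), SimConfig(seed=1))
        assert libs["C1D"] == {} and libs["A1D"] == {}

    def test_negative_effect_rejected(self):
        with pytest.raises(ConfigError):
            simulate_two_libraries(
                self._truth(), SimConfig(condition_effects={"item0": -1.0})
            )

    def test_unknown_effect_key_rejected(self):
        with pytest.raises(ConfigError, match="unknown"):
            simulate_two_libraries(
                self._truth(), SimConfig(condition_effects={"ghost": 2.0})
            )

    def test_overdispersed_counts_still_nonnegative(self):
        libs = simulate_two_libraries(
            self._truth(), SimConfig(seed=2, dispersion=0.5, depth_per_library=5000)
        )
        assert all(v >= 0 for v in libs["C1D"].values())


class TestPublishedTables:
    def test_key_phasirna_rpm_pair(self, published):
        row = published.table2[published.table2["phasirna_id"] == "11_1518_166(+)"].iloc[0]
        assert row["c1d_rpm"] == 1368.32 and row["a1d_rpm"] == 291.07

    def test_trf_class_total(self, published):
        val = published.fig1.query("library == 'C1D' and `class` == 'tRF'")["rpm_total"]
        assert float(val.iloc[0]) == 50520

    def test_fifteen_phasirnas(self, published):
        assert published.table2["phasirna_id"].nunique() == 15

    def test_loader_is_idempotent(self, published):
        again = load_published_tables()
        assert again.table2.equals(published.table2)
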