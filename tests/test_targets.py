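"""miRanda-style duplex scoring, nearest-neighbor energies, target scan."""

import numpy as np
import pytest

from oracles import best_alignment_enumerated, duplex_energy_by_summation
from trfphas.targets import (
    DEFAULT_WEIGHTS,
    DuplexAlignment,
    align_duplex,
    complementarity_score,
    duplex_free_energy,
    predict_targets,
    revcomp,
    stack_energy,
)

S21 = "ACGUACGUACGUACGUACGUA"


class TestComplementarityScore:
    def test_perfect_site_closed_form(self):
        """Perfect 21-mer: 7 seed positions at 4x5 plus 14 at 5 = 210."""
        aln = complementarity_score(S21, revcomp(S21))
        assert aln.score == 210.0
        assert all(state == "match" for state, *_ in aln.pairs)

    def test_non_complementary_window_scores_nothing(self):
        assert complementarity_score("A" * 21, "A" * 25) is None

    def test_central_mismatch_outside_seed_costs_eight(self):
        site = list(revcomp(S21))
        # sRNA position 14 (0-based, outside the 2-8 seed) faces site index 6
        site[len(site) - 1 - 14] = "C" if site[len(site) - 1 - 14] != "C" else "G"
        aln = complementarity_score(S21, "".join(site))
        assert aln.score == 210.0 - 8.0

    def test_seed_mismatch_costs_scaled(self):
        # aperiodic sRNA so a register-shifted alignment cannot sidestep
        # the planted mismatch
        srna = "AGCUUGACGGAUCCGUAAGCU"
        site = list(revcomp(srna))
        idx = len(site) - 1 - 4  # sRNA position 4, inside the seed
        site[idx] = "C" if site[idx] != "C" else "G"
        aln = complementarity_score(srna, "".join(site))
        assert aln.score == 210.0 - 4 * 8.0

    def test_length_guard(self):
        with pytest.raises(ValueError):
            complementarity_score("ACGU", "ACGU" * 3)

    def test_matches_exhaustive_enumeration_on_small_instances(self):
        """DP optimum equals brute-force enumeration of every gapped path."""
        rng = np.random.default_rng(17)
        bases = np.array(list("ACGU"))
        for _ in range(12):
            srna = "".join(rng.choice(bases, size=int(rng.integers(5, 8))))
            window = "".join(rng.choice(bases, size=int(rng.integers(6, 10))))
            want = best_alignment_enumerated(srna, window, DEFAULT_WEIGHTS)
            aln = align_duplex(srna, window)
            got = aln.score if aln else 0.0
            assert got == pytest.approx(want)

    def test_translation_invariance(self):
        pad = "AAAA"
        a = complementarity_score(S21, revcomp(S21))
        b = complementarity_score(S21, pad + revcomp(S21) + pad)
        assert a.score == b.score


class TestDuplexEnergy:
    @staticmethod
    def _cols(srna, target):
        from trfphas.targets import pair_state

        return [(pair_state(s, t), s, t) for s, t in zip(srna, target)]

    def test_gc_stack_ladder(self):
        """k identical GC/CG stacks sum to k times the table value."""
        for k in (1, 3, 8):
            cols = self._cols("G" * (k + 1), "C" * (k + 1))
            aln = DuplexAlignment("G" * (k + 1), "", 0.0, (0, 0), (0, 0), cols)
            assert duplex_free_energy(aln) == pytest.approx(k * -3.26)

    def test_empty_alignment_zero(self):
        aln = DuplexAlignment("", "", 0.0, (0, 0), (0, 0), [])
        assert duplex_free_energy(aln) == 0.0

    def test_mismatch_interrupts_stacking(self):
        cols = self._cols("GGAGG", "CCACC")  # central A:A mismatch
        aln = DuplexAlignment("GGAGG", "", 0.0, (0, 0), (0, 0), cols)
        assert duplex_free_energy(aln) == pytest.approx(2 * -3.26)

    def test_energy_monotone_under_stack_append(self):
        prev = 0.0
        for k in range(1, 12):
            cols = self._cols("G" * (k + 1), "C" * (k + 1))
            aln = DuplexAlignment("", "", 0.0, (0, 0), (0, 0), cols)
            e = duplex_free_energy(aln)
            assert e < prev
            prev = e

    def test_rotation_symmetric_lookup(self):
        assert stack_energy("A", "U", "C", "G") == stack_energy("G", "C", "U", "A")

    def test_random_duplexes_match_summation_oracle(self):
        rng = np.random.default_rng(23)
        bases = "ACGU"
        for _ in range(200):
            n = int(rng.integers(2, 15))
            srna = "".join(rng.choice(list(bases), size=n))
            target = "".join(rng.choice(list(bases), size=n))
            cols = self._cols(srna, target)
            aln = DuplexAlignment(srna, "", 0.0, (0, 0), (0, 0), cols)
            assert duplex_free_energy(aln) == pytest.approx(
                duplex_energy_by_summation(cols), abs=1e-12
            )

    def test_vienna_rna_sanity_cross_check(self):
        """Independent check: ViennaRNA agrees that GC-rich perfect duplexes
        are strongly stabilizing (rank order, not absolute values)."""
        RNA = pytest.importorskip("RNA")
        gc = "GCGCGCGCGCGCGCGCGCGCG"
        au = "AUAUAUAUAUAUAUAUAUAUA"
        ours = {}
        theirs = {}
        for name, s in (("gc", gc), ("au", au)):
            aln = complementarity_score(s, revcomp(s))
            ours[name] = aln.energy
            theirs[name] = RNA.duplexfold(s, revcomp(s)).energy
        assert ours["gc"] < ours["au"] < 0
        assert theirs["gc"] < theirs["au"] < 0


class TestPredictTargets:
    def test_planted_site_recovered_under_calibrated_gates(self):
        tx = "AUGC" * 8 + revcomp(S21) + "GCUA" * 8
        sites = predict_targets(
            [("ph1", S21)], [("tx1", tx)], score_threshold=100, energy_threshold=-10
        )
        passing = [s for s in sites if s.passes]
        assert len(passing) == 1
        site = passing[0]
        assert (site.start, site.end) == (32, 53)
        assert tx[site.start : site.end] == revcomp(S21)

    def test_two_srnas_one_transcript(self):
        other = "GGCAUUCGAUGGCAUCGAUGG"
        tx = revcomp(S21) + "AAAA" + revcomp(other)
        sites = predict_targets(
            [("a", S21), ("b", other)], [("tx", tx)],
            score_threshold=100, energy_threshold=-5,
        )
        assert {s.srna_id for s in sites if s.passes} == {"a", "b"}

    def test_paper_gates_pass_nothing_on_random_sequence(self):
        rng = np.random.default_rng(3)
        bases = list("ACGU")
        srna = "".join(rng.choice(bases, size=21))
        tx = "".join(rng.choice(bases, size=300))
        sites = predict_targets([("s", srna)], [("t", tx)])
        assert all(not s.passes for s in sites)

    def test_empty_transcriptome_warns_and_returns_empty(self):
        assert predict_targets([("s", S21)], []) == []

    def test_output_sorted_and_many_to_many(self):
        tx1 = revcomp(S21) + "A" * 10
        tx2 = "C" * 10 + revcomp(S21)
        sites = predict_targets(
            [("s", S21)], [("tx2", tx2), ("tx1", tx1)],
            score_threshold=100, energy_threshold=-5,
        )
        keys = [(s.srna_id, s.transcript_id, s.start) for s in sites]
        assert keys == sorted(keys)
        assert {s.transcript_id for s in sites if s.passes} == {"tx1", "tx2"}
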