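"""Report building, direction sums and class shares."""

import pandas as pd
import pytest

from trfphas.fixtures import R_FAMILIES, TF_FAMILIES
from trfphas.integrate import (
    PhasiTargetReport,
    TranscriptStatus,
    aggregate_direction_sums,
    build_report,
    class_share_summary,
    classify_transcript_status,
    report_from_fixture,
    transcript_gene,
)
from trfphas.targets import TargetSite


class TestTranscriptStatus:
    def test_undetected(self):
        assert classify_transcript_status(0.0, 0.0) == "undetected"

    def test_twofold_elevated(self):
        assert classify_transcript_status(10, 20) == "elevated"

    def test_small_change_unaltered(self):
        assert classify_transcript_status(10, 11) == "unaltered"

    def test_one_sided_detection(self):
        assert classify_transcript_status(0.0, 5.0) == "elevated"
        assert classify_transcript_status(5.0, 0.0) == "decreased"

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_transcript_status(-1, 2)

    def test_gene_of_versioned_transcript(self):
        assert transcript_gene("Solyc02g083900.2.1") == "Solyc02g083900"


class TestFixtureReport:
    def test_row_counts(self, published):
        """35 family rows, 32 with detected transcripts, over 15 phasiRNAs."""
        rep = report_from_fixture(published.table2)
        assert len(rep.rows) == 35
        assert rep.rows["n_transcripts"].notna().sum() == 32
        assert rep.rows["phasirna_id"].nunique() == 15

    def test_transcript_sums_consistent(self, published):
        rep = report_from_fixture(published.table2)
        got = rep.rows.dropna(subset=["n_transcripts"])
        assert (
            got["n_transcripts"] == got["n_up"] + got["n_down"] + got["n_unchanged"]
        ).all()

    def test_family_targeting_counts(self, published):
        rows = report_from_fixture(published.table2).rows
        r = rows[rows["family"].isin(R_FAMILIES)]["phasirna_id"].nunique()
        tf = rows[rows["family"].isin(TF_FAMILIES)]["phasirna_id"].nunique()
        assert (r, tf) == (12, 7)

    def test_shared_target_map_symmetric_pairs(self, published):
        rep = report_from_fixture(published.table2)
        assert frozenset({"1_1364_205(-)", "1_1364_226(-)"}) in rep.shared
        assert frozenset({"1_1364_249(+)", "10_1305_229(+)"}) in rep.shared
        assert all(len(k) == 2 for k in rep.shared)


class TestDirectionSums:
    def test_published_down_sum(self, published):
        rep = report_from_fixture(published.table2)
        assert aggregate_direction_sums(rep, "down", R_FAMILIES) == (
            4091.77, 2330.79, -1760.98,
        )

    def test_published_up_sum(self, published):
        rep = report_from_fixture(published.table2)
        assert aggregate_direction_sums(rep, "up", R_FAMILIES) == (
            316.07, 590.39, 274.32,
        )

    def test_directions_partition_the_selection(self, published):
        rows = report_from_fixture(published.table2).rows
        sel = rows[rows["family"].isin(R_FAMILIES)]
        down = set(sel[sel["direction"] == "down"]["phasirna_id"])
        up = set(sel[sel["direction"] == "up"]["phasirna_id"])
        assert down.isdisjoint(up)
        assert len(down | up) == 12

    def test_empty_report_gives_zero_triple(self):
        rep = PhasiTargetReport(
            rows=pd.DataFrame(
                columns=["phasirna_id", "direction", "rpm_C1D", "rpm_A1D", "family"]
            )
        )
        assert aggregate_direction_sums(rep, "down", R_FAMILIES) == (0.0, 0.0, 0.0)

    def test_bad_direction_rejected(self, published):
        rep = report_from_fixture(published.table2)
        with pytest.raises(ValueError):
            aggregate_direction_sums(rep, "sideways", R_FAMILIES)


class TestClassShares:
    def test_published_shares(self, published):
        sh = class_share_summary(published.fig1).set_index(["library", "class"])
        assert sh.loc[("C1D", "tRF"), "share_pct"] == 5.05
        assert sh.loc[("A1D", "phasiRNA"), "share_pct"] == 11.40
        assert sh.loc[("C1D", "miRNA"), "share_pct"] == 83.38

    def test_shares_sum_to_hundred(self, published):
        sh = class_share_summary(published.fig1)
        sums = sh.groupby("library")["share"].sum()
        assert (abs(sums - 100.0) < 0.01).all()


class TestBuildReport:
    @staticmethod
    def _records():
        return pd.DataFrame(
            {
                "id": ["ph_down", "ph_flat"],
                "rpm_C1D": [1000.0, 50.0],
                "rpm_A1D": [250.0, 52.0],
                "tier": ["down", "unchanged"],
            }
        )

    @staticmethod
    def _site(srna, tx, passes=True):
        return TargetSite(srna, tx, 10, 31, 150.0, -30.0, passes)

    def test_planted_negative_correlation_row(self):
        """A down phasiRNA targeting 3 elevated transcripts yields (3,3,0,0)."""
        statuses = {
            f"G{i}.1.1": TranscriptStatus(f"G{i}.1.1", "NBS-LRR", 5, 20, "elevated")
            for i in range(3)
        }
        sites = [self._site("ph_down", t) for t in statuses]
        rep = build_report(self._records(), sites, statuses)
        (row,) = rep.rows.to_dict("records")
        assert (
            row["n_transcripts"], row["n_up"], row["n_down"], row["n_unchanged"]
        ) == (3, 3, 0, 0)
        assert row["n_target_genes"] == 3
        assert row["direction"] == "down"

    def test_non_passing_sites_ignored(self):
        statuses = {"G0.1.1": TranscriptStatus("G0.1.1", "RLK", 5, 20, "elevated")}
        rep = build_report(
            self._records(), [self._site("ph_down", "G0.1.1", passes=False)], statuses
        )
        assert rep.rows.empty

    def test_non_responsive_phasirna_excluded(self):
        statuses = {"G0.1.1": TranscriptStatus("G0.1.1", "RLK", 5, 20, "elevated")}
        rep = build_report(self._records(), [self._site("ph_flat", "G0.1.1")], statuses)
        assert rep.rows.empty

    def test_sites_without_expression_record_raise(self):
        statuses = {"G0.1.1": TranscriptStatus("G0.1.1", "RLK", 5, 20, "elevated")}
        with pytest.raises(ValueError, match="no expression record"):
            build_report(self._records(), [self._site("ghost", "G0.1.1")], statuses)

    def test_shared_transcripts_tracked(self):
        records = pd.DataFrame(
            {
                "id": ["p1", "p2"],
                "rpm_C1D": [500.0, 400.0],
                "rpm_A1D": [100.0, 90.0],
                "tier": ["down", "down"],
            }
        )
        statuses = {"G0.1.1": TranscriptStatus("G0.1.1", "STK", 5, 20, "elevated")}
        sites = [self._site("p1", "G0.1.1"), self._site("p2", "G0.1.1")]
        rep = build_report(records, sites, statuses)
        assert rep.shared == {frozenset({"p1", "p2"}): {"G0.1.1"}}
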