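"""Integration of differential phasiRNAs, predicted targets and transcript
expression status.

This is the report layer: it joins the phasiRNA expression records with the
predicted target sites and a transcript FPKM table, producing one row per
(responsive phasiRNA, target gene family) with target-gene and
detected-transcript counts by status -- the layout of the published
stress-related phasiRNA table -- plus per-direction abundance sums and the
per-class RPM share summary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from trfphas.diffexp import LibraryCounts, normalize_rpm

log = logging.getLogger(__name__)

STATUS_FOLD_THRESHOLD = 0.585  # |log2 FC| of a 1.5x change
DETECTION_FLOOR = 0.1          # FPKM below which a transcript is undetected

REPORT_COLUMNS = [
    "phasirna_id", "direction", "rpm_C1D", "rpm_A1D", "family",
    "n_target_genes", "n_transcripts", "n_up", "n_down", "n_unchanged",
]


def classify_transcript_status(
    fpkm_c: float,
    fpkm_a: float,
    fold_threshold: float = STATUS_FOLD_THRESHOLD,
    floor: float = DETECTION_FLOOR,
) -> str:
    """Transcript expression status across the two conditions.

    ``undetected`` when both FPKM fall below the detection floor; otherwise
    ``elevated``/``decreased`` when ``|log2(fpkm_a / fpkm_c)|`` reaches the
    fold threshold (1.5x by default) with the matching sign, else
    ``unaltered``.  A transcript detected on one side only is classified by
    the sign of its (infinite) fold change.
    """
    if fpkm_c < 0 or fpkm_a < 0:
        raise ValueError("FPKM must be non-negative")
    if fpkm_c < floor and fpkm_a < floor:
        return "undetected"
    if fpkm_c == 0:
        return "elevated"
    if fpkm_a == 0:
        return "decreased"
    lfc = math.log2(fpkm_a / fpkm_c)
    if lfc >= fold_threshold:
        return "elevated"
    if lfc <= -fold_threshold:
        return "decreased"
    return "unaltered"


@dataclass
class TranscriptStatus:
    transcript_id: str
    family: str
    fpkm_c: float
    fpkm_a: float
    status: str


def transcript_gene(transcript_id: str) -> str:
    """Gene of a dot-versioned transcript id (``Solyc02g083900.2.1`` ->
    ``Solyc02g083900``)."""
    return transcript_id.split(".")[0]


@dataclass
class PhasiTargetReport:
    """Rows keyed by (phasiRNA, target family) plus the shared-transcript
    deduplication map (symmetric: keyed by unordered phasiRNA pairs)."""

    rows: pd.DataFrame
    shared: dict[frozenset, set] = field(default_factory=dict)


def build_report(
    phasi_records: pd.DataFrame,
    target_sites,
    statuses: dict[str, TranscriptStatus],
) -> PhasiTargetReport:
    """Build the (phasiRNA, family) report from expression records, target
    sites and transcript statuses.

    ``phasi_records`` is the diffexp expression table restricted to
    phasiRNAs (columns id, rpm_C1D, rpm_A1D, tier); only responsive
    (up/down) phasiRNAs with at least one passing site are reported.  A
    phasiRNA that has sites but no expression record is a consistency
    error.  Undetected transcripts are excluded from the sum/up/down/
    unchanged counts (reported via their absence).
    """
    expr = phasi_records.set_index("id")
    hits: dict[tuple[str, str], set[str]] = {}
    for site in target_sites:
        passes = site.passes if hasattr(site, "passes") else site["passes"]
        if not passes:
            continue
        srna_id = site.srna_id if hasattr(site, "srna_id") else site["srna_id"]
        tx_id = site.transcript_id if hasattr(site, "transcript_id") else site["transcript_id"]
        if srna_id not in expr.index:
            raise ValueError(f"target sites for {srna_id} but no expression record")
        if tx_id not in statuses:
            continue
        fam = statuses[tx_id].family
        hits.setdefault((srna_id, fam), set()).add(tx_id)

    rows = []
    tx_by_phasi: dict[str, set[str]] = {}
    for (srna_id, fam), tx_ids in sorted(hits.items()):
        rec = expr.loc[srna_id]
        if rec["tier"] not in ("up", "down"):
            continue
        tx_by_phasi.setdefault(srna_id, set()).update(tx_ids)
        detected = [t for t in tx_ids if statuses[t].status != "undetected"]
        n_up = sum(statuses[t].status == "elevated" for t in detected)
        n_down = sum(statuses[t].status == "decreased" for t in detected)
        n_unch = sum(statuses[t].status == "unaltered" for t in detected)
        rows.append(
            {
                "phasirna_id": srna_id,
                "direction": rec["tier"],
                "rpm_C1D": rec["rpm_C1D"],
                "rpm_A1D": rec["rpm_A1D"],
                "family": fam,
                "n_target_genes": len({transcript_gene(t) for t in tx_ids}),
                "n_transcripts": len(detected),
                "n_up": n_up,
                "n_down": n_down,
                "n_unchanged": n_unch,
            }
        )
    shared: dict[frozenset, set] = {}
    ids = sorted(tx_by_phasi)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            common = tx_by_phasi[a] & tx_by_phasi[b]
            if common:
                shared[frozenset({a, b})] = common
    return PhasiTargetReport(rows=pd.DataFrame(rows, columns=REPORT_COLUMNS), shared=shared)


def report_from_fixture(table2: pd.DataFrame) -> PhasiTargetReport:
    """Adapt the packaged Table-2-style fixture to the report layout."""
    rows = table2.rename(
        columns={
            "c1d_rpm": "rpm_C1D",
            "a1d_rpm": "rpm_A1D",
            "n_transcripts": "n_transcripts",
        }
    )
    shared: dict[frozenset, set] = {}
    if "footnote" in rows.columns:
        for letter, grp in rows.dropna(subset=["footnote"]).groupby("footnote"):
            members = set(grp["phasirna_id"])
            if letter.islower() and len(members) > 1:
                ids = sorted(members)
                for i, a in enumerate(ids):
                    for b in ids[i + 1 :]:
                        shared.setdefault(frozenset({a, b}), set()).add(letter)
    cols = [c for c in REPORT_COLUMNS if c in rows.columns] + ["footnote"]
    return PhasiTargetReport(rows=rows[cols], shared=shared)


def aggregate_direction_sums(
    report: PhasiTargetReport,
    direction: str,
    families: frozenset | set,
) -> tuple[float, float, float]:
    """(sum C1D RPM, sum A1D RPM, delta) over *distinct* phasiRNAs of one
    direction targeting at least one family in ``families``.

    Each phasiRNA is counted once no matter how many family rows it has.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    rows = report.rows
    sel = rows[(rows["direction"] == direction) & rows["family"].isin(families)]
    if sel.empty:
        log.warning("no %s phasiRNAs target families %s", direction, sorted(families))
        return 0.0, 0.0, 0.0
    per = sel.drop_duplicates(subset="phasirna_id")
    c = float(per["rpm_C1D"].sum())
    a = float(per["rpm_A1D"].sum())
    return round(c, 2), round(a, 2), round(a - c, 2)


def class_totals(libraries: dict[str, LibraryCounts]) -> pd.DataFrame:
    """Per-library RPM totals of the three jointly normalized classes."""
    rows = []
    for lib_id, lib in libraries.items():
        n = lib.N
        rows.append({"library": lib_id, "class": "miRNA",
                     "rpm_total": normalize_rpm(lib.mirna_total, n)})
        rows.append({"library": lib_id, "class": "tRF",
                     "rpm_total": normalize_rpm(sum(lib.trf_counts.values()), n)})
        rows.append({"library": lib_id, "class": "phasiRNA",
                     "rpm_total": normalize_rpm(sum(lib.phas_counts.values()), n)})
    return pd.DataFrame(rows)


def class_share_summary(totals: pd.DataFrame) -> pd.DataFrame:
    """Percentage share of each sRNA class within its library.

    ``totals`` has columns library / class / rpm_total (either computed by
    :func:`class_totals` or the packaged printed totals).  Shares are
    percentages of the combined miRNA + tRF + phasiRNA sum, with a
    two-decimal ``share_pct`` column; within a library they sum to 100 up
    to rounding.
    """
    out = totals.copy()
    lib_sums = out.groupby("library")["rpm_total"].transform("sum")
    out["share"] = out["rpm_total"] / lib_sums * 100.0
    out["share_pct"] = out["share"].round(2)
    return out
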