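"""Packaged published summary tables.

Three small fixtures ship with the package, transcribed from the published
study they replicate at desk scale:

* ``table2.tsv`` -- the 15 stress-related differentially expressed
  phasiRNAs, one row per (phasiRNA, target gene family): C1D/A1D RPM,
  target gene count, and detected-transcript counts (sum / up / down /
  unchanged).  Family rows with no detected transcripts carry empty
  transcript fields.  Footnote letters mark target genes shared between
  phasiRNAs (lower case) and the families they are subsets of (upper case).
* ``fig1_totals.tsv`` -- per-library RPM totals of the three jointly
  normalized sRNA classes (miRNA, tRF, phasiRNA).
* ``printed_pairs.tsv`` -- per-direction tRF/phasiRNA abundance totals and
  the dominant 20-nt Ala tRF's RPM pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

#: plant resistance-gene families of Table 2
R_FAMILIES = frozenset({"NBS-LRR", "STK", "RLK"})
#: transcription-factor families of Table 2
TF_FAMILIES = frozenset({"AP2/ERF", "ERF", "MYB", "NAC", "ARF", "GRAS", "bHLH", "WRKY"})


@dataclass
class PublishedTables:
    table2: pd.DataFrame
    fig1: pd.DataFrame
    printed_pairs: pd.DataFrame


def _read(name: str) -> pd.DataFrame:
    with resources.files("trfphas.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_published_tables() -> PublishedTables:
    """Load the packaged fixture tables.

    ``table2`` gains a ``direction`` column ("up"/"down") derived from the
    printed RPM pair (every fixture phasiRNA is differentially expressed,
    so the sign of the fold change is its direction).
    """
    table2 = _read("table2.tsv")
    table2["direction"] = (table2["a1d_rpm"] < table2["c1d_rpm"]).map(
        {True: "down", False: "up"}
    )
    fix = PublishedTables(
        table2=table2,
        fig1=_read("fig1_totals.tsv"),
        printed_pairs=_read("printed_pairs.tsv").set_index("item"),
    )
    _check(fix)
    return fix


def _check(fix: PublishedTables) -> None:
    ids = fix.table2["phasirna_id"].unique()
    if len(ids) != 15:
        raise AssertionError(f"table2 fixture holds {len(ids)} phasiRNAs, expected 15")
    if (fix.table2[["c1d_rpm", "a1d_rpm"]] < 0).any().any():
        raise AssertionError("negative RPM in table2 fixture")
    if (fix.fig1["rpm_total"] < 0).any():
        raise AssertionError("negative RPM in fig1 fixture")
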