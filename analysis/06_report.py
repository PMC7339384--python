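#!/usr/bin/env python
"""Reproduce the published summary arithmetic from the packaged fixtures.

Rebuilds the stress-related phasiRNA report, the per-direction abundance
sums over R-gene families, the per-class RPM shares, and the printed tRF
declines -- the desk-scale checks of the analysis.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study import RESULTS

from trfphas.fixtures import R_FAMILIES, TF_FAMILIES, load_published_tables
from trfphas.integrate import (
    aggregate_direction_sums,
    class_share_summary,
    report_from_fixture,
)


def main() -> None:
    fix = load_published_tables()
    report = report_from_fixture(fix.table2)
    out = RESULTS / "report"
    out.mkdir(parents=True, exist_ok=True)
    report.rows.to_csv(out / "phasi_target_report.tsv", sep="\t", index=False)

    down = aggregate_direction_sums(report, "down", R_FAMILIES)
    up = aggregate_direction_sums(report, "up", R_FAMILIES)
    (out / "direction_sums.tsv").write_text(
        "direction\trpm_C1D\trpm_A1D\tdelta\n"
        f"down\t{down[0]}\t{down[1]}\t{down[2]}\n"
        f"up\t{up[0]}\t{up[1]}\t{up[2]}\n"
    )
    shares = class_share_summary(fix.fig1)
    shares.to_csv(out / "class_shares.tsv", sep="\t", index=False)

    t2 = fix.table2
    print(f"{t2['phasirna_id'].nunique()} stress-related phasiRNAs; "
          f"{t2[t2.family.isin(R_FAMILIES)]['phasirna_id'].nunique()} target R genes, "
          f"{t2[t2.family.isin(TF_FAMILIES)]['phasirna_id'].nunique()} target TFs")
    print(f"down-regulated R-gene-targeting phasiRNAs: "
          f"{down[0]} -> {down[1]} RPM (delta {down[2]})")
    print(f"up-regulated: {up[0]} -> {up[1]} RPM (delta {up[2]})")
    sh = shares.set_index(["library", "class"])
    print(f"class shares: tRF C1D {sh.loc[('C1D', 'tRF'), 'share_pct']}%, "
          f"phasiRNA A1D {sh.loc[('A1D', 'phasiRNA'), 'share_pct']}%")
    pairs = fix.printed_pairs
    ala = pairs.loc["trf_ENSRNA049443699:1-20"]
    print(f"dominant Ala tRF decline: {round(ala['c1d_rpm'] - ala['a1d_rpm'], 2)} RPM")
    dtot = pairs.loc["trf_down_total"]
    print(f"down-regulated tRF total decline: "
          f"{round(dtot['c1d_rpm'] - dtot['a1d_rpm'], 2)} RPM")
    print(f"tables written to {out}")


if __name__ == "__main__":
    main()
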