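#!/usr/bin/env python
"""Align reads to the tRNA set, call tRF peaks and classify them.

Finding to expect from the planted cleavage profile: the dominant called
fragment is a 20-nt 5e-tRF on tRNA-Ala starting at the 5'-terminal G and
ending at a D-loop U.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study import RESULTS, SEED, build_study

from trfphas import trf
from trfphas.trna import partition_regions, write_region_bed


def main() -> None:
    study = build_study(SEED)
    trnas = study["trnas"]
    cfg = study["config"]
    out = RESULTS
    out.mkdir(parents=True, exist_ok=True)

    aln_by_lib = {}
    for lib, reads in study["reads_by_lib"].items():
        aln_by_lib[lib], unmapped = trf.align_exact(reads, trnas)
        print(f"{lib}: {len(aln_by_lib[lib])} alignments, {unmapped} unmapped sequences")

    pooled = aln_by_lib["C1D"] + aln_by_lib["A1D"]
    profiles = trf.build_end_profiles(pooled)
    seqs = {g.id: g.sequence for g in trnas}
    parts = {g.id: partition_regions(g) for g in trnas}
    called = []
    for gid, prof in profiles.items():
        for cand in trf.call_trf_peaks(prof, seqs[gid], cfg.min_support, cfg.end_tolerance):
            cand.labels = trf.classify_trf(cand, parts[gid], cfg.class_threshold)
            called.append(cand)
    table = trf.quantify_libraries(called, aln_by_lib, cfg.quant_slack)
    table.to_csv(out / "trf_table.tsv", sep="\t", index=False)
    (out / "trf_regions.bed").write_text(write_region_bed(list(parts.values())))
    (out / "trf_calls.bed").write_text(trf.write_trf_bed(called))

    top = max(called, key=lambda t: t.support)
    print(f"called {len(called)} tRF candidates on {len(profiles)} tRNAs")
    print(f"dominant tRF: {top.id} ({top.end - top.start} nt, labels "
          f"{','.join(sorted(top.labels))}, {top.support} copies), "
          f"5' base {top.sequence[0]}, 3' base {top.sequence[-1]}")
    # the planted 22-nt minor end variant shares the 20-nt fragment's 5' end,
    # so peak calling absorbs it into the modal 20-nt tRF; recovery is scored
    # per dominant (modal-end) planted fragment
    dominant = [t for t in study["truth"].trfs if t.end - t.start == 20]
    recovered = sum(
        1 for t in dominant
        if any(c.trna_id == t.trna_id and (c.start, c.end) == (t.start, t.end) for c in called)
    )
    print(f"dominant planted-tRF recovery: {recovered}/{len(dominant)} "
          f"(22-nt end variants merge into the modal 20-nt peak)")


if __name__ == "__main__":
    main()
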