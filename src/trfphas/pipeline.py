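"""End-to-end orchestration with a single config and reproducible seeds.

Two run modes cover the desk-scale uses of the pipeline:

* ``synthetic`` -- generate a tRNA reference, cleavage-biased tRF reads, a
  phased locus and two-condition libraries from :mod:`trfphas.synth`, then
  run alignment, tRF calling, PHAS calling, joint-RPM differential
  expression, target prediction against constructed complement-bearing
  transcripts, and the integration report.
* ``fixtures`` -- no reads: load the packaged published summary tables and
  reproduce the report-stage aggregates (direction sums, class shares).

Every stage is a pure function of (config, inputs); the run manifest hash
is identical across reruns of the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from trfphas import diffexp, integrate, phas, synth, targets, trf
from trfphas.fixtures import R_FAMILIES, load_published_tables
from trfphas.synth import SimConfig

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters, pre-filled with the study defaults."""

    mode: str = "synthetic"  # or "fixtures"
    seed: int = 0
    output_dir: str | None = None
    log_level: str = "INFO"
    # optional external inputs; when set, the path must exist at pre-flight
    trna_tsv: str | None = None
    genome_fasta: str | None = None
    exclusions_bed: str | None = None
    # synthetic generation
    sim: SimConfig = field(default_factory=SimConfig)
    # tRF calling
    min_support: int = 2
    end_tolerance: int = 2
    class_threshold: float = 0.75
    quant_slack: int = 3
    noise_rpm: float = 2.0
    reporting_rpm: float = 10.0
    # phasing
    phase_len: int = 21
    phase_score_threshold: float = phas.DEFAULT_SCORE_THRESHOLD
    # differential expression
    fc_responsive: float = 0.25
    fc_significant: float = 1.0
    p_threshold: float = 0.05
    # target prediction (study defaults; synthetic analyses calibrate down)
    target_score_threshold: float = targets.SCORE_THRESHOLD
    target_energy_threshold: float = targets.ENERGY_THRESHOLD
    # transcript status
    status_fold_threshold: float = integrate.STATUS_FOLD_THRESHOLD
    detection_floor: float = integrate.DETECTION_FLOOR

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["trf_cleavage_profile"] = [
            [s, e, p] for (s, e), p in self.sim.trf_cleavage_profile.items()
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.pop("sim", {}))
        if "trf_cleavage_profile" in sim:
            sim["trf_cleavage_profile"] = {
                (int(s), int(e)): float(p) for s, e, p in sim["trf_cleavage_profile"]
            }
        known = {f.name for f in dataclasses.fields(SimConfig)}
        d["sim"] = SimConfig(**{k: v for k, v in sim.items() if k in known})
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> list[str]:
    """Pre-flight findings; an empty list means the config is runnable.

    Each out-of-range parameter is reported together with its default.
    """
    findings: list[str] = []
    if config.mode not in ("synthetic", "fixtures"):
        findings.append(f"mode {config.mode!r}: must be 'synthetic' or 'fixtures'")
    if not (0.0 < config.class_threshold <= 1.0):
        findings.append(
            f"class_threshold {config.class_threshold}: must be in (0,1] (default 0.75)"
        )
    if config.phase_len < 18:
        findings.append(f"phase_len {config.phase_len}: below minimum 18 (default 21)")
    if config.min_support < 1:
        findings.append(f"min_support {config.min_support}: must be >= 1 (default 2)")
    if config.quant_slack < 0:
        findings.append(f"quant_slack {config.quant_slack}: must be >= 0 (default 3)")
    if config.p_threshold <= 0 or config.p_threshold > 1:
        findings.append(f"p_threshold {config.p_threshold}: must be in (0,1] (default 0.05)")
    if config.fc_responsive < 0 or config.fc_significant < config.fc_responsive:
        findings.append(
            "fold-change tiers: need 0 <= responsive <= significant (defaults 0.25/1.0)"
        )
    if config.noise_rpm < 0 or config.reporting_rpm < 0:
        findings.append("RPM filters must be non-negative (defaults 2/10)")
    try:
        config.sim.validate()
    except synth.ConfigError as exc:
        findings.append(f"sim: {exc}")
    for name in ("trna_tsv", "genome_fasta", "exclusions_bed"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            findings.append(f"{name} {path!r}: file not found")
    return findings


@dataclass
class RunManifest:
    config_hash: str
    stage_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    run_dir: str | None = None

    @property
    def hash(self) -> str:
        payload = json.dumps(
            {"config": self.config_hash, "stages": self.stage_counts}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def run_all(config: PipelineConfig) -> RunManifest:
    """Run every stage; any stage failure aborts naming the stage.

    Outputs (tables, BED, manifest) land under a timestamped directory in
    ``config.output_dir`` when one is set; the manifest hash is independent
    of the timestamp.
    """
    findings = validate_config(config)
    if findings:
        raise synth.ConfigError("; ".join(findings))
    manifest = RunManifest(config_hash=config.hash())
    outputs: dict[str, str] = {}
    if config.mode == "fixtures":
        _run_fixtures(config, manifest, outputs)
    else:
        _run_synthetic(config, manifest, outputs)
    if config.output_dir:
        run_dir = Path(config.output_dir) / f"run_{time.strftime('%Y%m%d-%H%M%S')}"
        run_dir.mkdir(parents=True, exist_ok=True)
        (run_dir / "config.yaml").write_text(config.to_yaml())
        for name, text in outputs.items():
            (run_dir / name).write_text(text)
        (run_dir / "manifest.json").write_text(
            json.dumps(
                {
                    "config_hash": manifest.config_hash,
                    "manifest_hash": manifest.hash,
                    "stage_counts": manifest.stage_counts,
                    "warnings": manifest.warnings,
                },
                indent=2,
            )
        )
        manifest.run_dir = str(run_dir)
    return manifest


def _run_fixtures(config, manifest, outputs):
    try:
        fix = load_published_tables()
        report = integrate.report_from_fixture(fix.table2)
        down = integrate.aggregate_direction_sums(report, "down", R_FAMILIES)
        up = integrate.aggregate_direction_sums(report, "up", R_FAMILIES)
        shares = integrate.class_share_summary(fix.fig1)
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("fixtures-report", exc) from exc
    manifest.stage_counts = {
        "table2_rows": len(report.rows),
        "phasirnas": report.rows["phasirna_id"].nunique(),
    }
    summary = (
        f"direction\trpm_C1D\trpm_A1D\tdelta\n"
        f"down\t{down[0]}\t{down[1]}\t{down[2]}\n"
        f"up\t{up[0]}\t{up[1]}\t{up[2]}\n"
    )
    outputs["direction_sums.tsv"] = summary
    outputs["class_shares.tsv"] = shares.to_csv(sep="\t", index=False)
    outputs["report.tsv"] = report.rows.to_csv(sep="\t", index=False)


def _build_library_reads(trnas, truth, libs, config):
    """Per-library collapsed tRF reads and phas alignment reads."""
    by_gene = {g.id: g for g in trnas}
    reads_by_lib: dict[str, list[tuple[str, int]]] = {}
    phas_by_lib: dict[str, list[tuple[str, int, str, int, int]]] = {}
    p = config.sim.phase_len
    for li, lib in enumerate(("C1D", "A1D")):
        rng = np.random.default_rng([int(config.seed), 100 + li])
        collapsed: dict[str, int] = {}
        for item in truth.trfs:
            count = libs[lib].get(item.item_id, 0)
            if count:
                seq = by_gene[item.trna_id].sequence[item.start : item.end]
                collapsed[seq] = collapsed.get(seq, 0) + count
        n_noise = int(round(sum(collapsed.values()) * config.sim.noise_fraction))
        for _ in range(n_noise):
            g = trnas[int(rng.integers(len(trnas)))]
            ln = int(rng.integers(18, min(30, len(g)) + 1))
            s = int(rng.integers(0, len(g) - ln + 1))
            seq = g.sequence[s : s + ln]
            collapsed[seq] = collapsed.get(seq, 0) + 1
        reads_by_lib[lib] = sorted(collapsed.items())

        phas_reads: dict[tuple[str, int, str, int], int] = {}
        for locus in truth.phas_loci:
            count = libs[lib].get(locus.item_id, 0)
            if count and locus.n_cycles:
                per = rng.multinomial(count, np.full(locus.n_cycles, 1 / locus.n_cycles))
                for k, c in enumerate(per):
                    if c:
                        key = (locus.ref_id, locus.start + k * p, "+", p)
                        phas_reads[key] = phas_reads.get(key, 0) + int(c)
        phas_by_lib[lib] = sorted((r, s, st, ln, c) for (r, s, st, ln), c in phas_reads.items())
    return reads_by_lib, phas_by_lib


def _run_synthetic(config, manifest, outputs):
    sim = dataclasses.replace(config.sim, seed=config.seed)
    stage = "simulate"
    try:
        trnas = synth.simulate_trna_set(sim)
        _, trf_truth = synth.simulate_trf_reads(trnas, sim)
        reference = synth.random_reference(sim)
        _, phas_truth = synth.simulate_phas_reads(reference, sim)
        truth = synth.GroundTruth(
            trfs=trf_truth.trfs,
            phas_loci=phas_truth.phas_loci,
            weights={**trf_truth.weights, **phas_truth.weights},
        )
        libs = synth.simulate_two_libraries(truth, sim)
        reads_by_lib, phas_by_lib = _build_library_reads(trnas, truth, libs, config)

        stage = "align"
        aln_by_lib = {}
        for lib, reads in reads_by_lib.items():
            aln_by_lib[lib], unmapped = trf.align_exact(reads, trnas)
            if unmapped:
                manifest.warnings.append(f"{lib}: {unmapped} unmapped read sequences")

        stage = "call-trfs"
        pooled = aln_by_lib["C1D"] + aln_by_lib["A1D"]
        profiles = trf.build_end_profiles(pooled)
        seq_by_gene = {g.id: g.sequence for g in trnas}
        called: list[trf.TRF] = []
        from trfphas.trna import partition_regions

        parts = {g.id: partition_regions(g) for g in trnas}
        for gid, prof in profiles.items():
            for cand in trf.call_trf_peaks(
                prof, seq_by_gene[gid], config.min_support, config.end_tolerance
            ):
                cand.labels = trf.classify_trf(cand, parts[gid], config.class_threshold)
                called.append(cand)
        trf_table = trf.quantify_libraries(called, aln_by_lib, config.quant_slack)

        stage = "call-phas"
        pooled_phas = sorted(set(phas_by_lib["C1D"]) | set(phas_by_lib["A1D"]))
        merged: dict[tuple, int] = {}
        for r, s, st, ln, c in phas_by_lib["C1D"] + phas_by_lib["A1D"]:
            merged[(r, s, st, ln)] = merged.get((r, s, st, ln), 0) + c
        pooled_phas = sorted((k[0], k[1], k[2], k[3], v) for k, v in merged.items())
        loci, excluded = phas.call_phas_loci(
            reference, pooled_phas, threshold=config.phase_score_threshold,
            p=config.phase_len,
        )
        phasirnas = []
        for locus in loci:
            phasirnas.extend(
                phas.extract_phasirnas(locus, phas_by_lib, reference[1], config.phase_len)
            )

        stage = "diffexp"
        lib_counts = {}
        for lib in ("C1D", "A1D"):
            trf_counts = {
                row["id"]: int(row[f"count_{lib}"]) for _, row in trf_table.iterrows()
            }
            phas_counts = {ph.id: ph.counts.get(lib, 0) for ph in phasirnas}
            lib_counts[lib] = diffexp.LibraryCounts(
                lib, trf_counts, phas_counts, libs["mirna_totals"][lib]
            )
        expr = diffexp.expression_table(lib_counts)
        trf_expr = expr[expr["class"] == "tRF"].reset_index(drop=True)
        trf_expr = trf.filter_low_trfs(trf_expr, config.noise_rpm)
        phas_expr = expr[expr["class"] == "phasiRNA"].reset_index(drop=True)

        stage = "predict-targets"
        rng = np.random.default_rng([int(config.seed), 200])
        top = sorted(phasirnas, key=lambda ph: -sum(ph.counts.values()))[:6]
        transcripts, statuses = _synthetic_transcripts(top, phas_expr, rng)
        sites = targets.predict_targets(
            [(ph.id, ph.sequence) for ph in top],
            transcripts,
            score_threshold=config.target_score_threshold,
            energy_threshold=config.target_energy_threshold,
        )

        stage = "integrate"
        report = integrate.build_report(phas_expr, sites, statuses)
        shares = integrate.class_share_summary(integrate.class_totals(lib_counts))
    except StageFailure:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageFailure(stage, exc) from exc

    manifest.stage_counts = {
        "trnas": len(trnas),
        "planted_trfs": len(truth.trfs),
        "called_trfs": len(called),
        "phas_loci": len(loci),
        "phas_excluded": len(excluded),
        "phasirnas": len(phasirnas),
        "expression_records": len(expr),
        "target_sites": len(sites),
        "report_rows": len(report.rows),
    }
    from io import StringIO

    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    buf = StringIO()
    SeqIO.write(
        [SeqRecord(Seq(l.precursor), id=l.id, description="PHAS precursor") for l in loci],
        buf,
        "fasta",
    )
    outputs["phas_precursors.fa"] = buf.getvalue()
    outputs["trf_table.tsv"] = trf_table.to_csv(sep="\t", index=False)
    outputs["trf_expression.tsv"] = trf_expr.to_csv(sep="\t", index=False)
    outputs["phasirna_expression.tsv"] = phas_expr.to_csv(sep="\t", index=False)
    outputs["phas_loci.bed"] = phas.write_locus_bed(loci)
    outputs["report.tsv"] = report.rows.to_csv(sep="\t", index=False)
    outputs["class_shares.tsv"] = shares.to_csv(sep="\t", index=False)


_FAMILY_CYCLE = ("NBS-LRR", "STK", "RLK", "AP2/ERF", "WRKY", "MYB")


def _synthetic_transcripts(top_phasirnas, phas_expr, rng):
    """Transcripts bearing one perfect complement site per top phasiRNA.

    Target status is planted opposite to the phasiRNA's direction (down
    phasiRNA -> elevated target), emulating negative regulation.
    """
    from trfphas.targets import revcomp

    expr = phas_expr.set_index("id")
    bases = np.array(list("ACGU"))
    transcripts = []
    statuses = {}
    for i, ph in enumerate(top_phasirnas):
        pad5 = "".join(rng.choice(bases, size=30))
        pad3 = "".join(rng.choice(bases, size=30))
        tx_id = f"TX{i + 1:02d}g{i + 1:06d}.1.1"
        transcripts.append((tx_id, pad5 + revcomp(ph.sequence) + pad3))
        tier = expr.loc[ph.id, "tier"] if ph.id in expr.index else "unchanged"
        if tier == "down":
            fpkm_c, fpkm_a = 5.0, 20.0
        elif tier == "up":
            fpkm_c, fpkm_a = 20.0, 5.0
        else:
            fpkm_c, fpkm_a = 10.0, 10.0
        statuses[tx_id] = integrate.TranscriptStatus(
            tx_id,
            _FAMILY_CYCLE[i % len(_FAMILY_CYCLE)],
            fpkm_c,
            fpkm_a,
            integrate.classify_transcript_status(fpkm_c, fpkm_a),
        )
    return transcripts, statuses
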