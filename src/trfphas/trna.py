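"""tRNA cloverleaf representation and tRF source-region partitioning.

A mature tRNA (72-90 nt) folds into the cloverleaf: acceptor stem, D-arm
(stem + dihydrouridine loop), anticodon arm, variable loop and T-arm.  tRFs
are named for the region of the cloverleaf they occupy -- 5e-tRF (5' end),
D-tRF, A-tRF (anticodon), V-tRF (variable region) and 3e-tRF (3' end).  This
module parses tRNAscan-SE output (or a simplified TSV) into
:class:`TRNAGene` records and derives the five source regions used by the
tRF classifier.

Coordinates are 0-based half-open internally; human-facing output (ids, BED
names) uses 1-based inclusive intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

#: canonical landmark keys, 5' to 3'; these six tile the gene completely
LANDMARK_ORDER = ("acceptor5", "d_arm", "ac_arm", "var_loop", "t_arm", "acceptor3")
#: inner loops recorded inside their arms
LOOP_KEYS = ("d_loop", "ac_loop", "t_loop")

REGION_LABELS = ("5e", "D", "A", "V", "3e")


class StructureError(ValueError):
    """Raised when landmarks are missing, unordered or do not tile the gene."""


class ParseError(ValueError):
    """Raised on a malformed record; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


@dataclass
class TRNAGene:
    """A tRNA sequence with cloverleaf landmark coordinates.

    ``landmarks`` maps the six tiling landmarks (:data:`LANDMARK_ORDER`) and
    the three inner loops (:data:`LOOP_KEYS`) to 0-based half-open
    ``(start, end)`` intervals on ``sequence``.  The six tiling landmarks
    must be ordered and cover ``[0, len)``; each loop must lie inside its
    arm.  The His isotype is permitted on input.
    """

    id: str
    isotype: str
    anticodon: str
    sequence: str
    landmarks: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        n = len(self.sequence)
        if not (72 <= n <= 90):
            raise StructureError(f"{self.id}: length {n} outside 72-90 nt")
        missing = [k for k in LANDMARK_ORDER + LOOP_KEYS if k not in self.landmarks]
        if missing:
            raise StructureError(f"{self.id}: missing landmarks {missing}")
        prev_end = 0
        for key in LANDMARK_ORDER:
            s, e = self.landmarks[key]
            if s != prev_end or e <= s:
                raise StructureError(
                    f"{self.id}: landmark {key}=[{s},{e}) breaks tiling at {prev_end}"
                )
            prev_end = e
        if prev_end != n:
            raise StructureError(f"{self.id}: landmarks end at {prev_end}, length {n}")
        for loop, arm in (("d_loop", "d_arm"), ("ac_loop", "ac_arm"), ("t_loop", "t_arm")):
            ls, le = self.landmarks[loop]
            as_, ae = self.landmarks[arm]
            if not (as_ <= ls < le <= ae):
                raise StructureError(f"{self.id}: {loop} not inside {arm}")


@dataclass
class RegionPartition:
    """The five tRF source regions derived from a gene's landmarks.

    ``regions`` maps each label in :data:`REGION_LABELS` to a 0-based
    half-open interval.  Adjacent regions overlap at documented junctions
    (``overlaps``); their union covers ``[0, length)`` and no position
    belongs to more than two regions.
    """

    gene_id: str
    length: int
    regions: dict[str, tuple[int, int]]
    overlaps: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)

    def validate(self) -> None:
        cover = [0] * self.length
        for label in REGION_LABELS:
            s, e = self.regions[label]
            if not (0 <= s < e <= self.length):
                raise StructureError(f"{self.gene_id}: region {label}=[{s},{e}) invalid")
            for i in range(s, e):
                cover[i] += 1
        if min(cover) < 1:
            raise StructureError(f"{self.gene_id}: regions do not cover the gene")
        if max(cover) > 2:
            raise StructureError(f"{self.gene_id}: >2 regions share a position")


def partition_regions(gene: TRNAGene) -> RegionPartition:
    """Derive the five tRF source regions from a gene's cloverleaf landmarks.

    The 5' region ends two bases short of the D-loop end, i.e. at the
    third-from-last D-loop base, so a gene whose D-loop ends at position 22
    yields a 20-nt 5e region -- the canonical 5e-tRF length.  The 3' region
    mirrors it, anchored two bases into the T-loop.  The interior regions
    carry 2-nt flanks that create the junction overlaps the dual
    classification rule relies on:

    ==== =====================================================
    5e   ``[0, d_loop.end - 2)``
    D    ``[d_loop.start - 2, ac_arm.start + 2)``
    A    ``[ac_arm.start - 2, ac_arm.end + 2)``
    V    ``[var_loop.start - 2, t_loop.start + 2)`` (variable
         loop plus the 5' T-stem)
    3e   ``[t_loop.start + 2, len)``
    ==== =====================================================
    """
    gene.validate()
    lm = gene.landmarks
    n = len(gene)
    d_loop = lm["d_loop"]
    ac_arm = lm["ac_arm"]
    var_loop = lm["var_loop"]
    t_loop = lm["t_loop"]
    regions = {
        "5e": (0, d_loop[1] - 2),
        "D": (d_loop[0] - 2, ac_arm[0] + 2),
        "A": (ac_arm[0] - 2, ac_arm[1] + 2),
        "V": (var_loop[0] - 2, t_loop[0] + 2),
        "3e": (t_loop[0] + 2, n),
    }
    part = RegionPartition(gene_id=gene.id, length=n, regions=regions)
    for a, b in zip(REGION_LABELS[:-1], REGION_LABELS[1:]):
        lo = max(regions[a][0], regions[b][0])
        hi = min(regions[a][1], regions[b][1])
        if lo < hi:
            part.overlaps[(a, b)] = (lo, hi)
    part.validate()
    return part


# ---------------------------------------------------------------------------
# parsing

_SS_DIALECT = "ss"
_TSV_DIALECT = "tsv"
_OUT_DIALECT = "out"
DIALECTS = (_SS_DIALECT, _TSV_DIALECT, _OUT_DIALECT)

TSV_COLUMNS = ("id", "isotype", "anticodon", "sequence") + LANDMARK_ORDER + LOOP_KEYS


def parse_trnascan(
    text: str, dialect: str
) -> tuple[list[TRNAGene], list[tuple[str, str]]]:
    """Parse tRNAscan-SE output (or the simplified TSV) into genes.

    Returns ``(genes, failures)`` where each failure is ``(record id,
    reason)`` -- records whose landmarks cannot be inferred are reported,
    never silently dropped.  ``dialect`` is one of ``"ss"`` (secondary
    structure file; only the header, ``Seq:`` and ``Str:`` lines are
    consumed), ``"tsv"`` (columns :data:`TSV_COLUMNS`, intervals as
    ``start-end`` 0-based half-open) or ``"out"`` (tabular; carries no
    structure, so every record is reported as a failure).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if dialect == _TSV_DIALECT:
        return _parse_tsv(text)
    if dialect == _OUT_DIALECT:
        return _parse_out(text)
    return _parse_ss(text)


def _parse_tsv(text: str) -> tuple[list[TRNAGene], list[tuple[str, str]]]:
    genes: list[TRNAGene] = []
    failures: list[tuple[str, str]] = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        log.warning("empty tRNA TSV")
        return genes, failures
    header = lines[0].rstrip("\n").split("\t")
    if tuple(header) != TSV_COLUMNS:
        raise ParseError(f"bad TSV header {header}", line=1)
    for ln_no, ln in enumerate(lines[1:], start=2):
        parts = ln.rstrip("\n").split("\t")
        if len(parts) != len(TSV_COLUMNS):
            raise ParseError(f"expected {len(TSV_COLUMNS)} columns, got {len(parts)}", ln_no)
        rec = dict(zip(TSV_COLUMNS, parts))
        try:
            landmarks = {
                key: _parse_interval(rec[key]) for key in LANDMARK_ORDER + LOOP_KEYS
            }
            gene = TRNAGene(
                id=rec["id"],
                isotype=rec["isotype"],
                anticodon=rec["anticodon"],
                sequence=rec["sequence"],
                landmarks=landmarks,
            )
            gene.validate()
        except (ValueError, StructureError) as exc:
            failures.append((rec["id"], str(exc)))
            continue
        genes.append(gene)
    return genes, failures


def _parse_interval(token: str) -> tuple[int, int]:
    s, _, e = token.partition("-")
    return int(s), int(e)


def _parse_out(text: str) -> tuple[list[TRNAGene], list[tuple[str, str]]]:
    # tabular .out rows carry no structure string, so landmark inference is
    # impossible; report every data row rather than dropping it
    failures: list[tuple[str, str]] = []
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith(("Sequence", "Name", "----")):
            continue
        parts = ln.split()
        if len(parts) < 6:
            continue
        failures.append((f"{parts[0]}.trna{parts[1]}", "no structure in .out dialect"))
    if not failures:
        log.warning("empty tRNAscan .out input")
    return [], failures


def _parse_ss(text: str) -> tuple[list[TRNAGene], list[tuple[str, str]]]:
    """Parse tRNAscan-SE ``.ss`` blocks (header / Type / Seq: / Str:)."""
    genes: list[TRNAGene] = []
    failures: list[tuple[str, str]] = []
    block: dict[str, str] = {}
    block_line = 0
    if not text.strip():
        log.warning("empty tRNAscan .ss input")

    def flush():
        if not block:
            return
        rec_id = block.get("id", f"record@{block_line}")
        try:
            genes.append(_gene_from_ss(block, block_line))
        except (ValueError, StructureError, KeyError) as exc:
            failures.append((rec_id, str(exc)))

    for ln_no, ln in enumerate(text.splitlines(), start=1):
        stripped = ln.strip()
        if not stripped:
            continue
        if stripped.startswith("Seq:"):
            block["seq"] = stripped[4:].strip()
        elif stripped.startswith("Str:"):
            block["str"] = stripped[4:].strip()
        elif stripped.startswith("Type:"):
            # e.g.  Type: Ala	Anticodon: AGC at 34-36 (34-36)	Score: 70.0
            for fieldtok in stripped.split("\t"):
                fieldtok = fieldtok.strip()
                if fieldtok.startswith("Type:"):
                    block["isotype"] = fieldtok.split(":", 1)[1].strip().split()[0]
                elif fieldtok.startswith("Anticodon:"):
                    block["anticodon"] = fieldtok.split(":", 1)[1].strip().split()[0]
        elif "Length:" in stripped:
            flush()
            block.clear()
            block_line = ln_no
            block["id"] = stripped.split()[0]
    flush()
    return genes, failures


def _gene_from_ss(block: dict[str, str], line: int) -> TRNAGene:
    seq = block.get("seq")
    struct = block.get("str")
    if not seq or not struct:
        raise ParseError("block lacks Seq:/Str: lines", line)
    if len(seq) != len(struct):
        raise ParseError("Seq and Str lengths differ", line)
    landmarks = landmarks_from_structure(struct)
    gene = TRNAGene(
        id=block.get("id", "?"),
        isotype=block.get("isotype", "Und"),
        anticodon=block.get("anticodon", "NNN"),
        sequence=seq.upper().replace("T", "U"),
        landmarks=landmarks,
    )
    gene.validate()
    return gene


def landmarks_from_structure(struct: str) -> dict[str, tuple[int, int]]:
    """Infer cloverleaf landmarks from a ``>``/``<``/``.`` structure string.

    Pairs are matched by bracket nesting; consecutive pairs are grouped into
    helices, of which exactly four are expected (acceptor, D, anticodon, T).
    Unpaired spacers between arms are folded into the preceding landmark so
    the six tiling landmarks cover the gene.
    """
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(struct):
        if ch == ">":
            stack.append(i)
        elif ch == "<":
            if not stack:
                raise StructureError("unbalanced structure string")
            pairs.append((stack.pop(), i))
    if stack:
        raise StructureError("unbalanced structure string")
    pairs.sort()
    helices: list[list[tuple[int, int]]] = []
    for p in pairs:
        if helices and p[0] == helices[-1][-1][0] + 1 and p[1] == helices[-1][-1][1] - 1:
            helices[-1].append(p)
        else:
            helices.append([p])
    if len(helices) != 4:
        raise StructureError(f"expected 4 helices, found {len(helices)}")
    acc, d_h, ac_h, t_h = helices
    n = len(struct)

    def five_side(h):
        return h[0][0], h[-1][0] + 1

    def loop(h):
        return h[-1][0] + 1, h[-1][1]

    def arm_end(h):
        return h[0][1] + 1

    d_start = five_side(d_h)[0]
    ac_start = five_side(ac_h)[0]
    t_start = five_side(t_h)[0]
    landmarks = {
        "acceptor5": (0, d_start),
        "d_arm": (d_start, ac_start),
        "d_loop": loop(d_h),
        "ac_arm": (ac_start, arm_end(ac_h)),
        "ac_loop": loop(ac_h),
        "var_loop": (arm_end(ac_h), t_start),
        "t_arm": (t_start, arm_end(t_h)),
        "t_loop": loop(t_h),
        "acceptor3": (arm_end(t_h), n),
    }
    return landmarks


# ---------------------------------------------------------------------------
# writers

def write_trna_tsv(genes: list[TRNAGene]) -> str:
    """Serialize genes to the simplified TSV dialect (round-trips losslessly)."""
    out = ["\t".join(TSV_COLUMNS)]
    for g in genes:
        row = [g.id, g.isotype, g.anticodon, g.sequence]
        row += [f"{s}-{e}" for s, e in (g.landmarks[k] for k in LANDMARK_ORDER + LOOP_KEYS)]
        out.append("\t".join(row))
    return "\n".join(out) + "\n"


def write_region_bed(partitions: list[RegionPartition]) -> str:
    """Region BED in tRNA-local coordinates (0-based half-open)."""
    rows = []
    for part in partitions:
        for label in REGION_LABELS:
            s, e = part.regions[label]
            rows.append(f"{part.gene_id}\t{s}\t{e}\t{label}")
    return "\n".join(rows) + ("\n" if rows else "")
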