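"""tRF calling: exact alignment, read-end peak calling, structural
classification and quantification.

The caller follows the read-end-profile strategy of small-RNA fragment
mappers: reads are aligned to mature tRNAs with no mismatches, 5'-end
density peaks define fragment starts, and the modal 3' end among the
supporting reads defines the fragment end.  Each called tRF is classified
against the five cloverleaf source regions by the 75%-overlap rule (a tRF
falling into a junction overlap carries both labels; one matching no region
is "others") and quantified by the <=3-bases-outside rule.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

#: maximum bases of a read allowed outside a tRF for the read to count toward it
QUANT_SLACK = 3
#: minimum fraction of a tRF inside a region for the region's label to apply
CLASS_THRESHOLD = 0.75


@dataclass
class AlignedRead:
    """An exact-substring placement of a collapsed read on one tRNA."""

    sequence: str
    count: int
    trna_id: str
    start: int
    end: int


@dataclass
class TRF:
    """A called tRF: interval on its tRNA, structural labels, counts."""

    trna_id: str
    start: int
    end: int
    sequence: str
    support: int
    labels: frozenset[str] = field(default_factory=frozenset)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def id(self) -> str:
        # 1-based inclusive in all human-facing output
        return f"{self.trna_id}:{self.start + 1}-{self.end}"


def align_exact(
    reads: list[tuple[str, int]], trnas
) -> tuple[list[AlignedRead], int]:
    """Align collapsed reads ``(sequence, count)`` to tRNAs, no mismatches.

    Every exact-substring occurrence on every tRNA is reported
    (multi-mapping preserved); reverse-complement hits are excluded by
    construction.  Returns the alignments and the number of distinct read
    sequences (length-filtered to 18-30 nt) that mapped nowhere.
    """
    alignments: list[AlignedRead] = []
    unmapped = 0
    for seq, count in reads:
        if not (18 <= len(seq) <= 30):
            log.warning("read of length %d outside 18-30 nt skipped", len(seq))
            continue
        hit = False
        for gene in trnas:
            pos = gene.sequence.find(seq)
            while pos != -1:
                alignments.append(AlignedRead(seq, count, gene.id, pos, pos + len(seq)))
                hit = True
                pos = gene.sequence.find(seq, pos + 1)
        if not hit:
            unmapped += 1
    if unmapped:
        log.info("%d read sequences unmapped", unmapped)
    return alignments, unmapped


@dataclass
class EndProfile:
    """Per-tRNA 5'/3' read-end copy-count profiles (pooled libraries)."""

    trna_id: str
    pairs: Counter = field(default_factory=Counter)  # (start, end) -> copies

    @property
    def total(self) -> int:
        return sum(self.pairs.values())

    def five_prime(self) -> Counter:
        c: Counter = Counter()
        for (s, _), n in self.pairs.items():
            c[s] += n
        return c

    def three_prime(self) -> Counter:
        c: Counter = Counter()
        for (_, e), n in self.pairs.items():
            c[e] += n
        return c


def build_end_profiles(alignments: list[AlignedRead]) -> dict[str, EndProfile]:
    profiles: dict[str, EndProfile] = {}
    for a in alignments:
        prof = profiles.setdefault(a.trna_id, EndProfile(a.trna_id))
        prof.pairs[(a.start, a.end)] += a.count
    return profiles


def call_trf_peaks(
    profile: EndProfile,
    trna_sequence: str,
    min_support: int = 2,
    end_tolerance: int = 2,
) -> list[TRF]:
    """Call tRF candidates from one tRNA's read-end profile.

    Iteratively: take the highest-support 5'-end position with at least
    ``min_support`` copies (ties broken leftmost), choose the modal 3' end
    among reads whose 5' end lies within ``end_tolerance`` of it (ties
    broken toward the longer fragment), emit the (start, end) candidate,
    mask its supporting reads, and repeat.  Candidates are returned sorted
    by support, descending.
    """
    remaining = Counter(profile.pairs)
    candidates: list[TRF] = []
    while remaining:
        five: Counter = Counter()
        for (s, _), n in remaining.items():
            five[s] += n
        start, peak_support = min(
            five.items(), key=lambda kv: (-kv[1], kv[0])
        )
        if peak_support < min_support:
            break
        cluster = {
            (s, e): n for (s, e), n in remaining.items() if abs(s - start) <= end_tolerance
        }
        ends: Counter = Counter()
        for (_, e), n in cluster.items():
            ends[e] += n
        end, _ = min(ends.items(), key=lambda kv: (-kv[1], -kv[0]))
        support = sum(cluster.values())
        candidates.append(
            TRF(
                trna_id=profile.trna_id,
                start=start,
                end=end,
                sequence=trna_sequence[start:end],
                support=support,
            )
        )
        for key in cluster:
            del remaining[key]
    candidates.sort(key=lambda t: (-t.support, t.start, t.end))
    return candidates


def classify_trf(trf, partition, threshold: float = CLASS_THRESHOLD) -> frozenset[str]:
    """Classify a tRF interval against the five-region partition.

    A region label applies iff ``|trf ∩ region| / |trf| >= 0.75``.  A tRF in
    a junction overlap can satisfy two regions and carries both labels; one
    satisfying none is ``others``.  ``trf`` may be a :class:`TRF` or a
    0-based half-open ``(start, end)`` tuple.
    """
    start, end = (trf.start, trf.end) if isinstance(trf, TRF) else trf
    if end <= start:
        raise ValueError(f"empty tRF interval [{start},{end})")
    length = end - start
    labels = set()
    for label, (rs, re) in partition.regions.items():
        overlap = min(end, re) - max(start, rs)
        if overlap > 0 and overlap / length >= threshold:
            labels.add(f"{label}-tRF")
    if not labels:
        return frozenset({"others"})
    return frozenset(labels)


def quantify_trf(trf, alignments: list[AlignedRead], slack: int = QUANT_SLACK) -> int:
    """Copies assignable to a tRF: reads with <=3 bases outside its interval.

    bases-outside = ``max(0, trf.start - read.start) + max(0, read.end -
    trf.end)``.  A read may count toward several qualifying tRFs.
    """
    start, end = (trf.start, trf.end) if isinstance(trf, TRF) else trf
    total = 0
    for a in alignments:
        outside = max(0, start - a.start) + max(0, a.end - end)
        if outside <= slack:
            total += a.count
    return total


def quantify_libraries(
    trfs: list[TRF],
    alignments_by_library: dict[str, list[AlignedRead]],
    slack: int = QUANT_SLACK,
) -> pd.DataFrame:
    """Per-library raw counts for a shared tRF catalogue.

    Peaks are called on pooled libraries; this quantifies each library
    separately against that common catalogue.
    """
    by_trna: dict[str, dict[str, list[AlignedRead]]] = {}
    for lib, alns in alignments_by_library.items():
        per = defaultdict(list)
        for a in alns:
            per[a.trna_id].append(a)
        by_trna[lib] = per
    rows = []
    for t in trfs:
        row = {
            "id": t.id,
            "trna_id": t.trna_id,
            "start": t.start,
            "end": t.end,
            "labels": ",".join(sorted(t.labels)) if t.labels else "",
        }
        for lib in alignments_by_library:
            count = quantify_trf(t, by_trna[lib].get(t.trna_id, []), slack)
            row[f"count_{lib}"] = count
            t.counts[lib] = count
        rows.append(row)
    return pd.DataFrame(rows)


def filter_low_trfs(
    table: pd.DataFrame, threshold: float = 2.0, rpm_columns: tuple[str, ...] = ("rpm_C1D", "rpm_A1D")
) -> pd.DataFrame:
    """Noise filter: keep a tRF iff its RPM reaches ``threshold`` in at
    least one library (only both-below-threshold rows are removed)."""
    keep = table[list(rpm_columns)].max(axis=1) >= threshold
    return table[keep].reset_index(drop=True)


def write_trf_bed(trfs: list[TRF]) -> str:
    """tRNA-local BED (0-based half-open), name = comma-joined labels."""
    rows = [
        f"{t.trna_id}\t{t.start}\t{t.end}\t{','.join(sorted(t.labels)) or '.'}\t{t.support}"
        for t in trfs
    ]
    return "\n".join(rows) + ("\n" if rows else "")
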