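"""miRanda-style phasiRNA target prediction.

A small RNA is scored against every window of every transcript by a local
alignment of the sRNA (5'->3') against the reverse complement of the
window, under miRanda-style weights: Watson-Crick pair +5, G:U wobble +1,
mismatch -3, gap open -9, gap extend -4, with substitution scores scaled
by 4 over sRNA positions 2-8 (the seed).  The duplex free energy is the
sum of nearest-neighbor stack energies over consecutive paired
dinucleotides from the packaged stack table (Watson-Crick values from the
standard Turner-style 37C set, representative G:U values), plus an optional
duplex initiation term (default 0, i.e. stacking energy only).  A site
passes when ``score >= score_threshold`` and ``energy <= energy_threshold``.

Note the conventional thresholds carried as defaults here (500 / -50
kcal/mol) are far outside what a 21-nt duplex can reach under these
weights (a perfect 21-mer scores 210); recovery-style analyses should use
calibrated gates.  Target-site conservation across related genomes is not
evaluated; sites carry a placeholder conservation field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

_COMPL = str.maketrans("ACGU", "UGCA")

#: default alignment weights (config-exposed); seed positions are 0-based
DEFAULT_WEIGHTS = {
    "match": 5.0,
    "wobble": 1.0,
    "mismatch": -3.0,
    "gap_open": -9.0,
    "gap_extend": -4.0,
    "seed_scale": 4.0,
    "seed_start": 1,
    "seed_end": 8,  # half-open: sRNA positions 2-8, 1-based
}

SCORE_THRESHOLD = 500.0
ENERGY_THRESHOLD = -50.0

_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "U"), ("U", "G")}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPL)[::-1]


def pair_state(srna_base: str, target_base: str) -> str:
    """Pair state of an sRNA base against the *target* base it faces."""
    if (srna_base, target_base) in _WC:
        return "match"
    if (srna_base, target_base) in _WOBBLE:
        return "wobble"
    return "mismatch"


def position_multiplier(i: int, weights: dict = DEFAULT_WEIGHTS) -> float:
    return weights["seed_scale"] if weights["seed_start"] <= i < weights["seed_end"] else 1.0


@dataclass
class DuplexAlignment:
    """A scored sRNA:target-site duplex.

    ``pairs`` lists alignment columns ``(state, srna_base, target_base)``
    with state in {match, wobble, mismatch, gap_s, gap_w}; gap_s consumes a
    target base, gap_w an sRNA base.  ``window_span`` is on the
    reverse-complemented window string.
    """

    srna: str
    window: str
    score: float
    srna_span: tuple[int, int]
    window_span: tuple[int, int]
    pairs: list[tuple[str, str, str]] = field(default_factory=list)
    energy: float = 0.0


def load_stack_table() -> dict[str, float]:
    """Nearest-neighbor stack energies (kcal/mol at 37C) from the packaged
    table; keys are ``5'XY3'/3'ZW5'`` stacks, looked up up to rotation."""
    text = resources.files("trfphas.data").joinpath("nn_stacks.tsv").read_text()
    table: dict[str, float] = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        stack, dg = line.split("\t")
        table[stack] = float(dg)
    return table


_STACKS: dict[str, float] | None = None


def _stacks() -> dict[str, float]:
    global _STACKS
    if _STACKS is None:
        _STACKS = load_stack_table()
    return _STACKS


def stack_energy(s1: str, t1: str, s2: str, t2: str, table: dict[str, float] | None = None) -> float:
    """Energy of the stack 5'-s1 s2-3' over 3'-t1 t2-5'; rotation-symmetric."""
    table = table or _stacks()
    key = f"{s1}{s2}/{t1}{t2}"
    if key in table:
        return table[key]
    rot = f"{t2}{t1}/{s2}{s1}"
    return table.get(rot, 0.0)


def duplex_free_energy(
    alignment: DuplexAlignment,
    table: dict[str, float] | None = None,
    initiation: float = 0.0,
) -> float:
    """Free energy of a duplex: initiation + nearest-neighbor stack sum.

    Only consecutive *paired* columns (match or wobble, no intervening gap
    or mismatch) contribute stacks; an alignment with no paired stack has
    energy 0 regardless of initiation.
    """
    stacks = 0
    energy = 0.0
    cols = alignment.pairs
    for a, b in zip(cols[:-1], cols[1:]):
        if a[0] in ("match", "wobble") and b[0] in ("match", "wobble"):
            energy += stack_energy(a[1], a[2], b[1], b[2], table)
            stacks += 1
    if stacks == 0:
        return 0.0
    return initiation + energy


def complementarity_score(
    srna: str, window: str, weights: dict = DEFAULT_WEIGHTS
) -> DuplexAlignment | None:
    """Best local alignment of ``srna`` against ``revcomp(window)``.

    Smith-Waterman with affine gaps; substitution scores at sRNA position
    ``i`` are multiplied by the seed factor for positions 2-8 (1-based).
    Gap penalties are unscaled.  Returns ``None`` when no positive-scoring
    alignment exists.  Ties break to the leftmost site on the
    reverse-complemented window, then the shortest alignment.
    """
    if not (18 <= len(srna) <= 25):
        raise ValueError("sRNA length must be 18-25 nt")
    return align_duplex(srna, window, weights)


def align_duplex(srna: str, window: str, weights: dict = DEFAULT_WEIGHTS) -> DuplexAlignment | None:
    """Raw local duplex aligner without the sRNA-length guard.

    Same scoring as :func:`complementarity_score`; useful for probing the
    aligner with short sequences.
    """
    return _smith_waterman(srna, window, weights)


def _smith_waterman(srna: str, window: str, weights: dict) -> DuplexAlignment | None:
    wrc = revcomp(window)
    m, n = len(srna), len(wrc)
    NEG = float("-inf")
    # M[i][j]: best score of alignment ending with srna[i-1] against wrc[j-1]
    M = [[0.0] * (n + 1) for _ in range(m + 1)]
    Ix = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in sRNA (consumes wrc)
    Iy = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in window (consumes sRNA)
    go, ge = weights["gap_open"], weights["gap_extend"]
    best = (0.0, 0, 0, None)  # score, i, j, matrix
    for i in range(m + 1):
        for j in range(n + 1):
            if i > 0 and j > 0:
                s_base, w_base = srna[i - 1], wrc[j - 1]
                t_base = _COMPL_MAP[w_base]
                state = pair_state(s_base, t_base)
                sub = weights[state] * position_multiplier(i - 1, weights)
                prev = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1], 0.0)
                M[i][j] = prev + sub
            elif i == 0 or j == 0:
                M[i][j] = 0.0
            if j > 0:
                Ix[i][j] = max(
                    max(M[i][j - 1], Iy[i][j - 1]) + go, Ix[i][j - 1] + ge
                )
            if i > 0:
                Iy[i][j] = max(
                    max(M[i - 1][j], Ix[i - 1][j]) + go, Iy[i - 1][j] + ge
                )
            # local optimum must end on a substitution column
            if M[i][j] > best[0] + 1e-12:
                best = (M[i][j], i, j, "M")
    score, bi, bj, _ = best
    if score <= 0 or bi == 0:
        return None
    # traceback from (bi, bj); the local alignment starts where the running
    # score bottoms out at the zero reset
    cols: list[tuple[str, str, str]] = []
    i, j, mat = bi, bj, "M"
    tol = 1e-9
    while i > 0 and j > 0:
        if mat == "M":
            s_base, w_base = srna[i - 1], wrc[j - 1]
            t_base = _COMPL_MAP[w_base]
            state = pair_state(s_base, t_base)
            sub = weights[state] * position_multiplier(i - 1, weights)
            cols.append((state, s_base, t_base))
            rest = M[i][j] - sub
            i, j = i - 1, j - 1
            if rest <= tol:
                break  # alignment started here (zero reset)
            if abs(M[i][j] - rest) < tol:
                mat = "M"
            elif abs(Ix[i][j] - rest) < tol:
                mat = "Ix"
            elif abs(Iy[i][j] - rest) < tol:
                mat = "Iy"
            else:
                break
        elif mat == "Ix":
            cols.append(("gap_s", "-", _COMPL_MAP[wrc[j - 1]]))
            opened = max(M[i][j - 1], Iy[i][j - 1]) + weights["gap_open"]
            if abs(Ix[i][j] - opened) < tol:
                mat = "M" if M[i][j - 1] >= Iy[i][j - 1] else "Iy"
            j -= 1
        else:  # Iy
            cols.append(("gap_w", srna[i - 1], "-"))
            opened = max(M[i - 1][j], Ix[i - 1][j]) + weights["gap_open"]
            if abs(Iy[i][j] - opened) < tol:
                mat = "M" if M[i - 1][j] >= Ix[i - 1][j] else "Ix"
            i -= 1
    cols.reverse()
    aln = DuplexAlignment(
        srna=srna,
        window=window,
        score=score,
        srna_span=(i, bi),
        window_span=(j, bj),
        pairs=cols,
    )
    aln.energy = duplex_free_energy(aln)
    return aln


_COMPL_MAP = {"A": "U", "U": "A", "C": "G", "G": "C", "N": "N", "-": "-"}


@dataclass
class TargetSite:
    """A predicted sRNA binding site on a transcript (0-based half-open)."""

    srna_id: str
    transcript_id: str
    start: int
    end: int
    score: float
    energy: float
    passes: bool
    conservation: float | None = None  # placeholder; not evaluated


def predict_targets(
    srnas: list[tuple[str, str]],
    transcripts: list[tuple[str, str]],
    score_threshold: float = SCORE_THRESHOLD,
    energy_threshold: float = ENERGY_THRESHOLD,
    weights: dict = DEFAULT_WEIGHTS,
    window_slack: int = 3,
) -> list[TargetSite]:
    """Scan every transcript window for every sRNA.

    Windows of ``len(sRNA) + window_slack`` start at every transcript
    position; overlapping hits of the same sRNA/transcript keep the best
    score (ties to the leftmost site).  Sites failing either gate are kept
    with ``passes=False``.  Many-to-many sRNA/transcript relations are
    preserved.  Output is sorted by (sRNA, transcript, site start).
    """
    import logging

    if not transcripts:
        logging.getLogger(__name__).warning("empty transcriptome: no target scan")
        return []
    sites: list[TargetSite] = []
    for srna_id, srna in srnas:
        wlen = len(srna) + window_slack
        for tx_id, tx in transcripts:
            best_by_region: list[TargetSite] = []
            for w in range(0, max(1, len(tx) - len(srna) + 1)):
                window = tx[w : w + wlen]
                if len(window) < len(srna):
                    continue
                aln = complementarity_score(srna, window, weights)
                if aln is None:
                    continue
                js, je = aln.window_span
                wl = len(window)
                site_start = w + wl - je
                site_end = w + wl - js
                cand = TargetSite(
                    srna_id,
                    tx_id,
                    site_start,
                    site_end,
                    aln.score,
                    aln.energy,
                    aln.score >= score_threshold and aln.energy <= energy_threshold,
                )
                merged = False
                for k, prev in enumerate(best_by_region):
                    if cand.start < prev.end and prev.start < cand.end:
                        if (cand.score, -cand.start) > (prev.score, -prev.start):
                            best_by_region[k] = cand
                        merged = True
                        break
                if not merged:
                    best_by_region.append(cand)
            sites.extend(best_by_region)
    sites.sort(key=lambda s: (s.srna_id, s.transcript_id, s.start))
    return sites
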