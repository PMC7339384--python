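"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route independent of the
implementation it checks: exact rational arithmetic for the two-library
count test, per-position interval scanning for tRF classification,
exhaustive path enumeration for duplex alignment, and direct table
summation for stack energies.
"""

from __future__ import annotations

from fractions import Fraction
from importlib import resources


# ---------------------------------------------------------------------------
# Audic-Claverie, exact rationals

def audic_tails_exact(x: int, y: int, r: Fraction) -> tuple[Fraction, Fraction]:
    """Inclusive lower and upper tail of p(.|x) at y, exactly.

    Uses the pmf recurrence p(k|x) = p(k-1|x) * r * (x+k) / (k * (1+r)) and
    the closed-form normalization (the conditional distribution is a
    negative binomial and sums to 1), so the infinite upper tail is
    1 - lower(y-1).
    """
    pk = Fraction(1) / (1 + r) ** (x + 1)  # p(0|x)
    lower = Fraction(0)
    lower_prev = Fraction(0)
    for k in range(y + 1):
        if k > 0:
            pk = pk * r * (x + k) / (k * (1 + r))
        lower_prev = lower
        lower += pk
    upper = 1 - lower_prev
    return lower, upper


def audic_pvalue_exact(x: int, y: int, n1, n2, symmetric: bool = True) -> Fraction:
    r = Fraction(n2) / Fraction(n1)
    tails = list(audic_tails_exact(x, y, r))
    if symmetric:
        tails += list(audic_tails_exact(y, x, 1 / r))
    return min(Fraction(1), 2 * min(tails))


# ---------------------------------------------------------------------------
# tRF classification, per-position brute force

def classify_brute_force(interval, partition) -> frozenset[str]:
    start, end = interval
    length = end - start
    labels = set()
    for label, (rs, re) in partition.regions.items():
        inside = sum(1 for pos in range(start, end) if rs <= pos < re)
        if 4 * inside >= 3 * length and inside > 0:  # exact >= 75%
            labels.add(f"{label}-tRF")
    return frozenset(labels) if labels else frozenset({"others"})


# ---------------------------------------------------------------------------
# duplex alignment, exhaustive enumeration

_RC = {"A": "U", "U": "A", "C": "G", "G": "C"}


def _pair_score(s: str, t: str, w: dict) -> float:
    if (s, t) in {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}:
        return w["match"]
    if (s, t) in {("G", "U"), ("U", "G")}:
        return w["wobble"]
    return w["mismatch"]


def best_alignment_enumerated(srna: str, window: str, w: dict) -> float:
    """Best local alignment score by exhaustive path enumeration.

    Enumerates every gapped alignment path that starts and ends on a
    substitution column, applying seed scaling and affine gap costs.
    Exponential: only for short sequences.
    """
    wrc = "".join(_RC[b] for b in reversed(window))
    m, n = len(srna), len(wrc)
    best = 0.0

    def sub(i: int, j: int) -> float:
        mult = w["seed_scale"] if w["seed_start"] <= i < w["seed_end"] else 1.0
        t = _RC[wrc[j]]  # target base faced by srna[i]
        return _pair_score(srna[i], t, w) * mult

    def rec(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if last == "S" and score > best:
            best = score
        if i < m and j < n:
            rec(i + 1, j + 1, score + sub(i, j), "S")
        if j < n:
            cost = w["gap_extend"] if last == "X" else w["gap_open"]
            rec(i, j + 1, score + cost, "X")
        if i < m:
            cost = w["gap_extend"] if last == "Y" else w["gap_open"]
            rec(i + 1, j, score + cost, "Y")

    for si in range(m):
        for wj in range(n):
            rec(si + 1, wj + 1, sub(si, wj), "S")
    return best


# ---------------------------------------------------------------------------
# stack-energy summation, independent table read

def load_stack_table_raw() -> dict[str, float]:
    text = resources.files("trfphas.data").joinpath("nn_stacks.tsv").read_text()
    out = {}
    for line in text.strip().splitlines()[1:]:
        key, val = line.split("\t")
        out[key] = float(val)
    return out


def duplex_energy_by_summation(columns, initiation: float = 0.0) -> float:
    """Sum stack energies over consecutive paired columns.

    ``columns`` are ``(state, srna_base, target_base)`` tuples; the stack of
    two adjacent paired columns is looked up as ``s1 s2 / t1 t2`` or its
    rotation ``t2 t1 / s2 s1``.
    """
    table = load_stack_table_raw()
    total = 0.0
    n_stacks = 0
    paired = {"match", "wobble"}
    for (st1, s1, t1), (st2, s2, t2) in zip(columns[:-1], columns[1:]):
        if st1 in paired and st2 in paired:
            key = f"{s1}{s2}/{t1}{t2}"
            rot = f"{t2}{t1}/{s2}{s1}"
            total += table.get(key, table.get(rot, 0.0))
            n_stacks += 1
    return initiation + total if n_stacks else 0.0
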