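"""Joint normalization and two-library differential expression.

tRF, phasiRNA and miRNA reads are normalized *as a whole*: the RPM of an
item is its raw count divided by the library's combined tRF + phasiRNA +
miRNA read total, times 10^6.  Differential expression between the two
(unreplicated) libraries uses the Audic-Claverie exact test: conditional on
``x`` counts in library 1, the count ``y`` in library 2 follows

    p(y | x) = (N2/N1)^y (x+y)! / (x! y! (1 + N2/N1)^(x+y+1)),

a negative-binomial distribution ``NB(x + 1, N1/(N1+N2))``.  The two-sided
p-value doubles the smaller inclusive tail, capped at 1; by default the
construction is symmetrized over the two conditioning orientations so that
``p(x, N1; y, N2) == p(y, N2; x, N1)`` exactly.

Response tiers follow fixed fold-change/p cut-offs: responsive at
``|log2FC| >= 0.25`` and ``p < 0.05``, significant at ``|log2FC| >= 1``,
unchanged below 0.25.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

FC_RESPONSIVE = 0.25
FC_SIGNIFICANT = 1.0
P_THRESHOLD = 0.05
NOISE_RPM = 2.0
REPORTING_RPM = 10.0

TIERS = ("up", "down", "unchanged", "non-responsive")


class NormalizationError(ValueError):
    pass


@dataclass
class LibraryCounts:
    """Raw counts of one library; ``N`` is the joint normalization total."""

    library_id: str
    trf_counts: dict[str, int] = field(default_factory=dict)
    phas_counts: dict[str, int] = field(default_factory=dict)
    mirna_total: int = 0

    @property
    def N(self) -> int:
        return sum(self.trf_counts.values()) + sum(self.phas_counts.values()) + self.mirna_total


def normalize_rpm(count: float, total: float) -> float:
    """``count / total * 1e6`` over the joint tRF+phasiRNA+miRNA total."""
    if total <= 0:
        raise NormalizationError("normalization total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / total * 1e6


def _log_pmf(k: np.ndarray, x: int, log_r: float, log_1pr: float) -> np.ndarray:
    return (
        k * log_r
        + gammaln(x + k + 1)
        - gammaln(x + 1)
        - gammaln(k + 1)
        - (x + k + 1) * log_1pr
    )


def _tails(x: int, y: int, r: float) -> tuple[float, float]:
    """Inclusive lower/upper tail of ``p(. | x)`` at ``y`` (ratio r = N2/N1)."""
    log_r = math.log(r)
    log_1pr = math.log1p(r)
    lower = float(np.sum(np.exp(_log_pmf(np.arange(0, y + 1), x, log_r, log_1pr))))
    # upper tail: sum far enough past both y and the distribution bulk
    mean = (x + 1) * r
    sd = math.sqrt((x + 1) * r * (1.0 + r))
    k_hi = int(max(y, mean) + 12.0 * sd + 60.0)
    k = np.arange(y, k_hi + 1)
    upper = float(np.sum(np.exp(_log_pmf(k, x, log_r, log_1pr))))
    return min(lower, 1.0), min(upper, 1.0)


def audic_pvalue(
    x: int, y: int, n1: float, n2: float, symmetric: bool = True
) -> float:
    """Two-sided Audic-Claverie p-value for counts ``x`` (library of size
    ``n1``) vs ``y`` (library of size ``n2``).

    Doubles the smaller inclusive tail of the conditional distribution,
    capped at 1.  With ``symmetric=True`` (default) the smaller tail is
    taken over both conditioning orientations, making the p-value exactly
    symmetric under ``(x, n1) <-> (y, n2)``.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    r = n2 / n1
    tails = list(_tails(x, y, r))
    if symmetric:
        tails += list(_tails(y, x, 1.0 / r))
    return min(1.0, 2.0 * min(tails))


def log2_fold_change(rpm_ref: float, rpm_alt: float, pseudocount: float = 0.0) -> float:
    """``log2((rpm_alt + c) / (rpm_ref + c))``; +/-inf when one side is zero
    and no pseudocount is used, nan when both are zero."""
    a, b = rpm_ref + pseudocount, rpm_alt + pseudocount
    if a == 0 and b == 0:
        return math.nan
    if a == 0:
        return math.inf
    if b == 0:
        return -math.inf
    return math.log2(b / a)


def classify_tier(
    log2fc: float,
    pvalue: float,
    fc_responsive: float = FC_RESPONSIVE,
    fc_significant: float = FC_SIGNIFICANT,
    p_threshold: float = P_THRESHOLD,
) -> tuple[str, bool]:
    """Response tier and significance flag of one expression record.

    ``up``/``down`` need ``|log2FC| >= 0.25`` with the matching sign and
    ``p < 0.05``; ``unchanged`` is ``|log2FC| < 0.25`` regardless of p;
    fold-changes passing 0.25 with ``p >= 0.05`` are ``non-responsive``.
    ``significant`` additionally requires ``|log2FC| >= 1``.  A both-zero
    item (nan fold change) is unchanged; a one-sided zero (infinite fold
    change) is classified by sign with significance from p alone.
    """
    if math.isnan(log2fc):
        return "unchanged", False
    if abs(log2fc) < fc_responsive:
        return "unchanged", False
    if pvalue >= p_threshold:
        return "non-responsive", False
    tier = "up" if log2fc > 0 else "down"
    return tier, abs(log2fc) >= fc_significant


def expression_table(
    libraries: dict[str, LibraryCounts],
    control: str = "C1D",
    treatment: str = "A1D",
    pseudocount: float = 0.0,
    symmetric_p: bool = True,
) -> pd.DataFrame:
    """Joint expression table for both item classes across two libraries.

    Columns: id, class, raw counts, RPMs, log2FC (treatment over control),
    Audic p, Benjamini-Hochberg q (reported for transparency only -- the
    tiers use raw p), tier and significance.
    """
    ctrl, trt = libraries[control], libraries[treatment]
    n1, n2 = ctrl.N, trt.N
    if n1 <= 0 or n2 <= 0:
        raise NormalizationError("both libraries need a positive joint total")
    rows = []
    for cls, ctrl_counts, trt_counts in (
        ("tRF", ctrl.trf_counts, trt.trf_counts),
        ("phasiRNA", ctrl.phas_counts, trt.phas_counts),
    ):
        for item in sorted(set(ctrl_counts) | set(trt_counts)):
            x = ctrl_counts.get(item, 0)
            y = trt_counts.get(item, 0)
            rpm_c = normalize_rpm(x, n1)
            rpm_a = normalize_rpm(y, n2)
            lfc = log2_fold_change(rpm_c, rpm_a, pseudocount)
            p = audic_pvalue(x, y, n1, n2, symmetric=symmetric_p)
            tier, sig = classify_tier(lfc, p)
            rows.append(
                {
                    "id": item,
                    "class": cls,
                    f"count_{control}": x,
                    f"count_{treatment}": y,
                    f"rpm_{control}": rpm_c,
                    f"rpm_{treatment}": rpm_a,
                    "log2fc": lfc,
                    "pvalue": p,
                    "tier": tier,
                    "significant": sig,
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["bh_q"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    else:
        df["bh_q"] = pd.Series(dtype=float)
    return df


def reporting_filter(
    table: pd.DataFrame,
    min_rpm: float = REPORTING_RPM,
    rpm_columns: tuple[str, str] = ("rpm_C1D", "rpm_A1D"),
) -> pd.DataFrame:
    """Detail-reporting filter: keep items reaching ``min_rpm`` (default 10
    RPM) in at least one library."""
    keep = table[list(rpm_columns)].max(axis=1) >= min_rpm
    return table[keep].reset_index(drop=True)
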