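"""Synthetic small-RNA data with known ground truth.

The generator emulates the study design the pipeline is built for: two
small-RNA libraries (control ``C1D``, treatment ``A1D``), a tRNA reference
whose dominant cleavage product is a 20-nt 5'-tRF starting at a 5'-terminal
G and ending at a D-loop U, 21-nt phased read ladders on a precursor
transcript, uniform background noise, and multiplicative condition effects
on chosen truth items.  Every generated record is linked to a
:class:`GroundTruth` entry so downstream callers can be scored against
planted truth.

All operations are deterministic functions of :class:`SimConfig` (including
its seed): the same config yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from trfphas.trf import classify_trf
from trfphas.trna import TRNAGene, partition_regions

READ_MIN, READ_MAX = 18, 30

# one representative anticodon per isotype; cycle order for generated sets
_ISOTYPES = [
    ("Ala", "AGC"),
    ("Gly", "GCC"),
    ("Val", "AAC"),
    ("Ser", "AGA"),
    ("Asp", "GUC"),
    ("Glu", "UUC"),
    ("Pro", "AGG"),
    ("Thr", "AGU"),
    ("Cys", "GCA"),
    ("Trp", "CCA"),
]


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


class GenerationError(RuntimeError):
    """A config is structurally valid but impossible to realize."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    ``trf_cleavage_profile`` maps ``(five_prime_offset, three_prime_offset)``
    read intervals on the tRNA to probabilities (summing to 1); the default
    concentrates 90% of cleavage on the canonical ``[0, 20)`` 5'-tRF.
    ``dispersion`` is the negative-binomial overdispersion of library counts
    (variance ``mu + dispersion * mu**2``); 0 gives exact-total multinomial
    sampling.
    """

    seed: int = 0
    n_trnas: int = 8
    trf_cleavage_profile: dict[tuple[int, int], float] = field(
        default_factory=lambda: {(0, 20): 0.9, (0, 22): 0.1}
    )
    phase_len: int = 21
    n_phase_cycles: int = 8
    noise_fraction: float = 0.1
    depth_per_library: int = 20_000
    condition_effects: dict[str, float] = field(default_factory=dict)
    dispersion: float = 0.0
    phas_antisense: bool = False
    mirna_depth_factor: float = 5.0
    #: sampling weight of tRNA-Ala relative to other isotypes; the study
    #: system's tRF population is dominated by a 20-nt Ala fragment
    ala_bias: float = 4.0

    def validate(self) -> None:
        if self.n_trnas < 1:
            raise ConfigError("n_trnas must be >= 1")
        if self.phase_len < READ_MIN:
            raise ConfigError(f"phase_len must be >= {READ_MIN}")
        if not (0.0 <= self.noise_fraction <= 1.0):
            raise ConfigError("noise_fraction must be in [0, 1]")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be non-negative")
        if self.depth_per_library < 0:
            raise ConfigError("depth_per_library must be non-negative")
        if self.trf_cleavage_profile:
            total = sum(self.trf_cleavage_profile.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"trf_cleavage_profile probabilities sum to {total}, not 1"
                )
            for (s, e) in self.trf_cleavage_profile:
                if s < 0 or e <= s:
                    raise ConfigError(f"trf_cleavage_profile interval ({s},{e}) invalid")
        for item, effect in self.condition_effects.items():
            if effect < 0:
                raise ConfigError(f"condition_effects[{item!r}] is negative")
        if self.mirna_depth_factor < 0:
            raise ConfigError("mirna_depth_factor must be non-negative")
        if self.ala_bias <= 0:
            raise ConfigError("ala_bias must be positive")


@dataclass
class PlantedTRF:
    item_id: str
    trna_id: str
    start: int
    end: int
    labels: frozenset[str]


@dataclass
class PlantedLocus:
    item_id: str
    ref_id: str
    start: int
    strand: str
    register: int
    n_cycles: int


@dataclass
class GroundTruth:
    """Planted items and their baseline library weights."""

    trfs: list[PlantedTRF] = field(default_factory=list)
    phas_loci: list[PlantedLocus] = field(default_factory=list)
    #: relative expected abundance of each item in the control library
    weights: dict[str, float] = field(default_factory=dict)

    def item_ids(self) -> list[str]:
        return [t.item_id for t in self.trfs] + [p.item_id for p in self.phas_loci]


def _rng(config: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), salt])


# ---------------------------------------------------------------------------
# tRNA reference

def simulate_trna_set(config: SimConfig) -> list[TRNAGene]:
    """Generate ``n_trnas`` random tRNAs with valid cloverleaf landmarks.

    Sequences are random within fixed landmark lengths (acceptor stem 7 nt
    per side, D-stem 4, D-loop 7-11, anticodon stem 5 + loop 7, variable
    loop 5-23, T-stem 5 + loop 7), giving 72-90 nt genes.  Every fourth gene
    is a tRNA-Ala with an 11-nt D-loop, a 5'-terminal G and a U at the last
    third base of the D-loop -- the canonical 20-nt 5'-tRF cleavage product.
    """
    config.validate()
    rng = _rng(config, 1)
    bases = np.array(list("ACGU"))
    genes: list[TRNAGene] = []
    for i in range(config.n_trnas):
        isotype, anticodon = _ISOTYPES[i % len(_ISOTYPES)]
        is_ala = isotype == "Ala"
        d_len = 11 if is_ala else int(rng.integers(7, 12))
        v_min = max(5, 20 - d_len)  # keeps total length >= 72 nt
        v_len = int(rng.integers(v_min, 24))
        seq, landmarks = _build_gene(rng, bases, d_len, v_len, anticodon)
        if is_ala:
            seq[0] = "G"
            d_loop = landmarks["d_loop"]
            seq[d_loop[1] - 3] = "U"  # 3' base of the 20-nt 5'-tRF
        gene = TRNAGene(
            id=f"tRNA-{isotype}-{anticodon}-{i + 1}",
            isotype=isotype,
            anticodon=anticodon,
            sequence="".join(seq),
            landmarks=landmarks,
        )
        gene.validate()
        genes.append(gene)
    return genes


def _build_gene(rng, bases, d_len: int, v_len: int, anticodon: str):
    acc5 = (0, 7)
    d_arm = (7, 7 + 4 + d_len)  # 5' D-stem folded into the arm; 3' stem in spacer
    d_loop = (11, 11 + d_len)
    ac_arm = (d_arm[1], d_arm[1] + 17)  # 5 + 7 + 5
    ac_loop = (ac_arm[0] + 5, ac_arm[0] + 12)
    var_loop = (ac_arm[1], ac_arm[1] + v_len)
    t_arm = (var_loop[1], var_loop[1] + 17)
    t_loop = (t_arm[0] + 5, t_arm[0] + 12)
    acc3 = (t_arm[1], t_arm[1] + 7)
    n = acc3[1]
    seq = list(rng.choice(bases, size=n))
    seq[ac_loop[0] + 2 : ac_loop[0] + 5] = list(anticodon)
    landmarks = {
        "acceptor5": acc5,
        "d_arm": d_arm,
        "d_loop": d_loop,
        "ac_arm": ac_arm,
        "ac_loop": ac_loop,
        "var_loop": var_loop,
        "t_arm": t_arm,
        "t_loop": t_loop,
        "acceptor3": acc3,
    }
    return seq, landmarks


# ---------------------------------------------------------------------------
# tRF reads

def simulate_trf_reads(
    trnas: list[TRNAGene], config: SimConfig
) -> tuple[list[tuple[str, int]], GroundTruth]:
    """Draw cleavage-biased tRF reads from a tRNA set.

    Returns collapsed reads ``(sequence, copy count)`` and a
    :class:`GroundTruth` listing every planted (tRNA, cleavage interval)
    fragment that received at least one read, labelled with its expected
    structural type from the region partition.  Reads are exact substrings
    of their source tRNA; intervals longer than 30 nt are clipped at the 3'
    end, intervals shorter than 18 nt are a configuration error.
    """
    config.validate()
    if not config.trf_cleavage_profile:
        raise ConfigError("trf_cleavage_profile is empty")
    rng = _rng(config, 2)
    profile = sorted(config.trf_cleavage_profile.items())
    for (s, e), _ in profile:
        if e - s < READ_MIN:
            raise ConfigError(f"cleavage interval ({s},{e}) shorter than {READ_MIN} nt")
        for g in trnas:
            if e > len(g):
                raise GenerationError(
                    f"cleavage interval ({s},{e}) exceeds {g.id} length {len(g)}"
                )

    depth = config.depth_per_library
    n_planted = int(round(depth * (1.0 - config.noise_fraction)))
    n_noise = depth - n_planted

    combos = [(g, s, min(e, s + READ_MAX)) for g in trnas for (s, e), _ in profile]
    probs = np.array(
        [
            p * (config.ala_bias if g.isotype == "Ala" else 1.0)
            for g in trnas
            for _, p in profile
        ],
        dtype=float,
    )
    probs /= probs.sum()
    counts = rng.multinomial(n_planted, probs) if n_planted > 0 else np.zeros(len(combos), int)

    from collections import Counter

    reads: Counter[str] = Counter()
    truth = GroundTruth()
    partitions = {g.id: partition_regions(g) for g in trnas}
    for (gene, s, e), c in zip(combos, counts):
        if c == 0:
            continue
        reads[gene.sequence[s:e]] += int(c)
        item_id = f"{gene.id}:{s + 1}-{e}"
        if item_id not in truth.weights:
            labels = classify_trf((s, e), partitions[gene.id])
            truth.trfs.append(PlantedTRF(item_id, gene.id, s, e, frozenset(labels)))
            truth.weights[item_id] = 0.0
        truth.weights[item_id] += int(c)

    for _ in range(n_noise):
        g = trnas[int(rng.integers(len(trnas)))]
        ln = int(rng.integers(READ_MIN, min(READ_MAX, len(g)) + 1))
        s = int(rng.integers(0, len(g) - ln + 1))
        reads[g.sequence[s : s + ln]] += 1

    collapsed = sorted(reads.items())
    return collapsed, truth


# ---------------------------------------------------------------------------
# phased reads

def simulate_phas_reads(
    reference: tuple[str, str], config: SimConfig
) -> tuple[list[tuple[str, int, str, int, int]], GroundTruth]:
    """Plant a phased 21-nt read ladder on a reference sequence.

    Returns alignment-style reads ``(ref id, start, strand, length, count)``
    and the planted locus truth.  Planted sense reads start at
    ``register + k * phase_len`` for ``k = 0 .. n_phase_cycles - 1``; when
    ``phas_antisense`` is set, matching antisense reads are planted 2 nt
    upstream (the Dicer 2-nt overhang convention).  Noise reads start
    uniformly over the reference on the sense strand.
    """
    config.validate()
    ref_id, seq = reference
    p = config.phase_len
    n_cycles = config.n_phase_cycles
    if n_cycles > 0 and len(seq) < p * n_cycles:
        raise GenerationError(
            f"reference {ref_id} ({len(seq)} nt) shorter than {p}*{n_cycles}"
        )
    rng = _rng(config, 3)
    truth = GroundTruth()
    from collections import Counter

    reads: Counter[tuple[str, int, str, int]] = Counter()
    depth = config.depth_per_library
    n_planted = int(round(depth * (1.0 - config.noise_fraction))) if n_cycles > 0 else 0
    n_noise = depth - n_planted

    if n_cycles > 0 and n_planted > 0:
        max_start = len(seq) - p * n_cycles
        s0 = int(rng.integers(0, max_start + 1))
        register = s0 % p
        item_id = f"{ref_id}_locus1"
        truth.phas_loci.append(
            PlantedLocus(item_id, ref_id, s0, "+", register, n_cycles)
        )
        truth.weights[item_id] = float(n_planted)
        per_cycle = rng.multinomial(n_planted, np.full(n_cycles, 1.0 / n_cycles))
        for k, c in enumerate(per_cycle):
            if c == 0:
                continue
            pos = s0 + k * p
            if config.phas_antisense and c >= 2:
                sense = int(c) - int(c) // 3
                anti = int(c) - sense
                reads[(ref_id, pos, "+", p)] += sense
                reads[(ref_id, pos - 2, "-", p)] += anti
            else:
                reads[(ref_id, pos, "+", p)] += int(c)

    for _ in range(n_noise):
        pos = int(rng.integers(0, len(seq) - p + 1))
        reads[(ref_id, pos, "+", p)] += 1

    collapsed = sorted((r, s, st, ln, c) for (r, s, st, ln), c in reads.items())
    return collapsed, truth


def random_reference(config: SimConfig, length: int = 2000, name: str = "chr1") -> tuple[str, str]:
    """A random nucleotide reference sequence, deterministic in the seed."""
    rng = _rng(config, 4)
    return name, "".join(rng.choice(np.array(list("ACGU")), size=length))


# ---------------------------------------------------------------------------
# two-condition libraries

def simulate_two_libraries(
    truth: GroundTruth, config: SimConfig
) -> dict[str, dict[str, int] | dict[str, float]]:
    """Draw per-item raw counts for the C1D and A1D libraries.

    The expected A1D count of item ``i`` is its C1D expectation times
    ``condition_effects.get(i, 1.0)``.  At ``dispersion == 0`` counts are
    multinomial, so they sum exactly to the library depth; at positive
    dispersion they are independent negative binomials with variance
    ``mu + dispersion * mu**2``.  miRNA reads are emitted only as a
    per-library scalar total (``mirna_depth_factor`` times the depth).
    """
    config.validate()
    items = truth.item_ids()
    unknown = set(config.condition_effects) - set(items) - {"miRNA"}
    if unknown:
        raise ConfigError(f"condition_effects for unknown items: {sorted(unknown)}")
    rng = _rng(config, 5)
    out: dict[str, dict] = {
        "C1D": {}, "A1D": {},
        "mirna_totals": {}, "depth": {},
    }
    mirna_base = int(round(config.depth_per_library * config.mirna_depth_factor))
    mirna_effect = config.condition_effects.get("miRNA", 1.0)
    out["mirna_totals"]["C1D"] = mirna_base
    out["mirna_totals"]["A1D"] = int(round(mirna_base * mirna_effect))
    if not items:
        out["depth"] = {"C1D": 0, "A1D": 0}
        return out

    w = np.array([truth.weights.get(i, 1.0) for i in items], dtype=float)
    if w.sum() <= 0:
        w = np.ones(len(items))
    mu1 = config.depth_per_library * w / w.sum()
    effects = np.array([config.condition_effects.get(i, 1.0) for i in items])
    mu2 = mu1 * effects

    for lib, mu in (("C1D", mu1), ("A1D", mu2)):
        depth = int(round(mu.sum()))
        out["depth"][lib] = depth
        if config.dispersion == 0.0:
            counts = (
                rng.multinomial(depth, mu / mu.sum()) if depth > 0 else np.zeros(len(mu), int)
            )
        else:
            d = config.dispersion
            counts = np.array(
                [
                    rng.negative_binomial(1.0 / d, 1.0 / (1.0 + d * m)) if m > 0 else 0
                    for m in mu
                ]
            )
        out[lib] = {item: int(c) for item, c in zip(items, counts)}
    return out
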