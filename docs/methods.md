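# Methods

`trfphas` implements a two-library small-RNA analysis for tomato-style
plant systems: identification and quantification of tRNA-derived fragments
(tRFs), detection of 21-nt phased secondary siRNAs (phasiRNAs), joint
normalization and exact-test differential expression between an untreated
control library (`C1D`) and an ABA-treated library (`A1D`), and
phasiRNA target prediction integrated with transcript expression status.
This note records the models, the defaults that matter, and the design
choices made where the procedure was genuinely open.

## tRNA anatomy and tRF source regions

A mature tRNA (72–90 nt) is represented by its cloverleaf landmarks:
acceptor stem (7 bp per side), D-arm (4-bp stem, 7–11-nt D-loop),
anticodon arm (5-bp stem, 7-nt loop), variable loop (4–23 nt) and T-arm
(5-bp stem, 7-nt loop). Landmarks come from tRNAscan-SE output (`.ss`
structure strings, bracket-matched into the four helices) or a simplified
TSV. Records whose landmarks cannot be inferred are reported, never
silently dropped.

tRFs are classified against five source regions derived from the
landmarks, in 0-based half-open coordinates:

| region | interval | rationale |
|---|---|---|
| 5e | `[0, d_loop.end − 2)` | ends at the third-from-last D-loop base; for an 11-nt D-loop this is exactly 20 nt, the canonical 5'-tRF length |
| D  | `[d_loop.start − 2, ac_arm.start + 2)` | D-loop plus flanks |
| A  | `[ac_arm.start − 2, ac_arm.end + 2)` | anticodon arm plus flanks |
| V  | `[var_loop.start − 2, t_loop.start + 2)` | variable loop **plus the 5' T-stem** |
| 3e | `[t_loop.start + 2, len)` | mirror of 5e, anchored 2 nt into the T-loop |

Only the 5e boundary is anatomically canonical; the interior boundaries
are this package's choices. The ±2-nt flanks create the junction overlap
zones that make dual classification possible. V deliberately extends
through the 5' T-stem rather than stopping 2 nt after the variable loop:
with a symmetric ±2 flank the T-stem would belong to no region, breaking
the invariant that the five regions cover the whole gene with at most two
regions per position. All boundaries are code-level constants of
`partition_regions` and the invariant is enforced (`RegionPartition.validate`).

## tRF calling

Reads (18–30 nt) are aligned to mature tRNAs as exact substrings — no
mismatches, multi-mapping preserved, reverse-complement hits excluded.
Calling works on pooled-library read-end profiles, FlaiMapper-style:

1. take the highest-support 5'-end position with ≥ `min_support` copies
   (default 2; ties leftmost);
2. collect reads whose 5' end lies within `end_tolerance` (default ±2 nt);
3. the modal 3' end among them fixes the fragment end (ties to the longer
   fragment, which preserves the dominant 20-nt boundary under symmetric
   end noise);
4. emit the candidate, mask its supporting reads, repeat.

A consequence of step 2 is that a minor end variant sharing a dominant
fragment's 5' end (e.g. a 22-nt variant of the 20-nt fragment) is absorbed
into the modal peak rather than called separately.

Classification: label L applies iff `|tRF ∩ region(L)| / |tRF| ≥ 0.75`
(the tRF's own length is the denominator). Two qualifying regions give a
dual label; none gives `others`. Quantification: a read counts toward a
tRF when at most 3 of its bases lie outside the tRF interval
(`max(0, trf.start − read.start) + max(0, read.end − trf.end) ≤ 3`); a
read satisfying this for several tRFs counts toward each. Peaks are called
on pooled libraries and quantified per library so both conditions share
one catalogue. tRFs below 2 RPM in both libraries are removed as noise;
detailed reporting further requires 10 RPM in at least one library.

## phasiRNA detection

A PHAS locus produces 21-nt siRNAs whose 5' ends share a residue class
(register) modulo the phase length p (default 21; 24 supported via
config). A sense read is phased iff `start ≡ r (mod p)`; an antisense
read iff `start + 2 ≡ r (mod p)` (Dicer 2-nt 3'-overhang convention).

Windows of 9 cycles (189 nt) slide in 1-cycle steps. For each register:
phased abundance `A_p`, total abundance `A_t`, occupied phased positions
`N_p`, ratio `R = A_p/A_t`, and the phased score

    score = N_p × R × ln(1 + A_p)

The combination is this package's choice: the published scoring systems
state the three components but not the formula. It is monotone in each
component and zero without phased signal. Windows need ≥ 4 occupied
phased positions to be scoreable; qualifying windows sharing a register
merge into loci; loci overlapping tRNA/rRNA annotations are excluded (the
classic false-positive sources). The calling threshold (default 12.0) was
calibrated once by simulation: over 200 uniform-noise runs (depth 2000 on
a 2-kb reference) the maximum best-window score was 3.7, while planted
loci at the hardest recovery condition tested (30% noise, 6 cycles, depth
500) score ≥ 31; 12.0 sits between with ~3× margin each way, and the
measured run-level false-positive rate on uniform noise is 0/100.

Each occupied phased position yields one phasiRNA (id style
`<ref>_<locus start, 1-based>_<position in precursor, 1-based>(<strand>)`);
its per-library count is the copy number of exactly-21-nt reads whose 5'
end and strand match the position exactly.

## Joint normalization and differential expression

tRF, phasiRNA and miRNA reads are normalized as a whole:
`RPM = count / N × 10⁶` with `N = Σ tRF + Σ phasiRNA + miRNA reads` of the
library. miRNA counts enter only through this denominator, so the
generator emits them as a per-library scalar.

The design is one library per condition, so significance uses the
Audic–Claverie exact test. Conditional on x counts in library 1 (total
N₁), the count y in library 2 (total N₂) follows

    p(y|x) = (N₂/N₁)^y (x+y)! / (x! y! (1+N₂/N₁)^(x+y+1)),

the negative binomial NB(x+1, N₁/(N₁+N₂)). The two-sided p doubles the
smaller inclusive tail, capped at 1. The textbook doubled-tail is not
symmetric in the two libraries; because the pipeline treats the libraries
exchangeably, the default symmetrizes by taking the smaller tail over both
conditioning orientations (a config flag restores the one-orientation
form). Tails are summed in log space (`lgamma`), the upper tail truncated
12 standard deviations past both y and the distribution bulk; agreement
with exact-rational summation is ≤ 4 × 10⁻¹³ relative over x, y ≤ 200 and
N₂/N₁ ∈ {½, 1, 2}.

Tiers use the fixed cut-offs: responsive (up/down) at |log₂FC| ≥ 0.25 and
p < 0.05, significant additionally at |log₂FC| ≥ 1, unchanged at
|log₂FC| < 0.25; items passing the fold-change but not p are reported as
non-responsive rather than folded into unchanged. Items expressed in only
one library keep their infinite fold change and are classified by sign
with significance from p alone (a configurable pseudocount, default off,
avoids this); both-zero items are unchanged. No multiple-testing
correction is applied to the tiers (matching the raw p < 0.05 design); a
Benjamini–Hochberg q column is emitted for transparency.

## Target prediction

A phasiRNA is scored against every window of every transcript by
Smith–Waterman local alignment of the sRNA against the reverse complement
of the window, with miRanda-style weights: Watson–Crick +5, G:U wobble +1,
mismatch −3, gap open −9, gap extend −4, substitution scores ×4 over sRNA
positions 2–8 (gap penalties unscaled). A perfect 21-nt duplex scores
4×(7×5) + 14×5 = 210. Windows are `len(sRNA) + 3` nt at every start;
overlapping hits keep the best score.

Duplex free energy is the sum of nearest-neighbor stack energies over
consecutive paired columns, from a packaged 21-entry table (canonical pair
stacks at 37 °C; the Watson–Crick entries are the standard Turner-style
values, the G:U entries are representative mid-range values — every use of
the table is oracle-checked by independent summation, so the gate logic
does not hinge on the exact wobble numbers). The duplex initiation term
defaults to 0 (stacking energy only) so that energy decreases
monotonically as stacks are appended and any paired duplex is ≤ 0;
a physical initiation penalty can be configured.

The conventional gates carried as defaults (score ≥ 500 and
ΔG ≤ −50 kcal/mol) are kept for fidelity but are unreachable for 21-nt
duplexes under these weights (a perfect duplex scores 210; −50 kcal/mol
requires a GC-rich perfect duplex). Desk-scale analyses and recovery tests
therefore use calibrated gates (score ≥ 100, ΔG ≤ −10), stated wherever
used. Target-site conservation across related genomes is not evaluated;
sites carry a placeholder conservation field.

## Integration

Transcript status across conditions: undetected if both FPKM < 0.1;
elevated/decreased at |log₂ FC| ≥ 0.585 (1.5×); else unaltered. These two
thresholds are this package's defaults (the upstream transcriptome
criteria are external to it) and are config keys; fixture-based checks
consume printed status columns directly rather than recomputing them.

The report joins responsive phasiRNAs with passing target sites and
transcript statuses into one row per (phasiRNA, target family), counting
distinct target genes (dot-versioned transcript ids collapse to genes)
and detected transcripts by status; undetected transcripts are excluded
from the counts and a symmetric map records transcripts shared between
phasiRNAs. Per-direction abundance sums deduplicate phasiRNAs across
family rows — a phasiRNA targeting three families is summed once. Class
shares are percentages of the combined miRNA + tRF + phasiRNA RPM total
per library, rounded to two decimals for reporting.

## Synthetic data: what it emulates and what it does not

The generator plants: random-sequence tRNAs with valid cloverleaf
landmarks (every fourth is a tRNA-Ala with an 11-nt D-loop, 5'-terminal G
and a U at the 20-nt fragment boundary; Ala draws cleavage reads with a
4× bias, making the 20-nt Ala 5'-tRF dominant); cleavage-biased reads
(default 90% `[0,20)`, 10% `[0,22)`); a 21-nt phased ladder at a random
register; uniform background noise; and two-condition counts with
multiplicative effects (multinomial at dispersion 0 — totals exactly equal
the depth — negative binomial with variance μ + d·μ² otherwise; NB is the
standard sequencing count model, the study itself states none). Default
problem sizes, chosen as desk-scale stand-ins for a real sRNA experiment:
8 tRNAs, 20 000 sRNA reads per library, miRNA totals 5× the sRNA depth,
10% noise, one PHAS locus of 8 cycles on a 2-kb reference.

Not emulated: adapter/quality artifacts and sequencing error (alignment is
exact-match by design, so error would only shrink depth), real tomato
sequence composition and genome-scale multi-mapping, miRNA-triggered
phasing biogenesis, replicate structure (the Audic test's one-library
design is the point), and isoform complexity in the transcript table.
Passing recovery tests therefore demonstrates the correctness of the
calling/scoring machinery under the stated noise models, not performance
on real libraries.

## Numerical and degenerate-input choices

- Coordinates: 0-based half-open everywhere internally; 1-based inclusive
  in ids and human-facing tables.
- Peak-calling ties: leftmost 5' peak, longer fragment at the 3' end.
- Alignment tie-break: leftmost site on the reverse-complemented window,
  then shortest; traceback prefers substitution continuation.
- The 75% rule compares `overlap/length ≥ 0.75` in floating point; with
  interval lengths ≤ 90 the comparison is exact at the boundary (the only
  representability-critical case, 4·overlap = 3·length, is a dyadic
  rational).
- `A_t = 0` windows score 0; empty profiles yield empty candidate lists;
  an empty transcriptome or empty report logs a warning and returns empty
  results rather than raising.
- Determinism: every stochastic step derives its generator from the config
  seed plus a fixed per-stage salt; identical configs give byte-identical
  outputs and identical run-manifest hashes.

## Known limitations

- The interior region boundaries (D/A/V flanks) are conventions; real
  anatomical assignments differ between tRNAs and classification near
  junctions depends on the ±2-nt choice.
- The phased score formula and its threshold are package choices;
  locus counts from other scoring systems are not comparable.
- The energy model is stack-only (no loop, bulge or dangling-end terms);
  it orders duplexes sensibly but is not a folding-grade ΔG.
- External-file mode of the pipeline validates paths and parses the
  supported formats but the end-to-end drivers target the synthetic and
  fixture modes; genome-scale inputs are out of scope.
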