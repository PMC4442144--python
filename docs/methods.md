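# Methods

This note records the models behind each module, the parameters that
matter, what the synthetic data does and does not emulate, and the design
choices made where more than one reasonable option existed.

## Duplex thermodynamics (`thermo`)

Melting temperatures and hybridization free energies use the unified
DNA/DNA nearest-neighbor parameter set (Allawi & SantaLucia 1997): ΔH/ΔS
sums over dinucleotide stacks plus terminal initiation terms (A·T vs G·C
termini), a symmetry entropy for self-complementary sequences, and the
entropic monovalent-salt correction ΔS += 0.368·(N−1)·ln[Na⁺]. Two-state
Tm uses total strand concentration C_T with x = 4 (non-self-complementary)
or 1; ΔG(T) = ΔH − T·ΔS. Defaults: 50 mM Na⁺, 500 nM total oligo, ΔG
reported at 37 °C. The parameter table ships as a plain-text resource and
is swappable via `DuplexParams.parameter_table_id` (e.g. for DNA:RNA
hybrid tables); all design decisions in this toolkit are
threshold-relative, so any consistent monotone parameter set preserves the
algorithms' behavior. The implementation agrees with
`Bio.SeqUtils.MeltingTemp.Tm_NN` (DNA_NN3, same conventions) to <1e-6 °C;
the test suite also carries an independent hand-summation oracle.

Two deliberate simplifications:

* **Mismatches** contribute a single uniform destabilization penalty
  (default +1.0 kcal/mol) per affected stack instead of the full
  internal-mismatch tables. The screen only uses ΔG *gaps* between highly
  similar sequences, where a uniform penalty ranks competitors the same
  way.
* **Tm is not monotone in duplex length.** Appending a weak A·T stack whose
  characteristic temperature lies below the current duplex Tm lowers the
  Tm slightly — a real property of the nearest-neighbor model, not a bug.
  Stability in ΔG, by contrast, is strictly monotone (every added stack is
  negative at 37 °C even after the salt correction), and that is the
  invariant the property tests assert.

No dangling-end or divalent-salt corrections, and no secondary-structure
prediction of the looped-out RNA.

## Ligamer design (`design`)

*Terminal arms* are anchored at the junction they must abut and trimmed
from the far end until Tm ≤ `tm_max` (65 °C); the returned arm is the
longest anchored arm at or below the ceiling (an arm whose full region
still melts below the ceiling is returned whole with an `exhausted` flag,
and a `low_tm` flag marks arms below `tm_floor` = 40 °C). *Internal arms*
are anchored at the two ends of their target piece and trimmed from the
inside outward; each arm must land in `arm_tm_target ± arm_tm_tolerance`
(60 ± 5 °C) and the assembled oligo (arms + barcode) must stay ≤ `max_len`
(60 nt). Where several (len_up, len_down) pairs qualify, the tie-break is
lexicographic — longest upstream arm, then longest downstream arm — making
design fully deterministic; the tests verify it against exhaustive
enumeration of the feasible set.

Pool planning covers a gene model with exactly 2 + (number of variant
exons) + (number of separating constitutive blocks) ligamers. Skip
outcomes (exon exclusion, the V0 acceptor) add no ligamer: the flanking
ligamers simply become adjacent on those isoforms, mirroring how
exon-excluded isoforms need fewer ligation events. Barcodes are drawn by
seeded rejection sampling (pairwise Hamming ≥ 3, no homopolymer > 3,
unique across the pool — uniqueness across the whole pool, not just within
a cluster, keeps decoding anchored). A per-ligamer barcode-length override
supports product-length tuning (gel-readout designs); the dual-pool
constructor recodes all internal ligamers by default so that every
cross-molecule junction is visible (a subset can be recoded instead, at
the cost of blind junctions).

The specificity screen replaces a genome-scale alignment with a
deterministic exact/1-mismatch substring search of every arm against a
covering transcript set, plus an all-pairs free-energy comparison within
each cluster: `gap` = (nearest near-cognate ΔG) − (cognate ΔG), flagged
below `dg_gap_min` (default 5 kcal/mol). Absolute ΔG values depend on the
parameter set; only gaps are interpreted.

**Orientation convention.** Arms and products are stored transcript-sense
(an arm string equals its footprint on the isoform); the synthesized oligo
is the reverse complement, emitted in the order sheet's
`synthesis_sequence` column. Tm/ΔG are invariant under the exchange and
the decoder tries both orientations, so no behavior depends on it.
Coordinates are 0-based half-open, local to the named region/variant
piece.

## Product index (`index`)

An isoform key is the `|`-joined list of chosen variant ids in transcript
order. The index holds one record per isoform: the ligamer chain is
derived from footprint positions (consecutive footprints must abut
exactly), verified against the pool's adjacency relation, and
concatenated. `rna_span` runs from the first to the last hybridized base
on the isoform — loops inside ligamers count, primer tails (never
hybridized) do not. Variants can carry an `excluded` flag so both the full
(e.g. 12 × 48 × 33 = 19,008) and reduced (12 × 47 × 33 = 18,612,
pseudo-exon dropped) spaces are constructible from one model; the index
can be built over either.

## Synthetic data (`simulate`)

The generator emulates the assay's control experiments:

* **Gene models.** Clusters of variant exons derived from a cluster
  consensus: each position keeps the consensus base with probability *s*
  (`similarity`) and is drawn uniformly otherwise, giving expected pairwise
  identity s² + (1−s²)/4 — 0.25 for independent sequences, 1.0 for
  identical ones. Defaults (150-nt variant exons, 200-nt separating
  blocks, s = 0.8) reflect cassette-exon architectures where duplicated
  variants are highly similar and the looped-out blocks are long, which is
  what makes >2-fold compression and near-cognate binding realistic
  features. Pieces are drawn so that both termini are designable (an
  in-window arm of ≤ 23 nt exists), emulating targets that passed probe
  design; composition elsewhere is unconstrained.
* **Mixtures** are multinomial draws over supplied isoform weights (the
  quantitative controls use 100:10:1).
* **Ligation artifacts.** With probability `switch_rate` a product is a
  chimera: one crossover at a uniformly chosen *separating constitutive
  block* (the shared-sequence context where template exchange actually
  happens), suffix chain from another molecule — from the other pool in a
  dual-pool run, since the differential-coding control mixes the two
  reactions before amplification. With probability `near_cognate_rate`
  one variant ligamer is replaced by its nearest near-cognate sibling
  (minimum arm-ΔG against the true exon). A near-cognate product is
  *sequence-identical* to the wrong isoform's cognate product — the
  physical oligo carries its own arms and barcode — so it is per-read
  indistinguishable and is quantified through the truth ledger, not the
  decoder (see below).
* **Reads.** 250-nt paired ends: mate 1 the product's 5′ prefix, mate 2
  the reverse complement of its 3′ suffix, overlapping whenever the
  product is shorter than 500 nt (all planned products are). Substitution
  errors are i.i.d. at `per_base_error`; qualities are constant and no
  indels are modeled, matching the substitution-tolerant decoder's scope.

Every product appears in a truth ledger (true isoform, pool, artifact
class), so decoders are validated read-by-read. What the generator does
*not* emulate: PCR amplification bias, position-dependent error profiles,
ligation-efficiency differences between chain lengths, and the
concentration dependence of trans hybridization (the switch rate is a free
parameter, not a physical model) — so passing tests demonstrate decoding
and statistics on idealized libraries, not robustness to those real-data
effects.

## Decoding (`decode`)

Mates are merged via their overlapping 3′ ends: the overlap maximizing
matching bases with mismatch fraction ≤ 10% and length ≥ 10 wins, overlap
conflicts resolve in favor of mate 1, and the conflicting positions are
recorded as low-confidence (exactly one mate erred there). Merged reads
are parsed left-to-right as ligamer chains — each segment verified against
the catalog within `max_mismatch_per_segment` (default 2, not counting
low-confidence positions), successors constrained by pool adjacency, both
orientations tried. Statuses are mutually exclusive:

* `assigned` — exactly one consistent isoform;
* `ambiguous` — multiple consistent chains (or conflicting orientations);
* `switched` — the parse mixes informative barcodes of both pools;
* `near_cognate` — the chain parses only when one segment pairs the
  barcode of variant Y with the arms of sibling X (the barcode/arm
  inconsistency signature); such hybrid reads are flagged, never silently
  merged into a count;
* `unassigned` — no decomposition, including mate pairs that fail to
  merge (the loss is explicit rather than silently dropped).

This barcode-anchored parse replaces free local alignment plus a
mapping-quality cutoff: it is deterministic, and the uniqueness
requirement plays the same role as the quality filter (discard anything
not uniquely explained). Counts cover assigned reads only; all statuses
sum to the input read-pair count.

## Coordination statistics (`stats`)

Marginal exon use per cluster is the assigned-read fraction containing
each variant. Expected combination frequencies under the no-coordination
null are products of marginals (pairwise or three-way); a complete
combination set sums to 1 and three-way expectations marginalize exactly
onto the pairwise ones. Each combination's observed count is tested with
an exact two-sided binomial test at n = total assigned reads, with
Benjamini–Hochberg q-values and flags at q ≤ 0.05. The expected values
here are deterministic functions of the observed marginals, so a
calibrated exact test is used rather than a two-condition count-dispersion
model; output frames carry this note in `DataFrame.attrs`, and simulation
under the null keeps the any-flag rate at or below the nominal level.
Combinations with expected count < 1 are tested but annotated
`low_power`. Replicate agreement is Pearson correlation of
log(count + 1) over the key union with a Fisher z-transformation p-value
(r is clipped inside (−1, 1) so p stays in (0, 1]).

## Problem sizes

The shipped tests and the acceptance script run entirely on synthetic
data at desk scale, chosen to exercise every code path in minutes on one
CPU: full 97-ligamer pool design and 19,008-product indexes for the
three-cluster architecture; decoding batteries of 10,000 reads (switch
control) and 50,000 reads (100:10:1 recovery) on a three-cluster,
eight-isoform model; 30-seed zero-error and 6-seed 0.5%-error decoder
batteries; 500-replicate null simulations for FDR control. Results that
require the original biological libraries (detected-isoform tallies,
replicate r values, flagged-combination counts on embryo samples) are out
of scope for these synthetic runs.
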