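# Methods

This note documents the models implemented in `aroscan`, the parameter
choices that matter, the numerical decisions taken where the design was
genuinely open, and what the synthetic-data tests do and do not show.

## Stickers, spacers, coordinates

Aromatic residues F, Y and W are treated as stickers; a spacer is the run
of non-aromatic residues strictly *between* two consecutive stickers
(adjacent stickers have spacer 0). Terminal flanks before the first and
after the last sticker are not spacers. All user-facing coordinates are
1-based inclusive residue positions; the BED export converts bit-exactly
to 0-based half-open. Ambiguity codes (B, J, O, U, X, Z) are rejected at
parse time rather than coerced — a silently substituted residue would
corrupt every patterning statistic downstream.

The "small inert" residue set used by the sticker-adjacency metric
defaults to {A, G, S}. The field has no canonical definition of this set,
so it is an explicit, configurable parameter rather than a constant.

## Periodic blocks and the periodicity score

A periodic block is a maximal run of ≥ 4 stickers whose internal spacers
all lie in one class: A = 4–9, B = 10–20, C = 21–30 residues (ranges from
stickers-and-spacers modelling of associative polymers). Detection is per
class and homogeneous: a run mixing classes (spacers 5, 15, 5) yields no
block, spacers < 4 or > 30 break runs for every class, and sub-runs of a
maximal run are never emitted — so "number of blocks" is well defined for
the score. Blocks of different classes may overlap. Blocks are called on
the full protein and then intersected with IDR intervals (≥ 1 shared
residue), not re-called inside clipped subsequences; clipping would
truncate spacers at the interval edges and change calls.

The per-protein periodicity score is 1.0·n_A + 1.1·n_B + 1.2·n_C over
IDR-overlapping blocks. The increasing weights encode that long uniform
spacing is less likely to arise by chance; they are convention, not
fitted. Ranking is by descending score with deterministic tie-breaks
(total stickers in blocks, then protein id), so output tables are
byte-stable under input permutation.

## Omega

The sequence (or span) is binarised, aromatic = 1. For blob windows of
size g at step 1, the window asymmetry is σᵢ = (f₁ᵢ − f₂ᵢ)² with
f₂ = 1 − f₁; δ is the mean squared deviation of σᵢ from the whole-span σ,
and Ω = δ/δ_max. This is the two-group restriction of the charge-patterning
κ statistic, applied to the aromatic/other partition. Proline is not
grouped with the aromatics.

**Blob size.** Ω is not length-normalised at fixed g, so g adapts to
composition: g = round(L / n_aro) — the mean inter-sticker spacing —
clamped to [2, L − 1]. Dividing the length by the aromatic *fraction*
instead (L²/n) exceeds the sequence length for every sequence and
clamps uselessly; it remains selectable (`blob_rule="literal"`) for
comparison but is not the default. Spans need ≥ 3 aromatics; Ω is
undefined (refused) below that or for all-aromatic spans.

**Normalisation.** δ_max is the δ of the most segregated arrangement of
the same composition: a single contiguous cluster of the minority species,
maximised over its placement along the span. Two details matter. First,
σ is symmetric under complementing the mask, so for (pathological) spans
that are majority-aromatic the cluster is formed of the non-aromatics.
Second, the placement maximum is required because edge windows cover a
terminal cluster less often than a central one; when g exceeds the cluster
width, N-terminal segregation alone under-normalises and Ω could exceed 1
(for L = 58, n = 3, g = 19 a central cluster scores ~1.6 against the
terminal reference). With the placement maximum, exhaustive enumeration
(all arrangements, L ≤ 16, minority ≥ 3, adaptive g) and 20,000 random
realistic masks (L ≤ 400, aromatic fraction ≤ 0.5) show Ω ∈ [0, 1]
throughout, with Ω = 1 attained exactly by the optimal contiguous cluster.
Outside the domain of use — a manually forced g ≳ L/2, or aromatic
fractions above ~0.85 — no simple constructive family bounds δ, and Ω can
exceed 1 there; the same caveat is documented for the reference κ
implementations.

**Null.** The empirical P is the fraction of n_shuffles (default 1,000)
composition-preserving shuffles whose Ω is *strictly lower* than observed
(a low P means unusually uniform dispersion). The generator is a named,
seeded PRNG recorded in every result; the shuffle batch is vectorised and
bit-reproducible. Under Bernoulli masks the empirical P is approximately
uniform (the calibration test bounds the sub-0.05 rate in [0.02, 0.10] at
500 masks).

## The K–S periodicity scan

Under independent aromatic occurrence at rate p, spacers are geometric on
{0, 1, 2, …}: F(s) = 1 − (1−p)^{s+1}, mean (1−p)/p. Each 100-residue
window (step 1) is tested: p is the within-window aromatic proportion,
spacers count only when both flanking stickers are inside the window, and
D = sup over the integer support of |empirical CDF − geometric CDF|, with
the two-sided P from the standard one-sample K–S tail at n = spacer count
(`scipy.stats.kstwo`). Using the continuous-null tail on discrete data is
conservative; the calibration tests quantify this (sub-0.05 window rate
≤ 7% on truly geometric spacers, per-protein significant-region rate
≈ 0.5–1.5% against the 5% bound). Windows with < 2 complete spacers or a
degenerate aromatic proportion are skipped and break window runs. The test
is two-sided, so strong clustering can be flagged as well as regularity.

Regions: the threshold is 0.5 × the mean window P *of that protein*
(a proteome-wide threshold can be passed explicitly); maximal runs of
consecutive tested windows strictly below it merge into regions spanning
first window start to last window end. Because spans extend a full window
past the last sub-threshold start, runs separated by fewer than 100
residues can produce overlapping spans; these are merged (min-P and best
window carried over) so regions are disjoint and ordered. A region is
significant when its best (argmin-P, first on ties) window contains ≥ 5
aromatics and min P ≤ 0.01; all raw regions are emitted alongside the
significant flag so both filters can be audited.

## Designers

All designs are substitutions or permutations confined to the target
region — no indels — so flanking domain coordinates are preserved. Every
variant carries an edit log whose application to the parent reproduces the
variant exactly (tested property).

- **AroLITE**: every regional F/Y/W → one of A/G/S. An aromatic-free
  region yields an identity variant with a warning, and the variant's Ω
  is undefined afterwards (flagged, not faked).
- **AroPERFECT**: native aromatics move to targets
  tᵢ = round((i − 0.5)·L/n) (region-local), keeping N→C order; displaced
  non-aromatics backfill in order, so the residue multiset is conserved.
  Rounding is half-up: banker's rounding at exact .5 ties produces
  alternating 3/5 spacers and breaks the evenness guarantee (consecutive
  output spacers differ by ≤ 1), which half-up restores. Collisions shift
  right to the next free slot.
- **AroPERFECT IS-k**: sticker slots at ceil((k+1)/2), then every k+1
  residues — exactly k non-aromatics between stickers, near-equal end
  margins. Native aromatics fill slots in order; shortfalls are topped up
  with tyrosine; surplus natives are converted to alanine at their
  original relative position and logged. When tyrosines are added the
  non-aromatic fill overflows by the same count and the C-terminal
  overflow is dropped (as substitutions); the sequence length never
  changes. Neither the surplus nor the shortfall case is standardised in
  the literature; both are explicit here.
- **AroPLUS**: every spacer s > max_spacer (default 15; terminal flanks
  bounded by the region edges count as spacers, so an aromatic-free
  region is one long flank) receives m = ceil((s+1)/(max+1)) − 1 tyrosine
  substitutions — the minimum bringing all sub-spacers ≤ max — placed for
  near-equal splits, left-biased on remainders. Native stickers are never
  touched. Minimal even splitting was chosen over recursive bisection
  because it introduces the fewest aromatics for a given spacer cap.
- **Shift**: every sticker swaps with the occupant of position + offset,
  processed N→C for negative and C→N for positive offsets so swaps never
  cascade; out-of-region targets raise with the offending stickers listed.
- **Scramble**: sticker positions are redrawn uniformly over all C(L, n)
  position sets from a seeded generator; letter order and composition are
  conserved. Uniformity is tested by chi-square against exact enumeration
  on a coarsened partition.
- **Tile**: fixed 40-residue tiles at 20-residue steps; an incomplete tail
  is dropped with a warning. Tiles are extractions (empty edit log), the
  one designer that does not preserve length.

## Synthetic data

The generator emulates the statistical structure the analyses assume, not
the biology of any real proteome. Background (non-sticker) residues are
i.i.d. from a disorder-like composition — G/S/P/Q/N/A-rich, charge- and
hydrophobe-depleted, aromatic-free (documented package constants, chosen
once as a plausible disordered-region profile). Sticker letters are drawn
F/Y/W ≈ 0.40/0.45/0.15. Sticker placement models: `bernoulli(p)` (default
p = 0.08, a typical disordered-region aromatic density; realises the
geometric-spacer null), `fixed(k, jitter)` (default k = 10, 20 stickers —
the idealised periodic signal), `clustered` (contiguous runs, the
segregated extreme). Default protein length is 400 residues so a 100-
residue window scan has ~300 windows per protein. IDR intervals cover the
sticker span for positives or exclude it for negative controls; a TF
subset is drawn at rate 0.3. Everything is generated from
`numpy.random.default_rng` seeded per cohort, and identical config + seed
gives byte-identical files.

What passing on this synthetic data shows: correct implementation of the
statistics, calibration of the scan against its own null, and power
against the idealised signal. What it does not show: performance on real
proteomes, where composition varies along sequences, disorder predictions
carry their own errors, and periodicity is partial — real-data counts
additionally depend on the predictor and database versions used for the
annotations, which is why the replicate harness reports diffs rather than
asserting equality.

## Problem sizes and determinism

Test and acceptance runs use sizes chosen to exercise each claim at
meaningful statistical resolution: exhaustive block-caller checks over all
{F,G} sequences to length 14 and all class-boundary spacer vectors to
length 4 (every behaviourally distinct run layout), plus 1,000 random
60-mers; 1,000 random K–S windows against the direct-recount oracle;
the full C(12,3) omega enumeration; 300 null proteins per aromatic density
(0.05 / 0.08 / 0.12) for the false-positive bound and 50 fixed-spacing
proteins for sensitivity; 500 Bernoulli masks for empirical-P calibration.
Every stochastic step takes an explicit seed, and the pipeline writes
sorted, schema-stable tables — rerunning with identical inputs and seeds
reproduces every table byte for byte, including the 1,000-shuffle omega
null.

## Known limitations

- Ω is meaningful only for minority-aromatic spans; for aromatic fractions
  above ~0.5 the complement symmetry governs, and above ~0.85 the
  normalisation family no longer bounds δ (see above).
- The K–S scan's continuous-null tail makes it conservative on discrete
  spacers; absolute P values are upper bounds, and the per-protein
  threshold (0.5 × mean window P) makes region calls relative within each
  protein.
- Replicating published proteome-scale counts requires externally pinned
  inputs (proteome build, TF database, disorder predictor version); block
  and region counts are sensitive to IDR boundary choices, which this
  package consumes but does not produce.
- The designers make no claim about the *activity* of designed variants;
  they guarantee only the stated sequence-level contracts.
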