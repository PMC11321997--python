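# aroscan

Quantifying the patterning of aromatic residues in intrinsically
disordered protein regions (IDRs), and designing sequence variants that
change that patterning.

## The problem

In the stickers-and-spacers view of disordered regions, aromatic residues
(F, Y, W — the "stickers") drive multivalent interactions, and the lengths
of the non-aromatic "spacers" between them set the region's material
behaviour: uniformly dispersed stickers favour liquid-like multivalent
binding, while clustered stickers favour segregation and aggregation.
Transcription-factor IDRs, prion-like domains and other low-complexity
regions differ systematically in this dispersion, and engineered variants
that redistribute the same aromatics can change a protein's condensation
and activity without altering its composition. `aroscan` provides the
sequence-level toolkit for this style of analysis:

- **Periodic block calling** (`aroscan.blocks`) — maximal runs of ≥ 4
  stickers whose spacers all fall in one length class (4–9, 10–20 or
  21–30 residues), intersected with IDR annotations and summarised as a
  weighted periodicity score per protein,
  score = 1.0·n_A + 1.1·n_B + 1.2·n_C.
- **Omega dispersion score** (`aroscan.omega`) — the sequence is binarised
  (aromatic = 1) and scanned with a blob window of size
  g = round(L / n_aro); with window sticker fraction f₁ and
  σᵢ = (2f₁ᵢ − 1)², the score is
  Ω = δ / δ_max where δ = meanᵢ(σᵢ − σ)², normalised by the maximally
  segregated arrangement of the same composition. Ω → 0 for uniform
  dispersion, 1 for full segregation. Significance comes from a seeded
  composition-preserving shuffle null: the empirical P is the fraction of
  shuffles with a *lower* Ω than observed.
- **K–S periodicity scan** (`aroscan.ksscan`) — under Poisson (Bernoulli)
  sticker placement at rate p, spacer lengths are geometric on {0, 1, …}
  with CDF F(s) = 1 − (1−p)^{s+1}. Every 100-residue window is tested by a
  one-sample Kolmogorov–Smirnov statistic against this expectation (p
  estimated within the window); runs of windows below half the protein's
  mean window P merge into regions, significant when the best window holds
  ≥ 5 aromatics and min P ≤ 0.01.
- **Mutant designers** (`aroscan.design`) — AroLITE (aromatics → A/G/S),
  AroPERFECT (uniform redistribution), AroPERFECT IS-k (exact spacing k,
  tyrosine top-up), AroPLUS (tyrosines split spacers > 15), pattern
  shifts, seeded scrambles, and 40-residue/20-overlap tiling — all pure
  substitutions/permutations with machine-readable edit logs.
- **Synthetic proteomes** (`aroscan.synthetic`) — seeded generators with
  ground-truth labels (Bernoulli/geometric null, fixed spacing, clustered)
  for calibration and power analysis.
- **Pipeline** (`aroscan.pipeline`, `aroscan` CLI) — the full flow with
  manifests, deterministic tables, and a replicate harness for pinned
  external proteome/TF/IDR inputs.

## Worked example

```python
from aroscan import ProteinRecord, omega_for_record

uniform    = ProteinRecord("uniform", "GSPQNGSPQF" * 10)        # F every 10
segregated = ProteinRecord("segregated", "F" * 10 + "GSPQN" * 18)

for rec in (uniform, segregated):
    res = omega_for_record(rec, n_shuffles=1000, seed=0)
    print(f"{rec.id:10s} omega = {res.omega:.3f}  "
          f"mean shuffle omega = {res.mean_random:.3f}  "
          f"empirical P = {res.empirical_p:.3f}")
```

prints

```
uniform    omega = 0.000  mean shuffle omega = 0.504  empirical P = 0.000
segregated omega = 0.942  mean shuffle omega = 0.512  empirical P = 0.998
```

The perfectly spaced arrangement is maximally mixed (Ω = 0; no random
shuffle of the same composition disperses better, so empirical P = 0),
while the clustered arrangement sits near the segregation maximum and
virtually every shuffle beats it. The `examples/` directory holds one
short narrative script per capability (block calling, omega, the K–S
scan, the designers, the full pipeline); each prints the numbers it
computes and a line on how to read them.

A command-line front end mirrors the library:

```bash
aroscan simulate --n-null 150 --n-periodic 50 --seed 1 --out sim/
aroscan run --fasta sim/proteome.fasta --idr sim/idr.tsv --tfs sim/tfs.tsv \
            --seed 1 --out run/
```

## Layout

```
src/aroscan/      seqcore, blocks, omega, ksscan, design, synthetic,
                  pipeline, cli
tests/            pytest suite with independent brute-force oracles
examples/         one narrative script per capability
docs/methods.md   models, parameter choices, numerical decisions, limits
scripts/          acceptance.py
```
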