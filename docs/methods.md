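# Methods

## Problem and model

An allele-specific siRNA (ASP-siRNA) is a 19-nt antisense guide designed
against a point mutation. Loaded into RISC it base-pairs with the mutant
mRNA perfectly and with the wild-type mRNA with exactly one mismatch, at the
guide position complementary to the variant. Designing a good ASP-siRNA
therefore means jointly optimizing two efficacies: inhibition of the mutant
allele (Eff_mut, to be maximized) and inhibition of the wild-type allele
(Eff_wild, to be minimized). The package predicts them with two tiers:

* **Tier 1 (Eff_mut)** — ε-support-vector regression with an RBF kernel on
  sequence-derived features of the guide, trained on tables of
  (guide, percent inhibition, target gene).
* **Tier 2 (Eff_wild)** — a multiplicative retention matrix:
  `Eff_wild = Eff_mut × R(p, g:t)` with `R ∈ [0,1]` indexed by the guide
  position `p ∈ 1..19` of the mismatch and the ordered guide:target base
  pair `g:t` (12 non-Watson-Crick pairs). The multiplicative rule guarantees
  `Eff_wild ≤ Eff_mut` and degrades gracefully at `Eff_mut = 0`; an
  absolute-efficacy mode (`Eff_wild = 100 × R`) is available as a config
  switch for matrices that store absolute efficacies rather than modifiers.

The candidate ranked first is the one maximizing the discrimination score
`Eff_mut − Eff_wild`.

## Coordinate and alphabet conventions

Sense-mRNA coordinates are 0-based half-open internally; all user-facing
reports are 1-based inclusive. Guide positions are 1-based 5'→3' on the
antisense strand, and guide position 1 pairs with the 3'-most base of the
19-nt sense window; hence a variant at sense offset `v` paired at guide
position `p` gives a window starting at `v − (19 − p)`. The "19 locations"
of a variant are counted on the guide strand (an assumption; the counting
strand is not fixed by convention in the field). The internal alphabet is
RNA; DNA input is accepted with T→U. G:U wobble pairs are classified as
mismatches in guide:target clash typing — the matrix tier penalizes any
non-Watson-Crick apposition — but count as base pairs in the structure
fold, where wobble pairing is standard.

## Features

| id | encoding | dim |
|----|----------|-----|
| m, d, t, tt, p | overlapping k-mer frequencies, k = 1..5, lexicographic over (A,C,G,U), normalized to sum 1 | 4, 16, 64, 256, 1024 |
| binary | 19 position blocks × 4 one-hot slots (A,C,G,U) | 76 |
| thermo | 18 nearest-neighbor stacking ΔG°37 of the guide:target duplex + total ΔG + 5'-terminal (first 4 steps) + 3'-terminal (last 4 steps) sums | 21 |
| struct | per-position paired flags from a Nussinov base-pair-maximization fold of the guide (min hairpin loop 3, ties resolved toward fewer pairs, deterministic traceback) | 19 |

Compositions are frequencies rather than raw counts so mixed-k hybrids stay
commensurate. Hybrid recipes concatenate components in order; the deployed
regressor uses `m+d+t+tt+binary` (416 dims). The thermodynamic parameter
set is the Xia et al. (1998) RNA/RNA Watson-Crick table, shipped as a
versioned TSV (`asirna/data/nn_rna_xia1998.tsv`); an alternative table can
be pointed to in code. The 18+1+1+1 split of the thermodynamic block and
the paired-flag definition of the structure block are this package's
definitions, chosen to match the conventional dimensionalities (21 and 19)
of these feature families; both sit behind encoder ids so alternates can be
swapped without touching the model tier.

## Model tier

Features are standardized (zero mean, unit variance, fitted on training data
only, inside a scikit-learn `Pipeline`) before the SVR — otherwise the
1024-dim pentanucleotide block would drown the 4-dim mono block. Efficacies
are regressed directly on the 0–100 scale and predictions clamped to
[0, 100]. Default hyperparameters are `C = 10`, `gamma = "scale"`,
`epsilon = 2`; `gamma = "scale"` adapts the kernel width to the feature
dimensionality, so the same default behaves sensibly from the 16-dim
dinucleotide recipe to the 1440-dim full hybrid. A grid search
(`C ∈ {1,10,100}`, `gamma ∈ {1e-3,1e-2,1e-1}`, `epsilon ∈ {1,5,10}`,
selected by inner 10-fold pooled PCC) is available via `tune` / `--tune`.

Duplicated guides are collapsed to their arithmetic-mean efficacy — the
least information-destroying deterministic rule — with a report of collapsed
groups.

Evaluation harnesses:

* **Random split** — seeded permutation hold-out (e.g. 922 → 737 + 185).
* **10-fold CV** — records are shuffled with the stated seed and dealt
  round-robin, giving a disjoint, exhaustive, near-equal partition
  (737 → sizes 74/73). The score is the PCC on the pooled out-of-fold
  predictions; per-fold PCCs are reported alongside.
* **LOTOCV** — one round per target gene with ≥10 records; smaller genes are
  pooled into a single "Others" round. Guides from one gene are typically
  single-nucleotide sliding variants of each other, so random k-fold CV
  leaks near-duplicates across folds and inflates performance; holding out
  an entire gene measures generalization to unseen targets. Each round also
  reports the within-training 10-fold PCC and the mean prediction bias on
  the held-out gene.

Models persist via joblib as a self-describing payload (format version,
feature recipe, hyperparameters, fitted pipeline, training-set fingerprint);
load → predict is bit-identical to the pre-save model.

## Default mismatch matrix

Empirical position×mismatch efficacy tables are experiment-specific and not
bundled; the built-in default is a synthetic matrix that encodes the
qualitative rules of the mismatch-tolerance literature and is labeled
non-authoritative. Construction: each clash class gets a retention envelope
(terminal value, cleavage-site value) — pur:pur (0.50, 0.05), mixed
(0.65, 0.15), pyr:pyr (0.80, 0.30) — interpolated linearly in a centrality
weight that is 1 at guide positions 9–11 (RISC cleaves the target opposite
guide position 10) and 0 at positions 1 and 19. Small fixed per-pair offsets
(≤0.03, e.g. G:G least tolerated within pur:pur) keep the ordered-pair
structure non-degenerate; class envelopes are separated by ≥0.10 so the
class ordering pur:pur ≤ mixed ≤ pyr:pyr holds cell-by-cell. All 228 cells
are validated on construction and on file load, and the TSV representation
round-trips losslessly.

## Off-target search

Seed search indexes every 6- or 7-mer of the target sense sequences and
looks up the reverse complement of the guide seed (positions 2–7 or 2–8) —
i.e. sites Watson-Crick complementary to the seed, with zero mismatches, as
seed-complementary 3'UTR sites are the dominant off-target mechanism. Full
search compares the guide's reverse complement against every 19-nt sense
window with one vectorized sliding comparison (valid because reverse
complementation preserves Hamming distance), default ceiling 3 mismatches
(overridable with a warning). Ambiguity codes never match. The search runs
on the sense strand of the user FASTA; gzip input is accepted and hit
tables are emitted as TSV (1-based) or BED (0-based half-open).

## Synthetic data

The generators define the study conditions for all tests:

* **Allele pairs** — uniform random context (default 41 nt, enough for full
  18-nt flanks) with one central substitution; emitted as lowercase-marked
  FASTA and re-parsed by the same reader users exercise.
* **Training tables** — guides drawn uniformly; efficacy =
  `clamp(f(guide) + N(0, noise_sd), 0, 100)` with noise sd 5 by default (a
  plausible replicate-level error for knockdown assays on the percent
  scale). Effect models: `linear_dinuc` (affine in the package's own
  dinucleotide composition, fixed weights spanning ±150 giving a latent
  signal sd of ≈20 points on random guides — a strong but not saturating
  signal against the default noise); `positional` (affine in the one-hot
  encoding); `gene_shifted` (`linear_dinuc` with the first gene offset by
  +30, a distribution shift that LOTOCV must expose as a strong negative
  prediction bias — note a pure mean shift leaves the PCC itself nearly
  unchanged, which is why the harness reports bias alongside PCC). Gene
  sizes are skewed and always include two genes with <10 records so the
  "Others" pooling rule is exercised. Effect models run through the real
  encoders, so parameter-recovery tests exercise the production feature
  path. n = 900 with an 180-record hold-out mirrors a realistic
  training-table size for this problem domain.
* **Planted genomes** — random background with seed complements or
  distance-d mutated guide complements planted at stated, non-overlapping
  positions. Background is rejection-sampled until no seed6/seed7
  complement of the guide survives outside planted intervals; full_d≥1
  plants force one substitution into the seed6-complement region of the
  window (shared with seed7), so a mutated full site never doubles as an
  unplanned seed hit. A full_d0 plant legitimately implies seed hits at
  fixed offsets (+12/+11 within the window), which truth-table tests
  account for.

What the generators do **not** emulate: the empirical efficacy distribution
of curated ASP-siRNA datasets, compositional bias and repeat structure of
real genomes, and target-site accessibility effects. Passing tests
therefore demonstrate correctness of the machinery (encodings, harness
partitions, search equivalence, matrix algebra) and recoverability of a
known signal — not predictive performance on laboratory data, which depends
on a curated training set and an empirical mismatch matrix supplied by the
user.

## Numerical choices and edge cases

* Ties in the structure fold go toward fewer pairs; the traceback prefers
  leaving the 3' base unpaired whenever that attains the optimum, making
  the per-position flags deterministic.
* k-mer frequencies use denominator 19−k+1 and sum to 1 within 1e-9.
* PCC raises on zero-variance inputs rather than returning NaN; LOTOCV
  rounds with degenerate held-out sets report NaN for that round only.
* Candidate enumeration never throws on short flanks — windows that would
  leave the context are skipped with a warning, so a variant at offset 0
  yields exactly one candidate (variant at guide position 19).
* Report writers emit no timestamps; identical inputs and seeds give
  byte-identical outputs.
* Problem sizes in the default test run and the acceptance script (n = 900
  training records, 10-kb planted genomes, 20 random genomes for the
  search-oracle check) were chosen as the smallest sizes at which the
  statistical contracts are comfortably powered.

## Known limitations

* Eff_wild is defined for a single mismatch only; multi-mismatch designs
  (e.g. a deliberate second mismatch to boost discrimination) are out of
  scope.
* The default matrix is rule-derived, not fitted; absolute Eff_wild values
  from it are indicative only, though orderings across positions and clash
  classes follow the literature's consensus.
* The thermodynamic and structure feature definitions are package
  conventions (see Features); models trained with them are internally
  consistent but not interchangeable with models trained on other tools'
  definitions.
* Guides are modeled as bare 19-mers: no dTdT overhangs, chemical
  modifications, shRNA hairpins, or multi-nucleotide variants.
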