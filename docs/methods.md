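# Methods

## Problem and model

Codon optimization back-translates a protein into a coding sequence (CDS)
suited to a heterologous host. `codonoptim` treats it as per-position
classification: given the amino-acid sequence, predict for each position a
distribution over the 64 codons, then decode a CDS.

The classifier is a bidirectional LSTM:

- **Input** — one vector per residue. Two encodings are provided:
  `onehot` (26 dimensions: the 20 standard residues plus the extended
  IUPAC letters and a stop symbol; Alanine is index 0, stop is last) and
  `nlft` (18 dimensions: z-scored physicochemical descriptors —
  hydropathy, mass, volume, polarity, isoelectric point, charge — plus
  squared and tanh-transformed variants). The `nlft` table is a
  descriptor-derived stand-in constructed from published per-residue
  scales; it is not a fitted embedding.
- **Recurrence** — stacked BiLSTM layers (default 2 × 256 units;
  concatenated forward/backward states feed the next layer). Standard
  LSTM gates with forget-gate bias initialized to 1.0 and Glorot weight
  initialization.
- **Output** — a softmax over 64 codons per position; training minimizes
  masked cross-entropy against the host's observed codons, with L2
  weight decay (1e-4) and inverted dropout (0.2) between layers.
- **Optimization** — Adam (lr 1e-3), global-norm gradient clipping at
  5.0, length-bucketed padded mini-batches of 32, 50 epochs; the
  parameters with the best validation loss are retained. Everything is
  implemented in NumPy (forward and backward passes written out), so the
  package has no deep-learning framework dependency and training is
  bit-reproducible for a given seed on one CPU.
- **Decoding** — `constrained` (default) takes the argmax *within* the
  residue's synonymous codon family, which makes a non-synonymous output
  impossible: the mutational rate is 0.00% by construction.
  `unconstrained` takes the global argmax and is provided for
  diagnostics. All argmax operations break ties lexicographically.

The `quick` profile (64 units, 1 layer, lr 5e-3, 10 epochs) is this
package's own small configuration for smoke tests and examples; it
trains in roughly 15 s on 300 short genes with one CPU.

## Baselines

For each residue, with synonymous family `F` and host family fractions
`f(c)`:

- **URC** samples uniformly from `F`.
- **BFC** samples `c ∈ F` with probability `f(c)`.
- **HFC** picks `argmax f(c)` (lexicographic ties). Because CAI weights
  are `w(c) = f(c) / max f over F`, the HFC output scores CAI exactly 1.0
  against its own table — an identity the test suite checks over random
  tables.
- **ERC** draws `k` URC candidates (default 100) and keeps the one with
  the highest CAI; with the same seed, `k = 1` reduces to URC.

## Metrics

- **CAI** (Sharp & Li): geometric mean of `w` over sense codons,
  excluding single-codon families (ATG, TGG) and stops; zero
  frequencies are floored at `w = 1e-4` so CAI is always defined.
- **GC content**, plus a 60-nt / 3-nt-step sliding window; 30–70% is
  treated as the ideal band.
- **CFD**: percentage of sense codons with `w` strictly below 0.30.
- **Negative repeats**: count of *maximal* distinct substrings of length
  ≥ 10 occurring at least twice (a repeat contained in a longer repeat
  is not counted). The implementation enumerates per length and stops at
  the first length with no repeats, justified by the substring lemma; the
  tests cross-check it against an independent brute-force oracle.
- **Cis-regulatory elements**: IUPAC motif hits on both strands
  (Shine-Dalgarno `AGGAGG`/`GGAGG`, Pribnow `TATAAT`, chi site
  `GCTGGTGG`, poly-A/poly-T 8-mers by default); overlapping hits count.
- **Mutational rate**: % of positions whose codon does not translate to
  the intended residue.

`evaluate` assembles per-sequence metrics, per-method summaries, and
pairwise tests (two-sample t-test on CAI; two-sided Mann-Whitney U on
repeat and cis-element counts).

## Curation

Raw CDS sets pass through: minimum length (90 aa) → greedy redundancy
clustering at 90% identity (longest sequence first; identity is the best
ungapped alignment found from shared-k-mer anchored diagonals, divided by
the shorter length — a deterministic approximation to CD-HIT) → ranking
by CAI and keeping the top N → a seeded split into 70/10/20 partitions,
where validation and test sizes are rounded half-up and train takes the
remainder; 7,406 genes therefore split 5,184 / 741 / 1,481.

## Synthetic hosts

Because the package must be verifiable offline, it generates its own
ground truth. A synthetic host draws, per amino acid (order 0) or per
(previous amino acid, amino acid) pair (order 1), a codon distribution
from a Dirichlet whose concentration is set by a `bias_strength` knob
(1.0 = deterministic host). Order-1 hosts are redrawn until context
materially matters (max total-variation distance between conditional
distributions > 0.2). Two analytic ceilings make claims falsifiable:

- `frequency_ceiling` — the best accuracy any frequency-only method can
  reach (expected max marginal probability per residue);
- `context_ceiling` — the same given the true one-step context.

A trained classifier beating `frequency_ceiling` on an order-1 host is
direct evidence it learned context; on an order-0 host it can only match
the ceiling. Both behaviours are asserted in the acceptance tests. The
40-gene benchmark fixture (`make_benchmark_fixture`) emulates the shape
of a realistic evaluation panel: 40 genes of 520–600 residues from a
moderately biased order-0 host.

What the generator deliberately omits: real genomes' GC skew and operon
structure, tRNA abundance dynamics, mRNA secondary structure, and
longer-range context than one residue.

## Numerical choices

- All tie-breaks (argmax over codons, cluster representatives, ERC
  candidates) are lexicographic/first-index, so every routine is
  deterministic given its seed.
- CAI weight floor `1e-4`; CFD threshold strict `<` 0.30.
- Split rounding: `floor(x + 0.5)` for validation/test counts.
- Gradient clipping at global norm 5.0; Adam defaults
  (β₁ 0.9, β₂ 0.999, ε 1e-8).
- Model archives are NumPy `.npz` files with a JSON metadata block
  (format version, configuration, alphabet, training history); loading
  validates the format and fails with a typed error on truncation.

## Limitations

- The full-profile network is small by deep-learning standards and
  trains on CPU; the package targets methodological fidelity and
  verifiability, not large-scale training throughput.
- The bundled *E. coli* K-12 usage table is a representative codon-usage
  snapshot for convenience; for production designs supply a usage table
  computed from your actual host strain's CDS set
  (`usage_from_sequences`).
- The clustering identity measure is ungapped; heavily indel-diverged
  duplicates may escape collapsing.
- The `nlft` encoding is descriptor-derived rather than learned; the
  test suite only asserts that `onehot` performs at least as well.
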