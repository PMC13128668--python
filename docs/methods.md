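# Methods

## Problem and model

Bacterial enzymes with short intracellular half-lives (< 1 h) are present
at low abundance and can become rate-limiting steps in synthetic
metabolic pathways. `protlife` implements a binary sequence classifier
that labels a protein *short-lived* or *long-lived* from three fused
representations:

1. **Residue-level embedding matrix** (d_local × L_padded, one channel),
   projected to a fixed-length vector by two Conv2D → ReLU →
   AveragePooling2D → Dropout blocks and flattened. Valid (no-padding)
   convolutions are used, so the build fails fast when a kernel exceeds
   the incoming spatial extent.
2. **Sequence-level embedding vector** (length d_global), centred and
   projected onto the smallest PCA basis explaining ≥ 95 % of training
   variance.
3. **Physicochemical descriptors** computed from sequence, z-scored
   (sample SD, *n*−1) and filtered by a per-feature one-way ANOVA F-test
   between the classes; features with p > 0.01 are discarded. For two
   classes F equals the squared pooled t statistic with p from F(1, n−2).

The three blocks are concatenated and passed through `n_layers` fully
connected ReLU layers with dropout into a single sigmoid unit giving
P(long-lived). Training minimises binary cross-entropy with Adam and
stops early when validation loss has not improved for 5 consecutive
epochs, restoring the best-validation weights. A probability of exactly
0.5 is classed long-lived (tie to the positive class). The network,
including the convolutional projection and Adam, is implemented directly
on numpy; all randomness (initialisation, dropout masks, minibatch
order) flows from one seeded generator, so (seed, data, config) fully
determine the weights.

## Descriptors and their ablation groups

| family | features (defaults) | group tag |
|---|---|---|
| CKSAAP, gaps 0–5 | 2,400 | GAPPED_KMER |
| DDE | 400 | GROUPED_COMPOSITION |
| CTD (7 attributes × 3 classes) | 147 | PHYSCHEM_PROPERTY |
| Moran autocorrelation (8 scales × 30 lags) | 240 | SEQUENCE_ORDER |
| SOCN (30 lags) | 30 | SEQUENCE_ORDER |

Definitions follow the standard toolkit conventions: CKSAAP blocks are
normalised by the number of gapped pairs so each 400-feature block sums
to 1; DDE standardises dipeptide frequencies against codon-multiplicity
expectations (Tm = (Ca/61)(Cb/61), Tv = Tm(1−Tm)/(L−1)); CTD uses the
Dubchak-style 3-class partitions for hydrophobicity, van der Waals
volume, polarity, polarizability, charge, secondary structure and
solvent accessibility, with distribution points at the 1st/25th/50th/
75th/100th percentile occurrence as % of length; Moran autocorrelation
z-scores each property scale over the 20 residues; SOCN sums squared
inter-residue physicochemical distances at each lag. Degenerate
denominators (a constant property profile on a homopolymer) yield 0,
never NaN, because downstream ANOVA requires finite input. Feature order
is canonical: family order as in the table, alphabetical residues,
ascending gap/lag.

Two data choices are the package's own. The Moran property basis is
eight classical published scales (Kyte–Doolittle hydropathy, Hopp–Woods
hydrophilicity, residue mass, isoelectric point, Grantham polarity and
volume, Chou–Fasman helix and sheet propensities); since scales are
z-scored over the residues, the basis defines shape only. The SOCN
distance matrix is built as the Euclidean distance over z-scored
hydropathy, hydrophilicity and residue mass (the quasi-sequence-order
convention): symmetric, zero diagonal, covering all 20 residues; a
Grantham-style polarity/volume variant is available as a second block.

## Data contract and redundancy reduction

Input sequences must use the 20 standard residues and be 50–1655 amino
acids long (a lenient parsing mode maps ambiguity codes B/J/O/U/X/Z to X;
gap characters are always an error). Half-lives may be given in minutes
or hours (explicit unit flag); *short-lived* means strictly < 60
minutes, so exactly 60 min is long-lived. Redundancy reduction follows
the greedy incremental scheme of common clustering tools at a 0.5
identity cutoff: records sorted longest-first (ties by id) join the
first cluster whose representative is ≥ 50 % identical, computed as
optimal global alignment matches (match 1, mismatch 0, gap 0 — the
longest common subsequence) divided by the shorter length. The k-mer
prefilter heuristics of the production tools are deliberately omitted:
at a few thousand sequences exact scoring is affordable and exactly
verifiable against a quadratic-time oracle.

## Hyperparameter selection

Eight hyperparameters are searched on a full Cartesian grid — kernel
(7, 9), filters (8, 16), dense layers (1, 2, 3), units (512, 1024,
input dimension), dropout (0.1, 0.2), learning rate (1e-3, 1e-5), max
epochs (10, 20, 30), batch size (32, 64, 128); 1,296 configurations —
scored by mean MCC over stratified 10-fold cross-validation with
feature processing (z-score, ANOVA, PCA) refit inside every fold on that
fold's training portion. All configurations share one set of folds
(cheaper, lower-variance comparisons); ties break to the
earlier-enumerated configuration. Stratification is an explicit choice:
with ~83 minority-class samples, unstratified folds risk near-empty
validation classes. The shipped default configuration is the selected
one: 7×7 kernel, 8 filters, 2 layers, units = input dimension, dropout
0.2, learning rate 1e-3, 6 epochs, batch 32.

Open design points resolved as follows: pooling windows are 2×2 stride 2
(configurable); convolutions use ReLU; dropout sits after each pooling
block and each dense layer at the single configured rate; early stopping
monitors validation loss with best-weights restoration; no class
weighting by default (an optional weight flag exists but is off);
padded embedding columns are zero and unmasked, so the CNN input shape
is static at d_local × 1655.

## Synthetic data and what passing means

The generator draws residues i.i.d. from class-conditional frequencies
(uniform by default; a proteome-like table optionally), lengths
log-uniform on [50, 1655], with class sizes defaulting to 1,035 long /
83 short. Signal is planted explicitly: a degron-like motif (default
the ssrA tag AANDENYALAA) overwritten at a uniform position in a
`p_motif` fraction of short-lived sequences; optional per-residue
composition bias; and an embedding effect that shifts the first
coordinate of the synthetic embedder's sequence vector by `effect_size`
whenever the motif is present. The synthetic embedder itself is a
content-hash-seeded Gaussian source — deterministic, id-independent —
standing in for a protein language model's output shape, not its
biology. Consequently the tests demonstrate *pipeline correctness and
signal recovery* (a planted, learnable class difference is found, and
permuted labels yield MCC ≈ 0), not real-data performance: synthetic
sequences lack phylogenetic correlation, domain structure and the
contextual information a pretrained embedder would contribute.

For ablation-ordering checks the generator offers a composition-matched
spaced-pair mode: both classes receive the same number of extra W and C
residues, but only short-lived sequences arrange them as W-x-x-C pairs.
A plain motif leaks into the composition-based families (a WWW motif is
visible to DDE's WW cell and CTD compositions), whereas the matched
arrangement confines the separating information essentially to the
gapped-k-mer group, with only dilute traces in lag descriptors.

## Problem sizes and numerical choices

Desk-scale runs (the test suite and `scripts/acceptance.py`) use a
24 × 160 synthetic residue embedding with a 64-dimensional sequence
vector, sequences of 50–150 residues, n = 400 (300 long / 100 short;
the generator's full imbalance at reduced n) with a 100-sequence
stratified hold-out, a reduced 8-configuration grid (layers × dropout ×
batch size at kernel 7, filters 8, units = input dim, lr 1e-3, 10
epochs), and 3 folds. The ablation run uses n = 300 with 8 planted
pairs per short sequence. Library defaults remain the full-scale ones
(d_local 128, d_global 512, L_padded 1655, 10 folds, 1,296-config grid
behind an explicit flag).

Network arithmetic is float32 with float64 loss accumulation and Adam
moments; probabilities are computed in float64 with a numerically stable
sigmoid/BCE. PCA uses a full SVD; component count is the smallest k
whose cumulative explained variance reaches the target. Zero-variance
descriptor columns are dropped before ANOVA (F undefined) and their
stored SD set to 1 so application never divides by zero. Moran treats
profile variance below 1e-10 (scales are O(1)) as degenerate.

## Known limitations

* Trained weights and cross-validation numbers obtained on the original
  curated dataset cannot be reproduced here; that corpus and the
  pretrained language-model weights are not packaged. Published
  reference values are discussed in the README but asserted nowhere.
* The pretrained-embedder adapter is a contract plus an actionable
  error, not a working loader; the package is fully functional with the
  synthetic embedder.
* Unmasked zero padding means very short sequences contribute many
  all-zero columns to the convolution; average pooling dilutes but does
  not remove this length artefact.
* The greedy clustering is quadratic in the number of sequences and
  intended for desk-scale corpora.
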