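# Methods

## Curation rules

Raw kinetic tables carry one row per measurement with columns
`enzyme_id, substrate_name, param, value, unit` and optionally
`sequence, smiles, organism, ec_number, enzyme_type` (the schema is this
package's own; sequences may instead come from a FASTA keyed by
`enzyme_id`).  Rows are dropped, and counted per category, when the
accession field lists several IDs, the SMILES is missing, or no sequence
can be resolved.

Units are normalized before any aggregation: canonical units are s⁻¹
for *k*cat and mM for *K*m, with an explicit conversion table
(min⁻¹ → ÷60, h⁻¹ → ÷3600; M → ×1000, µM → ÷1000, nM → ÷10⁶).  Units
absent from the table — including the empty string — are treated as
ambiguous and the rows removed.  Normalizing first means the max/min
retention below compares commensurable numbers; the alternative order is
not meaningful across mixed units.

For each (sequence, SMILES) pair with multiple measurements the maximum
*k*cat and the minimum *K*m are retained; labels are log10 of the
retained value.  Label noise is the *population* (÷n) standard deviation
of the log10 replicate values, computed before deduplication and
reported only for multi-replicate pairs; the log scale matches the
training target and the population convention is the natural choice for
describing the spread of the replicates actually observed.  The
efficiency dataset is the exact key intersection of the curated *k*cat
and *K*m datasets with label `log10 kcat − log10 Km`.

Mutants are distinct keys: the key is the exact amino-acid string, so
variants sharing one UniProt accession remain separate entries.
Sequences containing `X` are accepted as data but `X` is rejected as a
mutation target or wild-type residue in the engineering module.

## Sequence identity and unbiased splits

Identity is computed from a global alignment with match +1, mismatch 0
and linear gap −1 (Biopython `PairwiseAligner`), as identical aligned
columns divided by the length of the shorter sequence — the convention
of greedy identity clusterers.  Greedy clustering processes sequences
longest-first (id-lexicographic tie-break); a sequence joins the first
cluster whose representative reaches the threshold (default 0.4), else
founds a new cluster.  No k-mer prefilter is used: at desk scale the
O(n²) alignments complete in seconds, and a prefilter must not change
results anyway.

Folds are balanced by record count: clusters sorted by record count
descending (equal-sized clusters shuffled with the run seed) are each
assigned to the currently smallest fold, ties to the lowest fold index.
Whole-cluster assignment guarantees that no two folds share sequences at
or above the threshold; `audit_leakage` verifies the guarantee by
exhaustively aligning deduplicated cross-fold sequence pairs and
reporting the true maximum.  The random baseline is a seeded shuffle
dealt round-robin (fold sizes within 1).

## Features

A reaction is `concat(protein_embedding, molecule_embedding, MACCS)` in
that fixed order — 1024 + 768 + 167 = 1959 dimensions with the default
provider widths, which match the widths of the ProtT5-class protein and
MolT5-class molecule language models whose precomputed embeddings the
provider contract is designed to carry.  A provider is any deterministic
map from a string to a fixed-length vector; language-model plugins are
expected to mean-pool per-residue states to a single vector.  MACCS keys
come from RDKit.  No feature scaling is applied by default.

Synthetic providers make the package runnable without model downloads:
`iid_hash` gives each distinct string an independent N(0, 1/dim) vector
(categorical identity, near-orthogonal at high dim); `kmer_composition`
embeds a string as the mean of fixed seeded per-k-mer vectors (k = 3),
so embedding similarity increases with sequence similarity — the
property a real protein language model shares and the one that lets a
model recognize homologs of its training sequences.

Multi-substrate reactions average the per-substrate molecule features
(embedding and MACCS parts alike) or, at prediction time, average the
per-substrate predictions; both are arithmetic means.

## Regressors

The base regressor has exactly one hidden layer (default 256 ReLU
units) and a linear readout, trained with Adam (lr 10⁻³, weight decay
10⁻⁵, batch 64, 30 epochs by default) on an RMSE loss.  The readout is
zero-initialized with its bias set to the label mean at the start of
`fit`, so training starts from the best constant predictor — this makes
constant targets exact fixed points and removes a slow bias-drift phase.
Hidden activation, optimizer and the early-stopping default (off) are
package choices exposed in `RegressorConfig`; every run's randomness
(init, shuffling) flows from the single config seed, and per-fold seeds
derive from it.  An Extra-Trees backend (scikit-learn) satisfies the
same `fit`/`predict` contract for the tree-ensemble variant.

### Two-stage efficiency model

Stage 1 trains *k*cat and *K*m submodels on the parent labels of the
efficiency dataset's training records; their parameters are then frozen
(enforced by SHA-256 digests of the parameter arrays before/after
stage 2).  The initial estimate is the prediction difference in log10
space.  Stage 2 trains a correction network — dense layer to 256 dims,
feature-wise attention `A = softmax(W·h)`, `h_A = A ⊙ h` with a square
256×256 `W`, then a linear readout — jointly with two blend scalars
(a, b), both initialized to 1, minimizing RMSE of
`a·(f_kcat − f_Km) + b·g(x)` on the training fold (no separate
validation split for the blend).  The correction readout is
zero-initialized, so the untrained two-stage model reproduces the raw
log-difference exactly and training can only move away from it if that
reduces the loss.  Inference on new data defaults to averaging the fold
models (switchable).

`attention_gate` accepts a (d, d) matrix or a (d,) vector of weights —
the formula fixes neither — and normalizes over the feature axis, so
attention sums to 1 per sample.

## Evaluation

PCC, SCC and RMSE are implemented from their explicit formulas; SCC
uses `1 − 6Σd²/n(n²−1)` verbatim on tie-free data and Pearson on
average ranks otherwise.  Undefined metrics (zero variance, all-tied
pairs) return NaN and are excluded with a count rather than silently
skipped.  Mutant panels require ≥ N variants with N inclusive ("at
least N"); variant identity is the distinct amino-acid sequence, and two
distinct sequences both flagged wild-type under one reaction key is an
error.  Pairwise accuracy excludes experimentally tied pairs from
`M_total` and counts predicted ties as incorrect — the strict
convention, chosen so a constant predictor scores 0 rather than chance.
Per-reaction SCCs are averaged unweighted across reactions.  Mutation
effects are centered by each panel's own mean before pooling.

## Synthetic benchmark

`simulate_families` grows each family from a random ancestor (member 0,
kept unmutated) by iid substitutions, uniform over the 19 alternative
residues, no indels — identity to the founder is Binomial-exact,
1 − within_rate in expectation.  Labels decompose as
`μ + family + substrate + variant + ε` with all effects drawn once per
family / substrate / pair on the log10 scale.  Variant effects are
deliberately invisible to the synthetic embeddings: they are irreducible
noise to any model, so the random-vs-clustered performance gap is
attributable to family memorization alone.

The leakage benchmark defaults are 40 families × 10 members of
120-residue sequences at 5% within-family substitution, 8 substrates,
(σ_fam, σ_sub, σ_var, σ_ε) = (1.0, 0.5, 0.2, 0.2), k-mer-composition
providers, ten folds, default regressor config.  Provider widths are
256 (protein) and 64 (molecule) + 167 MACCS bits: the leakage
phenomenon is a property of the split and the label structure, not of
embedding width, and these widths keep the full experiment at a few
minutes on one CPU.  The two-stage benchmark uses 20 families × 8
members, 4 substrates, 128/32-d providers, 5 folds and 15 epochs —
sized so the cross-validated two-stage comparison completes in seconds.

What passing on synthetic data does and does not show: the generator
reproduces the homology and variance structure of curated kinetic data,
not its chemistry — real substrate effects are not linear in fingerprint
bits, real family effects are not spherical Gaussians, and real
embeddings carry information the k-mer stand-ins lack.  The leakage gap
and split guarantees transfer to real data because they depend only on
sequence identity structure; absolute PCC/RMSE values do not.

## Engineering conventions

Homolog mining removes candidates whose length differs from the
reference by strictly more than 20 residues (exactly 20 is kept), ranks
the rest by predicted `log10 kcat − log10 Km` — the efficiency proxy,
since the ranking combines both predicted parameters; single-parameter
ranking is a config switch — and keeps the top 150.  Pocket sites are
residues whose minimum heavy-atom distance to any ligand heavy atom is
≤ 12 Å (hydrogens ignored; Cα-only distance is not used), minus explicit
exclusions such as metal-coordinating histidines.  Saturation
mutagenesis produces exactly 19 × |sites| single-point mutants.  The
screen keeps the top ⌈M/2⌉ by model score, then requires ΔPSSM strictly
greater than 7; both filters are order-independent in their result set.
A second engineering round runs the same machinery with a multi-mutant
template passed as the wild-type.  PSSMs are consumed in the standard
PSI-BLAST ASCII layout (generation from an MSA is out of scope); columns
are keyed by header residue letters, so permuted layouts parse
identically.

## Numerical and degenerate-input choices

- RMSE-loss gradient at zero loss is defined as 0 (exact fit is a fixed
  point).
- Softmax is computed with max-shift for stability; attention
  normalization is asserted to 10⁻⁹ in tests.
- Metrics on fewer than 2 points, zero-variance inputs, or all-tied
  panels are NaN, never exceptions, except where the operation itself is
  meaningless (empty ensembles, empty substrate lists), which raise.
- Grid-search ties keep the earlier grid entry; cluster-size ties in
  fold balancing are broken by a seeded shuffle then lowest fold index.
- `deduplicate` keeps the first-seen record among exactly equal values,
  which cannot change the label.

## Known limitations

- The neural stack is pure numpy on CPU; it is sized for the desk-scale
  benchmarks here, not for GPU-scale training on full databases.
- Real language-model embeddings are supported only through the provider
  contract (precomputed matrices); the package never downloads or runs
  ProtT5/MolT5-class models.
- Name→SMILES resolution, database scraping, structure prediction,
  docking and MSA/PSSM generation are out of scope by design.
- The greedy clusterer reproduces the standard longest-first behaviour
  but not CD-HIT's word-filter heuristics; results can differ from
  CD-HIT on sequences near the threshold.
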