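# Methods

This note documents the models and procedures implemented in `idpseq`, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical conventions that make runs reproducible.

## The analysis in outline

The pipeline compares two protein sequence sets — disordered regions and
folded chains, both restricted by default to 50–150 residues — through three
lenses: predicted secondary-structure content versus aggregation propensity
per sequence; the geometry of the sets in amino-acid composition space
(PCA); and the location of each native sequence within the null distribution
generated by fully shuffling its own residues. Because a shuffle preserves
the composition exactly, the permutation experiment cleanly separates what a
property owes to composition (unchanged under shuffling) from what it owes
to residue arrangement (shifted relative to the null).

## Consensus secondary-structure prediction

Each ensemble member emits a per-residue three-state track (H = helix,
E = sheet, C = coil). The consensus assigns, at each position, the most
frequently voted state; when counts tie, the winner is the state voted by
the highest-priority predictor among those voting for a tied state, with
priority given by the listed order of the ensemble. An immediate
consequence, verified by test: a strict majority makes priorities
irrelevant.

Two predictors ship with the package so the machinery runs standalone:

* **Windowed propensity predictor.** Per-residue conformational propensities
  (the classical helix/sheet/turn parameters, shipped in
  `data/ss_propensity_scale.tsv`) are averaged over a centered window
  (default 7, truncated at the termini); the label is the argmax channel.
* **GOR-style predictor.** For class *s*, window offset *d* and residue *a*
  the model learns an information value
  `I(s; a, d) = log[(n(s,a,d)+c)/(n(¬s,a,d)+c)] − log[(n(s)+c)/(n(¬s)+c)]`
  from a labeled corpus (window 17 per the GOR-family convention,
  pseudocount c = 1). Prediction sums the information of the residues in the
  window at each position and takes the argmax class. The model serializes
  to a plain text table.

Argmax ties inside a single predictor resolve C, then H, then E: coil is the
unconditional fallback state, and a fixed order is required for
reproducibility. External predictions enter as TSV tracks; 8-state labels
are reduced by the standard mapping (G,H,I → H; E,B → E; rest → C), which is
shipped as a visible config table rather than hard-coded.

Accuracy is Q3, the per-residue agreement fraction. On held-out synthetic
corpora (see below) the built-in GOR predictor reaches Q3 ≈ 0.78 against a
chance level of 1/3; the exact value is recomputed by `scripts/acceptance.py`
rather than asserted here.

The end-to-end pipeline needs a trained GOR model before any user corpus
exists; it trains one at import time of the default property suite on a
synthetic labeled corpus with a fixed internal seed (20190703), making the
default model a deterministic, regenerable part of the pipeline rather than
a shipped artifact.

## Aggregation score and disorder index

The aggregation scorer slides a `window`-residue window (default 7) over the
sequence and averages a per-residue scale; any residue covered by a window
whose mean reaches `threshold` is aggregation-prone, the protein score is
the prone fraction, and maximal prone runs are reported as segments. The
shipped scale is the mean of Kyte–Doolittle hydropathy and β-sheet
propensity, each rescaled to [0, 1] — hydrophobic, β-prone stretches are the
canonical aggregation nucleators. The default threshold (0.692) was
calibrated once so that ~10% of residues of random globular-composition
sequences are prone; the value and the calibration rule are recorded in the
scale file itself. This scorer is a deterministic, documented scoring rule
in its own right; its absolute values are not comparable to any external
aggregation predictor's output scale. Sequences shorter than the window are
scored from the single whole-sequence window and logged.

The disorder index is the arithmetic mean of a supplied per-residue disorder
track over a region (1-based inclusive coordinates throughout the package).
No built-in disorder predictor exists by design: disorder tracks are inputs
(real predictor exports or synthetic tracks). A constant track returns the
constant exactly, not a float-summation approximation.

## Permutation experiment

Shuffles are uniformly random permutations of the residue index vector
(`numpy` Fisher–Yates), so all L! orderings are equiprobable and the
composition multiset is conserved identically. For each sequence, the
property is evaluated on the native arrangement and on `n_perm` shuffles
(default 1000); the native value is never added to its own null. The null is
summarized by its mean and sample standard deviation (n−1 denominator; the
choice is conventional and immaterial at n = 1000), and
`z = (native − null_mean)/null_sd`.

Degenerate nulls are handled exactly: when every null value is bit-identical
(homopolymers; composition-only properties), `null_sd` is exactly 0 and *z*
is flagged undefined — never silently 0. A subtlety worth stating: a
property is only *numerically* composition-only if it is computed from the
composition itself (fixed summation order); summing per-residue values in
sequence order varies at the 1e−16 level across arrangements and therefore
produces a legitimate, tiny null spread.

Dataset-level statistics report Pearson's *r* between native values and
per-sequence null means; identical vectors short-circuit to exactly 1.0, and
constant vectors leave *r* undefined (NaN, logged) rather than raising.

Reproducibility and order independence: each sequence gets a sub-seed
derived as a 63-bit SHA-256 hash of `(global_seed, sequence_id)`, so
per-sequence rows are identical regardless of dataset ordering, subsetting
or scheduling across workers.

The standard property set (structured/helix/sheet fraction via the built-in
two-predictor consensus, plus the aggregation score) is evaluated by a
batched numeric core that scores all shuffles of a sequence in one
vectorized pass; the scalar module APIs wrap the same core on single-row
batches, so batched and per-call results are bit-identical (tested).

## Compositional PCA

Sequences are mapped to normalized residue-frequency vectors (fixed
alphabetical residue order). PCA is covariance-based: centering by the
dataset mean, no variance scaling — frequencies share one scale, and
standardizing would inflate rare-residue (C, W) noise. A `standardize`
option exists for sensitivity checks. The eigenvector sign is fixed by
requiring the largest-magnitude loading of each component to be positive.
`k` defaults to 2; requesting more than `min(n_samples − 1, 20)` components
raises with the achievable number. Directions of zero data variance (the
frequency simplex constraint removes one) yield zero-variance components,
which keeps full-dimensional reconstruction exact — the package's
convention for rank-deficient data. Enrichment summaries rank residues by
signed loading, ties alphabetical.

## Overlap mapping

Region and chain sequences are compared over every alignment diagonal for
maximal ungapped runs in which all aligned residues match exactly, except
that mismatches are tolerated at the first and last three chain positions
(deposited chain termini may differ from the native sequence; region termini
get no such tolerance). Runs of at least 21 residues ("longer than 20",
read strictly) are hits. Candidate diagonals are found by exact 12-mer
seeding: a qualifying run of length m ≥ 21 contains a contiguous exact core
of at least m − 6 ≥ 15 residues, so a 12-mer seed cannot miss it and the hit
set equals a full all-diagonals scan (tested against an independent
brute-force oracle); when parameters break the core guarantee (small
`min_len` or very short inputs) the scan falls back to all diagonals.

A hit is accepted when the overlap covers the whole region, covers the whole
chain, or is terminal-anchored on opposite ends of the two sequences (a
chain starting or ending within a region) with no conflict outside the
tolerated positions — the last condition is automatic because runs only
contain non-conflicting positions and maximality means they end at a
sequence boundary or a conflict. The tolerance is applied strictly at chain
positions 1–3 and L−2..L, whether or not the chain terminus lies inside the
overlap.

Induced-fold candidates are regions with ≥ 1 accepted hit, ranked by total
accepted overlap length; the unfoldable subset is the top-*n* (default 30)
by disorder index among regions with zero accepted hits. All ties break by
lexicographic id and are logged. The downstream manual curation of induced
folds (visual assessment of fold complexity in the matched structures) is
out of scope: the package emits the candidate list only.

## Synthetic data: what it emulates, and what it does not

The generators stand in for curated sequence databases and external
predictor outputs:

* **Compositional profiles** (shipped as a documented table): a globular
  background (database-wide residue frequencies), a polar-tract profile with
  G/P/S/Q mass doubled, and a charged profile with E/K/A mass doubled —
  the enrichment directions characteristic of polar and polyampholyte
  disordered regions. Per-sequence compositions are drawn from a Dirichlet
  around the profile (concentration 300, chosen once so that each class
  shows visible compositional scatter while the three classes occupy
  distinct regions of composition space, as the fixtures are required to);
  residues are then i.i.d. draws, lengths uniform in 50–150.
* **Labeled corpora** come from a hidden-state Markov emitter over H/E/C
  (self-transition 0.9; state changes suppressed until a segment reaches 3
  positions, keeping helices/strands plausible) with per-state emission
  distributions built by reweighting the background by each state's
  conformational propensity squared — a learnable but far-from-deterministic
  state–residue coupling.
* **Disorder tracks** are profile-level constants (globular 0.1, polar 0.85,
  charged 0.9) plus Gaussian noise (sd 0.05), clipped to [0, 1].
* **Overlap fixtures** plant one shared segment per region/chain pair in a
  known containment or terminal configuration, with optional mutations
  confined to tolerated chain-terminal positions, and record the true hit.

What passing tests on these fixtures shows: the machinery is correct — vote
counting, tie-breaking, null construction, z calibration, matcher
completeness. What it does not show: performance on real proteins. I.i.d.
residues have no repeats, motifs or local correlation structure; the
Markov emitter is not a physical folding model; disorder tracks are not a
disorder predictor. Quantities tied to real databases and external
predictors (dataset counts, the published consensus accuracy on real folded
chains, specific figure geometries) are deliberately not reproduced —
tests assert the properties of the method, not those snapshot-dependent
numbers.

## Numerical conventions and limitations

* Coordinates are 1-based inclusive everywhere; the alphabet is the strict
  20-letter set, with an opt-in lenient mode mapping B→N, Z→Q, U→C, O→K,
  X→A (each substitution logged).
* All argmax/ranking operations have documented deterministic tie rules
  (C > H > E per predictor; listed-order priority in the consensus;
  alphabetical/lexicographic elsewhere).
* Every run is a pure function of (inputs, parameters, seed); output tables
  embed the run parameters in a comment header, and identically seeded runs
  are byte-identical.
* Problem sizes used in tests and the acceptance script (hundreds of
  sequences, 200–6000 permutations, 50-fixture matcher panels) were chosen
  as the smallest sets at which the statistical checks have comfortable
  power; all scale linearly if enlarged.
* The exhaustive overlap survey is quadratic in the number of sequence
  pairs; 12-mer seeding keeps constant factors small but very large chain
  sets would want an inverted index across chains, which is not implemented.
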