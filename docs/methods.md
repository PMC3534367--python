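# Methods

## The numbering model

The package implements a reference-anchored standard numbering scheme for
the ThDP-dependent decarboxylase superfamily. The coordinate system is
defined by one reference sequence (the *S. cerevisiae* pyruvate
decarboxylase in the family's canonical usage); every homolog residue is
labelled with the absolute position number of its structurally
equivalent reference residue. Equivalence is decided by a profile hidden
Markov model built from a curated multiple alignment of representative
family members, which is far more robust at ~20% pairwise identity than
any pairwise alignment to the reference could be.

### Profile construction

Match states are **exactly the alignment columns in which the reference
row has a residue**. This is the load-bearing design choice: it makes
match state *k* ↔ reference residue *k* a bijection, so every match
state carries one standard number and no match state is unnumbered. The
common alternative (HMMER's gap-fraction heuristic for match-column
selection) can create match states at columns where the reference is
gapped, which would break the transfer.

Parameters are estimated from the alignment:

* **Sequence weighting** (`weighting`, default `henikoff`): Henikoff
  position-based weights compensate the phylogenetic imbalance typical of
  curated reference sets. Weights are normalised to **total 1**, i.e.
  observed counts are weighted frequencies. This makes the profile
  invariant under duplication of alignment rows and gives the
  pseudocount weight a fixed meaning independent of alignment depth.
* **Emissions**: for match state *k*,
  `p(a) = (freq_k(a) + w_pc · bg(a)) / (1 + w_pc)` with
  `w_pc = pseudocount_weight` (default 1.0) and `bg` the weighted
  amino-acid frequency of the whole alignment (floored by a 0.1% uniform
  admixture so every symbol, including unseen X, has positive mass).
  Insert-state emissions are estimated the same way from insert-column
  residues. With `pseudocount_weight = 0` the no-smoothing limit is
  recovered (indicator emissions for a single-row alignment).
* **Transitions**: nine Plan7-style moves per node (M→M/I/D, I→M/I,
  D→M/D, begin→M/D, M→end), estimated from the weighted state paths of
  the alignment rows with the same mixing weight against a uniform prior
  over each state's moves. Insert-before-delete transitions, which Plan7
  cannot represent, are skipped during counting.
* **Alphabet**: the 20 amino acids plus X. Ambiguity codes B/Z/U/O/J are
  folded to X at parse time. X emits with log-odds 0 under every state so
  unknown residues never perturb the alignment path.

### Alignment and numbering transfer

Queries are aligned **glocally**: the model must be traversed from begin
to end (family membership is a global property), but any number of query
residues before entry and after exit are absorbed by flanking insert
states at zero log-odds, because real sequences frequently carry termini
absent from the reference (N-terminal extensions, tags, transit
peptides). All arithmetic is in log₂ space; scores are bits of log-odds
against the background model.

The Viterbi path is deterministic: ties prefer match over delete over
insert (favouring numbered residues), and among equal-scoring exit
points the latest one is taken. Residues in match state *k* get standard
number `refmap(k)` (ordinal 0); residues in interior insert state *k*
get base `refmap(k)` with insertion ordinals 1, 2, … consecutive within
a run, rendered `168i1` by default or `168a` in the lettered style used
by other families' schemes. The family's own literature never numbers
insertions; the `i`-ordinal extension is this package's choice, needed
so that every query residue carries exactly one label. Annotations
attach only to ordinal-0 residues; an annotated standard position that
is deleted in the query is listed in `missing_annotated` rather than
silently dropped (communicating "position 477 is absent here" matters
as much as numbering it).

The forward algorithm (log-sum over all paths, always ≥ the Viterbi
score) drives the **acceptance gate**, the package's replacement for a
database-prescreen step (historically a BLAST E < 10⁻¹⁰ cutoff against a
family database): a query is numbered only if its forward score reaches
`gate_threshold_bits`. The packaged default is **20 bits**: empirically,
forward log-odds of i.i.d. background sequences concentrate near zero
with a ceiling of about +10 bits across model lengths 50–563 (they must
traverse the whole model, and what they gain in lucky emissions they pay
in transitions), while true family members score roughly 0.3 bits per
match state and more — hundreds of bits for full-length models, ≥37 bits
even at 40% identity for a 120-state model. For unusually short profiles
(K ≲ 100) the seeded `calibrate_gate_threshold` routine (max background
score over *n* samples plus a margin) should be used instead. The gate is
a pluggable score test; nothing else in the pipeline depends on it, and
`--no-gate` / `gate_policy="bypass"` disable it.

### Alignment-column comparison

To compare the HMM-based alignment with one produced by another program,
columns of the two alignments are paired **through an anchor sequence**
(normally the reference): for each anchor residue, the column it
occupies in A is compared with the column it occupies in B. For every
other sequence, a mismatch is recorded iff a different residue *ordinal*
of that sequence (gap counting as a value, gap-vs-gap as agreement)
occupies the paired columns. Ordinals, not letters, are compared —
identical amino acids at different sequence positions are still
different residues. Anchoring is the only column-pairing rule that is
well defined for arbitrarily gapped alignments; it restricts the report
to reference-covered columns, which are exactly the standard-numbered
ones.

Mismatch counts over *n* non-anchor sequences fall into five categories.
For the canonical n = 15 validation setting the bins are {0}, [1,3],
[4,8], [9,12], [13,15] (identical, highly similar, similar, dissimilar,
divergent); for general *n* the same fractions of *n* apply as half-open
intervals (0, 3/15], (3/15, 8/15], (8/15, 12/15], (12/15, 1] on
mismatch/n, with integer bin edges by floor on the exclusive-left
boundaries. This reproduces the n = 15 bins bit-exactly and degenerates
gracefully (n = 1 leaves only {0} and {1}).

### Conservation groups

Per standard position, amino-acid counts are taken over ordinal-0
residues only; insertions are excluded and deleted positions do not
contribute to a sequence's counts. Frequencies are by default computed
among the sequences covering the position (an `all`-sequences
denominator is available; the two differ exactly by the coverage
fraction). Classification uses strict inequalities matching the family
literature's wording: **group 1** = majority > 0.90 and every other
amino acid ≤ 0.01; **group 2** = majority > 0.90 and runner-up > 0.03;
everything else **variable**. A majority of exactly 0.90 or a runner-up
of exactly 0.03 therefore does not qualify. The classifier normalises
its input, so raw counts and frequencies classify identically.

### Motifs

A motif is a run of consecutive standard positions, each with an allowed
amino-acid set (or wildcard). Derivation takes, per position, the amino
acids with conservation-table frequency strictly above `min_freq`
(default 0.03, mirroring the group-2 minority threshold; the cutoff
behind the family's published motifs is undocumented, so this default is
a package choice and is prominently parameterised); sets larger than
`wildcard_size` (default 10) collapse to `x`. Scanning is
position-independent substring matching, the way a motif search runs
against a database; X matches only wildcards. Evaluation is at the
sequence level (a sequence is predicted positive iff the motif matches
anywhere), yielding TP/FP/FN/TN with sensitivity TP/(TP+FN) and
precision TP/(TP+FP), reported as undefined when the denominator is 0.

## Synthetic data

The generators provide every input with known truth:

* `make_family`: a reference drawn i.i.d. from the Robinson–Robinson
  globular-protein composition; homologs by independent per-site
  substitution with probability (1 − identity) to a uniformly chosen
  different amino acid, plus indel events at a per-site rate (default
  0.01) with geometric lengths (default mean 2), insertions and
  deletions equiprobable. The exact residue correspondence and the
  implied true alignment are returned. Defaults (n = 16 representatives,
  ~300–563 residues, 40–70% identity) mirror the family's real setting
  of a 16-protein reference alignment over a superfamily whose members
  are long multi-domain proteins.
* `plant_comparison_pair` / `perturb_alignment`: alignment pairs where
  chosen sequences are shifted by one column at chosen anchor positions
  via gap moves, so the per-column mismatch set is known exactly.
* `make_motif_dataset`: positives embedding one sampled motif
  realisation (optionally broken at one position and verified match-free)
  and rejection-sampled negatives, so sequence-level confusion counts are
  known by construction.

What the synthetic model does **not** emulate: position-specific
substitution preferences, rate heterogeneity across sites and domains,
phylogenetic correlation between homologs (all are independent draws
from the reference), compositional bias of particular subfamilies, and
alignment errors in the reference alignment itself. Passing the
synthetic benchmarks therefore demonstrates the correctness and
calibration of the algorithms, not the field performance of the scheme
on real decarboxylases, which depends on the curated structure-guided
reference alignment. Likewise, the published database-wide conservation
percentages and motif sensitivity/precision figures (0.65/0.27 against
the PROSITE pattern's 0.59/0.42) were measured against specific database
snapshots and are intentionally not reproduced here.

## Numerical choices and edge cases

* All probabilities stored as float64; emission and transition rows sum
  to 1 within 1e-9 (validated after every build when smoothing is on).
* log₂(0) = −inf is used directly for zero-probability moves in the
  unsmoothed limit; the DP kernels (numba-compiled) propagate −inf
  correctly.
* Viterbi/forward were verified against brute-force path enumeration
  (≥200 random toy profiles, relative tolerance 1e-9).
* Profile serialisation is JSON with a SHA-256 parameter digest; loading
  verifies the digest, the format version and the alphabet, so a loaded
  profile reproduces scores bit-exactly or fails loudly.
* Degenerate inputs: single-row alignments build (with a warning) a
  profile equal to that sequence plus pseudocounts; empty sequences,
  all-gap rows, ragged alignments and duplicate ids are errors; all-gap
  columns are removed at load time with a logged count.
* The numbered-output TSV (query index, amino acid, standard number,
  insertion code, annotations; header lines with query id, reference id,
  profile checksum, gate score) is this package's own format; the
  family's historical web-tool download format is not publicly specified,
  so this layout is a re-specification rather than a reimplementation.

## Problem sizes used by the test suite and acceptance script

Oracle checks run on toy profiles (K ≤ 6, queries ≤ 6, hundreds of
cases); recovery benchmarks use 10–20 replicate families of 20 homologs ×
300 residues (tens of thousands of scored positions); gate calibration
uses 1000 background sequences of length 300; the self-numbering check
uses a 563-residue reference, the reference protein's true length. These
sizes give stable statistics (recovery fractions reproducible to ~1e-3
across seeds) at a few seconds per measurement.

## Known limitations

* Insert-state emissions are estimated from usually sparse insert-column
  counts; they are effectively close to background, which is also the
  standard modelling choice.
* The fixed 20-bit gate is calibrated for realistic model lengths; short
  toy profiles need explicit calibration.
* The comparison metric only scores reference-anchored columns; columns
  where the anchor is gapped (pure-insert columns) are not compared.
* Numbering accuracy degrades gracefully below ~40% identity but the
  scheme's validity at very low identity rests on the structure-guided
  reference alignment, which the synthetic benchmarks cannot test.
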