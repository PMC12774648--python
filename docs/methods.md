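# Methods

This note records the model behind `structannot`, the defaults that matter,
what the synthetic generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Dual-alphabet representation

Every protein is a `DualSequence`: an amino-acid string, a 3Di string of the
same length, and an optional per-residue confidence track in [0, 100]. The
3Di alphabet reuses the twenty standard letters; each token summarizes the
local tertiary geometry around a residue, so structural similarity reduces
to sequence alignment over a second alphabet. Confidence is defined as
100 × the maximum softmax probability of the predicted token (per-protein
value: the arithmetic mean), which makes it directly comparable across
proteins but *not* interchangeable with pLDDT.

Empirical 3Di similarity between two token strings is
`1 − levenshtein/max(len)`: max-length normalization keeps the score in
[0, 1] and symmetric (alignment-length normalization would do neither
without extra conventions).

Masking replaces tokens whose confidence is **strictly below** the threshold
with their lowercase form. Lowercase-as-masked keeps the track
human-readable, round-trips through FASTA, and makes masking trivially
idempotent; the serialization is configurable in the sense that masked state
is recoverable (`tdi_unmasked()`) and the AA track is never touched. The
default threshold is 25 — low enough to drop only tokens near the noise
floor, where removing the structural term helps more than it hurts.

## Alignment and scoring

Column score: `w_aa·S_AA + w_3di·S_3Di`, defaults `w_aa = w_3di = 1`
(equal weighting is the neutral choice; both terms are integer matrices of
comparable scale). The AA matrix is the published BLOSUM62; the bundled 3Di
matrix is a synthetic stand-in (diagonal 6, off-diagonal −3) — adequate
because in this package 3Di strings are themselves synthetic, and
replaceable by any NCBI-format matrix via `SearchParams`. Masked columns
contribute the AA term only, so a fully masked query scores exactly as an
AA-only search (a tested invariant).

Local alignment is affine-gap Smith–Waterman (Gotoh): a gap of length *L*
costs `gap_open + L·gap_extend`, defaults 10/1 (standard protein-search
values). The dynamic program is numba-compiled; the traceback never starts
or ends with a gap, and adjacent insertion/deletion runs are disallowed —
at these penalties they are never optimal, which is why the exhaustive
enumeration oracle (which permits them) agrees exactly on all tested
instances. `fident` is computed over substitution columns (gap columns
excluded); coverages are aligned span over full length per sequence.

Ties in search ranking break deterministically: E-value, then bits, then
coverage product, then target id.

## E-value calibration

Optimal local-alignment scores of random pairs follow a Gumbel law. We fit
(μ, β) by maximum likelihood (`scipy.stats.gumbel_r`) on the scores of
seeded decoy pairs drawn from database residue frequencies, then set
λ = 1/β and K = exp(μ/β)/(m·n) for decoy lengths m = n, giving
`E = K·m·N·exp(−λS)` over the database residue count N. Defaults: 500
decoy pairs of length 150 (at least 100 required; the Gumbel location is
then estimated to a couple of percent). In the ungapped limit the fitted λ
on uniform-composition BLOSUM62 decoys lands near the analytic 0.318; at
the default gap penalties the empirical λ is lower (≈0.21–0.22), as
expected for gapped statistics, and the Monte-Carlo soundness check (the
fraction of null pairs with E ≤ e tracks e/N over two orders of magnitude)
is the operative guarantee.

## Prefilter

The k-mer prefilter counts shared 5-mers over AA plus shared 6-mers over
3Di (masked-containing 3Di k-mers excluded) and keeps the top `max_seqs`
candidates with at least one shared k-mer, ties by target id. It is a
sensitivity knob only: hit sets grow monotonically with `max_seqs`, and
`exhaustive=True` bypasses it entirely (used by the calibration tests).

## Annotation transfer and confidence tiers

The ranked hit list is scanned for the first target whose label carries a
real function ("hypothetical protein", "unknown function" and the empty
string are treated as non-functional, case-insensitively). If only
unknown-function hits exist, the top hit's group id is kept with category
"unknown function" so that PHROG-membership statistics ("any hit") remain
distinct from functional-annotation statistics.

Tier rules (prostt5 mode; `conf` = query mean confidence):

* **high** — qcov ≥ 0.8 and tcov ≥ 0.8, and (fident > 0.30 or conf ≥ 60 or
  E < 1e-10);
* **medium** — (qcov ≥ 0.8 or tcov ≥ 0.8), and (fident > 0.30 or
  45 ≤ conf < 60), and E < 1e-5;
* **low** — everything else at or below the search E-value threshold.

The medium rule's E-value clause is conjunctive — the grammatically
possible reading that makes it part of the disjunction would let a
low-identity, low-confidence hit with modest coverage outrank the intent of
the high/medium/low ordering. Confidence bands are [60, 100] and [45, 60)
so the clauses are disjoint. In structures mode the confidence clauses are
dropped; tier is always computed on the best *functional* hit. Queries
lacking a confidence track in prostt5 mode are graded on the
structure-independent clauses only rather than erroring, since the clauses
are a strict subset.

## Curation rule engine

* Fragmentation: proteins above 3000 residues split into ceil(len/3000)
  contiguous parts; sizes differ by at most one residue when the length is
  not divisible (the minimal-imbalance reading of "equal sizes"). Boundary
  semantics: "over 3000" is strict, so 3000 stays unsplit.
* Best model: highest mean pLDDT; exact ties prefer colabfold over
  colabfold_enriched over esmfold (the predictor that wins the large
  majority of comparisons is the sensible tie-winner).
* Structural-hit acceptance: qcov ≥ 0.7 and tcov ≥ 0.7 and TM-score ≥ 0.6,
  and for alignments under 75 residues additionally E ≤ 0.01. All
  thresholds inclusive except "under 75".
* Dual evidence: with both a structural and an HMM hit (the latter
  pre-filtered at E ≤ 0.001 and 70% bidirectional consensus coverage), the
  agreement class is one of identical_phrog / same_annotation /
  same_category / one_unknown / conflicting_categories; the lower-E-value
  hit is assigned except in one_unknown, where the known-function hit wins.
* Propagation into unknown-function families: the modal non-vague
  annotation (vague = contains DUF / uncharacterized / hypothetical /
  putative, case-insensitive; vague strings are skipped, not counted as
  divergent) propagates iff its supporter fraction meets 100% (n ≤ 2),
  2/3 (n = 3) or 10% (n ≥ 4), and no runner-up non-vague annotation reaches
  half the leader's support (the configurable `divergence_margin`;
  "multiple divergent annotations" is otherwise qualitative). "Identical or
  very similar" is operationalized as exact match after lowercasing and
  punctuation stripping, with an optional synonym table for the rest — the
  original curation was manual, and the synonym table is where human
  judgement re-enters reproducibly.

## Benchmarking

Binary task: positives are the truth-known CDS; predicting any known
function on a truth-unknown CDS is a false positive. Multiclass micro-F1
is computed over truth-known CDS only (truth-unknown CDS with predictions
are the binary task's business); a prediction is correct iff it matches the
reference at the requested level, and unpredicted positives are false
negatives. Coarsening the level (group → product → category) can only merge
error classes, so micro-F1 is non-decreasing along the hierarchy whenever
the fixture's hierarchy is functional — a tested invariant. Per-category
F1 is one-vs-rest; categories absent from the truth are undefined (`None`)
unless spuriously predicted, in which case they score 0. Annotation rates
are reported overall and in length bins <100 / 100–250 / >250 residues.

## Synthetic generator

The generator emulates the statistical structure the evaluation needs, not
biophysics: database records are i.i.d. uniform-composition dual sequences
(lengths gamma-distributed, mean 220 residues, floor 60 — matching the
scale of real phage protein databases); each record is its own labelled
group with product drawn from a per-category pool, so group determines
product determines category. Homolog queries substitute AA and 3Di tokens
independently at set rates (substitutions always change the symbol),
apply geometric-length indels, and receive a confidence track
`clamp(100·base·(1−u) + noise, 0, 100)` with `u` the per-residue corruption
indicator, base 0.85 and Gaussian noise (σ = 8) — the simplest mechanism
that makes mean confidence and true 3Di similarity positively
rank-correlated, as observed for real 3Di predictors. The
`remote_homology` profile (AA divergence 0.2, 3Di divergence 0.05) encodes
the regime the method exists for: sequences drifting much faster than
structure. Decoys are fresh random sequences with clean confidence tracks.

What the generator does **not** emulate: realistic residue composition and
domain structure, correlated substitution processes, homologous families
with more than one member, or alignment-quality (TM-score/LDDT) columns —
so passing the recovery tests shows the machinery is correct and calibrated
on its stated conditions, not that real-genome annotation rates will match.

## Problem sizes and determinism

Every stochastic component takes an explicit seed (numpy `default_rng`) and
is a pure function of (spec, seed). The test suite runs the full pipeline
at database size 500 with 200 planted queries and 100 decoys, calibration
soundness on 10 000 null pairs, and oracle equivalence on 500 small pairs —
sizes chosen so the whole suite completes in well under a minute after JIT
warm-up while keeping binomial error bars far from the asserted thresholds.

## Known limitations

* TM-score and LDDT cannot be computed by a sequence-level aligner; they
  are accepted as optional input columns and used only by the curation
  rules.
* The Gumbel fit assumes the score distribution is not degenerate; databases
  with pathological single-symbol composition are rejected.
* Gene calling is out of scope: GenBank input supplies CDS coordinates, and
  protein-FASTA input yields coordinate-free records.
* The bundled 3Di matrix is synthetic; for real 3Di data supply the
  trained matrix file through `SearchParams`.
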