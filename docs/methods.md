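# Methods

This note records the models behind crossclean, the parameters that matter,
what the synthetic data does and does not emulate, and the numerical choices
made where the design was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Detection model

### Suspicious pairs

Two transcripts from different samples are suspicious when they share a
local nucleotide match with identity strictly above `min_identity` (default
95%) over strictly more than `min_length` (default 40) aligned columns.
Candidates are anchored by shared exact `seed_len`-mers (default 20,
canonical form, both strands); every anchored diagonal is scanned
exhaustively with a best-window search maximising the excess score
`100·matches − min_identity·length` over windows longer than `min_length`.
A positive optimum certifies the thresholds, so every reported hit carries a
verified identity and length — the detector can produce false negatives
(when no seed anchors the region) but no false positives relative to the
thresholds.

Three semantic choices:

* **Match-terminated windows.** Qualifying windows must begin and end on
  matched columns, as maximal-scoring segment pairs do. Without this, any
  39-match exact segment flanked by two mismatches would count as 39/41 =
  95.1% over 41 nt and the length threshold would lose its meaning.
* **Ungapped scan, no gapped refinement.** The divergence processes this
  tool targets (and the simulator implements) are substitution-dominated;
  on a seeded diagonal the exhaustive window scan is complete for ungapped
  matches, which keeps the detector/oracle relationship one-sided (a
  detector hit is always oracle-certifiable). A gapped heuristic extension
  would add sensitivity only for indel-divergent homologs while breaking
  that guarantee.
* **Within-sample matches are discarded.** Isoforms and paralogs of the
  same sample are similar for biological reasons and are not evidence of
  contamination.

The validation oracle (`sw_oracle`) is independent of the production path:
an exhaustive ungapped window search over *all* diagonals (no seeding,
vectorised over the sheared match matrix) OR an optimal gapped local
alignment at match +1 / mismatch −2 / gap −3 (gap columns count as
non-identities). It is quadratic and refuses sequences above 5 kb.

### Quantification

All assemblies are concatenated into a metatranscriptome under namespaced
ids (`sample::transcript`; the separator is rejected in input ids rather
than silently mangled). Reads are assigned by k-mer pseudo-alignment:

* k = 31 (odd, so the canonical min(forward, reverse-complement) form is
  unambiguous; 31 is the largest k fitting 2-bit-packed in a signed int64
  and the field's customary default). k-mers containing N are skipped.
* A sequencing unit is a read, or a mate pair with pooled k-mers. The unit
  is assigned to the entry (or entries) containing the largest number of
  its k-mers, provided that number reaches `min_kmer_frac` (default 0.7) of
  the unit's valid k-mers; ties are split equally. 0.7 tolerates the 0.5%
  simulated error and moderate within-read divergence while rejecting
  spurious assignments. No EM re-allocation: for the contamination decision
  only the focal/alien ratio matters, and the equal split is conservative —
  genuinely ambiguous transcripts drift toward `dubious` rather than toward
  a confident call.
* TPM uses the plain transcript length, not an effective length: the
  simulation defines abundance directly on transcripts, and no fragment
  length model is estimated. TPM is computed per sample over the **full**
  metatranscriptome denominator, so a transcript's values are comparable
  across samples; per-sample columns sum to 10^6 whenever any read maps.

### Classification

With N_f the focal-sample TPM and N_a the maximum alien TPM, thresholds
X = 2 (fold), Y = 300 TPM (over-expression), Z = 0.2 TPM (low coverage):
low_coverage if every sample is below Z; else over_expressed if at least
`overexp_min_samples` (default 3, focal included) samples exceed Y; else
clean if N_f > X·N_a, cross_contamination if N_f < N_a/X (source = argmax
alien, ties broken lexicographically with a logged warning), dubious
otherwise. Decisions embedded here:

* The absolute-level categories pre-empt the ratio rules: a transcript
  barely sequenced anywhere, or suspiciously abundant everywhere, has an
  untrustworthy ratio.
* Exact boundary equalities (N_f = X·N_a or N_f = N_a/X) fall to dubious:
  the clean/contamination inequalities are strict.
* N_a is the maximum over **all** alien samples, not only those with a
  suspect hit: the quantification yields all columns anyway and the maximum
  is the conservative contaminator candidate. (`classify_transcript`
  accepts any alien subset, so hit-restricted behaviour is reachable.)
* N_a = 0 with N_f > 0 is clean (N_f > X·0); N_f = N_a = 0 with every
  sample below Z is low_coverage.
* With two samples the 3-sample over-expression quorum can never fire; a
  warning says so.

### Network

Only strict cross_contamination calls enter the graph; each adds weight 1
to the edge source → contaminated sample, so in-weights equal per-sample
contaminant counts exactly (a test recomputes this by brute-force tally).
Node attributes: transcript count, percentage of own transcripts
contaminated, total out-going contamination events (a transcript
contaminating several targets counts once per event). `prune_weak_links`
returns a rendering copy without edges below 2% of the strongest edge;
exports always contain the full graph.

## Simulation model

The generator reproduces the benchmark setting of contamination between
closely related species:

* **Reference.** `n_transcripts` random sequences; lengths log-normal with
  median 1 kb (σ = 0.45 on the log scale, floor 200 nt) — a typical
  assembled-transcript length profile; abundances log-normal (σ = 1.5
  natural-log units, a realistic bulk RNA-seq spread) normalised to 10^6
  TPM, i.e. a virtual pool of one million mRNAs.
* **Divergence.** i.i.d. substitutions at the requested rate, uniform over
  the three alternative bases; no indels. The divergent sample inherits the
  reference abundance profile unchanged.
* **Transfer.** `n_mrnas` molecules (default 10,000) drawn multinomially
  from the source pool. Each sampled species survives sequencing + assembly
  with probability 0.483 at one transferred copy, 0.933 at ten or more,
  log-linear in copy number between — the curve is user-replaceable by a
  table. Survivors are appended **verbatim** to the recipient assembly with
  contaminant TPM equal to the transferred copy count (pool-to-pool
  bookkeeping); re-assembly is emulated by the survival curve, not
  executed. The combined profile is re-normalised to 10^6.
* **Reads.** Per-transcript fragment counts multinomial on TPM/10^6;
  fragment length normal(250, 25) truncated to [read length, transcript
  length]; read length 100 nt; mate 2 reverse-complemented from the
  fragment's 3' end; every base substituted with probability 0.005
  (substitution-only uniform error, no indels, no quality model; quality
  strings constant). All randomness flows through one seeded generator, so
  a bundle is byte-reproducible and its truth table exact.

What the synthetic data does **not** emulate: indel divergence and
rearrangements, chimeric or fragmented mis-assemblies, transcript-variant
redundancy within a sample, coverage biases (GC, positional), quality-score
structure, and re-assembly artefacts beyond the survival probability.
Passing the simulation benchmark therefore demonstrates the pipeline's
behaviour under substitution divergence and realistic abundance/transfer
dynamics, not robustness to assembly pathology — on real data those
pathologies mostly surface as dubious/low_coverage calls.

## Benchmark and problem sizes

The accuracy harness runs, per cell: reference + divergent copy,
unidirectional injection (divergent → reference), reads for both samples,
the full pipeline at default parameters, scoring against the truth table.
Sensitivity counts only strict cross_contamination calls on effective
(kept) contaminants — dubious and low_coverage calls on true contaminants
are misses, reported separately. The false-positive rate is computed over
all non-injected transcripts of both samples.

Desk-scale defaults — 500 transcripts and 200,000 read pairs per sample —
are a ~60–100× reduction of the original benchmark setting (tens of
thousands of transcripts, 20M reads), chosen so a full grid runs in minutes
while keeping several hundred effective contaminants per run. At this scale
relative abundances are correspondingly larger, so per-species transfer
copy numbers are higher than at full scale; the survival curve still spans
its full range. `scripts/acceptance.py` uses 3% and 5% divergence × three
seeds.

## Numerical choices

* Strict thresholds throughout (">" not "≥"), matching the rule
  definitions; window certification uses an excess-score tolerance of 1e-9.
* k-mer integer encoding is exact int64 arithmetic (base-4 polynomials,
  binary-doubling composition); no hashing, no collisions.
* Seeds occurring at more than 64 positions are skipped as repeat-like
  anchors; with ≥ 15-nt seeds on non-repetitive data this is vacuous.
* Fractional tie-splits are exact binary fractions for ≤ 2 tied entries
  (the common case); TPM conservation is asserted to 1e-6 relative.
* Degenerate inputs: all-zero counts give all-zero TPM; an empty truth
  table gives undefined (None) sensitivity; an empty graph prunes to
  itself.

## Known limitations

* Contaminants that receive zero reads in every sample are genuinely
  undetectable by an expression-based rule and land in low_coverage; at
  very shallow depth this caps sensitivity below 100%.
* Samples below ~1–2% divergence blur the suspect stage's identity
  threshold and the quantifier's read assignment simultaneously; calls
  shift toward dubious, which is the intended conservative behaviour.
* One internal quantifier is shipped; no external mapper back-ends. The
  classification layer is back-end-agnostic by contract (it consumes an
  expression matrix), so an external quantification can be substituted
  programmatically.
* No probabilistic contamination score: the rule system is deterministic
  thresholds, by design.
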