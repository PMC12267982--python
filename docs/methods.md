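# Methods

This note documents the models and procedures implemented in metabloom,
the defaults and why they were chosen, what the synthetic data does and
does not emulate, and the numerical choices that matter when reading or
extending the code.

## Sketching

Sequences are reduced to sets of 64-bit values before any comparison.

- **Canonicalization.** A k-mer and its reverse complement are the same
  observation on opposite strands; we encode both under the 2-bit order
  A < C < G < T and keep the numerically smaller one, making all matching
  strand-agnostic.
- **Hashing.** The canonical code is XOR-ed with a pre-mixed seed and
  passed through the splitmix64 finalizer. Bloom filters need uniformly
  distributed values; splitmix64 is a well-tested 64-bit mixer and is
  trivially seedable, which keeps index and query sketches reproducible
  and comparable. The seed is stored in the index and checked at query
  time.
- **Winnowing.** With window size w > k, each window of w − k + 1
  consecutive k-mers contributes only its minimum hash. Ties go to the
  leftmost position; since the output is the *set of values*, tie-breaking
  affects nothing observable. Windows are the standard sliding kind with
  no terminal densification, so a sequence shorter than w (but ≥ k)
  sketches to the empty set.
- **Ambiguous bases** invalidate exactly the k-mers that span them; a
  window whose k-mers are all invalid contributes nothing. A single N
  therefore costs at most k k-mers, never the whole read.
- **Defaults k = 19, w = 31.** Conventional for minimizer-based
  classifiers of short reads: k = 19 is long enough that random 19-mer
  collisions between unrelated genomes are negligible (4^19 ≈ 2.7e11),
  and w = 31 keeps roughly 2/(w − k + 2) ≈ 14% of k-mers, a good
  space/sensitivity trade at desk scale.

## Index

- **Bloom sizing.** `m = ceil(−h·n / ln(1 − p^(1/h)))` is the smallest
  filter with predicted false-positive rate ≤ p at n elements under the
  standard independence model. Defaults p = 0.05, h = 4, t_max = 64
  technical bins per IBF level.
- **Interleaving.** An IBF is stored as an (m × bins) boolean matrix: row
  j is bit j of every technical bin, so one hash probe gathers a
  membership row for all bins at once. Filters in one IBF must share one
  m; m is sized for the largest content assigned to that level.
- **Greedy layout.** Bins are sorted by cardinality (descending); the
  per-technical-bin capacity is `ceil(total_n / min(t_max, B))` for B
  user bins. Dividing by `min(t_max, B)` rather than t_max makes a
  collection of similar-sized bins lay out flat (one technical bin each)
  instead of being shredded to fill unused slots. A bin above capacity is
  split across `ceil(n / capacity)` technical bins, its sorted values
  dealt round-robin (deterministic and balanced). If the remaining bins
  outnumber the free technical bins, the smallest are merged; the number
  of merged bins is the fewest that keeps every child level at ≤ t_max
  members, which bounds recursion depth. The published HIBF literature
  optimizes the layout by dynamic programming; we deliberately use this
  greedy rule and treat the *query contract* — per-user-bin counts, no
  false negatives, Bloom-bounded false positives — as the compatibility
  surface. Degenerate imbalance that would overflow a level doubles the
  capacity until the level fits.
- **Split-part counts.** A user bin split over several technical bins
  reports the sum of its parts. A query value can double-count through a
  Bloom false positive in a sibling part, so aggregated counts are
  clamped to the query cardinality; querying a bin with its own full
  minimizer set therefore returns exactly its cardinality, and the
  remaining excess on partial queries is bounded in expectation by p·|q|
  per technical bin.
- **Merged bins** store the union of their members' values and act only
  as a gate: a positive count triggers descent into the child IBF, and
  counts are reported exclusively at user-bin resolution.
- **Serialization** is a magic-tagged binary format: JSON header (params,
  layout, target→taxid map, genome sizes, taxonomy) followed by the
  packed bit matrices in depth-first order. Construction and headers are
  fully deterministic, so identical inputs give bit-identical files.
  Truncation or a foreign magic number raises a format error rather than
  corrupting silently.

## Classification thresholds

Reads (mate pairs are sketched jointly as one union set — one
classification unit per pair, avoiding double counting) pass three stages:

1. **Cutoff** c ∈ [0, 1]: keep targets sharing ≥ `ceil(c · q_card)`
   minimizers; c = 0 keeps any positive count. Default 0.25.
2. **Spurious-match removal**: with the database's max false-positive
   rate p, a shared count explainable as Bloom noise is discarded. The
   threshold t\* is the smallest t with P(X ≥ t) < α for
   X ~ Binomial(q_card, p); counts ≥ t\* are kept. Default α = 1e−5.
   (The direction matters: as p → 0, t\* → 1 and any positive count
   survives.)
3. **Filter** f ∈ [0, 1]: keep matches with count ≥
   `best − f·(best − worst)`. f = 0 keeps best-score ties only; f = 1
   keeps everything. The filter can only prune extra matches of an
   already-classified read, never unclassify it. Default 0.

Classification is per read and order-independent; the `--threads` flag is
accepted as advisory (the implementation is sequential, which satisfies
the contract that multi-threaded results be identical trivially).

## Multi-match resolution

- **EM.** Targets carry weights initialized from unique-read counts plus
  a pseudocount of 1 (so targets with no unique evidence are not locked
  at zero; with no unique reads anywhere this is a uniform start).
  E-step: a read's responsibility for a candidate is proportional to the
  candidate's weight — shared-count magnitudes deliberately do not enter,
  so reassignment follows the distribution of uniquely matching reads.
  M-step: weights ∝ unique counts + summed responsibilities (no
  pseudocount here, so the update is exact EM and the observed-data
  log-likelihood is non-decreasing every iteration; the trace is kept on
  the returned state and asserted in tests). Iteration stops when the
  hard argmax assignments stop changing, or at max_iter = 100. Final
  ties break by higher shared count, then lexicographically smallest
  target id. Note that when nearly all reads are ambiguous between the
  same candidates, the *weights* estimate the mixture proportions
  correctly while the hard argmax assigns all ambiguous reads to the
  heaviest candidate — proportion questions should read the weights.
- **LCA.** Multi-matching reads are lifted to the lowest common ancestor
  of their candidates' taxa; unique reads are untouched.
- **EM + LCA.** EM first; reads whose candidates remain exactly tied in
  weight are lifted to the LCA of the tied candidates instead of being
  tie-broken arbitrarily.

Genome sizes enter only at the reporting stage, never the EM likelihood,
mirroring the pipeline order (classification → resolution → profiling).

## Profiling

Genome sizes per taxon are the arithmetic mean of assembly lengths in the
taxon's subtree (the aggregation had to be chosen; the mean is simple,
deterministic and testable against a brute-force subtree enumeration);
taxa without descendant assemblies inherit the nearest ancestor's value.

For each directly assigned taxon, corrected mass is read_count / size;
abundance is `classified_fraction · 100 · mass / Σ mass`, then counts and
masses cumulate bottom-up so each fully populated rank plus the
unclassified percentage sums to 100. The unclassified fraction is carried
explicitly: reporting a forced 100% over detected taxa inflates
abundances whenever the references do not cover the sample.

**Thresholding** removes rows with abundance ≤ the threshold, per rank
independently, and does **not** renormalize: the removed mass is carried
as a per-rank "filtered" percentage so conservation stays checkable. The
default threshold is 0; evaluation protocols typically apply something
like 0.005% to cut the false-positive tail.

One structural caveat: mass assigned above a rank (e.g. LCA assignments
at genus) has no representative at the species rank, so rank sums below
the assignment level undercount by that mass. Conservation at every rank
holds exactly when all assignments are at or below the reporting rank.

## Evaluation metrics

- **Binning** (per read, at a rank): a read is TP when the rank-ancestor
  of its predicted taxon equals that of its true taxon; a wrong
  at-rank prediction counts FP and FN; unclassified or above-rank
  predictions count FN. Reads whose *truth* does not resolve at the rank
  are excluded from the denominator (a genus-level truth cannot score
  species-level predictions). Precision = TP/(TP+FP), sensitivity =
  TP/(TP+FN), F1 = harmonic mean, zero denominators give 0.
- **Profiling** (per taxon, at a rank): presence/absence F1 over the two
  taxon sets, and the L1-norm error Σ|pred% − truth%| over their union —
  0 to 200 for profiles bounded by 100%. Thresholding before metric
  computation is the caller's choice.

## Synthetic communities

The simulator generates what the evaluation needs and nothing more:

- i.i.d. uniform ACGT genomes per species (unbalanced lengths, default
  50–150 kb — desk-scale stand-ins for Mb genomes), optional strains
  mutated from the species base genome by independent substitutions at a
  set divergence (strain 0 *is* the base; pairwise divergence between two
  non-base strains is therefore ≈ 2× the parameter);
- a fixed-ladder taxonomy (superkingdom → species, halving group indexes
  each step so adjacent species share lower ranks);
- an abundance vector (explicit per species or per genome, else
  log-normal σ = 1 — the long-tailed shape typical of real communities);
- uniform-position reads, paired from opposite fragment ends (default
  2 × 150 bp, insert 300) with independent substitution errors (default
  1%, a generous bound for modern short-read platforms);
- exact truth: per read the source assembly and species, and a taxonomic
  truth profile derived from the realized reads through the *same*
  genome-size-correction code path the reporter uses — read-fraction
  (sequence abundance) and organism-fraction (taxonomic abundance)
  bookkeeping cannot drift apart.

Everything is deterministic under the configured seed, to the byte.

What it does not emulate — and hence what passing tests do not show about
real data: indels and quality-correlated errors, shared gene content and
horizontal transfer between species (simulated genomes are unrelated, so
cross-species multi-matching is rare), plasmids, contamination, GC bias,
and real taxonomy quirks (missing ranks, merged nodes). Strain-level
hardness is emulated only through uniform substitution divergence.

## Problem sizes

Tests and the acceptance script run on deliberately small instances —
communities of 10–20 species of ~100 kb, 2,000–5,000 reads, indexes of
50–300 bins with up to 5·10^4 minimizers — chosen so the full suite
completes in well under a minute while still forcing every structural
case (splits, merges, multi-level descent, multimatch resolution).

## Known limitations

- The HIBF layout is greedy, not space-optimal; only query results are
  contractual.
- No long-read chunking, spaced seeds, syncmers, or protein alphabets.
- Indexes are rebuilt, not updated in place; no disk-streamed partitions.
- EM ignores match-count magnitudes by design; a likelihood over counts
  (or genome-size-aware EM) is out of scope.
- The spurious-match test treats query minimizers as independent Bloom
  probes; correlated minimizers from repeats slightly violate this.
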