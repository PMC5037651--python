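# Methods

## The model

seedlex implements seed-driven lexicon induction in a random-indexing word
space.  The distributional hypothesis — words occurring in similar contexts
tend to have similar meanings — is operationalised geometrically: each
semantic unit of a segmented corpus is a point in R^d, and candidate terms
for a semantic category are the unknown units closest (by cosine) to the
known terms of that category.

**Index vectors.**  Each unit receives a fixed sparse ternary vector with k
non-zero entries, k/2 of each sign, at positions drawn from a PCG64 generator
seeded by a SHA-256 hash of `(master_seed, unit)`.  Hash seeding makes the
space reproducible and independent of corpus streaming order, and the
balanced signs make every index vector sum to zero, so accumulation is
unbiased.  At d = 2000, k = 10 (the defaults), the expected number of
position collisions between two index vectors is 0.05, so random pairs are
nearly orthogonal — the property that lets a 2000-dimensional space stand in
for a vocabulary-sized co-occurrence matrix without explicit factorisation.

**Direction vectors.**  A unit's semantic vector is the sum of the (rotated)
index vectors of its window co-occurrents.  Rotation is one circular step:
left-context units are rotated left, right-context right, which encodes word
order ("direction vectors"); rotation by the window offset instead of one
step is available behind `rotate_by_offset` but off by default — one step is
the documented standard and the offset variant is a known alternative, not
the default behaviour.  All context positions carry equal weight.  Windows
never cross sentence boundaries and no boundary markers are added; in short,
sentence-final units simply have truncated windows.  Entries therefore stay
integers, which the persistence format and several exactness tests exploit.

**Frequency cutoff.**  Units occurring at most `min_frequency` times are not
eligible as seeds or candidates but still contribute context to other units'
vectors (the cutoff filters *terms used*, not evidence).  By default an
occurrence counts only when the sentence contains at least one other unit —
an isolated unit has no context; `count_isolated` switches to raw counts.

**Clustering.**  Seed vectors are agglomerated under centroid-cosine linkage:
at each step the two clusters whose unnormalised mean vectors have the
largest cosine are merged and the centroid is recomputed.  Cosine to a
centroid is scale-invariant, so normalising the centroid would change no
ranking; the unnormalised mean is kept because it is exactly recomputable
from the leaves.  Ties in the maximal cosine are broken by the pair whose
lexicographically smallest member is smallest — determinism is required for
reproducible runs and oracle tests, and the choice is otherwise arbitrary.
"Cluster level L" is the cut keeping the highest nodes of at most L members:
L = 1 treats each seed as its own cluster, L = |S| is the single root, and
increasing L walks monotonically up the tree (partitions nest).

**Ranking.**  Candidates are all eligible units outside the seed set —
held-out vocabulary terms included, since they are exactly what evaluation
must retrieve.  Cluster similarity is the maximum cosine to any partition
centroid; summed similarity is the sum of cosines to every seed vector.
Equal scores are ordered by ascending term.  No score threshold is applied:
lists are truncated by count, not by similarity.

**Evaluation.**  Each fold draws `seed_size` seed terms uniformly without
replacement from the eligible vocabulary (a duplicated seed would be
meaningless for clustering); the remaining n terms are held out and recall is
measured among the top m·n candidates, m = 1 … 10.  Folds are aggregated
with the arithmetic mean, nearest-rank 2.5 %/97.5 % percentiles and the
population variance (dividing by the number of folds — the statistics are
descriptive, not inferential).  The analytic baseline is the expectation for
a randomly ordered list of the V eligible units: t·n/V retrieved terms among
the top t.

A note on V in the null model: the candidate list excludes the seed terms, so
the exact null for the *measured* quantity uses the universe size V −
seed_size.  At the scale the method is designed for (hundreds of seeds among
tens of thousands of eligible units) the distinction is negligible and the
reported baseline uses V; the statistical calibration tests use the universe
size, because at test scale seed_size/V is a few percent and would otherwise
bias the comparison.

## The synthetic corpus

The generator emulates the one property the method needs from real data:
category terms co-occur preferentially with a category-specific inventory of
context words.  Each sentence has a topic (a category, or background with
probability 0.35).  Category sentences contain one to three vocabulary-term
slots; all remaining slots are context slots filled from the topic's
inventory (40 words per category, of which 12 are verbs carrying lemmas;
background draws from its own 3000-word vocabulary).  With probability α
(`mixing_rate`) any slot is instead filled uniformly from the global lexicon.
Case particles are interleaved after slots with probability 0.25, so both
pre-processing presets operate on realistic tag material.

Two design points deserve emphasis:

* **α = 1 is fully exchangeable by construction.**  Mixing draws come from
  the *global* lexicon, not from other categories' inventories: if mixed
  slots drew only from other categories, category terms would still co-occur
  with each other and with non-background words at α = 1, leaving exploitable
  signal.  With global draws, at α = 1 every slot of every sentence is an
  i.i.d. uniform pick, the category label is independent of everything, and
  pipeline recall must match the random baseline — which is exactly the
  degenerate case the evaluation is calibrated against.

* **Coupled randomness across α.**  Structure decisions (topics, lengths,
  slot types, particle positions, within-inventory picks), pool picks and
  mixing uniforms come from three independent streams, so corpora generated
  at different α from one seed differ only in the slots whose mixing uniform
  falls between the two α values.  Recall-versus-α comparisons therefore see
  the mixing effect, not resampling noise.

Term frequencies are Zipf-shaped (exponent 1.5 over the 150 terms of a
category, 0.5 over the background vocabulary), so a realistic fraction of
vocabulary terms falls below the frequency cutoff and is excluded from the
eligible vocabulary — mirroring the way low-frequency terms are the ones a
corpus-driven method cannot see.  An optional confound group (`confound=True`)
plants non-vocabulary terms sharing a high-frequency context verb with
category 0; such terms rank high by construction, documenting the confusable-
neighbour behaviour rather than hiding it.

### Reference benchmark conditions

`benchmark.py` fixes the conditions used by the test suite and the
reproduction script: default generator (3 × 150 vocabulary terms, α = 0.05,
~100k tokens), `content-lemma` preset, d = 2000, k = 10, w = 1, cutoff 5,
seed sets of 45 terms, 100 folds, multiples 1–10, and the degradation grid
α ∈ {0.05, 0.25, 0.5, 0.75, 1}.  The seed size and vocabulary Zipf exponent
follow from design arithmetic: with V ≈ 2700 eligible units, near-complete
recall at top 10n can exceed the baseline tenfold only if n ≲ V/100 ≈ 25, so
the Zipf exponent was set to leave ≈ 60 eligible terms per category and the
seed size to hold out n ≈ 15–20 of them.  Fold counts (100 rather than 500)
keep the full sweep within a few minutes on one CPU; the statistics reported
are means over folds, so only their standard errors widen.

### What the benchmark does and does not show

Passing on synthetic data shows the machinery is correct: accumulation,
clustering, ranking and the fold protocol do what the model says, recall
degrades monotonically as planted structure is removed, and the method
collapses to the analytic baseline when no structure exists.  It does not
show that real corpora of patient-authored text carry signal of any given
strength: real categories overlap, real context inventories are neither
disjoint nor fixed-size, morphological segmentation is noisy, and polysemy
and register variation have no synthetic counterpart.  Absolute recall values
on the benchmark are therefore not predictions for real vocabularies.

One realistic artefact does appear: the top of a ranked list is dominated by
the category's own context words (on the benchmark, roughly the first 40
positions), so recall in the top n is small even when recall at 10n is
essentially complete.  This is the planted analogue of the high-ranking
confusable neighbours observed when the method is applied to real corpora,
and it is why the evaluation inspects up to 10n candidates.

## Numerical choices and degenerate inputs

* Cosine with a zero vector raises an error — it is undefined and must not be
  silently 0.  Zero accumulated vectors essentially cannot occur above any
  reasonable cutoff, but the contract is explicit.
* Integer accumulation makes space construction, persistence round-trips and
  the brute-force accumulation oracle exact (no tolerance needed).  Clustering
  centroids are exact integer sums divided by counts, so the O(n³) oracle
  comparison is also exact.
* Rankings computed through a single BLAS matrix product and through
  per-vector cosines agree only to summation-order rounding (last ulp);
  equality tests on rankings round scores to 12 decimals before applying the
  lexicographic tie-break.
* Candidate scores are serialised with six decimals — enough to preserve
  ordering for realistic list lengths; reports are JSON, whose floats
  round-trip exactly.
* Percentiles use the nearest-rank definition (no interpolation); with one
  fold, both percentiles equal the single value.
* `recall_at` uses the whole list when it is shorter than m·n, and held-out
  terms absent from the candidate universe count as not retrieved at every
  multiple.

## Limitations

* Morphological analysis is out of scope: the package consumes tagged input
  and implements only the selection/lemmatisation policies.  Tag inventories
  differ across analysers; the policy table is the extension point.
* Inflection units (polarity/mood/voice) are treated as standalone tokens
  emitted upstream, not fused onto the verb.
* The emoticon inventory is a small default pattern list, user-extensible; no
  completeness claim is made.
* Only equal window weighting and one-step (or offset) rotation are
  implemented; other weighting schemes and embedding models are out of scope.
* Evaluation measures recall against an existing vocabulary only; precision
  of genuinely novel candidates requires human review (the unique-top-
  candidates reduction exists to support exactly that workflow).
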