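# Methods

## Model

Self-consistency grouping (SCG) clusters *n* objects using only the
*ordering* of pairwise scores. For an object *x*, rank(*x*, *y*) = *p* when
exactly *p* − 1 objects (including *x*) are more similar to *x* than *y* is;
every row of the rank matrix is a permutation of 1..*n*, rank(*x*, *x*) = 1,
and the relation is asymmetric. A set *S* with |*S*| = *k* < *n* is a
cluster iff rank(*x*, *y*) ≤ *k* for all ordered pairs in *S*; clusters of
size *n* are disallowed (a "cluster" containing everything carries no
information). Singletons pass trivially.

Two consequences drive everything else:

1. **Prefix structure.** Any cluster of size *k* containing *x* consists of
   exactly the *k* objects ranked 1..*k* by *x* (each member has rank ≤ *k*
   w.r.t. *x* and the row is a permutation). Hence all candidate clusters
   are row prefixes of the sorted-rank matrix.
2. **Laminarity.** Two clusters sharing an object are prefixes of the same
   row, so one contains the other. The full cluster family is laminar and is
   represented as a forest (leaves = objects, roots = independent clusters).

Assumptions worth stating: the input scoring need not be a metric, need not
be symmetric, and may even be an arbitrary per-object ranking that no
geometry realises — the algorithms only use the permutation structure.
Because only order matters, ranks (and therefore all outputs) are invariant
under strictly monotone transformations of the scores.

## Algorithms

All three algorithms test row prefixes with the O(k²) cluster test and
differ in scheduling. The *candidate index* of a prefix — its maximum
internal pairwise rank — is a lower bound on the size of any cluster
extending it, which lets the faster algorithms skip infeasible sizes.

- **A1** sweeps sizes f = 2..n; at each size each object not yet absorbed at
  this size is tested. Finds every cluster smallest-to-largest, so the
  forest carries the complete subcluster structure. Worst case O(n⁴).
- **A2** ("SCG-fast") scans one object at a time, jumping its prefix length
  to the candidate index after each failure, and stops a row when an
  already-claimed object enters the prefix, the candidate index reaches n,
  or the row ends; the largest cluster found (possibly the singleton) is
  then retired. It provably finds every independent cluster, but the
  internal structure it happens to record depends on the examination order
  (the implementation defaults to ascending id and accepts any order).
- **A3** gives every object an index starting at 2 and always processes the
  objects at the global minimum index (ascending id within a round).
  Successes bump all members past the level; failures raise the object's
  index to its candidate index; candidate index n retires the object for
  good. The minimum index is strictly increasing, all members of a cluster
  formed at level m provably hold index m, and the final forest equals A1's.

Both equivalences (A1 ≡ A3, A2 ≡ maximal clusters) are exercised in the test
suite against a brute-force enumerator over all subsets (bounded at n ≤ 15)
on hundreds of random instances — both arbitrary permutation matrices and
point-derived rank matrices.

**Examination accounting.** A1 charges every prefix test it performs. A2 and
A3 charge a test iff it succeeds or fails with an informative candidate
index (< n); a failure whose candidate index equals n merely retires the
object. This is the accounting used by the examination counters exposed on
every run object.

**Tie handling.** Equal scores are ordered by ascending object id (stable
sort), and the object itself is always rank 1 regardless of the stored
self-score. Tie-free inputs are unaffected by the rule. No other tie policy
is provided; a randomised rule would make the deterministic algorithms
order-dependent for no benefit.

**Sparse score lists.** Pair lists ("id1 id2 score") are densified with
missing pairs ranked strictly worse than every observed score (via a missing
mask, or a numeric fill one unit beyond the worst observation). A single
direction fills both ordered entries unless the opposite direction is listed
explicitly; duplicate records keep the better score with a warning (or raise
under a strict flag).

## Subcluster management

Forest merging follows the union-of-roots scheme: when a cluster forms, the
current roots of its members become children of a new node, so previously
found subclusters are attached intact. A merge whose member set straddles an
existing root raises `LaminarityError` — for genuine clusters this cannot
happen (laminarity above), so the error doubles as an internal consistency
check. Newick export lists children by ascending smallest member and quotes
labels only when necessary; nesting paths ("2/1" = first subcluster of the
second root) provide a flat TSV rendering of the hierarchy.

## Baselines and iSCG

Single/complete/average linkage are delegated to
`scipy.cluster.hierarchy.linkage`, cut either at a distance cut-off δ
(flat clusters whose linkage heights are ≤ δ — for complete linkage this is
exactly "merge while the maximum cross-pair distance is ≤ δ") or into a
requested number of groups (`maxclust`). Because these three linkages are
equivariant under a rigid shift of all distances, matrices containing
non-positive entries (noise-perturbed distances) are shifted into the
positive range and the cut-off shifted identically; the result is exact.
Single-linkage cutting is additionally verified in the tests against an
independent oracle (connected components of the ≤ δ threshold graph).

Iterative SCG collapses each independent cluster (singletons included) into
a super-object, recomputes inter-group distances by one of three strategies
— `min`, `avg` or `max` over cross pairs, SL/AL/CL-flavoured respectively —
rebuilds the ranks, and re-runs A3; iteration stops when a pass forms no
non-singleton cluster, when fewer than three groups remain (a size-m cluster
over m groups is disallowed), or at `max_iter`. Each pass's structure is
nested into the accumulated forest, so membership grows monotonically. For
`avg`, the default averages all original cross-member pairs; an alternative
(`avg_update="group"`) averages the previous level's group distances
unweighted, WPGMA-style — the choice matters only when group sizes are very
uneven, and both are exposed because neither is canonically "the" average.

## Evaluation metrics

A flat clustering is scored against a reference partition by decomposing
every cluster into unordered pairs; a pair is incorrect iff its members lie
in different reference groups. Counts are computed from the
cluster-by-reference contingency table (sums of C(m, 2) over cells and
margins), never from materialised pair lists, so they scale to large
partitions. Partition similarity defaults to the Jaccard index of the two
within-cluster pair sets (1 iff the pair sets coincide; two all-singleton
partitions are identical); Rand and adjusted Rand are available and delegate
to scikit-learn. Size histograms bucket cluster sizes 1..5 with a ">5"
overflow bucket.

## Noise-robustness simulation

The benchmark draws 20 points around each of four planar centers (0, 8),
(0, −8), (8, 0), (−8, 0) with independent N(0, 1) coordinate offsets —
blobs of spread ≈ 1 separated by ≈ 11–16, so the intended partition is
unambiguous at zero noise — computes all-pairs Euclidean distances, and
perturbs each unordered pair with one N(0, sd²) draw (symmetry preserved,
diagonal untouched) for sd on a grid from 0 to 3 in steps of 0.25, 100
replicates per sd. Per replicate and method it records the number of
clusters (singletons included; independent clusters for SCG via A2, flat
groups for CL/AL/SL at cut-offs 2 and 4) and the number of incorrect pairs
against the generating centers. Perturbed distances may be negative and are
deliberately not clamped: SCG consumes ranks, and clamping would manufacture
ties.

By default the point set is drawn once and replicates redraw only the
perturbation — the natural design for isolating measurement noise; a
`redraw_points` flag regenerates the points per replicate instead, which
additionally samples the generator's own variability. Under the default
conditions roughly 97% of point draws yield exactly the four generating
blobs as independent clusters; the remaining ~3% contain an outlying point
(≈ 3–4 SD from its center) that breaks the stringent rank condition for its
blob, fragmenting it. This is a property of the model, not a failure mode:
SCG responds to inconsistent ranks by splitting, never by mixing — across
the entire noise grid the incorrect-pair count stays at zero in every
replicate, while the cluster count climbs toward all-singletons.

Randomness is driven by a single master seed through
`numpy.random.SeedSequence` spawning, so every record is reproducible
bit-for-bit.

What the synthetic data does *not* emulate: real structural-similarity
scores are asymmetric, heavy-tailed, approximate and partially missing,
and reference classifications are human-curated; passing these tests shows
the machinery is correct under a clean metric, not that any particular
external corpus would be recovered at a given accuracy.

## Problem sizes and numerical choices

The test suite runs the brute-force oracle at n ≤ 12–16 (subset enumeration
is exponential) and the full noise sweep at its native size (80 points ×
13 SDs × 100 replicates — a few seconds, since A2 performs only a handful of
O(k²) prefix tests per object). The acceptance script reports the
independent-cluster count of SCG on clean four-blob data over 100 freshly
drawn replicate datasets, taking the mode over replicates as the reported
count (robust to the ~3% outlier draws discussed above). Internal object
ids are 1-based throughout the algorithmic layer; all file I/O speaks
user-supplied labels.

## Known limitations

- The cluster test is exact and stringent by design; there is no
  approximate or sampled variant, and A1 is impractical beyond a few
  thousand objects (use A2, optionally followed by A3 within each
  independent cluster).
- `n_clusters`-mode cutting inherits scipy's `maxclust` behaviour: with
  tied merge heights fewer than K groups can be returned.
- iSCG's iteration count is a blunt stringency dial; expect false positives
  to grow with iterations, and prefer the `min` strategy only when chaining
  between collapsed groups is acceptable.
- Rank construction materialises the full n × n matrix; memory is O(n²).
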