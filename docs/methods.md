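# Methods

This note records the scientific model behind `breps`, the parameters that
matter, the numerical and design choices taken where the design was open,
and what the synthetic benchmark does and does not demonstrate.

## Model and assumptions

The package assumes that isofunctional enzymes, even at moderate overall
identity, share a conserved arrangement of essential residues, and that
this arrangement can be read off the consensus of a multiple sequence
alignment of a sufficiently tight cluster of curated sequences. A pattern
is a deterministic motif — ordered literal, residue-set and bounded-
wildcard positions — not a probabilistic profile; matching is exact
regular-expression matching, which makes verification and search fully
reproducible but sacrifices the soft scoring an HMM would give.

Function is represented by EC numbers, with two further assumptions:
that annotation transfer inside a ≥50 %-identity reference cluster (with a
≤25 % length deviation and a publication requirement) is sound, and that
multiple EC numbers on one entry reflect distinct domains of a
multi-functional enzyme (hence AND-joined proposals).

## Pipeline parameters

| Parameter | Default | Meaning |
|---|---|---|
| length window | 100–7000 aa | seed filter; very short/long entries excluded |
| keyword filter | 6 uncertainty words | case-insensitive substring over the DE text |
| evidence level | PE 1 | protein-level evidence only |
| length deviation | ≤ 0.25 of seed | enrichment from a seed's reference cluster |
| E-value ceiling | 1e-3 | pairwise hits above this count as "no hit" |
| zero-E substitution | 10⁻¹⁸⁰·10⁻ˢ | disambiguates underflowed E-values by bit score s |
| min_leaves | 3 | smallest cluster node that seeds a pattern |
| max_height | none (finite) | merge-height cap for pattern nodes |
| min_informative | 6 | literal+set positions a pattern must have |
| weak_as_set | off | whether '.' columns become residue sets |
| similarity threshold | 0.5 | PAM score above which a pair gets an extension set |
| PPV cutoff | 1.0 | patterns with any false positive are excluded |
| EC match mode | fuzzy | verification comparison of proposal vs annotation |

Units: lengths in residues; distances, ceilings and merge heights on the
log₁₀ E-value scale; PAM scores in the Gonnet-matrix units (10·log₁₀ odds).

## Numerical choices

* **Log-space E-values.** `10^(−180−s)` underflows IEEE doubles for
  s > ≈128, so every distance is stored and compared as log₁₀ E; the
  linear-scale substitution function exists only as a convenience.
* **Symmetrization.** All-vs-all hits are direction-asymmetric; the
  smaller E-value of the two directions is kept. Complete linkage later
  takes maxima over members, so the per-pair choice must be fixed; the
  minimum keeps the strongest evidence.
* **No-hit sentinel.** Absent pairs carry +inf, which sorts after every
  real distance: clusters without alignment evidence merge last, and
  nodes merged at the sentinel are never selected for pattern generation
  even when no height cap is configured — otherwise the tree root
  (joining unrelated families) would always be the unique maximal node.
* **Tie-breaking.** Among equal-distance merge candidates the pair whose
  merged accession tuple sorts first (lexicographically smallest member
  first) merges first; clustering is therefore deterministic.
* **Monotonicity.** Complete-linkage heights are non-decreasing by
  construction (Lance–Williams maximum update); a guard clamps any
  floating-point regression to the previous height.
* **Wildcard spans.** Consecutive unconserved columns merge into one
  `x(min,max)` position with max = run length; columns containing gaps
  reduce min by one each. Per-column gap information bounds the true
  per-row gap count from above, so the span can only be wider than
  strictly necessary — matching stays correct for any row.
* **Non-standard residues.** X/B/Z/U are tolerated in sequences but no
  pattern position (including wildcards) matches them; columns reduced to
  non-standard residues become wildcards. Conservative: a pattern never
  claims a residue it cannot interpret.

## Design choices where the protocol was open

* **Consensus symbols** are recomputed from the standard Clustal strong
  and weak residue groups rather than trusted from any tool's output, so
  pattern rules are aligner-independent. ':' columns become residue sets
  of the *observed* residues; '.' columns default to wildcards because
  weakly conserved columns inflate false positives (config flag to widen).
* **min_informative = 6** keeps the random-match probability per window
  below ~20⁻⁶; shorter motifs are statistically meaningless on a database
  scale.
* **Node selection** (≥3 leaves, maximal non-nested, finite height) is a
  declared reconstruction of the original node-selection rule, exposed as
  configuration.
* **Similarity sets** are derived from Biopython's Gonnet 1992 (PAM250)
  matrix by brute force over all 190 residue pairs; for a pair (a,b) with
  score > 0.5, the set is {c : S(c,a) ≥ S(a,b) and S(c,b) ≥ S(a,b)}.
  Pairs with empty sets are omitted. Extension applies once, to a
  standard pattern; re-extending an extended pattern is rejected rather
  than silently iterated (iteration is not idempotent in general).
* **Consensus-EC algebra.** Candidates are seeded from every distinct
  input EC and folded through the other sequences by always pairing with
  the member EC preserving the deepest consensus (ties: lexicographically
  smallest EC); candidates strictly less specific than a compatible
  deeper candidate are pruned; all-undefined candidates expand into their
  contributing full ECs as OR-alternatives; candidates co-occurring
  within a single sequence are AND-joined. Alternatives keep input order.
* **Verification semantics.** Per-pattern truth comparison uses fuzzy EC
  matching (a proposal of `1.1.-.-` would otherwise always count against
  the pattern); strict matching is a config switch. N (sequences hit by
  no pattern) is a run-level quantity. A pattern that hits nothing has
  undefined PPV and is excluded at any cutoff, since its precision cannot
  be certified.
* **Pattern complexity** is reported as Σ log₂₀(20/|residues|) over
  informative positions — an information-style specificity score used
  for ranking in the database; extension strictly decreases it.
* **Database.** Single-file SQLite with the pattern serialized in a
  PROSITE-like text form (`A-x(2)-[FWY]-C`) that round-trips exactly;
  metadata stores the full build-parameter snapshot. User-facing match
  coordinates are 1-based inclusive; internally 0-based half-open.

## Synthetic benchmark

The generator emulates curated flat-file records (EC annotations, PE
levels, publication references), reference-cluster tables, and mutated
enzyme families: per family a random ancestor with designated conserved
blocks, members mutated at a per-site substitution rate outside the
blocks, plus uniform-random decoys as non-enzymes. The packaged benchmark
uses five families (one multi-functional) of six members, length 300,
substitution rate 0.03, three conserved 12-mer blocks, and 50 decoys —
small enough to run in seconds yet large enough that every pipeline stage
is exercised (clustering separates families; consensus columns contain
all three position kinds; the multi-functional family produces an AND
proposal; verification sees both enzymes and decoys).

What it does **not** emulate: real substitution biases (mutations are
uniform over the other 19 residues, so semi-conserved columns rarely fall
into Clustal strong groups), indel-rich alignments (substitution-only by
default; an indel mode exists), paralogy, shared domains between
families, or database-scale sequence diversity. Passing the benchmark
therefore demonstrates correctness of the machinery — selection,
clustering, pattern construction, annotation, verification, persistence —
not the biological detection rates achievable on real curated data.

## Problem sizes

Default test and benchmark sizes (tens of sequences, hundreds of
residues, 12-point clustering oracles, 1,000-sequence match simulations)
were chosen so the whole suite runs in seconds on one CPU while still
covering every code path; all sizes are parameters and scale up
unchanged.

## Known limitations

* Patterns are hard motifs: one mismatch at a literal position loses the
  hit; there is no score or E-value for a pattern match.
* Identity ≥50 % for enrichment is delegated entirely to the cluster
  table; no alignment is recomputed to re-check it.
* The packaged enzyme-name table is a small curated subset; unknown ECs
  get a placeholder name.
* The CLI accepts a `--seed` for interface stability, but the build is
  fully deterministic and consumes no randomness.
* Live database downloads, XML parsing, isoform handling and a server
  backend are out of scope.
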