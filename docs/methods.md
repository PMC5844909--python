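# Methods

## The classifier

`co1bayes` assigns CO1 barcode queries to leaf taxa (genera in a
genus-trained set, species in a species-trained set) with the RDP-style
naive Bayesian word-frequency model. Sequences are reduced to their 8 bp
words (every sliding window; windows containing any non-ACGT character
are skipped, with no expansion of ambiguity codes, so all counts stay
integral). Training counts per-sequence word *presence* — a word
occurring many times in one sequence counts once — giving the corpus
quantities *N* and *n(w)* and the per-taxon quantities *M<sub>G</sub>*
and *m<sub>G</sub>(w)*. The word prior is
P<sub>w</sub> = (n(w)+0.5)/(N+1), the class conditional
(m<sub>G</sub>(w)+P<sub>w</sub>)/(M<sub>G</sub>+1), and a query scores
each taxon by the naive sum of log conditionals over its word set.
These are the canonical formulas of the cited Bayesian classifier; both
numerator offsets keep every probability strictly inside (0, 1), so all
scores are finite.

Assumptions worth stating: word occurrences are treated as independent
given the taxon (the "naive" step — false for overlapping k-mers but
empirically robust), and the implicit prior over taxa is uniform, so the
posterior argmax is the likelihood argmax.

Decisions the underlying method leaves open, and what this package does:

- **Duplicate query words.** Queries are scored on their *distinct* word
  set by default, matching the presence semantics of training;
  `ModelConfig(use_distinct_words=False)` scores per occurrence.
- **Ties.** Exact score ties are broken by lexicographically smallest
  leaf-taxon name (then full lineage string) for cross-platform
  determinism.
- **Numerics.** Accumulation is in log space; the suite checks agreement
  with an exact rational-arithmetic re-implementation to 1e-9 relative
  tolerance on small instances.
- **Word size.** k = 8 by default and configurable (1–16); brute-force
  cross-checks run at k = 3–4 where exhaustive enumeration is cheap.

## Bootstrap support

The full word set decides the assignment. Each of T = 100 trials draws
⌊W/8⌋ words (clamped to ≥ 1) uniformly *without* replacement — the
subsample share is configurable, and a flag switches to
with-replacement — reclassifies, and records the winning lineage.
Support at a rank is the percentage of trials whose winner matches the
full-set assignment along the entire root-to-rank name path, rounded
half-up to an integer percent. Path (rather than single-name) agreement
makes support monotone non-decreasing toward the root by construction,
and coincides with ancestor-name agreement whenever taxon names are
unique within a rank. Trials vote on the full-set winner, not on a
per-trial mode, matching the "proportion of times the original
assignment is recovered" definition of support.

Each query's random stream derives from (global seed, CRC-32 of the
sequence id), so batch order and parallel decomposition cannot change
any result.

## Leave-one-out benchmarking

For each reference sequence the model's counts are decremented exactly
(N, M<sub>G</sub>, and each distinct word's n and m<sub>G</sub>); taxa
emptied by the removal are excluded from candidacy, which is what makes
a held-out *singleton* — sole representative of its leaf taxon —
structurally incapable of a correct leaf assignment. A fragment is
classified with bootstrap support and the counts are restored. The
decrement/restore path is checked against full retraining (the two must
agree to 1e-9).

Fragments are the full sequence or a contiguous substring of 400, 200,
100 or 50 bp at a uniform random start, one draw per
(sequence, length); replication per sequence is not attempted because
the benchmark design does not call for it. Primer-anchored mode instead
takes the 200 bp adjacent to a located primer site.

Outcomes at a (rank, cutoff): correct-and-passing TP, correct-below FN,
incorrect-and-passing FP, incorrect-below TN, with "passing" defined as
support ≥ cutoff (a strict `>` mode exists; `≥` matches the documented
"0.60 or greater" usage). Correctness, like support, is root-to-rank
path equality of names. Unclassifiable records (no valid words, or
sequence shorter than the fragment) are reported separately and kept
out of every denominator. TPR = TP/(TP+FN), FPR = FP/(FP+TN),
accuracy = (TP+TN)/all; a zero denominator yields rate 0 plus an
explicit flag rather than NaN.

ROC curves sweep the cutoff over 0–100 in steps of 10 (every published
cutoff lies on this grid); AUC is the trapezoid rule over FPR-sorted
points anchored at (0,0) and (1,1), and curves with no correct or no
incorrect records are flagged degenerate. Calibration reports, per
(rank, fragment length), the smallest grid cutoff with
TP/(TP+FP) ≥ 0.99 among that length's records, plus the reduction
1 − (TP+FP)/(classified); an unattainable target is reported as N/A,
never as the nearest miss. The reduction denominator counts classified
records only — unclassifiable ones are already reported apart, and
including them would conflate two different failure modes. Singletons
are excluded from calibration by the calling layer, since their leaf
assignments are wrong by construction.

Cross-validation with larger folds is deliberately absent: leave-one-out
is the benchmark of record here, and no fold design was specified to
follow.

## Primer tools

Primer location is an ungapped scan with IUPAC degeneracy honoured on
the primer side only (an N in the *sequence* matches nothing unless the
primer base is N, so runs of unknown sequence cannot fake a site).
Reverse primers are scanned as their reverse complement. The budget is
⌊primer length × 0.10⌋ substitutions — indels are out of scope because
anchored fragments of exact length presuppose ungapped placement — and
the best site is fewest-mismatches, ties to the 5′-most. Anchored
fragments take the 200 bp immediately 3′ of a forward site, or 5′ of a
reverse site reverse-complemented into read orientation; a located
primer with insufficient flank yields no fragment and does not count as
coverage. Coordinates are 0-based half-open throughout.

## The synthetic generator

The generator emulates the one property the classifier exploits: nested
similarity. A uniform random ancestor (650 bp, the full-barcode scale,
so defaults pass the ≥ 500 bp training filter) is mutated down a star
tree with per-branch substitution rates 0.15 (family), 0.05 (genus),
0.02 (species) and 0.005 (within species); each substitution picks one
of the three other bases uniformly. Ranks above family share one fixed
lineage. The rates were chosen once to bracket typical CO1 divergence
scales — congeneric species a few percent apart, confamilial genera
several times that — and to make genera recoverable but not trivially
so at 50 bp. A seeded fraction of leaf taxa is truncated to one
sequence *after* generation (defaults 0 — knobs at 0.23/0.33 mimic the
genus/species singleton shares reported for public CO1 data), so the
truth table still names the taxon and singleton records can be scored
as incorrect-at-leaf exactly as the benchmark requires.

What the generator does **not** emulate: codon structure, indels,
saturation/multiple hits, rate heterogeneity along the sequence,
coalescent genealogies, database abundance skew and misannotation.
Passing tests therefore demonstrate the correctness of the machinery
(counts, decrement/restore, voting, calibration guarantees) and the
qualitative patterns (accuracy monotone in rank and fragment length,
singleton behaviour) — not the absolute accuracy the classifier attains
on real, unevenly sampled barcode databases, which depends on database
coverage above all.

## Problem sizes and determinism

Default benchmarking runs use the 48-sequence generator default (4
families × 3 genera × 2 species × 2 sequences), 100 bootstrap trials,
and 5 generator seeds where stability across seeds is asserted; these
sizes make every result exactly reproducible in seconds while keeping
all taxa multi-member comparisons meaningful. Every stochastic step —
generation, fragment placement, subsampling — flows from named seeds,
and identical configuration yields byte-identical output files.

## Known limitations

- Leaf-taxon identity is the full lineage string; two genera with the
  same name under different families are distinct taxa, but rank-level
  homonyms would be conflated by name-path comparison at that rank.
- The model file is plain JSON; it is self-describing and versioned but
  not optimized for million-sequence reference sets.
- No hierarchical (per-rank) re-scoring: inclusive-rank answers come
  from the leaf winner's lineage plus bootstrap votes, as in the
  original method.
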