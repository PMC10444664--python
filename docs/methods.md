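# Methods

## The estimator

For a fixed k, two sequences x (length m) and y (length n) are compared
through a greedy co-linear chain of seeds — position pairs (i, j) with
x[i…i+k−1] = y[j…j+k−1]. Chain construction starts from a virtual dummy
seed (−1, −1) and repeats two moves until neither applies:

1. **Extension.** If the windows shifted one position right of the last
   seed are equal, (i+1, j+1) is the next seed. This is a constant-time
   check and consumes exact-match runs cheaply.
2. **Candidate selection.** Otherwise two candidates are formed. The
   first scans x left-to-right from the last seed for the smallest
   position i whose k-mer also occurs in y after the last seed, and
   pairs it with the occurrence j minimising the diagonal shift
   |(i − i_prev) − (j − j_prev)|, subject to that shift being ≤ k (the
   band keeps candidate seeds at similar distances from the previous
   seed; the bound also caps the per-position work at O(k) via a binary
   search in the occurrence list). The second candidate is the mirror
   scan of y. The candidate with the smaller diagonal shift wins, the
   first winning ties.

Because the scan demands only that *some* occurrence lies in the band,
a position whose k-mer occurs exclusively outside the band is skipped
and the scan continues; the chain is never silently truncated. Ties
among equally shifted occurrences go to the smallest position, making
the output deterministic. k-mers containing `N` are excluded from
indexing and can never seed; input is canonicalised to uppercase.

**Gap accounting.** Each region between consecutive seeds (and the
lead-in before the first seed, measured against the dummy, and the
tail after the last seed, measured against the sequence ends) carries a
gap of gap_x uncovered letters in x and gap_y in y, measured from the
end of the previous k-mer window. The smaller (zero-clamped) gap is
charged to substitutions; deletions/insertions are charged the
*unclamped* difference gap_x − gap_y, which equals the diagonal shift
between the two seeds and hence the net indel count between them. The
clamping asymmetry is deliberate: consecutive seeds selected off the
previous diagonal may overlap the previous window, and while
overlapping matched letters must not be charged as substitutions, the
diagonal shift is real and dropping it (clamping both sides) makes the
estimator *over*-count matches at small k, where spurious seeds
bridging mutated regions are common. With shift-preserving accounting
the estimator errs slightly low — consistent with a greedy chain being
at best as good as an optimal alignment — and the small-k inflation of
e_best disappears. An empty chain charges min(m, n) substitutions and
the length difference to the appropriate indel side.

The identity estimate is e = (m − (Σsub + Σdel)) / (m + Σins), clamped
to [0, 1]. The formula is asymmetric: m is the length of the *first*
sequence (the reference in reference-vs-all mode, the first-listed
sequence in all-pairs mode), and insertions extend the alignment length
beyond m while deletions do not.

## Selection and aggregation

The scan covers k ∈ [min_k, max_k], defaults 3 and 15 — the upper
default matching the minimizer length of Minimap2's default preset.
e_best is the maximum estimate; k_best the smallest k attaining it (the
smallest-k tie-break widens the subsequent search window); k_δ the
largest scanned k ≥ k_best with e_best − e_k ≤ δ, default δ = 0.05.
Larger k-mers make more specific, cheaper seeds, so among k values of
nearly equal estimated identity the largest is preferred; δ = 0
degenerates to k_best and is used when evaluating seed-count accuracy.

A pair enters the reported set when e_best ≥ e (threshold supplied by
the user). Aggregation to minimizer parameters takes κ = ⌈mean k_δ⌉
over every pair that produced at least one seed at some k — membership
in the reported set is *not* required, since the parameter grid is
computed per dataset without a threshold — and w = ⌈2κ/3⌉, the
window-to-length ratio of Minimap2's defaults. Seedless pairs carry no
k-mer information and are excluded with a warning.

## The alignment oracle

Ground truth is a unit-cost global alignment: an (m+1)×(n+1)
Levenshtein DP matrix filled row-wise with numpy (the within-row
insertion dependency is resolved by an accumulated running minimum over
candidate[j] − j), followed by a Python traceback. Among co-optimal
moves the traceback prefers match/substitution, then deletion, then
insertion; co-optimal alignments can differ in how they split indels,
so this preference pins down a deterministic optimal identity. The
optimal-alignment seed count at k decomposes the alignment into maximal
runs of match columns and sums max(0, run − k + 1) — the seeds a pair
of identical length-run fragments would share. The DP is cross-checked
against an independent edit-distance library (edlib) in the tests; the
library is never used as the implementation.

Evaluation offers two ground truths: `classify` labels a pair positive
when its optimal alignment identity reaches e, while
`classify_labeled` takes externally supplied labels. The synthetic
confusion-matrix harness uses the latter with the generating condition
as truth (low-divergence pairs are the positives), so that positives
and negatives partition by dataset at every threshold.

## Synthetic data

A dataset is n_pairs pairs (default 100 per condition), each an i.i.d.
uniform random DNA sequence of exactly the nominal length ℓ plus a
mutated copy produced by round(d·ℓ) edit operations — substitution,
insertion, deletion with probability 1/3 each, at uniform positions,
applied sequentially to the evolving sequence; substitutions always
change the base. Lengths ℓ ∈ [100, 15000] and divergences d ∈ [0.05,
0.25] span the conditions studied. Everything is reproducible
byte-for-byte from a single integer seed via numpy's `default_rng`.

What the generator does *not* emulate: sequencing-error profiles,
repeats, compositional bias, and long-range duplications. Passing tests
on this data show the estimator tracks uniform point divergence; they
do not certify behaviour on repetitive or low-complexity genomic
sequence, where spurious seed matches are systematically more likely.

Two quantitative caveats. First, the realised *optimal* divergence sits
below the nominal operation rate d: independent operations can overlap
or cancel, and insertions extend the alignment-length denominator, so
at d = 0.20 the realised optimal divergence is ≈ 0.17 (at d ≤ 0.10 the
gap is within 0.01–0.02). This is inherent to any per-base edit-op
generator under the identity formula above; nominal d is therefore a
condition label, not a guaranteed optimal divergence. Second, at high
divergence (d ≥ 0.20) and small k the greedy chain picks up some 10–20%
more seeds than an optimal alignment's match runs contain, so
seed-count accuracy against the oracle degrades there; at d ≤ 0.10 the
two counts agree within ±10% for essentially all pairs.

## Numerical and interface choices

- Identity values are computed in exact rational arithmetic
  (`fractions.Fraction`) before conversion to float, so printed values
  like 7/11 are exact to the last digit and ties in the δ rule are not
  perturbed by rounding.
- Chain results and gap accounts are immutable dataclasses; malformed
  chains (non-strictly-increasing coordinates) and inconsistent
  accounts (Σsub + Σdel > m) raise `ValueError` rather than clamp.
- k values exceeding the shorter sequence are skipped with a warning
  and the scanned range recorded; an empty scan range is an error.
- All-pairs mode enumerates unordered pairs once in input order;
  output TSV/JSON are byte-stable for fixed inputs and configuration.
- Evaluation-harness RNG seeds are derived per grid cell from a single
  base seed through `numpy.random.SeedSequence`, keeping cells
  independent and the whole harness reproducible from one integer.
- Problem sizes in the validation harnesses (100 pairs per condition,
  lengths up to 1000) match the study conditions they reproduce while
  keeping the full suite runnable in well under a minute per table.

## Known limitations

- The greedy chain is a heuristic: it can only underestimate the
  optimal identity in the best case and has no optimality guarantee;
  pathological repeat structures can mislead the band-constrained
  candidate selection.
- The (κ, w) aggregation is a single ceiling-of-mean summary; it does
  not optimise w independently of κ and emits parameters only, never
  alignments.
- Reference-vs-all mode requires the reference as the first sequence of
  the identity formula; comparing in the other orientation changes the
  estimate when indel counts are asymmetric.
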