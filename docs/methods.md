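# Methods

This note documents the models, conventions, and design choices behind
`snriso`, in the spirit of a methods appendix: what is computed, under what
assumptions, and where the genuinely open choices were made.

## Units of measurement: isoform groups

Gene copies with byte-identical mature sequences are indistinguishable to
any sequencing read, so the pipeline quantifies *isoform groups* — the
equivalence classes of identical sequence — rather than individual genes.
Group ids concatenate member gene ids (`U1:21D/95Ca/95Cb` style). All
reported fractions, dominance statistics, and truth comparisons are at
group level; a per-gene decomposition within a group is not identifiable
and is never attempted.

Sequences are stored as DNA: `U` is normalized to `T` on input (RNA and DNA
spellings are equivalent throughout), characters are uppercased, and only
`A C G T N` are accepted.

## Diagnostic regions and the class observable

For a fixed read length *k*, the signature of a read start *p* on group *g*
is the set of groups whose sequences contain `seq_g[p .. p+k−1]` anywhere
on the forward strand. Signatures are piecewise constant in *p*; maximal
constant runs are the *diagnostic regions*. Properties relied on elsewhere:

- regions partition every group's valid starts (`1 … L−k+1`, 1-based
  inclusive coordinates in every report);
- a region whose signature is the whole family is retained but flagged
  non-informative;
- any *k*-mer containing `N` matches nothing, and such starts are excluded
  from regions (they are also excluded from the partition check, which is
  computed over N-free starts).

Matching is forward-strand only: snRNA references are given in sense
orientation and strandedness carries no information in this setting.
Uniqueness is assessed *within the family* presented to the catalog; a
cross-family k-mer collision check runs once per pipeline run and warns,
approximating genome-wide unique mappability by family-level uniqueness.
Diagnostic regions are computed on ungapped sequences; the gapped alignment
is used only to report variable columns, because reads are matched against
real transcripts, not alignment rows.

## Read assignment

Assignment is exact-match (zero mismatches) by hash lookup of the read's
first *k* bases, equivalent to — and tested against — naive substring
search. Reads longer than *k* are trimmed from the 3′ end (their lowest-
quality end on the platforms in scope); reads shorter than *k* are unmapped
and tallied separately. One fixed *k* per run keeps the class semantics
coherent when libraries mix read lengths. Each read contributes exactly one
count to its full matched subset; no fractional apportioning happens at
assignment time.

## Fraction estimation

With design matrix `A[c,g]` (number of starts on *g* generating class *c*,
i.e. summed widths of *g*'s regions with signature *c*) and class counts
`y`, the expected-count model is `E[y] = A s` over per-start intensities
`s ≥ 0`. The default estimator solves the non-negative least-squares
problem (`scipy.optimize.nnls`) and normalizes; non-negativity is enforced
by the constraint, never by clamping. Fractions are renormalized to sum to
1 within 1e-9; test comparisons use 1e-6 unless a closed form justifies
tighter.

Per-start intensity is treated as proportional to expression fraction,
i.e. the group length weight is 1: snRNA paralogs within a family have
near-identical lengths, so start-count differences are negligible. A
`length_weights` hook exposes the general case but is not used by default.

`mode="unique"` implements the direct route — fractions proportional to
`count({g}) / A[{g},g]` — and requires every group to own a singleton
class; it errors otherwise, pointing to the linear system. On counts that
exactly equal their expectations the two routes agree (this is a test); on
sampled counts they differ by estimator noise, since the unique route
ignores ambiguous classes.

Groups with identical design columns are structurally confounded: no read
of length *k* can separate them. They are merged into one lumped composite
group (concatenated id) with a warning, mirroring how practitioners report
such pairs jointly, rather than returning an arbitrary split of an
unidentifiable quantity.

Class counts are sufficient: estimating on pooled counts equals estimating
on concatenated samples, so pooled-count workflows (e.g. summing noisy
IP-derived replicates before estimation) are supported by `merged_with`.

## Stage aggregation and dominance

Stage assignment comes from the sample sheet; stage order from the run
config. Stage means are arithmetic means of replicate fraction vectors,
renormalized; across-replicate SDs use the n−1 denominator and are reported
only when n ≥ 2. The dominance SD is the SD of the *stage-mean* fraction
vector across the subtype's groups — one value per stage — not an average
of per-sample SDs. The n−1 denominator is the package default with a
`ddof`/`sd_ddof` switch for the population convention; for *n* groups the
statistic ranges from 0 (even expression) to √(1/n) (one-hot). The
trajectory's monotone-trend flag is true iff the SD is non-decreasing along
the stage order (tolerance 1e-12; vacuously true for one stage). Dominant-
group ties break lexicographically with a warning.

## Variant screen

The screen places whole reads end-to-end at every offset of every group,
counting substitutions only (no indels anywhere in the package: exact-match
assignment and the screen are both substitution-aware only, matching
short-read snRNA practice at these lengths). A read is aligned if its best
placement has ≤ `max_mismatches` substitutions; the primary percentage uses
aligned reads as denominator, with the all-reads percentage also reported
since either convention is defensible. When nothing aligns the percentage
is reported as not-applicable, never 0.

## Synthetic data: what it emulates, and what it does not

The generator emulates the structure that makes this problem hard:
families of 3–7 near-identical paralogs (100–250 nt scale), some members
byte-identical, differing at a handful of planted sites; stage-wise mixture
trajectories in which one group's share grows over development; uniform
read starts; 33–51 nt reads; independent per-base substitution errors with
constant quality strings (qualities are never used downstream).

Planted residue assignments are drawn randomly subject to (a) pairwise
distinctness of groups and (b) every planted column truly varying, so that
recomputing variable columns from the emitted alignment recovers exactly
the planted sites; a deterministic mixed-radix fallback guarantees
feasibility when the group count approaches the 4^sites capacity. Random
assignment spreads differences across the planted columns, as in real
families, instead of concentrating discrimination in one or two positions.

Mixture trajectories draw each stage from a symmetric Dirichlet whose
concentration follows a schedule (default: geometric from 4.0 to 0.25),
placing the largest coordinate at the dominant index and ordering stages by
the dominant fraction. This enforces a non-decreasing dominant *fraction*
by construction; the dominance *SD* of the truth is usually, but not
necessarily, monotone (the non-dominant mass can redistribute), which is
why trend-recovery checks condition on the truth being monotone.

Deliberately not modeled: non-uniform coverage profiles (no data exists on
snRNA read-start bias, so uniform is the explicit assumption), indels,
quality-dependent errors, paired-end reads, colorspace data, and IP
enrichment effects. Passing tests therefore demonstrate correctness of the
inference machinery under these idealizations, not robustness to coverage
bias or structured error in real libraries.

## Numerical and problem-size choices

- Renormalization tolerance 1e-9; float comparisons in tests at 1e-6;
  closed-form checks at 1e-9.
- NNLS handles rank-deficiency through the lumping rule above; remaining
  degeneracies inherit scipy's minimum-residual solution.
- Alignment of unequal-length inputs uses a progressive center-star scheme
  (match +1, mismatch −1, gap −2, longest sequence as center, "once a gap
  always a gap"); equal-length inputs are used as-is, and a user-supplied
  aligned FASTA bypasses computation. This is adequate for near-identical
  paralogs and is not a general-purpose MSA.
- The benchmark sizes — 7-group 160-nt family, 5 stages × 2 replicates ×
  50,000 reads, 50 replicate studies — are chosen so multinomial noise on
  any fraction is ≈ 0.003, an order of magnitude below the 0.02 recovery
  tolerance, while a full benchmark completes in well under a minute.
- All randomness flows from explicit integer seeds (numpy `default_rng`);
  derived seeds are reduced modulo 2³¹−1. Reruns are byte-identical.

## Known limitations

- Within-family uniqueness is a stand-in for genome-wide unique
  mappability; pseudogenes or flanking repeats outside the provided FASTA
  are invisible to the catalog beyond the cross-family collision warning.
- The estimator assumes reads arise uniformly from transcript positions;
  strong 5′/3′ coverage bias would distort class proportions relative to
  region widths and bias fractions.
- The variant screen detects substitution-bearing placements only; a
  variant differing by an indel would surface as unmapped/unaligned reads
  rather than as mismatches.
- Absolute abundances are out of scope: all outputs are within-family
  fractions, and uncertainty reporting is limited to across-replicate SDs.
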