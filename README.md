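# snriso

Paralog-resolved quantification of spliceosomal snRNA isoform expression
from short RNA-seq reads.

## The problem

The major spliceosomal snRNAs (U1, U2, U4, U5) are each expressed from
small families of near-identical gene copies. In *Drosophila* these
families comprise five U1, six U2, three U4, and seven U5 genes, differing
at only a handful of nucleotide positions — and some copies are perfectly
identical. Generic read mappers assign multi-mapping reads at random among
such paralogs, so per-copy expression estimates from standard pipelines are
meaningless. Yet the relative expression of snRNA isoforms shifts over
development, with a single isoform per subtype coming to dominate in later
stages, which makes accurate paralog-level quantification biologically
interesting.

`snriso` is a library (plus a thin CLI) for researchers who want to measure
these fractions. It works from a FASTA of family members and FASTQs of
short reads (33–51 nt is the intended regime) and computes, per sample and
per ordered developmental stage:

- the fractional expression of every *distinguishable* isoform group,
- the per-stage **dominance SD** (how unevenly the groups are expressed),
- a mismatch **screen** for unannotated sequence variants.

A first-class synthetic-data generator produces families, developmental
mixture trajectories, and error-bearing reads with complete ground truth,
so the entire pipeline is testable without downloading any accession.

## Model and method

1. **Catalog.** Gene copies with byte-identical sequences collapse into
   *isoform groups* — the measurable units. For read length *k*, every
   valid read start on a group has a signature: the subset of groups whose
   sequences contain that *k*-mer anywhere (forward strand, exact match).
   Maximal runs of constant signature form *diagnostic regions*; singleton
   signatures give uniquely mappable reads.

2. **Assignment.** Each read (trimmed to *k*) is matched with zero
   mismatches via a *k*-mer index and contributes one count to its *class*
   — the full matched subset. Reads matching nothing are unmapped.

3. **Estimation.** Let `A[c,g]` be the number of starts on group *g* whose
   *k*-mer yields class *c*, and `y_c` the observed class counts. With
   per-start intensities `s_g`, the expected counts are `E[y] = A s`. The
   estimator solves

       min ‖A s − y‖₂   subject to  s ≥ 0

   (non-negative least squares) and normalizes `s` to fractions `f`. When
   every group owns a unique class this reduces to the direct
   unique-read ratio (`mode="unique"`); groups whose design columns are
   identical are structurally confounded and are reported as one lumped
   composite group. Replicates within a stage are averaged (renormalized),
   with across-replicate SDs (n−1) when n ≥ 2.

4. **Dominance.** Per stage, the SD of the mean fraction vector across the
   *n* groups: 0 when expression is even, √(1/n) when one group carries
   everything (n−1 denominator). A monotone-trend flag records whether the
   SD is non-decreasing along the stage order.

5. **Variant screen.** Every read is placed end-to-end against every group
   at every offset (substitutions only); the percentage of aligned reads
   with ≥ 1 mismatch flags possible unannotated variants.

## Worked example

`examples/03_developmental_trajectory.py` simulates a five-gene U1-like
family (two copies identical, so four measurable groups), five ordered
stages × two replicates × 20,000 48-nt reads, runs the full pipeline, and
compares against the planted truth:

```
$ python examples/03_developmental_trajectory.py
Dominance SD per stage (0 = even expression, 0.5 = one of four groups carries all reads):
  ovary      sd=0.0275 dominant=U1:g1
  early_emb  sd=0.0707 dominant=U1:g1
  late_emb   sd=0.2347 dominant=U1:g1
  larva      sd=0.2432 dominant=U1:g1
  pharate    sd=0.3582 dominant=U1:g1

Monotone increasing trend: True
Max |estimated - true| fraction over all stages: 0.0123
```

The dominance SD climbs from 0.03 (near-even expression across the four
groups) toward its one-hot ceiling of 0.5 as the dominant isoform takes
over, and every estimated stage-mean fraction lands within ~0.01 of the
planted mixture. The other examples cover catalog construction
(`01_build_catalog.py`), single-sample estimation with per-group errors
(`02_estimate_fractions.py`), and the variant screen recovering a planted
2% contamination (`04_variant_screen.py`).

The same pipeline runs from the shell on real data:

```bash
snriso catalog family.fasta --family U2 -k 48 --out catalog/
snriso estimate sample.fastq --fasta family.fasta --family U2 -k 48 --out fractions.tsv
snriso run config.yaml          # full multi-sample, multi-stage run
snriso simulate --out bench/    # synthetic end-to-end benchmark
```

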