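"""Screen reads for unannotated sequence variants via mismatch counting.

If a sample expressed an snRNA variant gene that is missing from the
catalog, its reads would still place against the known paralogs but carry
systematic mismatches. The screen aligns every read end-to-end against all
group sequences (substitutions only) and reports what percentage of aligned
reads contain at least one mismatch: near 0% means the catalog explains the
sample; an elevated value flags potential unannotated variants. Here 2% of
reads are simulated from a variant carrying one private substitution.
"""

from snriso import (
    ReadSimConfig,
    SyntheticFamilySpec,
    generate_family,
    simulate_reads,
    variant_screen,
)

spec = SyntheticFamilySpec(
    n_genes=3, seq_length=150, n_variable_sites=3,
    identical_partition=((1,), (2,), (3,)), seed=21, family_name="U2",
)
family = generate_family(spec)

# Clean reads from the known paralogs...
config = ReadSimConfig(reads_per_sample=4900, read_length=40, seed=2)
reads, _ = simulate_reads(family, [0.5, 0.3, 0.2], config)

# ...plus 100 reads from an unannotated variant: the first paralog with a
# private substitution at position 75 (well inside every 40-mer window
# starting at 50..74).
ref = family.groups[0].representative_sequence
variant = ref[:74] + ("A" if ref[74] != "A" else "G") + ref[75:]
for i in range(100):
    start = 50 + (i % 25)
    reads.append((f"variant_{i}", variant[start : start + 40]))

report = variant_screen(reads, list(family.groups), max_mismatches=2)
print(f"reads screened:        {report.n_reads}")
print(f"aligned (<=2 subst.):  {report.n_aligned}")
print(f"with >=1 mismatch:     {report.n_with_mismatch}")
print(f"percent with mismatch: {report.percent_with_mismatch:.2f}%")
print("\nThe planted variant contributes 2% of reads; every one of its "
      "reads covering the private site shows up as a mismatched alignment, "
      "so the screen recovers the planted contamination level.")
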