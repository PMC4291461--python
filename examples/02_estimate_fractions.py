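"""Estimate isoform-group fractions for one simulated RNA-seq sample.

50,000 error-free 48-nt reads are drawn from a known 7-group mixture
(mimicking the U5 subtype, whose seven gene copies are all distinguishable),
assigned by exact k-mer match into matched-group-subset classes, and
deconvolved with non-negative least squares. The printed comparison shows
the estimation error achievable at this depth.
"""

import numpy as np

from snriso import (
    ReadSimConfig,
    SyntheticFamilySpec,
    assign_reads,
    build_design_matrix,
    build_index,
    diagnostic_regions,
    estimate_fractions,
    generate_family,
    simulate_reads,
)

spec = SyntheticFamilySpec(
    n_genes=7, seq_length=160, n_variable_sites=8,
    identical_partition=tuple((i,) for i in range(1, 8)),
    seed=11, family_name="U5",
)
family = generate_family(spec)
true_fractions = np.array([0.40, 0.25, 0.15, 0.08, 0.06, 0.04, 0.02])

config = ReadSimConfig(reads_per_sample=50_000, read_length=48, seed=1)
reads, _truth = simulate_reads(family, true_fractions, config)

index = build_index(family.groups, read_length=48)
_assignments, class_counts = assign_reads(reads, index, sample_id="demo",
                                          collect_assignments=False)
design = build_design_matrix(diagnostic_regions(family.groups, 48),
                             family.groups)
estimate = estimate_fractions(class_counts, design, mode="linear_system")

print(f"{class_counts.n_total} reads, {class_counts.n_unmapped} unmapped, "
      f"{estimate.n_informative_reads} informative")
print(f"\n{'group':12s} {'true':>8s} {'estimated':>10s} {'error':>8s}")
for j, gid in enumerate(family.group_ids):
    est = estimate.fractions[gid]
    print(f"{gid:12s} {true_fractions[j]:8.4f} {est:10.4f} "
          f"{abs(est - true_fractions[j]):8.4f}")
print("\nFractions sum to 1 by construction; errors at this depth are "
      "dominated by multinomial sampling noise (a few parts in a thousand).")
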