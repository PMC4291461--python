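"""Simulate a developmental study and track isoform dominance across stages.

Five ordered stages with two replicate samples each are simulated from
mixtures in which one isoform's share grows over development. The pipeline
writes the standard result tables; the dominance SD -- the standard
deviation of the fraction vector across a subtype's isoform groups -- rises
from near 0 (even expression) toward its one-hot maximum as a single
isoform takes over, and the recovery report compares estimates with the
planted truth.
"""

import sys
import tempfile
from pathlib import Path

import pandas as pd

from snriso import ReadSimConfig, SyntheticFamilySpec, simulate_and_run

outdir = Path(sys.argv[1]) if len(sys.argv) > 1 else Path(
    tempfile.mkdtemp(prefix="snriso_demo_")
)

spec = SyntheticFamilySpec(
    n_genes=5, seq_length=160, n_variable_sites=6,
    identical_partition=((1,), (2,), (3,), (4, 5)),  # genes 4 and 5 identical
    seed=6, family_name="U1",
)
config = ReadSimConfig(reads_per_sample=20_000, read_length=48,
                       replicates_per_stage=2, seed=6)
stages = ["ovary", "early_emb", "late_emb", "larva", "pharate"]

result_dir, recovery = simulate_and_run(spec, stages, config, outdir)

traj = pd.read_csv(result_dir / "dominance_trajectory.tsv", sep="\t")
print("Dominance SD per stage (0 = even expression, "
      "0.5 = one of four groups carries all reads):")
for row in traj.itertuples():
    print(f"  {row.stage_label:10s} sd={row.dominance_sd:.4f} "
          f"dominant={row.dominant_group}")
print(f"\nMonotone increasing trend: {bool(traj['monotone_trend'].iloc[0])}")
print(f"Max |estimated - true| fraction over all stages: "
      f"{recovery['max_abs_error']:.4f}")
print(f"Results written to {result_dir}")
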