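"""End-to-end orchestration: catalog -> assignment -> estimation -> dominance.

A run is described by a :class:`RunConfig` (one YAML file) plus a sample
sheet (TSV: sample_id, fastq_path, stage_label, family). Outputs are plain
TSV/JSON files in the output directory; reruns with identical inputs are
byte-identical (all randomness flows from the single config seed, iteration
order is sorted everywhere, and the manifest carries no timestamps).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assign import assign_reads, build_index, variant_screen
from .catalog import (
    DiagnosticRegion,
    build_alignment,
    check_cross_family_collisions,
    collapse_identical,
    diagnostic_regions,
    find_variable_sites,
    load_family,
)
from .dominance import trajectory
from .errors import ValidationError
from .estimate import aggregate_stage, build_design_matrix, estimate_fractions
from .synthetic import (
    MixtureTruth,
    ReadSimConfig,
    SyntheticFamilySpec,
    generate_family,
    generate_mixture_trajectory,
    simulate_reads,
    write_fastq,
)

__all__ = ["RunConfig", "SampleSheet", "run", "simulate_and_run"]

MIN_READ_LENGTH = 10


@dataclass
class RunConfig:
    """Everything a reproducible run needs, loadable from one YAML file."""

    families: dict[str, str]  # family name -> FASTA path
    sample_sheet: str
    read_length: int
    stage_order: list[str]
    output_dir: str
    aligned_fasta: dict[str, str] = field(default_factory=dict)
    estimation_mode: str = "linear_system"
    sd_ddof: int = 1
    variant_screen: bool = False
    max_mismatches: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        try:
            return cls(**data)
        except TypeError as exc:
            raise ValidationError(f"{path}: bad config keys: {exc}") from exc

    def validate(self) -> None:
        if self.read_length < MIN_READ_LENGTH:
            raise ValidationError(
                f"read_length must be >= {MIN_READ_LENGTH}, got {self.read_length}"
            )
        if self.estimation_mode not in ("unique", "linear_system"):
            raise ValidationError(f"unknown estimation_mode {self.estimation_mode!r}")
        if self.sd_ddof not in (0, 1):
            raise ValidationError("sd_ddof must be 0 or 1")
        if not self.families:
            raise ValidationError("no families configured")
        if len(self.stage_order) != len(set(self.stage_order)):
            raise ValidationError("stage_order contains duplicates")

    def canonical_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class SampleSheet:
    """Rows of (sample_id, fastq_path, stage_label, family)."""

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "fastq_path", "stage_label", "family")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in cls.REQUIRED if c not in frame.columns]
        if missing:
            raise ValidationError(f"{path}: sample sheet missing columns {missing}")
        if frame["sample_id"].duplicated().any():
            dupes = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"{path}: duplicate sample_ids {dupes}")
        return cls(frame=frame)

    def validate_against(self, config: RunConfig) -> None:
        stages = set(config.stage_order)
        for row in self.frame.itertuples():
            if row.stage_label not in stages:
                raise ValidationError(
                    f"sample {row.sample_id!r}: stage {row.stage_label!r} "
                    "not in stage_order"
                )
            if row.family not in config.families:
                raise ValidationError(
                    f"sample {row.sample_id!r}: family {row.family!r} not configured"
                )
            if not Path(row.fastq_path).exists():
                raise ValidationError(
                    f"sample {row.sample_id!r}: missing FASTQ {row.fastq_path}"
                )


def _regions_frame(regions: Sequence[DiagnosticRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "carrier_group": r.carrier_group,
                "group_subset": ";".join(sorted(r.group_subset)),
                "start_min_1based": r.start_min_1based,
                "start_max_1based": r.start_max_1based,
                "read_length": r.read_length,
                "informative": r.informative,
            }
            for r in regions
        ]
    )


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def run(config: RunConfig) -> Path:
    """Execute a full quantification run and write all result tables.

    Per family: catalog tables (groups, variable sites, diagnostic regions),
    per-sample class counts and fraction estimates, per-stage summaries, the
    dominance trajectory, and optionally the variant-screen report; plus a
    run manifest with the config hash.
    """
    config.validate()
    sheet = SampleSheet.from_tsv(config.sample_sheet)
    sheet.validate_against(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    family_groups = {}
    catalog_rows = []
    site_rows = []
    region_frames = []
    designs = {}
    for fam in sorted(config.families):
        genes = load_family(config.families[fam], fam)
        groups = collapse_identical(genes)
        family_groups[fam] = groups
        alignment = build_alignment(groups, config.aligned_fasta.get(fam))
        for g in groups:
            catalog_rows.append(
                {
                    "family": fam,
                    "group_id": g.group_id,
                    "members": ";".join(g.members),
                    "length": len(g.representative_sequence),
                }
            )
        for site in find_variable_sites(alignment):
            site_rows.append(
                {
                    "family": fam,
                    "column_1based": site.column_1based,
                    "residues": ";".join(
                        f"{g}={r}" for g, r in sorted(site.residues.items())
                    ),
                }
            )
        regions = diagnostic_regions(groups, config.read_length)
        rf = _regions_frame(regions)
        rf.insert(0, "family", fam)
        region_frames.append(rf)
        designs[fam] = build_design_matrix(regions, groups)
    check_cross_family_collisions(family_groups, config.read_length)

    _write_tsv(pd.DataFrame(catalog_rows), out / "groups.tsv")
    _write_tsv(
        pd.DataFrame(site_rows, columns=["family", "column_1based", "residues"]),
        out / "variable_sites.tsv",
    )
    _write_tsv(pd.concat(region_frames, ignore_index=True), out / "regions.tsv")

    indexes = {
        fam: build_index(groups, config.read_length)
        for fam, groups in family_groups.items()
    }

    count_rows = []
    fraction_rows = []
    screen_rows = []
    estimates_by_fam_stage: dict[tuple[str, str], list] = {}
    for row in sheet.frame.sort_values("sample_id").itertuples():
        _assignments, table = assign_reads(
            row.fastq_path,
            indexes[row.family],
            sample_id=row.sample_id,
            collect_assignments=False,
        )
        for cls in sorted(table.counts, key=lambda c: sorted(c)):
            count_rows.append(
                {
                    "sample_id": row.sample_id,
                    "family": row.family,
                    "class": ";".join(sorted(cls)),
                    "count": table.counts[cls],
                }
            )
        count_rows.append(
            {
                "sample_id": row.sample_id,
                "family": row.family,
                "class": "__unmapped__",
                "count": table.n_unmapped,
            }
        )
        est = estimate_fractions(
            table, designs[row.family], mode=config.estimation_mode
        )
        estimates_by_fam_stage.setdefault((row.family, row.stage_label), []).append(est)
        for gid in sorted(est.fractions):
            fraction_rows.append(
                {
                    "sample_id": row.sample_id,
                    "family": row.family,
                    "stage_label": row.stage_label,
                    "group_id": gid,
                    "fraction": est.fractions[gid],
                    "n_informative_reads": est.n_informative_reads,
                    "method": est.method,
                }
            )
        if config.variant_screen:
            report = variant_screen(
                row.fastq_path,
                family_groups[row.family],
                max_mismatches=config.max_mismatches,
            )
            screen_rows.append(
                {
                    "sample_id": row.sample_id,
                    "family": row.family,
                    "n_reads": report.n_reads,
                    "n_aligned": report.n_aligned,
                    "n_with_mismatch": report.n_with_mismatch,
                    "percent_with_mismatch": report.percent_with_mismatch,
                    "percent_of_all_reads": report.percent_of_all_reads,
                }
            )

    _write_tsv(pd.DataFrame(count_rows), out / "class_counts.tsv")
    _write_tsv(pd.DataFrame(fraction_rows), out / "fractions.tsv")
    if config.variant_screen:
        _write_tsv(pd.DataFrame(screen_rows), out / "variant_screen.tsv")

    stage_rows = []
    trajectory_rows = []
    for fam in sorted(family_groups):
        summaries = []
        for stage in config.stage_order:
            ests = estimates_by_fam_stage.get((fam, stage))
            if not ests:
                continue
            summary = aggregate_stage(ests, stage, sd_ddof=config.sd_ddof)
            summaries.append(summary)
            for gid in sorted(summary.mean_fraction):
                stage_rows.append(
                    {
                        "family": fam,
                        "stage_label": stage,
                        "group_id": gid,
                        "mean_fraction": summary.mean_fraction[gid],
                        "sd_across_samples": (
                            summary.sd_across_samples[gid]
                            if summary.sd_across_samples is not None
                            else ""
                        ),
                        "n_samples": summary.n_samples,
                    }
                )
        if summaries:
            traj = trajectory(summaries, family=fam, ddof=config.sd_ddof)
            for stage, sd, dom in zip(
                traj.stage_labels, traj.dominance_sd, traj.dominant_group
            ):
                trajectory_rows.append(
                    {
                        "family": fam,
                        "stage_label": stage,
                        "dominance_sd": sd,
                        "dominant_group": dom,
                        "monotone_trend": traj.monotone_trend,
                    }
                )

    _write_tsv(pd.DataFrame(stage_rows), out / "stage_summary.tsv")
    _write_tsv(pd.DataFrame(trajectory_rows), out / "dominance_trajectory.tsv")

    manifest = {
        "config": asdict(config),
        "config_sha256": config.canonical_hash(),
        "snriso_version": __version__,
        "seed": config.seed,
        "n_samples": int(len(sheet.frame)),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def simulate_and_run(
    family_spec: SyntheticFamilySpec,
    stage_labels: Sequence[str],
    read_config: ReadSimConfig,
    output_dir: str | Path,
    alpha_schedule: Sequence[float] | str | None = None,
    dominant_index: int = 0,
    estimation_mode: str = "linear_system",
    variant_screen: bool = False,
) -> tuple[Path, dict]:
    """Generate a synthetic study, run the pipeline on it, report recovery.

    Writes the family FASTA, per-sample FASTQs and truth tables, the sample
    sheet and config under ``output_dir/data``, executes :func:`run`, and
    emits ``recovery.json`` comparing estimated stage-mean fractions with the
    planted mixture truth (per-stage max absolute error, dominance-trend
    agreement).
    """
    outdir = Path(output_dir)
    data_dir = outdir / "data"
    result_dir = outdir / "results"
    data_dir.mkdir(parents=True, exist_ok=True)

    family = generate_family(family_spec)
    fam_name = family_spec.family_name
    fasta = data_dir / f"{fam_name}.fasta"
    with open(fasta, "w") as fh:
        for gene in family.genes:
            fh.write(f">{gene.gene_id}\n{gene.sequence}\n")

    n_groups = len(family.groups)
    truth = generate_mixture_trajectory(
        n_groups,
        stage_labels,
        alpha_schedule=alpha_schedule,
        dominant_index=dominant_index,
        seed=family_spec.seed + 1,
    )
    truth.frame(family.group_ids).to_csv(
        data_dir / "mixture_truth.tsv", sep="\t", index=False
    )

    sheet_rows = []
    for si, stage in enumerate(stage_labels):
        for rep in range(read_config.replicates_per_stage):
            sample_id = f"{stage}_rep{rep + 1}"
            sample_seed = (
                read_config.seed + 1000 * si + rep
            ) % (2**31 - 1)
            cfg = ReadSimConfig(
                reads_per_sample=read_config.reads_per_sample,
                read_length=read_config.read_length,
                error_rate=read_config.error_rate,
                replicates_per_stage=read_config.replicates_per_stage,
                seed=sample_seed,
            )
            reads, truth_table = simulate_reads(
                family, truth.fractions[si], cfg, read_id_prefix=f"{sample_id}_r"
            )
            fastq = data_dir / f"{sample_id}.fastq"
            write_fastq(reads, fastq)
            truth_table.to_csv(
                data_dir / f"{sample_id}.truth.tsv", sep="\t", index=False
            )
            sheet_rows.append(
                {
                    "sample_id": sample_id,
                    "fastq_path": str(fastq),
                    "stage_label": stage,
                    "family": fam_name,
                }
            )
    sheet_path = data_dir / "samples.tsv"
    pd.DataFrame(sheet_rows).to_csv(sheet_path, sep="\t", index=False)

    config = RunConfig(
        families={fam_name: str(fasta)},
        sample_sheet=str(sheet_path),
        read_length=read_config.read_length,
        stage_order=list(stage_labels),
        output_dir=str(result_dir),
        estimation_mode=estimation_mode,
        variant_screen=variant_screen,
        seed=read_config.seed,
    )
    run(config)

    stage_frame = pd.read_csv(result_dir / "stage_summary.tsv", sep="\t")
    traj_frame = pd.read_csv(result_dir / "dominance_trajectory.tsv", sep="\t")
    group_order = list(family.group_ids)
    per_stage_err: dict[str, float] = {}
    for si, stage in enumerate(stage_labels):
        sub = stage_frame[stage_frame["stage_label"] == stage]
        est = {r.group_id: r.mean_fraction for r in sub.itertuples()}
        errs = [
            abs(est.get(g, 0.0) - truth.fractions[si][j])
            for j, g in enumerate(group_order)
        ]
        per_stage_err[stage] = float(max(errs))

    true_sds = [
        float(np.std(truth.fractions[si], ddof=1)) for si in range(len(stage_labels))
    ]
    true_monotone = all(b >= a - 1e-12 for a, b in zip(true_sds, true_sds[1:]))
    est_monotone = bool(traj_frame["monotone_trend"].iloc[0])
    recovery = {
        "per_stage_max_abs_error": per_stage_err,
        "max_abs_error": max(per_stage_err.values()),
        "true_dominance_sd": true_sds,
        "estimated_dominance_sd": traj_frame["dominance_sd"].tolist(),
        "true_trend_monotone": true_monotone,
        "estimated_trend_monotone": est_monotone,
        "trend_agreement": true_monotone == est_monotone,
    }
    with open(outdir / "recovery.json", "w") as fh:
        json.dump(recovery, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result_dir, recovery
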