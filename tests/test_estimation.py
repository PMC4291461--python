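"""Fraction estimation: design matrix, deconvolution, stage aggregation."""

import numpy as np
import pytest

from snriso import (
    ClassCountTable,
    ClassDesignMatrix,
    EstimationError,
    FractionEstimate,
    ReadSimConfig,
    aggregate_stage,
    assign_reads,
    build_design_matrix,
    build_index,
    diagnostic_regions,
    estimate_fractions,
    simulate_reads,
)
from snriso.catalog import DiagnosticRegion

from conftest import make_groups


def table(counts, sample_id="s"):
    c = {frozenset(k): v for k, v in counts.items()}
    n = sum(c.values())
    return ClassCountTable(sample_id=sample_id, counts=c, n_total=n)


def design(classes, groups, A):
    return ClassDesignMatrix(
        classes=tuple(frozenset(c) for c in classes),
        groups=tuple(groups),
        A=np.asarray(A),
    )


class TestBuildDesignMatrix:
    def test_widths_accumulate_per_class(self):
        a, b = "AACCGGTTAG", "AACCGCTTAG"  # self-unique starts 3-6, shared 1-2 & 7
        groups = make_groups(a, b)
        regions = diagnostic_regions(groups, 4)
        dm = build_design_matrix(regions, groups)
        rows = {c: dm.A[i].tolist() for i, c in enumerate(dm.classes)}
        assert rows[frozenset(["G1"])] == [4, 0]
        assert rows[frozenset(["G2"])] == [0, 4]
        assert rows[frozenset(["G1", "G2"])] == [3, 3]

    def test_single_group_total_starts(self):
        groups = make_groups("ACGTACGTAC")
        dm = build_design_matrix(diagnostic_regions(groups, 4), groups)
        assert dm.A.tolist() == [[7]]  # L - k + 1

    def test_group_without_self_unique_starts(self):
        # C differs from A and B only at one shared column; A and B also
        # differ from each other elsewhere. C has a self-unique region but
        # reads from A over the shared column land in the {A,B} class.
        base = "AACCGGTTAGCA"
        a = base
        b = base[:1] + "G" + base[2:]
        c = base[:6] + "A" + base[7:]
        groups = make_groups(a, b, c, prefix="P")
        dm = build_design_matrix(diagnostic_regions(groups, 4), groups)
        ab = dm.A[dm.classes.index(frozenset(["P1", "P2"]))]
        assert ab[0] > 0 and ab[1] > 0 and ab[2] == 0

    def test_overlapping_regions_rejected(self):
        groups = make_groups("ACGTACGTAC")
        bad = [
            DiagnosticRegion("G1", frozenset(["G1"]), 1, 5, 4),
            DiagnosticRegion("G1", frozenset(["G1"]), 5, 7, 4),
        ]
        with pytest.raises(EstimationError):
            build_design_matrix(bad, groups)

    def test_gapped_regions_rejected(self):
        groups = make_groups("ACGTACGTAC")
        bad = [DiagnosticRegion("G1", frozenset(["G1"]), 2, 7, 4)]
        with pytest.raises(EstimationError):
            build_design_matrix(bad, groups)


class TestEstimateFractions:
    def test_two_unique_classes_closed_form(self):
        dm = design([["A"], ["B"]], ["A", "B"], [[5, 0], [0, 5]])
        est = estimate_fractions(table({("A",): 80, ("B",): 20}), dm)
        assert est.fractions["A"] == pytest.approx(0.8, abs=1e-9)
        assert est.fractions["B"] == pytest.approx(0.2, abs=1e-9)

    def test_triangular_system_closed_form(self):
        # Classes {A}, {B}, {B,C} with unit widths and counts (50, 30, 50):
        # s_A=50, s_B=30, s_C=50-30=20 -> fractions (0.5, 0.3, 0.2).
        dm = design([["A"], ["B"], ["B", "C"]], ["A", "B", "C"],
                    [[1, 0, 0], [0, 1, 0], [0, 1, 1]])
        est = estimate_fractions(
            table({("A",): 50, ("B",): 30, ("B", "C"): 50}), dm
        )
        assert est.fractions["A"] == pytest.approx(0.5, abs=1e-9)
        assert est.fractions["B"] == pytest.approx(0.3, abs=1e-9)
        assert est.fractions["C"] == pytest.approx(0.2, abs=1e-9)
        assert est.method == "linear_system"
        assert est.n_informative_reads == 130

    def test_zero_counts_rejected(self):
        dm = design([["A"], ["B"]], ["A", "B"], [[1, 0], [0, 1]])
        with pytest.raises(EstimationError):
            estimate_fractions(table({}), dm)

    def test_confounded_groups_lumped(self):
        dm = design([["A", "B"], ["C"]], ["A", "B", "C"],
                    [[3, 3, 0], [0, 0, 3]])
        with pytest.warns(UserWarning, match="lumped"):
            est = estimate_fractions(
                table({("A", "B"): 60, ("C",): 40}), dm
            )
        assert set(est.fractions) == {"A/B", "C"}
        assert sum(est.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert est.fractions["A/B"] == pytest.approx(0.6, abs=1e-6)

    def test_unique_mode_requires_singleton_classes(self):
        dm = design([["A", "B"], ["C"]], ["A", "B", "C"],
                    [[3, 3, 0], [0, 0, 3]])
        with pytest.raises(EstimationError, match="linear_system"):
            estimate_fractions(table({("C",): 5}), dm, mode="unique")

    def test_unknown_classes_warned_and_dropped(self):
        dm = design([["A"], ["B"]], ["A", "B"], [[1, 0], [0, 1]])
        with pytest.warns(UserWarning, match="dropped"):
            est = estimate_fractions(
                table({("A",): 50, ("B",): 50, ("Z",): 7}), dm
            )
        assert est.n_informative_reads == 100

    def test_unique_and_linear_agree_on_consistent_counts(self, u5_like_family):
        # When class counts equal their expectations A @ s exactly, the
        # deconvolution and the unique-reads shortcut give the same answer.
        k = 48
        dm = build_design_matrix(
            diagnostic_regions(u5_like_family.groups, k), u5_like_family.groups
        )
        fracs = np.array([0.35, 0.2, 0.15, 0.1, 0.1, 0.05, 0.05])
        expected = dm.A @ (1000 * fracs)
        counts = ClassCountTable(
            sample_id="exact",
            counts={c: float(v) for c, v in zip(dm.classes, expected)},
            n_total=int(expected.sum()),
        )
        est_lin = estimate_fractions(counts, dm, mode="linear_system")
        est_unq = estimate_fractions(counts, dm, mode="unique")
        for g in est_lin.fractions:
            assert est_lin.fractions[g] == pytest.approx(
                est_unq.fractions[g], abs=1e-6
            )
            assert est_lin.fractions[g] == pytest.approx(
                fracs[list(u5_like_family.group_ids).index(g)], abs=1e-6
            )

    def test_pooling_equals_summed_counts(self, u5_like_family):
        k = 48
        index = build_index(u5_like_family.groups, k)
        dm = build_design_matrix(
            diagnostic_regions(u5_like_family.groups, k), u5_like_family.groups
        )
        fracs = np.full(7, 1 / 7)
        tables = []
        all_reads = []
        for seed in (21, 22):
            cfg = ReadSimConfig(reads_per_sample=4000, read_length=k, seed=seed)
            reads, _ = simulate_reads(u5_like_family, fracs, cfg)
            all_reads.extend(reads)
            tables.append(
                assign_reads(reads, index, collect_assignments=False)[1]
            )
        _, concat_table = assign_reads(all_reads, index,
                                       collect_assignments=False)
        est_concat = estimate_fractions(concat_table, dm)
        est_pooled = estimate_fractions(tables[0].merged_with(tables[1]), dm)
        for g in est_concat.fractions:
            assert est_concat.fractions[g] == pytest.approx(
                est_pooled.fractions[g], abs=1e-12
            )


class TestAggregateStage:
    def two_estimates(self):
        return [
            FractionEstimate("s1", {"A": 0.6, "B": 0.4}, 100, "unique"),
            FractionEstimate("s2", {"A": 0.8, "B": 0.2}, 100, "unique"),
        ]

    def test_mean_and_sample_sd(self):
        summary = aggregate_stage(self.two_estimates(), "early")
        assert summary.mean_fraction["A"] == pytest.approx(0.7)
        assert summary.mean_fraction["B"] == pytest.approx(0.3)
        assert summary.sd_across_samples["A"] == pytest.approx(0.1414, abs=1e-4)
        assert summary.sd_across_samples["B"] == pytest.approx(0.1414, abs=1e-4)
        assert summary.n_samples == 2

    def test_single_sample_has_no_sd(self):
        summary = aggregate_stage(self.two_estimates()[:1], "ovary")
        assert summary.sd_across_samples is None
        assert summary.mean_fraction["A"] == pytest.approx(0.6)

    def test_identical_samples_zero_sd(self):
        est = FractionEstimate("s", {"A": 0.5, "B": 0.5}, 10, "unique")
        summary = aggregate_stage([est] * 4, "mid")
        assert summary.sd_across_samples["A"] == 0.0
        assert summary.dominance_sd == 0.0

    def test_mixed_group_sets_rejected(self):
        ests = [
            FractionEstimate("s1", {"A": 1.0}, 10, "unique"),
            FractionEstimate("s2", {"B": 1.0}, 10, "unique"),
        ]
        with pytest.raises(EstimationError):
            aggregate_stage(ests, "late")

    def test_means_renormalized(self):
        ests = self.two_estimates()
        summary = aggregate_stage(ests, "x")
        assert sum(summary.mean_fraction.values()) == pytest.approx(1.0,
                                                                    abs=1e-9)
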