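"""Catalog: FASTA loading, group collapsing, alignment, diagnostic regions."""

import pytest
from hypothesis import given, settings, strategies as st

from snriso import (
    CatalogError,
    SyntheticFamilySpec,
    build_alignment,
    collapse_identical,
    diagnostic_regions,
    find_variable_sites,
    generate_family,
    load_family,
)
from snriso.catalog import ParalogGene

from conftest import make_groups, naive_matched_groups


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path


class TestLoadFamily:
    def test_loads_normalizes_and_uppercases(self, tmp_path):
        p = write_fasta(tmp_path / "u1.fa", [
            ("U1:21D", "acguACGU"), ("U1:82Eb", "ACGTACGT"), ("U1:95Cc", "AAAAAAAA"),
        ])
        genes = load_family(p, "U1")
        assert [g.gene_id for g in genes] == ["U1:21D", "U1:82Eb", "U1:95Cc"]
        assert genes[0].sequence == "ACGTACGT"

    def test_empty_duplicate_and_bad_alphabet_rejected(self, tmp_path):
        with pytest.raises(CatalogError):
            load_family(write_fasta(tmp_path / "e.fa", []), "U1")
        with pytest.raises(CatalogError):
            load_family(
                write_fasta(tmp_path / "d.fa", [("a", "ACGT"), ("a", "ACGT")]), "U1"
            )
        with pytest.raises(CatalogError):
            load_family(write_fasta(tmp_path / "x.fa", [("a", "ACXT")]), "U1")


class TestCollapseIdentical:
    def test_identical_sequences_share_group(self):
        genes = [
            ParalogGene("U1:21D", "U1", "ACGT"),
            ParalogGene("U1:95Ca", "U1", "ACGT"),
            ParalogGene("U1:82Eb", "U1", "ACGA"),
        ]
        groups = collapse_identical(genes)
        assert [g.group_id for g in groups] == ["U1:21D/95Ca", "U1:82Eb"]
        assert groups[0].members == ("U1:21D", "U1:95Ca")

    def test_all_distinct_gives_singletons(self):
        genes = [ParalogGene(f"g{i}", "F", s)
                 for i, s in enumerate(["AAAA", "AAAC", "AACC", "ACCC"])]
        assert len(collapse_identical(genes)) == 4

    def test_six_genes_five_isoforms(self):
        # Mirrors a six-gene family in which exactly two members are identical.
        seqs = ["AAAA", "AAAC", "AACA", "ACAA", "ACAA", "CAAA"]
        genes = [ParalogGene(f"U2:{i}", "U2", s) for i, s in enumerate(seqs)]
        groups = collapse_identical(genes)
        assert len(groups) == 5
        merged = [g for g in groups if len(g.members) == 2]
        assert merged and merged[0].members == ("U2:3", "U2:4")

    def test_idempotent(self, u5_like_family):
        groups = u5_like_family.groups
        again = collapse_identical(
            [ParalogGene(g.group_id.replace("/", "_"), "F",
                         g.representative_sequence) for g in groups]
        )
        assert [g.representative_sequence for g in again] == [
            g.representative_sequence for g in groups
        ]


class TestAlignmentAndVariableSites:
    def test_equal_length_identity_alignment(self):
        groups = make_groups("ACGTA", "ACGTT")
        aln = build_alignment(groups)
        assert aln == {"G1": "ACGTA", "G2": "ACGTT"}

    def test_unequal_lengths_insert_one_gap(self):
        groups = make_groups("ACGT", "ACGGT")
        aln = build_alignment(groups)
        assert {len(v) for v in aln.values()} == {5}
        assert aln["G2"] == "ACGGT"
        assert aln["G1"].count("-") == 1

    def test_user_supplied_alignment_returned_verbatim(self, tmp_path):
        p = write_fasta(tmp_path / "aln.fa", [("G1", "AC-GT"), ("G2", "ACGGT")])
        groups = make_groups("ACGT", "ACGGT")
        aln = build_alignment(groups, aligned_fasta=p)
        assert aln == {"G1": "AC-GT", "G2": "ACGGT"}

    def test_no_variable_sites_on_identical_rows(self):
        assert find_variable_sites({"a": "AAAA", "b": "AAAA"}) == []

    def test_single_substitution_column(self):
        sites = find_variable_sites({"a": "AATA", "b": "AACA"})
        assert len(sites) == 1
        assert sites[0].column_1based == 3
        assert set(sites[0].residues.values()) == {"T", "C"}

    def test_gap_counts_as_distinct_residue(self):
        sites = find_variable_sites({"a": "AC-GT", "b": "ACGGT"})
        assert [s.column_1based for s in sites] == [3]

    def test_ragged_alignment_rejected(self):
        with pytest.raises(CatalogError):
            find_variable_sites({"a": "ACGT", "b": "ACG"})


class TestDiagnosticRegions:
    # Two length-10 sequences differing only at position 6 (1-based);
    # with k=4, exactly the starts 3..6 cover the variable position.
    SEQ_A = "AACCGGTTAG"
    SEQ_B = "AACCGCTTAG"

    def test_unique_and_shared_intervals(self):
        groups = make_groups(self.SEQ_A, self.SEQ_B, prefix="S")
        regions = diagnostic_regions(groups, 4)
        by_carrier = {}
        for r in regions:
            by_carrier.setdefault(r.carrier_group, []).append(r)
        for gid in ("S1", "S2"):
            self_regions = [r for r in by_carrier[gid]
                            if r.group_subset == frozenset([gid])]
            assert len(self_regions) == 1
            assert (self_regions[0].start_min_1based,
                    self_regions[0].start_max_1based) == (3, 6)
            shared = [r for r in by_carrier[gid]
                      if r.group_subset == frozenset(["S1", "S2"])]
            assert {(r.start_min_1based, r.start_max_1based) for r in shared} \
                == {(1, 2), (7, 7)}
            assert all(not r.informative for r in shared)

    def test_single_group_whole_length_region(self):
        groups = make_groups("ACGTACGTAC")
        regions = diagnostic_regions(groups, 4)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start_min_1based, r.start_max_1based) == (1, 7)
        assert r.group_subset == frozenset(["G1"])

    def test_shared_column_yields_two_group_class(self):
        # A and B agree at the single column where C differs from both:
        # reads over that column from A match {A, B} but not C.
        base = "AACCGGTTAGCA"
        a = base
        b = base[:1] + "G" + base[2:]   # differs from A at column 2
        c = base[:6] + "A" + base[7:]   # differs from A and B at column 7
        groups = make_groups(a, b, c, prefix="P")
        regions = diagnostic_regions(groups, 4)
        ab = [r for r in regions
              if r.carrier_group == "P1"
              and r.group_subset == frozenset(["P1", "P2"])]
        assert ab, "expected an {A,B}-but-not-C region on A"
        covered = set()
        for r in ab:
            covered |= set(range(r.start_min_1based, r.start_max_1based + 1))
        assert any(p <= 7 <= p + 3 for p in covered)

    def test_read_length_exceeding_min_length_rejected(self):
        with pytest.raises(CatalogError):
            diagnostic_regions(make_groups("ACGTACGT"), 9)

    def test_n_kmers_excluded_from_regions(self):
        groups = make_groups("ACGTNACGTT")
        regions = diagnostic_regions(groups, 4)
        covered = set()
        for r in regions:
            covered |= set(range(r.start_min_1based, r.start_max_1based + 1))
        assert covered == {1, 6, 7}  # only N-free starts


class TestRegionProperties:
    @given(seed=st.integers(0, 5000), k=st.sampled_from([20, 33, 48]))
    @settings(max_examples=20, deadline=None)
    def test_partition_and_soundness(self, seed, k):
        spec = SyntheticFamilySpec(
            n_genes=4, seq_length=90, n_variable_sites=4,
            identical_partition=((1,), (2,), (3, 4)), seed=seed,
        )
        fam = generate_family(spec)
        regions = diagnostic_regions(fam.groups, k)
        for g in fam.groups:
            mine = [r for r in regions if r.carrier_group == g.group_id]
            width = sum(r.width for r in mine)
            assert width == len(g.representative_sequence) - k + 1
            for r in mine:
                for start in range(r.start_min_1based, r.start_max_1based + 1):
                    kmer = g.representative_sequence[start - 1 : start - 1 + k]
                    assert naive_matched_groups(kmer, fam.groups, k) \
                        == r.group_subset

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=15, deadline=None)
    def test_longer_reads_distinguish_no_fewer_groups(self, seed):
        spec = SyntheticFamilySpec(
            n_genes=5, seq_length=120, n_variable_sites=5,
            identical_partition=tuple((i,) for i in range(1, 6)), seed=seed,
        )
        fam = generate_family(spec)

        def self_unique(k):
            regions = diagnostic_regions(fam.groups, k)
            return {
                r.carrier_group
                for r in regions
                if r.group_subset == frozenset([r.carrier_group])
            }

        assert self_unique(25) <= self_unique(40)
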