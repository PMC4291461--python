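"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's indexed/deconvolution code
paths: read assignment is checked against naive substring search, and region
signatures against direct k-mer enumeration.
"""

from __future__ import annotations

import pytest

from snriso import (
    IsoformGroup,
    ReadSimConfig,
    SyntheticFamilySpec,
    generate_family,
)


def naive_matched_groups(seq: str, groups, k: int) -> frozenset[str]:
    """Oracle: trim to k, then substring-search every group's sequence."""
    if len(seq) < k:
        return frozenset()
    key = seq[:k].upper().replace("U", "T")
    if "N" in key:
        return frozenset()
    return frozenset(
        g.group_id for g in groups if key in g.representative_sequence
    )


def make_groups(*seqs: str, prefix: str = "G") -> list[IsoformGroup]:
    """Singleton isoform groups from explicit sequences (test scaffolding)."""
    return [
        IsoformGroup(
            group_id=f"{prefix}{i + 1}", members=(f"{prefix}{i + 1}",),
            representative_sequence=s,
        )
        for i, s in enumerate(seqs)
    ]


@pytest.fixture
def small_family():
    """3 genes, first two identical: two isoform groups, 2 planted sites."""
    spec = SyntheticFamilySpec(
        n_genes=3,
        seq_length=100,
        n_variable_sites=2,
        identical_partition=((1, 2), (3,)),
        seed=7,
    )
    return generate_family(spec)


@pytest.fixture
def u5_like_family():
    """7 distinct groups at snRNA-like length, as for the U5 subtype."""
    spec = SyntheticFamilySpec(
        n_genes=7,
        seq_length=160,
        n_variable_sites=8,
        identical_partition=tuple((i,) for i in range(1, 8)),
        seed=11,
        family_name="U5",
    )
    return generate_family(spec)
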