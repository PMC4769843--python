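"""Shared fixtures: synthetic genes and HSP construction helpers."""

from __future__ import annotations

import pytest

from genecapture import Hsp, SeedTranscript
from genecapture import simdata


@pytest.fixture(scope="session")
def as1():
    """The 14-exon asparagine synthetase fixture gene."""
    return simdata.as1_fixture()


@pytest.fixture(scope="session")
def as1_seed(as1):
    return as1.seed_transcript()


@pytest.fixture(scope="session")
def demo():
    return simdata.demo_genes()


def mk_hsp(
    contig_id: str,
    seed_id: str,
    seed_start: int,
    seed_end: int,
    contig_start: int = 0,
    strand: str = "+",
    contig_length: int = 10_000,
) -> Hsp:
    """A synthetic gap-free HSP with perfect identity for scoring tests."""
    length = seed_end - seed_start
    return Hsp(
        contig_id=contig_id,
        seed_id=seed_id,
        contig_start=contig_start,
        contig_end=contig_start + length,
        seed_start=seed_start,
        seed_end=seed_end,
        strand=strand,
        identity_fraction=1.0,
        score=float(length),
        contig_length=contig_length,
    )


def plain_seed(seed_id: str, length: int) -> SeedTranscript:
    """A seed whose content is irrelevant (scoring/tiling tests)."""
    return SeedTranscript(id=seed_id, sequence="A" * length)
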