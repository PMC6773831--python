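"""Shared fixtures: all inputs are generated programmatically at test time.

Session scope keeps alignment-heavy fixtures built once; every fixture is
seeded so the suite is fully deterministic.
"""

import pytest

from numtaudit import (ReadConfig, ReferenceSet, make_mito_genome,
                       one_mismatch_fixture, two_mismatch_fixture)


@pytest.fixture(scope="session")
def small_mito():
    """1 kb repeat-free circular mito contig."""
    return make_mito_genome(1000, 11)


@pytest.fixture(scope="session")
def plain_refset():
    """2 kb mito contig with no nuclear homology at all."""
    return ReferenceSet(make_mito_genome(2000, 3))


@pytest.fixture(scope="session")
def omf():
    """(refset, snv): nuMT one mismatch from its mito source, mismatch at
    the focal position, 100 bp flanks."""
    return one_mismatch_fixture(1, mito_length=3000, background_length=1500)


@pytest.fixture(scope="session")
def omf_2kb():
    """Smaller one-mismatch fixture for full-realignment oracle checks."""
    return one_mismatch_fixture(5, mito_length=2000, background_length=1000)


@pytest.fixture(scope="session")
def tmf():
    """(refset, background_snv, focal_snv): nuMT two mismatches from its
    source; the background SNV's alt equals one nuclear base."""
    return two_mismatch_fixture(2, mito_length=3000, background_length=1500)


@pytest.fixture(scope="session")
def se100():
    return ReadConfig(100, "single")
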