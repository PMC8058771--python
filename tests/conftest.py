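from __future__ import annotations

import pytest

from fuse import FixtureSpec, ProteinCatalog, ProteinRecord, load_scheme, make_fixture


@pytest.fixture(scope="session")
def default_scheme():
    return load_scheme()


@pytest.fixture
def small_catalog() -> ProteinCatalog:
    """Five kept proteins plus one NMD-biotype record, pre-partitioned."""
    kept = [
        ProteinRecord(f"P{i}", f"T{i}", f"G{i}", f"GENA{i}", "protein_coding", 100 + i)
        for i in range(5)
    ]
    excluded = [
        ProteinRecord("PX", "TX", "GX", "NMD1", "nonsense_mediated_decay", 80)
    ]
    return ProteinCatalog(records=kept, excluded=excluded)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One default synthetic bundle (2 families of 5, 2 excluded), reused
    across read-only tests."""
    out = tmp_path_factory.mktemp("bundle")
    spec = FixtureSpec(n_excluded=2, seed=11)
    paths, truth = make_fixture(spec, out)
    return spec, paths, truth
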