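"""Shared fixtures: synthetic worlds generated at test time (no stored data)."""

import pytest

from occurate import simulate


@pytest.fixture(scope="session")
def world():
    """A mid-sized synthetic world with all error classes planted (fixed seed)."""
    cfg = simulate.SyntheticConfig(seed=11, n_records=20_000)
    return simulate.generate_world(cfg)


@pytest.fixture(scope="session")
def ledger(world):
    return world.truth.records.set_index("recordID")


@pytest.fixture(scope="session")
def standardised(world):
    """Per-source standardisation maps + consensus for the session world."""
    from occurate import taxonomy

    raw = world.records["scientificName"].dropna().unique()
    maps = {s: taxonomy.standardise(raw, lk) for s, lk in world.lookups.items()}
    consensus = taxonomy.build_consensus(maps)
    return maps, consensus
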