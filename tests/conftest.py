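"""Shared fixtures: small synthetic runs reused across test modules."""

import numpy as np
import pytest

import polagg as pg


@pytest.fixture(scope="session")
def small_run():
    """Short default-parameter run: 12 wells, 10 h (a few hundred cycles)."""
    cfg = pg.SimConfig(seed=101, n_wells=12, duration=10.0)
    table, log = pg.simulate_lineages(cfg)
    return cfg, table, log


@pytest.fixture(scope="session")
def small_filtered(small_run):
    _, table, _ = small_run
    return pg.filter_complete_cycles(table)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_record(
    role="mother",
    generation=1,
    t0=0.0,
    t1=40.0,
    lengths=((0.0, 2.8), (20.0, 3.6), (40.0, 5.6)),
    lineage="L0",
    sibling_id=None,
    cycle_id="",
    transect=None,
):
    """Hand-built cell-cycle record for unit tests."""
    return pg.CellCycleRecord(
        lineage_id=lineage,
        well_id="W0",
        role=pg.Role(role),
        generation=generation,
        birth_time=t0,
        division_time=t1,
        length_series=[(t0 + dt, L) for dt, L in lengths],
        width=0.8,
        cycle_id=cycle_id,
        sibling_id=sibling_id,
    )
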