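"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from rupturekit.phantoms import PlateSpec, WellSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_plate(seed: int = 0, n_cells: int = 500,
               conditions: list[tuple[str, float]] | None = None,
               replicates: tuple[int, ...] = (1, 2, 3),
               **well_kwargs) -> PlateSpec:
    """Small screen plate builder used across tests."""
    conditions = conditions or [("CTRL", 0.10)]
    wells = [WellSpec(well_id=f"{cond}_r{rep}", condition=cond, replicate=rep,
                      n_cells=n_cells, rupture_prob=p, **well_kwargs)
             for cond, p in conditions for rep in replicates]
    return PlateSpec(wells=wells, seed=seed)


def screen_plate(seed: int, n_cells: int = 1000) -> PlateSpec:
    """The canonical recovery design: control, one up-hit, one down-hit,
    eight nulls, three replicates."""
    conds = [("CTRL", 0.10), ("HIT_UP", 0.25), ("HIT_DOWN", 0.03)] + \
        [(f"NULL{i}", 0.10) for i in range(1, 9)]
    return make_plate(seed=seed, n_cells=n_cells, conditions=conds)
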