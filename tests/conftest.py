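"""Shared fixtures: packaged example systems and a random-system factory."""

from __future__ import annotations

import numpy as np
import pytest

from paritybn.expressions import BoolFunc
from paritybn.fixtures import (
    cascaded_switch,
    motif_avoidant_demo,
    mutual_inhibition_switch,
    phase_switch_synthetic,
    projection_demo,
)
from paritybn.system import BooleanSystem


@pytest.fixture
def worked_example() -> BooleanSystem:
    return motif_avoidant_demo()


@pytest.fixture
def toggle_switch() -> BooleanSystem:
    return mutual_inhibition_switch()


@pytest.fixture
def cascade() -> BooleanSystem:
    return cascaded_switch()


@pytest.fixture
def slave_toggle() -> BooleanSystem:
    return projection_demo()


@pytest.fixture
def phase_switch() -> BooleanSystem:
    return phase_switch_synthetic()


def random_system(rng: np.random.Generator, n_max: int = 8, n_min: int = 2) -> BooleanSystem:
    """A random Boolean system with mixed in-degrees (test workhorse)."""
    n = int(rng.integers(n_min, n_max + 1))
    names = tuple(f"x{i}" for i in range(n))
    funcs = {}
    for i in range(n):
        k = int(rng.integers(1, min(n, 4) + 1))
        regs = sorted(rng.choice(n, size=k, replace=False))
        table = int(rng.integers(0, 1 << (1 << k)))
        funcs[names[i]] = BoolFunc(tuple(names[r] for r in regs), table)
    return BooleanSystem(names, funcs)


def random_systems(seed: int, count: int, n_max: int = 8, n_min: int = 2):
    rng = np.random.default_rng(seed)
    return [random_system(rng, n_max, n_min) for _ in range(count)]
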