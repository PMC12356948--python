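"""Shared fixtures: scaled-down TaNa ensembles reused across the suite.

The heavy simulation fixtures are session-scoped and shared by every test
that needs real model output, so the full mutation-rate grid is simulated
exactly once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from tanainfo import ModelParams, run_ensemble
from tanainfo.popstats import default_burn_in

# Scaled-down study conditions used by the phenomenology tests: the standard
# model parameters at a reduced ensemble (40 runs x 800 generations per rate
# on the sweep grid plus the 0.06 extreme).
GRID_RATES = (0.005, 0.01, 0.02, 0.03, 0.04, 0.042, 0.045, 0.05, 0.06)
GRID_RUNS = 40
GRID_GENS = 800

# Larger ensembles (joint dimension 12 at scale 6 needs >= 120 members at
# the default 10:1 ratio) for the individuality crossover.
CROSSOVER_RATES = (0.02, 0.04, 0.045)
CROSSOVER_RUNS = 124
CROSSOVER_GENS = 800

MASTER_SEED = 20260925


@pytest.fixture(scope="session")
def grid_ensembles():
    """Ensembles of the standard model on the mutation-rate grid."""
    return {
        pm: run_ensemble(
            ModelParams(p_mut=pm), GRID_RUNS, GRID_GENS, master_seed=MASTER_SEED
        )
        for pm in GRID_RATES
    }


@pytest.fixture(scope="session")
def crossover_ensembles():
    """Bigger ensembles at the rates bracketing the error transition."""
    return {
        pm: run_ensemble(
            ModelParams(p_mut=pm),
            CROSSOVER_RUNS,
            CROSSOVER_GENS,
            master_seed=MASTER_SEED + 1,
        )
        for pm in CROSSOVER_RATES
    }


@pytest.fixture(scope="session")
def small_ensemble():
    """One small ensemble for contract/io tests (not for statistics)."""
    return run_ensemble(ModelParams(p_mut=0.01), 4, 120, master_seed=7)


def post_burn_in_window(ensemble):
    h = ensemble.horizon
    return default_burn_in(h + 1), h


class ScriptedRNG:
    """Deterministic stand-in for a Generator: scripted draws for branch tests."""

    def __init__(self, uniforms, integer_draws=()):
        self._u = list(uniforms)
        self._i = list(integer_draws)

    def random(self):
        return self._u.pop(0)

    def integers(self, n):
        if self._i:
            return self._i.pop(0) % n
        return 0
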