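"""Shared fixtures: deterministic RNGs, micro-states, and the scaled-down
monolayer state points reused across the analysis and acceptance tests."""

import numpy as np
import pytest

from polyanchor.engine import SimulationConfig, run_replicas
from polyanchor import observables as obs


@pytest.fixture
def rng():
    return np.random.default_rng(20160617)


def _state_point(kappa, n_chains, salt=0.01, seed=11, reps=3,
                 ath=20_000, eq=60_000, prod=60_000, rows=50, cols=50):
    cfg = SimulationConfig(
        n_chains=n_chains,
        rigidity=kappa,
        salt_concentration=salt,
        steps_athermal=ath,
        steps_equilibration=eq,
        steps_production=prod,
        analysis_interval=50,
        seed=seed,
        n_replicas=reps,
        n_rows=rows,
        n_cols=cols,
    )
    trajs, manifests = run_replicas(cfg)
    return cfg, trajs, manifests


# the desk-scale study conditions: full 50x50 monolayer and 98:1:1
# composition, step counts reduced uniformly, 3 replicas per state point

@pytest.fixture(scope="session")
def run_flexible_lowcp():
    """kappa=0, N_c=2 (C_p=0.00092), C_i=0.01 M."""
    return _state_point(0.0, 2)


@pytest.fixture(scope="session")
def run_semiflexible_lowcp():
    """kappa=10, N_c=2, C_i=0.01 M."""
    return _state_point(10.0, 2)


# the high-concentration points keep C_p = 0.0037 on a proportionally
# smaller monolayer (4 chains over 34x36 sites), the sanctioned lattice
# scale-down: same surface densities, ~4x cheaper per step

@pytest.fixture(scope="session")
def run_flexible_highcp():
    """kappa=0, C_p=0.0037 (4 chains / 34x36 lattice), C_i=0.01 M."""
    return _state_point(0.0, 4, rows=34, cols=36,
                        ath=10_000, eq=100_000, prod=50_000)


@pytest.fixture(scope="session")
def run_stiff_highcp():
    """kappa=100, C_p=0.0037 (4 chains / 34x36 lattice), C_i=0.01 M."""
    return _state_point(100.0, 4, rows=34, cols=36,
                        ath=10_000, eq=100_000, prod=50_000)


@pytest.fixture(scope="session")
def run_flexible_highsalt():
    """kappa=0, N_c=2, C_i=0.1 M (strong screening)."""
    return _state_point(0.0, 2, salt=0.1)


@pytest.fixture(scope="session")
def sequestration_lowcp(run_flexible_lowcp):
    _, trajs, _ = run_flexible_lowcp
    spec = obs.ZoneSpec()
    return obs.aggregate_sequestration(
        [obs.sequestration_stats(t, spec) for t in trajs]
    )
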