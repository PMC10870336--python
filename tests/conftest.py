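"""Shared fixtures: small seed populations and the scaled-down replicate grid.

The session-scoped ``desk_grid`` fixture runs the desk-scale fixation
experiment once (K = 100, rescaled background-selection regime, a favored
and a disfavored benefit on either side of the Hamilton threshold b = 0.2)
and is shared by every test that interrogates its outcomes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sibaltruism.genetics import GenomeParams
from sibaltruism.lifecycle import LifecycleParams, burn_in
from sibaltruism.experiment import run_cell
from sibaltruism.stats import estimate_fixation

# Desk-scale study conditions (see docs/methods.md): K = 100 with the
# background-selection intensity rescaled to keep Ne*s*h >> 1.
DESK_K = 100
DESK_COST = 0.1
DESK_U_DEL = 5e-7
DESK_S_BGS = -0.06
DESK_BURN_GENS = 400
DESK_P0 = 1.0 / (6 * DESK_K)

# (name, b, s_del, rho, n_replicates): replicate counts sized by a power
# analysis on the diffusion predictions so each directional comparison has
# a multi-sigma expected separation.
DESK_CELLS = [
    ("fav_nobgs", 0.3, 0.0, 1e-8, 5_000),
    ("fav_bgs", 0.3, DESK_S_BGS, 1e-8, 5_000),
    ("fav_bgs_highrho", 0.3, DESK_S_BGS, 1e-4, 5_000),
    ("dis_nobgs", 0.16, 0.0, 1e-8, 30_000),
    ("dis_bgs", 0.16, DESK_S_BGS, 1e-8, 30_000),
]

GRID_MASTER_SEED = 20240301
N_SEED_POPS = 4


@pytest.fixture(scope="session")
def neutral_seed_pop():
    """Mutation-free K=100 population (burn-in of length zero)."""
    genome = GenomeParams(u_del=0.0, s_del=0.0)
    life = LifecycleParams(K=DESK_K, c=0.0, b=0.0, burn_in_gens=0)
    pop, _ = burn_in(genome, life, seed=12345, record_pi_every=0)
    return pop


@pytest.fixture(scope="session")
def desk_grid():
    """Run the desk-scale fixation grid once per session.

    Returns a dict with per-cell :class:`FixationEstimate`s and a tidy
    per-replicate outcome table (benefit, bgs, fixed) for the cells at the
    default recombination rate.
    """
    seed_pops: dict[tuple[float, float], list] = {}
    for s_del, rho in {(s, r) for _, _, s, r, _ in DESK_CELLS}:
        genome = GenomeParams(u_del=DESK_U_DEL, s_del=s_del, rho=rho)
        life = LifecycleParams(K=DESK_K, c=DESK_COST, b=0.0, burn_in_gens=DESK_BURN_GENS)
        root = np.random.SeedSequence(GRID_MASTER_SEED, spawn_key=(0, hash((s_del, rho)) % 2**16))
        seed_pops[(s_del, rho)] = [
            burn_in(genome, life, ss, record_pi_every=0)[0] for ss in root.spawn(N_SEED_POPS)
        ]

    estimates = {}
    rows = []
    for ci, (name, b, s_del, rho, n_rep) in enumerate(DESK_CELLS):
        life = LifecycleParams(K=DESK_K, c=DESK_COST, b=b, burn_in_gens=0)
        cell_seed = np.random.SeedSequence(GRID_MASTER_SEED, spawn_key=(1, ci))
        outcomes = run_cell(seed_pops[(s_del, rho)], life, n_rep, cell_seed)
        estimates[name] = estimate_fixation(outcomes)
        if rho == 1e-8:
            rows.append(
                pd.DataFrame(
                    {
                        "benefit": b,
                        "bgs": int(s_del not in (0.0, -1.0)),
                        "fixed": [int(o.fixed) for o in outcomes],
                    }
                )
            )
    return {
        "estimates": estimates,
        "outcomes": pd.concat(rows, ignore_index=True),
        "p0": DESK_P0,
    }
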