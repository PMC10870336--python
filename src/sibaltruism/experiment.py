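"""Scenario configuration, seed-population generation, and replicate grids.

A scenario couples the genomic and lifecycle parameters with grids over the
social benefit ``b``, the deleterious effect ``s_del``, and the recombination
rate ``rho``.  For each grid cell, replicates are seeded from a pool of
burn-in populations at mutation–selection balance (cycled uniformly) and run
to fixation or loss; outcomes are written next to the matching analytic
predictions.

Two presets are provided: ``full`` (K = 1000, 5000-generation burn-in, one
million replicates per cell — cluster-scale) and ``desk`` (K = 100, shorter
burn-in, tens of thousands of replicates — minutes on one CPU).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genetics import GenomeParams, Haplotype, Individual
from .lifecycle import (
    LifecycleParams,
    Population,
    ReplicateOutcome,
    burn_in,
    run_replicate,
)
from . import theory

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "desk_preset",
    "full_preset",
    "generate_seed_populations",
    "run_cell",
    "run_grid",
    "predictions_table",
    "make_fixture_population",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one experiment grid."""

    # genome (rho varies per grid cell)
    L: int = 100_000
    u_del: float = 5e-8
    h_del: float = 0.5
    altruism_pos: int = 1000
    # lifecycle
    K: int = 1000
    litter_size: int = 4
    c: float = 0.1
    burn_in_gens: int = 5000
    max_gens: Optional[int] = None
    social_mode: str = "additive"
    # grids
    b_grid: tuple[float, ...] = (0.0, 0.19, 0.2, 0.21, 0.3)
    s_grid: tuple[float, ...] = (0.0, -0.006, -0.008, -0.010, -0.012, -0.014, -1.0)
    rho_grid: tuple[float, ...] = (1e-8,)
    # sampling
    n_replicates: int = 1_000_000
    n_seed_pops: int = 10
    master_seed: int = 1
    scale: str = "full"
    outdir: str = "results"

    def __post_init__(self) -> None:
        if not self.b_grid or not self.s_grid or not self.rho_grid:
            raise ValueError("parameter grids must be non-empty")
        if self.n_replicates < 1 or self.n_seed_pops < 1:
            raise ValueError("n_replicates and n_seed_pops must be >= 1")

    def genome(self, s_del: float, rho: float) -> GenomeParams:
        return GenomeParams(
            L=self.L, rho=rho, u_del=self.u_del, s_del=s_del,
            h_del=self.h_del, altruism_pos=self.altruism_pos,
        )

    def lifecycle(self, b: float) -> LifecycleParams:
        return LifecycleParams(
            K=self.K, litter_size=self.litter_size, c=self.c, b=b,
            burn_in_gens=self.burn_in_gens, max_gens=self.max_gens,
            social_mode=self.social_mode,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("b_grid", "s_grid", "rho_grid"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            d = tomllib.loads(path.read_text())
        else:
            d = json.loads(path.read_text())
        return cls.from_dict(d)


def desk_preset(master_seed: int = 1, **overrides) -> ScenarioConfig:
    """Desk-scale preset: K = 100, short burn-in, 2e4 replicates per cell.

    Background selection is rescaled to stay in the Hudson–Kaplan regime at
    the reduced population size: at K = 100 the full-scale s_del = −0.01
    gives Ne·s·h < 1 (the deleterious mutations drift, and background
    selection all but vanishes), so the desk preset uses s_del = −0.06 with
    u_del = 5e-7 (U = 0.1), keeping Ne·s·h = 4 and a predicted diversity
    reduction B ≈ 0.19.
    """
    base = dict(
        K=100, burn_in_gens=400, n_replicates=20_000, n_seed_pops=4,
        u_del=5e-7, b_grid=(0.0, 0.16, 0.19, 0.2, 0.21, 0.3),
        s_grid=(0.0, -0.06), master_seed=master_seed, scale="desk",
    )
    base.update(overrides)
    return ScenarioConfig(**base)


def full_preset(master_seed: int = 1, **overrides) -> ScenarioConfig:
    """Full-scale preset (cluster-scale: one million replicates per cell)."""
    return ScenarioConfig(master_seed=master_seed, scale="full", **overrides)


# ---------------------------------------------------------------------------
# seed populations
# ---------------------------------------------------------------------------

def _seed_sequences(config: ScenarioConfig, s_idx: int, rho_idx: int) -> list[np.random.SeedSequence]:
    root = np.random.SeedSequence(config.master_seed, spawn_key=(0, s_idx, rho_idx))
    return root.spawn(config.n_seed_pops)


def generate_seed_populations(
    config: ScenarioConfig,
    outdir: Optional[str | Path] = None,
    record_pi_every: int = 100,
) -> tuple[dict[tuple[float, float], list[Path]], pd.DataFrame]:
    """Burn in ``n_seed_pops`` populations per (s_del, rho) grid value.

    Snapshots are written as versioned JSON under ``outdir/seeds``; the pi
    trajectories recorded during burn-in are returned and saved as a tidy CSV
    (columns generation, s_del, rho, seed_id, pi).  Runs that go extinct are
    reported per seed.
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    seed_dir = outdir / "seeds"
    seed_dir.mkdir(parents=True, exist_ok=True)
    life = config.lifecycle(b=0.0)
    paths: dict[tuple[float, float], list[Path]] = {}
    rows = []
    for si, s_del in enumerate(config.s_grid):
        for ri, rho in enumerate(config.rho_grid):
            genome = config.genome(s_del, rho)
            cell_paths = []
            for j, ss in enumerate(_seed_sequences(config, si, ri)):
                pop, trace = burn_in(genome, life, ss, record_pi_every)
                path = seed_dir / f"s{si}_rho{ri}_seed{j}.json"
                pop.save(path)
                cell_paths.append(path)
                rows.extend(
                    {"generation": g, "s_del": s_del, "rho": rho, "seed_id": j, "pi": pi}
                    for g, pi in trace
                )
            paths[(s_del, rho)] = cell_paths
    trace_df = pd.DataFrame(rows)
    trace_df.to_csv(outdir / "pi_traces.csv", index=False)
    return paths, trace_df


# ---------------------------------------------------------------------------
# replicate grids
# ---------------------------------------------------------------------------

def run_cell(
    seed_pops: Sequence[Population],
    life: LifecycleParams,
    n_replicates: int,
    cell_seed: np.random.SeedSequence,
) -> list[ReplicateOutcome]:
    """Run replicates for one grid cell, cycling uniformly across seed pops.

    Per-replicate RNG streams are spawned by counter so replicates are
    order-independent and individually reproducible.
    """
    streams = cell_seed.spawn(n_replicates)
    out = []
    n_seeds = len(seed_pops)
    for i in range(n_replicates):
        out.append(run_replicate(seed_pops[i % n_seeds], life, streams[i]))
        if (i + 1) % 5000 == 0:
            logger.info(
                "cell b=%.3g: %d/%d replicates, %d fixed",
                life.b, i + 1, n_replicates, sum(o.fixed for o in out),
            )
    return out


def _provenance_header(config: ScenarioConfig) -> str:
    return (
        f"# sibaltruism scenario hash={config.config_hash} "
        f"master_seed={config.master_seed} scale={config.scale}\n"
    )


def run_grid(
    config: ScenarioConfig,
    outdir: Optional[str | Path] = None,
    seed_paths: Optional[dict[tuple[float, float], list[Path]]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every (b, s_del, rho) cell and write outcomes + predictions CSVs.

    Per-cell outcome files under ``outdir/cells`` double as completion
    markers, so an interrupted grid resumes where it stopped.  Returns
    (outcomes, predictions) data frames.
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    cells_dir = outdir / "cells"
    cells_dir.mkdir(parents=True, exist_ok=True)
    if seed_paths is None:
        seed_paths, _ = generate_seed_populations(config, outdir)

    frames = []
    cell_index = 0
    for si, s_del in enumerate(config.s_grid):
        for ri, rho in enumerate(config.rho_grid):
            pops = None
            for bi, b in enumerate(config.b_grid):
                cell_index += 1
                cell_id = f"b{bi}_s{si}_rho{ri}"
                cell_file = cells_dir / f"{cell_id}.csv"
                if cell_file.exists():
                    frames.append(pd.read_csv(cell_file))
                    continue
                if pops is None:
                    pops = [Population.load(p) for p in seed_paths[(s_del, rho)]]
                life = config.lifecycle(b)
                cell_seed = np.random.SeedSequence(
                    config.master_seed, spawn_key=(1, bi, si, ri)
                )
                outcomes = run_cell(pops, life, config.n_replicates, cell_seed)
                df = pd.DataFrame(
                    {
                        "scenario_id": cell_id,
                        "s_del": s_del,
                        "c": config.c,
                        "b": b,
                        "rho": rho,
                        "replicate_seed": [o.replicate_seed for o in outcomes],
                        "fixed": [int(o.fixed) for o in outcomes],
                        "generations": [o.generations for o in outcomes],
                        "censored": [int(o.censored) for o in outcomes],
                    }
                )
                df.to_csv(cell_file, index=False)
                frames.append(df)

    outcomes_df = pd.concat(frames, ignore_index=True)
    predictions = predictions_table(config)
    header = _provenance_header(config)
    for name, df in (("outcomes.csv", outcomes_df), ("predictions.csv", predictions)):
        with open(outdir / name, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
    return outcomes_df, predictions


def predictions_table(config: ScenarioConfig, sigma2: float = 0.75) -> pd.DataFrame:
    """Analytic predictions for every grid cell: Ne_bg, S, predicted p_fix.

    Mirrors the full-scale analytic pipeline: sigma2-measured Ne, the
    background-selection reduction, then the diffusion integral with a fully
    dominant focal allele inserted at p0 = 1/(6K).
    """
    Ne = theory.effective_size_from_variance(config.K, sigma2)
    p0 = 1.0 / (6 * config.K)
    rows = []
    for s_del in config.s_grid:
        for rho in config.rho_grid:
            genome = config.genome(s_del, rho)
            for b in config.b_grid:
                S = theory.altruism_selection_coefficient(config.c, b)
                ne_eff = (
                    Ne if s_del == 0.0
                    else theory.ne_background_selection(Ne, genome.U, s_del, genome.h_del, genome.R)
                )
                rows.append(
                    {
                        "s_del": s_del, "rho": rho, "c": config.c, "b": b,
                        "Ne_bg": ne_eff, "S": S,
                        "p_fix_pred": theory.fixation_probability_diffusion(ne_eff, S, 1.0, p0),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

def make_fixture_population(
    table: Sequence[dict], genome: Optional[GenomeParams] = None
) -> Population:
    """Build a deterministic Population from a tiny hand-written genotype table.

    Each row is a mapping with keys ``hap_a`` and ``hap_b`` (lists of sorted
    deleterious positions) and optional booleans ``alt_a``/``alt_b``.  At most
    20 individuals; malformed rows raise a ValueError listing every offending
    row.
    """
    genome = genome if genome is not None else GenomeParams()
    if len(table) == 0 or len(table) > 20:
        raise ValueError(f"fixture must list 1..20 individuals, got {len(table)}")
    errors = []
    individuals = []
    for i, row in enumerate(table):
        try:
            haps = []
            for side in ("hap_a", "hap_b"):
                pos = np.asarray(row.get(side, []), dtype=np.int64)
                if pos.size and (pos.min() < 1 or pos.max() > genome.L):
                    raise ValueError(f"{side} positions outside [1, {genome.L}]")
                if np.any(pos == genome.altruism_pos):
                    raise ValueError(f"{side} occupies the altruism locus")
                if not np.all(np.diff(pos) >= 0):
                    pos = np.sort(pos)
                haps.append(pos)
            individuals.append(
                Individual(
                    hap_a=Haplotype(haps[0], bool(row.get("alt_a", False))),
                    hap_b=Haplotype(haps[1], bool(row.get("alt_b", False))),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValueError("invalid fixture rows:\n" + "\n".join(errors))
    return Population.from_individuals(
        individuals, genome, rng=np.random.default_rng(0)
    )
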