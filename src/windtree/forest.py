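"""Island-forest simulation: the yearly cycle, death rules, initialisation
and the single-elimination tournament driver.

One year consists of, in order: (1) light interception, (2) felt-stress
calculation (fixed ``U0`` over fixed azimuths), (3) secondary growth with
maintenance and weakening, (4) storm pruning at a random speed and azimuth,
(5) death, (6) primary growth from the reserve, (7) seed dispersal and
germination.  A single shared random stream with a fixed draw order makes
runs bit-reproducible for a given configuration and seed.

For speed, the per-segment passes (light, load propagation, allocation) run
on concatenated struct-of-arrays of the whole forest; trees remain the unit
of ownership for topology changes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import allocation as alloc
from . import genome as gn
from . import light as lt
from . import mechanics as mech
from .architecture import Tree
from .params import RunConfig, SimulationParams, TournamentConfig


@dataclass
class YearBudget:
    """Per-tree carbon bookkeeping of the secondary phase of one year."""

    tree_ids: np.ndarray
    production: np.ndarray
    maintenance: np.ndarray
    growth: np.ndarray
    leftover: np.ndarray        # banked into reserves
    primary_spent: np.ndarray   # reserve debited in the primary phase


@dataclass
class _Global:
    """Concatenated segment arrays of all living trees."""

    offsets: np.ndarray
    tree_index: np.ndarray
    parent: np.ndarray
    depth: np.ndarray
    nchild: np.ndarray
    t: np.ndarray
    base: np.ndarray
    d: np.ndarray
    strength: np.ndarray
    sigma_rel: np.ndarray
    light: np.ndarray
    levels: list[np.ndarray]

    @property
    def n(self) -> int:
        return self.parent.shape[0]


class Forest:
    """A population of trees on a circular island of radius ``R``."""

    def __init__(self, params: SimulationParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.year = 0
        self.trees: list[Tree] = []
        self.sky = lt.sky_directions(params.n_sky_angles, params.n_sky_bands)
        self.summary_rows: list[dict] = []
        self.storm_rows: list[dict] = []
        self.last_budget: YearBudget | None = None
        self._next_id = 0

    # -- initialisation ---------------------------------------------------

    def sow(self, genome: gn.Genome, position: tuple[float, float],
            lineage_id: int | None = None) -> Tree:
        tree = Tree(
            self.params, genome, position, self.rng,
            tree_id=self._next_id,
            lineage_id=self._next_id if lineage_id is None else lineage_id,
            birth_year=self.year,
        )
        self._next_id += 1
        self.trees.append(tree)
        return tree

    def random_position(self) -> tuple[float, float]:
        r = self.params.R * math.sqrt(self.rng.uniform())
        phi = self.rng.uniform(0.0, 2.0 * math.pi)
        return r * math.cos(phi), r * math.sin(phi)

    # -- queries ----------------------------------------------------------

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def count_species(self) -> int:
        """Distinct founding lineages among living trees."""
        return len({t.lineage_id for t in self.trees})

    def biomasses(self) -> np.ndarray:
        return np.array([float(np.sum(t.segment_volumes())) for t in self.trees])

    # -- the yearly cycle -------------------------------------------------

    def _gather(self) -> _Global:
        trees = self.trees
        ns = np.array([t.n for t in trees], dtype=np.int64)
        offsets = np.concatenate([[0], np.cumsum(ns)])
        parent = np.concatenate(
            [t.col("parent").astype(np.int64) + (t.col("parent") >= 0) * off
             for t, off in zip(trees, offsets[:-1])]) if trees else np.zeros(0, np.int64)
        cat = lambda name: (np.concatenate([t.col(name) for t in trees])
                            if trees else np.zeros((0,)))
        depth = cat("depth").astype(np.int64)
        g = _Global(
            offsets=offsets,
            tree_index=np.repeat(np.arange(len(trees)), ns),
            parent=parent,
            depth=depth,
            nchild=cat("nchild"),
            t=cat("t").reshape(-1, 3) if trees else np.zeros((0, 3)),
            base=cat("base").reshape(-1, 3) if trees else np.zeros((0, 3)),
            d=cat("d"),
            strength=cat("strength"),
            sigma_rel=np.zeros(int(ns.sum())),
            light=np.zeros(int(ns.sum())),
            levels=mech.level_index(depth),
        )
        return g

    def yearly_cycle(self) -> None:
        """Advance the forest by one year (steps 1-7)."""
        params = self.params
        self.year += 1
        year = self.year
        n_births = 0
        n_deaths = 0
        pruned_volume = 0.0

        g = self._gather() if self.trees else None

        if g is not None and g.n > 0:
            twig = g.nchild == 0
            # Step 1: light interception.
            centers = g.base[twig] + params.L * g.t[twig]
            l = lt.intercept_light(centers, params.alpha_fol, params.L, self.sky)
            g.light[twig] = l

            # Step 2: felt stress at U0 over the fixed azimuths.
            u8 = mech.azimuth_directions(params.n_wind_orientations)
            sig = mech.stress_at(g.parent, g.depth, g.t, g.d, twig,
                                 params.U0, u8, params)
            g.sigma_rel = sig.max(axis=1)

            # Step 3: secondary growth.  The safety factor comes from each
            # tree's own secondary network.
            nfol = np.where(twig, 1.0, 0.0)
            for idx in reversed(g.levels):
                p = g.parent[idx]
                ok = p >= 0
                if ok.any():
                    np.add.at(nfol, p[ok], nfol[idx[ok]])
            S = np.empty(g.n)
            for i, tree in enumerate(self.trees):
                sl = slice(g.offsets[i], g.offsets[i + 1])
                _, _, _, _, secondary = tree.decoded()
                S[sl] = gn.secondary_policy(g.sigma_rel[sl], nfol[sl], secondary)
            res = alloc.allocate_secondary_arrays(
                g.parent, g.depth, g.nchild, g.d, g.sigma_rel, S, g.light,
                params, levels=g.levels)
            new_strength = alloc.update_strength(g.strength, res.maint_frac,
                                                 params)
            # Per-tree bookkeeping.
            nt = len(self.trees)
            ti = g.tree_index
            budget = YearBudget(
                tree_ids=np.array([t.id for t in self.trees]),
                production=np.bincount(ti, weights=res.production, minlength=nt),
                maintenance=np.bincount(ti, weights=res.maint_paid, minlength=nt),
                growth=np.bincount(ti, weights=res.growth_volume, minlength=nt),
                leftover=np.bincount(ti, weights=res.leftover, minlength=nt),
                primary_spent=np.zeros(nt),
            )
            self.last_budget = budget
            # Write the updated state back onto the trees.
            for i, tree in enumerate(self.trees):
                sl = slice(g.offsets[i], g.offsets[i + 1])
                tree.col("d")[:] = res.new_d[sl]
                tree.col("strength")[:] = new_strength[sl]
                tree.col("sigma_rel")[:] = g.sigma_rel[sl]
                tree.col("light")[:] = g.light[sl]
                tree.reserve += float(budget.leftover[i])

            # Step 4: storm pruning.
            event = mech.sample_wind(self.rng, params, year=year)
            d_new = res.new_d
            sigma_storm = mech.stress_at(
                g.parent, g.depth, g.t, d_new, twig, event.U,
                np.array([math.cos(event.azimuth), math.sin(event.azimuth), 0.0]),
                params)
            volumes = math.pi * params.L * d_new ** 2 / 4.0
            removed = mech.storm_removal_mask(
                g.parent, g.depth, sigma_storm, volumes, new_strength,
                self.rng, params)
            if removed.any():
                for i, tree in enumerate(self.trees):
                    sl = slice(g.offsets[i], g.offsets[i + 1])
                    mask = removed[sl]
                    if mask.any():
                        pruned_volume += tree.remove_segments(mask)
            self.storm_rows.append({
                "year": year, "U": event.U, "azimuth": event.azimuth,
                "pruned_volume": pruned_volume,
            })
        else:
            self.last_budget = None
            event = mech.sample_wind(self.rng, params, year=year)
            self.storm_rows.append({
                "year": year, "U": event.U, "azimuth": event.azimuth,
                "pruned_volume": 0.0,
            })

        # Step 5: death.
        n_deaths += len(self.apply_death())

        # Steps 6-7: primary growth and reproduction.
        seeds: list[alloc.SeedSpec] = []
        parents: list[Tree] = []
        id_pos = ({int(tid): k for k, tid in enumerate(self.last_budget.tree_ids)}
                  if self.last_budget is not None else {})
        for tree in self.trees:
            _, _, _, primary, _ = tree.decoded()
            before = tree.reserve
            P_seg, P_seed, p = gn.primary_policy(
                tree.reserve, tree.n_foliages, primary, params.V0)
            _, tree_seeds = alloc.primary_growth(
                tree, P_seg, P_seed, p, self.rng, year=year, params=params)
            if tree.id in id_pos:
                self.last_budget.primary_spent[id_pos[tree.id]] = \
                    before - tree.reserve
            seeds.extend(tree_seeds)
            parents.extend([tree] * len(tree_seeds))

        for seed, parent_tree in zip(seeds, parents):
            landing = alloc.disperse_seed(seed, self.rng, params)
            if landing is None:
                continue
            child_genome = gn.mutate(parent_tree.genome, self.rng,
                                     params.p_mut, params.delta_g)
            self.sow(child_genome, landing, lineage_id=parent_tree.lineage_id)
            n_births += 1

        # Yearly summary, including the stand-level carbon budget.
        B = self.biomasses()
        Btot = float(B.sum())
        B2 = float((B ** 2).sum())
        budget = self.last_budget
        self.summary_rows.append({
            "year": year,
            "n_trees": self.n_trees,
            "n_species": self.count_species(),
            "total_biomass": Btot,
            "N_bar": Btot ** 2 / B2 if B2 > 0 else 0.0,
            "M_bar": B2 / Btot if Btot > 0 else 0.0,
            "storm_U": event.U,
            "pruned_volume": pruned_volume,
            "n_deaths": n_deaths,
            "n_births": n_births,
            "production": float(budget.production.sum()) if budget else 0.0,
            "maintenance": float(budget.maintenance.sum()) if budget else 0.0,
            "growth": float(budget.growth.sum()) if budget else 0.0,
            "reserve_total": float(sum(t.reserve for t in self.trees)),
        })

    def apply_death(self) -> list[Tree]:
        """Remove senescent, failed and storm-felled trees.

        A tree dies when it is older than ``max_age``, or older than
        ``juvenile_age`` with fewer than ``min_segments`` segments, or when
        its trunk broke.
        """
        params = self.params
        dead, alive = [], []
        for tree in self.trees:
            age = tree.age(self.year)
            if (not tree.alive or tree.n == 0 or age > params.max_age
                    or (age > params.juvenile_age
                        and tree.n < params.min_segments)):
                tree.alive = False
                dead.append(tree)
            else:
                alive.append(tree)
        self.trees = alive
        return dead

    # -- outputs ----------------------------------------------------------

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(self.summary_rows)

    def storms(self) -> pd.DataFrame:
        return pd.DataFrame(self.storm_rows)


def init_forest(config: RunConfig,
                genomes: list[gn.Genome] | None = None) -> Forest:
    """Sow ``n_initial`` single-segment trees at random positions in the disc.

    Genomes are uniform random unless a list (or a genome file in the config)
    is provided, in which case trees draw from it cyclically after an initial
    shuffle.
    """
    rng = np.random.default_rng(config.seed)
    forest = Forest(config.params, rng)
    pool = genomes
    if pool is None and config.genome_file is not None:
        pool = gn.load_genomes(config.genome_file)
    if pool is not None:
        order = rng.permutation(len(pool))
    for k in range(config.n_initial):
        if pool is None:
            g = gn.random_genome(rng)
        else:
            g = gn.Genome(pool[order[k % len(pool)]].genes.copy())
        forest.sow(g, forest.random_position())
    return forest


def run(config: RunConfig,
        genomes: list[gn.Genome] | None = None,
        out_dir=None) -> Forest:
    """Run a full island simulation; optionally write run artefacts.

    Fixed ``config`` and seed give bit-identical event logs.  Artefacts:
    ``summary.csv`` and ``storms.csv``, plus snapshots every
    ``snapshot_every`` years under ``snapshot_<year>/`` when requested.
    """
    from . import io as wio

    forest = init_forest(config, genomes)
    for _ in range(config.years):
        forest.yearly_cycle()
        if (out_dir is not None and config.snapshot_every
                and forest.year % config.snapshot_every == 0):
            wio.write_snapshot(forest, out_dir, tag=f"snapshot_{forest.year}")
    if out_dir is not None:
        wio.write_run_logs(forest, out_dir)
    return forest


def oldest_genomes(forest: Forest, n: int) -> list[gn.Genome]:
    """Genomes of the ``n`` oldest living trees (ties broken by id)."""
    ranked = sorted(forest.trees, key=lambda t: (t.birth_year, t.id))
    if len(ranked) < n:
        warnings.warn(
            f"only {len(ranked)} living trees for {n} requested winners")
    return [gn.Genome(t.genome.genes.copy()) for t in ranked[:n]]


def tournament(tconfig: TournamentConfig, out_dir=None) -> list[list[list[gn.Genome]]]:
    """Single-elimination tournament between island forests.

    Round 1 sows random genomes in ``n_forests`` islands; each island runs for
    the round's duration, after which the genomes of the oldest trees (the
    winners) are collected.  Later rounds halve the number of islands, sowing
    each from the merged winner pools of two previous islands.  Returns the
    winner pools per round; optionally writes ``winners_round<k>_forest<j>.txt``
    genome files.
    """
    from . import genome as gnm

    rng = np.random.default_rng(tconfig.seed)
    pools: list[list[gnm.Genome]] | None = None
    all_rounds: list[list[list[gnm.Genome]]] = []
    n_forests = tconfig.n_forests
    years = tconfig.years_first
    rnd = 1
    while n_forests >= 1:
        round_pools: list[list[gnm.Genome]] = []
        for j in range(n_forests):
            cfg = RunConfig(
                params=tconfig.params,
                n_initial=(tconfig.n_initial_first if pools is None
                           else tconfig.n_initial_later),
                years=years,
                seed=int(rng.integers(0, 2 ** 31 - 1)),
            )
            sow_pool = None
            if pools is not None:
                sow_pool = pools[2 * j] + pools[2 * j + 1]
            forest = run(cfg, genomes=sow_pool)
            winners = oldest_genomes(forest, tconfig.n_winners)
            round_pools.append(winners)
            if out_dir is not None:
                import os
                os.makedirs(out_dir, exist_ok=True)
                gnm.save_genomes(
                    os.path.join(out_dir, f"winners_round{rnd}_forest{j}.txt"),
                    winners)
        all_rounds.append(round_pools)
        pools = round_pools
        if n_forests == 1:
            break
        n_forests //= 2
        years = tconfig.years_later
        rnd += 1
    return all_rounds
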