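"""The memetic, cellular evolutionary search engine.

The search lives in the d-dimensional PCA-reduced space. Each generation,
every parent spawns one offspring by a variance-scaled uniform perturbation
(asexual reproduction), every offspring is lifted to a refined conformation
and scored by the refinement backend (local improvement), and survivors are
chosen by a crowding rule on a 2D grid over the top two PCs (local
selection): an offspring competes only with parents in nearby grid cells and
replaces the worst of them if fitter (lower energy). Every improved offspring
is archived, so the full archive - not just the final population - is the
sample-based representation of the energy landscape.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pca_space import PCABasis, ReducedCoords, align_to_basis, project, reconstruct
from .refinement import RefinementBackend, RefinementResult
from .superposition import kabsch_superpose
from .trace_io import StructureRecord

__all__ = [
    "EAConfig",
    "Individual",
    "GridIndex",
    "ArchiveEnsemble",
    "RunResult",
    "reproduce",
    "improve",
    "local_select",
    "seeding_schedule",
    "seed_population",
    "run",
    "population_diversity",
]

logger = logging.getLogger(__name__)

_VALID_C = {1, 9, 25, 49}


@dataclass
class EAConfig:
    """Search configuration.

    population_size -- number of concurrent individuals P (500 by default)
    n_generations   -- fixed generation count N (100 by default; convergence
                       is typically observed by generation 50)
    s_max           -- maximum reproduction step along PC1, in PC units (1.0)
    d               -- search dimensionality (top-d PCs; 10 by default)
    neighborhood_C  -- crowding neighborhood size: member count of the
                       (2k+1)^2 cell block (1, 9, 25, 49) or inf for global
                       selection; 25 by default
    cell_width      -- grid cell width over (PC1, PC2), in PC units (1.0)
    energy_threshold-- post-hoc functional cutoff in backend units; never
                       applied during the search (None = derive from seeds)
    rng_seed        -- seed for the single run RNG
    """

    population_size: int = 500
    n_generations: int = 100
    s_max: float = 1.0
    d: int = 10
    neighborhood_C: float = 25
    cell_width: float = 1.0
    energy_threshold: float | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.s_max <= 0:
            raise ValueError("s_max must be positive")
        if self.cell_width <= 0:
            raise ValueError("cell_width must be positive")
        if not (math.isinf(self.neighborhood_C) or int(self.neighborhood_C) in _VALID_C):
            raise ValueError(f"neighborhood_C must be one of {sorted(_VALID_C)} or inf")


@dataclass(eq=False)
class Individual:
    """One point of the search with its refined conformation and fitness."""

    coords: ReducedCoords
    energy: float
    trace: np.ndarray
    generation_born: int
    lineage: int | None = None  # parent archive id
    id: int = -1  # assigned on archiving

    def cell(self, cell_width: float) -> tuple[int, int]:
        v = self.coords.values
        return (
            int(math.floor(v[0] / cell_width)),
            int(math.floor(v[1] / cell_width)),
        )


class GridIndex:
    """2D occupancy grid over (PC1, PC2) with floor indexing at origin 0.

    Maps integer cells to population slot indices; negative coordinates land
    in cells -1, -2, ... via floor.
    """

    def __init__(self, cell_width: float = 1.0):
        if cell_width <= 0:
            raise ValueError("cell_width must be positive")
        self.cell_width = float(cell_width)
        self.cells: dict[tuple[int, int], set[int]] = {}

    @classmethod
    def from_population(cls, population: Sequence[Individual], cell_width: float) -> "GridIndex":
        g = cls(cell_width)
        for slot, ind in enumerate(population):
            g.add(slot, ind)
        return g

    def cell_of(self, ind: Individual) -> tuple[int, int]:
        return ind.cell(self.cell_width)

    def add(self, slot: int, ind: Individual) -> None:
        self.cells.setdefault(self.cell_of(ind), set()).add(slot)

    def remove(self, slot: int, ind: Individual) -> None:
        c = self.cell_of(ind)
        members = self.cells.get(c, set())
        members.discard(slot)
        if not members and c in self.cells:
            del self.cells[c]

    def neighborhood_slots(self, center: tuple[int, int], C: float) -> list[int]:
        """Slots whose cell lies in the sqrt(C) x sqrt(C) block around `center`.

        C = inf returns every indexed slot.
        """
        if math.isinf(C):
            out = set()
            for members in self.cells.values():
                out |= members
            return sorted(out)
        k = (int(math.isqrt(int(C))) - 1) // 2
        out = set()
        for di in range(-k, k + 1):
            for dj in range(-k, k + 1):
                out |= self.cells.get((center[0] + di, center[1] + dj), set())
        return sorted(out)

    def occupied_cells(self) -> int:
        return len(self.cells)


class ArchiveEnsemble:
    """Append-only archive of every improved individual ever produced."""

    def __init__(self) -> None:
        self.individuals: list[Individual] = []

    def append(self, ind: Individual) -> Individual:
        ind.id = len(self.individuals)
        self.individuals.append(ind)
        return ind

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    @property
    def energies(self) -> np.ndarray:
        return np.array([i.energy for i in self.individuals])

    def to_dataframe(self) -> pd.DataFrame:
        if not self.individuals:
            return pd.DataFrame(columns=["id", "generation", "energy"])
        d = self.individuals[0].coords.d
        rows = []
        for ind in self.individuals:
            row = {"id": ind.id, "generation": ind.generation_born, "energy": ind.energy}
            for j in range(d):
                row[f"pc{j + 1}"] = ind.coords.values[j]
            rows.append(row)
        return pd.DataFrame(rows)


def reproduce(
    parent: Individual, basis: PCABasis, config: EAConfig, rng: np.random.Generator
) -> ReducedCoords:
    """Variance-scaled uniform perturbation of a parent.

    For each coordinate i, a step s_i ~ Uniform[-s_max, +s_max] is drawn and
    scaled by Var(PC_i)/Var(PC_1), so perturbations are largest along the
    directions of greatest experimental variance:

        offspring_i = parent_i + s_i * Var(PC_i) / Var(PC_1)
    """
    d = parent.coords.d
    var = np.asarray(basis.variances[:d], dtype=float)
    if var[0] <= 0:
        raise ValueError("leading PC variance is zero: degenerate basis")
    s = rng.uniform(-config.s_max, config.s_max, size=d)
    return ReducedCoords(values=parent.coords.values + s * (var / var[0]))


def improve(
    coords: ReducedCoords,
    basis: PCABasis,
    backend: RefinementBackend,
    sequence: str,
    rng: np.random.Generator,
    generation: int = 0,
    lineage: int | None = None,
) -> Individual:
    """Lift a reduced-space point to a refined, scored individual.

    The CA trace is recovered from the coordinates, refined by the backend,
    stripped of any rigid-body drift the refinement introduced (Kabsch back
    onto the pre-refinement trace), and re-projected, since refinement may
    legitimately move the trace within the reduced space.
    """
    trace = reconstruct(coords, basis)
    result: RefinementResult = backend.refine(trace, sequence, rng)
    refined = np.asarray(result.refined_trace, dtype=float)
    if refined.shape != trace.shape:
        raise ValueError("backend changed the trace length")
    tf, _ = kabsch_superpose(refined, trace)
    aligned = tf.apply(refined)
    new_coords = project(aligned, basis, coords.d)
    return Individual(
        coords=new_coords,
        energy=float(result.energy),
        trace=aligned,
        generation_born=generation,
        lineage=lineage,
    )


def local_select(
    parents: Sequence[Individual],
    offspring: Sequence[Individual],
    grid: GridIndex,
    config: EAConfig,
    rng: np.random.Generator,
) -> list[Individual]:
    """Crowding selection on the (PC1, PC2) grid.

    Offspring are processed in a seeded-random order. Each offspring gathers
    the current parents whose cell lies in the sqrt(C) x sqrt(C) block
    centered on its own cell; an empty neighborhood falls back to all
    parents. The offspring replaces the worst-fitness (highest-energy)
    candidate - ties broken toward the lowest slot index, incumbent retained
    on equal energy - and a surviving offspring immediately becomes a parent
    for offspring processed later in the same generation (overlapping model).
    """
    P = len(parents)
    if len(offspring) != P:
        raise ValueError(f"|parents|={P} != |offspring|={len(offspring)}")
    pop = list(parents)
    order = rng.permutation(P)
    for idx in order:
        off = offspring[idx]
        center = grid.cell_of(off)
        slots = grid.neighborhood_slots(center, config.neighborhood_C)
        if not slots:
            slots = list(range(P))
        worst = max(slots, key=lambda s: (pop[s].energy, -s))
        if off.energy < pop[worst].energy:
            grid.remove(worst, pop[worst])
            pop[worst] = off
            grid.add(worst, off)
    return pop


def _improve_or_clone(
    parent: Individual,
    coords: ReducedCoords,
    basis: PCABasis,
    backend: RefinementBackend,
    sequence: str,
    rng: np.random.Generator,
    generation: int,
    archive: ArchiveEnsemble,
) -> Individual:
    """Improve an offspring; on backend failure the parent keeps its slot
    (the failed offspring is discarded and not archived)."""
    try:
        ind = improve(
            coords, basis, backend, sequence, rng, generation=generation, lineage=parent.id
        )
    except Exception as exc:  # noqa: BLE001 - backend contract: warn and keep parent
        logger.warning("backend failure at generation %d: %s; parent retains slot", generation, exc)
        return Individual(
            coords=parent.coords,
            energy=parent.energy,
            trace=parent.trace,
            generation_born=parent.generation_born,
            lineage=parent.lineage,
            id=parent.id,
        )
    archive.append(ind)
    return ind


def seeding_schedule(n_seeds: int, population_size: int) -> tuple[list[int], int]:
    """Arithmetic of the seeding rule: population sizes after each doubling
    and the number of single additions needed to reach P.

    E.g. ``seeding_schedule(46, 500) == ([46, 92, 184, 368], 132)``.
    """
    if not (1 <= n_seeds <= population_size):
        raise ValueError("need 1 <= n_seeds <= population_size")
    sizes = [n_seeds]
    while 2 * sizes[-1] <= population_size:
        sizes.append(2 * sizes[-1])
    return sizes, population_size - sizes[-1]


def seed_population(
    seed_records: Sequence[StructureRecord],
    basis: PCABasis,
    backend: RefinementBackend,
    config: EAConfig,
    rng: np.random.Generator,
    sequence: str | None = None,
) -> tuple[list[Individual], ArchiveEnsemble]:
    """Seed the initial population from experimental structures.

    Each seed trace is aligned to the basis frame, projected, and improved;
    the population is then repeatedly doubled (every member spawns one
    improved offspring, all retained) while doubling would not exceed P, and
    finally topped up one offspring at a time from uniformly-chosen members.
    E.g. 46 seeds with P = 500 gives 46 -> 92 -> 184 -> 368, then 132 single
    additions.
    """
    P = config.population_size
    if not (1 <= len(seed_records) <= P):
        raise ValueError(f"need between 1 and P={P} seeds, got {len(seed_records)}")
    if sequence is None:
        sequence = seed_records[0].sequence
    archive = ArchiveEnsemble()

    pop: list[Individual] = []
    for rec in seed_records:
        aligned = align_to_basis(rec.ca_trace, basis)
        coords = project(aligned, basis, config.d)
        ind = improve(coords, basis, backend, sequence, rng, generation=0, lineage=None)
        archive.append(ind)
        pop.append(ind)

    while 2 * len(pop) <= P:
        new = []
        for parent in list(pop):
            coords = reproduce(parent, basis, config, rng)
            new.append(
                _improve_or_clone(parent, coords, basis, backend, sequence, rng, 0, archive)
            )
        pop.extend(new)
    while len(pop) < P:
        parent = pop[int(rng.integers(len(pop)))]
        coords = reproduce(parent, basis, config, rng)
        pop.append(_improve_or_clone(parent, coords, basis, backend, sequence, rng, 0, archive))
    return pop, archive


@dataclass
class RunResult:
    archive: ArchiveEnsemble
    generation_stats: pd.DataFrame
    final_population: list[Individual]
    config: EAConfig = field(repr=False, default=None)


def run(
    config: EAConfig,
    seed_records: Sequence[StructureRecord],
    basis: PCABasis,
    backend: RefinementBackend,
    sequence: str | None = None,
) -> RunResult:
    """Full search: seeding, then N generations of reproduce/improve/select.

    Every improved offspring is archived. Per-generation statistics record the
    best and median population energy and the occupied-cell diversity. The
    entire run is a deterministic function of the config (including
    ``rng_seed``) and its inputs.
    """
    rng = np.random.default_rng(config.rng_seed)
    if sequence is None:
        sequence = seed_records[0].sequence
    pop, archive = seed_population(seed_records, basis, backend, config, rng, sequence=sequence)

    stats = []

    def record(gen: int) -> None:
        energies = np.array([i.energy for i in pop])
        stats.append(
            {
                "generation": gen,
                "best_energy": float(energies.min()),
                "median_energy": float(np.median(energies)),
                "diversity": population_diversity(pop, config.cell_width),
            }
        )

    record(0)
    for gen in range(1, config.n_generations + 1):
        offspring = []
        for parent in pop:
            coords = reproduce(parent, basis, config, rng)
            offspring.append(
                _improve_or_clone(parent, coords, basis, backend, sequence, rng, gen, archive)
            )
        grid = GridIndex.from_population(pop, config.cell_width)
        pop = local_select(pop, offspring, grid, config, rng)
        record(gen)

    return RunResult(
        archive=archive,
        generation_stats=pd.DataFrame(stats),
        final_population=pop,
        config=config,
    )


def population_diversity(
    population: Sequence[Individual], grid: "GridIndex | float" = 1.0
) -> float:
    """Fraction of the population occupying distinct (PC1, PC2) cells.

    1/P means total collapse into one cell, 1.0 means every individual sits
    in its own cell.
    """
    if not population:
        raise ValueError("empty population")
    width = grid.cell_width if isinstance(grid, GridIndex) else float(grid)
    cells = {ind.cell(width) for ind in population}
    return len(cells) / len(population)
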