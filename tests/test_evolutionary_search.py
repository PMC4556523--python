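import math

import numpy as np
import pytest
from conftest import crowding_oracle, make_individual

from sifter.evolutionary_search import (
    ArchiveEnsemble,
    EAConfig,
    GridIndex,
    improve,
    local_select,
    population_diversity,
    reproduce,
    run,
    seed_population,
    seeding_schedule,
)
from sifter.pca_space import PCABasis, ReducedCoords, project
from sifter.refinement import Basin, IdentityBackend, SurrogateBackend, synthetic_landscape_backend
from sifter.synthetic_fixtures import records_from_traces


def toy_basis(variances=(4.0, 2.0, 1.0), m=4):
    """Hand-built basis with prescribed variances and trivial geometry."""
    p = 3 * m
    comps = np.eye(p)[:, : len(variances)]
    return PCABasis(
        mean_trace=np.zeros(p),
        components=comps,
        variances=np.asarray(variances, dtype=float),
        n_samples=10,
    )


class TestReproduce:
    def test_zero_variance_dimension_unchanged(self):
        basis = toy_basis(variances=(4.0, 2.0, 0.0))
        parent = make_individual(1.0, -2.0, 0.0, extra_dims=1)
        cfg = EAConfig(population_size=1, d=3, rng_seed=0)
        child = reproduce(parent, basis, cfg, np.random.default_rng(0))
        assert child.values[2] == parent.coords.values[2]

    def test_leading_step_bounded_by_smax(self):
        basis = toy_basis()
        parent = make_individual(0.0, 0.0, 0.0, extra_dims=1)
        cfg = EAConfig(population_size=1, d=3, s_max=1.0)
        rng = np.random.default_rng(1)
        for _ in range(200):
            child = reproduce(parent, basis, cfg, rng)
            assert abs(child.values[0]) <= 1.0

    def test_step_std_scales_with_variance_ratio(self):
        basis = toy_basis(variances=(4.0, 2.0, 1.0))
        parent = make_individual(0.0, 0.0, 0.0, extra_dims=1)
        cfg = EAConfig(population_size=1, d=3, s_max=1.0)
        rng = np.random.default_rng(2)
        steps = np.array(
            [reproduce(parent, basis, cfg, rng).values for _ in range(20000)]
        )
        stds = steps.std(axis=0)
        ratios = stds / stds[0]
        assert ratios == pytest.approx([1.0, 0.5, 0.25], rel=0.05)

    def test_degenerate_leading_variance_raises(self):
        basis = toy_basis(variances=(0.0, 0.0))
        parent = make_individual(0.0, 0.0, 0.0)
        cfg = EAConfig(population_size=1, d=2)
        with pytest.raises(ValueError, match="degenerate"):
            reproduce(parent, basis, cfg, np.random.default_rng(0))


class TestImprove:
    def test_identity_backend_roundtrips_coords(self, small_basis):
        _, _, basis = small_basis
        coords = ReducedCoords(values=np.array([1.5, -0.5, 2.0]))
        ind = improve(coords, basis, IdentityBackend(), "A" * 20, np.random.default_rng(0))
        assert np.allclose(ind.coords.values, coords.values, atol=1e-6)
        assert ind.energy == 0.0

    def test_synthetic_backend_scores_basin_center(self, small_basis):
        _, _, basis = small_basis
        center = np.array([2.0, 1.0])
        backend = synthetic_landscape_backend(
            [Basin(center=center, depth=1.7, width=1.0)], basis, d=2
        )
        ind = improve(
            ReducedCoords(values=center), basis, backend, "A" * 20, np.random.default_rng(0)
        )
        assert ind.energy == pytest.approx(-1.7, abs=1e-6)

    def test_surrogate_backend_on_seed_trace(self, small_basis):
        _, aligned, basis = small_basis
        seed_coords = project(aligned[0], basis, basis.k)
        backend = SurrogateBackend(seeds=[aligned[0].copy()])
        ind = improve(seed_coords, basis, backend, "A" * 20, np.random.default_rng(0))
        # anchor term is exactly zero; only marginal ~3.8 A contacts contribute
        assert ind.energy == pytest.approx(0.0, abs=1e-4)
        assert np.allclose(ind.coords.values, seed_coords.values, atol=1e-2)


class TestLocalSelect:
    def cfg(self, C, P=1):
        return EAConfig(population_size=P, neighborhood_C=C, cell_width=1.0, d=2)

    def test_fitter_offspring_in_same_cell_survives(self):
        parent = make_individual(0.5, 0.5, energy=5.0)
        child = make_individual(0.6, 0.4, energy=1.0)
        grid = GridIndex.from_population([parent], 1.0)
        out = local_select([parent], [child], grid, self.cfg(1), np.random.default_rng(0))
        assert out == [child]

    def test_worse_offspring_rejected_and_ties_keep_incumbent(self):
        parent = make_individual(0.5, 0.5, energy=1.0)
        worse = make_individual(0.6, 0.4, energy=2.0)
        tie = make_individual(0.6, 0.4, energy=1.0)
        for child in (worse, tie):
            grid = GridIndex.from_population([parent], 1.0)
            out = local_select([parent], [child], grid, self.cfg(1), np.random.default_rng(0))
            assert out == [parent]

    def test_empty_neighborhood_competes_globally(self):
        parents = [make_individual(0.5, 0.5, 1.0), make_individual(1.5, 0.5, 9.0)]
        # offspring far outside any C25 block around the parents
        child = make_individual(40.5, 40.5, 0.5)
        other = make_individual(1.5, 0.5, 20.0)  # loses everywhere
        grid = GridIndex.from_population(parents, 1.0)
        out = local_select(
            parents, [child, other], grid, self.cfg(25, P=2), np.random.default_rng(0)
        )
        # child displaced the globally worst parent (slot 1, energy 9.0)
        assert child in out
        assert parents[0] in out

    def test_size_mismatch_raises(self):
        p = [make_individual(0, 0, 1.0)]
        grid = GridIndex.from_population(p, 1.0)
        with pytest.raises(ValueError, match="parents"):
            local_select(p, [], grid, self.cfg(1), np.random.default_rng(0))

    @pytest.mark.parametrize("C", [1, 9, 25, math.inf])
    def test_matches_brute_force_oracle(self, C):
        rng = np.random.default_rng(42)
        for _ in range(40):
            P = int(rng.integers(2, 9))
            parents = [
                make_individual(rng.uniform(0, 2), rng.uniform(0, 2), rng.normal())
                for _ in range(P)
            ]
            offspring = [
                make_individual(rng.uniform(0, 2), rng.uniform(0, 2), rng.normal())
                for _ in range(P)
            ]
            sel_seed = int(rng.integers(2**31))
            grid = GridIndex.from_population(parents, 1.0)
            got = local_select(
                parents, offspring, grid,
                EAConfig(population_size=P, neighborhood_C=C, cell_width=1.0, d=2),
                np.random.default_rng(sel_seed),
            )
            order = np.random.default_rng(sel_seed).permutation(P)
            expected = crowding_oracle(parents, offspring, C, 1.0, order)
            assert got == expected


class TestGridIndex:
    def test_floor_indexing_handles_negatives(self):
        g = GridIndex(1.0)
        ind = make_individual(-0.5, -1.5, 0.0)
        assert g.cell_of(ind) == (-1, -2)

    def test_every_member_indexed_once(self):
        inds = [make_individual(i * 0.4, 0.0, 0.0) for i in range(10)]
        g = GridIndex.from_population(inds, 1.0)
        slots = sorted(s for members in g.cells.values() for s in members)
        assert slots == list(range(10))


class TestSeeding:
    def test_doubling_schedule_arithmetic(self):
        assert seeding_schedule(46, 500) == ([46, 92, 184, 368], 132)
        assert seeding_schedule(1, 4) == ([1, 2, 4], 0)
        assert seeding_schedule(5, 5) == ([5], 0)

    def test_seed_population_matches_schedule(self, small_basis):
        _, aligned, basis = small_basis
        seeds = records_from_traces(aligned[:5], "A" * 20)
        cfg = EAConfig(population_size=24, d=3, rng_seed=0)
        pop, archive = seed_population(
            seeds, basis, IdentityBackend(), cfg, np.random.default_rng(0)
        )
        assert len(pop) == 24
        assert len(archive) == 24
        sizes, singles = seeding_schedule(5, 24)
        assert sizes == [5, 10, 20] and singles == 4
        # id layout mirrors the phases: seeds, then doubling batches, then singles
        assert [i.lineage for i in archive][:5] == [None] * 5
        for start, end in zip(sizes[:-1], sizes[1:]):
            batch = archive.individuals[start:end]
            assert all(b.lineage is not None and b.lineage < start for b in batch)

    def test_no_reproduction_when_seeds_fill_population(self, small_basis):
        _, aligned, basis = small_basis
        seeds = records_from_traces(aligned[:6], "A" * 20)
        cfg = EAConfig(population_size=6, d=3)
        pop, archive = seed_population(
            seeds, basis, IdentityBackend(), cfg, np.random.default_rng(0)
        )
        assert len(pop) == len(archive) == 6
        assert all(i.lineage is None for i in archive)

    def test_too_many_seeds_raise(self, small_basis):
        _, aligned, basis = small_basis
        seeds = records_from_traces(aligned[:5], "A" * 20)
        cfg = EAConfig(population_size=3, d=3)
        with pytest.raises(ValueError, match="seeds"):
            seed_population(seeds, basis, IdentityBackend(), cfg, np.random.default_rng(0))


def four_basin_backend(basis, d=3):
    basins = [
        Basin(center=np.array([3.0, 3.0, 0.0]), depth=2.0, width=1.0),
        Basin(center=np.array([-3.0, 3.0, 0.0]), depth=1.5, width=1.0),
        Basin(center=np.array([3.0, -3.0, 0.0]), depth=1.2, width=1.0),
        Basin(center=np.array([-3.0, -3.0, 0.0]), depth=1.0, width=1.0),
    ]
    return synthetic_landscape_backend(basins, basis, d=d, gradient_steps=2)


class TestRun:
    def small_cfg(self, **kw):
        defaults = dict(
            population_size=20, n_generations=5, d=3, neighborhood_C=9, rng_seed=7
        )
        defaults.update(kw)
        return EAConfig(**defaults)

    def test_zero_generations_archive_is_seeding_only(self, small_basis):
        _, aligned, basis = small_basis
        seeds = records_from_traces(aligned[:5], "A" * 20)
        res = run(self.small_cfg(n_generations=0), seeds, basis, IdentityBackend())
        assert len(res.archive) == 20  # exactly the seeding evaluations

    def test_archive_growth_arithmetic(self, small_basis):
        _, aligned, basis = small_basis
        seeds = records_from_traces(aligned[:5], "A" * 20)
        cfg = self.small_cfg()
        res = run(cfg, seeds, basis, four_basin_backend(basis))
        assert len(res.archive) == cfg.population_size * (1 + cfg.n_generations)

    def test_population_size_constant(self, small_basis):
        _, aligned, basis = small_basis
        seeds = records_from_traces(aligned[:5], "A" * 20)
        res = run(self.small_cfg(), seeds, basis, four_basin_backend(basis))
        assert len(res.final_population) == 20

    def test_best_energy_non_increasing(self, small_basis):
        _, aligned, basis = small_basis
        seeds = records_from_traces(aligned[:5], "A" * 20)
        res = run(self.small_cfg(n_generations=10), seeds, basis, four_basin_backend(basis))
        best = res.generation_stats["best_energy"].to_numpy()
        assert np.all(np.diff(best) <= 1e-12)

    def test_identical_seeds_give_bit_identical_archives(self, small_basis):
        _, aligned, basis = small_basis
        seeds = records_from_traces(aligned[:5], "A" * 20)
        r1 = run(self.small_cfg(), seeds, basis, four_basin_backend(basis))
        r2 = run(self.small_cfg(), seeds, basis, four_basin_backend(basis))
        assert len(r1.archive) == len(r2.archive)
        for a, b in zip(r1.archive, r2.archive):
            assert a.energy == b.energy
            assert np.array_equal(a.coords.values, b.coords.values)
            assert np.array_equal(a.trace, b.trace)

    def test_stats_columns(self, small_basis):
        _, aligned, basis = small_basis
        seeds = records_from_traces(aligned[:5], "A" * 20)
        res = run(self.small_cfg(n_generations=2), seeds, basis, IdentityBackend())
        assert list(res.generation_stats.columns) == [
            "generation", "best_energy", "median_energy", "diversity",
        ]
        assert len(res.generation_stats) == 3


class TestDiversity:
    def test_single_cell_collapse(self):
        pop = [make_individual(0.1 * i / 10, 0.2, 0.0) for i in range(10)]
        assert population_diversity(pop, 1.0) == pytest.approx(0.1)

    def test_all_distinct_cells(self):
        pop = [make_individual(float(i), 0.0, 0.0) for i in range(10)]
        assert population_diversity(pop, 1.0) == pytest.approx(1.0)

    def test_empty_population_raises(self):
        with pytest.raises(ValueError, match="empty"):
            population_diversity([], 1.0)


def test_config_validation():
    with pytest.raises(ValueError, match="neighborhood_C"):
        EAConfig(neighborhood_C=7)
    with pytest.raises(ValueError, match="s_max"):
        EAConfig(s_max=0.0)
    EAConfig(neighborhood_C=math.inf)  # global selection is valid


def test_archive_assigns_sequential_ids():
    archive = ArchiveEnsemble()
    for i in range(3):
        ind = make_individual(0.0, 0.0, float(i))
        archive.append(ind)
        assert ind.id == i
    df = archive.to_dataframe()
    assert list(df["id"]) == [0, 1, 2]
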