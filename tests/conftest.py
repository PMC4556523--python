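import math

import numpy as np
import pytest

from sifter.evolutionary_search import Individual
from sifter.pca_space import ReducedCoords, compute_pca
from sifter.superposition import align_ensemble
from sifter.synthetic_fixtures import make_mode_spec, make_toy_trace, sample_mode_ensemble


@pytest.fixture
def helix20():
    return make_toy_trace(20, "helix")


@pytest.fixture(scope="session")
def two_mode_data():
    """n=500 ensemble from two orthogonal modes with variances 4 and 1."""
    spec = make_mode_spec(n_residues=166, mode_variances=(4.0, 1.0), n_samples=500, rng_seed=0)
    training, _ = sample_mode_ensemble(spec)
    aligned = align_ensemble(training)
    basis = compute_pca(aligned)
    return spec, aligned, basis


@pytest.fixture(scope="session")
def small_basis():
    """Fast 20-residue, 3-mode basis for search-engine tests."""
    spec = make_mode_spec(n_residues=20, mode_variances=(4.0, 2.0, 1.0), n_samples=40, rng_seed=3)
    training, _ = sample_mode_ensemble(spec)
    aligned = align_ensemble(training)
    return spec, aligned, compute_pca(aligned)


def make_individual(pc1, pc2, energy, extra_dims=0):
    """Bare individual for selection tests (trace is irrelevant there)."""
    values = np.array([pc1, pc2] + [0.0] * extra_dims)
    return Individual(
        coords=ReducedCoords(values=values),
        energy=float(energy),
        trace=np.zeros((3, 3)),
        generation_born=0,
    )


def crowding_oracle(parents, offspring, C, cell_width, order):
    """Direct enumeration of the crowding replacement rule.

    Processes offspring in the given order; each competes with every parent
    whose (PC1, PC2) cell lies in the sqrt(C) x sqrt(C) block around its own
    cell (empty neighborhood -> all parents), replacing the highest-energy
    candidate (ties toward the lowest slot) iff strictly fitter.
    """
    pop = list(parents)
    P = len(pop)

    def cell(ind):
        return (
            math.floor(ind.coords.values[0] / cell_width),
            math.floor(ind.coords.values[1] / cell_width),
        )

    for idx in order:
        off = offspring[idx]
        oc = cell(off)
        if math.isinf(C):
            cand = list(range(P))
        else:
            k = (math.isqrt(int(C)) - 1) // 2
            cand = [
                s
                for s in range(P)
                if abs(cell(pop[s])[0] - oc[0]) <= k and abs(cell(pop[s])[1] - oc[1]) <= k
            ]
            if not cand:
                cand = list(range(P))
        worst = max(cand, key=lambda s: (pop[s].energy, -s))
        if off.energy < pop[worst].energy:
            pop[worst] = off
    return pop
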