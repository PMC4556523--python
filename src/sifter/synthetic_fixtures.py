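"""Synthetic test inputs with known ground truth.

Everything the rest of the package consumes can be generated here without
any downloads: toy CA traces with ideal geometry, trace ensembles built from
a base trace plus a prescribed set of orthonormal deformation modes with
known variances (so PCA output can be checked against the generating
spectrum), multi-basin energy specifications for the search oracle, and
small PDB-format fixture files.

Generated deformation modes are smooth along the chain (low-frequency cosine
profiles) and orthogonal to the six rigid-body directions of the base trace,
so that rigid alignment leaves the deformations essentially untouched. Mode
amplitudes are Gaussian; real crystallographic ensembles are not, but the
fixtures only need a known covariance structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .refinement import Basin
from .trace_io import StructureRecord

__all__ = [
    "ModeSpec",
    "make_toy_trace",
    "rigid_body_modes",
    "make_mode_spec",
    "sample_mode_ensemble",
    "make_basin_spec",
    "two_mode_spec",
    "ten_mode_spec",
    "write_synthetic_pdb",
]

# Default study-scale shape: a 166-residue chain, 46 training and 40 withheld
# samples, 10 deformation modes.
DEFAULT_N_RESIDUES = 166
DEFAULT_N_TRAINING = 46
DEFAULT_N_WITHHELD = 40
# Spectrum decays so ~90% of the variance sits in the top modes while the
# weakest mode still carries enough amplitude for dimensionality selection to
# resolve it against a 0.1 A reconstruction threshold.
DEFAULT_MODE_VARIANCES = (40.0, 33.0, 27.0, 22.0, 18.0, 15.0, 13.0, 11.0, 10.0, 9.0)


def make_toy_trace(n_residues: int, geometry: str = "helix") -> np.ndarray:
    """Deterministic toy CA trace with ideal geometry.

    "helix": rise 1.5 A per residue, 100 degrees per turn, radius 2.3 A
    (consecutive CA-CA distances ~3.8 A). "extended": collinear chain at
    3.8 A spacing.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    i = np.arange(n_residues, dtype=float)
    if geometry == "helix":
        theta = np.deg2rad(100.0) * i
        return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])
    if geometry == "extended":
        return np.column_stack([3.8 * i, np.zeros(n_residues), np.zeros(n_residues)])
    raise ValueError(f"unknown geometry {geometry!r}")


def rigid_body_modes(base_trace: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3M x 6) of the rigid-body directions of a trace:
    three translations and three infinitesimal rotations about the centroid."""
    x = np.asarray(base_trace, dtype=float)
    m = x.shape[0]
    c = x - x.mean(axis=0)
    cols = []
    for ax in range(3):
        t = np.zeros((m, 3))
        t[:, ax] = 1.0
        cols.append(t.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        cols.append(np.cross(np.broadcast_to(e, (m, 3)), c).ravel())
    q, _ = np.linalg.qr(np.column_stack(cols))
    return q


@dataclass(frozen=True)
class ModeSpec:
    """A base trace plus orthonormal deformation modes with known variances."""

    base_trace: np.ndarray
    modes: np.ndarray  # 3M x k, orthonormal columns
    mode_variances: np.ndarray  # k, positive, non-increasing
    n_samples: int
    rng_seed: int

    def __post_init__(self) -> None:
        g = self.modes.T @ self.modes
        if not np.allclose(g, np.eye(self.modes.shape[1]), atol=1e-8):
            raise ValueError("modes must be mutually orthonormal")
        v = np.asarray(self.mode_variances, dtype=float)
        if np.any(v < 0):
            raise ValueError("mode variances must be non-negative")
        if np.any(np.diff(v) > 0):
            raise ValueError("mode variances must be non-increasing")


def _smooth_profiles(m: int, k: int, rng: np.random.Generator, n_freq: int = 12) -> np.ndarray:
    """k random smooth 3M-vectors: low-frequency cosine profiles per axis."""
    i = np.arange(m)
    basis = np.stack(
        [np.cos(np.pi * f * (i + 0.5) / m) for f in range(1, n_freq + 1)]
    )  # n_freq x m
    out = np.empty((3 * m, k))
    for j in range(k):
        disp = np.zeros((m, 3))
        for ax in range(3):
            coeff = rng.normal(size=n_freq) / np.arange(1, n_freq + 1)
            disp[:, ax] = coeff @ basis
        out[:, j] = disp.ravel()
    return out


def make_mode_spec(
    n_residues: int = DEFAULT_N_RESIDUES,
    mode_variances: Sequence[float] = DEFAULT_MODE_VARIANCES,
    n_samples: int = DEFAULT_N_TRAINING,
    rng_seed: int = 0,
    geometry: str = "helix",
) -> ModeSpec:
    """Build a ModeSpec with smooth internal modes orthogonal to rigid motions.

    Raw smooth profiles are orthogonalized against the six rigid-body
    directions of the base trace and against each other (Gram-Schmidt), then
    normalized, giving an exactly orthonormal internal-deformation basis.
    """
    base = make_toy_trace(n_residues, geometry)
    k = len(mode_variances)
    rng = np.random.default_rng(rng_seed)
    rigid = rigid_body_modes(base)
    raw = _smooth_profiles(n_residues, k, rng)
    modes = []
    for j in range(k):
        v = raw[:, j]
        v = v - rigid @ (rigid.T @ v)
        for u in modes:
            v = v - u * (u @ v)
        nv = np.linalg.norm(v)
        if nv < 1e-10:
            raise RuntimeError("degenerate random mode; change rng_seed")
        modes.append(v / nv)
    return ModeSpec(
        base_trace=base,
        modes=np.column_stack(modes),
        mode_variances=np.asarray(mode_variances, dtype=float),
        n_samples=n_samples,
        rng_seed=rng_seed,
    )


def sample_mode_ensemble(
    spec: ModeSpec, n_withheld: int = 0
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Draw trace samples base + sum_i a_i mode_i with a_i ~ Normal(0, var_i).

    Returns (training, withheld); the withheld set is drawn independently
    from the same seeded stream after the training set. Deterministic per
    spec.
    """
    rng = np.random.default_rng(spec.rng_seed)
    sig = np.sqrt(spec.mode_variances)

    def draw(n: int) -> list[np.ndarray]:
        amps = rng.normal(size=(n, len(sig))) * sig
        flat = spec.base_trace.ravel()[None, :] + amps @ spec.modes.T
        return [f.reshape(-1, 3) for f in flat]

    return draw(spec.n_samples), draw(n_withheld) if n_withheld else []


def make_basin_spec(
    d: int,
    k_basins: int,
    min_separation: float = 5.0,
    depth_range: tuple[float, float] = (1.0, 2.0),
    width_range: tuple[float, float] = (0.8, 1.2),
    center_range: float = 8.0,
    rng_seed: int = 0,
    max_tries: int = 1000,
) -> list[Basin]:
    """Sample k Gaussian basins with well-separated centers.

    Centers live in the top-2 coordinates (uniform in
    [-center_range, center_range]^2, zero elsewhere) with pairwise top-2
    distance >= min_separation, by rejection sampling; depths and widths are
    uniform in their ranges. Deterministic per seed.
    """
    if k_basins < 1:
        raise ValueError("need at least one basin")
    rng = np.random.default_rng(rng_seed)
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < k_basins:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {k_basins} centers >= {min_separation} apart "
                f"in [-{center_range}, {center_range}]^2 after {max_tries} tries"
            )
        tries += 1
        c2 = rng.uniform(-center_range, center_range, size=2)
        if all(np.linalg.norm(c2 - c[:2]) >= min_separation for c in centers):
            c = np.zeros(d)
            c[:2] = c2
            centers.append(c)
    basins = []
    for c in centers:
        depth = float(rng.uniform(*depth_range))
        width = float(rng.uniform(*width_range))
        basins.append(Basin(center=c, depth=depth, width=width))
    return basins


def two_mode_spec(
    n_samples: int = 500, n_residues: int = DEFAULT_N_RESIDUES, rng_seed: int = 0
) -> ModeSpec:
    """Two orthogonal modes with variances 4 and 1 (the PCA check fixture)."""
    return make_mode_spec(
        n_residues=n_residues,
        mode_variances=(4.0, 1.0),
        n_samples=n_samples,
        rng_seed=rng_seed,
    )


def ten_mode_spec(
    n_samples: int = DEFAULT_N_TRAINING,
    n_residues: int = DEFAULT_N_RESIDUES,
    rng_seed: int = 0,
) -> ModeSpec:
    """Study-scale ten-mode fixture with the default decaying spectrum."""
    return make_mode_spec(
        n_residues=n_residues,
        mode_variances=DEFAULT_MODE_VARIANCES,
        n_samples=n_samples,
        rng_seed=rng_seed,
    )


def records_from_traces(
    traces: Sequence[np.ndarray], sequence: str, prefix: str = "synth"
) -> list[StructureRecord]:
    """Wrap raw traces as crystallographic StructureRecords (synthetic)."""
    return [
        StructureRecord(
            id=f"{prefix}{i:03d}",
            sequence=sequence,
            ca_trace=np.asarray(t, dtype=float),
            experimental_method="crystallographic",
            metadata={"synthetic": True},
        )
        for i, t in enumerate(traces)
    ]


def basin_search_setup(
    ensemble_seed: int = 7,
    basin_seed: int = 11,
    n_residues: int = 60,
    mode_variances: Sequence[float] = (40.0, 25.0, 16.0, 9.0, 4.0),
    n_training: int = 30,
    n_seeds: int = 10,
    k_basins: int = 4,
    min_separation: float = 5.0,
    gradient_steps: int = 3,
):
    """Standard multi-basin search benchmark: basis, seed records, basins, backend.

    A 60-residue, five-mode ensemble defines the reduced space; ``k_basins``
    well-separated Gaussian wells in its top-2 coordinates define the energy
    oracle. Seed records are the first ``n_seeds`` training traces. The basin
    specification is the ground truth against which search output is judged.
    """
    from .pca_space import compute_pca
    from .refinement import synthetic_landscape_backend
    from .superposition import align_ensemble

    spec = make_mode_spec(
        n_residues=n_residues,
        mode_variances=mode_variances,
        n_samples=n_training,
        rng_seed=ensemble_seed,
    )
    training, _ = sample_mode_ensemble(spec)
    aligned = align_ensemble(training)
    basis = compute_pca(aligned)
    basins = make_basin_spec(
        d=len(mode_variances),
        k_basins=k_basins,
        min_separation=min_separation,
        rng_seed=basin_seed,
    )
    backend = synthetic_landscape_backend(
        basins, basis, d=len(mode_variances), gradient_steps=gradient_steps
    )
    seeds = records_from_traces(aligned[:n_seeds], "A" * n_residues)
    return basis, seeds, basins, backend


def write_synthetic_pdb(
    path,
    trace: np.ndarray,
    sequence: str,
    chain: str = "A",
    method: str = "X-RAY DIFFRACTION",
    skip_residues: Sequence[int] = (),
    start_resnum: int = 1,
) -> None:
    """Write a minimal synthetic PDB file with one CA atom per residue.

    ``skip_residues`` omits the CA line of those 0-based positions (for gap
    fixtures); author numbering still advances, so the gap is detectable.
    """
    from .refinement import _AA3  # 3-letter code table

    tr = np.asarray(trace, dtype=float)
    lines = [
        "HEADER    SYNTHETIC FIXTURE",
        f"EXPDTA    {method}",
    ]
    serial = 1
    skip = set(skip_residues)
    for i, (x, y, z) in enumerate(tr):
        if i in skip:
            continue
        res = _AA3.get(sequence[i], "UNK")
        lines.append(
            f"ATOM  {serial:5d}  CA  {res} {chain}{start_resnum + i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
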