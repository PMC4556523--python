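"""Lifting reduced-space samples to refined conformations with an energy.

A sampled point only becomes comparable to others once it is mapped to a
conformation and scored. In the original multiscale workflow that lift is:
CA-trace recovery -> backbone reconstruction -> all-atom side-chain packing
and minimization with an external engine. Here the engine slot is a pluggable
:class:`RefinementBackend` contract. Two self-contained backends ship with
the package:

* :class:`SurrogateBackend` -- a coarse CA-level relaxation minimizing a
  clash-plus-anchor energy by bounded steepest descent; and
* :func:`synthetic_landscape_backend` -- an analytic multi-basin Gaussian
  energy over the reduced coordinates, used as the test oracle for the
  evolutionary search.

External all-atom engines plug in through :class:`ExternalCommandBackend`.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.spatial.distance import cdist

from . import pca_space
from .pca_space import PCABasis
from .superposition import DegenerateGeometryError, kabsch_superpose

__all__ = [
    "RefinementResult",
    "RefinementBackend",
    "Basin",
    "IdentityBackend",
    "SurrogateBackend",
    "SyntheticLandscapeBackend",
    "ExternalCommandBackend",
    "reconstruct_backbone",
    "surrogate_energy",
    "surrogate_refine",
    "synthetic_landscape_backend",
]

# Ideal trans-peptide internal coordinates (Angstrom / degrees).
R_N_CA = 1.458
R_CA_C = 1.525
R_C_N = 1.329
R_C_O = 1.231
ANG_CA_C_N = 116.2
ANG_C_N_CA = 121.7


def _peptide_offsets() -> tuple[float, float, float, float, float]:
    """Planar ideal-peptide offsets of C(i) and N(i+1) in the local frame of
    the CA(i)->CA(i+1) bond.

    Solved once from the ideal internal coordinates: place C at the origin and
    N along +x, attach both CA atoms at their ideal bond lengths/angles in the
    trans (anti) configuration, then express C and N in (u, q) coordinates,
    where u is the unit CA->CA vector and q an in-plane perpendicular.
    Returns (a_C, b_C, a_N, b_N, d_ideal).
    """
    c = np.array([0.0, 0.0])
    n = np.array([R_C_N, 0.0])
    ang1 = np.deg2rad(ANG_CA_C_N)
    ca_i = c + R_CA_C * np.array([np.cos(ang1), np.sin(ang1)])
    ang2 = np.deg2rad(180.0 - ANG_C_N_CA)
    ca_j = n + R_N_CA * np.array([np.cos(ang2), -np.sin(ang2)])
    u = ca_j - ca_i
    d_ideal = float(np.linalg.norm(u))
    u /= d_ideal
    q = np.array([-u[1], u[0]])
    a_c = float(np.dot(c - ca_i, u))
    b_c = float(np.dot(c - ca_i, q))
    a_n = float(np.dot(n - ca_j, u))
    b_n = float(np.dot(n - ca_j, q))
    return a_c, b_c, a_n, b_n, d_ideal


_A_C, _B_C, _A_N, _B_N, _D_IDEAL = _peptide_offsets()


def _bond_frames(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-bond unit vectors u and in-plane perpendiculars q.

    The peptide-plane orientation q is derived from the local chain geometry
    (cross products of consecutive virtual bonds), which makes the whole
    construction equivariant under proper rigid motions. Exactly collinear
    stretches fall back to a fixed-axis perpendicular.
    """
    nb = len(ca) - 1
    bonds = np.diff(ca, axis=0)
    u = bonds / np.linalg.norm(bonds, axis=1, keepdims=True)
    q = np.empty_like(u)
    for i in range(nb):
        ref = u[i - 1] if i > 0 else (u[i + 1] if nb > 1 else None)
        normal = np.cross(ref, u[i]) if ref is not None else np.zeros(3)
        if np.linalg.norm(normal) < 1e-8:
            # collinear neighborhood: any perpendicular; pick deterministically
            axis = np.zeros(3)
            axis[int(np.argmin(np.abs(u[i])))] = 1.0
            normal = np.cross(axis, u[i])
        normal /= np.linalg.norm(normal)
        qi = np.cross(normal, u[i])
        q[i] = qi / np.linalg.norm(qi)
    return u, q


def reconstruct_backbone(ca_trace: np.ndarray) -> dict[str, np.ndarray]:
    """Place backbone N, C, O atoms on a CA trace by ideal peptide geometry.

    For every consecutive CA pair the carbonyl C of the first residue and the
    amide N of the second are placed at their ideal planar trans-peptide
    offsets, anchored on the local bond frame; the along-bond offsets scale
    with the observed CA-CA distance so the C-N peptide bond stays near its
    ideal 1.329 A for near-ideal traces. Terminal atoms use the frame of the
    nearest real bond. CA positions are returned exactly as given.

    This is an analytic idealized placement: it reproduces ideal bond lengths
    on well-formed traces but performs no dihedral library fitting.
    """
    ca = np.asarray(ca_trace, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3:
        raise ValueError(f"trace must be (M, 3), got {ca.shape}")
    m = ca.shape[0]
    if m < 4:
        raise ValueError(f"need >= 4 residues to reconstruct a backbone, got {m}")
    u, q = _bond_frames(ca)
    d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    scale = d / _D_IDEAL

    n_at = np.empty_like(ca)
    c_at = np.empty_like(ca)
    for i in range(m - 1):
        c_at[i] = ca[i] + (_A_C * scale[i]) * u[i] + _B_C * q[i]
        n_at[i + 1] = ca[i + 1] + (_A_N * scale[i]) * u[i] + _B_N * q[i]
    # terminal completions from the nearest real bond frame
    n_at[0] = ca[0] + _A_N * u[0] + _B_N * q[0]
    c_at[m - 1] = ca[m - 1] + _A_C * u[m - 2] + _B_C * q[m - 2]

    o_at = np.empty_like(ca)
    for i in range(m):
        if i < m - 1:
            n_next = n_at[i + 1]
        else:
            n_next = c_at[i] + (c_at[i - 1] - n_at[i])  # virtual continuation
        v1 = c_at[i] - ca[i]
        v2 = c_at[i] - n_next
        v1 /= np.linalg.norm(v1)
        nv2 = np.linalg.norm(v2)
        v2 = v2 / nv2 if nv2 > 1e-9 else v1
        bis = v1 + v2
        nb = np.linalg.norm(bis)
        bis = bis / nb if nb > 1e-9 else v1
        o_at[i] = c_at[i] + R_C_O * bis
    return {"N": n_at, "CA": ca.copy(), "C": c_at, "O": o_at}


@dataclass(frozen=True)
class RefinementResult:
    refined_trace: np.ndarray
    energy: float
    backend_name: str
    backbone: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.energy):
            raise ValueError("refinement energy must be finite")


@runtime_checkable
class RefinementBackend(Protocol):
    """Contract: (CA trace, sequence) -> (refined trace, energy).

    Implementations must be deterministic given their inputs and the rng
    state, and must not change the trace length.
    """

    name: str
    energy_threshold_hint: float | None

    def refine(
        self, ca_trace: np.ndarray, sequence: str, rng: np.random.Generator
    ) -> RefinementResult: ...


@dataclass
class IdentityBackend:
    """Returns the input trace unchanged with energy 0 (testing/plumbing)."""

    name: str = "identity"
    energy_threshold_hint: float | None = None

    def refine(self, ca_trace, sequence, rng) -> RefinementResult:
        return RefinementResult(
            refined_trace=np.asarray(ca_trace, dtype=float).copy(),
            energy=0.0,
            backend_name=self.name,
        )


# ---------------------------------------------------------------------------
# Surrogate CA-level relaxation
# ---------------------------------------------------------------------------

CLASH_DISTANCE = 3.8  # A; non-local CA pairs closer than this are penalized


def _clash_energy_grad(x: np.ndarray, w: float) -> tuple[float, np.ndarray]:
    m = x.shape[0]
    dmat = cdist(x, x)
    i, j = np.triu_indices(m, k=3)
    d = dmat[i, j]
    viol = CLASH_DISTANCE - d
    mask = viol > 0
    e = w * float(np.sum(viol[mask] ** 2))
    g = np.zeros_like(x)
    if np.any(mask):
        ii, jj, dd, vv = i[mask], j[mask], d[mask], viol[mask]
        dd = np.maximum(dd, 1e-9)
        coeff = (-2.0 * w * vv / dd)[:, None]
        diffs = x[ii] - x[jj]
        np.add.at(g, ii, coeff * diffs)
        np.add.at(g, jj, -coeff * diffs)
    return e, g


def _anchor_energy_grad(
    x: np.ndarray, seeds: Sequence[np.ndarray], w: float
) -> tuple[float, np.ndarray]:
    best, best_aligned = None, None
    for s in seeds:
        s = np.asarray(s, float)
        try:
            tf, r = kabsch_superpose(s, x)
            aligned = tf.apply(s)
        except DegenerateGeometryError:
            # collinear seed/trace: centroid alignment only
            aligned = s - s.mean(axis=0) + x.mean(axis=0)
            r = float(np.sqrt(np.mean(np.sum((aligned - x) ** 2, axis=1))))
        if best is None or r < best:
            best, best_aligned = r, aligned
    e = w * best**2
    # envelope theorem: the optimal superposition is stationary, so the
    # gradient of the superposed RMSD^2 treats the aligned seed as fixed
    g = (2.0 * w / x.shape[0]) * (x - best_aligned)
    return float(e), g


def surrogate_energy(
    trace: np.ndarray,
    seeds: Sequence[np.ndarray],
    w_clash: float = 1.0,
    w_anchor: float = 0.5,
) -> float:
    """E = w_clash * sum_{|i-j|>=3} max(0, 3.8 - d_ij)^2 + w_anchor * minRMSD(trace, seeds)^2."""
    x = np.asarray(trace, dtype=float)
    if not seeds:
        raise ValueError("surrogate energy needs at least one seed trace")
    ec, _ = _clash_energy_grad(x, w_clash)
    ea, _ = _anchor_energy_grad(x, seeds, w_anchor)
    return ec + ea


def surrogate_refine(
    ca_trace: np.ndarray,
    sequence: str,
    seeds: Sequence[np.ndarray],
    rng: np.random.Generator,
    w_clash: float = 1.0,
    w_anchor: float = 0.5,
    n_steps: int = 50,
    step: float = 0.05,
) -> RefinementResult:
    """Bounded steepest-descent relaxation of the surrogate energy.

    Each step moves atoms at most ``step`` Angstrom along the negative
    gradient, with backtracking so that the energy never increases. The seeds
    must already live in the working reference frame.
    """
    if not seeds:
        raise ValueError("surrogate_refine needs at least one seed trace")
    x = np.asarray(ca_trace, dtype=float).copy()

    def eg(z):
        ec, gc = _clash_energy_grad(z, w_clash)
        ea, ga = _anchor_energy_grad(z, seeds, w_anchor)
        return ec + ea, gc + ga

    e, g = eg(x)
    for _ in range(n_steps):
        gmax = float(np.max(np.linalg.norm(g, axis=1)))
        if gmax < 1e-12:
            break
        eta = step / gmax
        improved = False
        for _ in range(8):
            xn = x - eta * g
            en, gn = eg(xn)
            if en < e:
                x, e, g = xn, en, gn
                improved = True
                break
            eta *= 0.5
        if not improved:
            break
    return RefinementResult(refined_trace=x, energy=float(e), backend_name="surrogate")


@dataclass
class SurrogateBackend:
    """RefinementBackend wrapping :func:`surrogate_refine` with fixed seeds."""

    seeds: list[np.ndarray]
    w_clash: float = 1.0
    w_anchor: float = 0.5
    n_steps: int = 50
    step: float = 0.05
    name: str = "surrogate"
    energy_threshold_hint: float | None = None

    def refine(self, ca_trace, sequence, rng) -> RefinementResult:
        return surrogate_refine(
            ca_trace,
            sequence,
            self.seeds,
            rng,
            w_clash=self.w_clash,
            w_anchor=self.w_anchor,
            n_steps=self.n_steps,
            step=self.step,
        )


# ---------------------------------------------------------------------------
# Synthetic multi-basin landscape backend (EA test oracle)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Basin:
    """One Gaussian well in reduced coordinates: depth and width > 0."""

    center: np.ndarray
    depth: float
    width: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).ravel())
        if self.depth <= 0 or self.width <= 0:
            raise ValueError("basin depth and width must be positive")


def basin_energy(z: np.ndarray, basins: Sequence[Basin]) -> float:
    """E(z) = -sum_k depth_k * exp(-||z - c_k||^2 / (2 width_k^2))."""
    z = np.asarray(z, dtype=float).ravel()
    e = 0.0
    for b in basins:
        dz = z - b.center[: z.shape[0]]
        e -= b.depth * np.exp(-float(dz @ dz) / (2.0 * b.width**2))
    return float(e)


def basin_energy_grad(z: np.ndarray, basins: Sequence[Basin]) -> np.ndarray:
    z = np.asarray(z, dtype=float).ravel()
    g = np.zeros_like(z)
    for b in basins:
        dz = z - b.center[: z.shape[0]]
        g += (b.depth / b.width**2) * np.exp(-float(dz @ dz) / (2.0 * b.width**2)) * dz
    return g


@dataclass
class SyntheticLandscapeBackend:
    """Analytic multi-basin energy over the reduced coordinates.

    ``refine`` projects the incoming trace (assumed to be in the basis frame),
    optionally takes a few gradient-descent steps in reduced space (the
    analogue of local energy minimization), and returns the corresponding
    trace with its basin energy.
    """

    basins: list[Basin]
    basis: PCABasis
    d: int
    gradient_steps: int = 0
    learning_rate: float = 0.4
    name: str = "synthetic-landscape"
    energy_threshold_hint: float | None = None

    def refine(self, ca_trace, sequence, rng) -> RefinementResult:
        z = pca_space.project(ca_trace, self.basis, self.d).values
        for _ in range(self.gradient_steps):
            z = z - self.learning_rate * basin_energy_grad(z, self.basins)
        e = basin_energy(z, self.basins)
        if self.gradient_steps > 0:
            out = pca_space.reconstruct(pca_space.ReducedCoords(values=z), self.basis)
        else:
            out = np.asarray(ca_trace, dtype=float).copy()
        return RefinementResult(refined_trace=out, energy=e, backend_name=self.name)


def synthetic_landscape_backend(
    basins: Sequence[Basin | tuple],
    basis: PCABasis,
    d: int | None = None,
    gradient_steps: int = 0,
    learning_rate: float = 0.4,
) -> SyntheticLandscapeBackend:
    """Build a synthetic multi-basin backend from basin specs.

    Each basin is a :class:`Basin` or a (center, depth, width) tuple. ``d``
    defaults to the dimensionality of the first basin center.
    """
    bs = [b if isinstance(b, Basin) else Basin(*b) for b in basins]
    if not bs:
        raise ValueError("need at least one basin")
    if d is None:
        d = bs[0].center.shape[0]
    return SyntheticLandscapeBackend(
        basins=bs, basis=basis, d=d, gradient_steps=gradient_steps, learning_rate=learning_rate
    )


# ---------------------------------------------------------------------------
# External engine adapter
# ---------------------------------------------------------------------------


@dataclass
class ExternalCommandBackend:
    """Adapter contract for external all-atom refinement engines.

    The command is run as ``cmd <input.pdb> <output.pdb> <energy.txt>``. The
    adapter writes the CA trace (with an ideal-geometry backbone) to the input
    PDB, and expects the engine to write refined coordinates to the output PDB
    and a single scalar energy to the energy file. The refined CA trace is
    read back with one CA per residue, in order.
    """

    command: list[str] = field(default_factory=list)
    name: str = "external"
    energy_threshold_hint: float | None = None

    def refine(self, ca_trace, sequence, rng) -> RefinementResult:
        if not self.command:
            raise ValueError("no external command configured")
        ca = np.asarray(ca_trace, dtype=float)
        with tempfile.TemporaryDirectory() as td:
            inp = Path(td) / "input.pdb"
            outp = Path(td) / "output.pdb"
            en = Path(td) / "energy.txt"
            _write_ca_pdb(inp, ca, sequence)
            subprocess.run([*self.command, str(inp), str(outp), str(en)], check=True)
            refined = _read_ca_pdb(outp)
            energy = float(en.read_text().split()[0])
        if refined.shape != ca.shape:
            raise ValueError("external backend changed the trace length")
        return RefinementResult(refined_trace=refined, energy=energy, backend_name=self.name)


_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def _write_ca_pdb(path, ca: np.ndarray, sequence: str) -> None:
    lines = []
    serial = 1
    for i, (x, y, z) in enumerate(ca):
        res = _AA3.get(sequence[i] if i < len(sequence) else "X", "UNK")
        lines.append(
            f"ATOM  {serial:5d}  CA  {res} A{i + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_ca_pdb(path) -> np.ndarray:
    coords = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(("ATOM", "HETATM")) and line[12:16].strip() == "CA":
            coords.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    return np.asarray(coords, dtype=float)
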