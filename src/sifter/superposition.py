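"""Optimal rigid-body superposition of CA traces.

The Kabsch algorithm finds the proper rotation + translation minimizing the
root-mean-squared deviation (RMSD) between two equal-length point sets.
Reflections are explicitly forbidden (mirror images are not conformations),
which is enforced by a sign correction on the smallest singular value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RigidTransform",
    "DegenerateGeometryError",
    "kabsch_superpose",
    "align_ensemble",
    "ca_rmsd",
]


class DegenerateGeometryError(ValueError):
    """Raised when point sets are too degenerate (e.g. collinear) to define
    a unique optimal rotation."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> R x + t.

    rotation is a 3x3 orthonormal matrix with determinant +1; translation is
    a 3-vector in Angstrom.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply the transform to an (M, 3) coordinate array."""
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying `other` first, then self."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )


def _as_trace(x: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"{name} must be an (M, 3) array, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return a


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Superpose `mobile` onto `reference`, returning the optimal proper rigid
    transform and the least RMSD.

    Both arguments are (M, 3) CA coordinate arrays with M >= 3. The returned
    transform T minimizes RMSD(T(mobile), reference) over all rotations with
    det = +1 and translations.
    """
    A = _as_trace(mobile, "mobile")
    B = _as_trace(reference, "reference")
    if A.shape != B.shape:
        raise ValueError(f"length mismatch: {A.shape[0]} vs {B.shape[0]}")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")

    ca, cb = A.mean(axis=0), B.mean(axis=0)
    Am, Bm = A - ca, B - cb
    H = Am.T @ Bm
    U, S, Vt = np.linalg.svd(H)
    # Collinear (or fully coincident-degenerate) point sets leave the rotation
    # about the common axis undetermined.
    scale = max(S[0], 1.0)
    if S[1] <= 1e-12 * scale:
        raise DegenerateGeometryError(
            "point sets are (near-)collinear; optimal rotation is not unique"
        )
    d = float(np.sign(np.linalg.det(Vt.T @ U.T)))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    moved = A @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - B) ** 2, axis=1))))
    return RigidTransform(rotation=R, translation=t), rmsd


def align_ensemble(traces: list[np.ndarray], reference_index: int = 0) -> list[np.ndarray]:
    """Superpose every trace onto ``traces[reference_index]``.

    The reference trace is returned unchanged (not merely up to numerical
    noise). All traces must have equal length.
    """
    if not traces:
        raise ValueError("empty ensemble")
    if not (0 <= reference_index < len(traces)):
        raise ValueError(f"reference_index {reference_index} out of range")
    ref = _as_trace(traces[reference_index], "reference trace")
    out: list[np.ndarray] = []
    for i, tr in enumerate(traces):
        if i == reference_index:
            out.append(ref.copy())
            continue
        tf, _ = kabsch_superpose(tr, ref)
        out.append(tf.apply(tr))
    return out


def ca_rmsd(a: np.ndarray, b: np.ndarray, superpose: bool = True) -> float:
    """CA RMSD between two equal-length traces.

    With ``superpose=True`` (default) the least RMSD over proper rigid motions
    is returned; otherwise the raw coordinate RMSD.
    """
    A = _as_trace(a, "a")
    B = _as_trace(b, "b")
    if A.shape != B.shape:
        raise ValueError(f"length mismatch: {A.shape[0]} vs {B.shape[0]}")
    if not superpose:
        return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))
    try:
        _, rmsd = kabsch_superpose(A, B)
    except DegenerateGeometryError:
        # Collinear traces: optimal superposition reduces to aligning the
        # principal axes; fall back to centered raw RMSD which is exact for
        # identical shapes and an upper bound otherwise.
        Ac = A - A.mean(axis=0)
        Bc = B - B.mean(axis=0)
        rmsd = float(np.sqrt(np.mean(np.sum((Ac - Bc) ** 2, axis=1))))
    return rmsd
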