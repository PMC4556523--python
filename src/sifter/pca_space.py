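"""The reduced search space: PCA over aligned, centered CA traces.

An ensemble of n aligned traces of M residues each is flattened into an
n x 3M matrix, row-centered by the average trace AT, and decomposed by SVD.
The orthonormal principal components (PCs) span the directions of maximal
structural variance; a trace CT maps into the reduced space by

    RS = (CT - AT) . U        (projection)
    CT = RS . U^T + AT        (reconstruction)

where U holds one PC per column. The search operates in the top-d projection
coordinates; d is chosen so that withheld traces reconstruct to within a
target RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .superposition import ca_rmsd, kabsch_superpose

__all__ = [
    "PCABasis",
    "ReducedCoords",
    "DimensionalitySelection",
    "compute_pca",
    "align_to_basis",
    "project",
    "reconstruct",
    "cumulative_variance",
    "select_dimensionality",
    "save_basis",
    "load_basis",
]


@dataclass(frozen=True, eq=False)
class ReducedCoords:
    """A point in the d-dimensional reduced search space."""

    values: np.ndarray  # (d,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float).ravel())

    @property
    def d(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class PCABasis:
    """PCA basis of the reduced search space.

    mean_trace  -- flattened 3M average trace (Angstrom)
    components  -- 3M x K matrix, orthonormal PCs as columns
    variances   -- K sample variances of the training projections, non-increasing
    n_samples   -- number of training traces
    svd_left    -- n x K left singular vectors of the centered matrix (audit)
    """

    mean_trace: np.ndarray
    components: np.ndarray
    variances: np.ndarray
    n_samples: int
    svd_left: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_residues(self) -> int:
        return int(self.mean_trace.shape[0]) // 3

    @property
    def k(self) -> int:
        return int(self.components.shape[1])

    @property
    def mean_as_trace(self) -> np.ndarray:
        return self.mean_trace.reshape(-1, 3)


def compute_pca(aligned_traces: Sequence[np.ndarray]) -> PCABasis:
    """PCA of an ensemble of aligned, equal-length CA traces.

    The caller is responsible for aligning the traces (see
    :func:`sifter.superposition.align_ensemble`); PCA itself only centers.
    Variances use the sample (n-1) normalization. PC signs are fixed
    deterministically so that each component's largest-magnitude entry is
    positive.
    """
    if len(aligned_traces) < 2:
        raise ValueError("need at least 2 traces for PCA")
    X = np.stack([np.asarray(t, dtype=float).ravel() for t in aligned_traces])
    n, p = X.shape
    if any(np.asarray(t).shape != np.asarray(aligned_traces[0]).shape for t in aligned_traces):
        raise ValueError("traces must all have the same length")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    K = min(n - 1, p)
    comps = Vt[:K].T  # p x K
    left = U[:, :K]
    # deterministic sign convention
    for j in range(K):
        i = int(np.argmax(np.abs(comps[:, j])))
        if comps[i, j] < 0:
            comps[:, j] = -comps[:, j]
            left[:, j] = -left[:, j]
    variances = (S[:K] ** 2) / (n - 1)
    return PCABasis(
        mean_trace=mean,
        components=comps,
        variances=variances,
        n_samples=n,
        svd_left=left,
    )


def align_to_basis(trace: np.ndarray, basis: PCABasis) -> np.ndarray:
    """Kabsch-align a trace onto the basis mean trace.

    Projection assumes the trace lives in the basis reference frame; traces
    that were not part of the training alignment must first pass through here.
    """
    tf, _ = kabsch_superpose(np.asarray(trace, dtype=float), basis.mean_as_trace)
    return tf.apply(trace)


def project(trace: np.ndarray, basis: PCABasis, d: int) -> ReducedCoords:
    """Project an aligned trace onto the top d PCs: values_i = (CT - AT) . PC_i."""
    flat = np.asarray(trace, dtype=float).ravel()
    if flat.shape[0] != basis.mean_trace.shape[0]:
        raise ValueError(
            f"trace length {flat.shape[0] // 3} does not match basis ({basis.n_residues})"
        )
    if not (1 <= d <= basis.k):
        raise ValueError(f"d must be in [1, {basis.k}], got {d}")
    values = (flat - basis.mean_trace) @ basis.components[:, :d]
    return ReducedCoords(values=values)


def reconstruct(coords: ReducedCoords, basis: PCABasis) -> np.ndarray:
    """Recover the CA trace of a reduced-space point: CT = RS . U^T + AT."""
    if coords.d > basis.k:
        raise ValueError(f"coords dimensionality {coords.d} exceeds basis K={basis.k}")
    flat = basis.mean_trace + basis.components[:, : coords.d] @ coords.values
    return flat.reshape(-1, 3)


def cumulative_variance(basis: PCABasis) -> np.ndarray:
    """Cumulative variance fractions per PC; the final entry is 1.0."""
    total = float(np.sum(basis.variances))
    if total <= 1e-12:
        raise ValueError("all variances are zero: degenerate (identical) training data")
    return np.cumsum(basis.variances) / total


class DimensionalitySelection(NamedTuple):
    d: int
    table: pd.DataFrame  # columns: d, median_rmsd, mean_rmsd, max_rmsd
    threshold_met: bool


def select_dimensionality(
    basis: PCABasis,
    withheld: Sequence[np.ndarray],
    candidate_ds: Sequence[int],
    rmsd_threshold: float = 0.5,
) -> DimensionalitySelection:
    """Choose the search dimensionality from reconstruction error on withheld traces.

    For each candidate d the withheld traces (already aligned to the basis
    frame) are projected and reconstructed, and the distribution of
    reconstruction RMSDs recorded. The smallest d whose *median* RMSD is at or
    below ``rmsd_threshold`` is selected. If no candidate qualifies, the
    largest candidate is returned with ``threshold_met=False``.

    Raw (non-superposed) RMSD is used so that the error is exactly the norm of
    the rank-truncation residual, which is non-increasing in d.
    """
    if not withheld:
        raise ValueError("need at least one withheld trace")
    cds = sorted(int(d) for d in candidate_ds)
    if not cds:
        raise ValueError("no candidate dimensionalities given")
    rows = []
    medians: dict[int, float] = {}
    for d in cds:
        rmsds = []
        for tr in withheld:
            rec = reconstruct(project(tr, basis, d), basis)
            rmsds.append(ca_rmsd(tr, rec, superpose=False))
        rmsds = np.asarray(rmsds)
        medians[d] = float(np.median(rmsds))
        rows.append(
            {
                "d": d,
                "median_rmsd": medians[d],
                "mean_rmsd": float(np.mean(rmsds)),
                "max_rmsd": float(np.max(rmsds)),
            }
        )
    table = pd.DataFrame(rows)
    for d in cds:
        if medians[d] <= rmsd_threshold:
            return DimensionalitySelection(d=d, table=table, threshold_met=True)
    return DimensionalitySelection(d=cds[-1], table=table, threshold_met=False)


_BASIS_VERSION = 1


def save_basis(basis: PCABasis, path) -> None:
    """Persist a basis to an .npz bundle with a version header."""
    np.savez(
        path,
        version=np.array([_BASIS_VERSION]),
        mean_trace=basis.mean_trace,
        components=basis.components,
        variances=basis.variances,
        n_samples=np.array([basis.n_samples]),
        svd_left=basis.svd_left if basis.svd_left is not None else np.empty((0, 0)),
    )


def load_basis(path) -> PCABasis:
    with np.load(path) as z:
        version = int(z["version"][0])
        if version != _BASIS_VERSION:
            raise ValueError(f"unsupported basis bundle version {version}")
        svd_left = z["svd_left"]
        return PCABasis(
            mean_trace=z["mean_trace"],
            components=z["components"],
            variances=z["variances"],
            n_samples=int(z["n_samples"][0]),
            svd_left=svd_left if svd_left.size else None,
        )
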