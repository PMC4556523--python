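"""Post-processing: functional filtering and sample-based landscape grids.

The archive of refined conformations is filtered by a conservative energy
threshold (derived from the refined seed structures: no conformation may
score worse than the worst refined experimental structure), then binned on a
2D grid over the top two PCs. Each cell carries the median (or variance) of
the energies of its members; cell values are reported as offsets from the
grid minimum, which is how such landscapes are conventionally displayed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .evolutionary_search import ArchiveEnsemble, Individual
from .pca_space import PCABasis, align_to_basis, project
from .superposition import ca_rmsd
from .trace_io import StructureRecord

__all__ = [
    "LandscapeGrid",
    "filter_functional",
    "derive_threshold",
    "grid_landscape",
    "map_references",
    "recovery_rmsd",
    "label_basins",
]

logger = logging.getLogger(__name__)


@dataclass
class LandscapeGrid:
    """Per-cell statistics of a 2D energy landscape.

    cells maps integer (i, j) = (floor(pc1/cell_size), floor(pc2/cell_size))
    to (count, value), where value is the chosen statistic of the member
    energies. ``offsets`` exposes the display convention: differences from
    the minimum cell value (non-negative).
    """

    cell_size: float
    statistic: str
    cells: dict[tuple[int, int], tuple[int, float]]

    @property
    def min_value(self) -> float:
        return min(v for _, v in self.cells.values())

    @property
    def offsets(self) -> dict[tuple[int, int], float]:
        m = self.min_value
        return {c: v - m for c, (_, v) in self.cells.items()}

    def to_dataframe(self) -> pd.DataFrame:
        m = self.min_value
        rows = [
            {
                "cell_i": c[0],
                "cell_j": c[1],
                "count": n,
                "statistic_value": v,
                "offset_value": v - m,
            }
            for c, (n, v) in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows)

    def to_array(self) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
        """Dense (values, counts) arrays over the bounding box plus the
        (i_min, j_min) origin offset; empty cells hold NaN / 0."""
        keys = list(self.cells)
        i0 = min(k[0] for k in keys)
        j0 = min(k[1] for k in keys)
        ni = max(k[0] for k in keys) - i0 + 1
        nj = max(k[1] for k in keys) - j0 + 1
        vals = np.full((ni, nj), np.nan)
        counts = np.zeros((ni, nj), dtype=int)
        for (i, j), (n, v) in self.cells.items():
            vals[i - i0, j - j0] = v
            counts[i - i0, j - j0] = n
        return vals, counts, (i0, j0)


def filter_functional(
    archive: "ArchiveEnsemble | Sequence[Individual]", threshold: float
) -> list[Individual]:
    """Retain individuals with energy <= threshold (boundary inclusive)."""
    inds = list(archive)
    kept = [i for i in inds if i.energy <= threshold]
    if not kept:
        logger.warning(
            "functional filter at %.3f retained nothing (min energy %.3f)",
            threshold,
            min((i.energy for i in inds), default=math.nan),
        )
    return kept


def derive_threshold(seed_energies: Sequence[float]) -> float:
    """Functional cutoff: the worst (highest) refined seed-structure energy.

    No retained conformation may score worse than the worst refined
    experimental structure.
    """
    if len(seed_energies) == 0:
        raise ValueError("need at least one seed energy")
    return float(max(seed_energies))


def grid_landscape(
    projections: Sequence[tuple[float, float]] | np.ndarray,
    energies: Sequence[float] | np.ndarray,
    cell_size: float = 1.0,
    statistic: str = "median",
) -> LandscapeGrid:
    """Bin (pc1, pc2) points into cells and aggregate energies per cell.

    statistic is "median" or "variance" (sample variance, n-1 divisor; a
    single-member cell has variance 0). Cells are floor-indexed from origin 0,
    so every point contributes to exactly one cell.
    """
    pts = np.asarray(projections, dtype=float)
    en = np.asarray(energies, dtype=float)
    if pts.ndim != 2 or pts.shape[1] < 2:
        raise ValueError("projections must be (n, >=2)")
    if pts.shape[0] != en.shape[0]:
        raise ValueError(f"{pts.shape[0]} projections vs {en.shape[0]} energies")
    if statistic not in ("median", "variance"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    buckets: dict[tuple[int, int], list[float]] = {}
    for (x, y), e in zip(pts[:, :2], en):
        c = (int(math.floor(x / cell_size)), int(math.floor(y / cell_size)))
        buckets.setdefault(c, []).append(float(e))
    cells = {}
    for c, es in buckets.items():
        arr = np.asarray(es)
        if statistic == "median":
            v = float(np.median(arr))
        else:
            v = float(np.var(arr, ddof=1)) if arr.size > 1 else 0.0
        cells[c] = (int(arr.size), v)
    return LandscapeGrid(cell_size=float(cell_size), statistic=statistic, cells=cells)


def map_references(
    refs: Sequence[StructureRecord],
    basis: PCABasis,
    roles: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Project reference structures onto (PC1, PC2) for landscape overlay.

    Each reference trace is Kabsch-aligned to the basis mean and projected on
    the top two PCs. ``roles`` maps record ids to "training"/"validation";
    unknown ids get "unknown". Length-mismatched records are skipped with a
    warning rather than failing the whole table.
    """
    roles = roles or {}
    rows = []
    for rec in refs:
        if rec.ca_trace.shape[0] != basis.n_residues:
            logger.warning(
                "skipping %s: trace length %d != basis %d",
                rec.id, rec.ca_trace.shape[0], basis.n_residues,
            )
            continue
        aligned = align_to_basis(rec.ca_trace, basis)
        pc = project(aligned, basis, 2).values
        rows.append(
            {
                "id": rec.id,
                "pc1": float(pc[0]),
                "pc2": float(pc[1]),
                "role": roles.get(rec.id, "unknown"),
            }
        )
    return pd.DataFrame(rows, columns=["id", "pc1", "pc2", "role"])


def recovery_rmsd(
    refs: Sequence[StructureRecord],
    functional: Sequence[Individual],
    roles: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Minimum superposed CA RMSD from each reference to the functional set.

    The validation metric: a low value means the search recovered a
    conformation close to that experimental structure.
    """
    if not functional:
        raise ValueError("functional ensemble is empty")
    roles = roles or {}
    rows = []
    for rec in refs:
        best = min(ca_rmsd(rec.ca_trace, ind.trace, superpose=True) for ind in functional)
        rows.append(
            {"id": rec.id, "rmsd": float(best), "role": roles.get(rec.id, "unknown")}
        )
    return pd.DataFrame(rows, columns=["id", "rmsd", "role"])


def label_basins(grid: LandscapeGrid, depth_cutoff: float) -> dict[tuple[int, int], int]:
    """Label basins as 4-connected components of low cells.

    A cell belongs to a basin when its offset from the grid minimum is at most
    ``depth_cutoff``. Components are numbered 1, 2, ... by ascending minimum
    cell value (basin 1 holds the global minimum).
    """
    if not grid.cells:
        raise ValueError("empty landscape grid")
    vals, _, (i0, j0) = grid.to_array()
    low = np.zeros(vals.shape, dtype=bool)
    m = grid.min_value
    with np.errstate(invalid="ignore"):
        low[np.nan_to_num(vals - m, nan=np.inf) <= depth_cutoff] = True
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    labels, n = ndimage.label(low, structure=structure)
    # order components by their minimum value
    comp_min = []
    for lab in range(1, n + 1):
        comp_min.append((float(np.nanmin(vals[labels == lab])), lab))
    order = {lab: rank + 1 for rank, (_, lab) in enumerate(sorted(comp_min))}
    out = {}
    for (i, j), (_, v) in grid.cells.items():
        lab = labels[i - i0, j - j0]
        if lab > 0:
            out[(i, j)] = order[lab]
    return out
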