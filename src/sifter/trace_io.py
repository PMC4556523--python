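"""Structure input: CA-trace extraction, inclusion filtering, threading.

The structural currency of the whole package is the CA trace -- an (M, 3)
array of one alpha-carbon position per residue, in residue order. This module
reads PDB-format coordinate files (via gemmi), derives one-letter sequences,
applies the ensemble inclusion criteria (crystallographic only, no missing
internal fragments, at most ``max_mutations`` substitutions versus a
reference sequence), threads traces onto a target sequence, flags structural
outliers, and (de)serializes traces as flat text.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
from Bio import SeqIO

from .superposition import align_ensemble, ca_rmsd

__all__ = [
    "StructureRecord",
    "EnsembleDataset",
    "read_structure",
    "read_fasta_sequence",
    "filter_structures",
    "thread_trace",
    "flag_outliers",
    "write_trace",
    "read_trace",
    "validate_trace",
]

logger = logging.getLogger(__name__)

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

# CA-CA distances outside this band are physically implausible (trans peptide
# ~3.8 A, cis ~2.9 A); violations warn but do not reject.
CA_CA_BAND = (2.8, 4.1)


def validate_trace(trace: np.ndarray, warn_geometry: bool = True) -> np.ndarray:
    """Validate a CA trace: (M>=3, 3) finite coordinates; warn on implausible
    consecutive CA-CA distances."""
    a = np.asarray(trace, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"trace must be (M, 3), got {a.shape}")
    if a.shape[0] < 3:
        raise ValueError(f"trace must have >= 3 residues, got {a.shape[0]}")
    if not np.all(np.isfinite(a)):
        raise ValueError("trace contains non-finite coordinates")
    if warn_geometry:
        d = np.linalg.norm(np.diff(a, axis=0), axis=1)
        bad = (d < CA_CA_BAND[0]) | (d > CA_CA_BAND[1])
        if np.any(bad):
            warnings.warn(
                f"{int(bad.sum())} consecutive CA-CA distances outside "
                f"{CA_CA_BAND[0]}-{CA_CA_BAND[1]} A (min {d.min():.2f}, max {d.max():.2f})",
                stacklevel=2,
            )
    return a


@dataclass
class StructureRecord:
    """One experimental structure reduced to its CA trace.

    ``sequence`` and ``ca_trace`` always have matching length; the sequence
    uses the 20 standard one-letter codes plus 'X' for anything else.
    """

    id: str
    sequence: str
    ca_trace: np.ndarray
    experimental_method: str = "other"  # {crystallographic, nmr, other}
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ca_trace = validate_trace(self.ca_trace, warn_geometry=False)
        if len(self.sequence) != self.ca_trace.shape[0]:
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != "
                f"trace length {self.ca_trace.shape[0]}"
            )
        bad = set(self.sequence) - _STANDARD_AA - {"X"}
        if bad:
            raise ValueError(f"{self.id}: invalid sequence characters {sorted(bad)}")

    @property
    def has_internal_gap(self) -> bool:
        return bool(self.metadata.get("has_internal_gap", False))


@dataclass
class EnsembleDataset:
    """A curated trace ensemble split into PCA-training and withheld sets."""

    records: list[StructureRecord]
    reference_sequence: str
    training_ids: list[str]
    validation_ids: list[str]

    def __post_init__(self) -> None:
        ids = {r.id for r in self.records}
        train, val = set(self.training_ids), set(self.validation_ids)
        if train & val:
            raise ValueError(f"training/validation overlap: {sorted(train & val)}")
        missing = (train | val) - ids
        if missing:
            raise ValueError(f"role assigned to unknown ids: {sorted(missing)}")
        m = len(self.reference_sequence)
        for r in self.records:
            if r.ca_trace.shape[0] != m:
                raise ValueError(
                    f"{r.id}: trace length {r.ca_trace.shape[0]} != reference length {m}"
                )

    def subset(self, ids: Sequence[str]) -> list[StructureRecord]:
        by_id = {r.id: r for r in self.records}
        return [by_id[i] for i in ids]

    @property
    def training_records(self) -> list[StructureRecord]:
        return self.subset(self.training_ids)

    @property
    def validation_records(self) -> list[StructureRecord]:
        return self.subset(self.validation_ids)


def _one_letter(residue_name: str) -> str:
    info = gemmi.find_tabulated_residue(residue_name)
    if info is None or not info.is_amino_acid():
        return "X"
    code = info.one_letter_code.upper()
    return code if code in _STANDARD_AA else "X"


def _pick_ca(residue: gemmi.Residue) -> gemmi.Atom | None:
    """First CA by occupancy, then altloc label (deterministic altloc policy)."""
    cas = [a for a in residue if a.name == "CA" and a.element.name == "C"]
    if not cas:
        return None
    return sorted(cas, key=lambda a: (-a.occ, a.altloc))[0]


def read_structure(path, chain: str | None = None) -> StructureRecord:
    """Read one PDB-format file and extract the CA trace of one chain.

    Water and other non-polymer (hetero) residues are skipped. A record is
    flagged ``has_internal_gap`` when an internal polymer residue lacks a CA
    atom or when author residue numbering jumps between consecutive extracted
    residues (the signature of an unresolved internal fragment).
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse coordinate file {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    names = [ch.name for ch in model]
    if chain is None:
        if not names:
            raise ValueError(f"{path}: no chains")
        sel = model[0]
    else:
        if chain not in names:
            raise KeyError(f"{path}: chain {chain!r} not found (have {names})")
        sel = model[chain]

    coords, seq, resnums = [], [], []
    n_missing_ca = 0
    residues = [
        r
        for r in sel
        if r.name != "HOH" and gemmi.find_tabulated_residue(r.name) is not None
        and gemmi.find_tabulated_residue(r.name).is_amino_acid()
    ]
    for idx, res in enumerate(residues):
        ca = _pick_ca(res)
        if ca is None:
            if 0 < idx < len(residues) - 1:
                n_missing_ca += 1
            continue
        coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
        seq.append(_one_letter(res.name))
        resnums.append(res.seqid.num)
    if len(coords) < 3:
        raise ValueError(f"{path}: fewer than 3 CA atoms in chain {sel.name!r}")

    numbering_gap = bool(np.any(np.diff(resnums) > 1))
    has_gap = n_missing_ca > 0 or numbering_gap

    method = "other"
    em = dict(st.info).get("_exptl.method", "").upper()
    if "X-RAY" in em or "DIFFRACTION" in em:
        method = "crystallographic"
    elif "NMR" in em:
        method = "nmr"

    trace = validate_trace(np.asarray(coords))
    return StructureRecord(
        id=f"{path.stem}_{sel.name}",
        sequence="".join(seq),
        ca_trace=trace,
        experimental_method=method,
        metadata={
            "source_path": str(path),
            "chain": sel.name,
            "has_internal_gap": has_gap,
            "author_resnums": resnums,
        },
    )


def read_fasta_sequence(path) -> str:
    """Read the first sequence from a FASTA file, uppercased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return str(records[0].seq).upper()


def count_mutations(seq: str, reference: str) -> int:
    """Number of differing positions; 'X' counts as a mismatch (conservative)."""
    if len(seq) != len(reference):
        raise ValueError("sequences must have equal length")
    return sum(1 for a, b in zip(seq, reference) if a != b or a == "X")


def filter_structures(
    records: Sequence[StructureRecord],
    reference_sequence: str,
    max_mutations: int = 3,
) -> list[StructureRecord]:
    """Apply the ensemble inclusion criteria.

    Retains records that are crystallographic, have no internal gaps, match
    the reference sequence length, and carry at most ``max_mutations``
    substitutions relative to the reference. Rejection reasons are logged.
    Idempotent by construction: a filtered set passes unchanged.
    """
    if not reference_sequence:
        raise ValueError("reference_sequence must be non-empty")
    kept = []
    for r in records:
        if r.experimental_method != "crystallographic":
            logger.info("reject %s: method=%s (not crystallographic)", r.id, r.experimental_method)
            continue
        if r.has_internal_gap:
            logger.info("reject %s: missing internal fragment", r.id)
            continue
        if len(r.sequence) != len(reference_sequence):
            logger.info(
                "reject %s: length %d != reference %d",
                r.id, len(r.sequence), len(reference_sequence),
            )
            continue
        n_mut = count_mutations(r.sequence, reference_sequence)
        if n_mut > max_mutations:
            logger.info("reject %s: %d mutations > %d", r.id, n_mut, max_mutations)
            continue
        kept.append(r)
    return kept


def thread_trace(record: StructureRecord, target_sequence: str) -> StructureRecord:
    """Thread a CA trace onto a target sequence.

    Coordinates are untouched; only the sequence label changes. The original
    sequence is preserved in ``metadata['threaded_from']``.
    """
    if len(target_sequence) != record.ca_trace.shape[0]:
        raise ValueError(
            f"{record.id}: target sequence length {len(target_sequence)} != "
            f"trace length {record.ca_trace.shape[0]}"
        )
    meta = dict(record.metadata)
    meta["threaded_from"] = record.sequence
    return StructureRecord(
        id=record.id,
        sequence=target_sequence,
        ca_trace=record.ca_trace.copy(),
        experimental_method=record.experimental_method,
        metadata=meta,
    )


def flag_outliers(traces: Sequence[np.ndarray], k: float = 3.0) -> list[bool]:
    """Advisory structural-outlier flags.

    Traces are aligned to their ensemble mean (two alignment passes) and each
    trace's superposed RMSD to the mean is computed. Trace i is flagged when

        rmsd_i > median(rmsd) + k * scale,
        scale = max(1.4826 * MAD(rmsd), 0.1 * median(rmsd), 1e-9)

    The 1.4826 factor makes the MAD a consistent sigma estimate; the relative
    floor stops deviations smaller than 10% of the typical spread from being
    called outliers when the ensemble is very tight, and the absolute floor
    keeps numerically identical ensembles flag-free. The caller decides
    whether to exclude flagged traces.
    """
    if len(traces) < 3:
        raise ValueError("need at least 3 traces for outlier flagging")
    shapes = {np.asarray(t).shape for t in traces}
    if len(shapes) != 1:
        raise ValueError("traces must have equal length")
    aligned = align_ensemble(list(traces), reference_index=0)
    for _ in range(2):
        mean = np.mean(np.stack(aligned), axis=0)
        aligned = [a for a in align_ensemble([mean, *aligned], reference_index=0)[1:]]
    mean = np.mean(np.stack(aligned), axis=0)
    rmsds = np.array([ca_rmsd(a, mean, superpose=True) for a in aligned])
    med = float(np.median(rmsds))
    mad = float(np.median(np.abs(rmsds - med)))
    scale = max(1.4826 * mad, 0.1 * med, 1e-9)
    cutoff = med + k * scale
    return [bool(r > cutoff) for r in rmsds]


def write_trace(trace: np.ndarray, path) -> None:
    """Write a trace as flat text: one line per residue, `index x y z` to 3 dp."""
    a = validate_trace(trace, warn_geometry=False)
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(a):
            fh.write(f"{i}\t{x:.3f}\t{y:.3f}\t{z:.3f}\n")


def read_trace(path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}: malformed trace line {line!r}")
            rows.append([float(parts[1]), float(parts[2]), float(parts[3])])
    return validate_trace(np.asarray(rows), warn_geometry=False)
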