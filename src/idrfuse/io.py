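"""File formats, dataset curation and partitioning.

Everything the tool reads or writes lives here: FASTA sequences, per-residue
disorder labels (two dialects), CAID-style prediction tables, PDB-derived
structure metadata used by the ordered-protein curation filter, cross-
validation fold assignment and the fixed-length truncate/pad transform.

Conventions
-----------
* Residue indices are 1-based in every file and 0-based in memory.
* Label symbols: ``1`` = disordered, ``0`` = ordered, ``-`` = unlabeled
  (a residue with no experimental annotation, as in CAID Disorder-PDB).
* Sequences use the 20 canonical amino-acid letters plus ``X`` for anything
  nonstandard; unknown letters are mapped to ``X`` at read time with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"

# per-residue label states
ORDERED = 0
DISORDERED = 1
UNLABELED = -1

_SYMBOL_TO_STATE = {"0": ORDERED, "1": DISORDERED, "-": UNLABELED}
_STATE_TO_SYMBOL = {v: k for k, v in _SYMBOL_TO_STATE.items()}


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier and its amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise DataError(f"invalid protein id: {self.id!r}")
        if len(self.sequence) < 1:
            raise DataError(f"empty sequence for {self.id!r}")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise DataError(f"{self.id}: characters outside alphabet: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class StructureMetadata:
    """Per-entry structure facts consumed by the ordered-protein filter."""

    id: str
    resolution: float | None
    n_chains: int
    all_residues_resolved: bool
    has_nonstandard: bool

    def __post_init__(self):
        if self.resolution is not None and not self.resolution > 0:
            raise DataError(f"{self.id}: resolution must be > 0")
        if self.n_chains < 1:
            raise DataError(f"{self.id}: n_chains must be >= 1")


@dataclass(frozen=True)
class FoldAssignment:
    """Protein-level k-fold partition."""

    fold_of: Mapping[str, int]
    k: int
    seed: int


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Multi-line sequences are concatenated, letters uppercased, and any letter
    outside the 21-letter alphabet is mapped to ``X`` with a logged warning.
    """
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise DataError(f"header {rec.id!r} has an empty sequence")
        cleaned = []
        mapped = set()
        for c in seq:
            if c in ALPHABET:
                cleaned.append(c)
            else:
                cleaned.append("X")
                mapped.add(c)
        if mapped:
            logger.warning(
                "%s: mapped nonstandard letters %s to 'X'", rec.id, sorted(mapped)
            )
        records.append(ProteinRecord(id=rec.id, sequence="".join(cleaned)))
    if not records:
        logger.warning("%s: no FASTA records found", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def labels_to_string(states: np.ndarray) -> str:
    return "".join(_STATE_TO_SYMBOL[int(s)] for s in states)


def _parse_label_string(s: str, rec_id: str) -> np.ndarray:
    try:
        return np.array([_SYMBOL_TO_STATE[c] for c in s], dtype=np.int8)
    except KeyError as e:
        raise DataError(f"{rec_id}: unknown label symbol {e.args[0]!r}") from None


def read_labels(
    path: str | Path,
    dialect: str,
    sequences: Mapping[str, str] | None = None,
) -> dict[str, np.ndarray]:
    """Read per-residue labels; returns id -> int8 vector over {0, 1, -1}.

    ``fasta_aligned``: FASTA-shaped file whose "sequences" are label strings
    over ``{0, 1, -}``. ``caid_table``: a single-protein whitespace table of
    (1-based index, residue, [score,] label) rows; the id is the file stem
    unless a ``# id`` comment line is present.

    If ``sequences`` is given, label lengths are checked against it.
    """
    if dialect == "fasta_aligned":
        out: dict[str, np.ndarray] = {}
        with open(path) as fh:
            rec_id, chunks = None, []
            for line in list(fh) + [">"]:
                line = line.strip()
                if line.startswith(">"):
                    if rec_id is not None:
                        out[rec_id] = _parse_label_string("".join(chunks), rec_id)
                    rec_id, chunks = line[1:].split()[0] if len(line) > 1 else None, []
                elif line:
                    chunks.append(line)
    elif dialect == "caid_table":
        out = {Path(path).stem: _read_caid_table(path)}
    else:
        raise ValueError(f"unknown label dialect {dialect!r}")

    if sequences is not None:
        for rec_id, states in out.items():
            if rec_id in sequences and len(states) != len(sequences[rec_id]):
                raise DataError(
                    f"{rec_id}: label length {len(states)} != sequence length "
                    f"{len(sequences[rec_id])}"
                )
    return out


def _read_caid_table(path: str | Path) -> np.ndarray:
    states: list[int] = []
    with open(path) as fh:
        expected = 1
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise DataError(f"{path}:{lineno}: expected 3 or 4 columns")
            idx = int(parts[0])
            if idx != expected:
                raise DataError(
                    f"{path}:{lineno}: indices must be contiguous 1-based "
                    f"(expected {expected}, got {idx})"
                )
            expected += 1
            sym = parts[-1]
            if sym not in _SYMBOL_TO_STATE:
                raise DataError(f"{path}:{lineno}: unknown label symbol {sym!r}")
            states.append(_SYMBOL_TO_STATE[sym])
    return np.array(states, dtype=np.int8)


def write_labels_fasta(labels: Mapping[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec_id, states in labels.items():
            fh.write(f">{rec_id}\n{labels_to_string(states)}\n")


def write_predictions(
    record: ProteinRecord,
    scores: np.ndarray,
    path: str | Path,
    threshold: float = 0.5,
) -> None:
    """Write one protein's CAID-style prediction table.

    One row per residue: 1-based index, amino acid, score to 4 decimals and
    the binary call at ``threshold`` (score >= threshold -> disordered).
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(record):
        raise DataError(f"{record.id}: {len(scores)} scores for {len(record)} residues")
    if np.any((scores < 0) | (scores > 1)):
        raise DataError(f"{record.id}: scores must lie in [0, 1]")
    with open(path, "w") as fh:
        for i, (aa, s) in enumerate(zip(record.sequence, scores), start=1):
            call = 1 if s >= threshold else 0
            fh.write(f"{i} {aa} {s:.4f} {call}\n")


def read_metadata_table(path: str | Path) -> dict[str, StructureMetadata]:
    """Read the tab-separated structure-metadata table.

    Columns: id, resolution (empty/NA allowed), n_chains, all_resolved,
    has_nonstandard (booleans as 0/1 or true/false).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"id", "resolution", "n_chains", "all_resolved", "has_nonstandard"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"metadata table missing columns: {sorted(missing)}")

    def as_bool(v) -> bool:
        return str(v).strip().lower() in {"1", "true", "yes"}

    out = {}
    for row in df.itertuples(index=False):
        res = None if pd.isna(row.resolution) else float(row.resolution)
        out[str(row.id)] = StructureMetadata(
            id=str(row.id),
            resolution=res,
            n_chains=int(row.n_chains),
            all_residues_resolved=as_bool(row.all_resolved),
            has_nonstandard=as_bool(row.has_nonstandard),
        )
    return out


def filter_ordered_proteins(
    records: Sequence[ProteinRecord],
    metadata: Mapping[str, StructureMetadata],
    max_resolution: float = 2.0,
    min_length: int = 30,
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Apply the ordered-protein curation criteria.

    A record is kept only if its structure has a single chain, resolution
    <= 2.0 A, length >= 30 residues, every residue's coordinates resolved and
    no nonstandard amino acids. Returns surviving records plus a mapping of
    rejected id -> first failed criterion.
    """
    missing = [r.id for r in records if r.id not in metadata]
    if missing:
        raise DataError(f"missing metadata for ids: {missing}")
    kept: list[ProteinRecord] = []
    rejected: dict[str, str] = {}
    for rec in records:
        md = metadata[rec.id]
        if md.n_chains != 1:
            rejected[rec.id] = "multiple_chains"
        elif md.resolution is None or md.resolution > max_resolution:
            rejected[rec.id] = "resolution"
        elif len(rec) < min_length:
            rejected[rec.id] = "min_length"
        elif not md.all_residues_resolved:
            rejected[rec.id] = "unresolved_residues"
        elif md.has_nonstandard or "X" in rec.sequence:
            rejected[rec.id] = "nonstandard_residues"
        else:
            kept.append(rec)
    return kept, rejected


def make_cv_folds(ids: Sequence[str], k: int, seed: int) -> FoldAssignment:
    """Protein-level k-fold partition: shuffle with ``seed``, deal round-robin.

    Folds are disjoint, cover every id, and differ in size by at most one.
    """
    ids = list(ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds number of proteins ({len(ids)})")
    if len(set(ids)) != len(ids):
        raise DataError("duplicate protein ids")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    fold_of = {ids[j]: i % k for i, j in enumerate(order)}
    return FoldAssignment(fold_of=fold_of, k=k, seed=seed)


def pad_or_truncate(
    matrix: np.ndarray, max_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Force a feature matrix to exactly ``max_len`` rows.

    Longer inputs keep their first ``max_len`` rows (mask all valid); shorter
    inputs are zero-padded with a trailing invalid mask.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    matrix = np.asarray(matrix)
    L = matrix.shape[0]
    mask = np.zeros(max_len, dtype=bool)
    if L >= max_len:
        out = matrix[:max_len].copy()
        mask[:] = True
    else:
        out = np.zeros((max_len,) + matrix.shape[1:], dtype=matrix.dtype)
        out[:L] = matrix
        mask[:L] = True
    return out, mask
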