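"""Per-residue feature streams.

Two streams feed the fusion network:

* the **traditional** block, an L x 80 matrix ``[PSSM | AAindex-PCA | energy]``
  (20 + 20 + 40 columns) built from a PSI-BLAST profile, a PCA reduction of
  the AAindex physicochemical catalogue, and two pairwise contact-potential
  tables;
* the **PLM** block, an L x D_p concatenation of per-residue embeddings from
  an ordered list of protein-language-model backends (by default ProtT5 1024,
  ESM-2 1280, DR-BERT 768, OntoProtein 30, so D_p = 3102).

Real PLM weights are deliberately out of scope: backends implement a small
interface (`name`, `dim`, `embed`) and the package ships deterministic mock
backends at the published widths so the whole pipeline runs offline. The
packaged AAindex profiles and contact-potential matrices are synthetic
stand-ins (clearly labelled); loaders accept user-supplied real tables in the
same text formats.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .io import AMINO_ACIDS, DataError

__all__ = [
    "parse_psiblast_pssm",
    "read_pssm",
    "synthetic_aaindex_profiles",
    "AAIndexReducer",
    "fit_aaindex_reducer",
    "encode_aaindex",
    "EnergyTables",
    "load_energy_tables",
    "encode_energy",
    "TraditionalFeatureMatrix",
    "build_traditional",
    "ColumnStandardizer",
    "PLMFeatureMatrix",
    "MockPLMBackend",
    "DEFAULT_BACKEND_DIMS",
    "default_mock_backends",
    "build_plm",
]

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Published per-residue embedding widths of the four default backends.
DEFAULT_BACKEND_DIMS = {
    "prott5": 1024,
    "esm2": 1280,
    "drbert": 768,
    "ontoprotein": 30,
}


# ---------------------------------------------------------------------------
# PSSM
# ---------------------------------------------------------------------------

def parse_psiblast_pssm(
    text: str,
    sequence: str | None = None,
    scaling: bool = True,
) -> tuple[str, np.ndarray]:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` profile.

    Returns the residue letters and the first (log-odds) 20-column block as a
    float matrix in file row order. With ``scaling`` on (default) each entry x
    is squashed by the logistic 1/(1+e^-x) into (0, 1); with scaling off the
    file's integers are returned exactly.

    A data row must carry the position, the residue letter and 40 numeric
    columns (20 log-odds + 20 percentages); trailing per-row statistics are
    tolerated and ignored.
    """
    letters: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        parts = line.split()
        if len(parts) < 2 or not parts[0].isdigit():
            continue  # header, column-letter line, trailer statistics
        if len(parts[1]) != 1 or not parts[1].isalpha():
            continue
        numeric = parts[2:]
        if len(numeric) < 40:
            raise DataError(
                f"PSSM line {lineno}: expected 40 numeric columns, got {len(numeric)}"
            )
        try:
            values = [float(v) for v in numeric[:40]]
        except ValueError:
            raise DataError(f"PSSM line {lineno}: non-numeric column") from None
        letters.append(parts[1].upper())
        rows.append(values[:20])
    if not rows:
        raise DataError("no PSSM data rows found")
    seq = "".join(letters)
    if sequence is not None and seq != sequence:
        raise DataError(
            f"PSSM residues disagree with provided sequence "
            f"({seq[:10]}... vs {sequence[:10]}...)"
        )
    matrix = np.array(rows, dtype=np.float64)
    if scaling:
        matrix = 1.0 / (1.0 + np.exp(-matrix))
    return seq, matrix


def read_pssm(
    path: str | Path, sequence: str | None = None, scaling: bool = True
) -> tuple[str, np.ndarray]:
    """Read and parse a PSI-BLAST ASCII PSSM file. See :func:`parse_psiblast_pssm`."""
    return parse_psiblast_pssm(Path(path).read_text(), sequence, scaling)


# ---------------------------------------------------------------------------
# AAindex
# ---------------------------------------------------------------------------

def synthetic_aaindex_profiles(
    n_indices: int = 566, seed: int = 20210
) -> np.ndarray:
    """Deterministic synthetic stand-in for the AAindex catalogue.

    Returns a 20 x ``n_indices`` matrix (rows in canonical amino-acid order):
    one simulated physicochemical scale per column with heterogeneous location
    and spread, a sprinkle of missing values, and one constant column — the
    degenerate cases a real AAindex snapshot presents. It is *not* the real
    catalogue; pass your own 20 x 566 table to :func:`fit_aaindex_reducer`
    to use one.
    """
    rng = np.random.default_rng(seed)
    loc = rng.normal(0.0, 5.0, size=n_indices)
    spread = rng.uniform(0.2, 8.0, size=n_indices)
    profiles = loc + spread * rng.normal(size=(20, n_indices))
    # a handful of missing entries, as the real catalogue has
    nan_idx = rng.choice(20 * n_indices, size=max(1, n_indices // 40), replace=False)
    profiles.flat[nan_idx] = np.nan
    if n_indices >= 10:
        profiles[:, 7] = 3.14  # constant scale: exercises the variance floor
    return profiles


@dataclass(frozen=True)
class AAIndexReducer:
    """Fitted PCA reduction of per-amino-acid AAindex profiles.

    ``mean``/``scale`` are the per-index imputation/z-scoring statistics,
    ``components`` the orthonormal principal directions (rows), and
    ``letter_codes`` the precomputed 20 x n_components projection of each
    canonical amino acid (the encoding is a pure lookup).
    """

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray
    letter_codes: np.ndarray
    n_components: int


def fit_aaindex_reducer(
    profiles: np.ndarray,
    n_components: int = 20,
    scale_floor: float = 1e-12,
    weights: np.ndarray | None = None,
) -> AAIndexReducer:
    """Fit the AAindex PCA reducer on a 20 x n_indices profile matrix.

    Missing entries are imputed with the per-index mean over the 20 amino
    acids, each index is z-scored (scale floored at ``scale_floor`` so
    constant indices contribute ~0), and the top ``n_components`` principal
    directions of the 20 row-profiles are extracted by SVD. Component signs
    are fixed by forcing each component's largest-magnitude loading positive.

    By default every amino acid counts equally, making the encoding a
    dataset-independent lookup. Pass ``weights`` (length 20, e.g. amino-acid
    frequencies observed in a training set) to fit the PCA on the
    frequency-weighted population instead.
    """
    profiles = np.asarray(profiles, dtype=np.float64)
    if profiles.ndim != 2 or profiles.shape[0] != 20:
        raise ValueError("profiles must be a 20 x n_indices matrix")
    if n_components > min(profiles.shape):
        raise ValueError(
            f"n_components={n_components} exceeds matrix rank bound "
            f"{min(profiles.shape)}"
        )
    if weights is None:
        w = np.full(20, 1.0 / 20)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (20,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be 20 nonnegative values")
        w = w / w.sum()
    col_mean = np.nanmean(profiles, axis=0)
    imputed = np.where(np.isnan(profiles), col_mean, profiles)
    mean = w @ imputed
    var = w @ (imputed - mean) ** 2
    scale = np.maximum(np.sqrt(var), scale_floor)
    z = (imputed - mean) / scale
    _, s, vt = np.linalg.svd(np.sqrt(w)[:, None] * z * np.sqrt(20),
                             full_matrices=False)
    components = vt[:n_components]
    # deterministic sign: largest-magnitude loading of each component positive
    flip = np.sign(components[np.arange(n_components),
                              np.abs(components).argmax(axis=1)])
    flip[flip == 0] = 1.0
    components = components * flip[:, None]
    explained = (s[:n_components] ** 2) / (profiles.shape[0] - 1)
    letter_codes = z @ components.T
    return AAIndexReducer(
        mean=mean,
        scale=scale,
        components=components,
        explained_variance=explained,
        letter_codes=letter_codes,
        n_components=n_components,
    )


def encode_aaindex(sequence: str, reducer: AAIndexReducer) -> np.ndarray:
    """Encode a sequence as L x n_components AAindex-PCA rows.

    Identical letters give identical rows; ``X`` takes the mean profile,
    which projects to the zero vector after centering.
    """
    if not isinstance(reducer, AAIndexReducer):
        raise TypeError("reducer must be a fitted AAIndexReducer")
    out = np.zeros((len(sequence), reducer.n_components), dtype=np.float64)
    for i, aa in enumerate(sequence):
        if aa in _AA_INDEX:
            out[i] = reducer.letter_codes[_AA_INDEX[aa]]
        # 'X' stays the zero row (centered mean profile)
    return out


# ---------------------------------------------------------------------------
# Contact-potential energies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnergyTables:
    """Two symmetric 20 x 20 pairwise contact-potential matrices.

    Rows/columns follow the canonical amino-acid order ``ACDEFGHIKLMNPQRSTVWY``.
    """

    table_a: np.ndarray
    table_b: np.ndarray

    def __post_init__(self):
        for name, t in (("table_a", self.table_a), ("table_b", self.table_b)):
            if t.shape != (20, 20):
                raise DataError(f"{name} must be 20x20")
            if not np.allclose(t, t.T, atol=1e-9):
                raise DataError(f"{name} must be symmetric")


def _read_energy_matrix(path) -> np.ndarray:
    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    header = lines[0].split()
    if "".join(header) != AMINO_ACIDS:
        raise DataError(f"{path}: header must list amino acids {AMINO_ACIDS}")
    rows = []
    for ln in lines[1:]:
        parts = ln.split()
        rows.append([float(v) for v in parts[1:]])
    m = np.array(rows, dtype=np.float64)
    if m.shape != (20, 20):
        raise DataError(f"{path}: expected 20x20 matrix, got {m.shape}")
    return m


def load_energy_tables(
    path_a: str | Path | None = None, path_b: str | Path | None = None
) -> EnergyTables:
    """Load the two contact-potential matrices.

    With no arguments, loads the packaged synthetic stand-in tables
    (``contact_potential_synthetic_{a,b}.tsv``); pass paths to use real
    published potentials in the same whitespace-separated format (header row
    of amino-acid letters, one labelled row per residue type).
    """
    if path_a is None or path_b is None:
        pkg = resources.files("idrfuse") / "data"
        path_a = path_a or pkg / "contact_potential_synthetic_a.tsv"
        path_b = path_b or pkg / "contact_potential_synthetic_b.tsv"
    return EnergyTables(_read_energy_matrix(path_a), _read_energy_matrix(path_b))


def encode_energy(sequence: str, tables: EnergyTables) -> np.ndarray:
    """Encode a sequence as L x 40 contact-potential rows.

    Each residue contributes its 20-value row from table A followed by its
    row from table B; ``X`` takes each table's column-wise mean row.
    """
    mean_a = tables.table_a.mean(axis=0)
    mean_b = tables.table_b.mean(axis=0)
    out = np.empty((len(sequence), 40), dtype=np.float64)
    for i, aa in enumerate(sequence):
        if aa in _AA_INDEX:
            j = _AA_INDEX[aa]
            out[i, :20] = tables.table_a[j]
            out[i, 20:] = tables.table_b[j]
        else:
            out[i, :20] = mean_a
            out[i, 20:] = mean_b
    return out


# ---------------------------------------------------------------------------
# Traditional block
# ---------------------------------------------------------------------------

@dataclass
class ColumnStandardizer:
    """Per-column standardization with persisted training statistics."""

    mean: np.ndarray | None = None
    std: np.ndarray | None = None

    def fit(self, matrices: Sequence[np.ndarray]) -> "ColumnStandardizer":
        stacked = np.vstack(matrices)
        self.mean = stacked.mean(axis=0)
        self.std = np.maximum(stacked.std(axis=0), 1e-12)
        return self

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise ValueError("standardizer is not fitted")
        return (matrix - self.mean) / self.std


@dataclass(frozen=True)
class TraditionalFeatureMatrix:
    """L x 80 traditional block with named column spans."""

    values: np.ndarray
    block_spans: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"pssm": (0, 20), "aaindex": (20, 40),
                                 "energy": (40, 80)}
    )

    def block(self, name: str) -> np.ndarray:
        a, b = self.block_spans[name]
        return self.values[:, a:b]


def build_traditional(
    sequence: str,
    pssm: np.ndarray,
    reducer: AAIndexReducer,
    tables: EnergyTables,
    standardizer: ColumnStandardizer | None = None,
) -> TraditionalFeatureMatrix:
    """Concatenate [PSSM | AAindex | energy] into the L x 80 traditional block."""
    pssm = np.asarray(pssm, dtype=np.float64)
    if pssm.shape[0] != len(sequence):
        raise DataError(
            f"PSSM has {pssm.shape[0]} rows for a length-{len(sequence)} sequence"
        )
    values = np.hstack([
        pssm,
        encode_aaindex(sequence, reducer),
        encode_energy(sequence, tables),
    ])
    if standardizer is not None:
        values = standardizer.transform(values)
    return TraditionalFeatureMatrix(values=values)


# ---------------------------------------------------------------------------
# PLM backends
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PLMFeatureMatrix:
    """L x D_p concatenated PLM embeddings with per-backend column spans."""

    values: np.ndarray
    backend_spans: tuple[tuple[str, int], ...]

    @property
    def d_p(self) -> int:
        return self.values.shape[1]


class MockPLMBackend:
    """Deterministic stand-in for a protein-language-model backend.

    ``embed`` draws each residue's vector from a generator seeded by a stable
    hash of (seed, backend name, residue letter, position), so the output is
    reproducible, position- and letter-sensitive, and needs no model weights.
    """

    def __init__(self, name: str, dim: int, seed: int = 0):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.name = name
        self.dim = dim
        self.seed = seed

    def embed(self, sequence: str) -> np.ndarray:
        out = np.empty((len(sequence), self.dim), dtype=np.float64)
        for pos, aa in enumerate(sequence):
            key = f"{self.seed}|{self.name}|{aa}|{pos}".encode()
            rng = np.random.default_rng(zlib.crc32(key))
            out[pos] = rng.standard_normal(self.dim)
        return out


def mock_plm_backend(name: str, dim: int, seed: int = 0) -> MockPLMBackend:
    return MockPLMBackend(name, dim, seed)


def default_mock_backends(seed: int = 0) -> list[MockPLMBackend]:
    """The four mock backends at the published widths, in the canonical
    concatenation order ProtT5, ESM-2, DR-BERT, OntoProtein (D_p = 3102)."""
    return [
        MockPLMBackend(name, dim, seed)
        for name, dim in DEFAULT_BACKEND_DIMS.items()
    ]


def build_plm(sequence: str, backends: Sequence) -> PLMFeatureMatrix:
    """Concatenate backend embeddings (in the given order) into L x D_p."""
    blocks = []
    spans = []
    for backend in backends:
        m = np.asarray(backend.embed(sequence), dtype=np.float64)
        if m.shape[0] != len(sequence):
            raise DataError(
                f"backend {backend.name!r} returned {m.shape[0]} rows for a "
                f"length-{len(sequence)} sequence"
            )
        if m.shape[1] != backend.dim:
            raise DataError(
                f"backend {backend.name!r} returned width {m.shape[1]}, "
                f"declared {backend.dim}"
            )
        blocks.append(m)
        spans.append((backend.name, backend.dim))
    if not blocks:
        raise ValueError("at least one backend required")
    return PLMFeatureMatrix(values=np.hstack(blocks), backend_spans=tuple(spans))
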