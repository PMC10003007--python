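"""Readers, writers and encodings for the formats the framework touches.

Genomic input is a FASTA genome plus BED peaks (0-based half-open); the
single-cell side is a peak-by-cell matrix from an ``.h5ad`` file or a
MatrixMarket ``.mtx`` with ``barcodes.tsv`` / ``peaks.tsv`` sidecars.
Sequences are one-hot encoded (A, C, G, T channels; N as uniform 0.25 so
every position carries unit mass).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from Bio import SeqIO

__all__ = [
    "GenomeIndex",
    "Peak",
    "PeakSet",
    "PeakCellMatrix",
    "OneHotBatch",
    "read_fasta",
    "write_fasta",
    "read_bed_peaks",
    "write_bed_peaks",
    "extract_sequences",
    "one_hot_encode",
    "one_hot_decode",
    "load_peak_cell_matrix",
    "save_peak_cell_matrix",
    "binarize",
    "split_peaks",
]

_ALPHABET = "ACGT"
_IUPAC_TO_N = str.maketrans("RYSWKMBDHVU", "N" * 11)
_ONE_HOT = {
    "A": (1.0, 0.0, 0.0, 0.0),
    "C": (0.0, 1.0, 0.0, 0.0),
    "G": (0.0, 0.0, 1.0, 0.0),
    "T": (0.0, 0.0, 0.0, 1.0),
    "N": (0.25, 0.25, 0.25, 0.25),
}


@dataclass
class GenomeIndex:
    """Contig name -> uppercased A/C/G/T/N sequence."""

    contigs: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.contigs


@dataclass(frozen=True)
class Peak:
    contig: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.contig}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class PeakSet:
    peaks: list[Peak]

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i):
        if isinstance(i, (list, np.ndarray)):
            return PeakSet([self.peaks[j] for j in i])
        return self.peaks[i]


@dataclass
class PeakCellMatrix:
    """Cells x peaks matrix of non-negative counts (or binary indicators)."""

    matrix: np.ndarray | sp.spmatrix
    cell_ids: list[str]
    peak_ids: list[str]
    cell_labels: list[str] | None = None

    def __post_init__(self):
        n, p = self.matrix.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.peak_ids) != p:
            raise ValueError(f"{len(self.peak_ids)} peak ids for {p} columns")
        if self.cell_labels is not None and len(self.cell_labels) != n:
            raise ValueError("cell_labels length does not match cell count")
        if self.min() < 0:
            raise ValueError("peak-by-cell matrix must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.matrix.shape[1]

    def min(self) -> float:
        return float(self.matrix.min())

    def dense(self) -> np.ndarray:
        if sp.issparse(self.matrix):
            return np.asarray(self.matrix.todense(), dtype=float)
        return np.asarray(self.matrix, dtype=float)


@dataclass
class OneHotBatch:
    """(n sequences, L, 4) one-hot tensor over channel order A, C, G, T."""

    tensor: np.ndarray
    peak_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.tensor.ndim != 3 or self.tensor.shape[2] != 4:
            raise ValueError("one-hot tensor must have shape (n, L, 4)")

    @property
    def n(self) -> int:
        return self.tensor.shape[0]

    @property
    def length(self) -> int:
        return self.tensor.shape[1]

    def __getitem__(self, idx) -> "OneHotBatch":
        idx = np.atleast_1d(np.asarray(idx))
        ids = [self.peak_ids[i] for i in idx] if self.peak_ids else []
        return OneHotBatch(self.tensor[idx], ids)


# ---------------------------------------------------------------------------


def _clean_sequence(seq: str, origin: str) -> str:
    seq = seq.upper().translate(_IUPAC_TO_N)
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-IUPAC characters {sorted(bad)} in {origin}")
    return seq


def read_fasta(path: str | os.PathLike) -> GenomeIndex:
    """Read a FASTA file into a :class:`GenomeIndex` (uppercased, IUPAC->N)."""
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise ValueError(f"duplicate contig name {record.id!r}")
        seq = _clean_sequence(str(record.seq), record.id)
        if not seq:
            raise ValueError(f"empty sequence for contig {record.id!r}")
        contigs[record.id] = seq
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeIndex(contigs)


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def read_bed_peaks(path: str | os.PathLike) -> PeakSet:
    """Read BED3+ records (0-based half-open); track/comment lines are skipped."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if (not line or line.startswith(("#", "track", "browser"))):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected >=3 tab-separated columns")
            contig, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as err:
                raise ValueError(f"line {lineno}: non-integer coordinates") from err
            if start >= end:
                raise ValueError(f"line {lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
            peaks.append(Peak(contig, start, end, name, strand))
    return PeakSet(peaks)


def write_bed_peaks(peaks: PeakSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            name = p.name if p.name is not None else "."
            fh.write(f"{p.contig}\t{p.start}\t{p.end}\t{name}\n")


def extract_sequences(genome: GenomeIndex, peaks: PeakSet, target_length: int
                      ) -> list[str]:
    """Resize each peak symmetrically about its midpoint to ``target_length``
    and read the + strand sequence, filling out-of-contig overhang with N."""
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    out: list[str] = []
    for peak in peaks:
        if peak.contig not in genome:
            raise KeyError(f"contig {peak.contig!r} not in genome")
        contig_seq = genome.contigs[peak.contig]
        start = peak.midpoint - target_length // 2
        end = start + target_length
        left_pad = max(0, -start)
        right_pad = max(0, end - len(contig_seq))
        core = contig_seq[max(0, start):min(len(contig_seq), end)]
        out.append("N" * left_pad + core + "N" * right_pad)
    return out


def one_hot_encode(sequences: list[str], peak_ids: list[str] | None = None
                   ) -> OneHotBatch:
    if not sequences:
        raise ValueError("no sequences to encode")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("sequences have ragged lengths")
    tensor = np.empty((len(sequences), L, 4), dtype=np.float64)
    for i, seq in enumerate(sequences):
        try:
            tensor[i] = [_ONE_HOT[ch] for ch in seq.upper()]
        except KeyError as err:
            raise ValueError(f"illegal character {err} in sequence {i}") from None
    return OneHotBatch(tensor, list(peak_ids) if peak_ids else [])


def one_hot_decode(batch: OneHotBatch) -> list[str]:
    """Argmax decode; exact inverse of :func:`one_hot_encode` on A/C/G/T."""
    idx = batch.tensor.argmax(axis=2)
    return ["".join(_ALPHABET[j] for j in row) for row in idx]


# ---------------------------------------------------------------------------


def _load_mtx(path: str) -> PeakCellMatrix:
    import scipy.io

    directory = os.path.dirname(os.path.abspath(path))
    mat = scipy.io.mmread(path)  # stored peaks x cells (feature-major)
    if sp.issparse(mat):
        mat = np.asarray(mat.todense())
    mat = np.asarray(mat, dtype=float).T  # -> cells x peaks
    cells = pd.read_csv(os.path.join(directory, "barcodes.tsv"),
                        sep="\t", header=None)[0].astype(str).tolist()
    peaks = pd.read_csv(os.path.join(directory, "peaks.tsv"),
                        sep="\t", header=None)[0].astype(str).tolist()
    labels = None
    label_path = os.path.join(directory, "labels.tsv")
    if os.path.exists(label_path):
        labels = pd.read_csv(label_path, sep="\t", header=None)[0].astype(str).tolist()
    return PeakCellMatrix(mat, cells, peaks, labels)


_LABEL_COLUMNS = ("cell_type", "celltype", "label", "cell_label", "CellType")


def _load_h5ad(path: str) -> PeakCellMatrix:
    import anndata

    adata = anndata.read_h5ad(path)
    labels = None
    for col in _LABEL_COLUMNS:
        if col in adata.obs.columns:
            labels = adata.obs[col].astype(str).tolist()
            break
    return PeakCellMatrix(adata.X, adata.obs_names.astype(str).tolist(),
                          adata.var_names.astype(str).tolist(), labels)


def load_peak_cell_matrix(path: str | os.PathLike, format: str | None = None
                          ) -> PeakCellMatrix:
    """Load a peak-by-cell matrix, oriented cells x peaks.

    ``format`` is ``"h5ad"`` or ``"mtx"``; inferred from the suffix if omitted.
    MTX input is feature-major (peaks x cells) with ``barcodes.tsv`` and
    ``peaks.tsv`` sidecars next to it; a ``labels.tsv`` sidecar, when present,
    supplies cell-type labels.  h5ad observations are cells.
    """
    path = str(path)
    if format is None:
        format = "h5ad" if path.endswith(".h5ad") else "mtx"
    if format == "h5ad":
        return _load_h5ad(path)
    if format == "mtx":
        return _load_mtx(path)
    raise ValueError(f"unknown format {format!r}")


def save_peak_cell_matrix(matrix: PeakCellMatrix, directory: str | os.PathLike,
                          stem: str = "matrix") -> str:
    """Write MTX (peaks x cells) plus sidecars; returns the .mtx path."""
    import scipy.io

    os.makedirs(directory, exist_ok=True)
    mtx_path = os.path.join(str(directory), f"{stem}.mtx")
    dense = matrix.dense().T  # peaks x cells on disk
    scipy.io.mmwrite(mtx_path, sp.coo_matrix(dense), precision=17)
    pd.Series(matrix.cell_ids).to_csv(
        os.path.join(str(directory), "barcodes.tsv"),
        sep="\t", index=False, header=False)
    pd.Series(matrix.peak_ids).to_csv(
        os.path.join(str(directory), "peaks.tsv"),
        sep="\t", index=False, header=False)
    if matrix.cell_labels is not None:
        pd.Series(matrix.cell_labels).to_csv(
            os.path.join(str(directory), "labels.tsv"),
            sep="\t", index=False, header=False)
    return mtx_path


def binarize(matrix: PeakCellMatrix) -> PeakCellMatrix:
    """Return a new matrix with entries mapped to 1 where > 0, else 0 (pure)."""
    if matrix.min() < 0:
        raise ValueError("cannot binarize a matrix with negative entries")
    if sp.issparse(matrix.matrix):
        binary = matrix.matrix.sign().astype(float)
    else:
        binary = (np.asarray(matrix.matrix) > 0).astype(float)
    return replace(matrix, matrix=binary)


def split_peaks(peaks: PeakSet, fractions: tuple[float, float, float],
                seed: int) -> tuple[PeakSet, PeakSet, PeakSet]:
    """Disjoint, exhaustive train/val/test split, reproducible under ``seed``."""
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {sum(fractions)}, expected 1")
    n = len(peaks)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    sizes = [int(np.floor(f * n)) for f in fractions]
    remainders = [f * n - s for f, s in zip(fractions, sizes)]
    for _ in range(n - sum(sizes)):  # largest-remainder apportionment
        i = int(np.argmax(remainders))
        sizes[i] += 1
        remainders[i] = -1.0
    bounds = np.cumsum([0] + sizes)
    groups = [sorted(order[bounds[i]:bounds[i + 1]]) for i in range(3)]
    return tuple(peaks[g] for g in groups)  # type: ignore[return-value]
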