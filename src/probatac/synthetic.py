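"""Desk-scale synthetic scATAC-seq datasets with known regulatory structure.

The generator plants TF motifs (PWM consensus samples) into random
background peaks, assigns each cell type a motif-activity profile, draws a
binary ground-truth accessibility matrix, and corrupts it the way the
downstream mixture model assumes real data are corrupted: bona fide open
entries carry counts near a Normal(mu, sigma); dropout events and spurious
background insertions leave low Gamma(shape, rate) residual counts.  Every
intermediate (clean truth, dropout mask, motif assignment) is retained so
each pipeline stage can be scored against ground truth.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequence_io import (OneHotBatch, Peak, PeakCellMatrix, PeakSet,
                          one_hot_encode, save_peak_cell_matrix, write_bed_peaks,
                          write_fasta)

__all__ = [
    "PWM",
    "SyntheticDesign",
    "SyntheticDataset",
    "make_pwm",
    "generate_background",
    "plant_motif",
    "simulate_dataset",
    "write_fixture",
    "default_design",
    "DEFAULT_MOTIF_CONSENSI",
]

_ALPHABET = "ACGT"
_INDEX = {b: i for i, b in enumerate(_ALPHABET)}

#: Consensus strings of the default planted motifs (one per cell type).
DEFAULT_MOTIF_CONSENSI = ("TGACTCAT", "CACGTGAC", "TTGATAAG")


@dataclass
class PWM:
    """Position probability matrix of shape (width, 4) over A, C, G, T."""

    name: str
    matrix: np.ndarray
    consensus: str | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (width, 4)")
        if self.width < 4:
            raise ValueError("PWM width must be >= 4")
        if np.any(self.matrix < 0):
            raise ValueError("PWM probabilities must be non-negative")
        rowsum = self.matrix.sum(axis=1)
        if np.any(np.abs(rowsum - 1.0) > 1e-9):
            raise ValueError("PWM rows must each sum to 1")
        if self.consensus is None:
            self.consensus = "".join(_ALPHABET[i] for i in self.matrix.argmax(axis=1))

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def sample(self, rng: np.random.Generator) -> str:
        draws = [rng.choice(4, p=row) for row in self.matrix]
        return "".join(_ALPHABET[i] for i in draws)


def make_pwm(consensus: str, match_prob: float, name: str | None = None) -> PWM:
    """PWM giving ``match_prob`` to the consensus base, the rest split evenly."""
    if not 0.25 <= match_prob <= 1.0:
        raise ValueError("match_prob must lie in [0.25, 1]")
    consensus = consensus.upper()
    if any(ch not in _INDEX for ch in consensus):
        raise ValueError(f"illegal consensus character in {consensus!r}")
    off = (1.0 - match_prob) / 3.0
    matrix = np.full((len(consensus), 4), off)
    for i, ch in enumerate(consensus):
        matrix[i, _INDEX[ch]] = match_prob
    return PWM(name or consensus, matrix, consensus)


def generate_background(length: int, n: int, seed: int,
                        dinuc_source: str | None = None) -> list[str]:
    """Random background sequences: i.i.d. uniform A/C/G/T, or a first-order
    Markov chain estimated from ``dinuc_source`` when one is given."""
    if length < 2:
        raise ValueError("background length must be >= 2")
    rng = np.random.default_rng(seed)
    if dinuc_source is None:
        draws = rng.integers(0, 4, size=(n, length))
        return ["".join(_ALPHABET[i] for i in row) for row in draws]
    src = dinuc_source.upper()
    if len(src) < 2:
        raise ValueError("dinuc_source must be at least 2 bp")
    trans = np.zeros((4, 4))
    for a, b in zip(src[:-1], src[1:]):
        trans[_INDEX[a], _INDEX[b]] += 1
    marginal = np.bincount([_INDEX[ch] for ch in src], minlength=4).astype(float)
    marginal /= marginal.sum()
    rows = trans.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        trans = np.where(rows > 0, trans / np.where(rows == 0, 1, rows), marginal)
    out = []
    for _ in range(n):
        state = rng.choice(4, p=marginal)
        chars = [state]
        for _ in range(length - 1):
            state = rng.choice(4, p=trans[state])
            chars.append(state)
        out.append("".join(_ALPHABET[i] for i in chars))
    return out


def plant_motif(sequence: str, pwm: PWM, position: int | str = "center",
                seed: int = 0) -> str:
    """Replace a window of ``sequence`` with a PWM sample; length preserved."""
    if pwm.width > len(sequence):
        raise ValueError("PWM wider than the sequence")
    if position == "center":
        pos = (len(sequence) - pwm.width) // 2
    else:
        pos = int(position)
    if not 0 <= pos <= len(sequence) - pwm.width:
        raise IndexError(f"insertion index {pos} out of bounds")
    instance = pwm.sample(np.random.default_rng(seed))
    return sequence[:pos] + instance + sequence[pos + pwm.width:]


# ---------------------------------------------------------------------------


@dataclass
class SyntheticDesign:
    """Study design for the generator.

    ``activity`` has shape (cell types, motifs) with entries in [0, 1]: the
    probability that a peak carrying that motif is truly accessible in a cell
    of that type (before per-cell capture-efficiency scaling).  ``p0`` is the
    base accessibility of motif-free peaks; ``noise_rate`` the chance a truly
    closed entry still records a spurious low count.  ``dropout`` is the
    full-depth dropout rate delta; the realised per-cell rate is
    ``1 - (1 - delta)^(1/e)`` for capture efficiency ``e``, so shallow cells
    lose most of their open entries — the depth gradient that dominates raw
    scATAC-seq matrices.
    """

    n_cell_types: int = 3
    cells_per_type: int = 200
    n_peaks: int = 1000
    peak_length: int = 300
    motifs: list[PWM] = field(default_factory=lambda: [
        make_pwm(c, 0.9) for c in DEFAULT_MOTIF_CONSENSI])
    activity: np.ndarray | None = None
    motif_prob: float = 0.5
    p0: float = 0.05
    capture_range: tuple[float, float] = (0.2, 1.0)
    dropout: float = 0.3
    noise_rate: float = 0.1
    gamma_shape: float = 2.0
    gamma_rate: float = 2.0
    normal_mean: float = 8.0
    normal_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.activity is None:
            # one motif strongly active per type, round-robin
            act = np.full((self.n_cell_types, len(self.motifs)), 0.02)
            for m in range(len(self.motifs)):
                act[m % self.n_cell_types, m] = 0.95
            self.activity = act
        self.activity = np.asarray(self.activity, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_cell_types < 2:
            raise ValueError("need at least 2 cell types")
        if self.n_peaks < 1 or self.cells_per_type < 1:
            raise ValueError("infeasible design: zero peaks or cells")
        if self.activity.shape != (self.n_cell_types, len(self.motifs)):
            raise ValueError("activity matrix shape must be (types, motifs)")
        probs = [self.motif_prob, self.p0, self.dropout, self.noise_rate,
                 *np.ravel(self.activity)]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if not np.all((self.activity > 0.5).any(axis=0)):
            raise ValueError("every motif must be active (> 0.5) in some cell type")
        lo, hi = self.capture_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("capture_range must satisfy 0 < lo <= hi <= 1")

    @property
    def n_cells(self) -> int:
        return self.n_cell_types * self.cells_per_type


@dataclass
class SyntheticDataset:
    sequences: list[str]
    observed: PeakCellMatrix
    truth: np.ndarray            # cells x peaks, binary
    dropout_mask: np.ndarray     # cells x peaks, 1 where a true-open entry dropped
    cell_labels: list[str]
    motif_assignment: list[str | None]  # per peak, motif name or None
    capture_efficiency: np.ndarray
    design: SyntheticDesign

    def one_hot(self) -> OneHotBatch:
        return one_hot_encode(self.sequences, self.observed.peak_ids)

    def pseudo_peaks(self, gap: int = 20) -> PeakSet:
        L = self.design.peak_length
        return PeakSet([
            Peak("synth", i * (L + gap), i * (L + gap) + L, pid)
            for i, pid in enumerate(self.observed.peak_ids)])


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    """Normal(mean, sd) conditioned on > 0, by rejection."""
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def simulate_dataset(design: SyntheticDesign) -> SyntheticDataset:
    """Draw a full synthetic dataset from ``design`` (deterministic per seed)."""
    design.validate()
    rng = np.random.default_rng(design.seed)
    T, P, L = design.n_cell_types, design.n_peaks, design.peak_length
    N = design.n_cells
    M = len(design.motifs)

    # --- peak sequences with planted motifs --------------------------------
    seq_seed = int(rng.integers(2 ** 31))
    sequences = generate_background(L, P, seq_seed)
    has_motif = rng.random(P) < design.motif_prob
    motif_idx = rng.integers(0, M, size=P)
    assignment: list[str | None] = []
    for i in range(P):
        if has_motif[i]:
            pwm = design.motifs[motif_idx[i]]
            sequences[i] = plant_motif(sequences[i], pwm, "center",
                                       seed=int(rng.integers(2 ** 31)))
            assignment.append(pwm.name)
        else:
            assignment.append(None)

    # --- ground-truth accessibility ----------------------------------------
    types = np.repeat(np.arange(T), design.cells_per_type)
    labels = [f"type{t}" for t in types]
    ceff = rng.uniform(*design.capture_range, size=N)
    # per-cell x per-peak rate: activity[type, motif] for motif peaks, p0 otherwise
    rate = np.empty((N, P))
    motif_cols = design.activity[:, motif_idx]          # (T, P)
    rate[:, :] = np.where(has_motif[None, :], motif_cols[types, :], design.p0)
    rate *= ceff[:, None]
    truth = (rng.random((N, P)) < rate).astype(np.int8)

    # --- corruption ---------------------------------------------------------
    # dropout is depth-dependent: a cell with capture efficiency e drops an
    # open entry with probability 1 - (1 - delta)^(1/e), i.e. the nominal
    # rate delta at full depth, rising sharply for shallow cells
    dropout_rate = 1.0 - (1.0 - design.dropout) ** (1.0 / ceff)
    dropout_mask = ((rng.random((N, P)) < dropout_rate[:, None])
                    & (truth == 1)).astype(np.int8)
    observed = np.zeros((N, P))
    open_clean = (truth == 1) & (dropout_mask == 0)
    observed[open_clean] = _truncated_normal(
        rng, design.normal_mean, design.normal_sd, int(open_clean.sum()))
    dropped = dropout_mask == 1
    observed[dropped] = rng.gamma(design.gamma_shape, 1.0 / design.gamma_rate,
                                  int(dropped.sum()))
    closed = truth == 0
    noisy = closed & (rng.random((N, P)) < design.noise_rate)
    observed[noisy] = rng.gamma(design.gamma_shape, 1.0 / design.gamma_rate,
                                int(noisy.sum()))

    cell_ids = [f"cell{i:04d}" for i in range(N)]
    peak_ids = [f"peak{i:05d}" for i in range(P)]
    matrix = PeakCellMatrix(observed, cell_ids, peak_ids, labels)
    return SyntheticDataset(sequences, matrix, truth, dropout_mask, labels,
                            assignment, ceff, design)


def default_design(seed: int = 0, **overrides) -> SyntheticDesign:
    """The reference study design used throughout the test suite."""
    return SyntheticDesign(seed=seed, **overrides)


# ---------------------------------------------------------------------------


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture(dataset: SyntheticDataset, directory: str | os.PathLike) -> dict:
    """Write the dataset as plain-text files; returns a checksum manifest."""
    if not dataset.sequences or dataset.observed.n_cells == 0:
        raise ValueError("cannot write an empty dataset")
    directory = str(directory)
    os.makedirs(directory, exist_ok=True)
    seq_path = os.path.join(directory, "peaks.fa")
    write_fasta({pid: seq for pid, seq in
                 zip(dataset.observed.peak_ids, dataset.sequences)}, seq_path)
    bed_path = os.path.join(directory, "peaks.bed")
    write_bed_peaks(dataset.pseudo_peaks(), bed_path)
    mtx_path = save_peak_cell_matrix(dataset.observed, directory)
    truth_path = os.path.join(directory, "truth.tsv")
    pd.DataFrame(dataset.truth, index=dataset.observed.cell_ids,
                 columns=dataset.observed.peak_ids).to_csv(truth_path, sep="\t")
    mask_path = os.path.join(directory, "dropout_mask.tsv")
    pd.DataFrame(dataset.dropout_mask, index=dataset.observed.cell_ids,
                 columns=dataset.observed.peak_ids).to_csv(mask_path, sep="\t")
    motif_path = os.path.join(directory, "motif_assignment.tsv")
    pd.DataFrame({"peak": dataset.observed.peak_ids,
                  "motif": [m or "." for m in dataset.motif_assignment]}
                 ).to_csv(motif_path, sep="\t", index=False)
    files = [seq_path, bed_path, mtx_path, truth_path, mask_path, motif_path,
             os.path.join(directory, "barcodes.tsv"),
             os.path.join(directory, "peaks.tsv"),
             os.path.join(directory, "labels.tsv")]
    manifest = {"seed": dataset.design.seed,
                "files": {os.path.basename(p): _sha256(p) for p in files}}
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
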