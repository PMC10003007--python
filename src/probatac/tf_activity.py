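"""TF-activity inference by motif insertion and in-silico mutagenesis.

Per-cell TF activity: dinucleotide-shuffled peak sequences serve as
backgrounds; the TF's motif is inserted at each background's centre and
the change in predicted accessibility, averaged over backgrounds, is the
cell-level activity score.  Dinucleotide shuffling uses the
Altschul-Erickson Eulerian-walk construction, so mono- and dinucleotide
counts are preserved exactly.

Per-nucleotide activity: in-silico saturation mutagenesis (ISM) mutates
every position to its three alternatives, records the per-cell change in
predicted accessibility, and centres the four scores at each position to
sum to zero.  The dot product of a PWM with the ISM scores over a motif
match window gives a per-cell PWM-ISM score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import motifs as bio_motifs

from .model import AccessibilityResults
from .sequence_io import one_hot_encode
from .synthetic import PWM

__all__ = [
    "MotifLibrary",
    "ActivityResult",
    "ISMResult",
    "read_jaspar_pfm",
    "dinucleotide_shuffle",
    "motif_activity",
    "activity_library",
    "ism",
    "pwm_ism_score",
]

_ALPHABET = "ACGT"


@dataclass
class MotifLibrary:
    motifs: list[PWM]

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.motifs]


def read_jaspar_pfm(path: str) -> MotifLibrary:
    """Parse JASPAR-format position frequency matrices into PWMs (counts are
    renormalised column-wise to probabilities)."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
        pwms = []
        for rec in records:
            counts = np.array([rec.counts[b] for b in _ALPHABET], float).T  # (w, 4)
            if np.any(counts < 0):
                raise ValueError(f"negative counts in motif {rec.matrix_id}")
            colsum = counts.sum(axis=1, keepdims=True)
            if np.any(colsum <= 0):
                raise ValueError(f"empty column in motif {rec.matrix_id}")
            name = rec.name or rec.matrix_id
            pwms.append(PWM(str(name), counts / colsum))
    if not pwms:
        raise ValueError(f"no motifs parsed from {path}")
    return MotifLibrary(pwms)


# ---------------------------------------------------------------------------
# dinucleotide shuffling (Altschul-Erickson)
# ---------------------------------------------------------------------------


def dinucleotide_shuffle(sequence: str, seed: int = 0) -> str:
    """Uniform-random Eulerian-walk shuffle preserving the exact dinucleotide
    multiset (hence mononucleotide counts and the terminal residue)."""
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValueError("sequence must be at least 2 bp")
    rng = np.random.default_rng(seed)
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq[:-1], seq[1:]):
        edges.setdefault(a, []).append(b)
    first, last = seq[0], seq[-1]
    vertices = list(edges.keys())

    def _sample_last_edges() -> dict[str, str] | None:
        # pick a candidate final edge for every vertex except the terminal one,
        # then verify each vertex reaches the terminal along final edges
        chosen = {}
        for v in vertices:
            if v == last:
                continue
            chosen[v] = edges[v][rng.integers(len(edges[v]))]
        for v in chosen:
            node, hops = v, 0
            while node != last:
                node = chosen.get(node)
                hops += 1
                if node is None or hops > len(chosen):
                    return None
        return chosen

    while True:
        chosen = _sample_last_edges()
        if chosen is not None:
            break

    walk_lists: dict[str, list[str]] = {}
    for v, targets in edges.items():
        pool = list(targets)
        if v in chosen:
            pool.remove(chosen[v])
        rng.shuffle(pool)
        if v in chosen:
            pool.append(chosen[v])
        walk_lists[v] = pool

    out = [first]
    pos = {v: 0 for v in edges}
    node = first
    for _ in range(len(seq) - 1):
        nxt = walk_lists[node][pos[node]]
        pos[node] += 1
        out.append(nxt)
        node = nxt
    return "".join(out)


# ---------------------------------------------------------------------------
# motif insertion
# ---------------------------------------------------------------------------


@dataclass
class ActivityResult:
    """TF x cell activity scores plus the per-sequence influence tensors."""

    tf_names: list[str]
    activity: np.ndarray                 # (TFs, cells) raw mean influence
    influence: list[np.ndarray]          # per TF: (backgrounds, cells)
    n_background: int
    seed: int

    def __post_init__(self):
        for row, infl in zip(self.activity, self.influence):
            if not np.allclose(row, infl.mean(axis=0), atol=1e-9):
                raise ValueError("activity must equal the mean influence")

    def normalized(self) -> np.ndarray:
        """Z-scored across cells per TF (for display; raw means are kept)."""
        mu = self.activity.mean(axis=1, keepdims=True)
        sd = self.activity.std(axis=1, keepdims=True)
        return (self.activity - mu) / np.where(sd == 0, 1.0, sd)


def _insert_consensus(background: str, pwm: PWM,
                      rng: np.random.Generator | None = None) -> str:
    """Insert the consensus (or, when ``rng`` is given, a PWM sample) at the
    background's centre."""
    pos = (len(background) - pwm.width) // 2
    instance = pwm.sample(rng) if rng is not None else pwm.consensus
    return background[:pos] + instance + background[pos + pwm.width:]


def _logit(p: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    p = np.clip(p, eps, 1 - eps)
    return np.log(p / (1 - p))


def _make_backgrounds(peaks: list[str], n_background: int, seed: int
                      ) -> list[str]:
    if n_background < 1:
        raise ValueError("need at least one background sequence")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(peaks), size=n_background,
                       replace=n_background > len(peaks))
    return [dinucleotide_shuffle(peaks[i], seed=int(rng.integers(2 ** 31)))
            for i in picks]


def motif_activity(results: AccessibilityResults, pwm: PWM, peaks: list[str],
                   n_background: int = 32, seed: int = 0,
                   sample_instances: int = 0,
                   scale: str = "probability") -> ActivityResult:
    """Cell-level activity of one TF: mean over backgrounds of
    y(background with motif) - y(background).

    ``sample_instances > 0`` averages over that many PWM draws per background
    instead of inserting the consensus; ``scale="logit"`` measures the
    difference on the pre-sigmoid scale.
    """
    if pwm.width > results.config.input_length:
        raise ValueError("motif wider than the model input")
    transform = _logit if scale == "logit" else (lambda y: y)
    backgrounds = _make_backgrounds(peaks, n_background, seed)
    y_bg = transform(results.predict(one_hot_encode(backgrounds)))
    if sample_instances > 0:
        rng = np.random.default_rng(seed + 1)
        influence = np.mean(
            [transform(results.predict(one_hot_encode(
                [_insert_consensus(b, pwm, rng) for b in backgrounds]))) - y_bg
             for _ in range(sample_instances)], axis=0)
    else:
        inserted = [_insert_consensus(b, pwm) for b in backgrounds]
        influence = transform(results.predict(one_hot_encode(inserted))) - y_bg
    return ActivityResult([pwm.name], influence.mean(axis=0)[None, :],
                          [influence], n_background, seed)


def activity_library(results: AccessibilityResults, library: MotifLibrary | list[PWM],
                     peaks: list[str], n_background: int = 32, seed: int = 0,
                     scale: str = "probability") -> ActivityResult:
    """Activity of every motif in a library against a shared background set."""
    motifs = list(library)
    transform = _logit if scale == "logit" else (lambda y: y)
    backgrounds = _make_backgrounds(peaks, n_background, seed)
    y_bg = transform(results.predict(one_hot_encode(backgrounds)))
    activity, influences = [], []
    for pwm in motifs:
        inserted = [_insert_consensus(b, pwm) for b in backgrounds]
        infl = transform(results.predict(one_hot_encode(inserted))) - y_bg
        activity.append(infl.mean(axis=0))
        influences.append(infl)
    return ActivityResult([m.name for m in motifs], np.vstack(activity),
                          influences, n_background, seed)


# ---------------------------------------------------------------------------
# in-silico saturation mutagenesis
# ---------------------------------------------------------------------------


@dataclass
class ISMResult:
    """(positions, 4 nucleotides, cells) centred accessibility changes."""

    scores: np.ndarray
    reference: str

    def __post_init__(self):
        sums = self.scores.sum(axis=1)
        if not np.allclose(sums, 0.0, atol=1e-6):
            raise ValueError("ISM scores must sum to zero per position and cell")


def ism(results: AccessibilityResults, sequence: str,
        batch_size: int = 64, scale: str = "probability") -> ISMResult:
    """Mutate every position to its three alternatives, record the per-cell
    change in predicted accessibility (post-sigmoid by default,
    ``scale="logit"`` for pre-sigmoid), and centre the four per-position
    scores to sum to zero."""
    transform = _logit if scale == "logit" else (lambda y: y)
    sequence = sequence.upper()
    L = results.config.input_length
    if len(sequence) != L:
        raise ValueError(f"sequence length {len(sequence)} != model input {L}")
    y_ref = transform(results.predict(one_hot_encode([sequence])))[0]
    n_cells = y_ref.shape[0]
    deltas = np.zeros((L, 4, n_cells))
    mutants, where = [], []
    for p, ref_base in enumerate(sequence):
        for b, base in enumerate(_ALPHABET):
            if base == ref_base:
                continue
            mutants.append(sequence[:p] + base + sequence[p + 1:])
            where.append((p, b))
    y_mut = transform(results.predict(one_hot_encode(mutants),
                                      batch_size=batch_size))
    for (p, b), y in zip(where, y_mut):
        deltas[p, b] = y - y_ref
    deltas -= deltas.mean(axis=1, keepdims=True)
    return ISMResult(deltas, sequence)


def pwm_ism_score(ism_result: ISMResult, pwm: PWM, offset: int) -> np.ndarray:
    """Per-cell dot product of the PWM with the ISM scores over the window
    starting at ``offset``."""
    L = ism_result.scores.shape[0]
    if offset < 0 or offset + pwm.width > L:
        raise ValueError("PWM window out of range")
    window = ism_result.scores[offset:offset + pwm.width]   # (w, 4, cells)
    return np.einsum("wb,wbc->c", pwm.matrix, window)
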