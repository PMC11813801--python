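"""Scoring models for binding-site motifs.

The classic position weight matrix (PWM) scores a window as the sum of
per-position log-odds weights.  Heterogeneous models (e.g. dinucleotide-based
ones trained by external software) are supported through precomputed
per-position score tables; both expose the same scanning surface
(``strand_scores``) so the downstream calibration/recognition stages never
need to know which model they are looking at.  Reverse-complement handling is
the scanner's job, never the model's.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from motifpairs.io_formats import (
    MotifMatrixFile,
    SequenceRecord,
    SequenceSet,
    reverse_complement,
)

ALPHABET = "ACGT"
N_CODE = 4

_ENC = np.full(128, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENC[ord(_b)] = _i

UNIFORM_BACKGROUND = np.full(4, 0.25)


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes A=0, C=1, G=2, T=3, N=4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@runtime_checkable
class ScoringModel(Protocol):
    """Uniform scanning contract: a name, a window length, per-strand scores."""

    name: str

    @property
    def length(self) -> int: ...

    def strand_scores(self, record: SequenceRecord) -> tuple[np.ndarray, np.ndarray]:
        """Scores at every window offset on the plus and minus strands.

        Each array has ``len(seq) - L + 1`` entries (empty when the sequence
        is shorter than the motif); undefined windows are NaN.  The minus
        strand array is indexed by the window start on the forward sequence;
        its entry scores the reverse complement of that window.
        """
        ...


@dataclass
class PositionWeightMatrix:
    """Additive log-odds model of a motif.

    ``weights`` is an L x 4 matrix (columns A, C, G, T) of natural-log odds
    against ``background``; a window's score is the sum of the weights of its
    bases and is therefore bounded by the sums of column-wise minima/maxima.
    """

    name: str
    weights: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != 4:
            raise ValueError("PWM weights must be L x 4")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("PWM weights must be finite")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")
        # 5th column scores the N code as NaN so it poisons any window sum
        self._ext = np.hstack([self.weights, np.full((self.weights.shape[0], 1), np.nan)])

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    @property
    def min_score(self) -> float:
        return float(self.weights.min(axis=1).sum())

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    @property
    def score_range(self) -> tuple[float, float]:
        return (self.min_score, self.max_score)

    def window_score(self, window: str) -> float:
        """Score one L-mer; NaN if it contains a base outside {A,C,G,T}."""
        if len(window) != self.length:
            raise ValueError(
                f"window length {len(window)} != motif length {self.length}"
            )
        codes = encode(window.upper())
        return float(self._ext[np.arange(self.length), codes].sum())

    def position_scores(self, seq: str) -> np.ndarray:
        """Scores of all windows of one strand; NaN where a window has an N."""
        L = self.length
        codes = encode(seq)
        if codes.size < L:
            return np.empty(0, dtype=float)
        windows = sliding_window_view(codes, L)
        return self._ext[np.arange(L), windows].sum(axis=1)

    def strand_scores(self, record: SequenceRecord) -> tuple[np.ndarray, np.ndarray]:
        plus = self.position_scores(record.seq)
        # scanning the reverse complement, then flipping, indexes minus-strand
        # windows by their forward start coordinate
        minus = self.position_scores(reverse_complement(record.seq))[::-1]
        return plus, minus


def build_pwm(
    matrix: MotifMatrixFile,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> PositionWeightMatrix:
    """Turn a count matrix into a PWM with Laplace-style regularization.

    weight[i][b] = ln((count[i][b] + pc * bg[b]) / (rowsum[i] + pc) / bg[b])

    The pseudocount mass is distributed according to the background, so a
    count row proportional to the background yields an all-zero weight row.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
    if bg.shape != (4,) or np.any(bg <= 0):
        raise ValueError("background must be 4 strictly positive probabilities")
    bg = bg / bg.sum()
    counts = matrix.counts
    rowsum = counts.sum(axis=1, keepdims=True)
    weights = np.log((counts + pseudocount * bg) / (rowsum + pseudocount) / bg)
    return PositionWeightMatrix(name=matrix.name, weights=weights, background=bg)


def matrix_from_consensus(
    consensus: str, name: str | None = None, count: float = 10.0
) -> MotifMatrixFile:
    """Count matrix of a single consensus word (``count`` observations)."""
    consensus = consensus.upper()
    if not consensus or any(b not in ALPHABET for b in consensus):
        raise ValueError("consensus must be a non-empty word over ACGT")
    counts = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        counts[i, ALPHABET.index(b)] = count
    return MotifMatrixFile(name=name or consensus, counts=counts)


class ExternalScoreModel:
    """Motif model given by a precomputed per-position score table.

    Stands in for recognition models whose training happens in external
    software: the table maps (sequence id, strand, 0-based window start on
    the forward sequence) to a raw recognition score.  Positions missing from
    the table are undefined (NaN).
    """

    def __init__(
        self,
        name: str,
        length: int,
        scores: dict[tuple[str, str, int], float],
        seq_lengths: dict[str, int],
    ) -> None:
        if length < 1:
            raise ValueError("model length must be >= 1")
        self.name = name
        self._length = int(length)
        self._scores = dict(scores)
        self._seq_lengths = dict(seq_lengths)

    @property
    def length(self) -> int:
        return self._length

    def window_score_at(self, seq_id: str, strand: str, offset: int) -> float:
        return self._scores.get((seq_id, strand, offset), math.nan)

    def strand_scores(self, record: SequenceRecord) -> tuple[np.ndarray, np.ndarray]:
        n = len(record.seq) - self._length + 1
        if n <= 0:
            return np.empty(0), np.empty(0)
        plus = np.full(n, np.nan)
        minus = np.full(n, np.nan)
        for strand, arr in (("+", plus), ("-", minus)):
            for off in range(n):
                key = (record.id, strand, off)
                if key in self._scores:
                    arr[off] = self._scores[key]
        return plus, minus


def load_external_scores(
    path: str | Path,
    sequence_set: SequenceSet,
    name: str | None = None,
    length: int | None = None,
) -> ExternalScoreModel:
    """Load an external score table (TSV: seq_id, strand, offset, score).

    Header comment lines of the form ``# name=X length=L`` may carry the
    model name and window length; a ``length`` argument overrides them and
    one of the two must be present.  Every row must reference a sequence of
    ``sequence_set`` at a valid window offset.
    """
    path = Path(path)
    seq_lengths = {rec.id: len(rec.seq) for rec in sequence_set}
    scores: dict[tuple[str, str, int], float] = {}
    header_name = None
    header_length = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.search(r"name=(\S+)", line)
            if m:
                header_name = m.group(1)
            m = re.search(r"length=(\d+)", line)
            if m:
                header_length = int(m.group(1))
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 4:
            raise ValueError(f"bad score row (need 4 columns): {line!r}")
        seq_id, strand, offset_s, score_s = parts
        if seq_id not in seq_lengths:
            raise ValueError(f"score table references unknown sequence id {seq_id!r}")
        if strand not in ("+", "-"):
            raise ValueError(f"bad strand {strand!r} (must be + or -)")
        offset = int(offset_s)
        scores[(seq_id, strand, offset)] = float(score_s)
    L = length if length is not None else header_length
    if L is None:
        raise ValueError("model length not given (argument or '# length=' header)")
    for (seq_id, strand, offset) in scores:
        if offset < 0 or offset > seq_lengths[seq_id] - L:
            raise ValueError(
                f"offset {offset} out of range for sequence {seq_id!r} "
                f"(length {seq_lengths[seq_id]}, motif length {L})"
            )
    model_name = name or header_name or path.stem
    return ExternalScoreModel(model_name, L, scores, seq_lengths)
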