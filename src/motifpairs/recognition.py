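"""Per-sequence best-hit profiles and the joint motif.

Each sequence of a set is reduced to the ERR of its best motif hit over both
strands (the best hit is the window with the highest recognition score, hence
the smallest ERR).  Two heterogeneous motif models become comparable on this
scale, and the "joint" motif of a pair -- recognized wherever at least one of
the singles is -- is simply the elementwise minimum of the two profiles.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass

from motifpairs.calibration import ABOVE_CEILING, ErrTable
from motifpairs.io_formats import SequenceSet


@dataclass
class RecognitionProfile:
    """Index-aligned best-hit ERRs of one motif over one sequence set.

    ``best_err[i]`` is the minimum ERR over all hits of the motif in
    sequence i (both strands); sequences with no defined window (shorter than
    the motif or all N) carry the ``ABOVE_CEILING`` sentinel (+inf).
    """

    motif_label: str
    set_label: str
    best_err: np.ndarray

    def __post_init__(self) -> None:
        self.best_err = np.asarray(self.best_err, dtype=float)
        if self.best_err.ndim != 1:
            raise ValueError("best_err must be a 1-D array")

    def __len__(self) -> int:
        return len(self.best_err)


@dataclass
class DatasetPair:
    """Aligned positive (peaks, NF) and negative (background, NB) sets."""

    positive: SequenceSet
    negative: SequenceSet

    @property
    def nf(self) -> int:
        return len(self.positive)

    @property
    def nb(self) -> int:
        return len(self.negative)

    @property
    def ratio(self) -> float:
        """NF/NB, the coefficient correcting Precision for unequal set sizes."""
        return self.nf / self.nb


def best_hit_scores(model, seqs: SequenceSet) -> np.ndarray:
    """Maximum defined window score per sequence (both strands); NaN if none."""
    best = np.full(len(seqs), np.nan)
    for i, rec in enumerate(seqs):
        plus, minus = model.strand_scores(rec)
        m = -np.inf
        for arr in (plus, minus):
            if arr.size:
                finite = arr[~np.isnan(arr)]
                if finite.size:
                    m = max(m, float(finite.max()))
        if m > -np.inf:
            best[i] = m
    return best


def profile(
    model,
    table: ErrTable,
    seqs: SequenceSet,
    motif_label: str | None = None,
) -> RecognitionProfile:
    """Best-hit ERR of ``model`` for every sequence of ``seqs``.

    The table must come from calibrating the same model; sequences without a
    scoreable window map to the above-ceiling sentinel.
    """
    best = best_hit_scores(model, seqs)
    errs = table.score_to_err(best)
    return RecognitionProfile(
        motif_label=motif_label or getattr(model, "name", "motif"),
        set_label=seqs.label,
        best_err=np.asarray(errs, dtype=float),
    )


def joint_profile(a: RecognitionProfile, b: RecognitionProfile) -> RecognitionProfile:
    """Joint-motif profile: recognized when at least one single motif is.

    On the best-ERR scale the OR of two motifs is the elementwise minimum
    (above-ceiling sentinels are +inf, so they lose against any real hit).
    """
    if len(a) != len(b):
        raise ValueError(
            f"profiles are not aligned: lengths {len(a)} and {len(b)} differ"
        )
    return RecognitionProfile(
        motif_label=f"{a.motif_label}&{b.motif_label}",
        set_label=a.set_label,
        best_err=np.minimum(a.best_err, b.best_err),
    )


def recognized_fraction(prof: RecognitionProfile, errmax: float) -> float:
    """Fraction of sequences whose best hit clears ERR < errmax (strict)."""
    if not (0.0 < errmax <= 1.0):
        raise ValueError("errmax must lie in (0, 1]")
    return float(np.mean(prof.best_err < errmax))
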