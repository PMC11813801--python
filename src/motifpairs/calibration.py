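"""Threshold calibration on the expected-frequency (ERR) scale.

Raw recognition scores of different motif models are not comparable.  The
unified scale used throughout the analysis is the Expected Recognition Rate:
for a score threshold t, ERR(t) is the fraction of window positions in a
reference sequence set (typically genome promoters) whose score is >= t,
counted over both DNA strands.  ERR decreases as the threshold becomes more
stringent, so the 'Threshold vs. ERR' table is a monotone step function and
any raw score maps to the ERR of the most stringent tabulated threshold it
clears.  Scores too weak for any tabulated threshold map to the
``ABOVE_CEILING`` sentinel (+inf).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from motifpairs.io_formats import SequenceSet

logger = logging.getLogger(__name__)

#: Sentinel ERR for scores below every tabulated threshold.  +inf keeps the
#: best-hit semantics simple: the joint motif is an elementwise minimum and
#: "never recognized" loses against every real ERR.
ABOVE_CEILING = math.inf


@dataclass
class CalibrationConfig:
    """Bounds of the ERR scale.

    err_ceiling
        truncation point of the stored table (entries with larger ERR are
        useless for any analysis and are dropped), default 0.02.
    errmax
        the analysis bound ERRMAX: only thresholds with ERR strictly below it
        enter PR curves.  Recommended range 0.001-0.01; default 0.002.
    max_thresholds
        optional quantile-grid size; ``None`` keeps every distinct observed
        score as its own threshold (exact, the default).
    """

    err_ceiling: float = 0.02
    errmax: float = 0.002
    max_thresholds: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.errmax <= self.err_ceiling <= 1.0):
            raise ValueError(
                f"need 0 < errmax <= err_ceiling <= 1, got errmax={self.errmax}, "
                f"err_ceiling={self.err_ceiling}"
            )
        if self.max_thresholds is not None and self.max_thresholds < 1:
            raise ValueError("max_thresholds must be >= 1 or None")


#: default grid size when a quantile grid is requested for huge reference sets
DEFAULT_GRID_POINTS = 10_000


@dataclass
class ErrTable:
    """Monotone map from recognition-score threshold to expected frequency.

    ``thresholds`` is sorted descending (stringent first), ``errs`` ascending;
    err[k] is the fraction of scanned positions scoring >= thresholds[k].
    """

    thresholds: np.ndarray
    errs: np.ndarray
    n_positions: int
    model_name: str = ""

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.errs = np.asarray(self.errs, dtype=float)
        if self.thresholds.shape != self.errs.shape or self.thresholds.ndim != 1:
            raise ValueError("thresholds and errs must be 1-D arrays of equal length")
        if len(self.thresholds) > 1:
            if not np.all(np.diff(self.thresholds) < 0):
                raise ValueError("thresholds must be strictly decreasing")
            if not np.all(np.diff(self.errs) > 0):
                raise ValueError("errs must be strictly increasing")
        if len(self.errs) and (self.errs[0] <= 0 or self.errs[-1] > 1):
            raise ValueError("errs must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.thresholds)

    def score_to_err(self, score):
        """ERR of the most stringent tabulated threshold <= score.

        Step-function lookup: a score at or above the top threshold returns
        the smallest tabulated ERR; a score below every threshold returns
        ``ABOVE_CEILING``.  Accepts a scalar or an array (NaN -> sentinel).
        """
        scalar = np.isscalar(score)
        s = np.atleast_1d(np.asarray(score, dtype=float))
        out = np.full(s.shape, ABOVE_CEILING)
        if len(self.thresholds):
            asc = self.thresholds[::-1]  # ascending thresholds
            ok = ~np.isnan(s)
            # count of tabulated thresholds <= score
            cnt = np.searchsorted(asc, s[ok], side="right")
            vals = np.full(cnt.shape, ABOVE_CEILING)
            hit = cnt > 0
            # largest threshold <= s sits at descending index len - cnt
            vals[hit] = self.errs[len(self.thresholds) - cnt[hit]]
            out[ok] = vals
        return float(out[0]) if scalar else out


def err_table_from_scores(
    scores: np.ndarray,
    n_positions: int | None = None,
    err_ceiling: float = 0.02,
    model_name: str = "",
    max_thresholds: int | None = None,
) -> ErrTable:
    """Build an ERR table from a flat array of observed window scores.

    Every distinct score becomes a threshold; ERR is the survival fraction
    among ``n_positions`` scanned positions (defaults to ``len(scores)``).
    Entries with ERR above ``err_ceiling`` are dropped.
    """
    scores = np.asarray(scores, dtype=float)
    scores = scores[~np.isnan(scores)]
    if n_positions is None:
        n_positions = scores.size
    if n_positions <= 0 or scores.size == 0:
        raise ValueError("calibration set too small: no valid windows")
    uniq, counts = np.unique(scores, return_counts=True)
    # descending thresholds; survival counts accumulate from the top score
    thresholds = uniq[::-1]
    survival = np.cumsum(counts[::-1])
    errs = survival / float(n_positions)
    keep = errs <= err_ceiling
    thresholds, errs = thresholds[keep], errs[keep]
    if thresholds.size == 0:
        logger.warning(
            "model %r: no usable thresholds under err_ceiling=%g",
            model_name,
            err_ceiling,
        )
    if max_thresholds is not None and thresholds.size > max_thresholds:
        idx = np.unique(
            np.linspace(0, thresholds.size - 1, max_thresholds).round().astype(int)
        )
        thresholds, errs = thresholds[idx], errs[idx]
    return ErrTable(
        thresholds=thresholds,
        errs=errs,
        n_positions=int(n_positions),
        model_name=model_name,
    )


def collect_window_scores(model, seqs: SequenceSet) -> tuple[np.ndarray, int]:
    """All defined window scores of ``model`` over both strands of ``seqs``.

    Returns the flat score array and the number of scoreable positions
    (N-containing windows are excluded from both numerator and denominator).
    """
    chunks = []
    for rec in seqs:
        plus, minus = model.strand_scores(rec)
        for arr in (plus, minus):
            if arr.size:
                chunks.append(arr[~np.isnan(arr)])
    if not chunks:
        return np.empty(0), 0
    flat = np.concatenate(chunks)
    return flat, flat.size


def compute_err_table(
    model,
    promoters: SequenceSet,
    config: CalibrationConfig | None = None,
) -> ErrTable:
    """Calibrate a scoring model on a reference set.

    Scores are computed at every offset on both strands of every reference
    sequence; windows containing N (or sequences shorter than the motif)
    contribute to neither counts nor the denominator.
    """
    config = config or CalibrationConfig()
    scores, n_positions = collect_window_scores(model, promoters)
    if n_positions == 0:
        raise ValueError("calibration set too small: no valid windows")
    return err_table_from_scores(
        scores,
        n_positions=n_positions,
        err_ceiling=config.err_ceiling,
        model_name=getattr(model, "name", ""),
        max_thresholds=config.max_thresholds,
    )


def thresholds_under(table: ErrTable, errmax: float) -> np.ndarray:
    """Tabulated ERR values strictly below ``errmax``, ascending."""
    if not (0.0 < errmax <= 1.0):
        raise ValueError("errmax must lie in (0, 1]")
    return table.errs[table.errs < errmax].copy()


def base_composition(seqs: SequenceSet) -> np.ndarray:
    """Mononucleotide probabilities (A, C, G, T) of a set; Ns are ignored.

    Falls back to the uniform distribution if the set has no ACGT bases.
    """
    counts = np.zeros(4)
    for rec in seqs:
        for i, b in enumerate("ACGT"):
            counts[i] += rec.seq.count(b)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# On-disk format: TSV with one comment line of metadata


def write_err_table(table: ErrTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# model={table.model_name}\tn_positions={table.n_positions}\n")
        fh.write("threshold\terr\n")
        for t, e in zip(table.thresholds, table.errs):
            fh.write(f"{float(t)!r}\t{float(e)!r}\n")


def read_err_table(path: str | Path) -> ErrTable:
    model_name = ""
    n_positions = 0
    thresholds = []
    errs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for part in line[1:].split():
                    if part.startswith("model="):
                        model_name = part[len("model=") :]
                    elif part.startswith("n_positions="):
                        n_positions = int(part[len("n_positions=") :])
                continue
            if line.startswith("threshold"):
                continue
            t, e = line.split("\t")
            thresholds.append(float(t))
            errs.append(float(e))
    return ErrTable(
        thresholds=np.array(thresholds),
        errs=np.array(errs),
        n_positions=n_positions,
        model_name=model_name,
    )
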