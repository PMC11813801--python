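"""Corrected Precision-Recall curves, pAUPRC and RAUC.

Recall is the fraction of positive sequences recognized at a threshold
(REC = TPR = TP/NF).  Precision is corrected for the size imbalance of the
positive (NF) and negative (NB) sets:

    PREC = TPR / (TPR + FPR)  =  TP / (TP + FP * NF/NB)

so a no-skill model (identical hit-rate in both sets) sits exactly at the
constant baseline PREC_EXP = 0.5 regardless of NF/NB.  The partial area

    pAUPRC = 2 * sum_i { (PREC(i) + PREC(i-1))/2 - 0.5 } * { REC(i) - REC(i-1) }

runs over the thresholds whose expected frequency stays strictly below
ERRMAX; the factor 2 normalizes a perfect classifier to exactly 1.  Negative
values are possible and meaningful (selection toward the negative set).  For
a motif pair, RAUC = pAUPRC(joint) / max(pAUPRC(A), pAUPRC(B)); values above
one flag mutually exclusive occurrence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from motifpairs.recognition import RecognitionProfile

logger = logging.getLogger(__name__)

#: Precision of a model with no selectivity, after NF/NB correction.
PREC_EXP = 0.5


@dataclass
class AnalysisConfig:
    """Bounds of the partial-area computation."""

    errmax: float = 0.002
    prec_exp: float = PREC_EXP

    def __post_init__(self) -> None:
        if not (0.0 < self.errmax <= 1.0):
            raise ValueError("errmax must lie in (0, 1]")


@dataclass(frozen=True)
class PRPoint:
    """One threshold of the curve: counts, rates and corrected Precision."""

    err_threshold: float
    tp: int
    fp: int
    tpr: float
    fpr: float
    precision: float


@dataclass
class PRCurve:
    """Threshold-indexed (Recall, corrected Precision) points under ERRMAX.

    Points are ordered stringent to mild (err_threshold strictly increasing,
    Recall non-decreasing).  Integration uses a virtual origin at REC = 0
    whose Precision is carried from the first real point.
    """

    points: list[PRPoint]
    nf: int
    nb: int
    errmax: float

    @property
    def ni(self) -> int:
        """Number of thresholds on the curve (the mildest is index NI)."""
        return len(self.points)

    @property
    def recalls(self) -> np.ndarray:
        return np.array([p.tpr for p in self.points])

    @property
    def precisions(self) -> np.ndarray:
        return np.array([p.precision for p in self.points])


def corrected_precision(tpr: float, fpr: float) -> float:
    """Precision on the rate scale: TPR / (TPR + FPR).

    Dividing both counts by their set size makes the expected no-skill value
    0.5 whatever the NF/NB imbalance.  Undefined when both rates are zero.
    """
    if tpr < 0 or fpr < 0 or tpr > 1 or fpr > 1:
        raise ValueError("TPR and FPR must lie in [0, 1]")
    if tpr == 0 and fpr == 0:
        raise ValueError("precision undefined at TPR = FPR = 0")
    return tpr / (tpr + fpr)


def build_pr_curve(
    pos: RecognitionProfile,
    neg: RecognitionProfile,
    config: AnalysisConfig | None = None,
) -> PRCurve:
    """Corrected PR curve of one motif (or the joint motif) on a dataset pair.

    The threshold grid is the union of best-ERR values observed in either
    profile that lie strictly below ERRMAX; at grid value t a sequence counts
    as predicted when its best ERR <= t.  Thresholds predicting nothing in
    either set are dropped.
    """
    config = config or AnalysisConfig()
    nf, nb = len(pos), len(neg)
    pos_err = pos.best_err
    neg_err = neg.best_err
    observed = np.concatenate([pos_err, neg_err])
    observed = observed[np.isfinite(observed)]
    grid = np.unique(observed[observed < config.errmax])
    points: list[PRPoint] = []
    if grid.size:
        pos_sorted = np.sort(pos_err)
        neg_sorted = np.sort(neg_err)
        tps = np.searchsorted(pos_sorted, grid, side="right")
        fps = np.searchsorted(neg_sorted, grid, side="right")
        for t, tp, fp in zip(grid, tps, fps):
            if tp == 0 and fp == 0:
                continue
            tpr = tp / nf
            fpr = fp / nb
            points.append(
                PRPoint(
                    err_threshold=float(t),
                    tp=int(tp),
                    fp=int(fp),
                    tpr=tpr,
                    fpr=fpr,
                    precision=corrected_precision(tpr, fpr),
                )
            )
    if not points:
        logger.warning(
            "motif %r: no thresholds under ERRMAX=%g; pAUPRC will be 0",
            pos.motif_label,
            config.errmax,
        )
    return PRCurve(points=points, nf=nf, nb=nb, errmax=config.errmax)


def pauprc(curve: PRCurve, prec_exp: float = PREC_EXP) -> float:
    """Partial area under the corrected PR curve, baseline-subtracted.

    Trapezoid sum over the curve points with a virtual origin (REC = 0,
    Precision of the first real point), baseline ``prec_exp`` subtracted, and
    the whole sum doubled so that perfect separation scores exactly 1.
    An empty curve scores 0.
    """
    if not curve.points:
        return 0.0
    total = 0.0
    prev_rec = 0.0
    prev_prec = curve.points[0].precision
    for pt in curve.points:
        total += ((pt.precision + prev_prec) / 2.0 - prec_exp) * (pt.tpr - prev_rec)
        prev_rec = pt.tpr
        prev_prec = pt.precision
    return 2.0 * total


def rauc(pauprc_a: float, pauprc_b: float, pauprc_joint: float) -> float:
    """Ratio of areas: pAUPRC(joint) / max(pAUPRC(A), pAUPRC(B)).

    Values above one indicate that the joint motif outperforms both singles,
    i.e. the pair tends toward mutually exclusive occurrence.  NaN when
    neither single motif has positive area.
    """
    m = max(pauprc_a, pauprc_b)
    if m <= 0:
        return math.nan
    return pauprc_joint / m


@dataclass
class PairResult:
    """Areas and verdicts for one motif pair."""

    motif_a: str
    motif_b: str
    pauprc_a: float
    pauprc_b: float
    pauprc_joint: float
    rauc: float
    similarity_score: float | None = None
    similarity_flag: str = "na"

    def as_dict(self) -> dict:
        return {
            "motif_a": self.motif_a,
            "motif_b": self.motif_b,
            "pAUPRC_A": self.pauprc_a,
            "pAUPRC_B": self.pauprc_b,
            "pAUPRC_joint": self.pauprc_joint,
            "RAUC": self.rauc,
            "similarity_score": self.similarity_score,
            "similarity_flag": self.similarity_flag,
        }
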