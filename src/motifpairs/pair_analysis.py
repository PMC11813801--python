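"""Orchestration of the pair-analysis modes and the motif redundancy screen.

Four application modes are provided: one explicit pair, all pairs among K
motifs, one query motif against a whole collection, and the top-K motifs of a
collection (ranked by single-motif pAUPRC) against each other.  For pairs of
count-matrix motifs, a similarity screen flags near-identical matrices whose
high RAUC would be a trivial artifact of scoring the same sites twice:
redundant pairs stay in the output, flagged, never filtered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from motifpairs.calibration import CalibrationConfig, ErrTable, compute_err_table
from motifpairs.io_formats import MotifMatrixFile
from motifpairs.motif_models import build_pwm
from motifpairs.prcurve import (
    AnalysisConfig,
    PairResult,
    PRCurve,
    build_pr_curve,
    pauprc,
    rauc,
)
from motifpairs.recognition import (
    DatasetPair,
    RecognitionProfile,
    joint_profile,
    profile,
)

#: placement similarity at or above this is considered redundant
SIMILARITY_THRESHOLD = 0.9
#: ... provided the placement overlaps at least this fraction of the shorter motif
SIMILARITY_MIN_OVERLAP_FRACTION = 0.75
#: shortest alignment window considered when sliding one motif along the other
MIN_OVERLAP_COLUMNS = 4


@dataclass
class CalibratedMotif:
    """A scoring model together with its ERR table (and count matrix if any)."""

    name: str
    model: object
    table: ErrTable
    matrix: MotifMatrixFile | None = None
    metadata: dict = field(default_factory=dict)


@dataclass
class MotifCollection:
    """Uniquely named list of calibrated motifs."""

    motifs: list[CalibratedMotif]

    def __post_init__(self) -> None:
        names = [m.name for m in self.motifs]
        if len(set(names)) != len(names):
            raise ValueError("motif names must be unique within a collection")

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.motifs]


@dataclass
class PairMatrix:
    """Pairwise results: single areas plus symmetric RAUC/similarity tables."""

    names: list[str]
    pauprc_single: pd.Series
    rauc: pd.DataFrame
    similarity: pd.DataFrame
    results: list[PairResult]


def calibrate_motif(
    matrix: MotifMatrixFile,
    promoters,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    config: CalibrationConfig | None = None,
) -> CalibratedMotif:
    """Build a PWM from a count matrix and calibrate it on the reference set."""
    model = build_pwm(matrix, pseudocount=pseudocount, background=background)
    table = compute_err_table(model, promoters, config)
    return CalibratedMotif(name=matrix.name, model=model, table=table, matrix=matrix)


def _profiles(motif: CalibratedMotif, data: DatasetPair):
    pos = profile(motif.model, motif.table, data.positive, motif_label=motif.name)
    neg = profile(motif.model, motif.table, data.negative, motif_label=motif.name)
    return pos, neg


def _pair_from_profiles(
    name_a: str,
    name_b: str,
    prof_a: tuple[RecognitionProfile, RecognitionProfile],
    prof_b: tuple[RecognitionProfile, RecognitionProfile],
    config: AnalysisConfig,
    pauprc_a: float | None = None,
    pauprc_b: float | None = None,
    similarity: tuple[float, str] | None = None,
) -> PairResult:
    if pauprc_a is None:
        pauprc_a = pauprc(build_pr_curve(*prof_a, config), config.prec_exp)
    if pauprc_b is None:
        pauprc_b = pauprc(build_pr_curve(*prof_b, config), config.prec_exp)
    joint_pos = joint_profile(prof_a[0], prof_b[0])
    joint_neg = joint_profile(prof_a[1], prof_b[1])
    pauprc_j = pauprc(build_pr_curve(joint_pos, joint_neg, config), config.prec_exp)
    score, flag = similarity if similarity is not None else (None, "na")
    return PairResult(
        motif_a=name_a,
        motif_b=name_b,
        pauprc_a=pauprc_a,
        pauprc_b=pauprc_b,
        pauprc_joint=pauprc_j,
        rauc=rauc(pauprc_a, pauprc_b, pauprc_j),
        similarity_score=score,
        similarity_flag=flag,
    )


def pair_curves(
    a: CalibratedMotif,
    b: CalibratedMotif,
    data: DatasetPair,
    config: AnalysisConfig | None = None,
) -> list[tuple[str, PRCurve]]:
    """PR curves for motif A, motif B and their joint motif (in that order)."""
    config = config or AnalysisConfig()
    prof_a = _profiles(a, data)
    prof_b = _profiles(b, data)
    joint_pos = joint_profile(prof_a[0], prof_b[0])
    joint_neg = joint_profile(prof_a[1], prof_b[1])
    return [
        (a.name, build_pr_curve(*prof_a, config)),
        (b.name, build_pr_curve(*prof_b, config)),
        (f"{a.name}&{b.name}", build_pr_curve(joint_pos, joint_neg, config)),
    ]


def analyze_pair(
    a: CalibratedMotif,
    b: CalibratedMotif,
    data: DatasetPair,
    config: AnalysisConfig | None = None,
) -> PairResult:
    """Full analysis of one motif pair: areas, RAUC, redundancy screen.

    Similarity is computed only when both motifs carry count matrices
    (heterogeneous models have no matrix to compare).
    """
    config = config or AnalysisConfig()
    similarity = None
    if a.matrix is not None and b.matrix is not None:
        similarity = pwm_similarity(a.matrix, b.matrix)
    return _pair_from_profiles(
        a.name, b.name, _profiles(a, data), _profiles(b, data), config,
        similarity=similarity,
    )


def analyze_all_pairs(
    motifs: MotifCollection,
    data: DatasetPair,
    config: AnalysisConfig | None = None,
) -> PairMatrix:
    """All K*(K-1)/2 pairs of a collection; singles computed once and reused."""
    if len(motifs) < 2:
        raise ValueError("need at least 2 motifs for pairwise analysis")
    config = config or AnalysisConfig()
    names = motifs.names
    profiles = {m.name: _profiles(m, data) for m in motifs}
    singles = {
        name: pauprc(build_pr_curve(*prof, config), config.prec_exp)
        for name, prof in profiles.items()
    }
    k = len(names)
    rauc_m = pd.DataFrame(np.full((k, k), np.nan), index=names, columns=names)
    sim_m = pd.DataFrame(np.full((k, k), np.nan), index=names, columns=names)
    matrices = {m.name: m.matrix for m in motifs}
    results: list[PairResult] = []
    for name in names:
        if singles[name] > 0:
            rauc_m.loc[name, name] = 1.0
        if matrices[name] is not None:
            sim_m.loc[name, name] = 1.0
    for i in range(k):
        for j in range(i + 1, k):
            na, nb_ = names[i], names[j]
            similarity = None
            if matrices[na] is not None and matrices[nb_] is not None:
                similarity = pwm_similarity(matrices[na], matrices[nb_])
            res = _pair_from_profiles(
                na, nb_, profiles[na], profiles[nb_], config,
                pauprc_a=singles[na], pauprc_b=singles[nb_],
                similarity=similarity,
            )
            results.append(res)
            rauc_m.loc[na, nb_] = rauc_m.loc[nb_, na] = res.rauc
            if res.similarity_score is not None:
                sim_m.loc[na, nb_] = sim_m.loc[nb_, na] = res.similarity_score
    return PairMatrix(
        names=names,
        pauprc_single=pd.Series(singles, name="pAUPRC").loc[names],
        rauc=rauc_m,
        similarity=sim_m,
        results=results,
    )


def analyze_one_vs_collection(
    query: CalibratedMotif,
    collection: MotifCollection,
    data: DatasetPair,
    config: AnalysisConfig | None = None,
) -> list[PairResult]:
    """Pair the query with every collection motif, ranked by RAUC descending.

    Ties break by pAUPRC(joint) descending, then by motif name; NaN RAUC
    (neither single informative) ranks last.
    """
    if len(collection) == 0:
        raise ValueError("collection must be non-empty")
    config = config or AnalysisConfig()
    prof_q = _profiles(query, data)
    pauprc_q = pauprc(build_pr_curve(*prof_q, config), config.prec_exp)
    results = []
    for m in collection:
        similarity = None
        if query.matrix is not None and m.matrix is not None:
            similarity = pwm_similarity(query.matrix, m.matrix)
        results.append(
            _pair_from_profiles(
                query.name, m.name, prof_q, _profiles(m, data), config,
                pauprc_a=pauprc_q, similarity=similarity,
            )
        )

    def sort_key(r: PairResult):
        r_nan = isinstance(r.rauc, float) and math.isnan(r.rauc)
        return (r_nan, -(r.rauc if not r_nan else 0.0), -r.pauprc_joint, r.motif_b)

    return sorted(results, key=sort_key)


def analyze_collection_topk(
    collection: MotifCollection,
    k: int,
    data: DatasetPair,
    config: AnalysisConfig | None = None,
) -> PairMatrix:
    """All pairs among the k motifs with the largest single pAUPRC.

    Single areas are computed for the whole collection first; ties at the
    selection boundary break lexicographically by name for determinism.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(collection):
        raise ValueError(f"k={k} exceeds collection size {len(collection)}")
    config = config or AnalysisConfig()
    singles = {}
    for m in collection:
        prof = _profiles(m, data)
        singles[m.name] = pauprc(build_pr_curve(*prof, config), config.prec_exp)
    ranked = sorted(collection, key=lambda m: (-singles[m.name], m.name))
    top = MotifCollection(motifs=ranked[:k])
    return analyze_all_pairs(top, data, config)


# ---------------------------------------------------------------------------
# Matrix similarity screen


def _column_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two 4-vectors, with degenerate-column rules.

    Uninformative columns (zero variance, e.g. uniform) have no defined
    correlation; two identical flat columns count as perfectly similar, a
    flat column against an informative one as dissimilar.
    """
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt((xc ** 2).sum()))
    sy = float(np.sqrt((yc ** 2).sum()))
    eps = 1e-12
    if sx < eps and sy < eps:
        return 1.0 if np.allclose(x, y) else 0.0
    if sx < eps or sy < eps:
        return 0.0
    return float((xc * yc).sum() / (sx * sy))


def pwm_similarity(
    a: MotifMatrixFile,
    b: MotifMatrixFile,
    score_threshold: float = SIMILARITY_THRESHOLD,
    min_overlap_fraction: float = SIMILARITY_MIN_OVERLAP_FRACTION,
) -> tuple[float, str]:
    """Best alignment similarity of two count matrices.

    Column frequencies of B (in both orientations) are slid along A over every
    relative offset with at least ``min(4, min(LA, LB))`` overlapping columns;
    a placement scores the mean column-wise Pearson correlation.  The returned
    score is the maximum over placements.  The pair is flagged ``redundant``
    when some placement covering at least ``min_overlap_fraction`` of the
    shorter motif reaches ``score_threshold``.
    """
    fa = a.frequencies
    la, lb = a.length, b.length
    min_len = min(la, lb)
    min_overlap = min(MIN_OVERLAP_COLUMNS, min_len)
    need_cols = min_overlap_fraction * min_len
    best = -np.inf
    best_qualifying = -np.inf
    for fb in (b.frequencies, b.frequencies[::-1, ::-1]):
        for shift in range(-(lb - min_overlap), la - min_overlap + 1):
            lo = max(0, shift)
            hi = min(la, lb + shift)
            overlap = hi - lo
            if overlap < min_overlap:
                continue
            corrs = [
                _column_correlation(fa[i], fb[i - shift]) for i in range(lo, hi)
            ]
            score = float(np.mean(corrs))
            best = max(best, score)
            if overlap >= need_cols:
                best_qualifying = max(best_qualifying, score)
    flag = "redundant" if best_qualifying >= score_threshold else "distinct"
    return best, flag
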