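"""Self-contained synthetic universes for exercising the whole pipeline.

Three generators emulate the inputs of a real analysis without any downloads:
i.i.d. background sequences of controlled G/C content (stand-ins for genome
promoters and for peak flanks), negatives matched per-peak in length and G/C
fraction, and peak sets with motif instances implanted under three regimes --
independent, co-occurring (both motifs always land in the same peaks) and
mutually exclusive (never in the same peak).  A fourth generator draws the
Gaussian score mixtures used to exercise the PR-curve stage directly,
bypassing sequence scanning.

Implants overwrite the background at the chosen offset, preserving peak
length so position counts stay constant across regimes.  Each generator draws
from its own named pseudo-random stream derived from a single integer seed,
making every fixture bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from motifpairs.io_formats import (
    MotifMatrixFile,
    SequenceRecord,
    SequenceSet,
    reverse_complement,
)
from motifpairs.motif_models import ALPHABET

_STREAMS = {"background": 11, "negatives": 23, "implant": 37, "gaussian": 53}

#: default negatives per peak, so NB = 5 * NF
DEFAULT_PER_PEAK = 5

REGIMES = ("independent", "cooccur", "exclusive")


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(seed)])


@dataclass
class ImplantRegime:
    """How motif instances are distributed over peaks.

    kind
        ``independent`` -- per-peak indicators drawn independently;
        ``cooccur`` -- A and B always land in the same peaks (one indicator);
        ``exclusive`` -- a peak receives at most one of the two motifs.
    rate_a, rate_b
        per-peak implantation probabilities; ``cooccur`` requires them equal
        and ``exclusive`` requires rate_a + rate_b <= 1.
    motif_a, motif_b
        consensus words (implanted verbatim) or count matrices (instances
        sampled column-wise from the frequencies).
    """

    kind: str
    rate_a: float
    rate_b: float
    motif_a: str | MotifMatrixFile
    motif_b: str | MotifMatrixFile
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in REGIMES:
            raise ValueError(f"unknown regime kind {self.kind!r}")
        if not (0.0 <= self.rate_a <= 1.0 and 0.0 <= self.rate_b <= 1.0):
            raise ValueError("implantation rates must lie in [0, 1]")
        if self.kind == "cooccur" and self.rate_a != self.rate_b:
            raise ValueError("cooccur regime requires rate_a == rate_b")
        if self.kind == "exclusive" and self.rate_a + self.rate_b > 1.0:
            raise ValueError("exclusive regime requires rate_a + rate_b <= 1")


def gc_profile(seqs: SequenceSet) -> pd.DataFrame:
    """Per-sequence G/C fraction (over ACGT bases) and length."""
    rows = []
    for rec in seqs:
        acgt = sum(rec.seq.count(b) for b in ALPHABET)
        gc = (rec.seq.count("G") + rec.seq.count("C")) / acgt if acgt else 0.5
        rows.append({"id": rec.id, "gc": gc, "length": len(rec.seq)})
    return pd.DataFrame(rows).set_index("id")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=probs)
    return "".join(ALPHABET[c] for c in codes)


def _matched_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random sequence whose exact G/C count is round(gc * length).

    Fixing the composition (instead of sampling it) keeps every generated
    sequence within 1/(2*length) of the requested G/C fraction.
    """
    n_gc = int(round(gc * length))
    n_g = rng.binomial(n_gc, 0.5)
    n_a = rng.binomial(length - n_gc, 0.5)
    codes = np.concatenate(
        [
            np.full(n_g, 2, np.uint8),          # G
            np.full(n_gc - n_g, 1, np.uint8),   # C
            np.full(n_a, 0, np.uint8),          # A
            np.full(length - n_gc - n_a, 3, np.uint8),  # T
        ]
    )
    rng.shuffle(codes)
    return "".join(ALPHABET[c] for c in codes)


def gen_background(
    n: int,
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    label: str = "promoter",
    prefix: str = "bg",
) -> SequenceSet:
    """i.i.d. background sequences with P(G)+P(C) = gc, P(A)=P(T), P(G)=P(C)."""
    if n < 1 or length < 1:
        raise ValueError("n and length must be >= 1")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must lie in [0, 1]")
    rng = _rng(seed, "background")
    records = [
        SequenceRecord(id=f"{prefix}{i + 1}", seq=_random_seq(rng, length, gc))
        for i in range(n)
    ]
    return SequenceSet(records=records, label=label)


def gen_negatives(
    positives: SequenceSet,
    per_peak: int = DEFAULT_PER_PEAK,
    seed: int = 0,
) -> SequenceSet:
    """Per-peak matched negatives: same length, G/C fraction within 0.02.

    For each positive sequence ``per_peak`` random sequences are drawn with
    an exactly matched base composition, so NB = per_peak * NF.  Negatives
    contain no implanted motifs by construction.
    """
    if per_peak < 1:
        raise ValueError("per_peak must be >= 1")
    rng = _rng(seed, "negatives")
    records = []
    for rec in positives:
        acgt = sum(rec.seq.count(b) for b in ALPHABET)
        gc = (rec.seq.count("G") + rec.seq.count("C")) / acgt if acgt else 0.5
        for j in range(per_peak):
            records.append(
                SequenceRecord(
                    id=f"{rec.id}_neg{j + 1}",
                    seq=_matched_seq(rng, len(rec.seq), gc),
                )
            )
    return SequenceSet(records=records, label="negative")


def _draw_instance(motif: str | MotifMatrixFile, rng: np.random.Generator) -> str:
    if isinstance(motif, str):
        return motif.upper()
    freqs = motif.frequencies
    return "".join(ALPHABET[rng.choice(4, p=freqs[i])] for i in range(motif.length))


def _indicators(kind: str, rate_a: float, rate_b: float, rng) -> tuple[bool, bool]:
    if kind == "independent":
        return bool(rng.random() < rate_a), bool(rng.random() < rate_b)
    if kind == "cooccur":
        both = bool(rng.random() < rate_a)
        return both, both
    u = rng.random()
    if u < rate_a:
        return True, False
    if u < rate_a + rate_b:
        return False, True
    return False, False


def implant(
    peaks: SequenceSet, regime: ImplantRegime
) -> tuple[SequenceSet, pd.DataFrame]:
    """Implant motif instances into peaks under the regime's constraints.

    Instances are placed at uniform random offsets on a random strand
    (reverse-complemented when minus), overwriting the background.  When both
    motifs land in one peak their footprints never overlap.  Returns the new
    set and a truth table recording which motifs each peak received, where
    and on which strand.
    """
    rng = _rng(regime.seed, "implant")
    len_a = len(regime.motif_a) if isinstance(regime.motif_a, str) else regime.motif_a.length
    len_b = len(regime.motif_b) if isinstance(regime.motif_b, str) else regime.motif_b.length
    records = []
    rows = []
    for rec in peaks:
        n = len(rec.seq)
        if len_a >= n or len_b >= n:
            raise ValueError(
                f"motif longer than peak {rec.id!r} (length {n})"
            )
        has_a, has_b = _indicators(regime.kind, regime.rate_a, regime.rate_b, rng)
        seq = rec.seq
        row = {
            "peak_id": rec.id,
            "has_a": has_a,
            "has_b": has_b,
            "offset_a": pd.NA,
            "strand_a": pd.NA,
            "offset_b": pd.NA,
            "strand_b": pd.NA,
        }
        off_a = None
        if has_a:
            off_a = int(rng.integers(0, n - len_a + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            site = _draw_instance(regime.motif_a, rng)
            if strand == "-":
                site = reverse_complement(site)
            seq = seq[:off_a] + site + seq[off_a + len_a :]
            row["offset_a"], row["strand_a"] = off_a, strand
        if has_b:
            allowed = [
                o
                for o in range(n - len_b + 1)
                if off_a is None or o + len_b <= off_a or o >= off_a + len_a
            ]
            if not allowed:
                raise ValueError(
                    f"peak {rec.id!r} too short to hold both motifs without overlap"
                )
            off_b = int(allowed[rng.integers(0, len(allowed))])
            strand = "+" if rng.random() < 0.5 else "-"
            site = _draw_instance(regime.motif_b, rng)
            if strand == "-":
                site = reverse_complement(site)
            seq = seq[:off_b] + site + seq[off_b + len_b :]
            row["offset_b"], row["strand_b"] = off_b, strand
        records.append(SequenceRecord(id=rec.id, seq=seq))
        rows.append(row)
    truth = pd.DataFrame(rows)
    return SequenceSet(records=records, label="positive"), truth


# Gaussian mixture parameters of the illustrative score distributions:
# negatives ~ N(5, 2.5); positives ~ 50/50 mix of N(10, 1) (sites passing the
# expected-frequency bound) and N(5.5, 4) (sites failing it).
GAUSS_NEG = (5.0, 2.5)
GAUSS_POS_1 = (10.0, 1.0)
GAUSS_POS_2 = (5.5, 4.0)


def gen_gaussian_profiles(
    nf: int, nb: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Raw positive/negative score samples from the illustrative mixtures.

    Returns ``(positive_scores, negative_scores)`` for exercising the
    PR-curve machinery directly, without sequence scanning.
    """
    if nf < 1 or nb < 1:
        raise ValueError("nf and nb must be >= 1")
    rng = _rng(seed, "gaussian")
    neg = rng.normal(*GAUSS_NEG, size=nb)
    comp = rng.random(nf) < 0.5
    pos = np.where(
        comp,
        rng.normal(*GAUSS_POS_1, size=nf),
        rng.normal(*GAUSS_POS_2, size=nf),
    )
    return pos, neg
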