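"""Readers and writers for sequence sets, motif matrices and result tables.

Sequences travel as plain FASTA.  Motif count matrices are accepted in the
common text dialects (JASPAR pfm, Hocomoco-style pcm, MEME minimal, plain
TSV) and normalized to an L x 4 array with columns ordered A, C, G, T.
All result tables are TSV with '.' as the decimal separator: report scalars
are rounded to 4 decimals, curve points are written at full precision.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DIALECTS = ("jaspar", "hocomoco_pcm", "meme_minimal", "plain_tsv")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """One named DNA sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")


@dataclass
class SequenceSet:
    """Ordered collection of sequences; profiles are index-aligned to it."""

    records: list[SequenceRecord]
    label: str = "positive"

    def __post_init__(self) -> None:
        if len(self.records) == 0:
            raise ValueError("no sequences")
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(rec.seq) for rec in self.records], dtype=np.int64)


def normalize_sequence(raw: str) -> tuple[str, int]:
    """Uppercase, map U to T, replace other non-ACGTN letters by N.

    Returns the normalized string and the number of masked characters.
    """
    s = raw.upper().replace("U", "T")
    masked = sum(1 for c in s if c not in VALID_BASES)
    if masked:
        s = "".join(c if c in VALID_BASES else "N" for c in s)
    return s, masked


def read_fasta(path: str | Path, label: str = "positive") -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Non-ACGTN characters are masked to N (peaks genuinely contain Ns;
    scanning skips N-containing windows) with the count logged.
    """
    records: list[SequenceRecord] = []
    total_masked = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq, masked = normalize_sequence(str(rec.seq))
        total_masked += masked
        records.append(SequenceRecord(id=rec.id, seq=seq))
    if total_masked:
        logger.info("masked %d non-ACGTN characters to N in %s", total_masked, path)
    if not records:
        raise ValueError(f"no sequences in {path}")
    return SequenceSet(records=records, label=label)


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in seqs:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Motif matrices


@dataclass
class MotifMatrixFile:
    """Per-position nucleotide counts (or frequencies) defining a motif.

    ``counts`` is an L x 4 non-negative array with columns A, C, G, T.
    """

    name: str
    counts: np.ndarray
    source_dialect: str = "plain_tsv"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError(
                f"motif {self.name!r}: counts must be L x 4, got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError(f"motif {self.name!r}: negative matrix entry")
        rowsums = self.counts.sum(axis=1)
        if np.any(rowsums <= 0):
            raise ValueError(f"motif {self.name!r}: all-zero matrix row")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        """Counts normalized to per-position base frequencies."""
        return self.counts / self.counts.sum(axis=1, keepdims=True)

    def reverse_complement(self) -> "MotifMatrixFile":
        return MotifMatrixFile(
            name=f"{self.name}_rc",
            counts=self.counts[::-1, ::-1].copy(),
            source_dialect=self.source_dialect,
        )


_NUM_RE = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


def _numeric_rows(lines: Iterable[str]) -> list[list[float]]:
    rows = []
    for line in lines:
        vals = _NUM_RE.findall(line)
        if vals:
            rows.append([float(v) for v in vals])
    return rows


def _check_rect(rows: list[list[float]], name: str) -> np.ndarray:
    if not rows:
        raise ValueError(f"motif file {name!r}: no numeric rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError(f"motif file {name!r}: ragged rows")
    return np.array(rows, dtype=float)


def _parse_jaspar(text: str, fallback_name: str) -> tuple[str, np.ndarray]:
    name = fallback_name
    base_rows: dict[str, list[float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0] if line[1:].split() else fallback_name
            continue
        m = re.match(r"^([ACGTacgt])[\s:|\[]", line + " ")
        if not m:
            raise ValueError(f"motif file {name!r}: expected JASPAR base-labelled rows")
        base = m.group(1).upper()
        vals = [float(v) for v in _NUM_RE.findall(line[1:])]
        if not vals:
            raise ValueError(f"motif file {name!r}: empty row for base {base}")
        base_rows[base] = vals
    if set(base_rows) != set("ACGT"):
        raise ValueError(f"motif file {name!r}: JASPAR format needs rows A, C, G, T")
    width = len(base_rows["A"])
    if any(len(base_rows[b]) != width for b in "CGT"):
        raise ValueError(f"motif file {name!r}: ragged rows")
    counts = np.array([base_rows[b] for b in "ACGT"], dtype=float).T
    return name, counts


def _parse_hocomoco_pcm(text: str, fallback_name: str) -> tuple[str, np.ndarray]:
    name = fallback_name
    lines = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0] if line[1:].split() else fallback_name
            continue
        lines.append(line)
    arr = _check_rect(_numeric_rows(lines), name)
    if arr.shape[1] != 4:
        raise ValueError(f"motif file {name!r}: pcm rows must have 4 columns (A C G T)")
    return name, arr


def _parse_meme_minimal(text: str, fallback_name: str) -> tuple[str, np.ndarray]:
    name = fallback_name
    lines = text.splitlines()
    nsites = None
    w = None
    start = None
    for i, line in enumerate(lines):
        s = line.strip()
        if s.upper().startswith("MOTIF"):
            parts = s.split()
            if len(parts) > 1:
                name = parts[1]
        if s.lower().startswith("letter-probability matrix"):
            m_w = re.search(r"w=\s*(\d+)", s)
            m_n = re.search(r"nsites=\s*(\d+(?:\.\d+)?)", s)
            if m_w:
                w = int(m_w.group(1))
            if m_n:
                nsites = float(m_n.group(1))
            start = i + 1
            break
    if start is None:
        raise ValueError(f"motif file {name!r}: no letter-probability matrix header")
    rows = _numeric_rows(lines[start : start + (w if w else len(lines))])
    if w is not None:
        rows = rows[:w]
    arr = _check_rect(rows, name)
    if arr.shape[1] != 4:
        raise ValueError(f"motif file {name!r}: MEME matrix must have 4 columns")
    if nsites:
        arr = arr * nsites
    return name, arr


def _parse_plain(text: str, fallback_name: str) -> tuple[str, np.ndarray]:
    name = fallback_name
    lines = []
    for line in text.splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if s.startswith(">"):
            name = s[1:].split()[0] if s[1:].split() else fallback_name
            continue
        lines.append(s)
    arr = _check_rect(_numeric_rows(lines), name)
    if arr.shape[1] == 4:
        return name, arr
    if arr.shape[0] == 4:
        return name, arr.T
    raise ValueError(
        f"motif file {name!r}: matrix must be L x 4 or 4 x L, got {arr.shape}"
    )


def _sniff_dialect(text: str) -> str:
    stripped = [l.strip() for l in text.splitlines() if l.strip()]
    if any("letter-probability" in l.lower() or l.upper().startswith("MEME VERSION") for l in stripped):
        return "meme_minimal"
    body = [l for l in stripped if not l.startswith(">")]
    if body and all(re.match(r"^[ACGTacgt][\s:|\[]", l + " ") for l in body):
        return "jaspar"
    if stripped and stripped[0].startswith(">"):
        return "hocomoco_pcm"
    return "plain_tsv"


_PARSERS = {
    "jaspar": _parse_jaspar,
    "hocomoco_pcm": _parse_hocomoco_pcm,
    "meme_minimal": _parse_meme_minimal,
    "plain_tsv": _parse_plain,
}


def read_motif_matrix(path: str | Path, dialect: str = "auto") -> MotifMatrixFile:
    """Read a motif count matrix, normalizing orientation to L x 4 (A,C,G,T).

    ``dialect`` is one of ``jaspar``, ``hocomoco_pcm``, ``meme_minimal``,
    ``plain_tsv`` or ``auto`` (sniff from the content).
    """
    path = Path(path)
    text = path.read_text()
    if dialect == "auto":
        dialect = _sniff_dialect(text)
    if dialect not in _PARSERS:
        raise ValueError(f"unsupported motif dialect {dialect!r}")
    name, counts = _PARSERS[dialect](text, path.stem)
    return MotifMatrixFile(name=name, counts=counts, source_dialect=dialect)


# ---------------------------------------------------------------------------
# Result writers


def write_pr_curves(curves: Sequence[tuple[str, object]], path: str | Path) -> None:
    """Write labeled PR curves as one TSV with one block per curve.

    Columns: curve_label, threshold_ERR, Recall, Precision.  Blocks appear in
    the order given (by convention: motif A, motif B, joint).
    """
    if not curves:
        raise ValueError("write_pr_curves needs at least one curve")
    with open(path, "w") as fh:
        fh.write("curve_label\tthreshold_ERR\tRecall\tPrecision\n")
        for label, curve in curves:
            if len(curve.points) == 0:
                logger.warning(
                    "curve %r has no thresholds under ERRMAX; writing empty block",
                    label,
                )
            for pt in curve.points:
                fh.write(
                    f"{label}\t{float(pt.err_threshold)!r}"
                    f"\t{float(pt.tpr)!r}\t{float(pt.precision)!r}\n"
                )


def write_pair_report(result: object, path: str | Path) -> None:
    """Write a pair-analysis report as key-value TSV lines.

    Scalars are printed with 4 decimal places; undefined values print as NA.
    """

    def fmt(x: float | None) -> str:
        if x is None or (isinstance(x, float) and math.isnan(x)):
            return "NA"
        return f"{x:.4f}"

    with open(path, "w") as fh:
        fh.write(f"pAUPRC_A\t{fmt(result.pauprc_a)}\n")
        fh.write(f"pAUPRC_B\t{fmt(result.pauprc_b)}\n")
        fh.write(f"pAUPRC_joint\t{fmt(result.pauprc_joint)}\n")
        fh.write(f"RAUC\t{fmt(result.rauc)}\n")
        fh.write(f"similarity_score\t{fmt(result.similarity_score)}\n")
        fh.write(f"similarity_flag\t{result.similarity_flag}\n")
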