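"""Independent brute-force reference implementations used only by the tests.

These deliberately avoid the package's vectorized code paths: window scores
come from explicit python loops over every offset, the partial area is a
plain trapezoid sum over an exhaustively enumerated threshold list, and the
matrix similarity search enumerates every placement with a sum-formula
Pearson correlation.
"""

import math

from motifpairs.io_formats import reverse_complement


def oracle_err_table(pwm, seqs, err_ceiling=1.0):
    """(thresholds desc, errs asc, n_positions) by window enumeration."""
    scores = []
    for rec in seqs:
        for strand_seq in (rec.seq, reverse_complement(rec.seq)):
            for i in range(len(strand_seq) - pwm.length + 1):
                v = pwm.window_score(strand_seq[i : i + pwm.length])
                if not math.isnan(v):
                    scores.append(v)
    n = len(scores)
    thresholds = sorted(set(scores), reverse=True)
    entries = []
    for t in thresholds:
        err = sum(1 for x in scores if x >= t) / n
        if err <= err_ceiling:
            entries.append((t, err))
    return entries, n


def oracle_best_err(pwm, seq, entries):
    """Best-hit ERR of one sequence via exhaustive window scoring."""
    best = None
    for strand_seq in (seq, reverse_complement(seq)):
        for i in range(len(strand_seq) - pwm.length + 1):
            v = pwm.window_score(strand_seq[i : i + pwm.length])
            if not math.isnan(v) and (best is None or v > best):
                best = v
    if best is None:
        return math.inf
    for t, err in entries:  # entries sorted stringent (largest t) first
        if best >= t:
            return err
    return math.inf


def oracle_pauprc(pos_errs, neg_errs, errmax, prec_exp=0.5):
    """Trapezoid partial area from raw best-ERR lists."""
    nf, nb = len(pos_errs), len(neg_errs)
    grid = sorted(
        {e for e in list(pos_errs) + list(neg_errs) if math.isfinite(e) and e < errmax}
    )
    points = []
    for t in grid:
        tp = sum(1 for e in pos_errs if e <= t)
        fp = sum(1 for e in neg_errs if e <= t)
        if tp == 0 and fp == 0:
            continue
        tpr, fpr = tp / nf, fp / nb
        points.append((tpr, tpr / (tpr + fpr)))
    if not points:
        return 0.0
    total = 0.0
    prev_rec, prev_prec = 0.0, points[0][1]
    for rec, prec in points:
        total += ((prec + prev_prec) / 2.0 - prec_exp) * (rec - prev_rec)
        prev_rec, prev_prec = rec, prec
    return 2.0 * total


def _pearson(x, y):
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    vx = sxx - sx * sx / n
    vy = syy - sy * sy / n
    eps = 1e-12
    if vx < eps and vy < eps:
        return 1.0 if all(abs(a - b) < 1e-9 for a, b in zip(x, y)) else 0.0
    if vx < eps or vy < eps:
        return 0.0
    return (sxy - sx * sy / n) / math.sqrt(vx * vy)


def oracle_similarity(a_counts, b_counts, min_overlap_cols=4):
    """Max mean column Pearson over all placements and both orientations."""

    def freqs(counts):
        return [[v / sum(row) for v in row] for row in counts]

    def revcomp(freq):
        return [row[::-1] for row in freq[::-1]]

    fa = freqs(a_counts)
    fb0 = freqs(b_counts)
    la, lb = len(fa), len(fb0)
    minov = min(min_overlap_cols, la, lb)
    best = -math.inf
    for fb in (fb0, revcomp(fb0)):
        for shift in range(-lb + minov, la - minov + 1):
            lo, hi = max(0, shift), min(la, lb + shift)
            if hi - lo < minov:
                continue
            corrs = [_pearson(fa[i], fb[i - shift]) for i in range(lo, hi)]
            best = max(best, sum(corrs) / len(corrs))
    return best
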