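# Methods

This note records the model, its assumptions, all parameter defaults, the
numerical conventions, and the limits of the synthetic-data generator.

## Model and assumptions

The unit of analysis is a *motif pair* evaluated on a ChIP-seq peak set
(foreground, NF sequences) against a background set (NB sequences). The
method assumes:

- Peaks and background are comparable apart from binding signal. The
  generator (and the recommended practice) matches background to peaks in
  length exactly and in GC composition closely, at NB = 5·NF.
- A single best hit per sequence summarizes motif presence: the minimum
  best-ERR over all window offsets on both strands. Multiple-hit structure
  within one peak is not modeled.
- The reference set for calibration (genome promoters) is large enough that
  the empirical survival function of window scores is a stable estimate of
  the expected recognition rate. With the default 200 × 3 kb promoters and
  an 8-bp motif, ~1.2 M windows are scanned, so the smallest resolvable ERR
  is ~8·10⁻⁷.
- Motif models score windows independently; the only cross-model structure
  is the OR composition, which on the best-ERR scale is an elementwise
  minimum (idempotent, commutative, associative — verified by tests).

## Scoring and calibration

**PWM construction.** From an L×4 count matrix with background
probabilities bg (mononucleotide composition of the calibration set;
uniform fallback when the set is empty of ACGT):

    weight[i][b] = ln( (count[i][b] + pc·bg[b]) / (rowsum[i] + pc) / bg[b] )

with pseudocount pc = 1.0. A window score is the sum of per-position
weights; windows containing N are undefined and excluded from both the
numerator and the denominator of every ERR computation.

**Threshold vs. ERR table.** Every distinct observed window score in the
calibration set is a threshold; its ERR is the fraction of valid scanned
positions (both strands) scoring ≥ it. Entries with ERR above the table
ceiling (0.02) are dropped as useless. For very large calibration sets an
optional quantile grid (default 10,000 points, endpoints kept) bounds the
table size; the default keeps the exact table. A raw score maps to the ERR
of the most stringent tabulated threshold it clears; a score below every
threshold maps to the sentinel +inf ("never recognized"), which composes
correctly under the joint-motif minimum and under all comparisons.

**External models.** Models the package cannot score internally are
supplied as per-sequence window-score TSVs and treated identically.

## PR curves and areas

- Threshold grid: the distinct finite best-ERR values observed in the
  positive and negative profiles, restricted to ERR **strictly <** ERRMAX
  (default 0.002; recommended range 0.001–0.01).
- A sequence is recognized at grid point t when its best-ERR ≤ t
  (non-strict, so the sequence defining a grid point is counted at it).
- Corrected precision PREC = TP / (TP + FP·NF/NB); the point TP = FP = 0
  is undefined and such grid points are dropped.
- pAUPRC uses trapezoids above the 0.5 no-skill baseline, a virtual origin
  at (REC = 0, precision of the most stringent real point), and the factor
  2 so a perfect classifier scores exactly 1.0. Negative areas (classifiers
  worse than chance at stringent thresholds) are reported as-is.
- RAUC = pAUPRC(joint) / max(pAUPRC(A), pAUPRC(B)); NaN when the maximum
  is ≤ 0 (neither single motif shows skill, the ratio is meaningless).

## Similarity screen

A high RAUC is only evidence of mutually exclusive occurrence if the two
motifs are genuinely different. The screen computes the mean column-wise
Pearson correlation of frequency matrices over every relative offset and
both orientations, with minimum overlap min(4, min(LA, LB)). Degenerate
(zero-variance) columns: both flat and equal → r = 1; exactly one flat →
r = 0. A pair is flagged `redundant` when the best score ≥ 0.9 is achieved
at overlap ≥ 0.75·min(LA, LB); otherwise `distinct`; `na` when a motif has
no matrix (external model).

## Parameter defaults and rationale

| Parameter | Default | Rationale |
|---|---|---|
| ERRMAX | 0.002 | stringent-enough regime where PR differences reflect true sites; 0.001–0.01 reasonable |
| table ceiling | 0.02 | thresholds weaker than this never enter any analysis |
| pseudocount | 1.0 | standard background-weighted regularization |
| NB / NF | 5 | stabilizes FP counts; the corrected precision removes the ratio's bias |
| PREC_EXP | 0.5 | corrected no-skill baseline, independent of NF/NB |
| similarity threshold / overlap | 0.9 / 0.75·min(L) | flags near-identical matrices without catching composite motifs |
| synth: peaks / length | 500 × 300 bp | typical ChIP-seq peak-set scale |
| synth: promoters | 200 × 3 kb | ≥10⁶ calibration windows |

## Synthetic generator: what it does and does not emulate

It **does** provide: iid background at a target GC; exact-composition
GC- and length-matched negatives per peak; implantation of motif instances
(consensus verbatim, or column-sampled from a frequency matrix) at uniform
offsets on a uniform random strand, overwriting background; three regimes —
`independent` (two independent Bernoulli draws), `cooccur` (one shared
draw; requires equal rates), `exclusive` (at most one motif per peak;
requires rate_a + rate_b ≤ 1); non-overlapping placement when both motifs
land in one peak; a truth table with per-peak indicators, offsets and
strands; and Gaussian score mixtures (neg ~ N(mean 5, sd 2.5);
pos ~ 0.5·N(10, 1) + 0.5·N(5.5, 4)) for testing the calibration/PR
machinery without sequences.

It does **not** emulate: positional preference of sites within peaks,
dinucleotide or repeat structure of real genomic background, motif
instances with indels, overlapping/composite sites, or read-level noise.
Conclusions about the method's behavior on real data therefore rest on the
corrected-precision construction, not on the generator's realism.

Randomness uses named, decoupled streams
(`np.random.default_rng([stream_id, seed])` with fixed per-purpose stream
ids), so e.g. changing the implantation seed never perturbs the background
sequences.

## Numerical conventions

- Strictness: grid thresholds satisfy ERR < ERRMAX (strict); recognition at
  a threshold is best-ERR ≤ t (non-strict); `recognized_fraction` uses
  strict < ERRMAX.
- Sentinel: +inf for "no defined window" / "score below every threshold";
  NaN is confined to undefined raw window scores (N bases) and to RAUC when
  undefined.
- Ties: identical best-ERR values collapse into one grid point; ranking
  functions break RAUC ties by joint pAUPRC, then by name.
- ERR tables and PR curves are written with full `repr` float precision and
  roundtrip losslessly.
- Problem sizes exercised in the validation suite: ERR tables up to ~1.2 M
  windows, PR fixtures up to hundreds of sequences against brute-force
  oracles (agreement 1e-12 or exact), and a 20-seed × 2-regime recovery
  study at the default study conditions.

## Limitations

- Best-hit summarization ignores homotypic site clusters.
- RAUC compares the joint motif to the *better* single motif; a pair where
  one motif is uninformative can still reach RAUC slightly above 1 by
  chance — the recovery study's co-occurrence arm bounds this at ≈1.02
  under the default conditions.
- The similarity screen needs frequency matrices; external score-file
  models are never flagged redundant (`na`).
- ERR resolution is limited by the calibration-set size; thresholds rarer
  than one in the number of scanned windows cannot be represented.
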