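# Methods

## Consensus selection

Each PWM column `P` (probabilities over `n` characters, rows re-normalized
to sum to 1) is summarized by a character set. Writing `m` characters is
modelled as the perceived distribution `C(m)`: mass `1/m` on each of the
`m` most frequent characters. The minimal-JSD method selects

    m* = argmin_m  JSD(C(m), P) + (q/2)·m

with the Jensen–Shannon divergence in natural-log form,

    JSD(A, B) = ½ KLD(A, M) + ½ KLD(B, M),  M = ½(A + B),
    KLD(A, B) = Σ_j A(j) ln(A(j)/B(j)),

using the `0·ln 0 = 0` convention. The mixture `M` is strictly positive
wherever either argument is, so no pseudocounts are needed and
`0 ≤ JSD ≤ ln 2`. KLD is implemented in the standard weighted form: an
unweighted sum of log-ratios is constant in `A`'s weights and does not
define a divergence, and only the weighted form yields the guarantee that
`q = 1` forces `m* = 1` (checked as a property over random columns of
sizes 4 and 20).

Restricting the search to descending-frequency prefixes is lossless: among
all `m`-subsets, the uniform-over-subset distribution closest to `P` (by
JSD or MSE) is the one on the `m` largest probabilities. The test suite
asserts this against exhaustive subset search for alphabets up to size 6
rather than relying on the argument.

Numerical conventions:

* sorting ties (equal probabilities) break by alphabet order, so output is
  deterministic;
* objective ties break toward smaller `m` (the more definite consensus),
  which makes `m*(q)` exactly non-increasing in `q`;
* the penalty enters as `(q/2)·m` and applies identically to the JSD and
  MSE objectives; it is ignored with a logged warning for the rule-based
  Cavener and max methods;
* Cavener's thresholds (0.50, twice the runner-up, 0.75) are strict
  inequalities; boundary values fall through to the next rule. Cavener is
  defined only for 4-letter nucleotide alphabets and errors otherwise;
  exactly the three classical rules are implemented, with no additional
  margin requirement on the second rule.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `penalty_q` | 0 | ambiguity penalty in [0, 1]; 0 = pure information loss, 1 = single character per position |
| `max_characters` | none | hard cap on characters per position; the search simply stops at that prefix length |
| style | `compact` | `regex` spells out `[ACGT]`; `compact` writes `N`; `iupac` uses single ambiguity codes (4-letter nucleotide alphabets only) |
| trim | off | drop full-alphabet columns at both ends only; an all-N motif trims to the empty string with a warning |

MEME input: rows whose raw sum is within 0.05 of 1 are silently
re-normalized (published files routinely carry 3-decimal rounding); larger
deviations raise, since they usually indicate a count matrix. Background
frequency lines are parsed into record metadata but unused — the
conversion depends only on the probability matrix. Missing `ALPHABET=`
lines default to DNA with a warning. The `compact` style for
protein/custom alphabets degrades to `regex` with a warning (no N
convention exists there); `iupac` raises instead because single-code
output would be meaningless.

## Occurrence scanning

The PWM scanner scores every window on both strands by natural-log
log-odds against an i.i.d. background (uniform by default, overridable).
Zero PWM cells are floored at 1e-4 for scoring only. Scores are rounded to
bins of 1e-3 nats, and the exact null distribution of the window score is
the position-wise convolution of per-position score distributions under
the background — the same dynamic program used by conventional scanners.
P-values are survival probabilities P(score ≥ s); windows with p < 1e-5
(default) become sites scored −log10 p. Significance uses base-10 logs; a
constant log-base factor cannot change precision–recall ordering.
Consensus regex scanning reports every (possibly overlapping) match on
both strands at one-base steps, the reverse strand via the
reverse-complemented sequence with coordinates mapped back; consensus
matches have no intrinsic p-value and carry score 0. Coordinates are
0-based half-open; BED6 output encodes scores as
`round(1000·min(1, −log10 p / 10))`.

## Benchmark design

For each motif, PWM-scan hits are the truth sites; a consensus site
matching a truth site exactly (sequence, interval, strand — both scans
emit width-k windows, so fuzzy matching is unnecessary) inherits its
−log10 p score; other consensus sites are false positives with score 0;
unmatched truth sites are misses. Precision is traced over recall with
descending score threshold (tied scores enter together, so all score-0
false positives arrive in one final group) and integrated by the trapezoid
rule, starting the curve at recall 0 with the precision of the top-scoring
group. Scoring unmatched consensus sites at 0 is one defensible reading of
ranking sites without a scan p-value; since every false positive then sits
below every true positive's score, it gives the consensus the benefit of
the ranking and affects all methods identically. Empty-truth motifs yield
an undefined auPRC and are excluded from pairing (and listed in the
report). Methods are compared by mean auPRC and a paired-by-motif t-test
(`scipy.stats.ttest_rel`); zero-variance differences report a missing
p-value with a warning rather than a fabricated statistic.

## Synthetic data

Random motifs draw each column i.i.d. from a symmetric Dirichlet; the
concentration parameter is the single knob for information content
(0.05 ≈ near-deterministic columns, 100 ≈ near-uniform). The benchmark
uses concentration 0.5 and width 12, giving the mix of sharp and ambiguous
columns typical of curated TF motifs. The synthetic genome is i.i.d.
uniform-background sequence with instances sampled column-wise from each
PWM planted without overlap at recorded positions, half on the reverse
strand.

Benchmark problem size: 3 seeds (11, 12, 13), 50 motifs per seed, one 1 Mb
genome per seed, 50 planted instances per motif — large enough that mean
auPRC differences between methods are stable across seeds, small enough to
run on one CPU in a few minutes. The generator emulates none of the
correlated structure of real genomes (repeats, GC skew, motif clustering,
overlapping/degenerate motif families) and the i.i.d. Dirichlet columns
ignore inter-position dependence within motifs; the benchmark therefore
shows that the method ordering (JSD ≥ MSE/Cavener ≥ max, and penalty 0 ≥
penalty 0.5) is reproduced under clean planted-signal conditions, not that
any particular auPRC value transfers to genome-scale scans of curated
motif collections.

## Worked-example fixtures

The packaged fixtures contain two published frequency columns — the P73
position-2 column (0.077, 0, 0.726, 0.197) and the near-uniform column
(0.26, 0.25, 0.25, 0.24) — embedded in otherwise synthetic matrices. The
GATA2-like fixture is fully synthetic: pair columns (0.48, 0.44, 0.05,
0.03), single-character columns (0.90, 0.05, 0.03, 0.02), and a triple
(0.35, 0.33, 0.30, 0.02), chosen so minimal-JSD at q = 0 selects the
intended sets with a comfortable margin; its regex rendering is
`[GC][AT]GATAAG[GAC]`.

## Known limitations

* Per-position independence is assumed throughout; no cross-column
  dependencies, no information-content weighting of columns.
* Perceived distributions are uniform over the selected set; graded
  (non-uniform) consensus weights are out of scope.
* The scanner's p-values are exact only up to the 1e-3-nat discretization
  (tests bound the error by one bin against exhaustive enumeration for
  k ≤ 8).
* Trimming removes only exact full-alphabet columns, not
  nearly-full-alphabet ones.
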