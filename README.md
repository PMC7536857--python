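# pwmconsensus

Convert motif position weight matrices (PWMs) into wildcard-style consensus
sequences — `[GC][AT]GATAAG[GAC]` rather than a k×4 probability table —
while losing as little information as possible, and measure how faithfully
each consensus recovers the motif's occurrence sites.

Intended for anyone who works with sequence motifs: regulatory genomicists
labelling de-novo motifs, people feeding consensus patterns to genome
browsers or oligo-synthesis vendors, and tool builders who need a compact
textual stand-in for a PWM.

## The method

A PWM column is a probability vector `P` over the `n` alphabet characters
(DNA, RNA, protein, or a custom character set). Writing `m` characters at
that position of a consensus replaces `P` with the *perceived* distribution
`C(m)`: uniform mass `1/m` on the `m` most frequent characters, zero
elsewhere. The minimal-JSD method chooses

```
m* = argmin_m  JSD(C(m), P) + (q/2)·m ,     m = 1…n
```

where JSD is the Jensen–Shannon divergence (natural log, bounded by ln 2)
and `q ∈ [0, 1]` is an ambiguity penalty: `q = 0` (the default) minimizes
pure information loss, `q = 1` always forces a single character, exactly
reproducing the max-frequency method. Because the perceived mass is
uniform, the optimal character set is always a descending-frequency prefix,
so only `n` candidates per position need evaluating — the test suite
verifies this against brute-force search over all `2^n − 1` subsets.

Comparators included: minimal mean squared error (same search, MSE
objective), Cavener's 1987 rules (top character if > 0.50 and > 2× the
runner-up; top pair if their sum > 0.75; else N), and max frequency.

A planted-motif benchmark scores each method: consensus regex matches are
compared against "truth" sites from an exact-p-value PWM scan (discretized
log-odds null distribution, p < 1e-5) by area under the precision–recall
curve, paired per motif.

## Worked example

The bundled fixtures include a motif whose second column is the published
P73 frequency column (A 0.077, C 0, G 0.726, T 0.197):

```console
$ pwmconsensus convert examples.meme
P73_example     G[GT]GC
near_uniform    N
GATA2_like      [GC][AT]GATAAG[GAC]

$ pwmconsensus convert -m max examples.meme
P73_example     GGGC
near_uniform    A
GATA2_like      GAGATAAGG

$ pwmconsensus convert -s iupac examples.meme
P73_example     GKGC
near_uniform    N
GATA2_like      SWGATAAGV
```

At the P73 column the per-m JSD values are 0.106, 0.071, 0.089, 0.173, so
`m* = 2` and the consensus keeps {G, T} (`[GT]`, IUPAC `K`): G alone would
overstate certainty, three characters would dilute it. The near-uniform
column (0.26, 0.25, 0.25, 0.24) correctly becomes `N`, where max frequency
misleadingly reports `A`.

Flags mirror the library: `-m/--method` (jsd, mse, cavener, max),
`-s/--style` (iupac, regex, compact), `-t/--trim`, `-p/--penalty`,
`--maxCharacter`. Input is a MEME-format file or standard input; output is
TSV (name, consensus). `pwmconsensus generate` writes random synthetic
motifs; `pwmconsensus benchmark` runs the planted-motif evaluation.

Library use:

```python
from pwmconsensus import parse_meme, convert_motif, render, MethodConfig

motifs = parse_meme(open("examples.meme"))
cols = convert_motif(motifs[0], MethodConfig("jsd", penalty_q=0.0))
print(render(cols, motifs[0].alphabet))  # G[GT]GC
```

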