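"""Motif occurrence scanning: exact-p-value PWM scans and consensus regex scans.

The PWM scanner scores every window on both strands by log-odds against an
i.i.d. background and converts scores to p-values with the exact
discretized score distribution: per-position log-odds are rounded to a
fixed granularity and the null distribution of the window score is built by
position-wise convolution under the background, the same dynamic program
used by standard scanners such as FIMO.  Windows with p below the cutoff
become :class:`OccurrenceSite` records scored ``-log10 p``.

The consensus scanner finds every (possibly overlapping) regex match on
both strands, with the reverse strand searched on the reverse-complemented
sequence and coordinates mapped back.  Consensus matches carry no
intrinsic significance, so their score is 0.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core import ConsensusColumn
from .io import MotifRecord
from .render import RenderConfig, render

logger = logging.getLogger(__name__)

__all__ = [
    "OccurrenceSite",
    "ScoreDistribution",
    "scan_pwm",
    "scan_consensus",
    "sites_to_bed",
]

#: log-odds discretization bin width (nats)
GRANULARITY = 1e-3
#: pseudocount substituted for zero PWM cells when scoring
SCORE_PSEUDOCOUNT = 1e-4


@dataclass(frozen=True)
class OccurrenceSite:
    """A located motif match: 0-based half-open interval plus strand.

    ``score`` is the significance ``-log10 p`` for PWM scan hits and 0 for
    consensus regex matches (which carry no p-value).
    """

    sequence_id: str
    start: int
    end: int
    strand: str
    score: float = 0.0

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.sequence_id, self.start, self.end, self.strand)


class ScoreDistribution:
    """Exact null distribution of a discretized PWM log-odds score.

    Log-odds values are rounded to integer multiples of ``granularity``;
    the distribution of the width-k window score under an i.i.d. background
    is the k-fold convolution of the per-position score distributions,
    computed by shifting and accumulating a dense probability array.
    ``pvalue`` returns the survival probability P(score >= s).
    """

    def __init__(self, int_scores: np.ndarray, background: np.ndarray,
                 granularity: float = GRANULARITY) -> None:
        int_scores = np.asarray(int_scores, dtype=np.int64)
        background = np.asarray(background, dtype=float)
        k, n = int_scores.shape
        if background.shape != (n,):
            raise ValueError("background length must match alphabet size")
        self.granularity = granularity
        self.int_scores = int_scores

        mins = int_scores.min(axis=1)
        pmf = np.array([1.0])
        lo = 0
        for i in range(k):
            offs = int_scores[i] - mins[i]
            width = int(offs.max())
            new = np.zeros(pmf.size + width)
            for j in range(n):
                new[offs[j]:offs[j] + pmf.size] += background[j] * pmf
            pmf = new
            lo += int(mins[i])
        self.lo = lo
        self.pmf = pmf
        # survival function: P(score >= lo + t)
        self.sf = np.cumsum(pmf[::-1])[::-1]

    def pvalue(self, int_score: np.ndarray | int) -> np.ndarray | float:
        """P(score >= int_score) under the background model."""
        s = np.asarray(int_score, dtype=np.int64)
        idx = s - self.lo
        out = np.where(
            idx < 0, 1.0,
            np.where(idx >= self.sf.size, 0.0, self.sf[np.clip(idx, 0, self.sf.size - 1)]),
        )
        return float(out) if np.isscalar(int_score) or s.ndim == 0 else out


def _log_odds_bins(motif: MotifRecord, background: np.ndarray,
                   granularity: float = GRANULARITY) -> np.ndarray:
    probs = np.maximum(motif.matrix, SCORE_PSEUDOCOUNT)
    lods = np.log(probs / background)
    return np.rint(lods / granularity).astype(np.int64)


def _encode(sequence: str, characters: tuple[str, ...]) -> np.ndarray:
    lut = np.full(256, -1, dtype=np.int64)
    for j, c in enumerate(characters):
        lut[ord(c)] = j
        lut[ord(c.lower())] = j
    codes = lut[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    return codes


def _window_scores(codes: np.ndarray, int_scores: np.ndarray) -> np.ndarray:
    k = int_scores.shape[0]
    nwin = codes.size - k + 1
    scores = np.zeros(nwin, dtype=np.int64)
    valid = np.ones(nwin, dtype=bool)
    for i in range(k):
        c = codes[i:i + nwin]
        bad = c < 0
        valid &= ~bad
        scores += int_scores[i][np.where(bad, 0, c)]
    scores[~valid] = np.iinfo(np.int64).min  # windows with unknown characters
    return scores


def scan_pwm(motif: MotifRecord, sequences: Mapping[str, str],
             p_cutoff: float = 1e-5,
             background: np.ndarray | None = None) -> list[OccurrenceSite]:
    """Scan sequences with a PWM; report sites with exact p-value < cutoff.

    Both strands are scanned for complementable (nucleotide) alphabets.
    Returned sites are scored ``-log10 p``.
    """
    if not 0.0 < p_cutoff < 1.0:
        raise ValueError("p_cutoff must be in (0, 1)")
    n = motif.alphabet.size
    bg = np.full(n, 1.0 / n) if background is None else np.asarray(background, float)
    bg = bg / bg.sum()
    int_scores = _log_odds_bins(motif, bg)
    dist = ScoreDistribution(int_scores, bg)
    k = motif.width

    strands = [("+", int_scores)]
    if motif.alphabet.complement_map is not None:
        # reverse-complement scan == scanning with the reverse-complemented matrix
        comp_idx = np.array(
            [motif.alphabet.index(motif.alphabet.complement(c))
             for c in motif.alphabet.characters]
        )
        rc_scores = int_scores[::-1][:, comp_idx]
        strands.append(("-", rc_scores))

    sites: list[OccurrenceSite] = []
    any_wide_enough = False
    for seq_id, seq in sequences.items():
        if len(seq) < k:
            continue
        any_wide_enough = True
        codes = _encode(seq, motif.alphabet.characters)
        for strand, mat in strands:
            scores = _window_scores(codes, mat)
            pvals = np.asarray(dist.pvalue(scores))
            hits = np.nonzero(pvals < p_cutoff)[0]
            for pos in hits:
                sites.append(
                    OccurrenceSite(
                        sequence_id=seq_id,
                        start=int(pos),
                        end=int(pos) + k,
                        strand=strand,
                        score=float(-np.log10(pvals[pos])),
                    )
                )
    if not any_wide_enough:
        logger.warning("motif %s (width %d) is wider than every sequence",
                       motif.name, k)
    sites.sort(key=lambda s: (s.sequence_id, s.start, s.strand))
    return sites


def consensus_regex(columns: list[ConsensusColumn], motif: MotifRecord) -> str:
    """Regex-style rendering of consensus columns, suitable for re.compile."""
    return render(columns, motif.alphabet, RenderConfig(style="regex"))


def scan_consensus(pattern: str, sequences: Mapping[str, str],
                   alphabet=None) -> list[OccurrenceSite]:
    """Find all (overlapping) regex matches on both strands, score 0.

    ``pattern`` is a consensus regex (bare characters and bracket classes,
    fixed width).  The reverse strand is searched by scanning the
    reverse-complemented sequence and mapping coordinates back; this
    requires an alphabet with a complement map (defaults to DNA).
    """
    from .alphabet import DNA

    alphabet = alphabet or DNA
    # fixed-width pattern: width = number of top-level tokens
    width = len(re.findall(r"\[[^\]]+\]|[^\[\]]", pattern))
    overlap = re.compile(f"(?=({pattern}))", re.IGNORECASE)

    sites: list[OccurrenceSite] = []
    for seq_id, seq in sequences.items():
        L = len(seq)
        for m in overlap.finditer(seq):
            sites.append(OccurrenceSite(seq_id, m.start(), m.start() + width, "+"))
        if alphabet.complement_map is not None:
            rc = alphabet.reverse_complement(seq)
            for m in overlap.finditer(rc):
                start = L - m.start() - width
                sites.append(OccurrenceSite(seq_id, start, start + width, "-"))
    sites.sort(key=lambda s: (s.sequence_id, s.start, s.strand))
    return sites


def sites_to_bed(sites: list[OccurrenceSite], name: str) -> str:
    """BED6 text for a site list; score = round(1000 * min(1, -log10 p / 10))."""
    lines = []
    for s in sites:
        bed_score = int(round(1000 * min(1.0, s.score / 10.0)))
        lines.append(f"{s.sequence_id}\t{s.start}\t{s.end}\t{name}\t{bed_score}\t{s.strand}")
    return "\n".join(lines) + ("\n" if lines else "")
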