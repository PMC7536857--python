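"""Synthetic motif generation and packaged worked-example fixtures.

Random motifs draw each column independently from a symmetric Dirichlet:
small concentration gives sharp, information-rich columns (one dominant
character), large concentration gives near-uniform, ambiguous columns.
This single knob spans the range of column sharpness seen in curated TF
motif databases and makes every other module testable without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import DNA, Alphabet
from .io import MotifRecord

__all__ = ["MotifGeneratorConfig", "random_motifs", "worked_example_motifs"]


@dataclass(frozen=True)
class MotifGeneratorConfig:
    """Knobs for the random-motif generator.

    concentration is the symmetric Dirichlet parameter per column: 0.05 is
    near-deterministic, 1.0 is flat-prior, 100 is near-uniform.
    """

    alphabet: Alphabet = DNA
    width: int = 12
    concentration: float = 0.5
    count: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("width must be >= 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if self.count < 0:
            raise ValueError("count must be >= 0")


def random_motifs(config: MotifGeneratorConfig) -> list[MotifRecord]:
    """Draw ``count`` random motifs, reproducibly for a given seed."""
    rng = np.random.default_rng(config.seed)
    n = config.alphabet.size
    out = []
    for i in range(config.count):
        mat = rng.dirichlet([config.concentration] * n, size=config.width)
        mat = mat / mat.sum(axis=1, keepdims=True)
        out.append(
            MotifRecord(
                name=f"synthetic_{i:03d}",
                alphabet=config.alphabet,
                matrix=mat,
                source_metadata={"generator": f"dirichlet({config.concentration:g})",
                                 "seed": str(config.seed)},
            )
        )
    return out


# Fixture columns. Only the P73 position-2 frequencies (0.077, 0, 0.726,
# 0.197) and the near-uniform (0.26, 0.25, 0.25, 0.24) column are published
# values; every other cell below is a synthetic construction chosen so the
# minimal-JSD method (q=0) selects the intended character set.
_SHARP = {  # single-character columns, m*=1
    "A": [0.90, 0.05, 0.03, 0.02],
    "C": [0.05, 0.90, 0.03, 0.02],
    "G": [0.05, 0.03, 0.90, 0.02],
    "T": [0.05, 0.03, 0.02, 0.90],
}


def _pair(first: str, second: str) -> list[float]:
    # m*=2 column: 0.48/0.44 on the pair, 0.05/0.03 on the rest
    rest = [c for c in "ACGT" if c not in (first, second)]
    probs = dict.fromkeys("ACGT", 0.0)
    probs[first], probs[second] = 0.48, 0.44
    probs[rest[0]], probs[rest[1]] = 0.05, 0.03
    return [probs[c] for c in "ACGT"]


def _triple(chars: str) -> list[float]:
    # m*=3 column: 0.35/0.33/0.30 on the triple in the given order
    rest = [c for c in "ACGT" if c not in chars][0]
    probs = dict.fromkeys("ACGT", 0.0)
    for c, p in zip(chars, (0.35, 0.33, 0.30)):
        probs[c] = p
    probs[rest] = 0.02
    return [probs[c] for c in "ACGT"]


def worked_example_motifs() -> list[MotifRecord]:
    """Three small packaged fixtures (synthetic except where noted).

    * ``P73_example`` — a 4-position DNA motif whose second position is the
      published P73 frequency column (A 0.077, C 0, G 0.726, T 0.197); the
      minimal-JSD consensus there is {G, T}.
    * ``near_uniform`` — a single near-uniform column (0.26, 0.25, 0.25,
      0.24), the motivating failure case for max-frequency consensus.
    * ``GATA2_like`` — a 9-position motif whose q=0 minimal-JSD regex
      rendering is ``[GC][AT]GATAAG[GAC]``.
    """
    p73 = MotifRecord(
        name="P73_example",
        alphabet=DNA,
        matrix=np.array(
            [
                _SHARP["G"],
                [0.077, 0.0, 0.726, 0.197],  # published frequencies
                _SHARP["G"],
                _SHARP["C"],
            ]
        ),
    )
    near_uniform = MotifRecord(
        name="near_uniform",
        alphabet=DNA,
        matrix=np.array([[0.26, 0.25, 0.25, 0.24]]),
    )
    gata2 = MotifRecord(
        name="GATA2_like",
        alphabet=DNA,
        matrix=np.array(
            [
                _pair("G", "C"),
                _pair("A", "T"),
                _SHARP["G"],
                _SHARP["A"],
                _SHARP["T"],
                _SHARP["A"],
                _SHARP["A"],
                _SHARP["G"],
                _triple("GAC"),
            ]
        ),
    )
    return [p73, near_uniform, gata2]
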