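"""Per-position consensus character-set selection for motif matrices.

Given one column ``P`` of a position weight matrix (a probability vector
over the ``n`` alphabet characters), a consensus representation replaces
``P`` with a *perceived* distribution ``C(m)``: uniform mass ``1/m`` over
the ``m`` most frequent characters and zero elsewhere.  The minimal-JSD
method picks the ``m`` whose perceived distribution loses the least
information relative to ``P``:

    m* = argmin_m  D(C(m), P) + (q/2) * m

where ``D`` is the Jensen-Shannon divergence (natural log) and
``q in [0, 1]`` is an ambiguity penalty favouring fewer characters; ``q=1``
always yields ``m*=1`` (the single most frequent character), recovering the
max-frequency method.  A minimal-MSE variant substitutes mean squared error
for ``D``.  Because the perceived mass is uniform, the optimal character
set is always a descending-frequency prefix, so only ``n`` candidates need
to be evaluated instead of ``2^n - 1`` subsets (a property the test suite
verifies against brute-force subset search).

Two classical baselines are included: Cavener's 1987 rules (single
character if its frequency exceeds 0.50 and twice the runner-up; top pair
if their sum exceeds 0.75; else the full set ``N``) and the naive
max-frequency method.

Notes on the divergence: KLD is the standard weighted form
``sum_j A(j) ln(A(j)/B(j))`` with the ``0 ln 0 = 0`` convention, and
``JSD(A, B) = KLD(A, M)/2 + KLD(B, M)/2`` with ``M = (A+B)/2``.  The
mixture is strictly positive wherever either argument is, so JSD never
needs pseudocounts and is bounded by ``ln 2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import MotifRecord

logger = logging.getLogger(__name__)

__all__ = [
    "METHODS",
    "ColumnDistribution",
    "MethodConfig",
    "ConsensusColumn",
    "kl_divergence",
    "js_divergence",
    "mean_squared_error",
    "select_m_star",
    "cavener_column",
    "max_column",
    "convert_column",
    "convert_motif",
]

METHODS = ("jsd", "mse", "cavener", "max")


def kl_divergence(a: np.ndarray, b: np.ndarray) -> float:
    """Kullback-Leibler divergence ``sum_j a_j ln(a_j / b_j)`` (nats).

    Terms with ``a_j = 0`` contribute zero; ``a_j > 0`` with ``b_j = 0``
    raises, since the divergence is then infinite.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    support = a > 0
    if np.any(b[support] <= 0):
        raise ValueError("KL divergence undefined: a > 0 where b = 0")
    av = a[support]
    return float(np.sum(av * np.log(av / b[support])))


def js_divergence(a: np.ndarray, b: np.ndarray) -> float:
    """Jensen-Shannon divergence, natural log: symmetric, in ``[0, ln 2]``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    m = 0.5 * (a + b)
    return 0.5 * kl_divergence(a, m) + 0.5 * kl_divergence(b, m)


def mean_squared_error(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared difference ``(1/n) sum_j (a_j - b_j)^2``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


@dataclass(frozen=True)
class ColumnDistribution:
    """One PWM column with its descending-frequency character order.

    ``order`` is a permutation of character indices such that
    ``probs[order[0]] >= probs[order[1]] >= ...``; ties are broken by
    alphabet order, making everything downstream deterministic.
    """

    probs: np.ndarray
    order: np.ndarray

    @classmethod
    def from_probs(cls, probs: np.ndarray) -> "ColumnDistribution":
        p = np.asarray(probs, dtype=float)
        if p.ndim != 1 or p.size < 2:
            raise ValueError("column must be a 1-D probability vector, length >= 2")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"column probabilities sum to {p.sum()}, not 1")
        # stable sort on -p keeps alphabet order among ties
        order = np.argsort(-p, kind="stable")
        return cls(probs=p, order=order)

    @property
    def sorted_probs(self) -> np.ndarray:
        return self.probs[self.order]


@dataclass(frozen=True)
class MethodConfig:
    """Conversion method plus its tuning knobs.

    ``penalty_q`` is the ambiguity penalty in [0, 1]; it enters the
    objective as ``(q/2) * m`` and only affects the jsd and mse methods.
    ``max_characters`` caps the number of characters per position.
    """

    method: str = "jsd"
    penalty_q: float = 0.0
    max_characters: int | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if not 0.0 <= self.penalty_q <= 1.0:
            raise ValueError(f"penalty_q must be in [0, 1], got {self.penalty_q}")
        if self.max_characters is not None and self.max_characters < 1:
            raise ValueError("max_characters must be >= 1")

    @property
    def label(self) -> str:
        if self.method in ("jsd", "mse") and self.penalty_q != 0.0:
            return f"{self.method}(q={self.penalty_q:g})"
        return self.method


@dataclass(frozen=True)
class ConsensusColumn:
    """The chosen character set for one motif position.

    ``characters`` lists the ``m_star`` selected characters in descending
    frequency; ``per_m_divergence`` holds the raw divergence for every
    candidate prefix size (None for the rule-based cavener/max methods,
    which optimize nothing).
    """

    m_star: int
    characters: tuple[str, ...]
    objective_value: float
    per_m_divergence: tuple[float, ...] | None = None
    indices: tuple[int, ...] = field(default=(), compare=False)

    @property
    def charset(self) -> frozenset[str]:
        return frozenset(self.characters)


def _perceived(n: int, m: int) -> np.ndarray:
    c = np.zeros(n)
    c[:m] = 1.0 / m
    return c


def select_m_star(col: ColumnDistribution, config: MethodConfig,
                  characters: tuple[str, ...] | None = None) -> ConsensusColumn:
    """Minimize divergence-plus-penalty over descending-frequency prefixes.

    Evaluates ``D(C(m), P) + (q/2) m`` for ``m = 1..min(n, max_characters)``
    with D = JSD or MSE per ``config.method`` and returns the minimizing
    prefix; objective ties go to the smaller ``m`` (the more definite
    consensus), which makes ``m*(q)`` exactly non-increasing in ``q``.
    ``per_m_divergence`` reports raw D for every ``m`` up to ``n`` even when
    ``max_characters`` restricts the search.
    """
    if config.method not in ("jsd", "mse"):
        raise ValueError(f"select_m_star requires jsd or mse, got {config.method!r}")
    divergence = js_divergence if config.method == "jsd" else mean_squared_error
    p_sorted = col.sorted_probs
    n = p_sorted.size
    m_cap = n if config.max_characters is None else min(n, config.max_characters)

    raw = np.array([divergence(_perceived(n, m), p_sorted) for m in range(1, n + 1)])
    objective = raw + 0.5 * config.penalty_q * np.arange(1, n + 1)
    m_star = int(np.argmin(objective[:m_cap])) + 1  # argmin takes first == smallest m

    idx = tuple(int(j) for j in col.order[:m_star])
    if characters is None:
        chars = tuple(str(j) for j in idx)
    else:
        chars = tuple(characters[j] for j in idx)
    return ConsensusColumn(
        m_star=m_star,
        characters=chars,
        objective_value=float(objective[m_star - 1]),
        per_m_divergence=tuple(float(v) for v in raw),
        indices=idx,
    )


def cavener_column(col: ColumnDistribution,
                   characters: tuple[str, ...] | None = None) -> ConsensusColumn:
    """Cavener's 1987 heuristic rules (4-letter nucleotide alphabets only).

    Single top character if its frequency strictly exceeds 0.50 *and*
    strictly exceeds twice the second-highest; else the top pair if their
    sum strictly exceeds 0.75; else the full set (N).  Boundary values fall
    through to the next rule.
    """
    p = col.sorted_probs
    n = p.size
    if n != 4:
        raise ValueError(
            "Cavener's rules are defined only for 4-letter nucleotide "
            f"alphabets, got {n} characters"
        )
    if p[0] > 0.50 and p[0] > 2.0 * p[1]:
        m = 1
    elif p[0] + p[1] > 0.75:
        m = 2
    else:
        m = 4
    idx = tuple(int(j) for j in col.order[:m])
    chars = tuple((characters[j] if characters else str(j)) for j in idx)
    return ConsensusColumn(m_star=m, characters=chars, objective_value=float("nan"),
                           per_m_divergence=None, indices=idx)


def max_column(col: ColumnDistribution,
               characters: tuple[str, ...] | None = None) -> ConsensusColumn:
    """Single most frequent character (ties broken by alphabet order)."""
    j = int(col.order[0])
    chars = (characters[j] if characters else str(j),)
    return ConsensusColumn(m_star=1, characters=chars, objective_value=float("nan"),
                           per_m_divergence=None, indices=(j,))


def convert_column(probs: np.ndarray, config: MethodConfig,
                   characters: tuple[str, ...] | None = None) -> ConsensusColumn:
    """Apply the configured method to a single probability column."""
    col = ColumnDistribution.from_probs(probs)
    if config.method in ("jsd", "mse"):
        return select_m_star(col, config, characters)
    if config.method == "cavener":
        return cavener_column(col, characters)
    return max_column(col, characters)


def convert_motif(motif: MotifRecord, config: MethodConfig) -> list[ConsensusColumn]:
    """Convert every position of a motif independently.

    The optimum at each position depends only on that column, so the result
    is one :class:`ConsensusColumn` per motif position, in order.  The
    ambiguity penalty is ignored (with a warning) for the rule-based
    cavener and max methods.
    """
    if config.method in ("cavener", "max") and config.penalty_q != 0.0:
        logger.warning(
            "penalty_q=%g has no effect with method %r; ignoring",
            config.penalty_q, config.method,
        )
    chars = motif.alphabet.characters
    return [convert_column(row, config, chars) for row in motif.matrix]
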