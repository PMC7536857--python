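"""Render per-position consensus columns as text.

Three styles:

* ``iupac`` — one ambiguity code per position (S for {C,G}, N for the full
  set, ...); nucleotide alphabets only.
* ``regex`` — a bare character for single-character positions, a bracket
  class ``[GT]`` otherwise, characters in descending frequency order.
* ``compact`` (default) — regex, but a full-alphabet position renders as
  ``N`` instead of ``[ACGT]``; non-nucleotide alphabets fall back to regex
  with a warning since no N convention exists for them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .alphabet import Alphabet
from .core import ConsensusColumn

logger = logging.getLogger(__name__)

__all__ = ["STYLES", "RenderConfig", "render", "trim_consensus"]

STYLES = ("iupac", "regex", "compact")


@dataclass(frozen=True)
class RenderConfig:
    """Output style plus the trim flag (drop full-alphabet ends)."""

    style: str = "compact"
    trim: bool = False

    def __post_init__(self) -> None:
        if self.style not in STYLES:
            raise ValueError(f"unknown style {self.style!r}; choose from {STYLES}")


def trim_consensus(columns: list[ConsensusColumn], alphabet: Alphabet) -> list[ConsensusColumn]:
    """Drop leading and trailing full-alphabet (N) columns.

    Interior full-alphabet columns are kept.  If every column is the full
    alphabet the result is empty (logged as a warning by :func:`render`).
    """
    n = alphabet.size
    lo = 0
    hi = len(columns)
    while lo < hi and columns[lo].m_star == n:
        lo += 1
    while hi > lo and columns[hi - 1].m_star == n:
        hi -= 1
    return columns[lo:hi]


def _render_column(col: ConsensusColumn, alphabet: Alphabet, style: str) -> str:
    if style == "iupac":
        table = alphabet.iupac_table
        assert table is not None
        return table[col.charset]
    if col.m_star == 1:
        return col.characters[0]
    if style == "compact" and col.m_star == alphabet.size:
        return "N"
    return "[" + "".join(col.characters) + "]"


def render(columns: list[ConsensusColumn], alphabet: Alphabet,
           config: RenderConfig | None = None) -> str:
    """Render consensus columns to a single string in the configured style."""
    config = config or RenderConfig()
    style = config.style
    if style == "iupac":
        if not (alphabet.is_nucleotide and alphabet.iupac_table and alphabet.size == 4):
            raise ValueError(
                "iupac style requires a 4-letter nucleotide alphabet, "
                f"got {alphabet.kind} ({alphabet.size} characters)"
            )
    if style == "compact" and not alphabet.is_nucleotide:
        logger.warning(
            "compact style has no N convention for %s alphabets; using regex",
            alphabet.kind,
        )
        style = "regex"
    if config.trim:
        columns = trim_consensus(columns, alphabet)
        if not columns:
            logger.warning("all positions are full-alphabet; trimmed consensus is empty")
            return ""
    if not columns:
        raise ValueError("no consensus columns to render")
    return "".join(_render_column(c, alphabet, style) for c in columns)
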