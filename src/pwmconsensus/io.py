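"""Reading and writing motifs in MEME minimal text format.

The MEME minimal format is the de-facto exchange format for motif
probability matrices: a version line, an ``ALPHABET=`` declaration, optional
background letter frequencies, then one ``MOTIF`` block per motif with a
``letter-probability matrix:`` header followed by one row of probabilities
per motif position.  This module parses that format over arbitrary
alphabets (DNA, RNA, protein, or custom character sets), validates the
matrices, and writes records back out such that a parse/write round trip is
the identity to 1e-6 per cell.

Rows whose raw sum deviates from 1 by at most 0.05 (routine 3-decimal
rounding in published files) are silently re-normalized; a larger deviation
signals a count matrix or a corrupt file and raises.
"""

from __future__ import annotations

import io as _io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import numpy as np

from .alphabet import DNA, Alphabet, infer_alphabet

logger = logging.getLogger(__name__)

__all__ = [
    "MotifRecord",
    "MemeParseError",
    "MotifDimensionError",
    "parse_meme",
    "parse_meme_text",
    "write_meme",
    "write_meme_text",
]

#: rows whose raw sum is within this of 1 are re-normalized; beyond it we raise
ROW_SUM_SLACK = 0.05


class MemeParseError(ValueError):
    """Malformed MEME structure (version line, ALPHABET line, headers)."""


class MotifDimensionError(ValueError):
    """Matrix row length or row count inconsistent with the declared motif."""


@dataclass
class MotifRecord:
    """A named position weight matrix.

    Parameters
    ----------
    name
        Motif identifier.
    alphabet
        The :class:`~pwmconsensus.alphabet.Alphabet` the columns refer to.
    matrix
        ``(k, n)`` array of probabilities, one row per motif position; rows
        must sum to 1 within 1e-4 and are re-normalized to sum exactly.
    source_metadata
        Free-form key/value strings carried over from the source file
        (version, strands, background frequencies, nsites, E-value).
    """

    name: str
    alphabet: Alphabet
    matrix: np.ndarray
    source_metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2:
            raise MotifDimensionError(f"motif {self.name!r}: matrix must be 2-D")
        k, n = mat.shape
        if k < 1:
            raise MotifDimensionError(f"motif {self.name!r}: needs at least one position")
        if n != self.alphabet.size:
            raise MotifDimensionError(
                f"motif {self.name!r}: {n} columns but alphabet has "
                f"{self.alphabet.size} characters"
            )
        if np.any(mat < 0) or np.any(mat > 1):
            raise ValueError(f"motif {self.name!r}: probabilities must lie in [0, 1]")
        sums = mat.sum(axis=1)
        bad = np.abs(sums - 1.0) > 1e-4
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"motif {self.name!r}: row {i + 1} sums to {sums[i]:.6f}, not 1"
            )
        self.matrix = mat / sums[:, None]

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def __eq__(self, other: object) -> bool:  # cell-wise comparison
        if not isinstance(other, MotifRecord):
            return NotImplemented
        return (
            self.name == other.name
            and self.alphabet.characters == other.alphabet.characters
            and self.matrix.shape == other.matrix.shape
            and bool(np.allclose(self.matrix, other.matrix, atol=1e-6))
        )


_VERSION_RE = re.compile(r"^MEME\s+version\s+(\S+)", re.IGNORECASE)
_ALPHABET_RE = re.compile(r"^ALPHABET\s*=\s*(\S+)\s*$", re.IGNORECASE)
_MOTIF_RE = re.compile(r"^MOTIF\s+(\S+)(?:\s+(\S+))?", re.IGNORECASE)
_LPM_RE = re.compile(r"^letter-probability\s+matrix:?\s*(.*)$", re.IGNORECASE)
_NUMBER_ROW_RE = re.compile(r"^[\s]*[-+0-9.eE][-+0-9.eE\s]*$")


def _parse_lpm_header(rest: str) -> dict[str, str]:
    # "alphabet= 4 w= 9 nsites= 18 E= 0" -> {"alphabet": "4", "w": "9", ...}
    out: dict[str, str] = {}
    for m in re.finditer(r"(\S+?)=\s*(\S+)", rest):
        out[m.group(1).lower()] = m.group(2)
    return out


def parse_meme(stream: TextIO | Iterable[str]) -> list[MotifRecord]:
    """Parse a MEME minimal-format text stream into motif records.

    The alphabet is inferred from the ``ALPHABET=`` line: the character sets
    ACGT, ACGU and the 20 standard amino acids map to dna/rna/protein, any
    other set becomes a custom alphabet in file order.  If the line is
    absent, DNA is assumed with a warning.  Matrix rows are re-normalized to
    sum to 1; raw sums outside ``1 +/- 0.05`` raise :class:`ValueError`.

    Returns records in file order.
    """
    lines = list(stream)
    n_lines = len(lines)
    pos = 0

    def next_content(start: int) -> int:
        i = start
        while i < n_lines and not lines[i].strip():
            i += 1
        return i

    pos = next_content(0)
    if pos >= n_lines:
        raise MemeParseError("empty input: expected a 'MEME version' line")
    m = _VERSION_RE.match(lines[pos].strip())
    if not m:
        raise MemeParseError(
            f"line {pos + 1}: expected 'MEME version ...', got {lines[pos].strip()!r}"
        )
    metadata: dict[str, str] = {"version": m.group(1)}
    pos += 1

    alphabet: Alphabet | None = None
    records: list[MotifRecord] = []
    current_name: str | None = None
    in_background = False

    while pos < n_lines:
        raw = lines[pos]
        line = raw.strip()
        pos += 1
        if not line:
            in_background = False
            continue

        if line.upper().startswith("ALPHABET"):
            m = _ALPHABET_RE.match(line)
            if not m:
                raise MemeParseError(f"line {pos}: malformed ALPHABET line {line!r}")
            alphabet = infer_alphabet(m.group(1))
            metadata["alphabet"] = "".join(alphabet.characters)
            continue
        if line.lower().startswith("strands"):
            metadata["strands"] = line.split(":", 1)[-1].strip()
            continue
        if line.lower().startswith("background letter frequencies"):
            metadata.setdefault("background", "")
            in_background = True
            continue
        if in_background and _NUMBER_ROW_RE.match(line) is None and not _MOTIF_RE.match(line):
            # "A 0.25 C 0.25 ..." continuation lines
            metadata["background"] = (metadata.get("background", "") + " " + line).strip()
            continue

        motif_match = _MOTIF_RE.match(line)
        if motif_match:
            in_background = False
            current_name = motif_match.group(1)
            # find the letter-probability header
            pos = next_content(pos)
            if pos >= n_lines:
                raise MemeParseError(
                    f"motif {current_name!r}: missing letter-probability matrix"
                )
            header_line = lines[pos].strip()
            # URL / alternate-name lines may precede the matrix header
            while pos < n_lines and not _LPM_RE.match(header_line):
                if _MOTIF_RE.match(header_line):
                    raise MemeParseError(
                        f"motif {current_name!r}: missing letter-probability matrix"
                    )
                pos = next_content(pos + 1)
                header_line = lines[pos].strip() if pos < n_lines else ""
            if pos >= n_lines:
                raise MemeParseError(
                    f"motif {current_name!r}: missing letter-probability matrix"
                )
            lpm = _LPM_RE.match(header_line)
            assert lpm is not None
            fields = _parse_lpm_header(lpm.group(1))
            pos += 1

            if alphabet is None:
                logger.warning("no ALPHABET line before MOTIF %s; assuming DNA", current_name)
                alphabet = DNA

            rows: list[list[float]] = []
            while pos < n_lines:
                row_line = lines[pos].strip()
                if not row_line or not _NUMBER_ROW_RE.match(row_line):
                    break
                try:
                    rows.append([float(tok) for tok in row_line.split()])
                except ValueError as exc:
                    raise MemeParseError(
                        f"line {pos + 1}: bad probability row {row_line!r}"
                    ) from exc
                pos += 1

            if not rows:
                raise MemeParseError(f"motif {current_name!r}: empty probability matrix")
            for i, row in enumerate(rows):
                if len(row) != alphabet.size:
                    raise MotifDimensionError(
                        f"motif {current_name!r} position {i + 1}: row has "
                        f"{len(row)} values, alphabet has {alphabet.size}"
                    )
            if "w" in fields and int(fields["w"]) != len(rows):
                raise MotifDimensionError(
                    f"motif {current_name!r}: header declares w={fields['w']} "
                    f"but matrix has {len(rows)} rows"
                )

            mat = np.array(rows, dtype=float)
            if np.any(mat < 0):
                i, j = np.argwhere(mat < 0)[0]
                raise ValueError(
                    f"motif {current_name!r} position {int(i) + 1}: negative "
                    f"probability {mat[i, j]}"
                )
            sums = mat.sum(axis=1)
            off = np.abs(sums - 1.0) > ROW_SUM_SLACK
            if np.any(off):
                i = int(np.argmax(off))
                raise ValueError(
                    f"motif {current_name!r} position {i + 1}: row sums to "
                    f"{sums[i]:.4f}; expected 1 within {ROW_SUM_SLACK} "
                    "(count matrix or corrupt file?)"
                )
            mat = mat / sums[:, None]

            meta = dict(metadata)
            for key in ("nsites", "e"):
                if key in fields:
                    meta[key] = fields[key]
            records.append(
                MotifRecord(
                    name=current_name, alphabet=alphabet, matrix=mat, source_metadata=meta
                )
            )
            continue

        # any other header-ish line is carried as metadata
        logger.debug("ignoring line %d: %r", pos, line)

    return records


def parse_meme_text(text: str) -> list[MotifRecord]:
    """Convenience wrapper: parse MEME records from a string."""
    return parse_meme(_io.StringIO(text))


def write_meme(motifs: list[MotifRecord], stream: TextIO) -> None:
    """Write records as MEME minimal format; re-parses to the same records.

    All motifs must share one alphabet.  Probabilities are printed with
    eight decimals, which keeps the parse/write round trip (including the
    parser's row re-normalization) within 1e-6 per cell.
    """
    alphabets = {m.alphabet.characters for m in motifs}
    if len(alphabets) > 1:
        raise ValueError("cannot write motifs with mixed alphabets to one MEME file")

    stream.write("MEME version 4\n\n")
    if motifs:
        chars = motifs[0].alphabet.characters
        stream.write(f"ALPHABET= {''.join(chars)}\n\n")
        if motifs[0].alphabet.is_nucleotide:
            stream.write("strands: + -\n\n")
    for motif in motifs:
        stream.write(f"MOTIF {motif.name}\n")
        k, n = motif.matrix.shape
        nsites = motif.source_metadata.get("nsites", "20")
        stream.write(
            f"letter-probability matrix: alphabet= {n} w= {k} nsites= {nsites} E= 0\n"
        )
        for row in motif.matrix:
            stream.write(" " + " ".join(f"{p:.8f}" for p in row) + "\n")
        stream.write("\n")


def write_meme_text(motifs: list[MotifRecord]) -> str:
    """Convenience wrapper: render records to a MEME-format string."""
    buf = _io.StringIO()
    write_meme(motifs, buf)
    return buf.getvalue()
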