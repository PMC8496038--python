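"""Position frequency matrices: normalization, information content, palindromy, I/O.

A :class:`PositionMatrix` stores one probability 4-vector per motif position
(alphabet order A, C, G, T).  :class:`MotifRecord` attaches identity and
provenance (member TFs, arity, per-member strand flags) to a matrix.

Supported interchange formats: MEME minimal, JASPAR ``.pfm`` (4 rows of
counts/probabilities), and a TSV dialect with header ``pos A C G T``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ALPHABET",
    "PositionMatrix",
    "MotifRecord",
    "DegenerateColumnError",
    "MotifParseError",
    "normalize",
    "information_content",
    "effective_length",
    "reverse_complement",
    "is_palindromic",
    "column_correlation",
    "read_motifs",
    "write_motifs",
]

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G

#: default pseudocount for probability matrices / raw count matrices
DEFAULT_PROB_PSEUDOCOUNT = 1e-3
DEFAULT_COUNT_PSEUDOCOUNT = 1.0


class DegenerateColumnError(ValueError):
    """A count column is all zero and no pseudocount was supplied."""


class MotifParseError(ValueError):
    """A motif file is malformed; the message names the offending line."""


@dataclass(frozen=True)
class PositionMatrix:
    """Column-wise base probabilities of a motif.

    ``probs`` has shape ``(length, 4)``; row *i* is the distribution over
    A, C, G, T at motif position *i*.  Every row sums to 1 within 1e-6.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.probs, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4 or arr.shape[0] < 1:
            raise ValueError(f"expected (L, 4) matrix with L >= 1, got shape {arr.shape}")
        if np.any(arr < -1e-12):
            raise ValueError("probabilities must be non-negative")
        sums = arr.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each position must sum to 1 (did you forget normalize()?)")
        object.__setattr__(self, "probs", arr)

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def __len__(self) -> int:
        return self.length

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PositionMatrix):
            return NotImplemented
        return self.probs.shape == other.probs.shape and np.allclose(
            self.probs, other.probs, atol=1e-9
        )

    def __hash__(self) -> int:  # frozen dataclass with array payload
        return hash((self.probs.shape, round(float(self.probs.sum()), 6)))

    def isclose(self, other: "PositionMatrix", atol: float = 1e-6) -> bool:
        return self.probs.shape == other.probs.shape and np.allclose(
            self.probs, other.probs, atol=atol
        )

    def consensus(self) -> str:
        """Highest-probability base at each position."""
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))


@dataclass(frozen=True)
class MotifRecord:
    """A motif plus provenance.

    ``arity`` equals the number of member TFs (1 = monomer, 2 = dimer,
    >= 3 multimer).  ``orientation_notes`` carries one ``'+'``/``'-'`` flag
    per member recording the strand each member was placed on.
    """

    id: str
    tf_members: tuple[str, ...]
    matrix: PositionMatrix
    orientation_notes: tuple[str, ...] = ()
    metadata: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        members = tuple(self.tf_members)
        object.__setattr__(self, "tf_members", members)
        if len(members) < 1:
            raise ValueError("a motif needs at least one member TF")
        notes = tuple(self.orientation_notes) or ("+",) * len(members)
        if len(notes) != len(members):
            raise ValueError("orientation_notes must match tf_members")
        if any(n not in "+-" for n in notes):
            raise ValueError("orientation flags must be '+' or '-'")
        object.__setattr__(self, "orientation_notes", notes)

    @property
    def arity(self) -> int:
        return len(self.tf_members)


def normalize(counts_matrix: np.ndarray, pseudocount: float = 0.0) -> PositionMatrix:
    """Turn a base-major 4 x L count matrix into a probability matrix.

    Rows of the input are A, C, G, T; columns are motif positions.  Each
    output column is ``(count + pseudocount) / (colsum + 4 * pseudocount)``.

    Raises
    ------
    DegenerateColumnError
        if some column is all zero and ``pseudocount`` is zero.
    """
    arr = np.asarray(counts_matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != 4:
        raise ValueError(f"expected a 4 x L base-major matrix, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    colsums = arr.sum(axis=0)
    if pseudocount == 0 and np.any(colsums == 0):
        bad = int(np.flatnonzero(colsums == 0)[0])
        raise DegenerateColumnError(f"column {bad} is all zero with zero pseudocount")
    probs = (arr + pseudocount) / (colsums + 4 * pseudocount)
    return PositionMatrix(probs.T)


def information_content(m: PositionMatrix) -> float:
    """Total information content in bits: sum over columns of 2 + sum p*log2 p."""
    p = m.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    ic = float((2.0 + plogp.sum(axis=1)).sum())
    return max(ic, 0.0)


def effective_length(m: PositionMatrix) -> float:
    """Base-pair-equivalent motif length: information content divided by 2."""
    return information_content(m) / 2.0


def reverse_complement(m: PositionMatrix) -> PositionMatrix:
    """Columns reversed, A<->T and C<->G swapped.  An involution."""
    return PositionMatrix(m.probs[::-1, _COMPLEMENT_INDEX])


def column_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation between two probability 4-vectors.

    Convention for zero-variance (uniform) columns: 1.0 if both are uniform,
    0.0 if exactly one is.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    vx = x.std()
    vy = y.std()
    if vx < 1e-12 and vy < 1e-12:
        return 1.0
    if vx < 1e-12 or vy < 1e-12:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def is_palindromic(m: PositionMatrix, min_correlation: float = 0.8) -> bool:
    """Whether the motif equals its reverse complement, up to correlation.

    Computes the mean per-column Pearson correlation between ``m`` and
    ``reverse_complement(m)`` at zero offset and compares it against
    ``min_correlation``.
    """
    if not -1.0 <= min_correlation <= 1.0:
        raise ValueError("min_correlation must be in [-1, 1]")
    rc = reverse_complement(m)
    pccs = [column_correlation(m.probs[i], rc.probs[i]) for i in range(m.length)]
    return float(np.mean(pccs)) >= min_correlation


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_FORMATS = ("meme", "jaspar", "tsv")


def _members_to_str(rec: MotifRecord) -> str:
    parts = []
    for name, strand in zip(rec.tf_members, rec.orientation_notes):
        parts.append(f"{name}(-)" if strand == "-" else name)
    return "+".join(parts)


def _members_from_str(s: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    members, strands = [], []
    for tok in s.split("+"):
        if tok.endswith("(-)"):
            members.append(tok[:-3])
            strands.append("-")
        else:
            members.append(tok)
            strands.append("+")
    return tuple(members), tuple(strands)


def write_motifs(records: Sequence[MotifRecord], path: str | Path, format: str = "meme") -> None:
    """Serialize motif records.  Round-trips through :func:`read_motifs`."""
    if format not in _FORMATS:
        raise ValueError(f"unknown motif format {format!r}; choose from {_FORMATS}")
    path = Path(path)
    lines: list[str] = []
    if format == "meme":
        lines += [
            "MEME version 4",
            "",
            "ALPHABET= ACGT",
            "",
            "strands: + -",
            "",
            "Background letter frequencies",
            "A 0.25 C 0.25 G 0.25 T 0.25",
            "",
        ]
        for rec in records:
            lines.append(f"MOTIF {rec.id} {_members_to_str(rec)}")
            lines.append(
                f"letter-probability matrix: alength= 4 w= {rec.matrix.length} nsites= 20 E= 0"
            )
            for row in rec.matrix.probs:
                lines.append(" ".join(f"{v:.6f}" for v in row))
            lines.append("")
    elif format == "jaspar":
        for rec in records:
            lines.append(f">{rec.id} {_members_to_str(rec)}")
            for b in range(4):
                lines.append(" ".join(f"{v:.6f}" for v in rec.matrix.probs[:, b]))
    else:  # tsv
        for rec in records:
            lines.append(f"# motif {rec.id} members={_members_to_str(rec)}")
            lines.append("pos\tA\tC\tG\tT")
            for i, row in enumerate(rec.matrix.probs):
                lines.append(f"{i + 1}\t" + "\t".join(f"{v:.6f}" for v in row))
            lines.append("")
    path.write_text("\n".join(lines) + "\n")


def read_motifs(path: str | Path, format: str = "meme") -> list[MotifRecord]:
    """Parse motifs from ``path`` in the given dialect.

    An empty file yields an empty list (with a logged warning).  Malformed
    content raises :class:`MotifParseError` naming the offending line.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown motif format {format!r}; choose from {_FORMATS}")
    text = Path(path).read_text()
    if not text.strip():
        logger.warning("motif file %s is empty", path)
        return []
    lines = text.splitlines()
    if format == "meme":
        return _read_meme(lines)
    if format == "jaspar":
        return _read_jaspar(lines)
    return _read_tsv(lines)


def _probs_record(id_: str, member_str: str, rows: list[list[float]], lineno: int) -> MotifRecord:
    arr = np.asarray(rows, dtype=float)
    colsums = arr.sum(axis=1)
    if np.any(colsums <= 0):
        raise MotifParseError(f"line {lineno}: zero-sum matrix column in motif {id_!r}")
    arr = arr / colsums[:, None]
    members, strands = _members_from_str(member_str) if member_str else ((id_,), ("+",))
    return MotifRecord(id=id_, tf_members=members, matrix=PositionMatrix(arr),
                       orientation_notes=strands)


def _read_meme(lines: list[str]) -> list[MotifRecord]:
    records: list[MotifRecord] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise MotifParseError(f"line {i + 1}: MOTIF line lacks an identifier")
            motif_id = parts[1]
            member_str = parts[2] if len(parts) > 2 else ""
            i += 1
            while i < n and not lines[i].strip().startswith("letter-probability matrix"):
                if lines[i].strip().startswith("MOTIF"):
                    raise MotifParseError(f"line {i + 1}: motif {motif_id!r} has no matrix")
                i += 1
            if i >= n:
                raise MotifParseError(f"line {n}: motif {motif_id!r} has no matrix")
            header = lines[i].strip()
            width = None
            toks = header.replace("=", " = ").split()
            for j, t in enumerate(toks):
                if t == "w" and j + 2 < len(toks):
                    width = int(toks[j + 2])
            if width is None:
                raise MotifParseError(f"line {i + 1}: matrix header lacks w= field")
            rows = []
            i += 1
            for k in range(width):
                if i >= n or not lines[i].strip():
                    raise MotifParseError(
                        f"line {i + 1}: motif {motif_id!r} declares w={width} "
                        f"but only {k} rows found"
                    )
                try:
                    rows.append([float(v) for v in lines[i].split()])
                except ValueError as exc:
                    raise MotifParseError(f"line {i + 1}: bad matrix row: {exc}") from exc
                if len(rows[-1]) != 4:
                    raise MotifParseError(f"line {i + 1}: expected 4 values per row")
                i += 1
            records.append(_probs_record(motif_id, member_str, rows, i))
        else:
            i += 1
    return records


def _read_jaspar(lines: list[str]) -> list[MotifRecord]:
    records: list[MotifRecord] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise MotifParseError(f"line {i + 1}: expected '>' header, got {line[:30]!r}")
        parts = line[1:].split(maxsplit=1)
        motif_id = parts[0]
        member_str = parts[1].strip() if len(parts) > 1 else ""
        base_rows = []
        for b in range(4):
            if i + 1 + b >= n:
                raise MotifParseError(f"line {n}: motif {motif_id!r} needs 4 base rows")
            raw = lines[i + 1 + b].strip().strip("ACGT").strip().strip("[]")
            try:
                base_rows.append([float(v) for v in raw.split()])
            except ValueError as exc:
                raise MotifParseError(f"line {i + 2 + b}: bad count row: {exc}") from exc
        widths = {len(r) for r in base_rows}
        if len(widths) != 1:
            raise MotifParseError(
                f"line {i + 2}: row lengths differ in motif {motif_id!r}: {sorted(widths)}"
            )
        arr = np.asarray(base_rows, float).T  # to position-major
        records.append(_probs_record(motif_id, member_str, arr.tolist(), i + 5))
        i += 5
    return records


def _read_tsv(lines: list[str]) -> list[MotifRecord]:
    records: list[MotifRecord] = []
    motif_id: str | None = None
    member_str = ""
    rows: list[list[float]] = []
    start_line = 0

    def flush(lineno: int) -> None:
        nonlocal motif_id, rows
        if motif_id is not None:
            if not rows:
                raise MotifParseError(f"line {lineno}: motif {motif_id!r} has no rows")
            records.append(_probs_record(motif_id, member_str, rows, lineno))
        motif_id, rows = None, []

    for i, line in enumerate(lines):
        s = line.strip()
        if s.startswith("# motif"):
            flush(i)
            toks = s.split()
            motif_id = toks[2]
            member_str = ""
            for t in toks[3:]:
                if t.startswith("members="):
                    member_str = t[len("members="):]
            start_line = i + 1
        elif s.startswith("pos"):
            continue
        elif s:
            if motif_id is None:
                raise MotifParseError(f"line {i + 1}: data row before any '# motif' header")
            vals = s.split("\t") if "\t" in s else s.split()
            if len(vals) != 5:
                raise MotifParseError(f"line {i + 1}: expected 5 columns, got {len(vals)}")
            try:
                pos = int(vals[0])
                rows.append([float(v) for v in vals[1:]])
            except ValueError as exc:
                raise MotifParseError(f"line {i + 1}: bad TSV row: {exc}") from exc
            if pos != len(rows):
                raise MotifParseError(
                    f"line {i + 1}: position {pos} out of order (expected {len(rows)})"
                )
    flush(len(lines))
    return records
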