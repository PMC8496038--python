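"""Chain dimeric motifs into 3-6-TF multimeric motifs.

A 3-TF motif A-B-C is formed from dimers A-B and C-B by ungapped alignment
of the two dimer matrices (maximizing summed per-column Pearson correlation
over both orientations), then averaging the overlapping columns per base per
position; non-overlapping columns are kept unchanged.  Chaining is only
legal through a shared member whose monomer half is palindromic, so the
shared half reads identically from either side.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .motif_model import (
    MotifRecord,
    PositionMatrix,
    column_correlation,
    reverse_complement,
)

__all__ = [
    "DimerAnnotation",
    "AlignmentResult",
    "ChainingError",
    "MergeError",
    "align_pfms",
    "merge_dimers",
    "extend_multimer",
    "enumerate_chains",
    "write_chain_table",
]

DEFAULT_MIN_OVERLAP = 4


class ChainingError(ValueError):
    """Dimers cannot be chained (no shared palindromic member)."""


class MergeError(ValueError):
    """Alignment exists but does not satisfy merge preconditions."""


@dataclass(frozen=True)
class DimerAnnotation:
    """A dimeric motif with located monomer halves.

    ``half_spans`` are two 0-based half-open column ranges locating the two
    monomer halves inside the dimer matrix, ordered as ``member_order``.
    """

    motif: MotifRecord
    half_spans: tuple[tuple[int, int], tuple[int, int]]
    palindromic_halves: tuple[bool, bool]
    member_order: tuple[str, str]

    def __post_init__(self) -> None:
        if self.motif.arity != 2:
            raise ValueError("DimerAnnotation requires an arity-2 motif")
        (a0, a1), (b0, b1) = self.half_spans
        L = self.motif.matrix.length
        spans = sorted([(a0, a1), (b0, b1)])
        if not (0 <= spans[0][0] < spans[0][1] <= spans[1][0] < spans[1][1] <= L):
            raise ValueError(f"half_spans {self.half_spans} must be disjoint and inside [0,{L})")

    def is_member_palindromic(self, name: str) -> bool:
        for member, flag in zip(self.member_order, self.palindromic_halves):
            if member == name:
                return flag
        raise KeyError(name)

    def other_member(self, name: str) -> str:
        a, b = self.member_order
        if name == a:
            return b
        if name == b:
            return a
        raise KeyError(name)


@dataclass(frozen=True)
class AlignmentResult:
    """Best ungapped placement of matrix b against matrix a.

    ``offset`` is the position of b's first column relative to a's first
    column (may be negative).  ``score`` is the sum of per-column Pearson
    correlations over the overlap.
    """

    offset: int
    orientation: str  # "forward" | "reverse-complement"
    overlap_length: int
    score: float


def _standardized(probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column z-columns such that row dot products equal Pearson correlations.

    Uniform (zero-variance) columns get all-zero rows and are flagged; their
    correlation is handled by the both-uniform convention separately.
    """
    mean = probs.mean(axis=1, keepdims=True)
    sd = probs.std(axis=1, keepdims=True)
    uniform = sd[:, 0] < 1e-12
    z = np.divide(probs - mean, 2.0 * sd, out=np.zeros_like(probs), where=sd > 1e-12)
    return z, uniform


def align_pfms(a: PositionMatrix, b: PositionMatrix, min_overlap: int = DEFAULT_MIN_OVERLAP) -> AlignmentResult:
    """Exhaustive ungapped alignment over all offsets of b and rc(b) against a.

    The score of a placement is the sum of per-column Pearson correlations
    over the overlap (both-uniform column pairs contribute 1, mixed pairs 0).
    Ties are broken by larger overlap, then forward orientation, then smaller
    offset.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    la, lb = a.length, b.length
    if min_overlap > min(la, lb):
        raise ValueError(
            f"min_overlap={min_overlap} exceeds the shorter matrix length {min(la, lb)}"
        )
    za, ua = _standardized(a.probs)
    best: AlignmentResult | None = None
    for orientation, mat in (("forward", b), ("reverse-complement", reverse_complement(b))):
        zb, ub = _standardized(mat.probs)
        for offset in range(-(lb - min_overlap), la - min_overlap + 1):
            lo = max(0, offset)
            hi = min(la, offset + lb)
            overlap = hi - lo
            if overlap < min_overlap:
                continue
            sa = slice(lo, hi)
            sb = slice(lo - offset, hi - offset)
            score = float(np.einsum("ij,ij->", za[sa], zb[sb]))
            score += int(np.sum(ua[sa] & ub[sb]))  # both-uniform convention
            cand = AlignmentResult(offset, orientation, overlap, score)
            if best is None or _better(cand, best):
                best = cand
    assert best is not None
    return best


def _better(x: AlignmentResult, y: AlignmentResult) -> bool:
    if not np.isclose(x.score, y.score, atol=1e-12):
        return x.score > y.score
    if x.overlap_length != y.overlap_length:
        return x.overlap_length > y.overlap_length
    if x.orientation != y.orientation:
        return x.orientation == "forward"
    return x.offset < y.offset


def _merge_matrices(a: PositionMatrix, b: PositionMatrix, aln: AlignmentResult) -> PositionMatrix:
    """Place b at ``aln.offset`` (rc'd if needed) and average overlapping columns."""
    mat_b = b if aln.orientation == "forward" else reverse_complement(b)
    start = min(0, aln.offset)
    end = max(a.length, aln.offset + mat_b.length)
    out = np.zeros((end - start, 4))
    weight = np.zeros(end - start)
    out[-start : -start + a.length] += a.probs
    weight[-start : -start + a.length] += 1
    bpos = aln.offset - start
    out[bpos : bpos + mat_b.length] += mat_b.probs
    weight[bpos : bpos + mat_b.length] += 1
    return PositionMatrix(out / weight[:, None])


def merge_dimers(
    ab: DimerAnnotation,
    cb: DimerAnnotation,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> MotifRecord:
    """Merge two dimers sharing a palindromic member into a 3-TF motif."""
    shared = set(ab.member_order) & set(cb.member_order)
    if len(shared) != 1:
        raise ChainingError(
            f"dimers {ab.motif.id!r} and {cb.motif.id!r} must share exactly one member "
            f"(shared: {sorted(shared)})"
        )
    b = shared.pop()
    if not (ab.is_member_palindromic(b) and cb.is_member_palindromic(b)):
        raise ChainingError(f"shared member {b!r} must be palindromic in both dimers")
    aln = align_pfms(ab.motif.matrix, cb.motif.matrix, min_overlap)
    if aln.overlap_length < min_overlap:
        raise MergeError(f"alignment overlap {aln.overlap_length} < min_overlap {min_overlap}")
    merged = _merge_matrices(ab.motif.matrix, cb.motif.matrix, aln)
    members = (ab.other_member(b), b, cb.other_member(b))
    return MotifRecord(
        id="+".join(members),
        tf_members=members,
        matrix=merged,
        metadata={"source_dimers": [ab.motif.id, cb.motif.id], "offsets": [0, aln.offset],
                  "orientations": ["forward", aln.orientation]},
    )


def extend_multimer(
    multi: MotifRecord,
    dimer: DimerAnnotation,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> MotifRecord:
    """Extend an arity>=3 motif by one TF using a dimer sharing a terminal member."""
    if multi.arity < 3:
        raise ValueError("extend_multimer expects an arity >= 3 motif")
    first, last = multi.tf_members[0], multi.tf_members[-1]
    shared = None
    for terminal in (last, first):
        if terminal in dimer.member_order:
            shared = terminal
            break
    if shared is None:
        raise ChainingError(
            f"dimer {dimer.motif.id!r} shares no terminal member of {multi.id!r} "
            f"(terminals: {first!r}, {last!r})"
        )
    if not dimer.is_member_palindromic(shared):
        raise ChainingError(f"shared member {shared!r} must be palindromic in the dimer")
    aln = align_pfms(multi.matrix, dimer.motif.matrix, min_overlap)
    if aln.overlap_length < min_overlap:
        raise MergeError(f"alignment overlap {aln.overlap_length} < min_overlap {min_overlap}")
    merged = _merge_matrices(multi.matrix, dimer.motif.matrix, aln)
    new = dimer.other_member(shared)
    if shared == last:
        members = multi.tf_members + (new,)
    else:
        members = (new,) + multi.tf_members
    sources = list(multi.metadata.get("source_dimers", [])) + [dimer.motif.id]
    return MotifRecord(
        id="+".join(members),
        tf_members=members,
        matrix=merged,
        metadata={"source_dimers": sources},
    )


def _chain_key(members: Sequence[str]) -> tuple[str, ...]:
    """Canonical member tuple, collapsing a chain with its reversal."""
    fwd = tuple(members)
    rev = tuple(reversed(members))
    return min(fwd, rev)


def enumerate_chains(
    dimer_catalog: Sequence[DimerAnnotation],
    max_arity: int = 3,
    limit: int | None = None,
    seed: int | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[MotifRecord]:
    """Enumerate legal multimeric motifs up to ``max_arity``.

    Chains are deduplicated up to full reverse complement (member-order
    reversal).  When more than ``limit`` chains exist at some arity, a seeded
    uniform subsample of size ``limit`` is kept, making the output
    deterministic under ``seed``.
    """
    if not 3 <= max_arity <= 6:
        raise ValueError("max_arity must be in 3..6")
    rng = np.random.default_rng(seed)

    # arity 3: ordered dimer pairs sharing a palindromic member
    frontier: list[tuple[MotifRecord, int]] = []  # (record, last dimer index)
    seen: set[tuple[str, ...]] = set()
    results: list[MotifRecord] = []
    for i, d1 in enumerate(dimer_catalog):
        for j, d2 in enumerate(dimer_catalog):
            if i == j:
                continue
            try:
                rec = merge_dimers(d1, d2, min_overlap)
            except (ChainingError, MergeError):
                continue
            key = _chain_key(rec.tf_members)
            if key in seen:
                continue
            seen.add(key)
            frontier.append((rec, j))
    frontier = _maybe_sample(frontier, limit, rng)
    results.extend(rec for rec, _ in frontier)

    for _arity in range(4, max_arity + 1):
        nxt: list[tuple[MotifRecord, int]] = []
        for rec, last_idx in frontier:
            for j, d in enumerate(dimer_catalog):
                if j == last_idx:  # no dimer used twice consecutively
                    continue
                try:
                    ext = extend_multimer(rec, d, min_overlap)
                except (ChainingError, MergeError):
                    continue
                key = _chain_key(ext.tf_members)
                if key in seen:
                    continue
                seen.add(key)
                nxt.append((ext, j))
        nxt = _maybe_sample(nxt, limit, rng)
        results.extend(rec for rec, _ in nxt)
        frontier = nxt
    return results


def _maybe_sample(items: list, limit: int | None, rng: np.random.Generator) -> list:
    if limit is None or len(items) <= limit:
        return items
    idx = sorted(rng.choice(len(items), size=limit, replace=False))
    return [items[i] for i in idx]


def write_chain_table(records: Iterable[MotifRecord], path: str | Path) -> None:
    """TSV sidecar with chain provenance: id, members, source dimer ids."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["chain_id", "arity", "members", "source_dimers"])
        for rec in records:
            w.writerow(
                [
                    rec.id,
                    rec.arity,
                    ",".join(rec.tf_members),
                    ",".join(rec.metadata.get("source_dimers", [])),
                ]
            )
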