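"""Double-strand PWM scanning with exact p-value score thresholds.

The score threshold for a p-value is computed by dynamic programming over
the discretized log-odds score distribution under an i.i.d. background
(column-by-column convolution), the classic exact method.  Scanning then
reports every position on the requested strands whose (discretized) score
reaches the threshold.

Coordinates are 0-based half-open on the forward strand regardless of hit
strand.  Ambiguous bases (anything outside ACGT) score minus infinity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .motif_model import MotifRecord, PositionMatrix

__all__ = [
    "ScanConfig",
    "Hit",
    "log_odds",
    "threshold_from_pvalue",
    "scan",
    "hit_count_features",
    "write_hits_bed",
    "PwmScorer",
]

_BASE_TO_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_TO_CODE[ord(_b)] = _i
    _BASE_TO_CODE[ord(_b.lower())] = _i

#: additive penalty for ambiguous bases, large enough to sink any window
_N_PENALTY = -(10 ** 7)

try:  # optional numba fast path for long-sequence scans; results are identical
    from numba import njit as _njit

    @_njit(cache=True)
    def _hits_kernel(codes, q, t):  # pragma: no cover - exercised via hit_starts
        L = q.shape[0]
        n = codes.shape[0] - L + 1
        # rest[j] = best achievable score from columns j..L-1 (A,C,G,T only)
        rest = np.zeros(L + 1, dtype=np.int64)
        for j in range(L - 1, -1, -1):
            m = q[j, 0]
            for b in range(1, 4):
                if q[j, b] > m:
                    m = q[j, b]
            rest[j] = rest[j + 1] + m
        cap = 1024
        starts = np.empty(cap, dtype=np.int64)
        scores = np.empty(cap, dtype=np.int64)
        k = 0
        for i in range(n):
            acc = np.int64(0)
            ok = True
            for j in range(L):
                acc += q[j, codes[i + j]]
                if acc + rest[j + 1] < t:
                    ok = False
                    break
            if ok and acc >= t:
                if k == cap:
                    cap *= 2
                    ns = np.empty(cap, dtype=np.int64)
                    ns[:k] = starts[:k]
                    starts = ns
                    nsc = np.empty(cap, dtype=np.int64)
                    nsc[:k] = scores[:k]
                    scores = nsc
                starts[k] = i
                scores[k] = acc
                k += 1
        return starts[:k], scores[:k]

except Exception:  # pragma: no cover
    _hits_kernel = None


def encode(sequence: str) -> np.ndarray:
    """Sequence to int8 codes: A,C,G,T -> 0..3, anything else -> 4."""
    return _BASE_TO_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScanConfig:
    """Scanning parameters.

    ``score_discretization`` is the number of bins spanning the total score
    range used by the exact-threshold DP and by hit calling.
    """

    p_value: float = 1e-4
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    score_discretization: int = 1000
    strands: str = "both"  # "both" | "forward"
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must be in (0, 1]")
        bg = np.asarray(self.background, float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0) or np.any(bg <= 0):
            raise ValueError("background must be 4 positive probabilities summing to 1")
        if self.strands not in ("both", "forward"):
            raise ValueError("strands must be 'both' or 'forward'")
        if self.score_discretization < 10:
            raise ValueError("score_discretization must be >= 10")


@dataclass(frozen=True)
class Hit:
    sequence_id: str
    start: int
    end: int
    strand: str
    motif_id: str
    score: float


def log_odds(
    m: PositionMatrix,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 0.0,
) -> np.ndarray:
    """Per-position log2-odds score matrix, shape (L, 4).

    Cell = log2((p + pseudocount) / bg).  With zero pseudocount, zero
    probabilities give -inf.
    """
    bg = np.asarray(background, float)
    if np.any(bg <= 0):
        raise ValueError("background entries must be > 0")
    with np.errstate(divide="ignore"):
        return np.log2((m.probs + pseudocount) / bg)


def _finite_scores(scores: np.ndarray) -> np.ndarray:
    """Replace -inf cells by a finite value no word can recover from."""
    scores = np.asarray(scores, float)
    if np.all(np.isfinite(scores)):
        return scores
    finite = scores[np.isfinite(scores)]
    span = float(finite.max(initial=0.0) - finite.min(initial=0.0)) * scores.shape[0] + 1.0
    return np.where(np.isfinite(scores), scores, finite.min(initial=0.0) - span)


def _discretize(scores: np.ndarray, bins: int) -> tuple[np.ndarray, float]:
    """Integer cell scores q = round(score * scale); scale spans the sum range."""
    scores = _finite_scores(scores)
    max_sum = scores.max(axis=1).sum()
    min_sum = scores.min(axis=1).sum()
    span = max_sum - min_sum
    scale = bins / span if span > 0 else 1.0
    return np.rint(scores * scale).astype(np.int64), scale


def _score_distribution(q: np.ndarray, background: np.ndarray) -> tuple[np.ndarray, int]:
    """Exact pmf of the integer word score under i.i.d. background.

    Returns (pmf, offset) where pmf[i] = P(score == offset + i).
    """
    lo = int(q.min(axis=1).sum())
    hi = int(q.max(axis=1).sum())
    pmf = np.zeros(hi - lo + 1)
    # running support [cur_lo, cur_hi]
    cur = np.array([1.0])
    cur_lo = 0
    for row in q:
        new_lo = cur_lo + int(row.min())
        new = np.zeros(len(cur) + int(row.max() - row.min()))
        for b in range(4):
            shift = int(row[b]) - int(row.min())
            new[shift : shift + len(cur)] += background[b] * cur
        cur = new
        cur_lo = new_lo
    pmf[cur_lo - lo : cur_lo - lo + len(cur)] = cur
    return pmf, lo


def _threshold_int(
    scores: np.ndarray, background: np.ndarray, p: float, bins: int
) -> tuple[int, float]:
    """Smallest integer threshold T with P(q-score >= T) <= p, plus the scale."""
    q, scale = _discretize(scores, bins)
    pmf, offset = _score_distribution(q, background)
    tail = np.cumsum(pmf[::-1])[::-1]
    qualifying = np.flatnonzero(tail <= p + 1e-15)
    if len(qualifying) == 0:
        warnings.warn(
            f"p={p} admits no word; returning a threshold above the maximum score",
            stacklevel=3,
        )
        return offset + len(pmf), scale
    return offset + int(qualifying[0]), scale


def threshold_from_pvalue(
    scores: np.ndarray,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    p: float = 1e-4,
    bins: int = 1000,
) -> float:
    """Score threshold t such that P(word score >= t | i.i.d. background) <= p.

    Computed exactly on the discretized score lattice; the returned value is
    the smallest qualifying lattice score.  p = 1 returns the minimum
    possible score; a p too small for any word returns max score + epsilon
    with a warning.
    """
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    t_int, scale = _threshold_int(np.asarray(scores, float), np.asarray(background, float), p, bins)
    return t_int / scale


class PwmScorer:
    """Precomputed integer score matrices and threshold for one motif."""

    def __init__(self, motif: MotifRecord, cfg: ScanConfig):
        self.motif = motif
        self.cfg = cfg
        bg = np.asarray(cfg.background, float)
        self.scores = log_odds(motif.matrix, bg, cfg.pseudocount)
        self.t_int, self.scale = _threshold_int(
            self.scores, bg, cfg.p_value, cfg.score_discretization
        )
        q, _ = _discretize(self.scores, cfg.score_discretization)
        # column 4 = ambiguous base sentinel
        self.q_fwd = np.hstack([q, np.full((len(q), 1), _N_PENALTY, dtype=np.int64)])
        q_rc = q[::-1, [3, 2, 1, 0]]
        self.q_rev = np.hstack([q_rc, np.full((len(q), 1), _N_PENALTY, dtype=np.int64)])

    @property
    def length(self) -> int:
        return self.motif.matrix.length

    def window_scores(self, codes: np.ndarray, strand: str) -> np.ndarray:
        """Integer score of every length-L window of an encoded sequence."""
        L = self.length
        n = len(codes) - L + 1
        if n <= 0:
            return np.zeros(0, dtype=np.int64)
        q = self.q_fwd if strand == "+" else self.q_rev
        acc = np.zeros(n, dtype=np.int64)
        for j in range(L):
            acc += q[j, codes[j : j + n]]
        return acc

    def hit_starts(self, codes: np.ndarray, strand: str) -> tuple[np.ndarray, np.ndarray]:
        """Start positions with integer score >= threshold, plus those scores."""
        q = self.q_fwd if strand == "+" else self.q_rev
        if _hits_kernel is not None and len(codes) >= 10_000:
            return _hits_kernel(
                np.ascontiguousarray(codes), np.ascontiguousarray(q), self.t_int
            )
        ws = self.window_scores(codes, strand)
        starts = np.flatnonzero(ws >= self.t_int)
        return starts, ws[starts]


def scan(
    sequence: str,
    motif: MotifRecord,
    cfg: ScanConfig = ScanConfig(),
    sequence_id: str = "seq",
) -> list[Hit]:
    """All motif matches at the configured p-value on the requested strands.

    A sequence shorter than the motif yields an empty list.  Scores are
    reported on the discretized log2-odds lattice used for hit calling.
    """
    scorer = PwmScorer(motif, cfg)
    codes = encode(sequence)
    hits: list[Hit] = []
    strands = ("+", "-") if cfg.strands == "both" else ("+",)
    for strand in strands:
        starts, scores = scorer.hit_starts(codes, strand)
        for s, q_sum in zip(starts, scores):
            hits.append(
                Hit(
                    sequence_id=sequence_id,
                    start=int(s),
                    end=int(s) + scorer.length,
                    strand=strand,
                    motif_id=motif.id,
                    score=float(q_sum / scorer.scale),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def hit_count_features(
    sequences: Sequence[tuple[str, str]],
    motif_set: Sequence[MotifRecord],
    cfg: ScanConfig = ScanConfig(),
) -> pd.DataFrame:
    """Hit-count feature table: one row per sequence, one column per motif.

    ``sequences`` is a list of (id, DNA) pairs.  Counts hits on the strands
    requested in ``cfg``; a plus and a minus hit on the same interval both
    count.  Duplicate motif ids or an empty motif set are errors.
    """
    if len(motif_set) == 0:
        raise ValueError("motif set must be non-empty")
    ids = [m.id for m in motif_set]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate motif ids in motif set")
    if len(sequences) == 0:
        return pd.DataFrame(columns=ids, dtype=np.int64)

    max_len = max(m.matrix.length for m in motif_set)
    sep = max_len  # run of N's between sequences; windows across never score
    seq_ids = [sid for sid, _ in sequences]
    offsets = np.zeros(len(sequences) + 1, dtype=np.int64)
    chunks = []
    pos = 0
    for i, (_, s) in enumerate(sequences):
        offsets[i] = pos
        chunks.append(encode(s))
        chunks.append(np.full(sep, 4, dtype=np.int8))
        pos += len(s) + sep
    offsets[-1] = pos
    codes = np.concatenate(chunks) if chunks else np.zeros(0, dtype=np.int8)

    counts = np.zeros((len(sequences), len(motif_set)), dtype=np.int64)
    strands = ("+", "-") if cfg.strands == "both" else ("+",)
    for j, motif in enumerate(motif_set):
        scorer = PwmScorer(motif, cfg)
        for strand in strands:
            starts, _ = scorer.hit_starts(codes, strand)
            if len(starts):
                rows = np.searchsorted(offsets, starts, side="right") - 1
                np.add.at(counts[:, j], rows, 1)
    return pd.DataFrame(counts, index=seq_ids, columns=ids)


def write_hits_bed(hits: Iterable[Hit], path: str | Path) -> None:
    """BED6: chrom, start, end, motif id, round(100 * log-odds), strand."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.start}\t{h.end}\t{h.motif_id}\t"
                f"{round(100 * h.score)}\t{h.strand}\n"
            )
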