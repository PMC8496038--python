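"""Seeded generators for every input the pipeline needs.

Produces monomeric motif catalogs with a target information content,
dimer catalogs in which a configurable fraction of TF pairs cooperate
(with palindromic shared halves so chaining is possible), and labeled
sequence sets with implanted billboard or fixed-geometry motif clusters
plus GC-matched negatives.  Everything is deterministic under the spec
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .motif_model import (
    ALPHABET,
    MotifRecord,
    PositionMatrix,
    is_palindromic,
    reverse_complement,
)
from .multimer_builder import DimerAnnotation

__all__ = [
    "SyntheticSpec",
    "SeqExample",
    "LabeledSequences",
    "PlacementError",
    "InfeasibleSpecError",
    "make_monomer_catalog",
    "make_dimer_catalog",
    "make_labeled_sequences",
    "random_background",
    "sample_site",
    "write_fasta",
    "write_bed",
    "write_manifest",
]

N_CHROMOSOMES = 23  # synthetic chromosome tags chr1..chr23, assigned round-robin


class PlacementError(RuntimeError):
    """Sites could not be placed without overlap within the attempt budget."""


class InfeasibleSpecError(ValueError):
    """The requested information content exceeds 2 bits per position."""


@dataclass(frozen=True)
class SyntheticSpec:
    n_tfs: int = 100
    monomer_length: tuple[int, int] = (6, 10)
    target_ic_bits: float = 12.0
    cooperativity_fraction: float = 0.03
    palindrome_fraction: float = 0.3
    gc: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.cooperativity_fraction, self.palindrome_fraction):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        lo, hi = self.monomer_length
        if lo < 4 or hi < lo:
            raise ValueError("monomer_length must be a range with min >= 4")


@dataclass(frozen=True)
class SeqExample:
    id: str
    chromosome: str
    sequence: str
    label: str  # "positive" | "negative"


@dataclass
class LabeledSequences:
    records: list[SeqExample]
    implants: list[tuple[str, int, int, str, str]]  # seq_id, start, end, motif_id, strand
    spec: SyntheticSpec | None = None
    mode: str = "billboard"


def _column_ic(q: float) -> float:
    """IC of a column with dominant-base probability q, others (1-q)/3."""
    rest = (1.0 - q) / 3.0
    terms = q * np.log2(q) if q > 0 else 0.0
    if rest > 0:
        terms += 3 * rest * np.log2(rest)
    return 2.0 + terms


def _q_for_column_ic(target: float) -> float:
    """Invert dominant-base probability from a per-column IC target in [0, 2]."""
    if target >= 2.0 - 1e-9:
        return 1.0
    if target <= 1e-9:
        return 0.25
    return float(brentq(lambda q: _column_ic(q) - target, 0.25 + 1e-9, 1.0 - 1e-12))


def _motif_columns(length: int, per_col_ic: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    probs = np.empty((length, 4))
    for i in range(length):
        q = _q_for_column_ic(float(per_col_ic[i]))
        probs[i] = (1.0 - q) / 3.0
        probs[i, consensus[i]] = q
    return probs


def make_monomer_catalog(spec: SyntheticSpec) -> list[MotifRecord]:
    """n_tfs seeded PFMs with mean IC within 1 bit of the target.

    The first ``palindrome_fraction`` of TFs (after a seeded shuffle) get
    palindromic matrices (even length, mirror-complement columns) so dimer
    chaining through them is legal downstream.
    """
    lo, hi = spec.monomer_length
    if spec.target_ic_bits > 2 * hi:
        raise InfeasibleSpecError(
            f"target IC {spec.target_ic_bits} bits exceeds the 2 bits/bp cap at length {hi}"
        )
    rng = np.random.default_rng(spec.seed)
    n_pal = int(np.floor(spec.palindrome_fraction * spec.n_tfs))
    pal_flags = np.zeros(spec.n_tfs, dtype=bool)
    pal_flags[:n_pal] = True
    rng.shuffle(pal_flags)

    records: list[MotifRecord] = []
    for t in range(spec.n_tfs):
        length = int(rng.integers(lo, hi + 1))
        if pal_flags[t]:
            length += length % 2  # palindromes need even length
        length = min(length, hi + 1)  # keep close to requested range
        # feasible per-column target, capped at 2 bits, with slight downward jitter
        base = min(2.0, spec.target_ic_bits / length)
        per_col = base - rng.uniform(0.0, min(0.04, base), size=length)
        consensus = rng.integers(0, 4, size=length)
        if pal_flags[t]:
            half = length // 2
            consensus[length - half :] = 3 - consensus[:half][::-1]  # complement mirror
            per_col[length - half :] = per_col[:half][::-1]
        probs = _motif_columns(length, per_col, consensus)
        records.append(
            MotifRecord(id=f"TF{t:04d}", tf_members=(f"TF{t:04d}",), matrix=PositionMatrix(probs))
        )
    return records


def make_dimer_catalog(monomers: Sequence[MotifRecord], spec: SyntheticSpec) -> list[DimerAnnotation]:
    """Join a seeded ``cooperativity_fraction`` of TF pairs into dimers.

    Each dimer is monomer A, a uniform gap of 0-4 columns, then monomer B,
    each half on a random strand.  Palindromy flags come from the source
    monomers themselves.
    """
    n = len(monomers)
    if n < 2:
        raise ValueError("need at least 2 monomers")
    rng = np.random.default_rng(spec.seed + 1)
    ii, jj = np.triu_indices(n, k=1)
    n_pairs = len(ii)
    count = int(np.floor(spec.cooperativity_fraction * n_pairs))
    chosen = rng.choice(n_pairs, size=count, replace=False) if count else np.array([], dtype=int)

    dimers: list[DimerAnnotation] = []
    for d, pair_idx in enumerate(sorted(chosen.tolist())):
        a, b = monomers[ii[pair_idx]], monomers[jj[pair_idx]]
        gap = int(rng.integers(0, 5))
        strand_a = "+" if rng.random() < 0.5 else "-"
        strand_b = "+" if rng.random() < 0.5 else "-"
        mat_a = a.matrix if strand_a == "+" else reverse_complement(a.matrix)
        mat_b = b.matrix if strand_b == "+" else reverse_complement(b.matrix)
        cols = np.vstack([mat_a.probs, np.full((gap, 4), 0.25), mat_b.probs])
        span_a = (0, mat_a.length)
        span_b = (mat_a.length + gap, mat_a.length + gap + mat_b.length)
        motif = MotifRecord(
            id=f"D{d:04d}:{a.id}+{b.id}",
            tf_members=(a.id, b.id),
            matrix=PositionMatrix(cols),
            orientation_notes=(strand_a, strand_b),
        )
        dimers.append(
            DimerAnnotation(
                motif=motif,
                half_spans=(span_a, span_b),
                palindromic_halves=(is_palindromic(a.matrix), is_palindromic(b.matrix)),
                member_order=(a.id, b.id),
            )
        )
    return dimers


def random_background(length: int, gc: float, seed: int | np.random.Generator = 0) -> str:
    """i.i.d. random DNA with the requested GC fraction (split evenly G/C, A/T)."""
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    if length == 0:
        return ""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return "".join(ALPHABET[c] for c in codes)


def sample_site(matrix: PositionMatrix, rng: np.random.Generator) -> str:
    """Draw one site sequence from the PFM column distributions."""
    out = []
    for row in matrix.probs:
        out.append(ALPHABET[rng.choice(4, p=row / row.sum())])
    return "".join(out)


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def make_labeled_sequences(
    motifs: Sequence[MotifRecord],
    mode: str = "billboard",
    n_pos: int = 100,
    n_neg: int = 100,
    length: int = 200,
    sites_per_positive: int = 5,
    spec: SyntheticSpec = SyntheticSpec(),
) -> LabeledSequences:
    """Positive sequences with implanted motif sites plus GC-matched negatives.

    billboard mode implants ``sites_per_positive`` sites (each drawn from a
    uniformly chosen motif of ``motifs``, sampled from its PFM, random
    strand) at non-overlapping uniform positions.  saoc mode implants one
    instance of one (multimeric) motif.  Negatives are background only at
    the same GC.  Ground-truth implant coordinates are returned BED-style.
    """
    if mode not in ("billboard", "saoc"):
        raise ValueError("mode must be 'billboard' or 'saoc'")
    if not motifs:
        raise ValueError("need at least one motif to implant")
    rng = np.random.default_rng(spec.seed + 2)
    records: list[SeqExample] = []
    implants: list[tuple[str, int, int, str, str]] = []

    for i in range(n_pos):
        sid = f"pos{i:05d}"
        seq = list(random_background(length, spec.gc, rng))
        taken: list[tuple[int, int]] = []
        n_sites = sites_per_positive if mode == "billboard" else 1
        for _ in range(n_sites):
            motif = motifs[int(rng.integers(len(motifs)))]
            site = sample_site(motif.matrix, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            placed = _revcomp(site) if strand == "-" else site
            w = len(placed)
            if w > length:
                raise PlacementError(f"site of width {w} does not fit in length {length}")
            for attempt in range(1000):
                start = int(rng.integers(0, length - w + 1))
                if all(start + w <= s or start >= e for s, e in taken):
                    break
            else:
                raise PlacementError(
                    f"could not place {n_sites} non-overlapping sites in {length} bp"
                )
            taken.append((start, start + w))
            seq[start : start + w] = placed
            implants.append((sid, start, start + w, motif.id, strand))
        records.append(
            SeqExample(sid, f"chr{(i % N_CHROMOSOMES) + 1}", "".join(seq), "positive")
        )

    for i in range(n_neg):
        sid = f"neg{i:05d}"
        records.append(
            SeqExample(
                sid,
                f"chr{(i % N_CHROMOSOMES) + 1}",
                random_background(length, spec.gc, rng),
                "negative",
            )
        )
    return LabeledSequences(records=records, implants=implants, spec=spec, mode=mode)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_fasta(ds: LabeledSequences, path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=f"{r.chromosome} {r.label}")
        for r in ds.records
    ]
    seqio_write(recs, str(path), "fasta")


def write_bed(ds: LabeledSequences, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, start, end, motif_id, strand in ds.implants:
            fh.write(f"{sid}\t{start}\t{end}\t{motif_id}\t0\t{strand}\n")


def write_manifest(ds: LabeledSequences, path: str | Path) -> None:
    payload = {
        "mode": ds.mode,
        "spec": asdict(ds.spec) if ds.spec is not None else None,
        "n_records": len(ds.records),
        "n_implants": len(ds.implants),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
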