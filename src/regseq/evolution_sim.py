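"""Neutral-mutation turnover simulation.

Sequences are mutated at an inter-species neutral substitution rate (each
base independently replaced, with probability ``rate``, by one of the three
alternative bases chosen uniformly), then re-scored — either through a
trained classifier's calibrated decision threshold, or by rescanning
multimeric-motif hit loci at their original score thresholds.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .motif_model import ALPHABET, MotifRecord
from .pwm_scanner import PwmScorer, ScanConfig, encode
from .classifier_pipeline import TrainedModel, score_sequences

__all__ = [
    "EvolutionConfig",
    "TurnoverReport",
    "mutate",
    "classifier_dropout",
    "HitLoci",
    "collect_hit_loci",
    "multimer_turnover",
    "write_turnover_tsv",
]

RATE_HUMAN_MACAQUE = 0.06
RATE_HUMAN_MOUSE = 0.49


@dataclass(frozen=True)
class EvolutionConfig:
    rate: float = RATE_HUMAN_MACAQUE
    seed: int = 0
    replicates: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.rate <= 1:
            raise ValueError("rate must be in [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class TurnoverReport:
    n_elements: int
    n_retained: int
    retained_fraction: float
    per_replicate: list[tuple[int, int]]  # (n, retained) per replicate
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        assert 0.0 <= self.retained_fraction <= 1.0


def _binomial_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Clopper-Pearson interval for a pooled retention count."""
    if n == 0:
        return (0.0, 1.0)
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _report(per_replicate: list[tuple[int, int]]) -> TurnoverReport:
    n = sum(a for a, _ in per_replicate)
    k = sum(b for _, b in per_replicate)
    lo, hi = _binomial_ci(k, n)
    return TurnoverReport(
        n_elements=n,
        n_retained=k,
        retained_fraction=k / n if n else 0.0,
        per_replicate=per_replicate,
        ci_low=lo,
        ci_high=hi,
    )


_MUT_OFFSET = np.array(
    [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]], dtype=np.int8
)  # alternatives per base code


def mutate(seq: str, cfg: EvolutionConfig, rng: np.random.Generator | None = None) -> str:
    """Substitute each base independently with probability ``cfg.rate``.

    Replacements are uniform over the three alternative bases; ambiguous
    characters are left untouched; length is preserved.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    codes = encode(seq)
    out = codes.copy()
    hit = (rng.random(len(codes)) < cfg.rate) & (codes < 4)
    if hit.any():
        alt = rng.integers(0, 3, size=int(hit.sum()))
        out[hit] = _MUT_OFFSET[codes[hit], alt]
    chars = np.array(list(ALPHABET + "N"))
    return "".join(chars[out])


def classifier_dropout(
    model: TrainedModel,
    elements: Sequence[tuple[str, str]],
    cfg: EvolutionConfig,
) -> TurnoverReport:
    """Mutate positive-scoring elements and count how many still score positive.

    ``elements`` are (id, sequence) pairs that all score at or above the
    model's calibrated decision threshold before mutation.
    """
    if len(elements) == 0:
        raise ValueError("element set must be non-empty")
    pre = score_sequences(model, list(elements))
    if np.any(pre < model.decision_threshold):
        bad = int(np.sum(pre < model.decision_threshold))
        raise ValueError(f"{bad} element(s) score below the decision threshold pre-mutation")
    rng = np.random.default_rng(cfg.seed)
    per_rep: list[tuple[int, int]] = []
    for _ in range(cfg.replicates):
        mutated = [(sid, mutate(s, cfg, rng)) for sid, s in elements]
        post = score_sequences(model, mutated)
        per_rep.append((len(elements), int(np.sum(post >= model.decision_threshold))))
    return _report(per_rep)


@dataclass
class HitLoci:
    """Pre-mutation multimer hit loci, stratified by (arity, cutoff)."""

    loci: dict[tuple[int, float], list[tuple[int, np.ndarray]]]
    scorers: dict[tuple[int, float], "PwmScorer"]


def collect_hit_loci(
    motifs: Sequence[MotifRecord],
    corpus: str | np.ndarray,
    p_cutoffs: Sequence[float] = (1e-11, 1e-10, 1e-9),
    scan_config: ScanConfig = ScanConfig(),
) -> HitLoci:
    """Scan a corpus for multimer hits and keep each hit locus plus flanks.

    Each motif is scanned once at the loosest cutoff; stricter strata are
    derived by filtering hit scores against their own thresholds (the
    discretization is shared, so this is exact).  A locus is the hit window
    plus one motif length of flank on either side.
    """
    codes = corpus if isinstance(corpus, np.ndarray) else encode(corpus)
    strands = ("+", "-") if scan_config.strands == "both" else ("+",)
    loci: dict[tuple[int, float], list[tuple[int, np.ndarray]]] = {}
    scorers: dict[tuple[int, float], PwmScorer] = {}
    loosest = max(p_cutoffs)
    for mi, motif in enumerate(motifs):
        L = motif.matrix.length
        for cutoff in p_cutoffs:
            scorers[(mi, cutoff)] = PwmScorer(motif, ScanConfig(
                p_value=cutoff,
                background=scan_config.background,
                score_discretization=scan_config.score_discretization,
                strands=scan_config.strands,
                pseudocount=scan_config.pseudocount,
            ))
            loci.setdefault((motif.arity, cutoff), [])
        base = scorers[(mi, loosest)]
        for strand in strands:
            starts, scores = base.hit_starts(codes, strand)
            for s, q_sum in zip(starts, scores):
                lo = max(0, int(s) - L)
                hi = min(len(codes), int(s) + 2 * L)
                locus = codes[lo:hi].copy()
                for cutoff in p_cutoffs:
                    if q_sum >= scorers[(mi, cutoff)].t_int:
                        loci[(motif.arity, cutoff)].append((mi, locus))
    return HitLoci(loci=loci, scorers=scorers)


def multimer_turnover(
    motifs: Sequence[MotifRecord],
    corpus: str | np.ndarray,
    p_cutoffs: Sequence[float] = (1e-11, 1e-10, 1e-9),
    cfg: EvolutionConfig = EvolutionConfig(),
    scan_config: ScanConfig = ScanConfig(),
    precollected: HitLoci | None = None,
) -> dict[tuple[int, float], TurnoverReport | None]:
    """Scan a corpus for multimer hits, mutate each hit locus, and rescan.

    For every (arity, cutoff) stratum: hits are corpus windows scoring at or
    above the cutoff threshold; each hit locus plus one motif-length flank
    on either side is mutated and rescanned, and the hit is retained if any
    window of the mutated locus still reaches the same threshold.  Strata
    with zero pre-mutation hits are reported as ``None`` (NA), not zero.
    ``precollected`` reuses hit loci across mutation rates.
    """
    collected = precollected or collect_hit_loci(motifs, corpus, p_cutoffs, scan_config)
    loci, scorers = collected.loci, collected.scorers
    strands = ("+", "-") if scan_config.strands == "both" else ("+",)
    rng = np.random.default_rng(cfg.seed)

    out: dict[tuple[int, float], TurnoverReport | None] = {}
    for stratum, entries in sorted(loci.items()):
        if not entries:
            out[stratum] = None
            continue
        _, cutoff = stratum
        per_rep: list[tuple[int, int]] = []
        for _ in range(cfg.replicates):
            retained = 0
            for mi, locus in entries:
                mutated = _mutate_codes(locus, cfg.rate, rng)
                sc = scorers[(mi, cutoff)]
                ok = False
                for strand in strands:
                    hs, _ = sc.hit_starts(mutated, strand)
                    if len(hs):
                        ok = True
                        break
                retained += ok
            per_rep.append((len(entries), retained))
        out[stratum] = _report(per_rep)
    return out


def _mutate_codes(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    hit = (rng.random(len(codes)) < rate) & (codes < 4)
    if hit.any():
        alt = rng.integers(0, 3, size=int(hit.sum()))
        out[hit] = _MUT_OFFSET[codes[hit], alt]
    return out


def write_turnover_tsv(
    reports: Mapping[tuple[int, float], TurnoverReport | None],
    rate: float,
    path: str | Path,
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["arity", "cutoff", "rate", "n", "retained", "fraction", "ci_lo", "ci_hi"])
        for (arity, cutoff), rep in sorted(reports.items()):
            if rep is None:
                w.writerow([arity, cutoff, rate, 0, "NA", "NA", "NA", "NA"])
            else:
                w.writerow([
                    arity, cutoff, rate, rep.n_elements, rep.n_retained,
                    f"{rep.retained_fraction:.6f}", f"{rep.ci_low:.6f}", f"{rep.ci_high:.6f}",
                ])
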