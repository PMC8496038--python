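"""Hit-count-feature logistic-regression classification of regulatory sequence.

Features are per-motif hit counts at a fixed scanning p-value, z-scored per
feature.  Training/evaluation uses chromosome-held-out splits; feature
selection supports RFE, L1 and elastic-net modes.  A trained model can tile
a long region into overlapping windows and calibrate its decision threshold
to a target genome-wide positivity rate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .motif_model import MotifRecord
from .pwm_scanner import PwmScorer, ScanConfig, encode, hit_count_features
from .synthetic_data import SeqExample

__all__ = [
    "LabeledDataset",
    "TrainedModel",
    "build_dataset",
    "load_fasta_bed",
    "chromosome_split_train",
    "score_sequences",
    "tile_and_score",
    "calibrate_threshold",
    "save_model",
    "load_model",
    "DEFAULT_TRAIN_CHROMS",
    "DEFAULT_TEST_CHROMS",
]

DEFAULT_TRAIN_CHROMS = tuple(f"chr{i}" for i in range(1, 17))
DEFAULT_TEST_CHROMS = tuple(f"chr{i}" for i in range(17, 24))


@dataclass
class LabeledDataset:
    """Sequences, raw hit-count features, and per-feature scaler parameters."""

    records: list[SeqExample]
    features: pd.DataFrame  # raw integer counts, rows align with records
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    motifs: list[MotifRecord]
    scan_config: ScanConfig

    @property
    def motif_ids(self) -> list[str]:
        return list(self.features.columns)

    @property
    def labels(self) -> np.ndarray:
        return np.array([1 if r.label == "positive" else 0 for r in self.records])

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([r.chromosome for r in self.records])

    def scaled(self) -> np.ndarray:
        """Z-scored features; zero-variance features map to all zeros."""
        sd = np.where(self.scaler_sd > 0, self.scaler_sd, 1.0)
        x = (self.features.to_numpy(float) - self.scaler_mean) / sd
        x[:, self.scaler_sd == 0] = 0.0
        return x


@dataclass
class TrainedModel:
    """Logistic model over motif hit-count features.

    ``weights`` is indexed by motif id with zeros for unselected features;
    ``decision_threshold`` lives on the decision-function (log-odds) scale.
    """

    weights: pd.Series
    intercept: float
    selected_features: list[str]
    decision_threshold: float
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    motifs: list[MotifRecord] = field(default_factory=list, repr=False)
    scan_config: ScanConfig = field(default_factory=ScanConfig)


def build_dataset(
    positives: Sequence[SeqExample],
    negatives: Sequence[SeqExample],
    motifs: Sequence[MotifRecord],
    scan_config: ScanConfig = ScanConfig(),
) -> LabeledDataset:
    """Assemble a labeled dataset with z-scored hit-count features.

    Warns when positives and negatives are imbalanced by more than 1%.
    """
    n_pos, n_neg = len(positives), len(negatives)
    if n_pos and n_neg:
        imbalance = abs(n_pos - n_neg) / max(n_pos, n_neg)
        if imbalance > 0.01:
            warnings.warn(f"dataset imbalanced: {n_pos} positives vs {n_neg} negatives")
    records = list(positives) + list(negatives)
    feats = hit_count_features([(r.id, r.sequence) for r in records], list(motifs), scan_config)
    x = feats.to_numpy(float)
    return LabeledDataset(
        records=records,
        features=feats,
        scaler_mean=x.mean(axis=0),
        scaler_sd=x.std(axis=0),
        motifs=list(motifs),
        scan_config=scan_config,
    )


def load_fasta_bed(
    fasta_path: str | Path,
    bed_path: str | Path,
    length: int = 200,
    label: str = "positive",
) -> list[SeqExample]:
    """Adapter for user-supplied FASTA + BED peaks.

    Each BED interval is replaced by a window of ``length`` bp centered on
    the interval midpoint; peaks closer than length/2 to a sequence end are
    dropped with a warning.
    """
    from Bio import SeqIO

    if not 20 <= length <= 600:
        raise ValueError("length must be in [20, 600]")
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    out: list[SeqExample] = []
    half = length // 2
    with open(bed_path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if chrom not in seqs:
                warnings.warn(f"BED line {i + 1}: unknown sequence {chrom!r}; dropped")
                continue
            center = (start + end) // 2
            lo, hi = center - half, center - half + length
            if lo < 0 or hi > len(seqs[chrom]):
                warnings.warn(f"BED line {i + 1}: peak too close to sequence end; dropped")
                continue
            out.append(SeqExample(f"{chrom}:{lo}-{hi}", chrom, seqs[chrom][lo:hi], label))
    return out


def _fit_estimator(selection: str, params: dict, seed: int) -> LogisticRegression:
    if selection == "l1":
        return LogisticRegression(
            penalty="l1", solver="saga", C=params.get("C", 0.00125),
            max_iter=params.get("max_iter", 5000), random_state=seed,
        )
    if selection == "elasticnet":
        return LogisticRegression(
            penalty="elasticnet", solver="saga", C=params.get("C", 0.0007),
            l1_ratio=params.get("l1_ratio", 0.5),
            max_iter=params.get("max_iter", 5000), random_state=seed,
        )
    # default / RFE base estimator: plain L2 logistic regression
    return LogisticRegression(max_iter=params.get("max_iter", 5000), random_state=seed)


def chromosome_split_train(
    ds: LabeledDataset,
    train_chroms: Sequence[str] = DEFAULT_TRAIN_CHROMS,
    test_chroms: Sequence[str] = DEFAULT_TEST_CHROMS,
    selection: str = "none",
    params: dict | None = None,
    seed: int = 0,
) -> tuple[TrainedModel, float]:
    """Fit on the train chromosomes, report AUROC on the held-out ones."""
    params = dict(params or {})
    train_set, test_set = set(train_chroms), set(test_chroms)
    if train_set & test_set:
        raise ValueError(f"train/test chromosomes overlap: {sorted(train_set & test_set)}")
    if selection not in ("none", "rfe_k", "l1", "elasticnet"):
        raise ValueError(f"unknown selection mode {selection!r}")

    chroms = ds.chromosomes
    y = ds.labels
    x = ds.scaled()
    tr = np.isin(chroms, list(train_set))
    te = np.isin(chroms, list(test_set))
    if tr.sum() == 0 or te.sum() == 0:
        raise ValueError("empty train or test split")

    motif_ids = ds.motif_ids
    if selection == "rfe_k":
        k = int(params.get("k", 150))
        if k >= len(motif_ids):
            selection = "none"
    if selection == "rfe_k":
        rfe = RFE(_fit_estimator("none", params, seed), n_features_to_select=k)
        rfe.fit(x[tr], y[tr])
        mask = rfe.support_
        est = _fit_estimator("none", params, seed)
        est.fit(x[tr][:, mask], y[tr])
        coefs = np.zeros(len(motif_ids))
        coefs[mask] = est.coef_[0]
        intercept = float(est.intercept_[0])
        selected = [m for m, keep in zip(motif_ids, mask) if keep]
        score = x[te][:, mask] @ est.coef_[0] + intercept
    else:
        est = _fit_estimator(selection, params, seed)
        est.fit(x[tr], y[tr])
        coefs = est.coef_[0]
        intercept = float(est.intercept_[0])
        if selection in ("l1", "elasticnet"):
            selected = [m for m, c in zip(motif_ids, coefs) if c != 0]
        else:
            selected = list(motif_ids)
        score = x[te] @ coefs + intercept

    auroc = float(roc_auc_score(y[te], score))
    model = TrainedModel(
        weights=pd.Series(coefs, index=motif_ids),
        intercept=intercept,
        selected_features=selected,
        decision_threshold=0.0,
        scaler_mean=ds.scaler_mean,
        scaler_sd=ds.scaler_sd,
        motifs=ds.motifs,
        scan_config=ds.scan_config,
    )
    return model, auroc


def _scale(model: TrainedModel, counts: np.ndarray) -> np.ndarray:
    sd = np.where(model.scaler_sd > 0, model.scaler_sd, 1.0)
    x = (counts.astype(float) - model.scaler_mean) / sd
    x[:, model.scaler_sd == 0] = 0.0
    return x


def score_sequences(model: TrainedModel, sequences: Sequence[tuple[str, str]]) -> np.ndarray:
    """Decision-function scores for raw sequences (features recomputed)."""
    feats = hit_count_features(list(sequences), model.motifs, model.scan_config)
    x = _scale(model, feats.to_numpy())
    return x @ model.weights.to_numpy() + model.intercept


def tile_and_score(
    model: TrainedModel,
    region: str,
    window: int = 200,
    stride: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Score every window of a long region; returns (starts, scores).

    Hit counts per window are derived from a single full-region scan per
    motif (a hit is assigned to every window that fully contains it), which
    is equivalent to scanning each window separately.
    """
    if len(region) < window:
        raise ValueError("region shorter than window")
    starts = np.arange(0, len(region) - window + 1, stride)
    codes = encode(region)
    counts = np.zeros((len(starts), len(model.motifs)), dtype=np.int64)
    strands = ("+", "-") if model.scan_config.strands == "both" else ("+",)
    for j, motif in enumerate(model.motifs):
        scorer = PwmScorer(motif, model.scan_config)
        L = scorer.length
        for strand in strands:
            hit_starts, _ = scorer.hit_starts(codes, strand)
            for s in hit_starts:
                # windows [w, w+window) with w <= s and s + L <= w + window
                w_lo = int(np.ceil(max(0, s + L - window) / stride))
                w_hi = int(np.floor(s / stride))
                w_hi = min(w_hi, len(starts) - 1)
                if w_lo <= w_hi:
                    counts[w_lo : w_hi + 1, j] += 1
    x = _scale(model, counts)
    return starts, x @ model.weights.to_numpy() + model.intercept


def positive_base_fraction(
    starts: np.ndarray, scores: np.ndarray, threshold: float, window: int, region_length: int
) -> float:
    """Fraction of bases covered by at least one positive-scoring window."""
    covered = np.zeros(region_length, dtype=bool)
    for s in starts[scores >= threshold]:
        covered[s : s + window] = True
    return float(covered.mean())


def calibrate_threshold(scores: np.ndarray, target_positive_fraction: float = 0.01) -> float:
    """Threshold such that ~``target_positive_fraction`` of scores are >= it.

    Uses the (1 - target) empirical quantile; ties are broken toward fewer
    positives.  All-equal scores cannot be calibrated.
    """
    scores = np.asarray(scores, float)
    if len(scores) == 0:
        raise ValueError("empty score array")
    if not 0 < target_positive_fraction <= 1:
        raise ValueError("target_positive_fraction must be in (0, 1]")
    if np.all(scores == scores[0]):
        raise ValueError("cannot calibrate a threshold on all-equal scores")
    if target_positive_fraction == 1.0:
        return float(scores.min())
    s = np.sort(scores)[::-1]
    k = max(int(round(len(s) * target_positive_fraction)), 1)
    t = s[k - 1]
    # ties at t may inflate the positive count; move just above if so
    n_at_or_above = int(np.sum(scores >= t))
    if n_at_or_above > k:
        higher = s[s > t]
        t = float(higher.min()) if len(higher) else float(np.nextafter(t, np.inf))
    return float(t)


def save_model(model: TrainedModel, weights_path: str | Path, header_path: str | Path) -> None:
    """Weights as TSV (motif_id, weight); intercept/threshold/scaler as JSON."""
    model.weights.rename("weight").to_csv(weights_path, sep="\t", index_label="motif_id")
    payload = {
        "intercept": model.intercept,
        "decision_threshold": model.decision_threshold,
        "selected_features": model.selected_features,
        "scaler_mean": model.scaler_mean.tolist(),
        "scaler_sd": model.scaler_sd.tolist(),
        "scan_p_value": model.scan_config.p_value,
    }
    Path(header_path).write_text(json.dumps(payload, indent=2) + "\n")


def load_model(
    weights_path: str | Path,
    header_path: str | Path,
    motifs: Sequence[MotifRecord] = (),
    scan_config: ScanConfig | None = None,
) -> TrainedModel:
    tab = pd.read_csv(weights_path, sep="\t", index_col="motif_id")
    payload = json.loads(Path(header_path).read_text())
    return TrainedModel(
        weights=tab["weight"],
        intercept=payload["intercept"],
        selected_features=payload["selected_features"],
        decision_threshold=payload["decision_threshold"],
        scaler_mean=np.asarray(payload["scaler_mean"]),
        scaler_sd=np.asarray(payload["scaler_sd"]),
        motifs=list(motifs),
        scan_config=scan_config or ScanConfig(p_value=payload.get("scan_p_value", 1e-4)),
    )
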