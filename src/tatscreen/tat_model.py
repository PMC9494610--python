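"""Tumour-associated T-cell (TAT) sequence classifier.

Positive examples are CDR3beta sequences of PBMC clones shared with the
paired tumour (cTATs), after removal of anything present in the healthy
reference pool or in virus/bacteria exclusion lists; negatives are drawn
1:1 from the healthy pool. Sequences are one-hot encoded (20 amino-acid
channels + 1 padding channel, padded to length 17) and fed to a
three-layer convolutional network whose output is the probability that a
sequence belongs to a TAT.

Cross-validation splits positives at the *patient* level, never at the
sequence level, so the model cannot be credited for memorising
patient-specific repertoire quirks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from ._nn import SmallCnn
from .types import AA_ALPHABET, Repertoire, TcrPool

MIN_LEN = 12
MAX_LEN = 17
N_CHANNELS = 21  # 20 amino acids + padding
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
PAD_CHANNEL = 20

SERIALIZATION_VERSION = "tatscreen-model-1"


class EncodingError(ValueError):
    """Sequence cannot be one-hot encoded (bad length or alphabet)."""


@dataclass
class CnnConfig:
    """Architecture and training hyperparameters.

    The depth (three convolution layers) is the modelling choice; channel
    counts, kernel width, optimizer and schedule are declared defaults.
    """

    channels: tuple[int, ...] = (32, 64, 128)
    kernel: int = 3
    epochs: int = 60
    batch_size: int = 256
    learning_rate: float = 1e-3
    seed: int = 0


@dataclass
class TrainingSet:
    positives: list[tuple[str, str]]  # (cdr3_aa, subject_id)
    negatives: list[tuple[str, str]]  # (cdr3_aa, pool label)
    provenance: dict = field(default_factory=dict)

    @property
    def positive_sequences(self) -> list[str]:
        return [s for s, _ in self.positives]

    @property
    def negative_sequences(self) -> list[str]:
        return [s for s, _ in self.negatives]


@dataclass
class TatModel:
    net: SmallCnn
    config: CnnConfig
    history: dict[str, list[float]] = field(default_factory=dict)
    version: str = SERIALIZATION_VERSION

    def save(self, path: str | Path) -> None:
        """Single-file archive: JSON header (version, architecture,
        training config) + raw parameter arrays."""
        header = {
            "version": self.version,
            "state": {**self.net.state(), "channels": list(self.net.channels)},
            "config": {**self.config.__dict__, "channels": list(self.config.channels)},
            "history": self.history,
        }
        arrays = {f"param_{k}": v for k, v in self.net.params.items()}
        np.savez(path, header=np.array(json.dumps(header)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TatModel":
        with np.load(path, allow_pickle=False) as f:
            header = json.loads(str(f["header"]))
            params = {k[len("param_") :]: f[k] for k in f.files if k.startswith("param_")}
        cfg_d = header["config"]
        cfg = CnnConfig(**{**cfg_d, "channels": tuple(cfg_d["channels"])})
        net = SmallCnn.from_state(header["state"], params)
        return cls(net=net, config=cfg, history=header.get("history", {}), version=header["version"])


@dataclass
class CvReport:
    """Per-fold held-out metrics from patient-level cross-validation."""

    fold_metrics: pd.DataFrame  # columns: fold, roc_auc, prc_auc
    fold_subjects: dict[int, list[str]]
    histories: list[dict[str, list[float]]]

    @property
    def mean_roc_auc(self) -> float:
        return float(self.fold_metrics["roc_auc"].mean())


# ---------------------------------------------------------------------------
# encoding


def encodable(seq: str, max_len: int = MAX_LEN, min_len: int = MIN_LEN) -> bool:
    return min_len <= len(seq) <= max_len and all(c in _AA_INDEX for c in seq)


def encode_cdr3(seq: str, max_len: int = MAX_LEN) -> np.ndarray:
    """One-hot encode a CDR3 sequence to (max_len, 21).

    Row i is the one-hot of residue i; rows past the sequence end are the
    dedicated padding channel, so one network handles all lengths 12-17.
    """
    if not (MIN_LEN <= len(seq) <= max_len):
        raise EncodingError(f"sequence length {len(seq)} outside [{MIN_LEN}, {max_len}]: {seq!r}")
    mat = np.zeros((max_len, N_CHANNELS))
    for i, c in enumerate(seq):
        j = _AA_INDEX.get(c)
        if j is None:
            raise EncodingError(f"invalid amino acid {c!r} in {seq!r}")
        mat[i, j] = 1.0
    mat[len(seq) :, PAD_CHANNEL] = 1.0
    return mat


def decode_cdr3(mat: np.ndarray) -> str:
    """Inverse of :func:`encode_cdr3` (padding rows ignored)."""
    out = []
    for row in mat:
        j = int(row.argmax())
        if j == PAD_CHANNEL:
            break
        out.append(AA_ALPHABET[j])
    return "".join(out)


def encode_batch(seqs, max_len: int = MAX_LEN) -> np.ndarray:
    return np.stack([encode_cdr3(s, max_len) for s in seqs])


# ---------------------------------------------------------------------------
# training-set construction


def build_training_set(
    tat_reps: list[Repertoire],
    healthy_pool: TcrPool,
    exclusion: TcrPool | None = None,
    seed: int = 0,
) -> TrainingSet:
    """Positives = distinct TAT CDR3s minus pool minus exclusion lists;
    negatives = an equal-size uniform sample (without replacement) from
    the pool minus exclusions.

    ``tat_reps`` must already be restricted to the PBMCs_Shared
    compartment. Positives are deduplicated globally; a sequence seen in
    several patients is attributed to the first by sorted subject id.
    """
    excl = exclusion.sequences if exclusion is not None else frozenset()
    pos_subject: dict[str, str] = {}
    for rep in sorted(tat_reps, key=lambda r: r.subject_id):
        for clone in rep:
            seq = clone.cdr3_aa
            if seq in pos_subject or seq in healthy_pool.sequences or seq in excl:
                continue
            if not encodable(seq):
                continue
            pos_subject[seq] = rep.subject_id
    positives = sorted(pos_subject.items())
    if not positives:
        warnings.warn("no positive sequences remain after filtering", stacklevel=2)

    candidates = sorted(s for s in healthy_pool.sequences - excl if encodable(s))
    if len(candidates) < len(positives):
        raise ValueError(
            f"healthy pool too small: {len(candidates)} candidates for {len(positives)} positives"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=len(positives), replace=False)
    negatives = [(candidates[i], healthy_pool.label) for i in sorted(chosen)]
    return TrainingSet(
        positives=positives,
        negatives=negatives,
        provenance={
            "n_input_reps": len(tat_reps),
            "pool": healthy_pool.label,
            "n_excluded_by_pool_or_list": sum(len(r) for r in tat_reps) - len(positives),
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# training / prediction


def _fit(seqs_pos, seqs_neg, config: CnnConfig) -> tuple[SmallCnn, dict]:
    x = encode_batch(list(seqs_pos) + list(seqs_neg))
    y = np.concatenate([np.ones(len(seqs_pos)), np.zeros(len(seqs_neg))])
    net = SmallCnn(
        input_len=MAX_LEN,
        input_channels=N_CHANNELS,
        channels=config.channels,
        kernel=config.kernel,
        seed=config.seed,
    )
    history = net.fit(
        x,
        y,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        seed=config.seed,
    )
    return net, history


def train(ts: TrainingSet, config: CnnConfig | None = None) -> TatModel:
    """Fit the convolutional classifier on a full training set."""
    config = config or CnnConfig()
    if not ts.positives or not ts.negatives:
        raise ValueError("both classes must be non-empty")
    net, history = _fit(ts.positive_sequences, ts.negative_sequences, config)
    return TatModel(net=net, config=config, history=history)


def predict(model: TatModel, seqs) -> np.ndarray:
    """Per-sequence TAT probability; unencodable sequences yield NaN
    (with a warning) rather than failing the whole batch."""
    seqs = list(seqs)
    unique = sorted({s for s in seqs if encodable(s)})
    out = np.full(len(seqs), np.nan)
    n_bad = sum(not encodable(s) for s in seqs)
    if n_bad:
        warnings.warn(f"{n_bad} sequence(s) not encodable; returned NaN", stacklevel=2)
    if unique:
        # score each distinct sequence once: duplicates get bit-identical output
        probs = dict(zip(unique, model.net.predict_proba(encode_batch(unique))))
        for i, s in enumerate(seqs):
            if s in probs:
                out[i] = probs[s]
    return out


def cross_validate(
    ts: TrainingSet, k: int = 5, config: CnnConfig | None = None, seed: int = 0
) -> CvReport:
    """k-fold cross-validation with positives split by subject (patient),
    negatives split at random; held-out ROC-AUC / PRC-AUC per fold."""
    config = config or CnnConfig()
    subjects = sorted({subj for _, subj in ts.positives})
    if len(subjects) < k:
        raise ValueError(f"{len(subjects)} subjects < {k} folds")
    rng = np.random.default_rng(seed)
    subj_order = rng.permutation(len(subjects))
    subj_folds = np.array_split(subj_order, k)
    neg_order = rng.permutation(len(ts.negatives))
    neg_folds = np.array_split(neg_order, k)

    rows, fold_subjects, histories = [], {}, []
    for fold in range(k):
        test_subj = {subjects[i] for i in subj_folds[fold]}
        fold_subjects[fold] = sorted(test_subj)
        pos_tr = [s for s, subj in ts.positives if subj not in test_subj]
        pos_te = [s for s, subj in ts.positives if subj in test_subj]
        neg_te_idx = set(neg_folds[fold].tolist())
        neg_tr = [ts.negatives[i][0] for i in range(len(ts.negatives)) if i not in neg_te_idx]
        neg_te = [ts.negatives[i][0] for i in neg_folds[fold]]
        net, hist = _fit(pos_tr, neg_tr, config)
        histories.append(hist)
        x_te = encode_batch(pos_te + neg_te)
        y_te = np.concatenate([np.ones(len(pos_te)), np.zeros(len(neg_te))])
        p = net.predict_proba(x_te)
        rows.append(
            {
                "fold": fold,
                "roc_auc": roc_auc_score(y_te, p),
                "prc_auc": average_precision_score(y_te, p),
            }
        )
    return CvReport(
        fold_metrics=pd.DataFrame(rows), fold_subjects=fold_subjects, histories=histories
    )


# ---------------------------------------------------------------------------
# motif enrichment


@dataclass
class MotifEnrichment:
    """Positional amino-acid composition of high- vs low-probability
    predictions, per CDR3 length stratum, plus pooled log-odds."""

    per_length: dict[int, dict[str, pd.DataFrame]]  # {"high", "low", "log_odds"}
    pooled_log_odds: pd.DataFrame  # positions x amino acids

    def top_positions(self, n: int = 5) -> list[tuple[int, str, float]]:
        """The n largest pooled log-odds entries as (position, aa, value)."""
        stacked = self.pooled_log_odds.stack().sort_values(ascending=False)
        return [(int(pos), str(aa), float(v)) for (pos, aa), v in stacked.head(n).items()]


def _positional_counts(seqs: list[str], max_len: int) -> tuple[np.ndarray, np.ndarray]:
    counts = np.zeros((max_len, 20))
    denom = np.zeros(max_len)
    for s in seqs:
        for i, c in enumerate(s):
            counts[i, _AA_INDEX[c]] += 1
        denom[: len(s)] += 1
    return counts, denom


def motif_enrichment(
    seqs,
    probs,
    top_q: float = 0.25,
    bottom_q: float = 0.25,
    pseudocount: float = 0.5,
) -> MotifEnrichment:
    """Compare positional amino-acid frequencies between sequences with the
    highest and lowest predicted TAT probabilities.

    The high group is all sequences at or above the (1 - top_q) probability
    quantile, the low group at or below the bottom_q quantile. Frequencies
    are computed per length stratum (columns sum to 1 at each occupied
    position); log-odds are log2((f_high + pc) / (f_low + pc)).
    """
    seqs = list(seqs)
    probs = np.asarray(probs, dtype=float)
    if len(seqs) < 4:
        raise ValueError("need at least 4 sequences")
    hi_cut = np.nanquantile(probs, 1 - top_q)
    lo_cut = np.nanquantile(probs, bottom_q)
    high = [s for s, p in zip(seqs, probs) if p >= hi_cut]
    low = [s for s, p in zip(seqs, probs) if p <= lo_cut]

    aa_cols = list(AA_ALPHABET)
    per_length: dict[int, dict[str, pd.DataFrame]] = {}
    for length in sorted({len(s) for s in seqs}):
        h = [s for s in high if len(s) == length]
        lo = [s for s in low if len(s) == length]
        if not h or not lo:
            warnings.warn(f"length {length}: empty high/low stratum, skipped", stacklevel=2)
            continue
        ch, dh = _positional_counts(h, length)
        cl, dl = _positional_counts(lo, length)
        fh = ch / dh[:, None]
        fl = cl / dl[:, None]
        lo_mat = np.log2((fh + pseudocount / len(h)) / (fl + pseudocount / len(lo)))
        per_length[length] = {
            "high": pd.DataFrame(fh, columns=aa_cols),
            "low": pd.DataFrame(fl, columns=aa_cols),
            "log_odds": pd.DataFrame(lo_mat, columns=aa_cols),
        }

    max_len = max((len(s) for s in high + low), default=0)
    ch, dh = _positional_counts(high, max_len)
    cl, dl = _positional_counts(low, max_len)
    with np.errstate(invalid="ignore", divide="ignore"):
        fh = np.where(dh[:, None] > 0, ch / np.maximum(dh, 1)[:, None], np.nan)
        fl = np.where(dl[:, None] > 0, cl / np.maximum(dl, 1)[:, None], np.nan)
        pooled = np.log2(
            (fh + pseudocount / max(len(high), 1)) / (fl + pseudocount / max(len(low), 1))
        )
    pooled_df = pd.DataFrame(pooled, columns=aa_cols)
    pooled_df.index.name = "position"
    return MotifEnrichment(per_length=per_length, pooled_log_odds=pooled_df)
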