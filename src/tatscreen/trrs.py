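"""TCR repertoire risk score (TRRS).

For one PBMC sample the score is the number of unique CDR3 sequences the
classifier calls TAT (probability above a cutoff, default .66) divided by
the number of unique sequences also found in the healthy reference pool.
The denominator normalises for sequencing depth and for the baseline
amount of "ordinary" repertoire, so the ratio reflects TAT enrichment
rather than library size. The score is presence-based: clone counts never
enter it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .compartments import pool_overlap
from .tat_model import TatModel, encodable, predict
from .types import Repertoire, TcrPool

DEFAULT_THRESHOLD = 0.66


@dataclass
class TrrsResult:
    sample_id: str
    n_predicted_tats: int
    n_healthy_overlap: int
    trrs: float | None  # None when the pool overlap is zero
    prob_threshold: float = DEFAULT_THRESHOLD


def _sample_probs(rep: Repertoire, model: TatModel) -> tuple[list[str], np.ndarray]:
    seqs = sorted(s for s in rep.unique_sequences if encodable(s))
    if not seqs:
        return [], np.empty(0)
    return seqs, predict(model, seqs)


def _result_from_probs(
    rep: Repertoire,
    probs: np.ndarray,
    pool: TcrPool,
    prob_threshold: float,
) -> TrrsResult:
    n_tats = int((probs > prob_threshold).sum())
    n_overlap, _ = pool_overlap(rep, pool)
    if n_overlap == 0:
        warnings.warn(
            f"{rep.sample_id}: no overlap with pool {pool.label!r}; TRRS undefined",
            stacklevel=2,
        )
        score = None
    else:
        score = n_tats / n_overlap
    return TrrsResult(
        sample_id=rep.sample_id,
        n_predicted_tats=n_tats,
        n_healthy_overlap=n_overlap,
        trrs=score,
        prob_threshold=prob_threshold,
    )


def compute_trrs(
    rep: Repertoire,
    model: TatModel,
    pool: TcrPool,
    prob_threshold: float = DEFAULT_THRESHOLD,
) -> TrrsResult:
    """Score one (functional, length-filtered) PBMC repertoire."""
    _, probs = _sample_probs(rep, model)
    return _result_from_probs(rep, probs, pool, prob_threshold)


def score_cohort(
    reps: list[Repertoire],
    model: TatModel,
    pool: TcrPool,
    labels=None,
    prob_threshold: float = DEFAULT_THRESHOLD,
) -> tuple[pd.DataFrame, float | None]:
    """Per-sample TRRS table plus the cohort ROC-AUC against binary labels.

    ``labels`` (1 = tumour, 0 = control, parallel to ``reps``) may be
    omitted or single-class, in which case only scores are returned.
    """
    results = [compute_trrs(r, model, pool, prob_threshold) for r in reps]
    table = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "n_predicted_tats": [r.n_predicted_tats for r in results],
            "n_healthy_overlap": [r.n_healthy_overlap for r in results],
            "trrs": [r.trrs for r in results],
        }
    )
    auc = None
    if labels is not None:
        table["label"] = list(labels)
        usable = table.dropna(subset=["trrs"])
        if usable["label"].nunique() >= 2:
            auc = float(roc_auc_score(usable["label"], usable["trrs"]))
    return table, auc


def threshold_sensitivity(
    reps: list[Repertoire],
    model: TatModel,
    pool: TcrPool,
    labels,
    thresholds=(0.5, 0.6, 0.66, 0.7, 0.8),
) -> pd.DataFrame:
    """Cohort AUC across a grid of probability cutoffs.

    Predictions are computed once per sample and re-thresholded, so the
    scan costs one model pass regardless of grid size.
    """
    labels = np.asarray(labels)
    cached = [( _sample_probs(r, model), r) for r in reps]
    rows = []
    for th in thresholds:
        if not 0 < th <= 1:
            raise ValueError(f"threshold {th} outside (0, 1]")
        scores = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for (seqs, probs), rep in cached:
                scores.append(_result_from_probs(rep, probs, pool, th).trrs)
        mask = np.array([s is not None for s in scores])
        vals = np.array([s if s is not None else np.nan for s in scores], dtype=float)
        if len(np.unique(labels[mask])) >= 2 and np.nanstd(vals[mask]) > 0:
            auc = float(roc_auc_score(labels[mask], vals[mask]))
        else:
            auc = 0.5  # degenerate scores carry no ranking information
        rows.append({"threshold": th, "auc": auc})
    return pd.DataFrame(rows)


def risk_groups(results: list[TrrsResult], quantile: float = 0.5) -> dict[str, str]:
    """Split samples into high/low risk at a score quantile (default the
    median). Ties at the cut go to the high-risk group."""
    scored = [(r.sample_id, r.trrs) for r in results if r.trrs is not None]
    if len(scored) < 2:
        raise ValueError("need >= 2 samples with defined TRRS")
    cut = float(np.quantile([s for _, s in scored], quantile))
    return {sid: ("high" if s >= cut else "low") for sid, s in scored}
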