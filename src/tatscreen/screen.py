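"""Combined non-invasive screening model.

The repertoire risk score (TRRS, DNA level) and the TAT signature score
(RNA level) are complementary measurements of the same tumour-associated
T-cell response. A two-feature logistic regression combines them; the
final cancer risk score of a sample is the fitted probability.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

FEATURES = ("trrs", "signature_score")


@dataclass
class ScreeningModel:
    intercept: float
    coef: dict[str, float]
    feature_means: dict[str, float]
    feature_sds: dict[str, float]
    metadata: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "ScreeningModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls(**json.loads(text))


def _standardize(x: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    sds = np.where(sds == 0, 1.0, sds)
    return (x - means) / sds


def _logistic_fit(xs: np.ndarray, y: np.ndarray, ridge_alpha: float = 1e-4):
    """Maximum-likelihood logistic fit; on perfect separation (divergent
    ML estimates) fall back to a light ridge penalty."""
    design = sm.add_constant(xs, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res = sm.Logit(y, design).fit(disp=0)
        params = np.asarray(res.params)
        if np.all(np.isfinite(params)) and np.max(np.abs(params)) < 1e3:
            return params
        raise RuntimeError("divergent estimates")
    except Exception:
        warnings.warn("perfect separation; using ridge-penalised fit", stacklevel=3)
        clf = LogisticRegression(penalty="l2", C=1.0 / ridge_alpha, max_iter=5000).fit(xs, y)
        return np.concatenate([clf.intercept_, clf.coef_[0]])


def fit_combined(
    trrs_scores,
    sig_scores,
    labels,
    standardize: bool = True,
    ridge_alpha: float = 1e-4,
) -> ScreeningModel:
    """Fit the two-feature logistic screen (labels: 1 = tumour)."""
    x = np.column_stack([np.asarray(trrs_scores, float), np.asarray(sig_scores, float)])
    y = np.asarray(labels, int)
    if len(y) < 6 or len(np.unique(y)) < 2:
        raise ValueError("need >= 6 samples with both classes")
    means = x.mean(axis=0) if standardize else np.zeros(2)
    sds = x.std(axis=0, ddof=0) if standardize else np.ones(2)
    params = _logistic_fit(_standardize(x, means, sds), y, ridge_alpha)
    return ScreeningModel(
        intercept=float(params[0]),
        coef=dict(zip(FEATURES, (float(params[1]), float(params[2])))),
        feature_means=dict(zip(FEATURES, means.tolist())),
        feature_sds=dict(zip(FEATURES, np.where(sds == 0, 1.0, sds).tolist())),
        metadata={"n": int(len(y)), "standardized": standardize},
    )


def cancer_risk(model: ScreeningModel, trrs, sig) -> np.ndarray:
    """Final cancer risk score: fitted probability for (TRRS, signature)
    pairs. Missing (NaN) features propagate to a missing score."""
    t = np.atleast_1d(np.asarray(trrs, float))
    s = np.atleast_1d(np.asarray(sig, float))
    zt = (t - model.feature_means["trrs"]) / model.feature_sds["trrs"]
    zs = (s - model.feature_means["signature_score"]) / model.feature_sds["signature_score"]
    lin = model.intercept + model.coef["trrs"] * zt + model.coef["signature_score"] * zs
    return 1.0 / (1.0 + np.exp(-lin))


def _cv_auc(x: np.ndarray, y: np.ndarray, folds) -> float:
    """Pooled out-of-fold probability AUC with shared fold assignment."""
    oof = np.full(len(y), np.nan)
    for train_idx, test_idx in folds:
        if len(np.unique(y[train_idx])) < 2:
            continue
        means = x[train_idx].mean(axis=0)
        sds = x[train_idx].std(axis=0, ddof=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params = _logistic_fit(_standardize(x[train_idx], means, sds), y[train_idx])
        zt = _standardize(x[test_idx], means, sds)
        lin = params[0] + zt @ params[1:]
        oof[test_idx] = 1.0 / (1.0 + np.exp(-lin))
    mask = ~np.isnan(oof)
    return float(roc_auc_score(y[mask], oof[mask]))


def compare_components(
    trrs_scores, sig_scores, labels, cv: str | int = "loo", seed: int = 0
) -> pd.DataFrame:
    """Cross-validated and in-sample AUC for TRRS alone, signature alone
    and the combined model, with one shared fold assignment.

    ``cv`` is ``"loo"`` (leave-one-out; sensible for the small validation
    cohorts this screen targets) or an integer number of stratified folds.
    """
    x = np.column_stack([np.asarray(trrs_scores, float), np.asarray(sig_scores, float)])
    y = np.asarray(labels, int)
    if cv == "loo":
        splitter = LeaveOneOut()
        folds = list(splitter.split(x, y))
    else:
        splitter = StratifiedKFold(n_splits=int(cv), shuffle=True, random_state=seed)
        folds = list(splitter.split(x, y))
    feature_sets = {"trrs_only": [0], "signature_only": [1], "combined": [0, 1]}
    rows = []
    for name, cols in feature_sets.items():
        xi = x[:, cols]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            means, sds = xi.mean(axis=0), xi.std(axis=0, ddof=0)
            params = _logistic_fit(_standardize(xi, means, sds), y)
            lin = params[0] + _standardize(xi, means, sds) @ params[1:]
        rows.append(
            {
                "features": name,
                "cv_auc": _cv_auc(xi, y, folds),
                "in_sample_auc": float(roc_auc_score(y, lin)),
            }
        )
    return pd.DataFrame(rows)
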