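"""TAT transcriptional signature: derivation, scoring and TIGS.

From single-cell expression matrices whose cells carry TCR clonotype
labels, genes differentially expressed between CD8+ TATs (cells whose
clonotype is shared with the paired tumour) and non-clonal T cells
(clonotype seen exactly once) are computed per dataset; genes recurrently
DE across datasets, with a consistent direction, form the signature. The
signature is then scored on bulk PBMC RNA-seq as mean z-score of up-genes
minus mean z-score of down-genes, and related to tumour immunogenicity
(TIGS = tumour mutation burden x mean antigen-presenting-gene expression).

Expression values are assumed library-normalised and log2-scale
throughout, so differences of group means are log2 fold changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import floor

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

#: obs columns expected on a labelled single-cell matrix
OBS_COLUMNS = ("clonotype_id", "clone_frequency", "tat_flag", "cd8_flag")


@dataclass
class SignatureGeneSet:
    up: list[str]
    down: list[str]
    support: dict[str, int] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return self.up + self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)


def tat_cd8_mask(adata: AnnData) -> np.ndarray:
    return adata.obs["tat_flag"].to_numpy(bool) & adata.obs["cd8_flag"].to_numpy(bool)


def non_clonal_mask(adata: AnnData) -> np.ndarray:
    """Clone frequency exactly 1 and not a TAT. Cells at frequency 2 belong
    to neither the clonal (> 2) nor the non-clonal (= 1) group."""
    return (adata.obs["clone_frequency"].to_numpy() == 1) & ~adata.obs["tat_flag"].to_numpy(bool)


def de_genes(
    adata: AnnData,
    group_a: np.ndarray | None = None,
    group_b: np.ndarray | None = None,
    min_cells: int = 20,
    alpha: float = 0.05,
    lfc_threshold: float = 0.25,
) -> pd.DataFrame | None:
    """Per-gene Wilcoxon rank-sum DE between two cell groups.

    Defaults: group_a = CD8+ TAT cells, group_b = non-clonal cells. A DE
    call requires Benjamini-Hochberg adjusted p < ``alpha`` and
    |log2FC| >= ``lfc_threshold``. Returns None (with a warning) when a
    group has fewer than ``min_cells`` cells, so an underpowered dataset
    is skipped rather than contaminating the recurrence count.
    """
    a_mask = tat_cd8_mask(adata) if group_a is None else np.asarray(group_a, bool)
    b_mask = non_clonal_mask(adata) if group_b is None else np.asarray(group_b, bool)
    if a_mask.sum() < min_cells or b_mask.sum() < min_cells:
        warnings.warn(
            f"dataset {adata.uns.get('dataset_id', '?')}: group sizes "
            f"({int(a_mask.sum())}, {int(b_mask.sum())}) below min_cells={min_cells}; skipped",
            stacklevel=2,
        )
        return None
    xa = _dense(adata.X[a_mask])
    xb = _dense(adata.X[b_mask])
    lfc = xa.mean(axis=0) - xb.mean(axis=0)
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(xa, xb, axis=0, alternative="two-sided")
        p = np.asarray(res.pvalue, dtype=float)
    # zero-variance genes (identical in both groups) are untestable, not DE
    p = np.where(np.isnan(p), 1.0, p)
    padj = multipletests(p, method="fdr_bh")[1]
    de = (padj < alpha) & (np.abs(lfc) >= lfc_threshold)
    return pd.DataFrame(
        {
            "log2fc": lfc,
            "p": p,
            "p_adj": padj,
            "de": de,
            "direction": np.where(lfc > 0, "up", "down"),
        },
        index=pd.Index(adata.var_names, name="gene"),
    )


def recurrent_signature(
    tables: list[pd.DataFrame], min_datasets: int = 10, total: int | None = None
) -> SignatureGeneSet:
    """Genes DE with a consistent direction in *more than* ``min_datasets``
    of the per-dataset DE tables (strictly greater: 11 of 14 qualifies at
    the default, 10 of 14 does not). Direction is assigned by majority;
    the majority-direction count itself must clear the threshold, and an
    up/down tie excludes the gene."""
    tables = [t for t in tables if t is not None]
    if len(tables) < 2:
        raise ValueError("need >= 2 DE tables")
    total = total if total is not None else len(tables)
    up_counts: dict[str, int] = {}
    down_counts: dict[str, int] = {}
    for t in tables:
        called = t[t["de"]]
        for gene, direction in called["direction"].items():
            d = up_counts if direction == "up" else down_counts
            d[gene] = d.get(gene, 0) + 1
    up, down, support = [], [], {}
    for gene in sorted(set(up_counts) | set(down_counts)):
        n_up = up_counts.get(gene, 0)
        n_down = down_counts.get(gene, 0)
        if n_up == n_down:
            continue  # direction tie
        major = max(n_up, n_down)
        if major > min_datasets:
            (up if n_up > n_down else down).append(gene)
            support[gene] = major
    return SignatureGeneSet(
        up=up,
        down=down,
        support=support,
        config={"min_datasets": min_datasets, "n_tables": len(tables), "total": total},
    )


def signature_score(bulk: pd.DataFrame, sig: SignatureGeneSet) -> pd.Series:
    """Score bulk samples (rows) against a signature.

    Each gene is z-scored across samples; the score is the mean z of
    up-genes minus the mean z of down-genes. Requires >= 50% of signature
    genes present in the matrix.
    """
    present = [g for g in sig.genes if g in bulk.columns]
    missing = [g for g in sig.genes if g not in bulk.columns]
    if len(sig) == 0:
        raise ValueError("empty signature")
    if len(present) < 0.5 * len(sig):
        raise ValueError(
            f"only {len(present)}/{len(sig)} signature genes in matrix; missing: {missing}"
        )
    sub = bulk[present]
    sd = sub.std(axis=0, ddof=0).replace(0, np.nan)
    z = (sub - sub.mean(axis=0)) / sd
    z = z.fillna(0.0)  # zero-variance genes are uninformative
    up = [g for g in sig.up if g in z.columns]
    down = [g for g in sig.down if g in z.columns]
    score = pd.Series(0.0, index=bulk.index, name="signature_score")
    if up:
        score = score + z[up].mean(axis=1)
    if down:
        score = score - z[down].mean(axis=1)
    return score


def tigs(tmb: pd.Series, expr: pd.DataFrame, apm_genes: list[str]) -> pd.Series:
    """Tumour immunogenicity score: TMB x mean antigen-presenting-gene
    expression, per sample. Samples with missing TMB score NaN."""
    present = [g for g in apm_genes if g in expr.columns]
    if not present:
        raise ValueError("none of the antigen-presenting genes are in the matrix")
    mean_apm = expr[present].mean(axis=1)
    out = tmb.reindex(expr.index) * mean_apm
    out.name = "tigs"
    return out


# ---------------------------------------------------------------------------
# cross-dataset validation


@dataclass
class LooResult:
    """Leave-one-dataset-out validation: per-dataset held-out AUC plus the
    held-out scores/labels needed for permutation analysis."""

    table: pd.DataFrame  # dataset_id, auc, n_signature_genes
    details: dict[str, dict]


def _cells_and_labels(adata: AnnData, genes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    a = tat_cd8_mask(adata)
    b = non_clonal_mask(adata)
    keep = a | b
    present = [g for g in genes if g in adata.var_names]
    missing = [g for g in genes if g not in adata.var_names]
    x = np.zeros((int(keep.sum()), len(genes)))
    if missing:
        warnings.warn(f"{len(missing)} signature gene(s) absent; zero-imputed", stacklevel=2)
    if present:
        idx = [genes.index(g) for g in present]
        x[:, idx] = _dense(adata[keep, present].X)
    y = a[keep].astype(int)
    return x, y


def loo_dataset_validation(
    datasets: list[AnnData],
    min_datasets: int | None = None,
    min_cells: int = 20,
    alpha: float = 0.05,
    lfc_threshold: float = 0.25,
    seed: int = 0,
) -> LooResult:
    """Hold out each dataset in turn; derive the recurrent signature and a
    logistic TAT-vs-non-clonal model from the rest; report held-out AUC.

    ``min_datasets`` defaults to the 10-of-14 recurrence rule scaled to
    the number of training datasets (floor(n * 10/14)).
    """
    if len(datasets) < 3:
        raise ValueError("need >= 3 datasets")
    ids = [str(d.uns.get("dataset_id", i)) for i, d in enumerate(datasets)]
    de_tables = {
        i: de_genes(d, min_cells=min_cells, alpha=alpha, lfc_threshold=lfc_threshold)
        for i, d in enumerate(datasets)
    }
    rows, details = [], {}
    for i, held_out in enumerate(datasets):
        rest = [de_tables[j] for j in range(len(datasets)) if j != i and de_tables[j] is not None]
        md = min_datasets if min_datasets is not None else floor(len(rest) * 10 / 14)
        sig = recurrent_signature(rest, min_datasets=md)
        if len(sig) == 0:
            warnings.warn(f"held-out {ids[i]}: empty signature; AUC undefined", stacklevel=2)
            rows.append({"dataset_id": ids[i], "auc": np.nan, "n_signature_genes": 0})
            continue
        x_tr = []
        y_tr = []
        for j, d in enumerate(datasets):
            if j == i:
                continue
            x, y = _cells_and_labels(d, sig.genes)
            x_tr.append(x)
            y_tr.append(y)
        x_tr = np.vstack(x_tr)
        y_tr = np.concatenate(y_tr)
        scaler = StandardScaler().fit(x_tr)
        clf = LogisticRegression(max_iter=2000, random_state=seed).fit(
            scaler.transform(x_tr), y_tr
        )
        x_te, y_te = _cells_and_labels(held_out, sig.genes)
        scores = clf.predict_proba(scaler.transform(x_te))[:, 1]
        auc = float(roc_auc_score(y_te, scores)) if len(np.unique(y_te)) == 2 else np.nan
        rows.append({"dataset_id": ids[i], "auc": auc, "n_signature_genes": len(sig)})
        details[ids[i]] = {"scores": scores, "labels": y_te, "signature": sig}
    return LooResult(table=pd.DataFrame(rows), details=details)


def permutation_auc_null(
    scores: np.ndarray, labels: np.ndarray, n_perm: int = 1000, seed: int = 0
) -> np.ndarray:
    """Null AUC distribution obtained by permuting labels against fixed
    scores. Uses the rank-sum identity AUC = (R1 - n1(n1+1)/2)/(n1 n0),
    so each permutation costs O(n)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("need both classes to permute")
    ranks = stats.rankdata(scores)
    rng = np.random.default_rng(seed)
    out = np.empty(n_perm)
    for i in range(n_perm):
        pos = rng.choice(len(labels), size=n1, replace=False)
        out[i] = (ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    return out
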