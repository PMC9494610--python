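"""Clone-size diversity indices and the group/correlation statistics built
on them.

Clonality is 1 minus Shannon entropy normalised by log richness (0 =
perfectly even repertoire, ->1 = dominated by a single clone). The Gini
coefficient measures clone-size inequality. Both rise with antigen-driven
clonal expansion, which is why they track the shared-TCR fraction in blood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import Repertoire


@dataclass
class DiversityResult:
    sample_id: str
    richness: int
    shannon_entropy: float
    clonality: float | None  # undefined (None) for single-clone repertoires
    gini: float


def _as_counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise ValueError("counts must be a non-empty 1-D vector")
    return c


def shannon_entropy(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i (nats) of a clone-count vector."""
    c = _as_counts(counts)
    if np.any(c < 1):
        raise ValueError("all counts must be >= 1")
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def clonality(counts) -> float | None:
    """1 - H / ln(richness); None (0/0) for a single-clone vector."""
    c = _as_counts(counts)
    if c.size == 1:
        warnings.warn("clonality undefined for a single clone (0/0)", stacklevel=2)
        return None
    return float(1.0 - shannon_entropy(c) / np.log(c.size))


def gini(counts, *, corrected: bool = False) -> float:
    """Gini coefficient G = sum_ij |c_i - c_j| / (2 n sum c).

    Computed via the sorted (Lorenz) form in O(n log n). ``corrected``
    applies the small-sample factor n/(n-1).
    """
    c = _as_counts(counts)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("counts sum to zero; Gini undefined")
    n = c.size
    c = np.sort(c)
    # sum_ij |ci-cj| = 2 * sum_i (2i - n + 1) c_(i), i 0-based ascending
    i = np.arange(n)
    g = float(((2 * i - n + 1) * c).sum() / (n * total))
    if corrected and n > 1:
        g *= n / (n - 1)
    return g


def repertoire_diversity(rep: Repertoire) -> DiversityResult:
    """All indices for one repertoire (or compartment sub-repertoire)."""
    counts = rep.counts()
    if not counts:
        raise ValueError(f"empty repertoire {rep.sample_id!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clon = clonality(counts) if len(counts) > 1 else None
    return DiversityResult(
        sample_id=rep.sample_id,
        richness=len(counts),
        shannon_entropy=shannon_entropy(counts),
        clonality=clon,
        gini=gini(counts),
    )


def correlate_overlap_diversity(
    summaries, diversities, tissue: str = "PBMC", index: str = "clonality"
) -> tuple[float, float]:
    """Spearman rank correlation between per-subject shared-TCR proportion
    and an overall diversity index, within one tissue.

    ``summaries`` and ``diversities`` are parallel per-subject lists
    (:class:`~tatscreen.compartments.OverlapSummary`,
    :class:`DiversityResult`).
    """
    if tissue not in ("PBMC", "TIL"):
        raise ValueError(f"tissue must be 'PBMC' or 'TIL', got {tissue!r}")
    if index not in ("clonality", "gini"):
        raise ValueError(f"index must be 'clonality' or 'gini', got {index!r}")
    if len(summaries) != len(diversities) or len(summaries) < 3:
        raise ValueError("need >= 3 paired (summary, diversity) samples")
    attr = "pbmc_shared_prop_seq" if tissue == "PBMC" else "til_shared_prop_seq"
    x = [getattr(s, attr) for s in summaries]
    y = [getattr(d, index) for d in diversities]
    keep = [(a, b) for a, b in zip(x, y) if a is not None and b is not None]
    if len(keep) < 3:
        raise ValueError("fewer than 3 samples with defined values")
    xs, ys = zip(*keep)
    rho, p = stats.spearmanr(xs, ys)
    return float(rho), float(p)


def group_compare(values_a, values_b, test: str = "mann_whitney") -> tuple[float, float]:
    """Two-sided Mann-Whitney U between two groups of index values.

    Returns (U statistic of the first group, p-value).
    """
    if test != "mann_whitney":
        raise ValueError(f"unsupported test {test!r}")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
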