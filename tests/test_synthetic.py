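import numpy as np
import pytest

from tatscreen import (
    ExpressionSimConfig,
    RepertoireSimConfig,
    gen_cohort,
    gen_expression,
    gen_healthy_pool,
    gen_paired_repertoires,
)
from tatscreen.synthetic import DEFAULT_MOTIF


def test_generation_is_deterministic():
    cfg = RepertoireSimConfig(n_clones=200, seed=42)
    p1, t1, tr1 = gen_paired_repertoires(cfg)
    p2, t2, tr2 = gen_paired_repertoires(RepertoireSimConfig(n_clones=200, seed=42))
    assert p1.clones == p2.clones and t1.clones == t2.clones
    assert tr1["shared_sequences"] == tr2["shared_sequences"]
    e1, _ = gen_expression(ExpressionSimConfig(n_genes=100, n_cells=50, seed=1))
    e2, _ = gen_expression(ExpressionSimConfig(n_genes=100, n_cells=50, seed=1))
    assert np.array_equal(e1.X, e2.X)


def test_shared_fraction_extremes():
    pbmc0, til0, truth0 = gen_paired_repertoires(RepertoireSimConfig(n_clones=200, shared_fraction=0.0, seed=1))
    assert not pbmc0.unique_sequences & til0.unique_sequences
    assert not truth0["shared_sequences"]
    pbmc1, til1, _ = gen_paired_repertoires(RepertoireSimConfig(n_clones=200, shared_fraction=1.0, seed=1))
    assert til1.unique_sequences <= pbmc1.unique_sequences


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        RepertoireSimConfig(shared_fraction=1.5)
    with pytest.raises(ValueError):
        RepertoireSimConfig(length_probs={12: 0.5, 13: 0.2})
    with pytest.raises(ValueError):
        gen_expression(ExpressionSimConfig(n_genes=10, seed=0), signature_truth={"NOT_A_GENE": 1.0})


def test_healthy_pool_is_background_and_disjoint():
    cfg = RepertoireSimConfig(n_clones=100, seed=5)
    _, _, truth = gen_paired_repertoires(cfg)
    pool = gen_healthy_pool(cfg, n_sequences=5000, exclude=frozenset(truth["motif_sequences"]))
    assert len(pool) == 5000
    assert not pool.sequences & truth["motif_sequences"]
    # serine frequency at the motif position stays at background level
    motif = DEFAULT_MOTIF[0]
    freq = np.mean([s[motif.position] == motif.aa for s in pool.sequences])
    bg = cfg.background_freqs[motif.aa]
    assert abs(freq - bg) < 4 * np.sqrt(bg * (1 - bg) / len(pool))


def test_cohort_structure_and_motif_content():
    cfg = RepertoireSimConfig(n_clones=300, seed=6)
    reps, labels, pool = gen_cohort(cfg, n_tumour=3, n_healthy=3, tat_spike=0.10, n_hcmv=2)
    assert len(reps) == 8
    assert labels["group"].value_counts().to_dict() == {"tumour": 3, "healthy": 3, "hcmv": 2}
    motif = DEFAULT_MOTIF[0]

    def motif_rate(rep):
        private = [s for s in rep.unique_sequences if s not in pool.sequences]
        return np.mean([s[motif.position] == motif.aa for s in private])

    by_group = {g: np.mean([motif_rate(r) for r, grp in zip(reps, labels["group"]) if grp == g]) for g in ("tumour", "healthy", "hcmv")}
    assert by_group["tumour"] > by_group["healthy"] + 0.03
    assert abs(by_group["hcmv"] - by_group["healthy"]) < 0.05
    # every sample overlaps the pool (risk-score denominator is defined)
    assert all(len(r.unique_sequences & pool.sequences) > 0 for r in reps)


def test_hcmv_group_is_more_clonal():
    from tatscreen import repertoire_diversity

    cfg = RepertoireSimConfig(n_clones=400, seed=7)
    reps, labels, _ = gen_cohort(cfg, n_tumour=0, n_healthy=4, n_hcmv=4)
    clon = {g: np.mean([repertoire_diversity(r).clonality for r, grp in zip(reps, labels["group"]) if grp == g]) for g in ("healthy", "hcmv")}
    assert clon["hcmv"] > clon["healthy"]


def test_tat_spike_zero_makes_tumour_like_healthy():
    cfg = RepertoireSimConfig(n_clones=300, seed=8)
    reps, labels, pool = gen_cohort(cfg, n_tumour=3, n_healthy=3, tat_spike=0.0)
    motif = DEFAULT_MOTIF[0]
    rates = {
        g: np.mean(
            [
                np.mean([s[motif.position] == motif.aa for s in r.unique_sequences])
                for r, grp in zip(reps, labels["group"])
                if grp == g
            ]
        )
        for g in ("tumour", "healthy")
    }
    assert abs(rates["tumour"] - rates["healthy"]) < 0.04


def test_single_cell_expression_labels():
    cfg = ExpressionSimConfig(n_genes=300, n_cells=400, n_signature_genes=10, seed=2)
    adata, truth = gen_expression(cfg, mode="single_cell", dataset_id="dsX")
    for col in ("clonotype_id", "clone_frequency", "tat_flag", "cd8_flag"):
        assert col in adata.obs
    assert adata.uns["dataset_id"] == "dsX"
    assert set(truth) <= set(adata.var_names)
    # TAT cells are clonally expanded; some non-clonal cells exist
    assert (adata.obs.loc[adata.obs["tat_flag"], "clone_frequency"] > 2).all()
    assert (adata.obs["clone_frequency"] == 1).sum() > 50


def test_bulk_expression_shapes():
    cfg = ExpressionSimConfig(n_genes=200, n_signature_genes=8, seed=3)
    bulk, labels, truth = gen_expression(cfg, mode="bulk", n_tumour=7, n_healthy=5)
    assert bulk.shape == (12, 200)
    assert labels.sum() == 7
    up = [g for g, e in truth.items() if e > 0]
    assert bulk.loc[labels == 1, up].mean().mean() > bulk.loc[labels == 0, up].mean().mean()
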