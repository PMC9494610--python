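import numpy as np
import pandas as pd
import pytest

from tatscreen import (
    ExpressionSimConfig,
    SignatureGeneSet,
    de_genes,
    gen_expression,
    loo_dataset_validation,
    permutation_auc_null,
    recurrent_signature,
    signature_score,
    tigs,
)


def make_de_table(genes_up=(), genes_down=(), universe=("G1", "G2", "G3", "G4")):
    """Hand-built per-dataset DE table."""
    rows = {}
    for g in universe:
        if g in genes_up:
            rows[g] = {"log2fc": 1.0, "p": 1e-5, "p_adj": 1e-4, "de": True, "direction": "up"}
        elif g in genes_down:
            rows[g] = {"log2fc": -1.0, "p": 1e-5, "p_adj": 1e-4, "de": True, "direction": "down"}
        else:
            rows[g] = {"log2fc": 0.0, "p": 0.9, "p_adj": 0.95, "de": False, "direction": "up"}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene")


# -- differential expression ------------------------------------------------


@pytest.fixture(scope="module")
def sc_dataset():
    cfg = ExpressionSimConfig(n_genes=800, n_cells=500, n_signature_genes=20, effect=1.0, seed=3)
    adata, truth = gen_expression(cfg, mode="single_cell", dataset_id="ds0")
    return adata, truth


def test_de_recovers_planted_genes(sc_dataset):
    adata, truth = sc_dataset
    table = de_genes(adata)
    called = set(table.index[table["de"]])
    planted = set(truth)
    assert len(called & planted) >= 0.9 * len(planted)
    false_calls = called - planted
    assert len(false_calls) <= max(2, 0.05 * len(called))
    # planted directions recovered
    for g, eff in truth.items():
        if g in called:
            assert table.loc[g, "direction"] == ("up" if eff > 0 else "down")


def test_de_null_permutation_is_alpha_controlled(sc_dataset):
    # permute whole cell-label rows so groups are random w.r.t. expression
    adata, _ = sc_dataset
    rng = np.random.default_rng(0)
    perm = adata.copy()
    order = rng.permutation(perm.n_obs)
    for col in ("clone_frequency", "tat_flag", "cd8_flag"):
        perm.obs[col] = perm.obs[col].to_numpy()[order]
    table = de_genes(perm)
    # BH at FDR .05 on a global null: false calls near zero
    assert table["de"].sum() <= 5


def test_de_zero_effect_dataset_is_alpha_controlled():
    cfg = ExpressionSimConfig(n_genes=800, n_cells=500, n_signature_genes=20, effect=0.0, seed=21)
    adata, _ = gen_expression(cfg, mode="single_cell")
    table = de_genes(adata)
    assert table["de"].sum() <= 5


def test_de_zero_variance_gene_not_called(sc_dataset):
    adata, _ = sc_dataset
    flat = adata.copy()
    flat.X[:, 0] = 3.0
    table = de_genes(flat)
    assert not table.iloc[0]["de"]


def test_de_small_group_skipped_with_warning(sc_dataset):
    adata, _ = sc_dataset
    small = adata[:30].copy()
    with pytest.warns(UserWarning, match="min_cells"):
        assert de_genes(small, min_cells=200) is None


# -- recurrence rule --------------------------------------------------------


def test_recurrence_threshold_is_strict():
    tables_11 = [make_de_table(genes_up=("G1",)) for _ in range(11)] + [make_de_table() for _ in range(3)]
    tables_10 = [make_de_table(genes_up=("G1",)) for _ in range(10)] + [make_de_table() for _ in range(4)]
    assert recurrent_signature(tables_11).up == ["G1"]  # 11 of 14 qualifies
    assert len(recurrent_signature(tables_10)) == 0  # 10 of 14 does not


def test_recurrence_direction_tie_excluded():
    tables = [make_de_table(genes_up=("G1",)) for _ in range(6)] + [
        make_de_table(genes_down=("G1",)) for _ in range(6)
    ]
    assert len(recurrent_signature(tables, min_datasets=3)) == 0


def test_recurrence_is_order_invariant():
    tables = [make_de_table(genes_up=("G1", "G2"), genes_down=("G3",)) for _ in range(12)] + [
        make_de_table() for _ in range(2)
    ]
    a = recurrent_signature(tables)
    b = recurrent_signature(tables[::-1])
    assert (a.up, a.down, a.support) == (b.up, b.down, b.support)
    assert a.up == ["G1", "G2"] and a.down == ["G3"]


# -- scoring ----------------------------------------------------------------


def test_signature_score_toy_z_arithmetic():
    # 20 centred samples plus one extreme sample at +2/-2 SD
    rng = np.random.default_rng(1)
    base = rng.normal(0, 1, size=(40, 4))
    base = (base - base.mean(0)) / base.std(0)  # exact z-scores
    bulk = pd.DataFrame(base, columns=["U1", "U2", "D1", "D2"])
    sig = SignatureGeneSet(up=["U1", "U2"], down=["D1", "D2"])
    extreme = bulk.copy()
    extreme.iloc[0] = [2, 2, -2, -2] * bulk.std(0, ddof=0)[:4].to_numpy() + bulk.mean(0).to_numpy()
    score = signature_score(bulk, sig)
    # cohort-mean sample scores ~0; score = mean z(up) - mean z(down)
    manual = base[:, :2].mean(1) - base[:, 2:].mean(1)
    assert np.allclose(score.to_numpy(), manual)


def test_signature_score_affine_invariance_and_coverage():
    rng = np.random.default_rng(2)
    bulk = pd.DataFrame(rng.normal(2, 1, size=(15, 6)), columns=[f"G{i}" for i in range(6)])
    sig = SignatureGeneSet(up=["G0", "G1"], down=["G2"])
    s1 = signature_score(bulk, sig)
    s2 = signature_score(bulk * 3.5 + 11.0, sig)
    assert np.allclose(s1, s2)
    missing = SignatureGeneSet(up=["G0"], down=["NOPE1", "NOPE2"])
    with pytest.raises(ValueError, match="NOPE1"):
        signature_score(bulk, missing)


def test_signature_score_separates_planted_bulk_cohort():
    cfg = ExpressionSimConfig(n_genes=600, n_signature_genes=20, effect=1.0, seed=9)
    bulk, labels, truth = gen_expression(cfg, mode="bulk", n_tumour=20, n_healthy=12)
    sig = SignatureGeneSet(
        up=[g for g, e in truth.items() if e > 0], down=[g for g, e in truth.items() if e < 0]
    )
    score = signature_score(bulk, sig)
    from sklearn.metrics import roc_auc_score

    assert roc_auc_score(labels, score) >= 0.9


def test_tigs_product_linearity_and_missing():
    expr = pd.DataFrame({"TAP1": [2, 4], "B2M": [4, 8], "HLA-A": [6, 12]}, index=["s1", "s2"])
    tmb = pd.Series({"s1": 10.0, "s2": 0.0})
    out = tigs(tmb, expr, ["TAP1", "B2M", "HLA-A"])
    assert out["s1"] == pytest.approx(40.0)
    assert out["s2"] == 0.0
    doubled = tigs(tmb, expr * 2, ["TAP1", "B2M", "HLA-A"])
    assert doubled["s1"] == pytest.approx(80.0)
    out2 = tigs(pd.Series({"s1": 10.0}), expr, ["TAP1"])
    assert np.isnan(out2["s2"])
    with pytest.raises(ValueError):
        tigs(tmb, expr, ["ABSENT"])


# -- cross-dataset validation -----------------------------------------------


def test_loo_generalizes_on_shared_signal():
    base_cfg = ExpressionSimConfig(n_genes=400, n_cells=300, n_signature_genes=12, seed=30)
    _, truth = gen_expression(base_cfg, mode="single_cell")
    datasets = []
    for i in range(4):
        cfg = ExpressionSimConfig(n_genes=400, n_cells=300, n_signature_genes=12, seed=30 + i)
        adata, _ = gen_expression(cfg, mode="single_cell", dataset_id=f"d{i}", signature_truth=truth)
        datasets.append(adata)
    res = loo_dataset_validation(datasets, min_datasets=2)
    assert (res.table["auc"] >= 0.8).all()
    with pytest.raises(ValueError):
        loo_dataset_validation(datasets[:2])


def test_loo_no_shared_signal_is_chance_level():
    datasets = []
    for i in range(4):  # each dataset plants its own, disjoint signature
        cfg = ExpressionSimConfig(n_genes=400, n_cells=300, n_signature_genes=12, seed=50 + i)
        adata, _ = gen_expression(cfg, mode="single_cell", dataset_id=f"d{i}")
        datasets.append(adata)
    res = loo_dataset_validation(datasets, min_datasets=1)
    aucs = res.table["auc"].dropna()
    assert (aucs.sub(0.5).abs() < 0.15).all()


def test_permutation_null_centres_at_half():
    rng = np.random.default_rng(4)
    scores = rng.normal(size=300)
    labels = (rng.random(300) < 0.4).astype(int)
    null = permutation_auc_null(scores, labels, n_perm=500, seed=0)
    assert abs(null.mean() - 0.5) < 0.02
    assert null.std() < 0.1
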