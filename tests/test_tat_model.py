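import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from tatscreen import (
    CnnConfig,
    RepertoireSimConfig,
    TatModel,
    TcrPool,
    TrainingSet,
    build_training_set,
    cross_validate,
    decode_cdr3,
    encode_cdr3,
    motif_enrichment,
    predict,
    train,
)
from tatscreen.synthetic import _SeqFactory
from tatscreen.tat_model import EncodingError, PAD_CHANNEL
from tatscreen.types import AA_ALPHABET

from conftest import make_rep

SMALL = CnnConfig(channels=(8, 16, 16), epochs=15, batch_size=64, seed=0)


def seq_factory(seed=0):
    cfg = RepertoireSimConfig(seed=seed)
    return _SeqFactory(cfg, np.random.default_rng(seed))


def training_set(n=300, seed=0, motif=True, n_subjects=8):
    f = seq_factory(seed)
    pos = f.draw_many(n, motif=motif)
    neg = f.draw_many(n)
    return TrainingSet(
        positives=[(s, f"subj{i % n_subjects}") for i, s in enumerate(pos)],
        negatives=[(s, "pool") for s in neg],
    )


# -- encoding ---------------------------------------------------------------


valid_seq = st.text(alphabet=AA_ALPHABET, min_size=12, max_size=17)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(valid_seq)
def test_encode_decode_round_trip(seq):
    mat = encode_cdr3(seq)
    assert mat.shape == (17, 21)
    assert np.all(mat.sum(axis=1) == 1)  # every row one-hot
    assert np.all(mat[len(seq):, PAD_CHANNEL] == 1)
    assert decode_cdr3(mat) == seq


def test_encode_padding_and_errors():
    assert (encode_cdr3("C" + "A" * 10 + "F")[12:, PAD_CHANNEL] == 1).all()
    assert not encode_cdr3("C" + "A" * 15 + "F")[:, PAD_CHANNEL].any()
    with pytest.raises(EncodingError):
        encode_cdr3("CASSF")  # too short
    with pytest.raises(EncodingError):
        encode_cdr3("CASSBAAAAAAAF")  # invalid letter


# -- training set -----------------------------------------------------------


def test_build_training_set_subtracts_pool_and_balances():
    f = seq_factory(1)
    tat_seqs = f.draw_many(10)
    pool = TcrPool("pool", frozenset(tat_seqs[:2] + f.draw_many(50)))
    rep = make_rep({s: 1 for s in tat_seqs})
    ts = build_training_set([rep], pool, seed=0)
    assert sorted(s for s, _ in ts.positives) == sorted(tat_seqs[2:])
    assert len(ts.negatives) == len(ts.positives) == 8
    assert not set(ts.positive_sequences) & set(ts.negative_sequences)


def test_build_training_set_exclusion_and_determinism():
    f = seq_factory(2)
    tat_seqs = f.draw_many(12)
    pool = TcrPool("pool", frozenset(f.draw_many(60)))
    excl = TcrPool("vdjdb", frozenset(tat_seqs[:3]))
    rep = make_rep({s: 1 for s in tat_seqs})
    ts1 = build_training_set([rep], pool, exclusion=excl, seed=5)
    ts2 = build_training_set([rep], pool, exclusion=excl, seed=5)
    assert len(ts1.positives) == 9
    assert ts1.negatives == ts2.negatives  # seeded sampling reproduces exactly
    ts3 = build_training_set([rep], pool, exclusion=excl, seed=6)
    assert ts1.negatives != ts3.negatives


def test_build_training_set_pool_too_small():
    f = seq_factory(3)
    rep = make_rep({s: 1 for s in f.draw_many(30)})
    pool = TcrPool("tiny", frozenset(f.draw_many(5)))
    with pytest.raises(ValueError, match="pool too small"):
        build_training_set([rep], pool, seed=0)


def test_all_positives_in_pool_warns():
    f = seq_factory(4)
    seqs = f.draw_many(5)
    rep = make_rep({s: 1 for s in seqs})
    pool = TcrPool("pool", frozenset(seqs))
    with pytest.warns(UserWarning, match="no positive"):
        ts = build_training_set([rep], pool, seed=0)
    assert not ts.positives


# -- training / prediction --------------------------------------------------


@pytest.fixture(scope="module")
def small_model():
    return train(training_set(n=600, seed=0), SMALL)


def test_training_loss_decreases(small_model):
    loss = small_model.history["loss"]
    assert np.mean(loss[-2:]) < np.mean(loss[:2])


def test_predict_is_deterministic_bounded_and_handles_bad_seqs(small_model):
    f = seq_factory(9)
    seqs = f.draw_many(20)
    seqs = seqs + [seqs[0], "CASSB*AAAAAF"]
    with pytest.warns(UserWarning, match="not encodable"):
        p = predict(small_model, seqs)
    assert np.isnan(p[-1])
    good = p[:-1]
    assert np.all((good >= 0) & (good <= 1))
    assert p[0] == p[-2]  # duplicate sequence, identical probability
    assert np.array_equal(predict(small_model, seqs[:5]), p[:5])


def test_planted_motif_separation(small_model):
    f = seq_factory(13)
    pos, neg = f.draw_many(150, motif=True), f.draw_many(150)
    p = predict(small_model, pos + neg)
    assert np.nanmean(p[:150]) > np.nanmean(p[150:])
    auc = roc_auc_score([1] * 150 + [0] * 150, p)
    assert auc > 0.75


def test_model_serialization_round_trips_bit_exactly(small_model, tmp_path):
    path = tmp_path / "model.npz"
    small_model.save(path)
    loaded = TatModel.load(path)
    for k, v in small_model.net.params.items():
        assert np.array_equal(loaded.net.params[k], v)
    f = seq_factory(21)
    seqs = f.draw_many(10)
    assert np.array_equal(predict(loaded, seqs), predict(small_model, seqs))
    assert loaded.config == small_model.config


def test_degenerate_single_class_rejected():
    ts = training_set(n=10)
    ts.negatives = []
    with pytest.raises(ValueError):
        train(ts, SMALL)


# -- cross-validation -------------------------------------------------------


def test_cross_validation_splits_by_subject_without_leakage():
    ts = training_set(n=200, seed=5, n_subjects=10)
    cfg = CnnConfig(channels=(4, 8, 8), epochs=2, batch_size=64, seed=0)
    report = cross_validate(ts, k=5, config=cfg, seed=1)
    all_subjects = sorted({s for _, s in ts.positives})
    held_out = sorted(s for fold in report.fold_subjects.values() for s in fold)
    assert held_out == all_subjects  # folds partition subjects
    assert all(len(f) == 2 for f in report.fold_subjects.values())
    for fold, test_subj in report.fold_subjects.items():
        train_subj = set(all_subjects) - set(test_subj)
        assert not train_subj & set(test_subj)
    assert ((report.fold_metrics["roc_auc"] >= 0) & (report.fold_metrics["roc_auc"] <= 1)).all()


def test_cross_validation_requires_enough_subjects():
    ts = training_set(n=20, n_subjects=3)
    with pytest.raises(ValueError, match="subjects"):
        cross_validate(ts, k=5, config=SMALL)


# -- motif enrichment -------------------------------------------------------


def test_motif_enrichment_toy_high_group_frequency():
    high = ["CSSSAAAAAAAF", "CSSSGGGGGGGF", "CSSSDDDDDDDF"]
    low = ["CAAAAAAAAAAF", "CAGGGGGGGGGF", "CADDDDDDDDDF"]
    probs = [0.9, 0.9, 0.9, 0.1, 0.1, 0.1]
    res = motif_enrichment(high + low, probs)
    stratum = res.per_length[12]
    assert stratum["high"].loc[1, "S"] == 1.0
    assert stratum["low"].loc[1, "A"] == 1.0
    # frequency columns sum to 1 per occupied position
    assert np.allclose(stratum["high"].sum(axis=1), 1.0)
    assert res.top_positions(1)[0][:2] == (1, "S")


def test_motif_enrichment_null_is_flat():
    rng = np.random.default_rng(8)
    f = seq_factory(17)
    seqs = f.draw_many(2000)
    probs = rng.random(2000)
    res = motif_enrichment(seqs, probs)
    # no planted signal: each pooled log-odds entry within ~4 multinomial
    # SDs of zero (400 entries, so allow the multiplicity of the maximum)
    from tatscreen.tat_model import _positional_counts

    hi_cut, lo_cut = np.quantile(probs, [0.75, 0.25])
    high = [s for s, p in zip(seqs, probs) if p >= hi_cut]
    low = [s for s, p in zip(seqs, probs) if p <= lo_cut]
    max_len = max(len(s) for s in seqs)
    ch, dh = _positional_counts(high, max_len)
    cl, dl = _positional_counts(low, max_len)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(1 / (ch + 0.5) + 1 / (cl + 0.5)) / np.log(2)
    lo_mat = res.pooled_log_odds.to_numpy()
    mask = np.repeat(((dh > 0) & (dl > 0))[:, None], 20, axis=1)
    assert np.all(np.abs(lo_mat[mask]) <= 4 * se[mask] + 0.5)


def test_motif_enrichment_requires_sequences():
    with pytest.raises(ValueError):
        motif_enrichment(["CASSAAAAAAAF"], [0.5])
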