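import numpy as np
import pytest

from tatscreen import Repertoire, RepertoireSimConfig, TcrClone, gen_paired_repertoires
from tatscreen.tat_model import _AA_INDEX


def make_rep(seq_counts, sample_id="s1", subject_id="p1", tissue="PBMC", v="TRBV20", j="TRBJ2-1"):
    """Tiny repertoire from {cdr3: count} with shared V/J."""
    clones = [
        TcrClone(cdr3_aa=s, v_gene=v, j_gene=j, count=c, productive=True)
        for s, c in seq_counts.items()
    ]
    return Repertoire.from_clones(clones, sample_id=sample_id, subject_id=subject_id, tissue=tissue)


class _StubNet:
    """Deterministic stand-in for a trained network: probability .9 when
    the second residue is serine, .1 otherwise."""

    def predict_proba(self, x):
        return np.where(x[:, 1, _AA_INDEX["S"]] == 1, 0.9, 0.1)


class StubModel:
    """Duck-typed TatModel for arithmetic-level TRRS tests."""

    net = _StubNet()


@pytest.fixture
def stub_model():
    return StubModel()


@pytest.fixture(scope="session")
def paired_sim():
    cfg = RepertoireSimConfig(n_clones=800, shared_fraction=0.25, seed=7)
    pbmc, til, truth = gen_paired_repertoires(cfg)
    return cfg, pbmc, til, truth
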