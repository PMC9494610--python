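"""Score a PBMC cohort with the TCR repertoire risk score (TRRS).

A cohort of 12 tumour (5% TAT spike), 12 healthy and 3 infection-like
(expanded but motif-free) samples is generated, a classifier is trained
on separate material, and each sample is summarised as
(# predicted TATs) / (# sequences overlapping the healthy pool).
"""

import numpy as np

from tatscreen import (
    CnnConfig,
    RepertoireSimConfig,
    TrainingSet,
    compute_trrs,
    gen_cohort,
    gen_healthy_pool,
    risk_groups,
    score_cohort,
    train,
)
from tatscreen.synthetic import _SeqFactory

factory = _SeqFactory(RepertoireSimConfig(seed=3), np.random.default_rng(3))
ts = TrainingSet(
    positives=[(s, f"p{i % 20}") for i, s in enumerate(factory.draw_many(2000, motif=True))],
    negatives=[(s, "pool") for s in factory.draw_many(2000)],
)
model = train(ts, CnnConfig(epochs=25, seed=3))

cfg = RepertoireSimConfig(n_clones=800, seed=30)
pool = gen_healthy_pool(cfg)
reps, labels, pool = gen_cohort(cfg, n_tumour=12, n_healthy=12, tat_spike=0.05, pool=pool, n_hcmv=3)

table, auc = score_cohort(
    [r for r, g in zip(reps, labels["group"]) if g != "hcmv"],
    model, pool,
    labels.loc[labels["group"] != "hcmv", "label"].tolist(),
)
print(table.head(6).to_string(index=False))
print(f"\ntumour-vs-healthy TRRS AUC: {auc:.3f}")

hcmv_scores = [compute_trrs(r, model, pool).trrs for r, g in zip(reps, labels["group"]) if g == "hcmv"]
print(f"mean TRRS  tumour  : {table.loc[table.sample_id.str.startswith('tumour'), 'trrs'].mean():.3f}")
print(f"mean TRRS  healthy : {table.loc[table.sample_id.str.startswith('healthy'), 'trrs'].mean():.3f}")
print(f"mean TRRS  hcmv    : {float(np.mean(hcmv_scores)):.3f}")

groups = risk_groups(
    [compute_trrs(r, model, pool) for r in reps]
)
n_high = sum(v == "high" for v in groups.values())
print(f"\nmedian split: {n_high} high-risk / {len(groups) - n_high} low-risk samples")
print(
    "\nTumour samples score consistently above healthy ones, while infection-driven\n"
    "expansion without the TAT motif stays near the healthy range — the\n"
    "score reads out tumour-associated sequences, not expansion per se."
)
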