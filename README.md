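# tatscreen

Non-invasive cancer screening from the T-cell side of a blood draw.

T cells that infiltrate a tumour (TILs) and T cells circulating in blood
(PBMCs) can carry identical T-cell receptors. A blood T-cell clone whose
CDR3β sequence is also found among the patient's TILs is a *circulating
tumour-associated T cell* (cTAT): the tumour has left a fingerprint in the
repertoire that can be read without touching the tumour. `tatscreen`
implements the full analysis stack around that idea, for computational
immunologists working with bulk or single-cell TCRβ repertoires and paired
expression data:

1. **Compartments** — partition paired PBMC/TIL repertoires into the four
   sharing compartments (`PBMCs_Shared` = cTATs, `PBMCs_Only`,
   `TILs_Shared`, `TILs_Only`) by exact CDR3β match, and quantify overlap
   at sequence and clone level.
2. **Diversity** — clonality `1 − H/ln R` (Shannon entropy `H`, richness
   `R`), Gini coefficient `G = Σᵢⱼ|cᵢ−cⱼ| / (2 n Σc)` of clone counts,
   rank correlations and Mann–Whitney group comparisons.
3. **Classifier** — a three-layer 1-D convolutional network over one-hot
   encoded CDR3β sequences (lengths 12–17, 20 amino-acid channels + 1
   padding channel) that outputs the probability a sequence belongs to a
   TAT. Training sets pit cTAT sequences against a healthy-donor pool;
   cross-validation splits by *patient*, never by sequence.
4. **TRRS** — the TCR repertoire risk score of a PBMC sample:

   `TRRS = #{unique sequences with P(TAT) > 0.66} / #{unique sequences in the healthy pool}`

5. **Signature** — genes recurrently differentially expressed between
   CD8⁺ TATs and non-clonal T cells (clone frequency = 1) in more than 10
   of 14 single-cell datasets; scored on bulk RNA-seq as mean z(up-genes)
   − mean z(down-genes). TIGS = TMB × mean antigen-presenting-gene
   expression relates the signature to tumour immunogenicity.
6. **Screen** — a two-feature logistic model of TRRS + signature score;
   the fitted probability is the final cancer risk score.
7. **Synthetic data** — simulators for every input (paired repertoires
   with a planted shared fraction and TAT motif, healthy pools, screening
   cohorts including an HCMV-like expanded-but-motif-free group, and
   expression matrices with planted signature genes), so the whole
   pipeline is testable with known ground truth.

## Worked example

`examples/` contains one short script per capability. From
`examples/02_train_classifier.py` (train on 2 000 + 2 000 planted-motif
sequences, evaluate on fresh draws):

```
final training loss 0.199, accuracy 0.925
held-out ROC-AUC: 0.930
top positional log-odds (position is 0-based):
  position 1 residue S: log2 odds 8.97
  position 4 residue G: log2 odds 8.79
  position 15 residue P: log2 odds 4.39
```

The held-out AUC of 0.93 says the network separates TAT-like from
healthy-pool sequences; the log-odds table is the motif read-out — serine
at the second residue (position 1, the dominant planted preference) tops
it. `examples/03_trrs_cohort.py` then scores a 27-sample cohort
(tumour-vs-healthy TRRS AUC 0.92, with the infection-like control group
near the healthy range), and `examples/04_signature_and_screen.py` derives
a 16-gene signature (16/16 planted genes recovered) and combines both
scores (cross-validated AUC: TRRS alone 0.813, signature alone 0.808,
combined 0.889).

A thin CLI mirrors the library for shell use:

```bash
tatscreen simulate cohort --n-tumour 5 --n-healthy 5 --out simcohort
tatscreen io summarize simcohort/tumour_000.tsv
tatscreen compartments --pbmc pbmc.tsv --til til.tsv --out assignment.tsv
```

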