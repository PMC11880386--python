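# hiskit

Immune-checkpoint signature scoring and tumor-size-aware response
prediction for checkpoint-blockade studies.

## The problem

Immune checkpoint blockade (ICB, e.g. anti-PD1 antibodies) produces
durable responses in only a subset of tumors. One driver is the
*Heterogeneity of the Immune checkpoint Signature* (HIS): as tumors
progress they tend to upregulate many checkpoint genes at once, and such
HIS-high tumors resist single-checkpoint blockade, while tumors relying
on a single dominant checkpoint (HIS-low) stay sensitive to blocking that
checkpoint. Clinically, the same logic predicts that PD-L1 expression
(tumor proportion score, TPS) should predict anti-PD1 response better in
large tumors than small ones, and that combining TPS with baseline tumor
volume (BTV) should beat TPS alone.

`hiskit` packages the complete quantitative stack of that analysis:

* **HIS scoring** (`hiskit.expression`) — for a 34-gene checkpoint panel,
  the per-gene fold change FC_g = mean-FPKM(comparison)/mean-FPKM(baseline)
  is computed and the tumor state called **HIS-high** if ≥ 10 genes have
  FC ≥ 2.0, **HIS-low** if ≤ 5 do (counts of 6–9 are reported as
  indeterminate), plus directional up/down counts and per-gene z-scoring
  for distribution plots.
* **Preclinical growth analytics** (`hiskit.growth`) — caliper volumes
  V = a·b²·π/6, serpentine ("S-curve") allocation of size-ranked mice,
  tumor growth inhibition TGI% (endpoint or baseline-subtracted variant),
  and stable-or-shrinking responder calls.
* **Clinical prediction** (`hiskit.cohort`) — RECIST-style responder
  classification (>30 % shrinkage held ≥ 24 weeks), empirical ROC curves
  with the tie-corrected Mann–Whitney AUC, Youden-index cutoffs,
  reconstruction of response×TPS(×BTV) contingency tables from published
  margins, grouped-binomial logistic regression by IRLS, and DeLong's
  paired-AUC test. For a binary marker, AUC = (sensitivity+specificity)/2,
  which is what makes published operating points exactly recomputable.
* **Survival** (`hiskit.survival`) — Kaplan–Meier product-limit curves,
  the two-group log-rank test, and a binary-covariate Cox model
  (HR = exp(β) with 95 % Wald CI), implemented from their defining
  formulas and cross-checked against `lifelines` in the test suite.
* **Synthetic data** (`hiskit.simulate`) — seeded generators for FPKM
  matrices with planted fold changes, exponential growth curves, patient
  cohorts (exact cell expansion or generative sampling from a logistic
  model), and exponential survival times with a target hazard ratio.

The bivariate logistic model is

```
logit P(response) = β0 + β_BTV · [BTV ≤ cutoff] + β_TPS · [TPS ≥ cut]
```

Note the coding: **the BTV indicator is 1 for BTV-small tumors** (they
respond more often), so both published coefficients are positive. The
reference cohort's published equations, operating points, and baseline
margins ship in `hiskit.presets`.

## Worked example

Score a synthetic small-vs-large tumor experiment in which 21 of the 34
panel genes are upregulated three-fold in large tumors:

```bash
his simulate expression --config cfg.yaml --seed 7 --out demo/
his score --matrix demo/expression.tsv --samples demo/samples.tsv \
    --baseline small --comparison large
```

```json
{
  "label": "HIS_HIGH",
  "n_genes_fc_ge_cut": 21,
  "n_up": 21,
  "n_down": 0
}
```

21 genes clear FC ≥ 2.0, well past the ≥ 10 rule, so the large-tumor
group is HIS-high — the profile expected to resist anti-PD1 therapy.

Rebuild the reference NSCLC cohort's tables and models from its published
summary statistics alone:

```bash
his reconstruct --preset tps50
```

```json
{
  "auc_tps": 0.7119,
  "auc_bivariate": 0.7686,
  "auc_small_stratum": 0.6731,
  "auc_large_stratum": 0.7480,
  "tps_table": {"resp_pos": 43, "resp_neg": 34, "nonresp_pos": 7, "nonresp_neg": 45},
  "refit_model": {"intercept": -0.7347, "coef_btv": 1.2406, "coef_tps": 2.3980}
}
```

(values abridged and rounded). Read: the TPS ≥ 50 % indicator alone
predicts response with AUC 0.71; adding BTV lifts it to 0.77; within the
BTV-small stratum TPS is weak (0.67) but within BTV-large it is strong
(0.75); and the maximum-likelihood refit on the reconstructed table
reproduces the published equation logit = −0.7347 + 1.241·BTV + 2.398·TPS50
to printed precision.

Other entry points: `his predict` (cohort CSV → AUCs + DeLong test),
`his tgi` (caliper CSV → TGI%), `his survival` (KM/log-rank/Cox),
`his simulate`, and `his run` for a configured end-to-end pipeline.

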