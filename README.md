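# edrisk — admission-risk stratification of ED diagnosis codes

Emergency departments triage large volumes of ambulatory ("stable")
presentations whose eventual disposition — discharge or inpatient admission —
varies enormously by diagnosis. `edrisk` implements a pipeline that
stratifies ICD-10 primary-diagnosis codes by their empirical hospital
admission risk, so that low-risk diagnosis groups can be considered for
alternative care pathways (urgent-care clinics, telemedicine) and high-risk
groups flagged despite a low-acuity triage label.

The pipeline, intended for health-services researchers working with
presentation-level ED extracts:

1. **Per-code risk.** For each ICD-10 code *c* with *n_c* presentations and
   *a_c* admissions, the admission risk is the fraction *r_c = a_c / n_c*.
   Codes with fewer than 15 presentations are excluded as unstable
   (sensitivity threshold: 10).
2. **1-D k-means.** Codes are clustered on *r_c* by Lloyd's algorithm with
   D²-seeded random restarts and a Hartigan-style boundary-refinement pass,
   minimising the within-cluster sum of squares
   `WCSS = Σ_j Σ_{c∈C_j} (r_c − μ_j)²`. Because the data are
   one-dimensional, the *globally* optimal partition is computable by
   dynamic programming over sorted values (`kmeans_1d_exact`); the package
   uses it as a built-in verification oracle. The number of clusters is
   assessed with the gap statistic (uniform reference), the WCSS elbow, and
   silhouette / Calinski-Harabasz / Davies-Bouldin indices; the default
   pipeline records the full selection report and uses k = 4.
3. **Block coverage.** Codes map to WHO ICD-10 blocks (contiguous
   3-character ranges, e.g. J09–J18 "Influenza and pneumonia"). Blocks are
   ranked by presentation frequency to form a cumulative-coverage curve
   (how many blocks cover 60–100 % of presentations), and a block is
   *dominant* in a cluster when ≥ 75 % of its presentations fall there. A
   row-normalised block × cluster proportion matrix is exported for
   heatmaps.
4. **Ordinal association.** The association between presentation
   characteristics and risk-cluster membership is quantified with a
   proportional-odds model, `logit P(Y ≤ j | x) = θ_j − βᵀx`, fitted by
   Newton–Raphson with analytic Hessian; `exp(β)` > 1 reads "higher odds of
   a higher-risk cluster". Covariates: age, sex, ethnicity, categorised
   vitals (hypotension < 90 / hypertension > 130 mm Hg; bradycardia < 60 /
   tachycardia > 90 bpm; hypothermia < 35.5 / hyperthermia > 37.5 °C),
   Charlson comorbidity (none / mild 1–2 / moderate 3–4 / severe ≥ 5), and
   prior-six-month encounter counts.

Because presentation-level hospital data are not shareable, the package
includes a **synthetic registry generator** (`edrisk.simulate`) that
reproduces the statistical structure this analysis assumes — ~510 codes in
four latent risk tiers (centres 0.047 / 0.195 / 0.478 / 0.78), Zipf-like
code frequencies with low-risk codes disproportionately common, calibrated
covariate marginals, and configurable covariate effects on the admission
logit — so every stage has recoverable ground truth.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
registry (seed 1), writing tables under `results/` and the large registry
under `scratch/`:

```bash
python analysis/01_simulate_registry.py
python analysis/02_preprocess.py
python analysis/03_cluster_codes.py
python analysis/04_block_coverage.py
python analysis/05_ordinal_model.py
```

`03_cluster_codes.py` prints the model-selection table and the fitted
stratification:

```
  k   WCSS      gap(se)        silhouette   CH        DB
  1   34.9721   0.063(0.038)   -            -         -
  2   6.0197    0.434(0.042)   0.765        2438.4    0.402
  3   2.6426    0.439(0.039)   0.734        3095.1    0.371
  4   0.9450    0.896(0.038)   0.751        6061.1    0.347
  ...
gap argmax: k=4; parsimony (1-se) rule: k=2; using k=4 for clinically meaningful distinctions

k=4: WCSS 0.9450 (matches exact optimum), centroids [0.057, 0.216, 0.478, 0.778]

cluster  codes  presentations  share%  admission%
  1        263       122,004   61.0       6.0
  2        101        40,986   20.5      21.1
  3         72        26,107   13.1      47.0
  4         73        10,889    5.4      75.7
```

Reading this: the gap statistic peaks at four clusters, whose centroids are
the admission-risk levels of the four strata; cluster 1 holds 61 % of
presentations at a 6 % admission rate (candidate alternative-care group),
while the 5.4 % of presentations in cluster 4 are admitted 75.7 % of the
time despite their ambulatory triage class. The per-restart k-means solution
equals the dynamic-programming optimum. `04_block_coverage.py` then reports
that 51 of 184 nonempty blocks cover 80 % of presentations and that 121
blocks have ≥ 75 % single-cluster representation (71.2 % of the sample), and
`05_ordinal_model.py` prints the odds-ratio forest table (in this synthetic
registry covariates act within codes, not on code choice, so
cluster-membership ORs sit near 1 — a null-calibration of the stage).

The same pipeline is scriptable via the `edrisk` CLI
(`simulate / preprocess / cluster / coverage / associate / run-all`), e.g.

```bash
edrisk run-all --seed 1 --out results/
```

To analyse real data instead, point `run-all` (or `preprocess`) at a
delimited registry with columns `id, icd10, admitted, age, sex, ethnicity,
sbp, pulse, temp, cci, prior_ed, prior_inpt, prior_surg, prior_icu,
prior_hd, prior_ica, prior_infect`.

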