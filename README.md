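# atrcn — adaptive transfer learning for deep Cox survival networks

Prognosis models trained on a single cancer cohort are starved for
events: a few hundred patients, most of them censored, against thousands
of genes.  `atrcn` addresses this by *borrowing strength from similar
cohorts*.  It characterizes every candidate cohort by 22 survival and
expression descriptors, clusters cohorts in descriptor space to find the
ones most similar to the target, pre-trains a deep Cox
proportional-hazards network on those sources, fine-tunes it on the
target, and stratifies patients into high- and low-risk groups at the
median predicted risk.

It is aimed at computational biologists working with multi-cohort
survival studies (e.g. pan-cancer RNA-seq collections): inputs are plain
expression tables (genes × samples, TSV/CSV) and survival tables
(`sample_id,time,event` plus optional clinical covariates).

## The model

Each patient's hazard follows the proportional-hazards form

    λ(t | x) = λ0(t) · exp(h(x)),

with the log relative hazard h(x) parameterized by a relu network
(hidden widths 50–20–10; an empty hidden stack gives the linear Cox
model).  Training minimizes the negative log partial likelihood

    l(θ) = − Σ_{i:E_i=1} [ h(x_i) − log Σ_{j:T_j ≥ T_i} exp(h(x_j)) ],

full-batch, with analytic gradients and Adam.  Pre-training on pooled
source cohorts keeps risk sets *within* each cohort (the loss is the sum
of per-cohort partial likelihoods), so survival times are never compared
across cohorts with different baseline hazards.  Model quality is
measured by Harrell's C-index (0.5 = random, 1 = perfect) and the
log-rank test between median-split risk groups; clinical covariates are
tested against the risk groups by chi-square.  See `docs/methods.md` for
the full account.

A synthetic-study generator (`atrcn.synthetic`) produces multi-cohort
survival studies with planted cohort "families" sharing risk structure,
so the whole pipeline — selection, transfer, evaluation — is testable
without downloading any data.

## Worked example

Simulate a six-cohort, two-family study, pick the sources for target
`SIM00`, and run the full pipeline:

```bash
atrcn --seed 7 simulate --config sim.yaml --out demo_study
atrcn --seed 7 select --manifest demo_study/manifest.yaml --target SIM00 --out clusters.json
# k=2; pre-training set for SIM00: SIM01, SIM02

atrcn --seed 7 fit --manifest demo_study/manifest.yaml --target SIM00 \
      --config fit.yaml --out demo_fit
# CV C-index 0.768 (±0.007), log-rank p 4.91e-25; artifacts in demo_fit
```

The selection step recovered exactly the two cohorts planted in the
target's family.  The fit report says the fine-tuned network orders
held-out patient pairs correctly 76.8% of the time (mean over CV folds,
± fold SD), and splitting patients at the median predicted risk
separates their survival curves decisively (log-rank p ≪ 0.001).

A saved model can score an independent cohort:

```bash
atrcn evaluate --model demo_fit \
      --expression demo_study/SIM01_expression.tsv \
      --survival   demo_study/SIM01_survival.csv --out eval.json
# C-index 0.739, log-rank p 1.24e-10
```

The same stages are available as library functions
(`simulate_study`, `describe_cohort`, `choose_k_by_silhouette`,
`pretrain`/`finetune`/`atrcn_fit`, `evaluate_risk_scores`).

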