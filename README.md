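# pathsurv

Pathway-masked multitask deep survival network for gene-expression
prognosis, with an uncertainty-discounted integrated-gradients procedure
that ranks genes by their influence on the predicted hazard.

## The problem

Predicting cancer outcome from expression profiles is a p ≫ n problem:
cohorts of a few hundred patients, thousands of genes, and heavy right
censoring (public breast-cancer series range from ~12% to ~87% censored).
Deep survival networks discriminate well but are hard to interpret, and
plain gradient-based gene importances suffer from saturation and are
unstable. `pathsurv` addresses both ends:

- **Prediction.** The first layer is gated by a binary pathway×gene
  biadjacency matrix A (from a GMT file), so genes connect only to the
  curated pathways that contain them. The encoder feeds three jointly
  trained heads: a reconstruction decoder (loss L_D, weight γ), a
  deep-embedded-clustering head capturing patient heterogeneity
  (soft assignments t_ij ∝ (1+‖z_i−μ_j‖²)^-1, sharpened target S,
  loss L_C = KL(S‖T), weight β), and a Cox risk head trained with the
  negative partial log-likelihood
  L_P = −Σ_{i:event} [h(x_i) − log Σ_{j∈ℛ(T_i)} exp h(x_j)].
  Total loss: γ·L_D + β·L_C + L_P (defaults γ=1, β=10).
- **Interpretation.** Integrated gradients of the risk output,
  IG_i = (x_i−x′_i)·∫₀¹ ∂F/∂x_i dα, computed by Gauss–Legendre quadrature
  (with an exact piecewise variant for ReLU networks), repeated T times
  under Monte-Carlo dropout. Per-gene uncertainty
  U_i = std_t(lg_i)/|mean_t(lg_i)| is log-squashed and min–max normalized
  to U′∈[0,1], and genes are ranked by |V_i| where V_i = (1−U′_i)·IG_i —
  attributions that flip across dropout realizations are discounted.

Everything is testable offline: a seeded simulator generates cohorts with
planted prognostic genes grouped into pathways, proportional-hazards
outcomes, and censoring calibrated to a target rate.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Simulate the default cohort (400 patients, 1000 genes, 20 planted
prognostic genes with log-hazard coefficient 0.5 each, ~60% censoring),
train on 300 patients, evaluate on the 100 held out, and rank genes:

```python
import numpy as np
from pathsurv import (SyntheticSpec, simulate_cohort, simulate_pathways,
                      build_pathway_mask, NetworkConfig, train, predict_risk,
                      evaluate, AttributionConfig, attribute)

spec = SyntheticSpec(seed=1)
cohort, truth = simulate_cohort(spec)
mask = build_pathway_mask(simulate_pathways(spec), cohort.expression.gene_ids)

config = NetworkConfig(n_hidden1=128, n_hidden2=64, n_embedding=16,
                       learning_rate=3e-4, max_epochs=300, seed=1)
idx = np.random.default_rng(1001).permutation(400)
state, report = train(cohort.subset(idx[:300]), mask, config)

test = cohort.subset(idx[300:])
rep = evaluate(predict_risk(state, test.expression.values), test.survival)
attr = attribute(state, cohort.expression.values,
                 AttributionConfig(n_mc_runs=20, n_quadrature=32,
                                   method="gauss-legendre", seed=1))
```

This prints (`rep` fields and `attr.to_frame().head(8)`):

```
held-out C-index:     0.719
|log10 p| (log-rank): 3.08
mean td-AUC:          0.789
chosen k:             2
 gene mean_IG    U U_adj      V  rank  unstable_flag
g0453   0.238 0.12  0.00  0.237     1              0
g0970  -0.172 0.10  0.00 -0.171     2              0
g0437   0.119 0.10  0.00  0.118     3              0
g0618  -0.114 0.10  0.00 -0.114     4              0
g0344  -0.082 0.10  0.00 -0.082     5              0
g0018   0.063 0.11  0.00  0.063     6              0
g0006   0.058 0.11  0.00  0.058     7              0
g0732   0.044 0.11  0.00  0.044     8              0
```

The C-index of 0.719 sits between chance (0.5) and the true planted risk
(≈0.87); |log10 p| = 3.08 means the median split of predicted risk
separates survival at p ≈ 8×10⁻⁴. In the ranking, `V` is the
uncertainty-discounted importance: positive values are hazard-increasing
genes. `g0006` and `g0018` are planted prognostic genes; on this seed 5 of
the 20 planted genes land in the attribution top-20 (chance expectation
0.4; the median across the five study replicates is 8).

## Command line

Each stage is also a subcommand, round-tripping through TSV/GMT files:

```sh
pathsurv simulate  --config cfg.yaml --seed 1 --out data/
pathsurv train     --expr data/expression.tsv --surv data/survival.tsv \
                   --gmt data/pathways.gmt --lr 3e-4 --epochs 300 \
                   --out model.ckpt.npz
pathsurv cv        --expr ... --surv ... --gmt ... --out cv.json
pathsurv interpret --model model.ckpt.npz --expr data/expression.tsv \
                   --out importance.tsv
pathsurv evaluate  --model model.ckpt.npz --expr ... --surv ... \
                   --out report.json
pathsurv pipeline  --config cfg.yaml --seed 1 --out run/   # all of the above
```

The config file has `synthetic`, `network` and `attribution` sections
(unknown keys are rejected); one `--seed` drives every stage
deterministically — rerunning a pipeline with the same seed reproduces
`importance.tsv` byte for byte.

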