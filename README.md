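# grit — gene regulation inference by transport

`grit` fits a linear stochastic differential-equation model of gene
expression to **time-course single-cell snapshot data** and turns the fit
into gene-regulatory-network predictions. Because single-cell measurements
are destructive, no cell is observed twice: the data are cross-sectional
population snapshots `Y_0 .. Y_N` at times `T_0 .. T_N`, and the coupling
between consecutive snapshots is unknown. `grit` treats that coupling as an
entropy-regularized optimal-transport problem and the model fit as the
system whose one-step propagation moves each snapshot onto the next at
minimal transport cost:

    dx = (A x + b) dt + ε dw
    J(A, b) = Σ_k (1/ΔT_k) W((I + ΔT_k A) Y_{k-1} + ΔT_k b,  Y_k)
              + ‖A Λ_A^{1/2}‖_F² + λ_b ‖b‖²

where `W(P, Q)` is the Sinkhorn-solved entropic OT cost with squared
Euclidean ground cost. The entropic strength doubles as a noise
deconvolution: `ε_reg = 2 ε² ΔT` matches the Gibbs kernel to the model's
own transition density (`grit.matched_epsilon`). `J` is minimized by block
coordinate descent — Sinkhorn plans with the model fixed, an exact
ridge-regression update of `(A, b)` with the plans fixed — accelerated by
entropic continuation and safeguarded Anderson mixing.

On top of the fit:

* **Network inference** — per-target greedy forward–backward variable
  selection on the fixed-plan regression; the cost increment at a
  regulator's removal is its link confidence, with signs from the fitted
  drift matrix (`edge_confidence_scores`, `signed_edges`).
* **Perturbation / mutation targets** — joint control-vs-condition fits
  with a condition-specific load vector (or a condition-specific drift
  column for a known mutated gene); the condition parameters are scored
  like links (`fit_with_perturbation`, `fit_mutation_effect`).
* **Couplings, targets, velocities** — the converged plans give
  ancestor/descendant couplings, barycentric target points `Y_k M_kᵀ`
  (row-normalized), and difference-quotient velocity estimates.
* **Synthetic validation ladder** — generators with known ground-truth
  networks: discrete/continuous linear dynamics, Michaelis–Menten kinetics
  with Langevin noise, and hidden protein states (`grit.synthetic_data`).
* **Evaluation** — AUROC / AUPR / AUPR-ratio against a true adjacency,
  model error, convergence slopes (`grit.evaluation`).

Audience: computational biologists with snapshot (or pseudotime-binned)
scRNA-seq matrices who want dynamics-aware network inference, and
methods developers who need a transparent, tested reference implementation
of transport-based system identification.

## Worked example

```python
import numpy as np
from grit import (FitConfig, auroc, aupr, edge_confidence_scores, fit,
                  matched_epsilon, model_error, random_sparse_stable_system,
                  simulate_linear_discrete)

truth = random_sparse_stable_system(10, density=0.2, seed=1)   # A, b, network
series = simulate_linear_discrete(truth, N=5, m=2000, epsilon=0.2, seed=21)

config = FitConfig(epsilon=matched_epsilon(0.2))               # 2*0.2^2 = 0.08
result = fit(series, config)
scores = edge_confidence_scores(series, result.plans, config)

print(f"model error^2     {model_error(result.model, truth):.3f}")
print(f"link AUROC        {auroc(scores.score, truth.adjacency):.3f}")
print(f"link AUPR         {aupr(scores.score, truth.adjacency):.3f}")
```

Output:

```
model error^2     0.503
link AUROC        0.998
link AUPR         0.992
```

The squared Frobenius error of 0.503 is against ‖[A, b]‖²_F ≈ 62 for this
system (under 1%), and the near-perfect AUROC/AUPR mean true regulatory
links rank above almost every non-link. The same pipeline is available
from a shell:

```bash
grit simulate --kind lin-disc --n-genes 10 --cells 2000 --seed 1 --out-prefix sim
grit infer --expression sim_expression.csv --annotation sim_annotation.csv \
     --epsilon 0.08 --out edges.tsv
grit eval --edges edges.tsv --truth sim_truth.tsv
```

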