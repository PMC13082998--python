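# dpga — disease potential-driven graph attention for comorbidity risk

`dpga` predicts which hypertensive patients will go on to develop a target
comorbidity (for example COPD, diabetes mellitus, or coronary heart
disease) from their diagnosis histories, and explains cohort-level risk
structure through disease co-occurrence networks. It is aimed at clinical
data scientists working with case/control cohorts extracted from
electronic medical records, and ships a synthetic cohort generator so the
whole pipeline is runnable and testable without access to protected
patient data.

## The model

Patients are nodes of a graph G = (V, E, X): node features X ∈ {0,1}^{Z×F}
are binary disease-history indicators over a vocabulary of F ICD-10-like
codes, and an edge connects two patients who share at least `min_shared`
diagnosis codes. On this graph a stack of attention layers combines three
mechanisms:

* **Fusion attention.** A feature score
  e_ij^base = a_srcᵀ LeakyReLU(W h_i) + a_dstᵀ LeakyReLU(W h_j)
  is fused (summed) with a structural score
  e_ij^pos = (s_i ⊙ a_s)ᵀ(s_j ⊙ a_s) computed from learnable per-node
  position embeddings s_i, initialised from Laplacian eigenvectors and
  regularised toward graph smoothness.
* **Difference perception.** A Bregman divergence (squared-Euclidean
  generator) d_ij = ω‖h_i−h_j‖² + (1−ω)‖s_i−s_j‖² lowers the fused score,
  e_ij^adjust = e_ij^fusion − δ·d_ij, and drives a parallel
  similarity–difference message-passing branch
  R_ij = D_ij · exp((C_ij − βO_ij)/τ) with normalised aggregation and a
  μ-weighted self term.
* **Disease-potential masking.** Each patient gets a potential
  p_i = σ(Σ_{q∈D} X_iq) over a designated disease-feature set D; a
  per-edge mask m_ij is 1 when the receiving patient's potential strictly
  exceeds the sender's and a small ε (default 0.1) otherwise, multiplying
  the softmax numerator:
  α_ij = exp(e_ij^adjust)·m_ij / Σ_k exp(e_ik^adjust).
  Aggregation is h_i' = μ Σ_j α_ij W h_j.

Training is transductive (the whole graph message-passes; only training
labels enter the loss) with L = L_c + λ·L_p, binary cross-entropy plus a
graph-Laplacian penalty on the position embeddings, evaluated by accuracy
and macro-F1 over repeated 6:2:2 stratified splits.

The comorbidity-network module scores disease pairs by the phi
coefficient φ_uv = (N_uv Z − Y_u Y_v) / √(Y_u Y_v (Z−Y_u)(Z−Y_v)) with a
correlation t statistic, and contrasts case against control networks.

The package has no deep-learning framework dependency: the layers run on
a small numpy reverse-mode autodiff engine (`dpga.autodiff`) whose
gradients are verified against finite differences in the test suite.

## Worked example

```python
from dpga import (DPGAClassifier, SimulationConfig, DiseaseModule,
                  generate_cohort, build_graph)

cfg = SimulationConfig(
    n_case=200, n_control=200, n_features=80,
    modules=[DiseaseModule(features=tuple(range(30, 35))),
             DiseaseModule(features=tuple(range(60, 65)))],
    potential_features=tuple(range(25)), effect_size=0.3, seed=1)
sim = generate_cohort(cfg)
graph = build_graph(sim.cohort, min_shared=3)

clf = DPGAClassifier(hid=64, heads=4, drop=0.3, lam=1.0, lr=5e-4,
                     epochs=150, potential_features=cfg.potential_features,
                     seed=1)
summary = clf.evaluate(graph, runs=3)
print(summary.format_table())
```

prints

```
ACC 0.9542 ±0.0382	F1 0.9542 ±0.0382
```

i.e. on a 400-patient synthetic cohort whose cases carry a planted
potential gradient (25 disease features with +0.3 prevalence), three
independent split/train/test runs recover the outcome with mean test
accuracy ≈ 0.95 and a small across-run spread — the potential-masked
attention reads the planted severity gradient out of the patient graph.

The same pipeline is available from the shell:

```bash
dpga simulate --n-case 200 --n-control 200 --n-features 80 --outdir data/
dpga train --cohort data/cohort.csv --epochs 150 --runs 3 --outdir run/
dpga network --case data/cohort.csv --control data/cohort.csv --outdir net/
```

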