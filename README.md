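# pmnmix

Model-based clustering for **matrix-valued data** — stacks of p×q matrices
such as grayscale images, spatio-temporal panels, or multichannel signal
windows — with lasso regularization of both the cluster means and the
row/column precision matrices.

## The model

A p×q random matrix X follows the matrix normal law N_{p,q}(M, U, V) when
vec(X) ~ N_{pq}(vec(M), V ⊗ U): M is the mean matrix, U (p×p) the row
covariance, V (q×q) the column covariance. The Kronecker-separable
covariance reduces pq(pq+1)/2 free covariance parameters to
p(p+1)/2 + q(q+1)/2, which is what makes G-component mixtures of these
distributions estimable for image-sized matrices with small n.

`pmnmix` fits the penalized mixture by maximizing

```
Lp(Θ) = Σ_i log Σ_j π_j f(X_i | M_j, U_j, V_j)
        − λ₁ Σ_j |M_j|₁ − λ₂ Σ_j |U_j⁻¹|₁ − λ₃ Σ_j |V_j⁻¹|₁
```

with an EM algorithm whose M-step combines

* a closed-form elementwise soft-threshold update for each mean matrix
  (threshold (λ₁/Σ_i τ_ij)·U_j 1 V_j), which zeroes entries that do not
  discriminate between clusters;
* two graphical-lasso subproblems per component for the sparse row and
  column precisions, so zero entries of U⁻¹/V⁻¹ encode conditional
  independence between rows/columns;
* K-means initialization, multi-start, and an Aitken-accelerated stopping
  rule on the penalized log-likelihood.

Setting λ₂ = λ₃ = 0 recovers the mean-penalized matrix normal mixture; all
zeros recovers the unpenalized mixture. Hyperparameters (G, λ₁, λ₂, λ₃) are
selected by K-fold cross-validation of the held-out penalized
log-likelihood over a grid.

## Worked example

```python
from pmnmix import ScenarioSpec, sample_scenario, fit_pmnmm, predict_labels
from pmnmix import clustering_accuracy, adjusted_rand_index

# two-component 20x20 mixture: rectangle vs cross mean patterns,
# banded precision structures
spec = ScenarioSpec.scenario1(n=100, seed=3)
samples, truth = sample_scenario(spec)

model = fit_pmnmm(samples, G=2, penalties=(20, 0.001, 0.01),
                  n_restarts=5, seed=7)
labels, tau = predict_labels(samples, model)
print(f"ACC {clustering_accuracy(truth, labels):.3f}",
      f"ARI {adjusted_rand_index(truth, labels):.3f}",
      f"iterations {model.trace.n_iter}")
```

prints

```
ACC 1.000 ARI 1.000 iterations 74
```

ACC is the agreement fraction under the best one-to-one matching of
predicted to true clusters; ARI is the chance-corrected Hubert–Arabie
index (1 = identical partitions). Here the two groups are recovered
exactly; across many replicates of this scenario the mean ACC is ≈ 0.99.

The same pipeline is available from the shell:

```bash
pmnmix simulate --scenario 1 --n 100 --seed 7 --out data/
pmnmix fit --data data/data.h5 --g 2 --lambda1 20 --lambda2 0.001 \
           --lambda3 0.01 --out fit/
pmnmix evaluate --data data/data.h5 --labels fit/labels.csv
```

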