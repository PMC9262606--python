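# drsc — joint dimension reduction and (spatial) clustering

Clustering pipelines for single-cell and spatial transcriptomics usually run
in tandem: first reduce the expression matrix to a few components (PCA and
friends), then cluster the components.  The reduction step knows nothing
about the clusters, so the retained components mix cell-type signal with
everything else, and the clustering inherits the damage — visibly so when
residual noise varies across genes.

`drsc` implements DR-SC, a hierarchical model that performs both steps
jointly.  For spot $i$ with centered log-normalized expression
$\mathbf{x}_i \in \mathbb{R}^p$:

$$
\mathbf{x}_i = W\mathbf{z}_i + \boldsymbol\varepsilon_i,\quad
\boldsymbol\varepsilon_i \sim N(0, \Lambda) \qquad \text{(probabilistic PCA)}
$$
$$
\mathbf{z}_i \mid y_i = k \sim N(\mu_k, \Sigma_k) \qquad \text{(Gaussian mixture)}
$$
$$
\Pr(\mathbf{y}) \propto \exp\big\{\beta \textstyle\sum_{i\sim i'} \delta(y_i, y_{i'})\big\}
\qquad \text{(Potts hidden Markov random field)}
$$

The Potts layer smooths labels across the spot neighbor graph (square
lattice, Visium-style hexagonal, or k-nearest-neighbor for irregular bead
platforms); its strength β is estimated from the data by pseudo-likelihood.
With no spatial information (β = 0 or an empty graph) the model reduces
exactly to a latent Gaussian mixture, covering ordinary scRNA-seq.  Fitting
is an ICM-EM algorithm — iterated-conditional-modes label sweeps interleaved
with exact EM updates — with a provably non-decreasing objective, costing
$O(npq)$ per iteration (no $p\times p$ matrix is ever formed).  The number
of clusters is chosen automatically by a modified BIC with a
$\log(n)\log(\log(p+n))$ penalty.  See `docs/methods.md` for the full
derivation and all numerical choices.

The package also ships the two synthetic study designs used to validate the
method (Gaussian expression on a 70×70 Potts lattice; Poisson counts with a
log-linear latent layer), with ground truth attached, and the standard
evaluation metrics (ARI, NMI, mean canonical correlation, conditional
correlation).

## Worked example

```python
import drsc

# Gaussian scenario: 30x30 lattice, 7 clusters from a Potts field (beta=1),
# 10 latent dimensions, 300 genes, residual variance 9 on every gene.
em, graph, truth = drsc.simulate_sim1(rows=30, cols=30, K=7, q=10, p=300,
                                      beta=1.0, noise="homo", seed=1)

fit = drsc.fit_drsc(em, graph, K=7, q=10, options=drsc.FitOptions(seed=1))
print("converged:", fit.converged, "iterations:", fit.n_iter)
print("beta_hat:", fit.params.beta)
print("ARI  (joint fit):", round(drsc.ari(truth.y, fit.labels), 3))

y_tandem, scores = drsc.tandem_pca_gmm(em, K=7, q=10, seed=1)
print("ARI  (tandem PCA+GMM):", round(drsc.ari(truth.y, y_tandem), 3))
print("CCA  (joint embeddings):",
      round(drsc.mean_canonical_correlation(fit.embeddings, truth.z), 3))
print("CCA  (PCA scores):",
      round(drsc.mean_canonical_correlation(scores, truth.z), 3))
```

Output:

```
converged: True iterations: 18
beta_hat: 1.2
ARI  (joint fit): 0.708
ARI  (tandem PCA+GMM): 0.541
CCA  (joint embeddings): 0.539
CCA  (PCA scores): 0.461
```

The joint fit recovers the spatial clusters substantially better than the
two-step pipeline (ARI 0.71 vs 0.54) and its posterior embeddings track the
true latent features more closely (mean canonical correlation 0.54 vs 0.46);
the estimated smoothness (1.2) sits near the generating value 1.  To pick
the number of clusters automatically:

```python
best, table = drsc.select_K(em, graph, range(5, 10), q=10,
                            options=drsc.FitOptions(seed=1))
print(table)        # one row per K with its MBIC; `best` minimizes it
```

## Command line

The same steps are available as a thin CLI:

```bash
drsc simulate --scenario sim1 --beta 1 --seed 1 --out data/
drsc fit --expr data/expr.tsv --coords data/coords.tsv --platform lattice \
         --k 7 --q 10 --out fit/
drsc select-k --expr data/expr.tsv --coords data/coords.tsv \
              --platform lattice --k-range 5:9 --q 10 --out sel/
drsc evaluate --truth data/truth.tsv --fit fit/ --expr data/expr.tsv
```

`fit` writes `labels.tsv`, `embeddings.tsv`, `responsibilities.tsv`,
`params.npz`, `fit_summary.json` and `log.txt`; `select-k` adds
`selection.tsv`.  Raw counts (MatrixMarket `.mtx` plus barcode/feature TSVs,
10x orientation) are accepted via `--counts` and are library-size
log-normalized internally; `--n-top-genes` restricts to the most variable
genes.

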