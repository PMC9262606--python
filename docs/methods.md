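# Methods

## Model

For spot (or cell) $i = 1..n$ with centered log-normalized expression
$\mathbf{x}_i \in \mathbb{R}^p$, latent embedding $\mathbf{z}_i \in
\mathbb{R}^q$ and cluster label $y_i \in \{1..K\}$:

$$
\mathbf{x}_i = W \mathbf{z}_i + \boldsymbol{\varepsilon}_i,
\qquad \boldsymbol{\varepsilon}_i \sim N(0, \Lambda),
\qquad \Lambda = \mathrm{diag}(\lambda_1..\lambda_p),
$$
$$
\mathbf{z}_i \mid y_i = k \sim N(\mu_k, \Sigma_k),
$$
$$
\Pr(\mathbf{y}) \propto \exp\Big\{ \beta \sum_{i \sim i'} \delta(y_i, y_{i'}) \Big\},
$$

where $i \sim i'$ ranges over edges of the spot neighbor graph.  The first
layer is probabilistic PCA (dimension reduction), the second a Gaussian
mixture (clustering), and the third a K-state Potts prior (a hidden Markov
random field) that rewards equal labels on neighboring spots with strength
$\beta \ge 0$.  Marginally $\mathbf{x}_i \mid y_i = k \sim
N(W\mu_k,\; W \Sigma_k W^\top + \Lambda)$.  With an empty graph or $\beta =
0$ the model is exactly a latent Gaussian mixture on the probabilistic-PCA
layer, which is how non-spatial (scRNA-seq) data are handled.  The model has
no learned mixing proportions: with $\beta = 0$ the label prior is uniform
$1/K$.

The Potts normalizing constant $C(\beta)$ has no closed form and is never
computed; everything involving $\beta$ goes through the pseudo-likelihood
surrogate below.

## Fitting: ICM-EM

Let $\ell_{ik} = \log N(\mathbf{x}_i;\, W\mu_k,\, W\Sigma_k W^\top +
\Lambda)$ and $c_{ik} = \#\{i' \in N_i : y_{i'} = k\}$.  The traced
objective is the pseudo-marginal log-likelihood

$$
F(\theta, \beta, \mathbf{y}) = \sum_i \Big[
  \mathrm{lse}_k(\ell_{ik} + \beta c_{ik}) - \mathrm{lse}_k(\beta c_{ik})
\Big],
$$

i.e. each spot's class evidence weighted by the neighbor-informed
pseudo-prior $\pi_{ik} \propto e^{\beta c_{ik}}$.  One outer iteration:

1. **ICM sweeps** — visit spots in ascending index order, setting
   $y_i \leftarrow \arg\max_k\, \ell_{ik} + \beta c_{ik}$ with current
   neighbor labels, ties to the smallest $k$; repeat until no change or 10
   sweeps.  The new labels are accepted only if they do not decrease $F$
   (ascent guard; ICM increases the joint hard-label objective, which is not
   identical to $F$).
2. **Responsibilities** — $R_{ik} \propto \exp(\ell_{ik} + \beta c_{ik})$,
   normalized with log-sum-exp.
3. **E-step** — posterior moments of $\mathbf{z}_i$ per class:
   $S_k = (\Sigma_k^{-1} + W^\top \Lambda^{-1} W)^{-1}$,
   $m_{ik} = S_k(\Sigma_k^{-1}\mu_k + W^\top \Lambda^{-1}\mathbf{x}_i)$.
4. **M-step** — exact weighted maximizers of the complete-data expectation:
   weighted means/covariances for $\mu_k, \Sigma_k$; $W = A B^{-1}$ with
   $A = \sum_i \mathbf{x}_i \bar m_i^\top$, $B = \sum_{ik} R_{ik}(m_{ik}
   m_{ik}^\top + S_k)$, $\bar m_i = \sum_k R_{ik} m_{ik}$; then
   $\lambda_j = \frac1n \sum_{ik} R_{ik}[(x_{ij} - w_j^\top m_{ik})^2 +
   w_j^\top S_k w_j]$, floored at $10^{-8}$.
5. **$\beta$ update** — grid maximizer of the Potts pseudo-likelihood
   $\mathrm{PL}(\beta) = \sum_i [\sum_k R_{ik}\beta c_{ik} -
   \mathrm{lse}_k(\beta c_{ik})]$, ties to the smaller value; kept only if
   it does not lower $\mathrm{PL}$ relative to the current $\beta$ (relevant
   only for user grids that exclude the current value).

At the E-step point $F$ decomposes as $F = \sum_{ik} R_{ik}\ell_{ik} + H(R)
+ \mathrm{PL}(\beta)$, so steps 3–4 (standard EM for a mixture with fixed
weights) and step 5 (minorize–maximize on the $\beta$ coordinate) both
increase $F$ for fixed labels, and step 1 is guarded.  The recorded
objective trace is therefore non-decreasing by construction — an honest
ascent, not a clamp: no recorded value is ever edited, only label proposals
can be declined.

**Stopping.**  Relative change of $F$ below `tol` (default $10^{-5}$) or 30
outer iterations.  At finalization the responsibilities are recomputed at
the last parameters and hard labels are the row-argmax of $R$, so the
reported labels and responsibilities are always mutually consistent.

**Initialization** (the procedure is not dictated by the model): ordinary
PCA to $q$ dimensions, k-means on the scores (`n_init=10`, seeded) for
initial labels, $W$ = PCA loadings, $\Lambda$ = residual gene variances
(floored at $10^{-8}$), $\mu_k, \Sigma_k$ = within-cluster moments of the
scores, $\beta$ initialized at 1 for spatial data and 0 otherwise.  A label
vector may be supplied instead of k-means (`FitOptions(init=...)`), which is
how the label-permutation equivariance property is exercised.

**Numerics.**  All Gaussian evaluations use the Woodbury identity and the
matrix determinant lemma, costing $O(npq + K(nq^2 + q^3))$ per iteration
with $O(np + nKq)$ memory; no $p \times p$ matrix is ever formed.  Any
$\Sigma_k$ whose smallest eigenvalue drops below $10^{-8}$ gets a
$10^{-6} I$ ridge.  A cluster with responsibility mass below $10^{-8}$
keeps its previous $\mu_k, \Sigma_k$ and is logged; $K$ is never silently
reduced.  All argmax ties (labels, $\beta$ grid, model selection) break to
the smallest index.  A single integer seed drives PCA, k-means and every
simulation draw, so runs are reproducible bit-for-bit up to floating-point
associativity.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `K` | — | number of clusters (or scan a range with `select_K`) |
| `q` | 15 (CLI) / explicit | embedding dimension; 10 in the simulation studies |
| `beta_grid` | 0 to 4 in steps of 0.2 | candidate Potts smoothness values; covers the simulated β ∈ {0, 1} with headroom |
| `fix_beta` | None | hold β fixed (0 forces the non-spatial model) |
| `max_iter`, `tol` | 30, 1e-5 | outer-loop budget and relative-change stop |
| `icm_sweeps` | 10 | label sweeps per outer iteration |

β is unitless (a log-odds increment per agreeing neighbor); expression
values are on the natural-log scale of the library-size normalization.

## Model selection

$\mathrm{MBIC}(K) = -2\hat\ell + \mathrm{df}\cdot \log(n) \cdot
\log(\log(p+n))$, minimized over the candidate $K$.  $\hat\ell = F -
\mathrm{PL}(\beta) = \sum_{ik} R_{ik}\ell_{ik} + H(R)$ is the observed-data
part of the objective with the Potts pseudo-prior removed, so values are
comparable across fitted $\beta$; at $\beta = 0$ it is exactly the mixture
log-likelihood.  $\mathrm{df} = pq - q(q+1)/2 + p + Kq + Kq(q+1)/2 + 1$
(orthogonality-corrected loading, residual variances, class means and
covariances, $\beta$).  The inflation argument $p+n$ follows the
modified-BIC family for high-dimensional regimes and is exposed as
`inflation_arg`.  Each candidate $K$ is fitted with seed `base_seed + K`.

## Synthetic data

The generators emulate the two validation designs.

*Gaussian scenario* (`simulate_sim1`): labels from a K-state Potts model
($K=7$ default) on a 70×70 4-neighbor lattice, Gibbs-sampled (single-site,
100 sweeps from a uniform start; the 2×2 exact-enumeration test pins the
sampler to its target); $\mathbf{z}_i\mid y_i=k \sim N(\mu_k, \Sigma_k)$
with $q=10$; $W$ the Q factor of a QR decomposition of an iid standard
normal $p \times q$ draw ($p=1000$), columns sign-fixed; homoscedastic noise
$\lambda_j = 9$ or heteroscedastic $\lambda_j = 2 + 4|a_j|$, $a_j \sim
N(0,9)$; genes centered.

*Count scenario* (`simulate_sim2`): adds a gene offset $\tau_j \sim N(0,1)$,
uses $\lambda_j = 1$ (homo) or $0.1 + |a_j|$, $a_j \sim N(0,1)$ (hetero),
and draws $\tilde x_{ij} \sim \mathrm{Poisson}(\exp(x_{ij}))$.  The
exponential link is a deliberate interpretation — a Poisson mean must be
positive while $x_{ij}$ is real — with the linear predictor clipped at 30
before exponentiation (clips are logged).  The returned expression matrix is
the library-size log-normalized, gene-centered transform of the counts.

*Class means and covariances.*  Defaults are $\Sigma_k = I_q$ and
simplex-style means: class $k$ sits at `mean_scale` on latent coordinate
$k$ (coordinates reused with alternating sign if $K > q$), centered so all
pairwise separations equal `mean_scale`·√2.  `mean_scale = 9` was fixed
once so that the tandem PCA+GMM baseline scores ARI ≈ 0.65 under the
default homoscedastic regime — strong enough to be solvable, weak enough
that method differences are visible.  A circle layout in two coordinates was
rejected because it leaves most latent directions below the PCA
detectability threshold ($\mathrm{var} < \lambda\sqrt{p/n}$), making
embedding-recovery comparisons uninformative.

*What the generators do not emulate*: dropout/zero-inflation, batch
effects, spatially varying library size, irregular tissue boundaries, or
over-dispersion beyond what the latent layer induces in the count scenario.
Passing tests therefore demonstrate correctness of the algorithm under its
own generative assumptions and robustness to heteroscedastic noise — not
performance on any real tissue.

## Evaluation metrics

ARI (chance-corrected pair-counting, in [−1, 1]) and NMI (default sqrt
normalization; `min`/`max`/`arithmetic` exposed; two degenerate one-class
partitions score 1, one-sided degeneracy scores 0).  Embedding recovery is
the mean of the $q$ canonical correlations between the estimated and true
feature matrices (singular values of the product of orthonormal column
bases; invariant to invertible affine maps; rank-deficient directions score
0).  The conditional correlation regresses the estimated embeddings (plus
intercept) out of every gene and out of the one-hot labels and averages over
genes the largest absolute residual correlation — an operationalization of
"how much label signal the embeddings failed to absorb"; it is used only
for relative comparisons (smaller is better).

## Problem sizes used in the shipped checks

The replicate studies in the test suite run 50 replicates per noise regime
on a 30×30 lattice with $p = 150$; the cluster-number recovery test uses
the full 70×70 lattice with $p = 300$; `scripts/acceptance.py` runs the
full design ($70\times70$, $p = 1000$, $K \in 5..9$, five seeds).  These
sizes were chosen as the smallest at which the corresponding effects are
stable across seeds.

## Known limitations

* The ICM-EM scheme (hard ICM labels → neighbor-aware responsibilities →
  weighted M-step) is one concrete member of the family of such algorithms;
  it is validated by ascent, reduction and recovery properties rather than
  by matching any other implementation's update equations.
* The pseudo-likelihood treatment of β is consistent for label fields from
  the model but is a surrogate, not the intractable exact likelihood.
* β is updated every outer iteration; no schedule is provided.
* Model selection chooses K only; q is user-fixed.
* Single-sample fits only; no batch correction or multi-sample joint model.
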