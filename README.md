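# alphaem

Emission tomography (PET/SPECT) measurements are Poisson distributed, and
the standard reconstruction method for them is ML-EM (maximum-likelihood
expectation maximization). ML-EM famously approaches the true image at
early iterations and then diverges toward a noisy maximum-likelihood
solution, so in practice it is stopped early. `alphaem` is a small
research toolkit for studying whether the *Poisson-matched* weighting that
ML-EM embodies actually yields the best early-stopped image — and for
demonstrating that it does not: a one-parameter reweighting of the same
iteration reaches images closer to the truth, with the optimal weighting
depending on the total photon count of the scan.

## The algorithm

With image pixels $x_i$, measured ray sums $p_j$, system matrix $a_{ij}$
(intersection length of ray $j$ with pixel $i$), and forward projection
$q_j^{(n)} = \sum_i a_{ij} x_i^{(n)}$, classical ML-EM iterates

$$x_i^{(n+1)} = x_i^{(n)} \, \frac{\sum_j a_{ij}\, p_j / q_j^{(n)}}{\sum_j a_{ij}}.$$

`alphaem` implements the generalized family

$$x_i^{(n+1)} = x_i^{(n)} \,
\frac{\sum_j a_{ij}\, p_j / [q_j^{(n)}]^{\alpha}}
     {\sum_j a_{ij}\, q_j^{(n)} / [q_j^{(n)}]^{\alpha}},$$

which is identical to ML-EM at $\alpha = 1$, keeps every iterate
nonnegative for any $\alpha > 0$, and — rewritten in additive form — is a
variable-step gradient descent on the weighted least-squares objective
$F = \sum_j W_j (q_j - p_j)^2$ with per-ray weight $W_j = 1/[q_j]^{\alpha}$.
So $\alpha$ selects the noise model: $\alpha = 1$ is the nominal Poisson
(variance = mean) weighting, $\alpha < 1$ trusts high-count rays more,
$\alpha > 1$ less.

The simulation study that ships with the package asks, for each noise
level, which $(\alpha, n)$ minimizes the mean-square error

$$\mathrm{MSE} = \frac{1}{N}\sum_{i \in \text{support}} (x_i - \mathrm{true}_i)^2,
\qquad N = n_{\text{pixels}} \times \text{scaling factor},$$

against an analytic phantom (uniform ellipse, five hot discs, one cold
disc, activity ratios 1 : 2 : 0.5) projected *without pixelization* into a
120-view x 128-bin parallel-beam sinogram, with Poisson noise at count
scaling factors 0.1–1000 (expected totals $10^6$–$10^{10}$). Because the
data come from exact line integrals and the reconstruction uses a Siddon
pixel model, there is no inverse crime.

## Worked example

Reconstruct one noisy measurement at the lowest count level (~$10^6$
total counts) with classical ML-EM and with $\alpha = 2$:

```python
from alphaem import AlphaEM, NoiseLevel, poisson_measure
from alphaem.experiment import ExperimentPlan, prepare_study

ctx = prepare_study(ExperimentPlan(master_seed=7))
p = poisson_measure(ctx.mean_sinogram,
                    NoiseLevel(scale=0.1, seed=7, realization_index=1))

for alpha in (1.0, 2.0):
    res = AlphaEM(p, ctx.system_matrix, alpha=alpha).fit(
        max_iter=30, truth=ctx.truth_for_scale(0.1),
        eval_config=ctx.eval_config(0.1))
    print(res.summary())
```

Output (abridged to the stopping diagnostics):

```
alpha:              1
best iteration:     13 (MSE-optimal early stop)
best MSE:           0.125651
ROI stdev at best:  1.1016

alpha:              2
best iteration:     9 (MSE-optimal early stop)
best MSE:           0.119065
ROI stdev at best:  0.845411
```

At this count level the "incorrect" weighting $\alpha = 2$ stops earlier
and gets ~5% closer to the truth (and visibly less noisy background,
lower ROI stdev) than Poisson-matched ML-EM on the identical data. At
high count levels the pattern reverses: the optimum moves to
$\alpha < 1$ and to larger iteration numbers. `res.trace` holds the full
per-iteration MSE / log-likelihood / data-fidelity curves behind these
summaries.

The full factorial sweep (5 count levels x 5 realizations x
$\alpha = 0.1\ldots3.0$) is available from the command line:

```sh
alphaem experiment run --config plan.yaml --out study/
alphaem experiment report --out study/
```

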