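# countvae

Interpretable factor models for cells × genes count matrices, implemented as
a variational autoencoder with a **linear decoder**. The generative model is
a Gamma–Poisson (negative binomial) emission over gene proportions produced
by `softmax(z Wᵀ)`, scaled by a lognormal per-cell exposure. A neural
encoder amortizes inference of the latent coordinates `z` and the log
exposure; the decoder weight matrix `W` is directly interpretable as gene
loadings ("gene programs"). A logistic-normal (simplex) latent variant, a
nonlinear-decoder reference model, and an optional pre-softmax batch-norm
transform are included.

Everything (model, ELBO, backpropagation, Adam) is plain NumPy/SciPy — no
deep-learning framework required. Gradients are hand-derived and verified
against finite differences in the test suite.

## Layout

| module | contents |
| --- | --- |
| `countvae.model` | generative model: linear decoder, NB log-pmf, forward sampling |
| `countvae.inference` | encoder, reparameterized sampling, KL terms, ELBO |
| `countvae.training` | mini-batch training loop, epoch heuristic, held-out error |
| `countvae.interpretation` | loadings, factor covariance, eigen-ordering, top genes |
| `countvae.simulate` | synthetic scenarios with ground truth + recovery metrics |
| `countvae.io` / `countvae.cli` | MTX/CSV readers-writers and the CLI |

## Quick start (Python)

```python
import countvae as cv

spec = cv.SimScenario(n_cells=2000, n_genes=80, n_factors=3,
                      program_structure="block", seed=0)
params, meta = cv.make_scenario(spec)
counts, truth = cv.sample_generative(params, spec.n_cells, seed=0)

fit = cv.fit(counts,
             cv.ModelConfig(n_latent=3, latent_family="normal"),
             cv.TrainConfig(n_epochs=100, seed=0))

loadings = cv.get_loadings(fit)                       # genes x factors
report = cv.factor_report(fit, counts, k_top=10)      # ordered factors
print(report.variance_explained)
```

## CLI

```bash
countvae simulate --cells 2000 --genes 80 --factors 3 --seed 0 --out-dir sim/
countvae fit --data sim/counts.mtx --n-factors 3 --epochs 100 --seed 0 --out-dir run/
countvae loadings  --model run/model --out loadings.csv
countvae transform --model run/model --data sim/counts.mtx --out latent.csv
countvae report    --model run/model --data sim/counts.mtx --out report.json
```

`--epochs auto` applies the first-pass heuristic of one million divided by
the number of cells (at least one epoch). `--latent ln` selects the
simplex-valued logistic-normal latent space; its factor covariance is
always rank-deficient (one factor is linearly dependent on the others),
which the report flags. `fit` accepts a YAML config (`--config`) overriding
training options.

## Notes

- Training is deterministic given `TrainConfig.seed`; `n_restarts > 1`
  trains several seeded initializations and keeps the best final ELBO
  (useful for small latent dimensions, where factor discovery can stall in
  a local optimum).
- Count matrices are dense `int64` internally; the package targets
  desk-scale data (up to ~10⁵ cells × ~10³ genes).
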