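# stvcpanel

Bayesian **spatiotemporally varying coefficient (STVC)** models for areal
panel data, with the full analysis pipeline around them: covariate
screening, five nested hierarchical models, Bayesian model comparison, and
spatial/temporal coefficient products.

The package is aimed at spatial epidemiologists and health-geography
analysts who observe a positive outcome — the motivating case is
county-level hospital beds per 10,000 people over a decade — on an areal
map over several years, and want to know not just *whether* a covariate
matters but *where* and *when* its effect is stronger or weaker.

## The model

For areas `i = 1..I` on an adjacency graph and years `t = 1..T`, the
response is modeled on the log scale with a structured additive predictor.
The headline model (model 5, STVC) decomposes each standardized covariate's
effect into a spatial field and a temporal path:

    log Y_it = β0 + Σ_p (μ_p,i + γ_p,t) · x_p,it + ε_it,   ε_it ~ N(0, σ²)

* `μ_p,·` (the **space-coefficients**, SC) carry an intrinsic CAR / Besag
  prior on the areal graph: `μ_i | μ_-i ~ N(mean of neighbors, σ_f²/m_i)`;
* `γ_p,·` (the **time-coefficients**, TC) carry a first-order random-walk
  prior, `π(γ) ∝ exp(-Σ_t (γ_t - γ_{t-1})² / 2σ_γ²)`;
* precisions get diffuse Gamma priors; global terms flat priors.

Four benchmark models are nested inside it: ordinary multivariate
regression (1), the same plus spatial/temporal random intercepts (2), and
the TC-only (3) and SC-only (4) special cases. Inference is blocked Gibbs
sampling — the Gaussian likelihood makes every full conditional exact — and
models are compared by DIC, WAIC, their effective-parameter counts, the
leave-one-out logarithmic score from conditional predictive ordinates, and
R². Before modeling, candidate covariates pass a two-step screen: iterative
VIF filtering (threshold 5, per block) and random-forest MDI/MDA ranking.

A fully ground-truthed synthetic generator (lattice geography, spatially
autocorrelated coefficient fields, smooth temporal paths, log-Gaussian
noise, missing cells) makes the whole pipeline testable end-to-end without
any external data. See `docs/methods.md` for the complete methodology.

## Worked example

```python
import numpy as np
import stvcpanel as sp

# a ground-truthed panel: 10x10 lattice, 10 years, 3 covariates
cfg = sp.GeneratorConfig(n_se=2, n_ex=1, n_time_invariant=0, seed=7)
panel, truth = sp.generate_panel(cfg)
graph = sp.make_lattice_graph(cfg.rows, cfg.cols)
panel = sp.preprocess(panel)            # log response, z-scored covariates

fits = {}
for m in (1, 5):                        # ordinary regression vs STVC
    design = sp.build_model(sp.ModelSpec.for_model(m, panel), panel, graph)
    fits[m] = sp.fit_gibbs(design, sp.McmcConfig(chains=2, iterations=2000,
                                                 burn_in=1000, seed=1))

table = sp.compare_models([sp.score_model(fits[m]) for m in (1, 5)])
print(table.round(2).to_string(index=False))

r = np.corrcoef(fits[5].stacked("sc:SE1").mean(axis=0),
                truth.sc_fields["SE1"])[0, 1]
print(f"SC recovery (SE1): Pearson r = {r:.3f}")
```

prints

```
 model     DIC    WAIC  P_DIC  P_WAIC    LS   R2           best_on
     1 1000.84 1002.38   5.00    6.48  0.53 0.50     P_DIC, P_WAIC
     5 -175.44 -165.25 208.46  183.07 -0.07 0.91 DIC, WAIC, LS, R2
SC recovery (SE1): Pearson r = 0.781
```

Read: the STVC model wins every fit/prediction criterion (lower DIC, WAIC
and log score; R² 0.91 vs 0.50) because the data really do contain
spatially and temporally varying effects, while the ordinary regression
wins on complexity (about 5 effective parameters vs about 208) — the
classic fit-versus-parsimony trade-off this model family exposes. The
posterior-mean spatial coefficient field correlates with the known truth at
r = 0.78 on this single draw of the generator. Downstream,
`sp.extract_sc_table` / `sp.extract_tc_table` tabulate the coefficient
surfaces with credible bands, `sp.getis_ord_gstar` classifies them into
hot/cold spots, and `sp.estimate_response_maps` returns posterior response
surfaces on the original beds-per-10,000 scale, including at missing cells.

The same stages are available from the shell:

```sh
stvcpanel simulate --seed 7 --outdir runs/demo
stvcpanel screen runs/demo/panel.csv
stvcpanel fit runs/demo/panel.csv runs/demo/graph.gal --model 5 --out fit5.npz
stvcpanel map runs/demo/panel.csv runs/demo/graph.gal --fit 5:fit5.npz
stvcpanel run --config config.yaml     # full pipeline from one YAML
```

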