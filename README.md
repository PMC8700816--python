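# mixsurf

Mixture-design response surfaces on the composition simplex: Scheffé
polynomial fitting with response transforms, mixture ANOVA with a
lack-of-fit test against pure error, I-optimal design construction, and
Derringer–Suich desirability optimization — plus the closed-form
formulation metrics (Sauter mean diameter, DPPH IC50, droplet growth
ratio, FICI) used when the mixture being optimized is an emulsion
formulation.

## Who this is for

Formulation scientists and biostatisticians running *mixture
experiments*: experiments in which the factors are the proportions
`x₁, …, x_q` of components in a blend, constrained by `Σ xᵢ = 1`. The
canonical application bundled with the package is the lipid phase of an
essential-oil-loaded nanoemulsion — three oils (cumin, carvi, coriander)
blended to jointly minimize droplet size, antioxidant IC50 and two
bacterial survival counts — but the machinery is generic in `q`,
the model degree and the response goals.

## The models

Responses are fitted (optionally after a monotone transform such as
√y) with Scheffé canonical polynomials, which have no intercept because
of the mixture constraint:

- linear: `y = Σᵢ βᵢ xᵢ`
- quadratic: `y = Σᵢ βᵢ xᵢ + Σᵢ<ⱼ βᵢⱼ xᵢxⱼ`
- reduced cubic: `y = Σᵢ βᵢ xᵢ + Σᵢ<ⱼ βᵢⱼ xᵢxⱼ + Σᵢ<ⱼ δᵢⱼ xᵢxⱼ(xᵢ−xⱼ)`

The mixture ANOVA attributes the Type I (sequential) sum of squares to
the linear blending terms jointly, partial (drop-one) sums of squares to
each non-linear term, and splits the residual into lack of fit and pure
error using the design's replicate groups. Fit quality is summarized by
R², adjusted R², PRESS-based predicted R² and CV%.

For multi-response optimization, each predicted response ŷᵣ(x) is mapped
to an individual desirability dᵣ ∈ [0,1] by a Derringer–Suich ramp and the
overall desirability `D = (Π dᵣ^{wᵣ})^{1/Σwᵣ}` is maximized over the
simplex by a dense barycentric grid search plus Nelder–Mead polish.

## Worked example

`examples/02_optimize_blend.py` fits the four response models of the
bundled 17-run nanoemulsion study and finds the blend minimizing all
four responses at once:

```
optimal lipid-phase composition:
  EO_CU: 21.20%
  EO_CA: 61.82%
  EO_CO: 16.99%
overall desirability D = 0.9758
  d32_um: predicted 0.505 (individual desirability 1.000)
  ic50_mg_ml: predicted 6.879 (individual desirability 1.000)
  b_subtilis_cfu_ml: predicted 2.01e+05 (individual desirability 0.930)
  e_coli_cfu_ml: predicted 1.912e+06 (individual desirability 0.975)
```

A desirability near 1 means every response is predicted close to the
best value observed anywhere in the design: a carvi-rich blend with
roughly a fifth each of cumin and coriander oil is predicted to give the
smallest droplets (0.505 µm), the strongest antioxidant activity
(lowest IC50) and the fewest surviving colonies of both bacteria.
The other example scripts show fitting and ANOVA (`01`), I-optimal
design construction (`03`), simulation with known ground truth (`04`)
and the closed-form metrics (`05`).

The same stages are scriptable from the shell:

```sh
mixsurf fixture --out responses.csv
mixsurf fit --design responses_design.csv --responses responses.csv --model model.json
mixsurf pipeline --design responses_design.csv --responses responses.csv \
    --models models.json --goals goals.json
```

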