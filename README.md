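# stcokriging

Spatiotemporal cokriging (STCK) for multi-year environmental point
monitoring — built for the soil-contamination setting where several heavy
metals are measured together on annual campaigns and the goal is to map one
of them, using both its own historical samples and the correlated
co-measured metals.

## The method

Dependence in space and time is modeled by sum-metric (Bilonick-type)
auto- and cross-semivariograms

    γ(h_S, h_T) = C0 + C_T·h_T + C_S·g(h_S; a_S) + C_ST·g(h_ST; a_ST),
    h_ST = √(h_S² + α·h_T²)

with bounded structures g (spherical, gaussian, exponential) and a
geometric anisotropy ratio α (m²/yr²) that converts temporal lag to
spatial-equivalent distance. A **single α is shared by all auto- and
cross-models**, so one space–time metric defines neighborhoods for every
variable. All pair models are fitted **jointly** by a real-coded genetic
algorithm minimizing Σ wᵢ(γ̂ᵢ − γᵢ)² with wᵢ = Nᵢ/√γ̂ᵢ (for four variables:
51 free parameters). Prediction solves the ordinary-cokriging system in
semivariogram form — primary weights sum to 1, each secondary's to 0 — and
reports the kriging variance σ² = λᵀb.

The package covers the full workflow:

- tidy CSV point data, log2 transform, Pearson co-variable ranking
  (`stcokriging.data`)
- experimental ST semi- and cross-semivariograms with pair-count
  bookkeeping (`stcokriging.variogram`)
- sum-metric models, evaluation, validity diagnostics, model files
  (`stcokriging.models`)
- joint GA fitting with pre-estimated temporal slopes
  (`stcokriging.fitting`)
- k-nearest-per-variable cokriging, grids, leave-one-out validation,
  (k, co-variable) sweeps (`stcokriging.kriging`, `stcokriging.pipeline`)
- a coregionalized Gaussian field simulator with known truth, so the whole
  stack is testable end to end (`stcokriging.simulate`)

## Worked example

Simulate a two-metal field with cross-correlation 0.8, then predict Cd
using Cu as a co-variable and validate by leave-one-out:

```python
import numpy as np
import stcokriging as sk

rho = np.array([[1.0, 0.8], [0.8, 1.0]])
spec = sk.SyntheticFieldSpec(
    variables=("Cd", "Cu"),
    nugget=0.25 * rho,
    spatial=sk.StructureSpec("spherical", 1500.0, 0.75 * rho),
    alpha=2000.0,
    design=sk.SamplingDesign((2012.0, 2013.0, 2014.0), (25,) * 3,
                             (0, 4000, 0, 4000), 75),
    seed=42,
)
sim = sk.simulate(spec)                       # 150 samples, truth known

target = sk.STPoint(2000.0, 2000.0, 2014.0)
sol = sk.predict_point(sim.dataset, sim.truth, "Cd", ["Cu"], target, k=10)
print(f"estimate = {sol.estimate:.3f}, variance = {sol.variance:.3f}")

with_cov = sk.loocv(sim.dataset, sim.truth, "Cd", ["Cu"], k=10)
without  = sk.loocv(sim.dataset, sim.truth, "Cd", [], k=10)
print(f"LOOCV RMSE with Cu: {with_cov.rmse:.3f}   without: {without.rmse:.3f}")
```

Output:

```
estimate = 0.673, variance = 0.450
LOOCV RMSE with Cu: 0.432   without: 0.724
```

The estimate is the cokriged Cd value (here on the simulation's zero-mean
scale) and the variance its prediction uncertainty. The RMSE drop from
0.724 to 0.432 shows the point of cokriging: the co-located, correlated Cu
measurements sharpen the Cd prediction — the same qualitative behavior the
method exhibits on real multi-metal surveys, where prediction variance
falls as more neighbors and more co-variables are used.

The same workflow is available from the shell:

```sh
stck simulate --spec field.yaml --seed 3 --out-points pts.csv --out-truth truth.json
stck variogram --points-csv pts.csv --out vg.csv
stck fit --variograms-csv vg.csv --out-model model.json
stck predict --points-csv pts.csv --model-file model.json --primary Cd \
     --covariables Cu --grid 0,4000,0,4000,250 --time 2014 --out map.csv
stck cv --points-csv pts.csv --model-file model.json --primary Cd \
     --covariables Cu --k 10 --out cv.csv
stck sweep --points-csv pts.csv --model-file model.json --primary Cd \
     --k-range 4:20 --covariable-sweep ";Cu" --out sweep.csv
```

A reference fitted model set for four urban-topsoil metals (LogCu, LogCd,
LogPb, Zn; shared α = 2085) ships in `stcokriging.reference` — both as a
realistic example and as a stress case: like many independently fitted
pair models it is not a valid coregionalization, which
`stcokriging.validity_report` diagnoses and the predictor survives by
flooring negative variances.

See `docs/methods.md` for the model details, fitting strategy, simulator
design and known limitations.

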