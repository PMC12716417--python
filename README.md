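# streamisd

Size spectra, life-history traits and environmental flows in stream fish
assemblages: an inference pipeline linking the exponent of the individual
size distribution (ISD) to community traits, flow-regime alteration and
land use through a piecewise path model.

## The problem

In a stream fish assemblage, individual body masses follow an inverse power
law — many small fish, few large ones. Writing body mass as *x* on the
bounded interval [*x*min, *x*max], the ISD density is

    f(x) = (b + 1) x^b / (x_max^(b+1) − x_min^(b+1))        b ≠ −1

and the exponent *b* summarises size structure: higher (less negative) *b*
means relatively more large individuals. *b* shifts with warming, fishing,
hydrologic alteration and land use, making it a candidate indicator for
ecosystem-scale management. A trophic-transfer null expectation is
*b* = λ + log(TTE)/log(PPMR); at the canonical TTE = 0.10, PPMR = 10⁴ and
λ = −0.75 this gives *b* = −1.

`streamisd` implements the full chain of inference needed to ask *why* *b*
varies across sites:

1. **`streamisd.isd`** — maximum-likelihood estimation of *b* from raw
   individual masses under the bounded power law (PLB), with 95%
   profile-likelihood intervals, an inverse-CDF sampler, and the canonical
   TTE/PPMR relation. `BoundedPowerLaw` is a scikit-learn-style estimator.
2. **`streamisd.prep`** — record QC (most-recent sample per site,
   length–weight allometric outlier screening) and abundance-weighted
   community trait means (CWM).
3. **`streamisd.life_history`** — convex affinities of each species to the
   equilibrium / periodic / opportunistic life-history endpoints via Gower
   dissimilarity → nonmetric MDS → 3-archetype archetypal analysis, plus a
   redundancy filter for the community affinity axes.
4. **`streamisd.flow`** — annual observed/expected flow metrics →
   directional alteration designations (inflated / diminished /
   later / earlier) → 0–1 severity proportions per gage and metric,
   site–gage pairing by drainage area, and collinearity-based metric
   selection.
5. **`streamisd.sem`** — the piecewise path model: skewness-gated log
   transforms and z-scoring, bidirectional stepwise-AIC selection with
   forced controls (drainage area, ecoregion), directed-separation tests,
   Fisher's C fit statistic, and standardized direct / indirect / total
   effect decomposition on *b*. `PiecewisePathModel` is the estimator
   facade.
6. **`streamisd.synthetic`** — a generator that plants known standardized
   path coefficients at every layer (land use → flow → traits → *b* →
   individual masses) so each stage, and the whole pipeline, is testable by
   parameter recovery.
7. **`streamisd.cli` / `streamisd.pipeline`** — `streamisd` console script
   with `simulate`, `run`, and per-stage subcommands.

## Worked example

Fit an exponent to individual masses:

```python
from streamisd import BoundedPowerLaw, PLBParams, plb_sample, canonical_b

masses = plb_sample(2000, PLBParams(-1.43, 1.0, 450.0), seed=7)  # grams
est = BoundedPowerLaw().fit(masses)
print(f"b = {est.b_:.3f}  (95% CI {est.ci_[0]:.3f} to {est.ci_[1]:.3f})")
print(f"canonical b: {canonical_b(0.10, 1e4, -0.75):.2f}")
```

```
b = -1.432  (95% CI -1.461 to -1.403)
canonical b: -1.00
```

The estimate recovers the generating exponent (−1.43) within its profile
interval; the canonical relation gives the theoretical −1 baseline.

Run the whole pipeline on a simulated study:

```bash
streamisd simulate --seed 4 --out demo --n-sites 60 --n-species 80 \
    --individuals-per-site 200
streamisd run --input-dir demo --seed 4
```

```
sites modelled: 60
Fisher's C = 16.50 (df=22), P = 0.790
                    predictor    direct  indirect     total
                     pct_crop  0.000000 -0.381709 -0.381709
                pct_developed  0.000000  0.001134  0.001134
                drainage_area -0.025837  0.001602 -0.024235
       high_flow_timing_later -0.131094 -0.295000 -0.426094
 high_flow_frequency_inflated  0.120160  0.122881  0.243040
low_flow_magnitude_diminished -0.241232 -0.323767 -0.565000
                    cwm_ctmax -0.229589  0.000000 -0.229589
                  cwm_trophic  0.274564  0.000000  0.274564
            cwm_opportunistic -0.423667  0.000000 -0.423667
                 cwm_periodic  0.000000  0.000000  0.000000
```

A non-significant Fisher's C (P = 0.79 > 0.05) says the data are consistent
with the fitted causal structure. The effect table partitions each
predictor's standardized influence on *b*: here land-use effects on the
exponent run entirely through flow and traits (zero direct effect), while
trait effects are direct — the signature the planted model encodes.

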