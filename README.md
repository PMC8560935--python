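# marshres

Salt marshes in the southeastern U.S. recover from disturbance through a
mutualism: ribbed mussel (*Geukensia demissa*) mounds anchor and fertilize
cordgrass (*Spartina alterniflora*), which regrows clonally from those
remnant patches into bare mudflat. Invasive feral hogs (*Sus scrofa*)
attack this mutualism twice over — trampling recovering cordgrass edges
and preying on the mussels that seed recovery. `marshres` packages the
computational side of that story for ecologists studying invasion impacts
on ecosystem resilience:

* a **dynamical model** of mussel cover under hog predation, with three
  foraging behaviors as pluggable functional responses, equilibrium and
  bifurcation analysis (alternative stable states, fold collapse);
* a **spatially explicit recolonization simulator** (Fisher–KPP
  reaction–diffusion on a lattice) that turns model equilibria into
  whole-marsh recovery times;
* **patch metrics** — connected-component labeling of binary vegetation
  rasters, replacing manual patch digitization on drone mosaics;
* **synthetic-data generators** that emulate the field designs (a 2-year
  hog-exclusion experiment, a hog × mussel factorial, negative-binomial
  mussel transect surveys, a Bernoulli scat survey, and drone-style
  fragmented landscapes), each emitting its generating truth;
* **estimation stages** in statsmodels style (`Model.from_dataframe(...)
  .fit() -> FitResult`) mirroring the field analyses, so every estimator
  can be scored as parameter recovery against synthetic truth.

## The model

Mussel cover `M` is scaled to a maximum standing crop `K = 1`
(≈10% absolute marsh cover); cordgrass cover is proportional to it.
With logistic regrowth at rate `g` and a fixed hog density `H`:

    dM/dt = g·M·(1 − M/K) − M·f(M)

where the per-mussel predation pressure `f(M)` encodes the foraging mode:

| mode         | f(M)               | behaviour                              |
|--------------|--------------------|----------------------------------------|
| `none`       | `a·H`              | trampling only (Holling I)             |
| `incomplete` | `a·H·M/(M² + h²)`  | pressure fades as prey thins (III)     |
| `complete`   | `a·H/(M + h)`      | depensatory focus on remnants (II)     |

Under `complete` focusing the system is bistable: a stable vegetated
state coexists with a stable bare state, separated by an unstable
threshold, and the vegetated state vanishes at a saddle-node fold at
`H_fold = g(1+h)²/(4a)`, `M_fold = (1−h)/2`. Past the fold no remnant
mussel patches survive a die-off, so whole-marsh recovery time is
infinite (`NO_RECOVERY`).

## Worked example

```python
from marshres import HogMusselModel, ModelParams, fold_point
from marshres import synthetic as syn, fit_recovery_rates

m = HogMusselModel(ModelParams(g=1.0, a=1.0, h=0.2, H=0.3), "complete")
for eq in m.equilibria():
    print(f"M* = {eq.M:.4f}  [{eq.stability}]")
print("fold:", fold_point(m.params))

data, truth = syn.gen_patch_recovery(seed=42)   # exclusion experiment
print(fit_recovery_rates(data).summary())
```

prints

```
M* = 0.0000  [stable]
M* = 0.1551  [unstable]
M* = 0.6449  [stable]
fold: (0.36, 0.4)

recovery-rate LMM results
==============================================
term                            estimate      se
rate_exclusion                     15.79    1.12
rate_control                       5.346    1.12
----------------------------------------------
rate_difference                    10.44    1.59
----------------------------------------------
interaction time:treatment: stat=43.38 df=(1, 252) p=2.61e-10
```

The three equilibria show bistability at `H = 0.3`: a bare marsh
(`M* = 0`) and a vegetated marsh (`M* = 0.64`) are both stable, and the
unstable threshold at `M* = 0.16` is the tipping point — push the marsh
below it and it collapses. The fold says the vegetated state exists only
for `H < 0.36`. The fitted exclusion experiment (one random replicate)
recovers arm recovery rates near the generating truth of 17.85 and
6.85 % cover/yr, with a strongly significant time × exclusion
interaction: hog exclusion roughly triples the recovery rate.

A command-line interface wraps the same functionality:

```bash
marshres model equilibria --mode complete --hog 0.3
marshres model bifurcation --mode complete --out branches.csv
marshres gen factorial --out data/ --seed 1
marshres fit factorial --in data/factorial.csv --out fit.json
marshres patches --in mosaic.tif --out patches.csv
marshres reproduce --out results/ --seed 1
```

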