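# bagol — Bayesian grouping of localizations

Single-molecule localization microscopy (DNA-PAINT, dSTORM) reports each
blinking/binding event as an independent *localization* with its own
precision, but one fluorescently tagged molecule — an *emitter* — usually
produces many events.  `bagol` infers the emitters behind a localization
list: how many there are (K), where they sit, how many events each
produced, and optionally a per-emitter linear drift — by sampling the full
posterior over grouping configurations with reversible-jump MCMC.
Combining the ~λ events of an emitter improves its position estimate
roughly as 1/√λ, so with ~50 events per emitter, nanometer-precision maps
of molecular positions become possible.

The model: localization *i* allocated to emitter *k* is a Gaussian draw
per axis,

    x_i ~ N(mu_k + a_k t_i, sigma_i^2),

with the reported precision σᵢ, normalized acquisition time tᵢ ∈ [0, 1]
and drift a_k; the per-emitter event count follows Poisson(λ) (DNA-PAINT)
or a gamma-mixed Poisson (negative binomial; dSTORM blinking), with λ
either fixed or learned hierarchically under a Gamma(η, mean γ) prior.
Four jump types (Move / Allocate / Birth / Death) explore (K, μ, a, Z)
jointly; the chain yields a model-averaged *posterior image* and the
*MAPN* summary — the most probable number of emitters with coordinates
and grouped precisions extracted by k-means from the modal-K samples.
Pre-analysis filters (intensity, nearest-neighbor-count outlier removal),
field tiling with overlap stitching, Hungarian-matched Jaccard/RMSE
evaluation, point-pattern statistics (NND, Hopkins), template alignment
with consensus re-grouping, and full synthetic DNA-PAINT / dSTORM
generators are included.

## Worked example

```python
import numpy as np

from bagol import BayesianGrouper
from bagol.simulate import sim_8mer, blinks_from_emitters

# eight docking strands on a 10 nm-radius ring, ~50 binding events each,
# 120 nm PSF, 1800 mean photons per event
scene = sim_8mer(10.0, lam=50)
locs, _ = blinks_from_emitters(scene, rng=2)
print(f"{len(locs)} localizations, median precision "
      f"{float(np.median(locs.sigma_x)):.2f} nm")

est = BayesianGrouper(xi=50, xi_mode="fixed", n_samples=2000,
                      random_state=4).fit(locs)
print(est.n_emitters_)
print(round(float(est.emitter_precisions_.mean()), 4))
```

Output from this exact snippet:

```
390 localizations, median precision 3.59 nm
8
0.6099
```

390 raw localizations with ~3.6 nm individual precision are grouped into
exactly the 8 true emitters, whose grouped precisions average ~0.6 nm —
close to the ~1/√50 improvement that makes the 7.7 nm neighbor spacing of
the ring trivially resolvable.  The same analysis is available from the shell:

```bash
bagol simulate --geometry 8mer --radius 10 --lam 50 --seed 2 -o ring.csv
bagol run ring.csv --lam 50 --samples 2000 --seed 4 -o out/
bagol metrics --truth ring.truth.csv --mapn out/mapn.csv
```

`bagol run` writes MAPN coordinates (`mapn.csv`), posterior and MAPN
images (TIFF) and a JSON run report; `bagol filter` applies the intensity
and NND outlier filters (the NND filter is refused for dSTORM data, where
a single blink per emitter is legitimate); `bagol align` aligns repeated
structures to a template and re-groups the pooled coordinates into a
consensus.

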