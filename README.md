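# glycosim

Stochastic geometric simulation of individual sialic-acid coordinates in
the glycocalyx, with labeling-efficiency thinning and nearest-neighbor
distance analysis.

The glycocalyx — the dense layer of glycoproteins, glycolipids and other
glycoconjugates coating every cell — is organized at a scale only
single-molecule localization microscopy can resolve. To interpret such
point-cloud data, one needs a forward model: given known geometric
parameters (densities, glycan multiplicities, sugar–sugar distances), what
coordinate patterns and distance distributions should an experiment see?
`glycosim` generates such synthetic coordinate clouds for sialic acids (the
charged sugars capping many glycans), degrades them to realistic labeling
efficiencies, and summarizes them through k-nearest-neighbor distance
distributions. It is aimed at microscopists and glycobiologists
benchmarking super-resolution readouts of cell-surface glycans.

## Model

All lengths are microns, densities per µm², angles radians.

* **Anchors.** `round(ρ·A)` glycoprotein and glycolipid centers are placed
  uniformly in the field of view of area `A = FOV_x · FOV_y`. In 3D,
  protein-center heights follow a truncated skew-normal law
  `2/ω·φ((z−ξ)/ω)·Φ(α(z−ξ)/ω)` on `[lower, upper]`; lipids sit in the
  membrane plane.
* **Glycoproteins.** A protein draws its glycan count from a probability
  vector `P(n glycans)`, each glycan its sialic-acid count from
  `P(m sias)`. All sialic acids of a glycan lie on one radial shell of
  radius `d ~ N(μ_anchor, σ_anchor)` about the protein center (truncated at
  `±c·σ` and at 0); consecutive sialic acids are a chord
  `s ~ N(μ_sia, σ_sia)` apart, i.e. an angular step `2·arcsin(s/2d)`. The
  first sialic acid of each glycan must lie outside the forbidden
  sector/cone (half-angle `θ`) around every previously placed glycan of the
  same protein — a steric proxy for glycan bulk. In 3D everything stays on
  the upper hemisphere (membrane below).
* **Glycolipids.** At most one glycan; its sialic acids coincide exactly
  with the lipid anchor.
* **Mucins.** Rod-like, heavily O-glycosylated proteins: glycan anchors sit
  at uniformly random heights along a vertical backbone, each glycan placed
  with the same shell/chord rules but no steric exclusion (`θ = 0`).
* **Detection.** Labeling/detection efficiency `e` is a uniformly random
  subset of `round(e·N)` points (Bernoulli thinning optional).
* **Analysis.** k-th nearest-neighbor Euclidean distances (KD-tree), with
  median/quartile summaries per condition.

## Worked example

```python
import numpy as np
from glycosim import run_simulation, knn_distances, thin_cloud, summarize_by_condition
from glycosim.presets import get_preset

cfg = get_preset("distance-intra-glycan", seed=7)   # 5x5 µm, 125 proteins/µm²
cloud = run_simulation(cfg)
print(f"simulated {len(cloud)} sialic acids "
      f"({(cloud.anchor_kind == 'protein').sum()} from proteins, "
      f"{(cloud.anchor_kind == 'lipid').sum()} from lipids)")

rng = np.random.default_rng(7)
results = []
for eff in (1.0, 0.5):
    thinned = thin_cloud(cloud, eff, rng)
    results.append((f"{eff:.0%} labeled", knn_distances(thinned, k=1)))
print(summarize_by_condition(results).to_string(index=False))
```

prints

```
simulated 4141 sialic acids (2996 from proteins, 1145 from lipids)
   condition    n   median       q1       q3      min      max
100% labeled 4141 0.002758 0.002329 0.016896 0.000894 0.132982
 50% labeled 2070 0.030720 0.002713 0.068852 0.000947 0.192985
```

In this scenario most proteins carry one glycan with two sialic acids, so
at full labeling the median NN distance (2.8 nm) sits at the configured
sia–sia distance (2.5 ± 0.5 nm): each point's nearest neighbor is its
partner on the same glycan. At 50% labeling half the partners are dark and
the median jumps to ~31 nm, while the low quartile (surviving intact
pairs) barely moves — exactly the signature quantitative distance readouts
must correct for.

The same pipeline is available from a shell:

```bash
glycosim presets                                  # list built-in scenarios
glycosim presets --write distance-intra-glycan --out vars.txt --seed 7
glycosim simulate vars.txt --repeats 3 --efficiency 1.0 --efficiency 0.5 --out out/
glycosim analyze out/distance-intra-glycan_rep0_coords.csv --k 1
```

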