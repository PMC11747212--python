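# Methods

## Model overview

`glycosim` is a forward geometric model of sialic-acid positions on the
cell surface. It deliberately abstracts glycans to a small set of distance
laws rather than atomistic conformers: each simulated point is one terminal
(capping) sialic acid, attached to a glycoprotein, glycolipid, or mucin
anchor. The model's claims are therefore about *spatial statistics* (how
multiplicities, distance laws and densities shape nearest-neighbor
distributions), not about chemistry.

Assumptions baked into the model:

* Proteins are effectively spherical; their size enters only through the
  anchor→sialic-acid distance law.
* All glycan species within a run share one anchor-distance law and one
  sia–sia distance law (single Gaussians, truncated); no mixtures and no
  per-species subgrouping.
* Only terminal sialic acids are modeled; polysialic (non-capping) chains
  are out of scope.
* Sialic acids of one glycan share a radial shell about their anchor: the
  sugar sequence below the caps is typically identical, so their anchor
  distance is too. Consecutive caps are a chord apart drawn from the
  sia–sia law.
* Steric bulk of a glycan is modeled as a forbidden sector (2D) or cone
  (3D) of **half-angle** `forbidden_angle_glycans` around the direction of
  each previously placed glycan of the same protein. Only each glycan's
  *first* sialic acid is checked against the forbidden regions; later chain
  members may wander into them. This is a known approximation, relevant
  only at high sialic-acid multiplicities; it is reproduced deliberately,
  not patched.
* Glycolipid sialic acids coincide exactly with their anchor (a glycolipid
  carries at most one glycan with few caps, below the model's spatial
  resolution of interest). The resulting duplicate coordinates yield zero
  NN distances and are *kept* — an experiment would localize each
  fluorophore separately.
* In 3D, protein-derived sialic acids lie on the upper hemisphere of their
  anchor (membrane and protein body occupy the space below).
* Mucins are vertical rods; glycan anchors sit at uniform heights along the
  backbone and do not sterically exclude one another (they occupy different
  heights). Backbone tilt is not modeled.

## Parameters

| parameter | meaning | unit | default | rationale |
|---|---|---|---|---|
| `fov_x`, `fov_y` | field of view | µm | 1.0 | typical SMLM ROI scale |
| `prot_dens`, `lip_dens` | anchor densities | µm⁻² | scenario-specific | see helpers below |
| `prob_n_glycans_prot[i]` | P(protein has i glycans) | — | scenario-specific | multiplicity pattern under study |
| `prob_n_sias_*_glycan[i]` | P(glycan has i sias) | — | scenario-specific | |
| `mu_sias_glycoprot`, `sigma_sias_glycoprot` | anchor→sia distance law | µm | 0.012 / 0.002 | sia–anchor spans of 1–3.4 nm plus a minimal protein radius of 1–5 nm motivate a 12 nm mean |
| `mu_sias`, `sigma_sias` | sia–sia distance law | µm | 0.0025 / 0.0005 | 2.5 nm separates the two caps of the most common disialylated O-glycan |
| `cutoff_gaussians` | truncation half-width | sd | 2.0 | excludes unphysically large draws |
| `forbidden_angle_glycans` | steric half-angle | rad | 0.35 (~20°) | glycan bulk at a 12 nm shell; set to 0 for mucins |
| `mu/alpha/scale_glycanheight` | skew-normal height law | µm / — / µm | 0.005 / 4.0 / 0.01 | most protein centers near the membrane with a tail upward |
| `lower/upper_glycanheight` | height truncation | µm | 0 / 0.05 | glycoprotein ectodomains rarely exceed 50 nm |
| `mucin_lengths`, `mucin_n_glycans` | backbone lengths and glycan counts | µm / — | none | lengths chosen with equal probability per mucin |
| `seed` | master seed | — | none | full reproducibility |

Helper calculators give literature-anchored densities: hexagonal close
packing of 1-nm lipid heads gives `1/(2√3 r²) ≈ 2.9e5 µm⁻²`
(`lipid_density_from_radius`), a 1:75 protein:lipid ratio then gives
`≈ 3.8e3 µm⁻²` (`protein_density_from_ratio`) — both deliberately *upper*
estimates. `mucin_glycan_count(L)` = `round(L / 0.36 nm × 0.2)` (20%
O-glycosylated residues); 50/250/500 nm backbones give 28, 139 and 278
glycans. The bundled ocular preset uses [28, 139, 178]: published counts
for these mucin classes quote 178 for the 500 nm species, and preset
scenarios carry the quoted counts rather than silently re-deriving them.

## What the generator emulates — and what it does not

Preset scenarios are *study conditions*, not tuning knobs: benchmark
patterns with exactly countable outcomes (e.g. 50 µm⁻² anchors on 2×2 µm,
every protein one glycan with two caps), the three characteristic-distance
scenarios (125/625 µm⁻² on 5×5 µm with 70% multiplicity probabilities)
that isolate intra-glycan, inter-glycan and inter-protein spacing, and
realistic-density membranes. Where a scenario's source leaves parameters
open (glycolipid sialylation in the distance scenarios, glycan
multiplicities in the realistic membrane), values were fixed once at
biologically plausible levels — sparse lipid sialylation
(P(glycan) = 0.1, mostly monosialylated) so isolated lipid points do not
dominate the protein-driven distance peaks — and are documented in
`presets.py`.

Not emulated: localization error (jitter), fluorophore blinking and
overcounting, membrane curvature, excluded volume between different
proteins, glycan dynamics, and correlated (clustered) anchor placement.
Passing tests therefore demonstrate correctness of the geometric model and
its statistics, not quantitative agreement with any particular experiment;
real SMLM data additionally convolve the localization-error and blinking
processes this package does not model.

## Numerical choices

* **Truncation by rejection**, never clamping (clamping would create point
  masses at the cutoffs). Rejection budgets default to 1000 attempts;
  exhaustion raises a specific error (`OvercrowdedError` when no allowed
  direction exists, i.e. too many glycans for the available solid angle).
* **Distances are magnitudes**: the anchor and chord laws are additionally
  truncated at 0.
* **Chord feasibility**: a drawn chord must satisfy `s ≤ 2d`; infeasible
  draws are resampled within the budget, then `ChainInfeasibleError`.
* **3D chain steps** rotate the previous direction by `2·arcsin(s/2d)`
  along a uniformly chosen great circle, redrawing the tangent while the
  step would leave the upper hemisphere (budgeted).
* **Anchor counts** are `round(density·area)` for reproducible sizes; a
  Poisson option (`anchor_count_model: poisson`) restores count
  fluctuations.
* **Thinning** keeps exactly `round(e·N)` points without replacement
  (reproducible sizes); Bernoulli mode is a flag. Labeling and detection
  efficiency are collapsed into the single fraction `e`.
* **k-NN** uses a KD-tree in the cloud's native dimension (3D metric for 3D
  simulations; xy-projection available as a flag for comparison with 2D
  renderings). Quartiles use linear interpolation (numpy default, type 7).
* **Reproducibility**: per-repeat and per-thinning streams are spawned from
  the master seed via `numpy.random.SeedSequence`, so batches are
  reproducible and byte-identical across runs while repeats stay mutually
  independent. Coordinates are written with 9 decimal digits (sub-picometer
  at micron scale), the guaranteed round-trip precision.
* **Config files** are a flat `key: value` text format with floats written
  via `repr`, so numeric round trips are bit-exact; vectors are bracketed
  lists. The file keys are the historical variable names
  (`FOV_x`, `prob_x_glycoprots`, ...) for continuity with existing
  parameter sets.

## Design choices where the design was open

* `forbidden_angle_glycans` is interpreted as a **half**-angle measured
  from each blocked direction (total blocked opening `2θ` per glycan).
* Sialic acids may fall outside the FOV rectangle when their anchor is near
  an edge; they are kept (no wrapping or clipping), avoiding edge-density
  artifacts. Crop downstream if a hard FOV is needed.
* Lipid anchors in 3D sit exactly in the membrane plane (z = 0).
* Glycans that draw zero sialic acids leave nothing behind and do not block
  directions (there is no placed sialic acid to block around).
* The characteristic-distance scenarios run in 2D; the three distance
  scales are planar quantities and 2D keeps them crisp.

## Problem sizes

Default test and acceptance runs use FOVs of 1–25 µm² with up to ~3×10⁵
anchors and ~10⁵ sialic acids per cloud; distributional checks pool ≥10⁴
glycans. These sizes give sub-nanometer statistical resolution on the
distance laws while keeping a full run in minutes on a laptop. Larger FOVs
scale linearly in anchors; the per-protein placement loop dominates.

## Known limitations

* No localization-noise or blinking model: simulated NN distributions are
  sharper at short range than experimental SMLM data will be.
* The first-sia-only steric check can place later chain members inside
  forbidden regions at high multiplicities.
* Single-Gaussian distance laws cannot represent multimodal glycan
  populations; run separate simulations per population and merge the
  clouds if needed.
* Mucin backbones are vertical and rigid; real mucins tilt and flex.
* No parallelization; very large FOVs at close-packed lipid densities are
  memory- and time-bound.
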