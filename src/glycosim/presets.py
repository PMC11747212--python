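"""Ready-made simulation scenarios.

Three families:

* ``benchmark-*`` — minimal multiplicity patterns whose outcomes can be
  checked by eye and by exact counting (e.g. every protein carrying exactly
  one glycan with two sialic acids).
* ``distance-*`` — scenarios that isolate the three characteristic
  nearest-neighbor distances of the glycocalyx: sialic acids on the same
  glycan, on different glycans of the same protein, and on different
  proteins.
* realistic scenarios — membrane densities derived from hexagonal lipid
  packing and a 1:75 protein:lipid ratio, a mucin demonstration, and an
  ocular-surface glycocalyx with three mucin lengths in equal parts.

All lengths in microns.  Every factory accepts a ``seed`` and keyword
overrides for any config field.
"""

from __future__ import annotations

from .config import (
    SimulationConfig,
    lipid_density_from_radius,
    protein_density_from_ratio,
)

__all__ = ["PRESETS", "get_preset", "preset_names"]

# shared biologically motivated parameters: anchor distance 12 nm (sia–anchor
# distances of 1–3.4 nm plus a minimal protein radius of 1–5 nm), sia–sia
# distance 2.5 nm (disialylated O-glycan), Gaussian cutoff 2 sd, steric
# half-angle 0.35 rad (~20 deg), protein centers up to 50 nm above the membrane
_REALISTIC = dict(
    mu_sias_glycoprot=0.012,
    sigma_sias_glycoprot=0.002,
    mu_sias=0.0025,
    sigma_sias=0.0005,
    cutoff_gaussians=2.0,
    forbidden_angle_glycans=0.35,
    mu_glycanheight=0.005,
    alpha_glycanheight=4.0,
    scale_glycanheight=0.01,
    lower_glycanheight=0.0,
    upper_glycanheight=0.05,
    prob_n_glycans_lip=[0.9, 0.1],
    prob_n_sias_lip_glycan=[0.3, 0.7],
)


def _make(name: str, seed, overrides: dict, **fields) -> SimulationConfig:
    merged = dict(_REALISTIC)
    merged.update(fields)
    merged.update(overrides)
    return SimulationConfig(global_name=name, seed=seed, **merged)


def benchmark_half_single(seed: int | None = None, **overrides) -> SimulationConfig:
    """Half the proteins carry one glycan with exactly one sialic acid."""
    return _make(
        "benchmark-half-single",
        seed,
        overrides,
        mode="planar2d",
        fov_x=2.0,
        fov_y=2.0,
        prot_dens=50.0,
        lip_dens=50.0,
        prob_n_glycans_prot=[0.5, 0.5],
        prob_n_sias_prot_glycan=[0.0, 1.0],
    )


def benchmark_sia_pairs(seed: int | None = None, **overrides) -> SimulationConfig:
    """Every protein carries exactly one glycan with exactly two sialic acids."""
    return _make(
        "benchmark-sia-pairs",
        seed,
        overrides,
        mode="planar2d",
        fov_x=2.0,
        fov_y=2.0,
        prot_dens=50.0,
        lip_dens=50.0,
        prob_n_glycans_prot=[0.0, 1.0],
        prob_n_sias_prot_glycan=[0.0, 0.0, 1.0],
    )


def benchmark_mixed(seed: int | None = None, **overrides) -> SimulationConfig:
    """Proteins carry one or two glycans (50/50), glycans one or two sias (50/50)."""
    return _make(
        "benchmark-mixed",
        seed,
        overrides,
        mode="planar2d",
        fov_x=2.0,
        fov_y=2.0,
        prot_dens=50.0,
        lip_dens=50.0,
        prob_n_glycans_prot=[0.0, 0.5, 0.5],
        prob_n_sias_prot_glycan=[0.0, 0.5, 0.5],
    )


_DISTANCE_COMMON = dict(
    mode="planar2d",
    fov_x=5.0,
    fov_y=5.0,
    prot_dens=125.0,
    lip_dens=625.0,
)


def distance_intra_glycan(seed: int | None = None, **overrides) -> SimulationConfig:
    """70% of proteins carry 1 glycan; 70% of those glycans carry 2 sialic acids.

    The nearest neighbor of most points is its partner on the same glycan,
    so the NN peak sits at the sia–sia distance law."""
    return _make(
        "distance-intra-glycan",
        seed,
        overrides,
        **_DISTANCE_COMMON,
        prob_n_glycans_prot=[0.3, 0.7],
        prob_n_sias_prot_glycan=[0.3, 0.0, 0.7],
    )


def distance_inter_glycan(seed: int | None = None, **overrides) -> SimulationConfig:
    """70% of proteins carry 2 glycans; each glycan carries 1 sialic acid with 70%.

    The NN peak reflects the spacing of glycans on the same protein (twice
    the anchor distance scaled by the angular separation)."""
    return _make(
        "distance-inter-glycan",
        seed,
        overrides,
        **_DISTANCE_COMMON,
        prob_n_glycans_prot=[0.3, 0.0, 0.7],
        prob_n_sias_prot_glycan=[0.3, 0.7],
    )


def distance_inter_protein(seed: int | None = None, **overrides) -> SimulationConfig:
    """70% of proteins carry 1 glycan with 1 sialic acid in 70% of cases.

    Isolated points: the NN distribution reflects the random protein spacing
    and is the broadest of the three distance scenarios."""
    return _make(
        "distance-inter-protein",
        seed,
        overrides,
        **_DISTANCE_COMMON,
        prob_n_glycans_prot=[0.3, 0.7],
        prob_n_sias_prot_glycan=[0.3, 0.7],
    )


def realistic_membrane(seed: int | None = None, **overrides) -> SimulationConfig:
    """Upper-estimate membrane densities: close-packed 1-nm lipid heads and a
    1:75 protein:lipid ratio, moderate glycan multiplicities, 3D heights."""
    lip = lipid_density_from_radius(0.001)
    return _make(
        "realistic-membrane",
        seed,
        overrides,
        mode="planar3d",
        fov_x=1.0,
        fov_y=1.0,
        lip_dens=lip,
        prot_dens=protein_density_from_ratio(lip, 75),
        prob_n_glycans_prot=[0.2, 0.5, 0.3],
        prob_n_sias_prot_glycan=[0.2, 0.5, 0.3],
    )


def mucin_demo(seed: int | None = None, **overrides) -> SimulationConfig:
    """A sparse field of 250-nm mucins showing the stacked sialic-acid columns."""
    return _make(
        "mucin-demo",
        seed,
        overrides,
        mode="mucin3d",
        fov_x=1.0,
        fov_y=1.0,
        prot_dens=10.0,
        lip_dens=100.0,
        forbidden_angle_glycans=0.0,
        mucin_lengths=[0.25],
        prob_n_sias_prot_glycan=[0.1, 0.45, 0.45],
    )


def ocular_glycocalyx(seed: int | None = None, **overrides) -> SimulationConfig:
    """Ocular-surface glycocalyx: 50/250/500 nm mucins in equal parts.

    Glycan counts per backbone are 28/139/178; sialic acids per O-glycan are
    dominated by mono- and disialylated species with a 2.5 nm sia–sia
    distance (disialylated core-1 glycans)."""
    return _make(
        "ocular-glycocalyx",
        seed,
        overrides,
        mode="mucin3d",
        fov_x=1.0,
        fov_y=1.0,
        prot_dens=500.0,
        lip_dens=2500.0,
        forbidden_angle_glycans=0.0,
        mucin_lengths=[0.05, 0.25, 0.5],
        mucin_n_glycans=[28, 139, 178],
        mu_sias=0.0025,
        prob_n_sias_prot_glycan=[0.1, 0.45, 0.45],
    )


PRESETS = {
    "benchmark-half-single": benchmark_half_single,
    "benchmark-sia-pairs": benchmark_sia_pairs,
    "benchmark-mixed": benchmark_mixed,
    "distance-intra-glycan": distance_intra_glycan,
    "distance-inter-glycan": distance_inter_glycan,
    "distance-inter-protein": distance_inter_protein,
    "realistic-membrane": realistic_membrane,
    "mucin-demo": mucin_demo,
    "ocular-glycocalyx": ocular_glycocalyx,
}


def preset_names() -> list[str]:
    return list(PRESETS)


def get_preset(name: str, seed: int | None = None, **overrides) -> SimulationConfig:
    try:
        factory = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESETS)}"
        ) from None
    return factory(seed=seed, **overrides)
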