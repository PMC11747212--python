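"""Simulation parameter set: definition, validation, file IO and helper calculators.

All lengths are expressed in microns throughout the package; densities are
per square micron, angles in radians.

The on-disk format is a flat ``key: value`` document (one parameter per
line, ``#`` comments allowed, vectors as JSON-style bracketed lists).  The
file keys are the historical variable names of the original glycocalyx
simulation scripts (``FOV_x``, ``prob_x_glycoprots``, ...) so that existing
parameter sets carry over; in memory the fields use descriptive names.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SimulationConfig",
    "validate_config",
    "read_config",
    "write_config",
    "config_to_text",
    "lipid_density_from_radius",
    "protein_density_from_ratio",
    "mucin_glycan_count",
    "ConfigError",
    "MODES",
    "FILE_KEYS",
]

MODES = ("planar2d", "planar3d", "mucin3d")

#: probability-vector sums are accepted within this tolerance of 1.0
PROB_SUM_TOL = 1e-9


class ConfigError(ValueError):
    """Raised when a simulation is started from an invalid configuration."""


@dataclass
class SimulationConfig:
    """Complete parameter set for one simulation run.

    Probability vectors are indexed by count: entry ``i`` of
    ``prob_n_glycans_prot`` is the probability that a glycoprotein carries
    exactly ``i`` glycans, and likewise for the other vectors.  Glycolipids
    carry at most one glycan, so ``prob_n_glycans_lip`` has support {0, 1}.
    """

    # bookkeeping
    global_name: str = "simulation"
    path: str = "."
    variables_path: str = ""
    mode: str = "planar2d"

    # field of view (microns) and anchor densities (per square micron)
    fov_x: float = 1.0
    fov_y: float = 1.0
    prot_dens: float = 0.0
    lip_dens: float = 0.0

    # glycan / sialic-acid multiplicity distributions
    prob_n_glycans_prot: list[float] = field(default_factory=lambda: [1.0])
    prob_n_glycans_lip: list[float] = field(default_factory=lambda: [1.0])
    prob_n_sias_prot_glycan: list[float] = field(default_factory=lambda: [1.0])
    prob_n_sias_lip_glycan: list[float] = field(default_factory=lambda: [1.0])

    # distance laws (truncated Gaussians, microns)
    mu_sias_glycoprot: float = 0.012
    sigma_sias_glycoprot: float = 0.002
    mu_sias: float = 0.0025
    sigma_sias: float = 0.0005

    # steric exclusion half-angle (radians) and Gaussian truncation (in sd units)
    forbidden_angle_glycans: float = 0.0
    cutoff_gaussians: float = 2.0

    # protein-center height law (truncated skew normal, microns)
    mu_glycanheight: float = 0.005
    alpha_glycanheight: float = 4.0
    scale_glycanheight: float = 0.01
    lower_glycanheight: float = 0.0
    upper_glycanheight: float = 0.05

    # reproducibility / variants
    seed: int | None = None
    anchor_count_model: str = "fixed"  # "fixed": round(density*area); "poisson"

    # mucin mode: backbone lengths (microns) sampled with equal probability,
    # and the number of glycans per backbone of each length (computed from
    # mucin_glycan_count() when left unset)
    mucin_lengths: list[float] | None = None
    mucin_n_glycans: list[int] | None = None

    def validate(self) -> list[str]:
        return validate_config(self)

    @property
    def dimension(self) -> int:
        return 2 if self.mode == "planar2d" else 3

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def _check_prob_vector(name: str, vec, violations: list[str]) -> None:
    arr = np.asarray(vec, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        violations.append(f"{name}: must be a non-empty 1-d probability vector")
        return
    if np.any(arr < 0):
        violations.append(f"{name}: entries must be >= 0")
    if abs(arr.sum() - 1.0) > PROB_SUM_TOL:
        violations.append(f"{name}: entries must sum to 1 (got {arr.sum()!r})")


def validate_config(cfg: SimulationConfig) -> list[str]:
    """Check every configuration invariant; return one message per violation.

    An empty list means the configuration is valid.  Callers that need to
    abort on invalid input should raise :class:`ConfigError` themselves (the
    simulator does this).
    """
    v: list[str] = []
    if cfg.mode not in MODES:
        v.append(f"mode: must be one of {MODES}, got {cfg.mode!r}")
    if not cfg.fov_x > 0:
        v.append(f"fov_x: must be > 0, got {cfg.fov_x!r}")
    if not cfg.fov_y > 0:
        v.append(f"fov_y: must be > 0, got {cfg.fov_y!r}")
    if cfg.prot_dens < 0:
        v.append(f"prot_dens: must be >= 0, got {cfg.prot_dens!r}")
    if cfg.lip_dens < 0:
        v.append(f"lip_dens: must be >= 0, got {cfg.lip_dens!r}")

    for name in (
        "prob_n_glycans_prot",
        "prob_n_glycans_lip",
        "prob_n_sias_prot_glycan",
        "prob_n_sias_lip_glycan",
    ):
        _check_prob_vector(name, getattr(cfg, name), v)
    lip = np.asarray(cfg.prob_n_glycans_lip, dtype=float)
    if lip.size > 2 and np.any(lip[2:] > 0):
        v.append("prob_n_glycans_lip: support is limited to {0, 1} glycans per lipid")

    if not cfg.mu_sias_glycoprot > 0:
        v.append(f"mu_sias_glycoprot: must be > 0, got {cfg.mu_sias_glycoprot!r}")
    if not cfg.mu_sias > 0:
        v.append(f"mu_sias: must be > 0, got {cfg.mu_sias!r}")
    if cfg.sigma_sias_glycoprot < 0:
        v.append(f"sigma_sias_glycoprot: must be >= 0, got {cfg.sigma_sias_glycoprot!r}")
    if cfg.sigma_sias < 0:
        v.append(f"sigma_sias: must be >= 0, got {cfg.sigma_sias!r}")
    if not cfg.cutoff_gaussians > 0:
        v.append(f"cutoff_gaussians: must be > 0, got {cfg.cutoff_gaussians!r}")
    if not (0 <= cfg.forbidden_angle_glycans < math.pi):
        v.append(
            "forbidden_angle_glycans: must lie in [0, pi), got "
            f"{cfg.forbidden_angle_glycans!r}"
        )

    if cfg.mode == "planar3d":
        if not cfg.scale_glycanheight > 0:
            v.append(f"scale_glycanheight: must be > 0, got {cfg.scale_glycanheight!r}")
        if not cfg.lower_glycanheight < cfg.upper_glycanheight:
            v.append(
                "lower_glycanheight/upper_glycanheight: lower must be < upper, got "
                f"{cfg.lower_glycanheight!r} >= {cfg.upper_glycanheight!r}"
            )
    if cfg.mode == "mucin3d":
        if cfg.mucin_lengths is None or len(cfg.mucin_lengths) == 0:
            v.append("mucin_lengths: mucin3d mode requires at least one backbone length")
        else:
            if any(L <= cfg.lower_glycanheight for L in cfg.mucin_lengths):
                v.append(
                    "mucin_lengths: every backbone length must exceed lower_glycanheight"
                )
            if cfg.mucin_n_glycans is not None and len(cfg.mucin_n_glycans) != len(
                cfg.mucin_lengths
            ):
                v.append("mucin_n_glycans: must match mucin_lengths in length")
            if cfg.mucin_n_glycans is not None and any(
                n < 0 for n in cfg.mucin_n_glycans
            ):
                v.append("mucin_n_glycans: counts must be >= 0")

    if cfg.anchor_count_model not in ("fixed", "poisson"):
        v.append(
            "anchor_count_model: must be 'fixed' or 'poisson', got "
            f"{cfg.anchor_count_model!r}"
        )
    return v


# ---------------------------------------------------------------------------
# analytic helper calculators
# ---------------------------------------------------------------------------

def lipid_density_from_radius(head_radius: float) -> float:
    """Areal density of hexagonally close-packed lipid heads, per square micron.

    Models lipid head groups as disks of radius ``head_radius`` (microns) in
    a plane at hexagonal close packing, giving ``1 / (2 * sqrt(3) * r**2)``
    lipids per unit area.  A 1 nm head radius yields ~2.9e5 per square micron.
    """
    if not head_radius > 0:
        raise ValueError(f"head_radius must be > 0, got {head_radius!r}")
    return 1.0 / (2.0 * math.sqrt(3.0) * head_radius**2)


def protein_density_from_ratio(lip_dens: float, lipids_per_protein: float) -> float:
    """Protein areal density from a lipid density and a lipids-per-protein ratio.

    Membrane protein-to-lipid number ratios of 1:50 to 1:100 are typical;
    ``lipids_per_protein=75`` with the close-packed lipid density gives
    ~3.8e3 proteins per square micron.
    """
    if not lip_dens > 0:
        raise ValueError(f"lip_dens must be > 0, got {lip_dens!r}")
    if not lipids_per_protein > 0:
        raise ValueError(f"lipids_per_protein must be > 0, got {lipids_per_protein!r}")
    return lip_dens / lipids_per_protein


def mucin_glycan_count(
    length: float, aa_size: float = 0.00036, glycosylation_fraction: float = 0.2
) -> int:
    """Number of glycans on a mucin backbone of the given contour length.

    The backbone is ``length / aa_size`` amino acids (default 0.36 nm per
    residue) of which ``glycosylation_fraction`` (default 20%, typical for
    the O-glycosylated tandem-repeat region of membrane mucins) carry a
    glycan; the product is rounded to the nearest integer.
    """
    if not length > 0:
        raise ValueError(f"length must be > 0, got {length!r}")
    if not aa_size > 0:
        raise ValueError(f"aa_size must be > 0, got {aa_size!r}")
    if not 0 < glycosylation_fraction <= 1:
        raise ValueError(
            f"glycosylation_fraction must be in (0, 1], got {glycosylation_fraction!r}"
        )
    return int(round(length / aa_size * glycosylation_fraction))


# ---------------------------------------------------------------------------
# file IO — flat "key: value" document with the legacy variable names
# ---------------------------------------------------------------------------

#: file key -> dataclass field (keys not listed map to the same name)
_LEGACY_TO_FIELD = {
    "FOV_x": "fov_x",
    "FOV_y": "fov_y",
    "prob_x_glycoprots": "prob_n_glycans_prot",
    "prob_x_glycolips": "prob_n_glycans_lip",
    "prob_x_sias_prots": "prob_n_sias_prot_glycan",
    "prob_x_sias_lips": "prob_n_sias_lip_glycan",
    "sigma_sias_glycoprots": "sigma_sias_glycoprot",
}
_FIELD_TO_LEGACY = {f: k for k, f in _LEGACY_TO_FIELD.items()}

#: canonical key order in written files
FILE_KEYS = (
    "global_name",
    "path",
    "variables_path",
    "mode",
    "FOV_x",
    "FOV_y",
    "prot_dens",
    "lip_dens",
    "prob_x_glycoprots",
    "prob_x_glycolips",
    "prob_x_sias_prots",
    "prob_x_sias_lips",
    "mu_sias_glycoprot",
    "sigma_sias_glycoprots",
    "mu_sias",
    "sigma_sias",
    "forbidden_angle_glycans",
    "cutoff_gaussians",
    "mu_glycanheight",
    "alpha_glycanheight",
    "scale_glycanheight",
    "lower_glycanheight",
    "upper_glycanheight",
    "seed",
    "anchor_count_model",
    "mucin_lengths",
    "mucin_n_glycans",
)

_FIELD_NAMES = {f.name for f in dataclasses.fields(SimulationConfig)}


def _field_for_key(key: str) -> str:
    fname = _LEGACY_TO_FIELD.get(key, key)
    if fname not in _FIELD_NAMES:
        raise KeyError(
            f"unknown configuration key {key!r}; valid keys: {', '.join(FILE_KEYS)}"
        )
    return fname


def format_value(value) -> str:
    """Render a field value for the flat config file (floats via repr, so the
    text round-trips bit-exactly)."""
    if value is None:
        return "none"
    if isinstance(value, bool):
        raise TypeError("boolean config values are not used")
    if isinstance(value, (list, tuple, np.ndarray)):
        return "[" + ", ".join(format_value(x) for x in value) + "]"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    return str(value)


def parse_value(text: str):
    text = text.strip()
    if text == "":
        return ""
    if text.lower() in ("none", "null"):
        return None
    if text.startswith("["):
        return json.loads(text)
    for caster in (int, float):
        try:
            return caster(text)
        except ValueError:
            pass
    return text.strip("\"'")


def config_to_text(cfg: SimulationConfig) -> str:
    lines = []
    for key in FILE_KEYS:
        value = getattr(cfg, _field_for_key(key))
        lines.append(f"{key}: {format_value(value)}")
    return "\n".join(lines) + "\n"


def write_config(cfg: SimulationConfig, path: str | Path) -> Path:
    """Write the configuration as a flat key–value document."""
    path = Path(path)
    path.write_text(config_to_text(cfg))
    return path


def read_config(path: str | Path) -> SimulationConfig:
    """Read a flat key–value configuration document.

    Both the legacy file keys (``FOV_x``, ``prob_x_glycoprots``, ...) and the
    in-memory field names are accepted; unknown keys raise ``KeyError``.
    """
    fields: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key: value', got {raw!r}")
        key, _, rest = line.partition(":")
        fname = _field_for_key(key.strip())
        value = parse_value(rest)
        if fname == "seed" and value is not None:
            value = int(value)
        if fname == "mucin_n_glycans" and value is not None:
            value = [int(x) for x in value]
        fields[fname] = value
    return SimulationConfig(**fields)
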