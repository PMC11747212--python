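"""Generation of anchor positions and sialic-acid coordinates.

Three model variants share the same machinery:

* ``planar2d`` — anchors in the FOV plane, sialic acids in the same plane;
* ``planar3d`` — protein centers lifted above the membrane by a truncated
  skew-normal height, glycolipids in the membrane plane (z = 0), all
  protein-derived sialic acids on the upper hemisphere of their center;
* ``mucin3d`` — rod-like, heavily O-glycosylated proteins: glycan anchors
  stacked at uniformly random heights along a vertical backbone, with no
  steric exclusion between glycans (they sit at different heights anyway).

Geometry of one glycoprotein glycan: every sialic acid of a glycan lies on
the same radial shell of radius ``d`` about the protein center (the sugar
sequence preceding the terminal sialic acids is usually shared, so their
anchor distance is), where ``d`` follows the truncated Gaussian
(mu_sias_glycoprot, sigma_sias_glycoprot).  Consecutive sialic acids of the
chain are a chord ``s`` apart with ``s`` from the truncated Gaussian
(mu_sias, sigma_sias); on the shell this is an angular step of
``2*arcsin(s/(2d))``.  The first sialic acid of each glycan must avoid the
forbidden sector/cone (half-angle ``forbidden_angle_glycans``) around every
previously placed glycan of the same protein; later chain members are not
re-checked, reproducing the known approximation of the original model.

Glycolipid sialic acids coincide exactly with their lipid center (a
glycolipid carries at most one glycan with few sialic acids, all placed at
the anchor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import ConfigError, SimulationConfig, mucin_glycan_count, validate_config
from .geometry import (
    DEFAULT_MAX_ATTEMPTS,
    DirectionConstraint,
    SamplingBudgetError,
    TruncatedDistanceModel,
    TruncatedSkewNormalModel,
    sample_allowed_direction,
    sample_direction,
    sample_truncated_gaussian,
    sample_truncated_skew_normal,
)

__all__ = [
    "AnchorSet",
    "SiaCloud",
    "place_anchors",
    "simulate_protein_sias",
    "simulate_lipid_sias",
    "simulate_mucin_sias",
    "run_simulation",
    "ChainInfeasibleError",
    "KIND_PROTEIN",
    "KIND_LIPID",
]

KIND_PROTEIN = "protein"
KIND_LIPID = "lipid"


class ChainInfeasibleError(SamplingBudgetError):
    """Requested sia–sia chord repeatedly exceeded the shell diameter."""


@dataclass
class AnchorSet:
    """Positions of glycoprotein and glycolipid centers within the FOV."""

    protein_centers: np.ndarray  # (n_prot, dim)
    lipid_centers: np.ndarray  # (n_lip, dim)
    fov: tuple[float, float]

    @property
    def dimension(self) -> int:
        return self.protein_centers.shape[1]


@dataclass
class SiaCloud:
    """Sialic-acid coordinates plus per-point provenance.

    Provenance records which anchor produced each point (``anchor_kind`` in
    {"protein", "lipid"}, ``anchor_id`` indexing into the corresponding
    center array), which glycan of that anchor (``glycan_id``) and the
    position within the glycan's chain (``sia_index``).  Experimental data
    would not carry this information; it is retained for validation and can
    simply be ignored downstream.
    """

    positions: np.ndarray  # (n, dim) microns
    anchor_kind: np.ndarray  # (n,) str
    anchor_id: np.ndarray  # (n,) int
    glycan_id: np.ndarray  # (n,) int
    sia_index: np.ndarray  # (n,) int

    def __post_init__(self):
        n = len(self.positions)
        for name in ("anchor_kind", "anchor_id", "glycan_id", "sia_index"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match positions")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def dimension(self) -> int:
        return self.positions.shape[1]

    @classmethod
    def empty(cls, dimension: int) -> "SiaCloud":
        return cls(
            positions=np.empty((0, dimension)),
            anchor_kind=np.empty(0, dtype="<U7"),
            anchor_id=np.empty(0, dtype=np.int64),
            glycan_id=np.empty(0, dtype=np.int64),
            sia_index=np.empty(0, dtype=np.int64),
        )

    def subset(self, indices: np.ndarray) -> "SiaCloud":
        indices = np.asarray(indices)
        return SiaCloud(
            positions=self.positions[indices],
            anchor_kind=self.anchor_kind[indices],
            anchor_id=self.anchor_id[indices],
            glycan_id=self.glycan_id[indices],
            sia_index=self.sia_index[indices],
        )

    @classmethod
    def concatenate(cls, clouds: list["SiaCloud"], dimension: int) -> "SiaCloud":
        clouds = [c for c in clouds if len(c) > 0]
        if not clouds:
            return cls.empty(dimension)
        return cls(
            positions=np.concatenate([c.positions for c in clouds]),
            anchor_kind=np.concatenate([c.anchor_kind for c in clouds]),
            anchor_id=np.concatenate([c.anchor_id for c in clouds]),
            glycan_id=np.concatenate([c.glycan_id for c in clouds]),
            sia_index=np.concatenate([c.sia_index for c in clouds]),
        )

    def to_dataframe(self):
        import pandas as pd

        cols = {"x": self.positions[:, 0], "y": self.positions[:, 1]}
        if self.dimension == 3:
            cols["z"] = self.positions[:, 2]
        cols.update(
            anchor_kind=self.anchor_kind,
            anchor_id=self.anchor_id,
            glycan_id=self.glycan_id,
            sia_index=self.sia_index,
        )
        return pd.DataFrame(cols)


def _anchor_count(density: float, area: float, model: str, rng) -> int:
    mean = density * area
    if model == "poisson":
        return int(rng.poisson(mean))
    return int(round(mean))


def place_anchors(cfg: SimulationConfig, rng: np.random.Generator) -> AnchorSet:
    """Place protein and lipid centers uniformly in the FOV.

    Counts are deterministic ``round(density * area)`` by default (a Poisson
    option is available via ``anchor_count_model``).  In ``planar3d`` mode
    protein z-heights follow the truncated skew-normal law and lipids sit in
    the membrane plane (z = 0); in ``mucin3d`` mode backbones start at z = 0.
    """
    area = cfg.fov_x * cfg.fov_y
    n_prot = _anchor_count(cfg.prot_dens, area, cfg.anchor_count_model, rng)
    n_lip = _anchor_count(cfg.lip_dens, area, cfg.anchor_count_model, rng)
    dim = cfg.dimension

    prot = np.empty((n_prot, dim))
    prot[:, 0] = rng.uniform(0.0, cfg.fov_x, n_prot)
    prot[:, 1] = rng.uniform(0.0, cfg.fov_y, n_prot)
    if dim == 3:
        if cfg.mode == "planar3d":
            height_model = TruncatedSkewNormalModel(
                location=cfg.mu_glycanheight,
                shape=cfg.alpha_glycanheight,
                scale=cfg.scale_glycanheight,
                lower=cfg.lower_glycanheight,
                upper=cfg.upper_glycanheight,
            )
            prot[:, 2] = (
                sample_truncated_skew_normal(height_model, rng, size=n_prot)
                if n_prot
                else 0.0
            )
        else:  # mucin backbones rise from the membrane plane
            prot[:, 2] = 0.0

    lip = np.empty((n_lip, dim))
    lip[:, 0] = rng.uniform(0.0, cfg.fov_x, n_lip)
    lip[:, 1] = rng.uniform(0.0, cfg.fov_y, n_lip)
    if dim == 3:
        lip[:, 2] = 0.0

    return AnchorSet(protein_centers=prot, lipid_centers=lip, fov=(cfg.fov_x, cfg.fov_y))


class _CategoricalCdf:
    """Cheap categorical draws via searchsorted on the cumulative probabilities."""

    __slots__ = ("cdf",)

    def __init__(self, probs):
        self.cdf = np.cumsum(np.asarray(probs, dtype=float))

    def draw(self, rng) -> int:
        return int(np.searchsorted(self.cdf, rng.random(), side="right"))

    def draw_many(self, rng, n: int) -> np.ndarray:
        return np.searchsorted(self.cdf, rng.random(n), side="right")


class _GlycanChainSampler:
    """Shared machinery for placing one anchor's glycan chains.

    Precomputes the categorical CDFs and distance models once per simulation
    so the per-anchor hot loop stays cheap.
    """

    def __init__(self, cfg: SimulationConfig, max_attempts: int = DEFAULT_MAX_ATTEMPTS):
        self.dim = cfg.dimension
        self.hemisphere = self.dim == 3
        self.half_angle = cfg.forbidden_angle_glycans
        self.n_glycans_cdf = _CategoricalCdf(cfg.prob_n_glycans_prot)
        self.n_sias_cdf = _CategoricalCdf(cfg.prob_n_sias_prot_glycan)
        self.radial = TruncatedDistanceModel(
            cfg.mu_sias_glycoprot, cfg.sigma_sias_glycoprot, cfg.cutoff_gaussians
        )
        self.chord = TruncatedDistanceModel(
            cfg.mu_sias, cfg.sigma_sias, cfg.cutoff_gaussians
        )
        self.max_attempts = max_attempts

    # -- chain construction -------------------------------------------------

    def _draw_chord(self, shell_radius: float, rng) -> float:
        """A sia–sia chord that fits on the shell (s <= 2d), by resampling."""
        limit = 2.0 * shell_radius
        for _ in range(self.max_attempts):
            s = sample_truncated_gaussian(self.chord, rng, max_attempts=self.max_attempts)
            if s <= limit:
                return s
        raise ChainInfeasibleError(
            f"sia–sia distance law (mu={self.chord.mu}) repeatedly exceeded the "
            f"shell diameter {limit:.4g}; chain cannot be placed"
        )

    def _chain_2d(self, center, d: float, first_dir, m: int, rng) -> np.ndarray:
        angles = np.empty(m)
        angles[0] = math.atan2(first_dir[1], first_dir[0])
        for j in range(1, m):
            s = self._draw_chord(d, rng)
            step = 2.0 * math.asin(min(1.0, s / (2.0 * d)))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            angles[j] = angles[j - 1] + sign * step
        pts = np.empty((m, 2))
        pts[:, 0] = center[0] + d * np.cos(angles)
        pts[:, 1] = center[1] + d * np.sin(angles)
        return pts

    def _chain_3d(self, center, d: float, first_dir, m: int, rng) -> np.ndarray:
        dirs = np.empty((m, 3))
        dirs[0] = first_dir
        for j in range(1, m):
            s = self._draw_chord(d, rng)
            phi = 2.0 * math.asin(min(1.0, s / (2.0 * d)))
            cos_phi, sin_phi = math.cos(phi), math.sin(phi)
            u = dirs[j - 1]
            # rotate along a uniformly chosen great circle; keep the upper
            # hemisphere (membrane below), budgeted rejection on the tangent
            for _ in range(self.max_attempts):
                t = rng.standard_normal(3)
                t -= (t @ u) * u
                norm = np.linalg.norm(t)
                if norm < 1e-12:
                    continue
                cand = cos_phi * u + (sin_phi / norm) * t
                if not self.hemisphere or cand[2] >= 0.0:
                    dirs[j] = cand
                    break
            else:
                raise ChainInfeasibleError(
                    f"no upper-hemisphere chain step of angle {phi:.3f} rad found "
                    f"in {self.max_attempts} attempts"
                )
        return np.asarray(center) + d * dirs

    def place_glycan(self, center, constraint: DirectionConstraint, m: int, rng):
        """Place one glycan of ``m`` sialic acids; returns (points, first_dir)."""
        d = sample_truncated_gaussian(self.radial, rng, max_attempts=self.max_attempts)
        first_dir = sample_allowed_direction(
            self.dim, self.hemisphere, constraint, rng, max_attempts=self.max_attempts
        )
        if self.dim == 2:
            pts = self._chain_2d(center, d, first_dir, m, rng)
        else:
            pts = self._chain_3d(center, d, first_dir, m, rng)
        return pts, first_dir

    def sample_protein(self, center, rng):
        """All sialic acids of one glycoprotein.

        Returns ``(positions, glycan_ids, sia_indices)``; arrays are empty
        when the protein draws zero glycans or all its glycans are sia-free.
        """
        n_glycans = self.n_glycans_cdf.draw(rng)
        if n_glycans == 0:
            return (np.empty((0, self.dim)), _EMPTY_INT, _EMPTY_INT)
        blocked: list[np.ndarray] = []
        chunks = []
        glycan_ids = []
        for g in range(n_glycans):
            m = self.n_sias_cdf.draw(rng)
            if m == 0:
                # a sia-free glycan leaves no placed sialic acid to block around
                continue
            constraint = DirectionConstraint(
                blocked_directions=np.array(blocked)
                if blocked
                else np.empty((0, self.dim)),
                half_angle=self.half_angle,
            )
            pts, first_dir = self.place_glycan(center, constraint, m, rng)
            blocked.append(first_dir)
            chunks.append(pts)
            glycan_ids.append(np.full(m, g, dtype=np.int64))
        if not chunks:
            return (np.empty((0, self.dim)), _EMPTY_INT, _EMPTY_INT)
        positions = np.concatenate(chunks)
        gly = np.concatenate(glycan_ids)
        sia_idx = np.concatenate([np.arange(len(c), dtype=np.int64) for c in chunks])
        return positions, gly, sia_idx

    def sample_mucin(self, center_xy, n_glycans: int, lower: float, upper: float, rng):
        """All sialic acids of one mucin backbone at (x, y).

        Glycan anchors sit at uniform heights in [lower, upper]; no steric
        exclusion between glycans (they occupy different heights), so the
        forbidden half-angle is 0 regardless of the configured value.
        """
        no_constraint = DirectionConstraint(
            blocked_directions=np.empty((0, 3)), half_angle=0.0
        )
        chunks = []
        glycan_ids = []
        for g in range(n_glycans):
            m = self.n_sias_cdf.draw(rng)
            h = rng.uniform(lower, upper)
            if m == 0:
                continue
            anchor = np.array([center_xy[0], center_xy[1], h])
            pts, _ = self.place_glycan(anchor, no_constraint, m, rng)
            chunks.append(pts)
            glycan_ids.append(np.full(m, g, dtype=np.int64))
        if not chunks:
            return (np.empty((0, 3)), _EMPTY_INT, _EMPTY_INT)
        positions = np.concatenate(chunks)
        gly = np.concatenate(glycan_ids)
        sia_idx = np.concatenate([np.arange(len(c), dtype=np.int64) for c in chunks])
        return positions, gly, sia_idx


_EMPTY_INT = np.empty(0, dtype=np.int64)


def simulate_protein_sias(center, cfg: SimulationConfig, rng: np.random.Generator):
    """Sialic acids of a single glycoprotein centered at ``center``.

    Returns ``(positions, glycan_ids, sia_indices)``.  See the module
    docstring for the placement geometry.
    """
    sampler = _GlycanChainSampler(cfg)
    return sampler.sample_protein(np.asarray(center, dtype=float), rng)


def simulate_lipid_sias(center, cfg: SimulationConfig, rng: np.random.Generator):
    """Sialic acids of a single glycolipid: all coincide with the lipid center.

    With probability ``prob_n_glycans_lip[1]`` the lipid carries one glycan
    whose sialic-acid count follows ``prob_n_sias_lip_glycan``; every sialic
    acid is placed exactly at the anchor position.
    """
    probs = np.asarray(cfg.prob_n_glycans_lip, dtype=float)
    p_glycan = float(probs[1]) if probs.size > 1 else 0.0
    center = np.asarray(center, dtype=float)
    if rng.random() >= p_glycan:
        return np.empty((0, center.size))
    k = _CategoricalCdf(cfg.prob_n_sias_lip_glycan).draw(rng)
    return np.tile(center, (k, 1))


def simulate_mucin_sias(
    center_xy,
    cfg: SimulationConfig,
    n_glycans: int,
    rng: np.random.Generator,
    upper: float | None = None,
):
    """Sialic acids of one mucin backbone at planar position ``center_xy``.

    ``upper`` overrides the backbone length (defaults to
    ``cfg.upper_glycanheight``); glycan heights are uniform on
    [``cfg.lower_glycanheight``, upper].  Returns
    ``(positions, glycan_ids, sia_indices)``.
    """
    if n_glycans < 0:
        raise ValueError(f"n_glycans must be >= 0, got {n_glycans!r}")
    hi = cfg.upper_glycanheight if upper is None else upper
    if not cfg.lower_glycanheight < hi:
        raise ValueError(
            f"lower_glycanheight {cfg.lower_glycanheight!r} must be < upper bound {hi!r}"
        )
    sampler = _GlycanChainSampler(cfg)
    return sampler.sample_mucin(
        np.asarray(center_xy, dtype=float), n_glycans, cfg.lower_glycanheight, hi, rng
    )


def _simulate_all_lipids(centers: np.ndarray, cfg: SimulationConfig, rng) -> SiaCloud:
    """Vectorized glycolipid pass: sialic acids coincide with their centers."""
    n_lip, dim = centers.shape
    probs = np.asarray(cfg.prob_n_glycans_lip, dtype=float)
    p_glycan = float(probs[1]) if probs.size > 1 else 0.0
    counts = np.zeros(n_lip, dtype=np.int64)
    if p_glycan > 0 and n_lip > 0:
        has_glycan = rng.random(n_lip) < p_glycan
        idx = np.flatnonzero(has_glycan)
        counts[idx] = _CategoricalCdf(cfg.prob_n_sias_lip_glycan).draw_many(
            rng, idx.size
        )
    total = int(counts.sum())
    if total == 0:
        return SiaCloud.empty(dim)
    anchor_id = np.repeat(np.arange(n_lip, dtype=np.int64), counts)
    positions = centers[anchor_id]
    # within-anchor running index: 0..k-1 for each lipid's k sialic acids
    ends = np.cumsum(counts)
    sia_index = np.arange(total, dtype=np.int64) - np.repeat(ends - counts, counts)
    return SiaCloud(
        positions=positions,
        anchor_kind=np.full(total, KIND_LIPID, dtype="<U7"),
        anchor_id=anchor_id,
        glycan_id=np.zeros(total, dtype=np.int64),
        sia_index=sia_index,
    )


def _mucin_plan(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.asarray(cfg.mucin_lengths, dtype=float)
    if cfg.mucin_n_glycans is not None:
        counts = np.asarray(cfg.mucin_n_glycans, dtype=np.int64)
    else:
        counts = np.array([mucin_glycan_count(L) for L in lengths], dtype=np.int64)
    return lengths, counts


def run_simulation(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> SiaCloud:
    """Run one full simulation: place anchors, generate every sialic acid.

    Deterministic given ``(cfg, seed)``: when ``rng`` is omitted it is
    created from ``cfg.seed``.  Proteins are processed before lipids, in
    anchor order.  Raises :class:`~glycosim.config.ConfigError` on an
    invalid configuration; placement failures are re-raised with the
    offending anchor identified.
    """
    violations = validate_config(cfg)
    if violations:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(violations))
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    anchors = place_anchors(cfg, rng)
    dim = cfg.dimension
    sampler = _GlycanChainSampler(cfg)

    pos_chunks: list[np.ndarray] = []
    gly_chunks: list[np.ndarray] = []
    sia_chunks: list[np.ndarray] = []
    anchor_ids: list[np.ndarray] = []

    if cfg.mode == "mucin3d":
        lengths, counts = _mucin_plan(cfg)
        n_types = len(lengths)
        for i, center in enumerate(anchors.protein_centers):
            t = int(rng.integers(n_types)) if n_types > 1 else 0
            try:
                pos, gly, sia = sampler.sample_mucin(
                    center[:2], int(counts[t]), cfg.lower_glycanheight, float(lengths[t]), rng
                )
            except SamplingBudgetError as exc:
                raise type(exc)(f"mucin anchor {i}: {exc}") from exc
            if len(pos):
                pos_chunks.append(pos)
                gly_chunks.append(gly)
                sia_chunks.append(sia)
                anchor_ids.append(np.full(len(pos), i, dtype=np.int64))
    else:
        for i, center in enumerate(anchors.protein_centers):
            try:
                pos, gly, sia = sampler.sample_protein(center, rng)
            except SamplingBudgetError as exc:
                raise type(exc)(f"protein anchor {i}: {exc}") from exc
            if len(pos):
                pos_chunks.append(pos)
                gly_chunks.append(gly)
                sia_chunks.append(sia)
                anchor_ids.append(np.full(len(pos), i, dtype=np.int64))

    if pos_chunks:
        n_prot_sias = sum(len(p) for p in pos_chunks)
        protein_cloud = SiaCloud(
            positions=np.concatenate(pos_chunks),
            anchor_kind=np.full(n_prot_sias, KIND_PROTEIN, dtype="<U7"),
            anchor_id=np.concatenate(anchor_ids),
            glycan_id=np.concatenate(gly_chunks),
            sia_index=np.concatenate(sia_chunks),
        )
    else:
        protein_cloud = SiaCloud.empty(dim)

    lipid_cloud = _simulate_all_lipids(anchors.lipid_centers, cfg, rng)
    return SiaCloud.concatenate([protein_cloud, lipid_cloud], dim)
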