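"""Labeling / detection efficiency as random thinning of a coordinate cloud.

In fluorescence microscopy only targets carrying a label are observed, and
labeling efficiencies well below 100% are the norm.  Here labeling and
detection efficiency are collapsed into a single retention fraction; a
thinned cloud is a uniformly random subset of the simulated sialic acids.

The default thinning keeps exactly ``round(efficiency * N)`` points (drawn
without replacement), so replicate sizes are reproducible; per-point
Bernoulli thinning is available via ``method="bernoulli"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulator import SiaCloud

__all__ = ["ThinningPlan", "thin_cloud", "run_thinning_plan"]


@dataclass(frozen=True)
class ThinningPlan:
    """Which labeling efficiencies to emulate and how often to resample each."""

    efficiencies: tuple[float, ...] = (1.0,)
    replicates_per_efficiency: int = 1
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "efficiencies", tuple(self.efficiencies))
        for e in self.efficiencies:
            if not 0 < e <= 1:
                raise ValueError(f"efficiency must be in (0, 1], got {e!r}")
        if self.replicates_per_efficiency < 1:
            raise ValueError(
                f"replicates_per_efficiency must be >= 1, "
                f"got {self.replicates_per_efficiency!r}"
            )


def thin_cloud(
    cloud: SiaCloud,
    efficiency: float,
    rng: np.random.Generator,
    method: str = "exact",
) -> SiaCloud:
    """Random subset of the cloud emulating the given labeling efficiency.

    ``method="exact"`` keeps exactly ``round(efficiency * N)`` points without
    replacement; ``method="bernoulli"`` keeps each point independently with
    probability ``efficiency``.  Provenance is preserved; the original point
    order is kept (indices are sorted).
    """
    if not 0 < efficiency <= 1:
        raise ValueError(f"efficiency must be in (0, 1], got {efficiency!r}")
    n = len(cloud)
    if method == "exact":
        keep = int(round(efficiency * n))
        idx = np.sort(rng.choice(n, size=keep, replace=False)) if n else np.arange(0)
    elif method == "bernoulli":
        idx = np.flatnonzero(rng.random(n) < efficiency)
    else:
        raise ValueError(f"method must be 'exact' or 'bernoulli', got {method!r}")
    return cloud.subset(idx)


def run_thinning_plan(
    cloud: SiaCloud, plan: ThinningPlan, method: str = "exact"
) -> list[tuple[float, int, SiaCloud]]:
    """Apply every (efficiency, replicate) combination of the plan.

    Returns ``len(efficiencies) * replicates`` entries of
    ``(efficiency, replicate_index, thinned_cloud)``, deterministic for a
    given ``plan.seed`` (each combination gets an independent child stream).
    """
    ss = np.random.SeedSequence(plan.seed)
    children = ss.spawn(len(plan.efficiencies) * plan.replicates_per_efficiency)
    out = []
    i = 0
    for eff in plan.efficiencies:
        for rep in range(plan.replicates_per_efficiency):
            rng = np.random.default_rng(children[i])
            out.append((eff, rep, thin_cloud(cloud, eff, rng, method=method)))
            i += 1
    return out
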