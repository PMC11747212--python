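"""Persistence, batch orchestration and plotting.

Coordinate and analysis files are plain CSV (header row, '.' decimal
separator); coordinates are written with 9 decimal digits (sub-picometer at
micron scale), which is also the precision guaranteed by the write/read
round trip.  A copy of the configuration is saved beside every run so any
simulation can be reconstructed from its output directory alone.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import knn_distances, summarize_by_condition
from .config import (
    FILE_KEYS,
    SimulationConfig,
    ConfigError,
    config_to_text,
    format_value,
    validate_config,
    write_config,
)
from .detection import ThinningPlan, run_thinning_plan
from .simulator import SiaCloud, run_simulation

__all__ = [
    "RunManifest",
    "save_coordinates",
    "read_coordinates",
    "run_routine",
    "change_variable",
    "plot_cloud",
]

FLOAT_FORMAT = "%.9f"


@dataclass
class RunManifest:
    """Record of one batch run: what was simulated and where it was written."""

    global_name: str
    seed: int | None
    config_file: Path
    coordinate_files: list[Path] = field(default_factory=list)
    analysis_files: list[Path] = field(default_factory=list)
    summary_files: list[Path] = field(default_factory=list)
    plot_files: list[Path] = field(default_factory=list)
    started: str = ""
    finished: str = ""


def save_coordinates(cloud: SiaCloud, path: str | Path) -> Path:
    """Write a cloud as CSV: x, y[, z] (microns) plus provenance columns."""
    path = Path(path)
    df = cloud.to_dataframe()
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_coordinates(path: str | Path) -> SiaCloud:
    """Read a cloud written by :func:`save_coordinates` (lossless to 1e-9 µm)."""
    df = pd.read_csv(path)
    dim = 3 if "z" in df.columns else 2
    if len(df) == 0:
        return SiaCloud.empty(dim)
    cols = ["x", "y", "z"][:dim]
    return SiaCloud(
        positions=df[cols].to_numpy(dtype=float),
        anchor_kind=df["anchor_kind"].to_numpy(dtype="<U7"),
        anchor_id=df["anchor_id"].to_numpy(dtype=np.int64),
        glycan_id=df["glycan_id"].to_numpy(dtype=np.int64),
        sia_index=df["sia_index"].to_numpy(dtype=np.int64),
    )


def plot_cloud(cloud: SiaCloud, path: str | Path) -> Path:
    """xy scatter of the cloud; 3D clouds are colored by height (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 6))
    if len(cloud) > 0:
        if cloud.dimension == 3:
            sc = ax.scatter(
                cloud.positions[:, 0],
                cloud.positions[:, 1],
                c=cloud.positions[:, 2],
                s=4,
                cmap="viridis",
            )
            fig.colorbar(sc, ax=ax, label="z (µm)")
        else:
            ax.scatter(cloud.positions[:, 0], cloud.positions[:, 1], s=4)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_aspect("equal")
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def change_variable(config_path: str | Path, key: str, value) -> Path:
    """Update one key of a config file in place, leaving other lines untouched.

    ``key`` must be one of the documented file keys; unknown keys raise
    ``KeyError`` listing the valid ones.  A valid key not yet present in the
    file is appended.
    """
    if key not in FILE_KEYS:
        raise KeyError(
            f"unknown configuration key {key!r}; valid keys: {', '.join(FILE_KEYS)}"
        )
    config_path = Path(config_path)
    lines = config_path.read_text().splitlines(keepends=True)
    new_line = f"{key}: {format_value(value)}\n"
    replaced = False
    for i, line in enumerate(lines):
        stripped = line.strip()
        if stripped.startswith("#"):
            continue
        if stripped.partition(":")[0].strip() == key:
            lines[i] = new_line
            replaced = True
            break
    if not replaced:
        if lines and not lines[-1].endswith("\n"):
            lines[-1] += "\n"
        lines.append(new_line)
    config_path.write_text("".join(lines))
    return config_path


def _now() -> str:
    return datetime.datetime.now().isoformat(timespec="seconds")


def run_routine(
    cfg: SimulationConfig,
    repeats: int = 1,
    plan: ThinningPlan | None = None,
    k: int = 1,
    save_coords: bool = True,
    save_analysis: bool = True,
    plot: bool = False,
    out_dir: str | Path | None = None,
) -> RunManifest:
    """Run ``repeats`` independent simulations with optional thinning, k-NN
    analysis, persistence and plotting.

    Per-repeat random streams are spawned from ``cfg.seed`` with a
    counter-based seed sequence, so repeats are mutually independent yet the
    whole batch is reproducible (identical invocations give byte-identical
    files).  The configuration snapshot is always written beside the
    outputs.  Analysis runs only when ``plan`` is given; distances are then
    computed per (efficiency, replicate) and summarized per efficiency.
    """
    if repeats < 1:
        raise ValueError(f"repeats must be >= 1, got {repeats!r}")
    violations = validate_config(cfg)
    if violations:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(violations))

    out = Path(out_dir) if out_dir is not None else Path(cfg.path)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    manifest = RunManifest(
        global_name=cfg.global_name,
        seed=cfg.seed,
        config_file=out / f"{cfg.global_name}_variables.txt",
        started=_now(),
    )
    write_config(cfg, manifest.config_file)

    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(repeats)
    for r in range(repeats):
        rng = np.random.default_rng(children[r])
        cloud = run_simulation(cfg, rng)
        stem = f"{cfg.global_name}_rep{r}"
        if save_coords:
            manifest.coordinate_files.append(
                save_coordinates(cloud, out / f"{stem}_coords.csv")
            )
        if plot:
            manifest.plot_files.append(plot_cloud(cloud, out / f"{stem}_coords.png"))
        if plan is not None:
            records = []
            labeled = []
            for eff, rep, thinned in run_thinning_plan(cloud, plan):
                dist = knn_distances(thinned, k=k)
                labeled.append((eff, dist))
                records.append(
                    pd.DataFrame(
                        {
                            "efficiency": eff,
                            "replicate": rep,
                            "k": k,
                            "distance": dist.distances,
                        }
                    )
                )
            if save_analysis:
                analysis_path = out / f"{stem}_analysis.csv"
                pd.concat(records, ignore_index=True).to_csv(
                    analysis_path, index=False, float_format=FLOAT_FORMAT
                )
                manifest.analysis_files.append(analysis_path)
                summary_path = out / f"{stem}_analysis_summary.csv"
                summarize_by_condition(labeled).to_csv(
                    summary_path, index=False, float_format=FLOAT_FORMAT
                )
                manifest.summary_files.append(summary_path)
    manifest.finished = _now()
    return manifest
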