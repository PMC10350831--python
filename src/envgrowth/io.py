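"""Dataset reading/writing and provenance records.

CSV schemas use explicit unit-suffixed column names (``t_min``, ``x_um``,
``mass_pg``) to prevent unit drift; every run directory carries a
machine-readable ``provenance.json`` with the resolved configuration, seed
and package version.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .kinetics import CellTrajectory

TRAJECTORY_COLUMNS = [
    "cell_id",
    "t_min",
    "length_um",
    "width_um",
    "surface_um2",
    "volume_um3",
    "mass_pg",
]
SPOT_COLUMNS = ["frame", "t_s", "x_um", "y_um"]


def write_provenance(directory: Path, config: dict, seed: int) -> Path:
    """Write the provenance record next to a run's outputs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / "provenance.json"
    record = {"package": "envgrowth", "version": __version__, "seed": seed,
              "config": config}
    path.write_text(json.dumps(record, indent=2, default=str))
    return path


def write_trajectories(cells: list[CellTrajectory], path: Path) -> None:
    """One row per cell per frame; empty input writes headers only."""
    frames = [c.to_frame() for c in cells]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    )
    df.to_csv(path, index=False)


def read_trajectories(path: Path, events: dict | None = None) -> list[CellTrajectory]:
    """Rebuild :class:`CellTrajectory` objects from a trajectory CSV.

    ``events`` maps ``str(cell_id)`` to a dict with optional
    ``drug_add_time / mreb_stop_time / lysis_time`` entries.
    """
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    events = events or {}
    cells = []
    for cid, grp in df.groupby("cell_id"):
        grp = grp.sort_values("t_min")
        ev = events.get(str(int(cid)), {})
        cells.append(
            CellTrajectory(
                times_min=grp["t_min"].to_numpy(),
                mass_pg=grp["mass_pg"].to_numpy(),
                surface_um2=grp["surface_um2"].to_numpy(),
                volume_um3=grp["volume_um3"].to_numpy(),
                length_um=grp["length_um"].to_numpy(),
                width_um=grp["width_um"].to_numpy(),
                cell_id=int(cid),
                drug_add_time=ev.get("drug_add_time"),
                mreb_stop_time=ev.get("mreb_stop_time"),
                lysis_time=ev.get("lysis_time"),
            )
        )
    return cells


def write_spots(spots: pd.DataFrame, path: Path) -> None:
    cols = SPOT_COLUMNS + (["track_id"] if "track_id" in spots.columns else [])
    spots[cols].to_csv(path, index=False)


def read_spots(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SPOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_stacks(phase: np.ndarray, masks: np.ndarray, directory: Path, cell_id: int) -> None:
    """Multi-page TIFF stacks: 32-bit float phase, 8-bit masks."""
    import tifffile

    directory = Path(directory)
    tifffile.imwrite(
        directory / f"phase_cell{cell_id:03d}.tif",
        phase.astype(np.float32),
        photometric="minisblack",
    )
    tifffile.imwrite(
        directory / f"masks_cell{cell_id:03d}.tif",
        masks.astype(np.uint8),
        photometric="minisblack",
    )
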