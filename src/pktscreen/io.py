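"""Readers and writers for the toolkit's on-disk formats.

Feature tables and trajectories are plain CSV; plate layouts are YAML;
images and label masks are 16-bit TIFF (via tifffile).
"""

from __future__ import annotations

from pathlib import Path
import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import FEATURE_COLUMNS, PlateLayout, Treatment

__all__ = [
    "read_features", "write_features", "read_layout", "write_layout",
    "read_stack", "write_stack", "write_label_mask",
    "write_trajectories", "read_trajectories",
]


def write_features(features: pd.DataFrame, path) -> None:
    features[FEATURE_COLUMNS].to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table {path} is missing columns {sorted(missing)}")
    return df[FEATURE_COLUMNS]


def write_layout(layout: PlateLayout, path) -> None:
    doc = {
        "plate_id": layout.plate_id,
        "cell_line": layout.cell_line,
        "replicate": {"technical": layout.replicate[0],
                      "biological": layout.replicate[1]},
        "wells": {w: {"name": t.name, "kind": t.kind}
                  for w, t in sorted(layout.wells.items())},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_layout(path) -> PlateLayout:
    doc = yaml.safe_load(Path(path).read_text())
    wells = {w: Treatment(d["name"], d.get("kind", "smartpool"))
             for w, d in doc["wells"].items()}
    rep = doc.get("replicate", {})
    return PlateLayout(
        plate_id=doc["plate_id"], wells=wells,
        replicate=(int(rep.get("technical", 1)), int(rep.get("biological", 1))),
        cell_line=doc.get("cell_line", "Hs578T"))


def write_stack(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16))


def read_stack(path) -> np.ndarray:
    return tifffile.imread(path)


def write_label_mask(labels: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(labels, dtype=np.uint16))


def write_trajectories(trajectories, path) -> None:
    rows = []
    for t in trajectories:
        for k in range(t.n_samples):
            rows.append({"cell_id": t.cell_id,
                         "t_min": t.samples[k, 0],
                         "x_um": t.samples[k, 1],
                         "y_um": t.samples[k, 2]})
    pd.DataFrame(rows, columns=["cell_id", "t_min", "x_um", "y_um"]
                 ).to_csv(path, index=False)


def read_trajectories(path):
    from .datatypes import Trajectory
    df = pd.read_csv(path)
    out = []
    for cid, grp in df.groupby("cell_id", sort=True):
        out.append(Trajectory(cell_id=int(cid),
                              samples=grp[["t_min", "x_um", "y_um"]].values))
    return out
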