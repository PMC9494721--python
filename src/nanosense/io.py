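"""File I/O: images, stacks, ground truth, configs, and tabular outputs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .scene_sim import GroundTruth

__all__ = [
    "read_image",
    "write_image",
    "write_stack",
    "write_ground_truth",
    "read_config",
    "write_config",
    "write_sites_csv",
    "write_curve_csv",
    "write_trace_csv",
]


def read_image(path: str | Path) -> np.ndarray:
    return iio.imread(path)


def write_image(path: str | Path, img: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        iio.imwrite(path, img)


def write_stack(
    out_dir: str | Path,
    stack: Sequence[np.ndarray],
    z_list: Sequence[float],
    per_plane_png: bool = False,
) -> Path:
    """Write a z-stack as one multi-page TIFF (and optionally per-plane PNGs)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tiff_path = out_dir / "stack.tiff"
    tifffile.imwrite(tiff_path, np.stack(stack), metadata={"z_um": list(map(float, z_list))})
    if per_plane_png:
        for z, plane in zip(z_list, stack):
            iio.imwrite(out_dir / f"plane_z{float(z):+08.2f}.png", plane)
    return tiff_path


def write_ground_truth(out_dir: str | Path, truth: GroundTruth) -> None:
    """Centroids as JSON plus one uint16 label-mask PNG."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "cell_count": truth.cell_count,
        "centroids": [list(map(float, c)) for c in truth.centroids],
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(payload, indent=2))
    if truth.nucleus_masks:
        labels = np.zeros(truth.nucleus_masks[0].shape, dtype=np.uint16)
        for k, mask in enumerate(truth.nucleus_masks, start=1):
            labels[mask] = k
        iio.imwrite(out_dir / "labels.png", labels)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_config(path: str | Path, config: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def write_sites_csv(path: str | Path, sites, areas=None) -> None:
    rows = []
    for i, s in enumerate(sites):
        row = {"site_id": i, "row": s[0], "col": s[1]}
        if areas is not None:
            row["contour_area"] = areas[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_curve_csv(path: str | Path, curve) -> None:
    pd.DataFrame(
        {"z_um": curve.z, "metric": curve.metric_name, "value": curve.values}
    ).to_csv(path, index=False)


def write_trace_csv(path: str | Path, trace) -> None:
    pd.DataFrame({"distance_m": trace.distances, "current_A": trace.current}).to_csv(
        path, index=False
    )
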