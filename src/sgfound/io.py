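"""File-format plumbing: multi-page TIFF scenes with truth sidecars,
genotype/map TSVs, and YAML configs for the CLI."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic.scenes import CHANNELS, ImageScene, SceneConfig, SceneTruth

TIFF_SCALE = 65535.0


def write_scene(scene: ImageScene, path: str | Path, *, intensity_max: float = 1000.0) -> None:
    """Write a scene as a multi-page 16-bit TIFF (one page per channel, in
    the fixed order nuclei/v5/tial1, scaled by ``intensity_max``).  When
    ground truth is present it goes to sidecars: a spots CSV, a
    transfection CSV, and a 3-page integer label TIFF
    (cell/nucleus/spot)."""
    path = Path(path)
    stack = np.stack(
        [np.clip(scene.channels[ch] / intensity_max, 0, 1) * TIFF_SCALE for ch in CHANNELS]
    ).astype(np.uint16)
    tifffile.imwrite(path, stack, metadata={"axes": "CYX", "channels": list(CHANNELS)})
    if scene.truth is not None:
        base = path.with_suffix("")
        scene.truth.spots.to_csv(f"{base}_truth_spots.csv", index=False)
        tifffile.imwrite(
            f"{base}_truth_labels.tif",
            np.stack([
                scene.truth.cell_labels.astype(np.uint16),
                scene.truth.nucleus_labels.astype(np.uint16),
                scene.truth.spot_labels.astype(np.uint16),
            ]),
        )
        pd.DataFrame(
            {"cell_id": np.arange(1, len(scene.truth.transfected) + 1),
             "transfected": scene.truth.transfected}
        ).to_csv(f"{base}_truth_cells.csv", index=False)


def read_scene(path: str | Path, *, intensity_max: float = 1000.0) -> ImageScene:
    """Read a multi-page TIFF written by :func:`write_scene` (truth
    sidecars, if present, are reattached)."""
    path = Path(path)
    stack = tifffile.imread(path).astype(float) / TIFF_SCALE * intensity_max
    if stack.ndim != 3 or stack.shape[0] != len(CHANNELS):
        raise ValueError(f"expected a {len(CHANNELS)}-page TIFF, got shape {stack.shape}")
    channels = {ch: stack[i] for i, ch in enumerate(CHANNELS)}
    truth = None
    base = path.with_suffix("")
    spots_csv = Path(f"{base}_truth_spots.csv")
    labels_tif = Path(f"{base}_truth_labels.tif")
    cells_csv = Path(f"{base}_truth_cells.csv")
    if spots_csv.exists() and labels_tif.exists() and cells_csv.exists():
        lab = tifffile.imread(labels_tif).astype(np.int32)
        truth = SceneTruth(
            cell_labels=lab[0], nucleus_labels=lab[1], spot_labels=lab[2],
            transfected=pd.read_csv(cells_csv)["transfected"].to_numpy(dtype=bool),
            spots=pd.read_csv(spots_csv),
        )
    return ImageScene(channels=channels, truth=truth)


def write_genotype_panel(panel: pd.DataFrame, truth: dict, path: str | Path) -> None:
    path = Path(path)
    panel.to_csv(path, sep="\t", index=False)
    Path(str(path) + ".truth.json").write_text(json.dumps(truth, indent=2))


def read_genotype_panel(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_genetic_map(path: str | Path) -> pd.DataFrame:
    gmap = pd.read_csv(path, sep="\t")
    if not {"pos_bp", "cM"} <= set(gmap.columns):
        raise ValueError("genetic map TSV needs columns pos_bp and cM")
    return gmap


def load_scene_config(path: str | Path, seed: int | None = None) -> SceneConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("image_size", "spot_radius_px", "nucleus_axes_px"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if seed is not None:
        raw["seed"] = seed
    return SceneConfig(**raw)


def dump_config(config, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))
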