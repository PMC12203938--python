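"""Plain-file I/O: TIFF stacks, schema-versioned CSV tables, YAML configs."""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import GroundTruthManifest

SCHEMA_VERSION = "smstoich-table v1"


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a (frames, h, w) grayscale stack as multi-page TIFF."""
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))


def read_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(float)


def write_table(df: pd.DataFrame, path: str | Path, name: str) -> None:
    """CSV with a schema-version header line ``# smstoich-table v1 <name>``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# {SCHEMA_VERSION} {name}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_params(path: str | Path, params: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)


def read_params(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def manifest_to_frame(manifest: GroundTruthManifest) -> pd.DataFrame:
    rows = []
    for m in manifest.molecules:
        x, y = m.position if m.position is not None else (np.nan, np.nan)
        rows.append(
            {
                "molecule_id": m.molecule_id,
                "channel": m.channel,
                "subunits": m.subunits,
                "n_fluorophores": m.n_fluorophores,
                "complex_id": -1 if m.complex_id is None else m.complex_id,
                "x": x,
                "y": y,
                "bleach_frames": ";".join(str(s.bleach_frame) for s in m.steps),
                "step_heights": ";".join(f"{s.height:.6g}" for s in m.steps),
            }
        )
    return pd.DataFrame(rows)


def write_manifest(manifest: GroundTruthManifest, out_dir: str | Path, stem: str) -> None:
    """Manifest as CSV plus a run-parameters YAML next to it."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(manifest_to_frame(manifest), out / f"{stem}_manifest.csv", "manifest")
    params = dict(manifest.params)
    params["seed"] = manifest.seed
    params["transform_matrix"] = [list(map(float, row)) for row in manifest.transform.matrix]
    params["separation_violations"] = manifest.separation_violations
    write_params(out / f"{stem}_params.yaml", params)


def asdict_plain(obj) -> dict:
    """dataclass -> YAML-safe dict (tuples to lists)."""
    def clean(v):
        if isinstance(v, tuple):
            return [clean(x) for x in v]
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v

    return clean(dataclasses.asdict(obj))
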