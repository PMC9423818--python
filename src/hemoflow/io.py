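"""On-disk containers: raw quadrature frames, flow-image datasets, manifests.

Raw frames are stored one per file as NPZ keyed arrays (rxx, rxy, power_db)
plus scalar metadata (f_nyquist, frame_id, timepoint).  Flow-image datasets
are a directory of per-image ``.npy`` files plus a ``manifest.csv`` with
columns id, label, timepoint, source (and a path column pointing at the
pixel file).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from hemoflow.types import ContractError, FlowImage, Label, QuadratureFrame

FRAME_FORMAT_VERSION = 1


def save_frame(frame: QuadratureFrame, path: str | Path) -> None:
    np.savez(
        Path(path),
        rxx=frame.rxx,
        rxy=frame.rxy,
        power_db=frame.power_db,
        f_nyquist=np.float64(frame.f_nyquist),
        frame_id=np.str_(frame.frame_id),
        timepoint=np.str_(frame.timepoint),
        format_version=np.int64(FRAME_FORMAT_VERSION),
    )


def load_frame(path: str | Path) -> QuadratureFrame:
    with np.load(Path(path), allow_pickle=False) as data:
        version = int(data["format_version"])
        if version != FRAME_FORMAT_VERSION:
            raise ContractError(f"unsupported frame format version {version}")
        return QuadratureFrame(
            rxx=data["rxx"],
            rxy=data["rxy"],
            power_db=data["power_db"],
            f_nyquist=float(data["f_nyquist"]),
            frame_id=str(data["frame_id"]),
            timepoint=str(data["timepoint"]),
        )


def save_dataset(
    images: list[FlowImage], manifest: pd.DataFrame, out_dir: str | Path
) -> Path:
    """Write per-image pixel files and the manifest CSV; returns the CSV path."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    paths = {}
    for img in images:
        rel = f"images/{img.provenance}.npy"
        np.save(out_dir / rel, img.pixels)
        paths[img.provenance] = rel
    manifest["path"] = manifest["id"].map(paths).fillna("")
    csv_path = out_dir / "manifest.csv"
    manifest.to_csv(csv_path, index=False)
    return csv_path


def load_dataset(manifest_csv: str | Path) -> tuple[list[FlowImage], pd.DataFrame]:
    """Read a flow-image dataset back from its manifest CSV."""
    manifest_csv = Path(manifest_csv)
    root = manifest_csv.parent
    manifest = pd.read_csv(manifest_csv, keep_default_na=False)
    images = []
    kept = manifest[~manifest.get("excluded", False).astype(bool)]
    for _, row in kept.iterrows():
        pixels = np.load(root / row["path"])
        images.append(
            FlowImage(
                pixels=pixels,
                label=Label(row["label"]),
                provenance=row["id"],
                timepoint=str(row.get("timepoint", "")),
            )
        )
    return images, manifest
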