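"""Optional DICOM adapter: configured private tags -> QuadratureFrame.

Scanners that embed color-flow quadrature data in DICOM do so under
vendor-specific private tags; no tag layout is hard-coded here.  The caller
supplies a mapping from the fields the pipeline needs to tag paths, e.g.::

    tag_map = {
        "rxx": "0019,0010",
        "rxy": "0019,0011",
        "power_db": "0019,0012",
        "f_nyquist": "0019,0013",
    }
    frame = read_dicom_frame("frame.dcm", tag_map, shape=(128, 128))

Array-valued tags are expected to hold raw little-endian float32 rasters of
the given shape; ``f_nyquist`` may be a numeric element or raw bytes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pydicom

from hemoflow.types import ContractError, QuadratureFrame

REQUIRED_FIELDS = ("rxx", "rxy", "power_db", "f_nyquist")


def _parse_tag(tag_path: str) -> tuple[int, int]:
    try:
        group, elem = tag_path.replace("(", "").replace(")", "").split(",")
        return int(group, 16), int(elem, 16)
    except ValueError as exc:
        raise ContractError(f"malformed tag path {tag_path!r}") from exc


def _tag_bytes(ds: pydicom.Dataset, tag_path: str) -> bytes:
    tag = _parse_tag(tag_path)
    if tag not in ds:
        raise ContractError(f"tag {tag_path} not present in DICOM dataset")
    value = ds[tag].value
    if isinstance(value, bytes):
        return value
    raise ContractError(f"tag {tag_path} does not hold raw bytes")


def read_dicom_frame(
    path: str | Path,
    tag_map: dict[str, str],
    shape: tuple[int, int],
    frame_id: str = "",
    timepoint: str = "",
) -> QuadratureFrame:
    """Read one raw color-flow frame from a DICOM file via a tag map."""
    missing = [f for f in REQUIRED_FIELDS if f not in tag_map]
    if missing:
        raise ContractError(f"tag_map missing fields: {missing}")
    ds = pydicom.dcmread(str(path), force=True)

    def raster(field: str) -> np.ndarray:
        raw = _tag_bytes(ds, tag_map[field])
        arr = np.frombuffer(raw, dtype="<f4")
        if arr.size != shape[0] * shape[1]:
            raise ContractError(
                f"{field}: expected {shape[0] * shape[1]} values, got {arr.size}"
            )
        return arr.reshape(shape).astype(float)

    tag = _parse_tag(tag_map["f_nyquist"])
    if tag not in ds:
        raise ContractError(f"tag {tag_map['f_nyquist']} not present")
    fnyq_val = ds[tag].value
    if isinstance(fnyq_val, bytes):
        fnyq = float(np.frombuffer(fnyq_val, dtype="<f4")[0])
    else:
        fnyq = float(fnyq_val)

    return QuadratureFrame(
        rxx=raster("rxx"),
        rxy=raster("rxy"),
        power_db=raster("power_db"),
        f_nyquist=fnyq,
        frame_id=frame_id or Path(path).stem,
        timepoint=timepoint,
    )
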