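"""HDF5 / TIFF / CSV input-output for maps, imaging stacks and unit tables.

Map schema (HDF5): datasets ``/op_real``, ``/op_imag``, ``/od``, ``/mask``
plus free-form root attributes.  Stack schema: ``/trials/<id>/frames`` with
per-trial ``direction`` and ``eye`` attributes, or multi-frame TIFF files
(one per trial) with a sidecar JSON condition table.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .esd import ImagingStack
from .map_stats import ODMap, OPMap


def save_maps(path, op: OPMap, od: ODMap, attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("op_real", data=op.field.real)
        f.create_dataset("op_imag", data=op.field.imag)
        f.create_dataset("od", data=od.field)
        f.create_dataset("mask", data=op.mask.astype(np.uint8))
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_maps(path) -> tuple[OPMap, ODMap, dict]:
    with h5py.File(path, "r") as f:
        field = f["op_real"][()] + 1j * f["op_imag"][()]
        od = f["od"][()]
        mask = f["mask"][()].astype(bool) if "mask" in f else None
        attrs = dict(f.attrs)
    return OPMap(field, mask), ODMap(od, mask), attrs


def save_stack(path, stack: ImagingStack) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["frame_rate"] = stack.frame_rate
        f.attrs["stim_frames"] = stack.stim_frames
        grp = f.create_group("trials")
        for i in range(len(stack.data)):
            t = grp.create_dataset(f"{i:05d}", data=stack.data[i])
            t.attrs["direction"] = float(stack.directions[i])
            t.attrs["eye"] = str(stack.eyes[i])


def load_stack(path) -> ImagingStack:
    with h5py.File(path, "r") as f:
        keys = sorted(f["trials"].keys())
        data = np.stack([f["trials"][k][()] for k in keys])
        dirs = np.array([f["trials"][k].attrs["direction"] for k in keys], float)
        eyes = np.array([str(f["trials"][k].attrs["eye"]) for k in keys])
        return ImagingStack(data, dirs, eyes,
                            frame_rate=float(f.attrs.get("frame_rate", 5.0)),
                            stim_frames=tuple(f.attrs.get("stim_frames", (11, 35))))


def load_stack_tiff(directory, conditions_json) -> ImagingStack:
    """Stack from per-trial multi-frame TIFFs plus a sidecar JSON table.

    The JSON maps each TIFF filename to {"direction": deg or null, "eye": "L"/"R"/""}.
    """
    import tifffile

    directory = Path(directory)
    with open(conditions_json) as fh:
        table = json.load(fh)
    data, dirs, eyes = [], [], []
    for name in sorted(table):
        rec = table[name]
        data.append(tifffile.imread(directory / name).astype(float))
        d = rec.get("direction")
        dirs.append(np.nan if d is None else float(d))
        eyes.append(rec.get("eye") or "")
    return ImagingStack(np.stack(data), np.array(dirs), np.array(eyes))


def save_stack_tiff(directory, stack: ImagingStack, conditions_json=None) -> None:
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table = {}
    for i in range(len(stack.data)):
        name = f"trial_{i:05d}.tif"
        tifffile.imwrite(directory / name, stack.data[i].astype(np.float32))
        d = stack.directions[i]
        table[name] = {"direction": None if np.isnan(d) else float(d),
                       "eye": str(stack.eyes[i])}
    target = conditions_json or directory / "conditions.json"
    with open(target, "w") as fh:
        json.dump(table, fh, indent=1)
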