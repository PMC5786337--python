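"""Reading and writing: OME-TIFF movies, trace tables, configs, ground truth."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .config import KineticConfig
from .render import ImageStack
from .simulate import DepthTrace, GroundTruth

TRACE_COLUMNS = ["embryo", "cycle", "time_min", "intact_depth_um", "deepest_extent_um", "apical_z"]


def write_movie(path: str | Path, stack: ImageStack) -> None:
    """Write a movie as OME-TIFF with channel names and physical calibration."""
    tifffile.imwrite(
        str(path),
        stack.data,
        ome=True,
        metadata={
            "axes": stack.axes,
            "Channel": {"Name": list(stack.channel_names)},
            "PhysicalSizeX": stack.pixel_size,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.z_step,
            "PhysicalSizeZUnit": "µm",
            "TimeIncrement": stack.frame_interval,
            "TimeIncrementUnit": "s",
        },
    )


def read_movie(path: str | Path) -> ImageStack:
    """Read an OME-TIFF movie written by :func:`write_movie`."""
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        ome = tif.ome_metadata
    import xml.etree.ElementTree as ET

    root = ET.fromstring(ome)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Pixels", ns)
    if pixels is None:
        raise ValueError("missing calibration metadata: Pixels element")
    def attr(name):
        v = pixels.get(name)
        if v is None:
            raise ValueError(f"missing calibration metadata: {name}")
        return float(v)
    channels = [c.get("Name") or f"ch{i}" for i, c in enumerate(pixels.findall("ome:Channel", ns))]
    if data.ndim == 4:  # single channel squeezed
        data = data[:, None]
    return ImageStack(
        data=data,
        pixel_size=attr("PhysicalSizeX"),
        z_step=attr("PhysicalSizeZ"),
        frame_interval=attr("TimeIncrement"),
        channel_names=tuple(channels) if channels else ("membrane", "histone"),
    )


def write_traces(path: str | Path, traces: list[DepthTrace]) -> None:
    """Write depth traces as a delimited table (one row per timepoint)."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "embryo": tr.embryo_id,
                    "cycle": tr.cycle_index,
                    "time_min": tr.times,
                    "intact_depth_um": tr.intact_depth,
                    "deepest_extent_um": tr.deepest_extent,
                    "apical_z": tr.apical_z if tr.apical_z is not None else -1,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(path: str | Path) -> list[DepthTrace]:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"trace table missing columns: {missing}")
    traces = []
    for (embryo, cycle), grp in df.groupby(["embryo", "cycle"], sort=False):
        grp = grp.sort_values("time_min")
        apical = grp["apical_z"].to_numpy() if "apical_z" in grp else None
        traces.append(
            DepthTrace(
                embryo_id=str(embryo),
                cycle_index=int(cycle),
                times=grp["time_min"].to_numpy(float),
                intact_depth=grp["intact_depth_um"].to_numpy(float),
                deepest_extent=grp["deepest_extent_um"].to_numpy(float),
                apical_z=apical,
            )
        )
    return traces


def write_segmentation(path: str | Path, segmentations: dict) -> None:
    """Serialize segmentations as (embryo, cycle, phase, start, end, slope, depth_change)."""
    rows = []
    for (embryo, cycle), seg in segmentations.items():
        for s in seg.segments:
            rows.append(
                {
                    "embryo": embryo,
                    "cycle": cycle,
                    "phase": s.label,
                    "start_min": s.start,
                    "end_min": s.end,
                    "slope_um_per_min": s.slope,
                    "depth_change_um": s.depth_change,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def config_to_yaml(path: str | Path, config: KineticConfig) -> None:
    d = dataclasses.asdict(config)
    d["inferred"] = sorted(d["inferred"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def config_from_yaml(path: str | Path) -> KineticConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["inferred"] = frozenset(d.get("inferred", ()))
    return KineticConfig(**d)


def write_ground_truth(path: str | Path, gt: GroundTruth) -> None:
    d = dataclasses.asdict(gt)
    if d.get("nuclear_positions") is not None:
        d["nuclear_positions"] = np.asarray(d["nuclear_positions"]).tolist()
    Path(path).write_text(json.dumps(d, indent=1, default=float))
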