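"""File I/O: TIFF/PNG channels, truth records, time-lapse series.

Simulated channels are written as single-channel 16-bit grayscale TIFFs,
one file per channel (``<field>_<channel>.tif``); the truth record as JSON;
a leakage series as a multi-page TIFF plus a timestamps CSV with columns
``frame, t_seconds``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from imageio.v3 import imread as _imread

from .render import FieldTruth, MultiChannelField, TimeLapseSeries
from .segment import GrayImage


def _to_uint16(data: np.ndarray) -> np.ndarray:
    return np.clip(np.round(data), 0, 65535).astype(np.uint16)


def read_gray(path: str | Path, pixel_size_um: float = 1.0,
              channel: str = "") -> GrayImage:
    """Read a single-channel TIFF/PNG as a GrayImage."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = _imread(path)
    data = np.asarray(data, dtype=float)
    if data.ndim == 3:  # collapse an accidental RGB read
        data = data.mean(axis=-1)
    return GrayImage(data=data, pixel_size_um=pixel_size_um,
                     channel=channel or path.stem)


def write_field(field: MultiChannelField, out_dir: str | Path,
                name: str = "field") -> list[Path]:
    """Write each channel as ``<name>_<channel>.tif`` (uint16) plus the
    truth record as ``<name>_truth.json`` when present."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for channel, img in field.channels.items():
        path = out_dir / f"{name}_{channel}.tif"
        tifffile.imwrite(path, _to_uint16(img.data),
                         resolution=(1.0 / field.pixel_size_um,) * 2)
        written.append(path)
    if field.truth is not None:
        path = out_dir / f"{name}_truth.json"
        path.write_text(json.dumps(truth_record(field.truth), indent=1))
        written.append(path)
    return written


def truth_record(truth: FieldTruth) -> dict:
    """JSON-serializable ground-truth summary of a rendered field."""
    net = truth.network
    return {
        "dose_gy": truth.dose_gy,
        "network": {
            "branch_count": net.branch_count(),
            "junction_count": net.junction_count(),
            "total_length_um": net.total_length_um(),
            "area_factin_um2": net.area_um2("factin"),
            "area_laminin_um2": net.area_um2("laminin"),
            "perfused_area_fraction": net.perfused_area_fraction(),
            "regressed_area_fraction": net.regressed_area_fraction(),
            "segments": [
                {"diameter_um": s.diameter_um, "regressed": s.regressed,
                 "blocked": s.blocked,
                 "points_um": np.round(s.points, 3).tolist()}
                for s in net.segments
            ],
        },
        "cells": {
            "n_nuclei": int(len(truth.nuclei_px)),
            "nuclei_px": np.round(truth.nuclei_px, 2).tolist(),
            "live": truth.live.astype(int).tolist(),
            "caspase_positive": truth.caspase_positive.astype(int).tolist(),
            "focus_counts": truth.focus_counts.tolist(),
        },
    }


def write_series(series: TimeLapseSeries, out_dir: str | Path,
                 name: str = "leak") -> tuple[Path, Path]:
    """Write a leakage series: multi-page TIFF + timestamps CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stack = np.stack([_to_uint16(f.data) for f in series.frames])
    tif = out_dir / f"{name}.tif"
    tifffile.imwrite(tif, stack)
    csv = out_dir / f"{name}_timestamps.csv"
    pd.DataFrame({"frame": np.arange(len(series.frames)),
                  "t_seconds": series.timestamps_s}).to_csv(csv, index=False)
    return tif, csv


def read_series(tif_path: str | Path, csv_path: str | Path,
                window: tuple[int, int, int, int],
                vessel_diameter_um: float,
                background_intensity: float,
                pixel_size_um: float = 1.0) -> TimeLapseSeries:
    """Load a leakage series written by :func:`write_series` (or any
    multi-page TIFF with a ``frame, t_seconds`` CSV)."""
    stack = tifffile.imread(tif_path)
    if stack.ndim == 2:
        stack = stack[None]
    times = pd.read_csv(csv_path)["t_seconds"].to_numpy(dtype=float)
    frames = [GrayImage(data=frame.astype(float),
                        pixel_size_um=pixel_size_um, channel="dextran")
              for frame in stack]
    return TimeLapseSeries(frames=frames, timestamps_s=times, window=window,
                           vessel_diameter_um=vessel_diameter_um,
                           background_intensity=background_intensity)
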