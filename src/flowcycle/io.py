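"""Reading and writing the delimited-text data formats.

Histograms travel as 2-column TSV (channel_midpoint, count) with a JSON
sidecar (same path, `.json` suffix) carrying the calibration, cell count,
seed and generating parameters.  Per-cell event tables are plain CSV.
Channel convention: 0-based unit-width channels, midpoints at k + 0.5,
calibration expressed as channels per genome equivalent.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .population import DNAHistogram, PopulationSample

__all__ = [
    "read_histogram",
    "write_histogram",
    "sidecar_path",
    "write_events",
    "read_events",
]

_HEADER = (
    "# flowcycle DNA histogram\n"
    "# columns: channel_midpoint <TAB> count\n"
    "# channels are 0-based and unit width; calibration (channels per genome\n"
    "# equivalent) travels in the JSON sidecar\n"
)


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_histogram(hist: DNAHistogram, path) -> Path:
    """Write histogram TSV plus JSON sidecar; returns the TSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_HEADER)
        fh.write("channel_midpoint\tcount\n")
        for mid, cnt in zip(hist.midpoints, hist.counts):
            fh.write(f"{mid:g}\t{int(cnt)}\n")
    sidecar = {
        "version": __version__,
        "calibration": hist.calibration,
        "n_cells": hist.n_cells,
        "n_channels": hist.n_channels,
        **hist.meta,
    }
    with open(sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_histogram(path, calibration: float | None = None) -> DNAHistogram:
    """Parse a histogram TSV (+ optional JSON sidecar).

    Malformed rows are reported with their line number.  An explicit
    `calibration` overrides the sidecar value.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mids, counts = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", "\t").split()
            if fields[0] == "channel_midpoint":  # header row
                continue
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            try:
                mid = float(fields[0])
                cnt = int(float(fields[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
            if cnt < 0:
                raise ValueError(f"{path}:{lineno}: negative count {cnt}")
            mids.append(mid)
            counts.append(cnt)
    if not mids:
        raise ValueError(f"{path}: no histogram rows found")
    mids = np.asarray(mids)
    if mids.size > 1:
        widths = np.diff(mids)
        if np.any(widths <= 0):
            raise ValueError(f"{path}: channel midpoints must be strictly increasing")
        width = float(np.median(widths))
    else:
        width = 1.0
    edges = np.concatenate([mids - width / 2.0, [mids[-1] + width / 2.0]])

    meta: dict = {}
    sc = sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            meta = json.load(fh)
    if calibration is None:
        calibration = meta.get("calibration")
    return DNAHistogram(edges=edges, counts=np.asarray(counts), calibration=calibration,
                        meta=meta)


def write_events(sample: PopulationSample, path) -> Path:
    """Write a per-cell event table (age, dna_signal proxy, mass_signal) as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "age": sample.ages,
            "dna": sample.dna,
            "origins": sample.origins,
            "mass": sample.mass,
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def read_events(path) -> pd.DataFrame:
    """Read a per-cell event table written by :func:`write_events`."""
    df = pd.read_csv(path)
    required = {"age", "dna", "mass"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
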