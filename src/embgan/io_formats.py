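"""Readers and writers shared across the pipeline.

* multi-page TIFF volumes (8/16-bit integer and float stacks, slice order
  preserved, lossless round-trip);
* the nuclei archive dialect used by the established lineaging ecosystem:
  a zip of per-timepoint delimited text files, one record per nucleus with
  1-based indices, validity flag, predecessor/successor pointers, position
  (x, y in pixels, z in slice units), diameter and cell name. In-memory
  everything is 0-based; the conversion lives only in this module;
* YAML run configs and CSV reports.

All writers are deterministic byte-for-byte for identical inputs: fixed
field order, fixed float formatting, and fixed zip timestamps.

Nuclei file columns (comma-separated)::

    index, valid, predecessor, successor1, successor2, x, y, z, diameter, name

with -1 for absent pointers and floats printed to 3 decimals.
"""

from __future__ import annotations

import zipfile
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .trackgraph import Detection, TrackGraph
from .volumes import ImageVolume

__all__ = [
    "FormatError",
    "read_volume",
    "write_volume",
    "read_nuclei_archive",
    "write_nuclei_archive",
    "load_config",
    "save_config",
    "write_run_log",
]


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# TIFF volumes
# ---------------------------------------------------------------------------

def read_volume(path, spacing_um=(0.75, 0.5, 0.5), timepoint: int = 0) -> ImageVolume:
    """Read a multi-page TIFF into a volume (z = page order)."""
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # tifffile raises several error types
        raise FormatError(f"cannot read TIFF volume from {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"expected a 3D stack in {path}, got shape {data.shape}")
    return ImageVolume(data, spacing_um=spacing_um, timepoint=timepoint)


def write_volume(volume: ImageVolume, path) -> None:
    """Write a volume as a multi-page TIFF (one page per z slice)."""
    data = np.asarray(volume.data)
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")


# ---------------------------------------------------------------------------
# nuclei archives
# ---------------------------------------------------------------------------

_ZIP_DATE = (1980, 1, 1, 0, 0, 0)


def _frame_filename(timepoint: int) -> str:
    return f"t{timepoint + 1:03d}-nuclei"


def _format_record(
    index: int,
    valid: int,
    pred: int,
    succ1: int,
    succ2: int,
    det: Detection,
) -> str:
    z, y, x = det.center
    name = det.name or ""
    return (
        f"{index}, {valid}, {pred}, {succ1}, {succ2}, "
        f"{x:.3f}, {y:.3f}, {z:.3f}, {det.diameter:.3f}, {name}"
    )


def write_nuclei_archive(graph: TrackGraph, path) -> None:
    """Serialize a track graph to a zip of per-timepoint nuclei files.

    Records are written in detection-id order; indices are 1-based within
    each timepoint. Predecessor/successor pointers refer to indices at the
    previous/next timepoint. Deterministic byte-for-byte.
    """
    timepoints = graph.timepoints()
    index_of: dict[tuple[int, int], int] = {}
    for t in timepoints:
        for file_index, det in enumerate(
            sorted(graph.detections(t), key=lambda d: d.id), start=1
        ):
            index_of[det.key] = file_index
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for t in timepoints:
            lines = []
            for det in sorted(graph.detections(t), key=lambda d: d.id):
                pred = graph.predecessor(det.key)
                succ = graph.successors(det.key)
                lines.append(
                    _format_record(
                        index_of[det.key],
                        1,
                        index_of[pred] if pred else -1,
                        index_of[succ[0]] if len(succ) > 0 else -1,
                        index_of[succ[1]] if len(succ) > 1 else -1,
                        det,
                    )
                )
            info = zipfile.ZipInfo(_frame_filename(t), date_time=_ZIP_DATE)
            info.external_attr = 0o644 << 16
            zf.writestr(info, "\n".join(lines) + ("\n" if lines else ""))


def _parse_frame(text: str, timepoint: int, filename: str):
    records = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) < 9:
            raise FormatError(
                f"{filename}:{lineno}: expected >= 9 fields, got {len(parts)}"
            )
        try:
            index = int(parts[0])
            valid = int(parts[1])
            pred, s1, s2 = int(parts[2]), int(parts[3]), int(parts[4])
            x, y, z, diam = (float(v) for v in parts[5:9])
        except ValueError as exc:
            raise FormatError(f"{filename}:{lineno}: {exc}") from exc
        name = parts[9] if len(parts) > 9 else ""
        records.append((index, valid, pred, s1, s2, x, y, z, diam, name))
    return records


def read_nuclei_archive(path, spacing_um=(0.75, 0.5, 0.5)) -> TrackGraph:
    """Parse a nuclei archive back into a track graph.

    Dangling successor pointers raise a validation error that names the
    (timepoint, index) of the offending record. Empty per-timepoint files
    produce empty frames.
    """
    frames: dict[int, list] = {}
    with zipfile.ZipFile(path) as zf:
        for info in zf.infolist():
            stem = Path(info.filename).name
            if not (stem.startswith("t") and stem.endswith("-nuclei")):
                continue
            t = int(stem[1 : -len("-nuclei")]) - 1
            frames[t] = _parse_frame(zf.read(info).decode(), t, info.filename)
    graph = TrackGraph()
    key_of: dict[tuple[int, int], tuple[int, int]] = {}  # (t, file index) -> key
    for t in sorted(frames):
        seen = set()
        for rec in frames[t]:
            index, valid, *_ = rec
            if index in seen:
                raise FormatError(f"duplicate index {index} at timepoint {t}")
            seen.add(index)
            _, _, _, _, _, x, y, z, diam, name = rec
            det = graph.add_detection(
                Detection(
                    id=index - 1,
                    timepoint=t,
                    center=np.array([z, y, x], dtype=np.float64),
                    diameter=diam,
                    score=float(valid),
                    name=name or None,
                )
            )
            key_of[(t, index)] = det.key
    for t in sorted(frames):
        for rec in frames[t]:
            index, _, _, s1, s2, *_ = rec
            for succ_index in (s1, s2):
                if succ_index == -1:
                    continue
                if (t + 1, succ_index) not in key_of:
                    raise FormatError(
                        f"dangling successor pointer at (timepoint={t}, index={index})"
                        f" -> index {succ_index} at timepoint {t + 1}"
                    )
                graph.add_edge(key_of[(t, index)], key_of[(t + 1, succ_index)])
    return graph


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def write_run_log(path, seed: int, config: dict) -> dict:
    """Record what a run depended on: seed, a hash of the config, versions.

    Returns the written record so callers can embed it elsewhere too.
    """
    import hashlib
    import sys

    import numpy
    import scipy

    from . import __version__

    config_text = yaml.safe_dump(config, sort_keys=True)
    record = {
        "seed": int(seed),
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "config": config,
        "versions": {
            "embgan": __version__,
            "python": sys.version.split()[0],
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(record, fh, sort_keys=True)
    return record
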