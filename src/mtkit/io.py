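"""Readers and writers for the toolkit's on-disk formats.

Tracking tables: CSV with columns track_id, frame, t_s, x_um, y_um.
Movies/images: TIFF via tifffile.  PSM tables: TSV with columns psm_id,
genotype, isotype_hint, peptide, mods, score (a column mapping adapts
third-party exports).  Geometry and ground truth: JSON.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError
from .imaging import OocyteGeometry
from .transport import Trajectory

TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]
PSM_COLUMNS = ["psm_id", "genotype", "isotype_hint", "peptide", "mods", "score"]


def write_tracks_csv(path, tracks: Sequence[Trajectory]) -> None:
    rows = []
    for tr in tracks:
        for i, (t, (x, y)) in enumerate(zip(tr.times, tr.positions)):
            rows.append((tr.track_id, i, t, x, y))
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)


def read_tracks_csv(path, axis=None) -> list[Trajectory]:
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=False):
        grp = grp.sort_values("frame")
        tracks.append(
            Trajectory(
                track_id=str(tid),
                times=grp["t_s"].to_numpy(float),
                positions=grp[["x_um", "y_um"]].to_numpy(float),
                axis=axis,
            )
        )
    return tracks


def write_movie_tiff(path, stack: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16))


def read_movie_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_image_tiff(path, image: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_image_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_psm_tsv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_psm_tsv(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a PSM TSV; ``column_map`` renames third-party export columns to
    the canonical names (e.g. {"Sequence": "peptide"})."""
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = {"genotype", "peptide", "mods"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_geometry_json(path, geometry: OocyteGeometry) -> None:
    payload = {
        "cortex": geometry.cortex.tolist(),
        "ap_line": geometry.ap_line.tolist(),
        "line_width": geometry.line_width,
        "pixel_size": geometry.pixel_size,
    }
    Path(path).write_text(json.dumps(payload))


def read_geometry_json(path) -> OocyteGeometry:
    d = json.loads(Path(path).read_text())
    return OocyteGeometry(
        cortex=np.asarray(d["cortex"], dtype=float),
        ap_line=np.asarray(d["ap_line"], dtype=float),
        line_width=int(d.get("line_width", 50)),
        pixel_size=float(d.get("pixel_size", 1.0)),
    )


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=default))
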