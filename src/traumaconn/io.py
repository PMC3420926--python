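"""Artifact writers: NIfTI volumes, CSV tables, GraphML networks.

All CSV output goes through one writer with a fixed float format so that
identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import nibabel as nib
import numpy as np
import pandas as pd

from .connectome import Connectome
from .grid import VoxelGrid

FLOAT_FORMAT = "%.10g"


def write_csv(df: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format=FLOAT_FORMAT)
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")
    return path


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def save_nifti(volume: np.ndarray, grid: VoxelGrid, path) -> Path:
    """Write a volume with the grid's voxel-center affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vol = np.asarray(volume)
    if vol.dtype == bool:
        vol = vol.astype(np.uint8)
    nib.Nifti1Image(vol, grid.affine).to_filename(str(path))
    return path


def save_connectome(conn: Connectome, prefix) -> list[Path]:
    """Edge list + node table + strength matrix as CSV, and GraphML."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = [
        write_csv(conn.edges, prefix.with_suffix(".edges.csv")),
        write_csv(conn.nodes, prefix.with_suffix(".nodes.csv")),
        write_csv(conn.strength_matrix(), prefix.with_suffix(".strength.csv"), index=True),
    ]
    gpath = prefix.with_suffix(".graphml")
    nx.write_graphml(conn.to_networkx(), str(gpath))
    written.append(gpath)
    return written
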