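"""File formats shared by the pipeline stages.

Node time series are tab-separated text, frames in rows, header
``node_1..node_K``; the cohort manifest is a CSV table
(subject_id, group, condition, path, seed). Edge tables are CSV with
``subject_id, group, condition, edge_1_2 … edge_{K-1}_{K}`` columns.
Toy volumes travel as NIfTI with voxels arranged in a small 3D grid.
"""

from __future__ import annotations

import hashlib
import math
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synth import CohortTimeSeries, Subject


def node_columns(n_nodes: int) -> list[str]:
    return [f"node_{i}" for i in range(1, n_nodes + 1)]


def write_timeseries(path: str | Path, ts: np.ndarray) -> None:
    df = pd.DataFrame(np.asarray(ts, dtype=float), columns=node_columns(ts.shape[1]))
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_timeseries(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in df.columns if c.startswith("node_")]
    return df[cols].to_numpy(dtype=float)


def write_cohort(cohort: CohortTimeSeries, outdir: str | Path) -> Path:
    """Write one TSV per subject × condition plus a manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    groups = cohort.groups_of()
    for (sid, cond), ts in cohort.series.items():
        fname = f"{sid}_{cond}_timeseries.tsv"
        write_timeseries(outdir / fname, ts)
        rows.append(
            {
                "subject_id": sid,
                "group": groups[sid],
                "condition": cond,
                "path": fname,
                "seed": cohort.seed,
            }
        )
    manifest = pd.DataFrame(rows)
    mpath = outdir / "cohort_manifest.csv"
    manifest.to_csv(mpath, index=False)
    return mpath


def read_cohort(manifest_path: str | Path) -> CohortTimeSeries:
    mpath = Path(manifest_path)
    manifest = pd.read_csv(mpath)
    base = mpath.parent
    series: dict[tuple[str, str], np.ndarray] = {}
    subjects: list[Subject] = []
    seen = set()
    frames: dict[str, int] = {}
    n_nodes = None
    for row in manifest.itertuples(index=False):
        ts = read_timeseries(base / row.path)
        series[(row.subject_id, row.condition)] = ts
        frames.setdefault(row.condition, ts.shape[0])
        n_nodes = ts.shape[1]
        if row.subject_id not in seen:
            seen.add(row.subject_id)
            subjects.append(Subject(row.subject_id, row.group))
    seed = int(manifest["seed"].iloc[0]) if "seed" in manifest else None
    return CohortTimeSeries(
        subjects=subjects,
        series=series,
        frames_per_condition=frames,
        n_nodes=int(n_nodes),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# NIfTI packing: V voxels laid out in the smallest near-cubic 3D grid.

def _grid_shape(V: int) -> tuple[int, int, int]:
    n = max(1, math.ceil(V ** (1 / 3)))
    nx = n
    ny = n
    nz = math.ceil(V / (nx * ny))
    return nx, ny, nz


def vectors_to_nifti(data: np.ndarray, path: str | Path) -> tuple[int, ...]:
    """Pack a V×T (or V×K, or V) array into a NIfTI image; zero-pads the grid."""
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    V, T = data.shape
    nx, ny, nz = _grid_shape(V)
    grid = np.zeros((nx * ny * nz, T))
    grid[:V] = data
    img_data = grid.reshape(nx, ny, nz, T, order="C")
    if T == 1:
        img_data = img_data[..., 0]
    img = nib.Nifti1Image(img_data, affine=np.eye(4))
    img.header["descrip"] = f"strokefc toy grid V={V}".encode()[:80]
    nib.save(img, str(path))
    return img_data.shape


def nifti_to_vectors(path: str | Path, n_voxels: int | None = None) -> np.ndarray:
    """Inverse of :func:`vectors_to_nifti`; returns V×T (or V×1 for 3D images)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    nx, ny, nz, T = data.shape
    flat = data.reshape(nx * ny * nz, T, order="C")
    if n_voxels is None:
        desc = img.header["descrip"].tobytes().decode(errors="ignore")
        if "V=" in desc:
            n_voxels = int(desc.split("V=")[1].split("\x00")[0])
        else:
            n_voxels = flat.shape[0]
    return flat[:n_voxels]


def read_motion_trace(path: str | Path) -> np.ndarray:
    """6-column whitespace-delimited motion parameters, one row per frame."""
    arr = np.loadtxt(path)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != 6:
        raise ValueError(f"motion trace must have 6 columns, got {arr.shape[1]}")
    return arr


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
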