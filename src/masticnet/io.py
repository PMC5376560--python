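"""Readers and writers for every persisted artifact.

Tab-separated text for tables and matrices, NIfTI-1 for volumes and label
maps, JSON for ground truth and run metadata.  Every writer/reader pair is a
numeric round trip to 1e-12; malformed files are rejected with the offending
file and row named.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .motion import MotionTrace
from .network import ConnectivityMatrix
from .preprocess import LabelMap, ROITimeSeries
from .synthetic import GroundTruthRecord, SubjectPhenotype

PHENOTYPE_COLUMNS = ["subject_id", "age", "gender", "group", "mpi"]
MOTION_COLUMNS = ["tx", "ty", "tz", "rx", "ry", "rz"]


def phenotypes_to_frame(phenotypes: list[SubjectPhenotype]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(p) for p in phenotypes], columns=PHENOTYPE_COLUMNS)


def write_phenotypes(phenotypes, path) -> None:
    df = phenotypes if isinstance(phenotypes, pd.DataFrame) else phenotypes_to_frame(phenotypes)
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing phenotype columns {missing_cols}")
    for col in PHENOTYPE_COLUMNS:
        null = df[col].isna()
        if null.any():
            row = int(np.argmax(null.to_numpy())) + 2  # 1-based, after header
            raise ValueError(f"{path}: missing {col!r} value at line {row}")
    return df


def write_series(series: ROITimeSeries, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sampling_interval_s={series.sampling_interval_s!r}\n")
        fh.write(f"# stage={series.stage}\n")
        pd.DataFrame(np.asarray(series.data), columns=list(series.node_labels)).to_csv(
            fh, sep="\t", index=False
        )


def read_series(path) -> ROITimeSeries:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    if "sampling_interval_s" not in meta:
        raise ValueError(f"{path}: missing '# sampling_interval_s=' header line")
    data = df.to_numpy(dtype=float)
    if np.isnan(data).any():
        t, node = np.argwhere(np.isnan(data))[0]
        raise ValueError(f"{path}: NaN at timepoint {t}, node {df.columns[node]!r}")
    return ROITimeSeries(
        data=data,
        node_labels=tuple(df.columns),
        sampling_interval_s=float(meta["sampling_interval_s"]),
        stage=meta.get("stage", "raw"),
    )


def write_motion(trace: MotionTrace, path) -> None:
    pd.DataFrame(np.asarray(trace.data), columns=MOTION_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_motion(path) -> MotionTrace:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != MOTION_COLUMNS:
        raise ValueError(f"{path}: motion header must be {MOTION_COLUMNS}, got {list(df.columns)}")
    data = df.to_numpy(dtype=float)
    if np.isnan(data).any():
        t = int(np.argwhere(np.isnan(data))[0][0])
        raise ValueError(f"{path}: NaN motion value at timepoint {t}")
    return MotionTrace(data=data)


def write_connectivity(cm: ConnectivityMatrix, prefix) -> None:
    """Write labelled r and weight matrices as ``<prefix>_r.tsv`` / ``_weight.tsv``."""
    prefix = Path(prefix)
    labels = list(cm.node_labels)
    for name, mat in (("r", cm.r), ("weight", cm.weight)):
        pd.DataFrame(np.asarray(mat), index=labels, columns=labels).to_csv(
            prefix.parent / f"{prefix.name}_{name}.tsv", sep="\t"
        )


def read_connectivity(prefix) -> ConnectivityMatrix:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.parent / f"{prefix.name}_r.tsv", sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{prefix}_r.tsv: row and column labels disagree")
    return ConnectivityMatrix.from_r(df.to_numpy(dtype=float), tuple(df.columns))


def write_edge_list(edges, path) -> None:
    pd.DataFrame(edges, columns=["node_i", "node_j", "r", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def write_volume(volume: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine=np.eye(4)), str(path))


def read_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def write_label_map(label_map: LabelMap, path) -> None:
    """Label grid as int32 NIfTI with names in the NIfTI description-free JSON sidecar."""
    path = Path(path)
    nib.save(
        nib.Nifti1Image(np.asarray(label_map.grid, dtype=np.int32), affine=np.eye(4)),
        str(path),
    )
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    with open(str(sidecar) + "_labels.json", "w") as fh:
        json.dump({str(k): v for k, v in label_map.label_names.items()}, fh, indent=1)


def read_label_map(path) -> LabelMap:
    path = Path(path)
    grid = np.asarray(nib.load(str(path)).dataobj).astype(np.int32)
    sidecar = path.with_suffix("").with_suffix("")
    with open(str(sidecar) + "_labels.json") as fh:
        names = {int(k): v for k, v in json.load(fh).items()}
    return LabelMap(grid=grid, label_names=names)


def write_hub_table(table: pd.DataFrame, path) -> None:
    out = table.rename(columns={"t": "t", "is_hub": "flag"})
    out.to_csv(path, sep="\t", index=False)


def write_edge_table(table: pd.DataFrame, path) -> None:
    out = table.rename(columns={"significant": "flag"})
    out.to_csv(path, sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return {"index": list(obj.index), "columns": list(obj.columns), "data": obj.to_numpy().tolist()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_ground_truth(gt: GroundTruthRecord, path) -> None:
    payload = {f.name: _jsonable(getattr(gt, f.name)) for f in dataclasses.fields(gt)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_ground_truth(path) -> dict:
    """Ground truth is read back as a plain dict (arrays as nested lists)."""
    with open(path) as fh:
        return json.load(fh)
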