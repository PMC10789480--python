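"""Readers and writers for the pipeline's delimited-text formats.

Time series: tab-delimited, one row per timepoint, header of ROI ids.
Confounds: tab-delimited with fMRIPrep-dialect column names.
Connectivity matrices: tab-delimited square matrices with ROI ids as both
header row and first column.  Partitions: a two-column (roi_id,
network_label) table plus a network metadata table (network_label,
associative 0/1).  Participant tables: CSV.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import ConfoundSet, ConnectivityMatrix, ROITimeSeries
from .errors import SchemaError, ValidationError
from .segregation import NetworkPartition


def write_timeseries(path: str | Path, ts: ROITimeSeries) -> None:
    pd.DataFrame(ts.values, columns=ts.roi_ids).to_csv(path, sep="\t", index=False)


def read_timeseries(path: str | Path, sampling_interval: float) -> ROITimeSeries:
    df = pd.read_csv(path, sep="\t")
    return ROITimeSeries(df.to_numpy(dtype=float), sampling_interval, list(df.columns))


def write_confounds(path: str | Path, confounds: ConfoundSet) -> None:
    confounds.base.to_csv(path, sep="\t", index=False)


def read_confounds(path: str | Path) -> ConfoundSet:
    return ConfoundSet(pd.read_csv(path, sep="\t"))


def write_matrix(path: str | Path, m: ConnectivityMatrix) -> None:
    df = pd.DataFrame(m.z_values, index=m.roi_ids, columns=m.roi_ids)
    df.to_csv(path, sep="\t", index_label="roi_id")


def read_matrix(
    path: str | Path, state_label: str = "rest", variant: str = "full-correlation|gsr"
) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValidationError(f"{path}: row and column ROI ids disagree")
    return ConnectivityMatrix(
        df.to_numpy(dtype=float),
        list(df.columns.astype(str)),
        state_label=state_label,
        variant=variant,
    )


def write_partition(
    partition_path: str | Path, networks_path: str | Path, p: NetworkPartition
) -> None:
    pd.DataFrame(
        {"roi_id": list(p.roi_to_network), "network_label": list(p.roi_to_network.values())}
    ).to_csv(partition_path, sep="\t", index=False)
    pd.DataFrame(
        {
            "network_label": list(p.network_flags),
            "associative": [int(v) for v in p.network_flags.values()],
        }
    ).to_csv(networks_path, sep="\t", index=False)


def read_partition(
    partition_path: str | Path, networks_path: str | Path, provenance: str = ""
) -> NetworkPartition:
    rois = pd.read_csv(partition_path, sep="\t")
    nets = pd.read_csv(networks_path, sep="\t")
    for df, cols, path in (
        (rois, ("roi_id", "network_label"), partition_path),
        (nets, ("network_label", "associative"), networks_path),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
    return NetworkPartition(
        roi_to_network=dict(
            zip(rois["roi_id"].astype(str), rois["network_label"].astype(str))
        ),
        network_flags=dict(
            zip(nets["network_label"].astype(str), nets["associative"].astype(bool))
        ),
        provenance=provenance or str(partition_path),
    )


def load_bundled_partition(name: str = "yeo17_toy") -> NetworkPartition:
    """Load a bundled toy partition (``yeo17_toy`` or ``yeo7_toy``)."""
    pkg = importlib.resources.files("sysseg") / "data"
    part = pkg / f"{name}_partition.tsv"
    nets = pkg / f"{name}_networks.tsv"
    if not part.is_file():
        raise ValidationError(f"no bundled partition named {name!r}")
    return read_partition(str(part), str(nets), provenance=f"bundled:{name}")


def write_ground_truth(path: str | Path, truth: dict) -> None:
    """Plain-text key-value sidecar for scalar ground-truth parameters."""
    with open(path, "w") as fh:
        for key, val in truth.items():
            if isinstance(val, (int, float, str, bool)):
                fh.write(f"{key}\t{val}\n")
            elif isinstance(val, np.ndarray) and val.ndim == 1:
                fh.write(f"{key}\t{','.join(str(v) for v in val)}\n")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return cfg


def save_config(path: str | Path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
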