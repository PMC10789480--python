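"""End-to-end orchestration: simulate/ingest -> connectivity -> SyS -> stats.

A run is described by a :class:`RunConfig` (one input mode: ``simulate``,
``timeseries`` or ``matrices``), executes the stage DAG deterministically
under its seed, writes every intermediate artifact (connectivity matrices,
per-participant SyS table) so deposited-matrix users can enter
mid-pipeline, and returns a :class:`ReportBundle` with a provenance block
(config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .connectivity import timeseries_to_connectivity
from .errors import PartitionError, SysSegError, ValidationError
from .segregation import (
    NetworkPartition,
    compute_sys,
    mean_fc,
    partial_correlation_matrix,
)
from .stats import MediationResult, RegressionResult, fit_age_model, mediate
from .synthetic import CohortSpec, SignalSpec, generate_covariates, generate_timeseries

log = logging.getLogger("sysseg")

INPUT_MODES = ("simulate", "timeseries", "matrices")


@dataclass
class RunConfig:
    """Validated description of one pipeline run."""

    mode: str
    out_dir: str
    partition_path: str | None = None
    networks_path: str | None = None
    bundled_partition: str | None = None
    input_dir: str | None = None
    states: tuple[str, ...] = ("rest",)
    sampling_interval: float = 1.97
    n_timepoints: int = 261
    within_corr: float = 0.5
    confound_amplitude: float = 0.0
    spike_rate: float = 0.0
    cohort: dict = field(default_factory=dict)
    gsr: bool = True
    threshold: bool = True
    associative_only: bool = True
    partial: bool = False
    autocorr_correction: bool = False
    highpass: float = 0.01
    spike_k: float = 5.0
    fit_models: bool = True
    mediation: dict | None = None
    bootstrap_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in INPUT_MODES:
            raise ValidationError(f"mode must be one of {INPUT_MODES}, got {self.mode!r}")
        if self.mode in ("timeseries", "matrices"):
            if not self.input_dir:
                raise ValidationError(f"{self.mode} mode requires input_dir")
            if not Path(self.input_dir).is_dir():
                raise ValidationError(f"input_dir does not exist: {self.input_dir}")
        if (self.partition_path is None) != (self.networks_path is None):
            raise ValidationError("partition_path and networks_path go together")
        if self.partition_path is None and self.bundled_partition is None:
            raise ValidationError("a partition (file pair or bundled name) is required")
        for pth in (self.partition_path, self.networks_path):
            if pth is not None and not Path(pth).is_file():
                raise ValidationError(f"partition file does not exist: {pth}")

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        """Build from a config mapping.

        The mapping carries either a flat ``mode`` key or exactly one mode
        section (``simulate:``/``timeseries:``/``matrices:``) whose fields
        are hoisted; more than one input mode is a validation error.
        """
        cfg = dict(cfg)
        mode_keys = [m for m in INPUT_MODES if m in cfg]
        declared = cfg.get("mode")
        if declared is not None and mode_keys:
            raise ValidationError("config sets both 'mode' and a mode section")
        if declared is None:
            if len(mode_keys) != 1:
                raise ValidationError(
                    f"exactly one input mode must be set, found {mode_keys}"
                )
            mode = mode_keys[0]
            section = cfg.pop(mode) or {}
            cfg.update(section)
            cfg["mode"] = mode
        if "states" in cfg:
            cfg["states"] = tuple(cfg["states"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ValidationError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**cfg)

    def to_dict(self) -> dict:
        out = {}
        for name in self.__dataclass_fields__:
            val = getattr(self, name)
            out[name] = list(val) if isinstance(val, tuple) else val
        return out

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PartitionReport:
    """Fast-fail consistency report between a partition and matrix ROIs."""

    unlabeled_rois: list[str]
    empty_associative_networks: list[str]
    single_roi_associative_networks: list[str]

    @property
    def ok(self) -> bool:
        return not (
            self.unlabeled_rois
            or self.empty_associative_networks
            or self.single_roi_associative_networks
        )


def validate_partition_against_matrix(
    partition: NetworkPartition, roi_ids: list[str]
) -> PartitionReport:
    """List unlabeled ROIs and degenerate associative networks."""
    unlabeled = [r for r in roi_ids if r not in partition.roi_to_network]
    labeled = [r for r in roi_ids if r in partition.roi_to_network]
    counts: dict[str, int] = {}
    for r in labeled:
        counts[partition.roi_to_network[r]] = counts.get(partition.roi_to_network[r], 0) + 1
    empty = sorted(n for n in partition.associative_networks if counts.get(n, 0) == 0)
    single = sorted(n for n in partition.associative_networks if counts.get(n, 0) == 1)
    return PartitionReport(unlabeled, empty, single)


@dataclass
class ReportBundle:
    """Everything a run produces, with provenance."""

    sys_table: pd.DataFrame
    model_results: dict[str, RegressionResult]
    mediation_results: dict[str, MediationResult]
    provenance: dict


def _load_partition(config: RunConfig) -> NetworkPartition:
    if config.partition_path is not None:
        return sio.read_partition(config.partition_path, config.networks_path)
    return sio.load_bundled_partition(config.bundled_partition)


def _simulate_inputs(config: RunConfig, out: Path, partition: NetworkPartition):
    spec = CohortSpec(seed=config.seed, **config.cohort)
    table, truth = generate_covariates(spec)
    table.to_csv(out / "participants.csv", index=False)
    sio.write_ground_truth(out / "ground_truth.txt", truth)
    runs = []
    for i, row in table.iterrows():
        for s_idx, state in enumerate(config.states):
            sig = SignalSpec(
                partition=partition,
                n_timepoints=config.n_timepoints,
                sampling_interval=config.sampling_interval,
                within_corr=config.within_corr,
                confound_amplitude=config.confound_amplitude,
                spike_rate=config.spike_rate,
                seed=int(
                    np.random.default_rng(
                        [config.seed, int(i), 1000 + s_idx]
                    ).integers(2**31)
                ),
            )
            run = generate_timeseries(sig, sys_target=float(row[f"sys_frac_{state}"]))
            runs.append((row["participant_id"], state, run.timeseries, run.confounds))
    return table, runs


def _ingest_timeseries(config: RunConfig):
    root = Path(config.input_dir)
    runs = []
    for ts_path in sorted(root.glob("*_ts.tsv")):
        stem = ts_path.name[: -len("_ts.tsv")]
        pid, _, state = stem.rpartition("_state-")
        conf_path = root / f"{stem}_confounds.tsv"
        ts = sio.read_timeseries(ts_path, config.sampling_interval)
        conf = sio.read_confounds(conf_path) if conf_path.exists() else None
        runs.append((pid, state or "rest", ts, conf))
    if not runs:
        raise ValidationError(f"no '*_ts.tsv' files found in {root}")
    return runs


def _connectivity_stage(config: RunConfig, ts, conf, state: str):
    if config.partial:
        from .connectivity import denoise

        resid = denoise(
            ts, conf, highpass=config.highpass, spike_k=config.spike_k, gsr=config.gsr
        )
        m = partial_correlation_matrix(resid)
        m.state_label = state
        return m
    return timeseries_to_connectivity(
        ts,
        conf,
        highpass=config.highpass,
        spike_k=config.spike_k,
        gsr=config.gsr,
        autocorr_correction=config.autocorr_correction,
        state_label=state,
    )


def run(config: RunConfig) -> ReportBundle:
    """Execute the stage DAG for one configuration."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    partition = _load_partition(config)
    log.info("run start: mode=%s seed=%d digest=%s", config.mode, config.seed, config.digest())

    table = None
    matrices = []  # (participant_id, state, ConnectivityMatrix)
    if config.mode == "matrices":
        for m_path in sorted(Path(config.input_dir).glob("*_matrix.tsv")):
            stem = m_path.name[: -len("_matrix.tsv")]
            pid, _, state = stem.rpartition("_state-")
            matrices.append((pid, state or "rest", sio.read_matrix(m_path, state or "rest")))
        if not matrices:
            raise ValidationError(f"no '*_matrix.tsv' files in {config.input_dir}")
    else:
        if config.mode == "simulate":
            table, runs = _simulate_inputs(config, out, partition)
        else:
            runs = _ingest_timeseries(config)
        for pid, state, ts, conf in runs:
            try:
                m = _connectivity_stage(config, ts, conf, state)
            except SysSegError as exc:
                raise type(exc)(
                    f"stage=connectivity participant={pid} state={state}: {exc}"
                ) from exc
            sio.write_matrix(out / f"{pid}_state-{state}_matrix.tsv", m)
            matrices.append((pid, state, m))

    rows = []
    for pid, state, m in matrices:
        report = validate_partition_against_matrix(partition, m.roi_ids)
        if report.unlabeled_rois or report.empty_associative_networks:
            raise PartitionError(
                f"stage=segregation participant={pid} state={state}: "
                f"unlabeled={report.unlabeled_rois[:5]} "
                f"empty={report.empty_associative_networks}"
            )
        res = compute_sys(
            m,
            partition,
            associative_only=config.associative_only,
            threshold=config.threshold,
        )
        rows.append(
            {
                "participant_id": pid,
                "state": state,
                "variant": m.variant,
                "W": res.W,
                "B": res.B,
                "sys": res.sys,
                "mean_fc": mean_fc(m),
                "n_within_edges": res.n_within_edges,
                "n_between_edges": res.n_between_edges,
            }
        )
    sys_table = pd.DataFrame(rows).sort_values(["participant_id", "state"]).reset_index(drop=True)
    sys_table.to_csv(out / "sys_table.csv", index=False)

    model_results: dict[str, RegressionResult] = {}
    mediation_results: dict[str, MediationResult] = {}
    if table is not None and config.fit_models and len(table) >= 20:
        wide = sys_table.pivot(index="participant_id", columns="state", values="sys")
        merged = table.set_index("participant_id").join(wide, how="inner").reset_index()
        for state in config.states:
            fit = fit_age_model(merged[state].to_numpy(dtype=float), merged)
            model_results[f"sys_{state}~age"] = fit
            fit.to_frame().to_csv(out / f"model_sys_{state}_age.csv", index=False)
        if config.mediation:
            med_cfg = dict(config.mediation)
            state = med_cfg.get("state", config.states[0])
            cov_cols = med_cfg.get("covariates", ["age", "sex"])
            from .stats import encode_sex

            cov = np.column_stack(
                [
                    encode_sex(merged[c].to_numpy())
                    if c == "sex"
                    else merged[c].to_numpy(dtype=float)
                    for c in cov_cols
                ]
            )
            med = mediate(
                merged[med_cfg.get("x", "leq_ma")].to_numpy(dtype=float),
                merged[state].to_numpy(dtype=float),
                merged[med_cfg.get("y", "cognition_latent")].to_numpy(dtype=float),
                covariates=cov,
                reps=config.bootstrap_reps,
                seed=config.seed,
            )
            mediation_results[state] = med

    provenance = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": _version(),
        "n_matrices": len(matrices),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    return ReportBundle(sys_table, model_results, mediation_results, provenance)


def _version() -> str:
    from . import __version__

    return __version__
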