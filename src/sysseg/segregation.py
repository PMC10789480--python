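"""System segregation (SyS) from a connectivity matrix and a network partition.

SyS = (W - B) / W, where W is the mean within-network and B the mean
between-network edge weight (Fisher-z), averaged over the unordered ROI
pairs of the associative networks (sensory/limbic networks excluded by
default).  Negative edges are zeroed first, since global signal regression
induces spurious negative correlations; SyS is then bounded above by 1
(fully modular) with 0 meaning no modular structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityMatrix, ROITimeSeries
from .errors import (
    DegenerateInputError,
    PartitionError,
    UndefinedStatisticError,
    ValidationError,
)


@dataclass
class NetworkPartition:
    """ROI -> network map with an associative flag per network.

    ``network_flags[label]`` is True for higher-order ("associative")
    networks retained in the default SyS computation and False for
    sensory/motor/limbic networks.
    """

    roi_to_network: dict[str, str]
    network_flags: dict[str, bool]
    provenance: str = ""

    def __post_init__(self) -> None:
        unknown = {n for n in self.roi_to_network.values() if n not in self.network_flags}
        if unknown:
            raise PartitionError(f"networks without an associative flag: {sorted(unknown)}")

    @property
    def associative_networks(self) -> set[str]:
        return {n for n, flag in self.network_flags.items() if flag}

    def labels_for(self, roi_ids: list[str]) -> np.ndarray:
        missing = [r for r in roi_ids if r not in self.roi_to_network]
        if missing:
            raise PartitionError(f"ROI(s) missing from partition: {missing}")
        return np.array([self.roi_to_network[r] for r in roi_ids])


@dataclass
class SySResult:
    """Within mean W, between mean B and SyS = (W - B)/W for one matrix."""

    W: float
    B: float
    sys: float
    state_label: str
    variant: str
    n_within_edges: int
    n_between_edges: int


def threshold_negative(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Zero every negative off-diagonal edge; idempotent."""
    z = m.z_values.copy()
    z[z < 0] = 0.0
    return ConnectivityMatrix(z, list(m.roi_ids), state_label=m.state_label, variant=m.variant)


def compute_sys(
    m: ConnectivityMatrix,
    p: NetworkPartition,
    associative_only: bool = True,
    threshold: bool = True,
) -> SySResult:
    """System segregation for one connectivity matrix.

    W and B are unweighted means over upper-triangle edges whose endpoints
    share / do not share a network; with ``associative_only`` both
    endpoints must lie in associative networks.  ``threshold`` zeroes
    negative edges first.  Raises :class:`UndefinedStatisticError` when
    W = 0 rather than returning 0 or NaN.
    """
    if threshold:
        m = threshold_negative(m)
    labels = p.labels_for(m.roi_ids)
    if associative_only:
        assoc = np.array([p.network_flags[lab] for lab in labels], dtype=bool)
    else:
        assoc = np.ones(labels.shape[0], dtype=bool)
    iu = np.triu_indices(len(m.roi_ids), k=1)
    same = labels[iu[0]] == labels[iu[1]]
    keep = assoc[iu[0]] & assoc[iu[1]]
    within_mask = same & keep
    between_mask = (~same) & keep
    if not within_mask.any() or not between_mask.any():
        raise PartitionError(
            "partition leaves no within- or no between-network edges "
            "(need >=2 associative networks with >=2 ROIs each)"
        )
    edges = m.z_values[iu]
    w = float(edges[within_mask].mean())
    b = float(edges[between_mask].mean())
    if w == 0.0:
        raise UndefinedStatisticError("mean within-network connectivity W is 0")
    return SySResult(
        W=w,
        B=b,
        sys=(w - b) / w,
        state_label=m.state_label,
        variant=m.variant,
        n_within_edges=int(within_mask.sum()),
        n_between_edges=int(between_mask.sum()),
    )


def mean_fc(m: ConnectivityMatrix) -> float:
    """Mean off-diagonal upper-triangle z value (pre-thresholding).

    Exposed as a per-participant covariate for the statistical models
    (vascular/global confound adjustment variant).
    """
    iu = np.triu_indices(len(m.roi_ids), k=1)
    return float(m.z_values[iu].mean())


def partial_correlation_matrix(
    ts: ROITimeSeries, shrinkage: float | str = "auto"
) -> ConnectivityMatrix:
    """Partial correlations from a shrinkage-regularized inverse covariance.

    The covariance of the standardized series is shrunk toward a scaled
    identity -- with ``shrinkage="auto"`` the Ledoit-Wolf intensity is used
    -- inverted, and standardized to correlation scale
    (``p_ij = -theta_ij / sqrt(theta_ii theta_jj)``).  For two ROIs with no
    shrinkage this reduces to the Pearson correlation.  Returned as Fisher-z
    values with variant tag ``partial-correlation``.
    """
    if ts.n_timepoints <= 3:
        raise ValidationError("need more than 3 timepoints")
    x = ts.values
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise DegenerateInputError("zero-variance ROI in partial-correlation input")
    x = (x - x.mean(axis=0)) / sd
    emp = x.T @ x / x.shape[0]
    if shrinkage == "auto":
        from sklearn.covariance import ledoit_wolf

        _, intensity = ledoit_wolf(x, assume_centered=True)
    else:
        intensity = float(shrinkage)
        if not 0.0 <= intensity <= 1.0:
            raise ValidationError("shrinkage must be in [0, 1]")
    mu = np.trace(emp) / emp.shape[0]
    shrunk = (1.0 - intensity) * emp + intensity * mu * np.eye(emp.shape[0])
    try:
        theta = np.linalg.inv(shrunk)
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError("covariance not invertible even after shrinkage") from exc
    d = np.sqrt(np.diag(theta))
    p = -theta / np.outer(d, d)
    np.fill_diagonal(p, 0.0)
    p = np.clip((p + p.T) / 2.0, -0.999999, 0.999999)
    z = np.arctanh(p)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        z, list(ts.roi_ids), state_label="rest", variant="partial-correlation"
    )
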