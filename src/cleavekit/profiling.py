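"""Response-matrix analytics: d' clustering, cross-reactivity, dose series.

The single-compound response matrix holds a fold change and a log-scale
standard error per (sensor, condition).  The profile distance between two
sensors is

    d'(i, j) = max over shared conditions v of
               |log fc_i,v - log fc_j,v| / sqrt(se_i,v^2 + se_j,v^2)

i.e. the largest discrepancy in combined-standard-error units; sensors are
grouped by complete-linkage agglomerative clustering on d'.  Cross-
reactivity at a fold threshold f counts, per sensor, the compounds driving
at least f-fold change, and per compound takes the minimum over its
responding sensors.  Dose series report the minimum measured concentration
reaching a fold-change threshold, with masking of sensors confounded by
co-assayed companion compounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ConfigurationError, InputError, UndefinedDistanceError

__all__ = [
    "ResponseMatrix",
    "DoseSeries",
    "dprime",
    "dprime_matrix",
    "ClusterResult",
    "cluster_sensors",
    "linkage_to_newick",
    "CrossReactivity",
    "cross_reactivity",
    "MinDetection",
    "min_detectable_concentration",
]


@dataclass
class ResponseMatrix:
    """Sensors x conditions grid of (fc, se_log_fc); NaN marks missing cells."""

    fc: pd.DataFrame
    se_log: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.fc.index.equals(self.se_log.index) or not self.fc.columns.equals(
            self.se_log.columns
        ):
            raise InputError("fc and se_log grids must be aligned")
        if (self.fc <= 0).any().any():
            raise InputError("fold changes must be positive (NaN for missing)")
        if (self.se_log <= 0).any().any():
            raise InputError("standard errors must be positive (NaN for missing)")

    @property
    def sensors(self) -> list:
        return list(self.fc.index)

    @property
    def conditions(self) -> list:
        return list(self.fc.columns)

    @classmethod
    def from_records(
        cls,
        records: pd.DataFrame,
        condition_col: str = "test_condition",
    ) -> "ResponseMatrix":
        """Pivot long-format fold-change records into a response matrix."""
        fc = records.pivot(index="sensor_id", columns=condition_col, values="fc")
        se = records.pivot(index="sensor_id", columns=condition_col, values="se_log_fc")
        return cls(fc, se)

    def to_tsv(self, path) -> None:
        long = self.fc.stack().rename("fc").to_frame()
        long["se_log_fc"] = self.se_log.stack()
        long.reset_index().to_csv(path, sep="\t", index=False)


def dprime(matrix: ResponseMatrix, sensor_i, sensor_j) -> float:
    """Largest standardized log-fold-change discrepancy between two sensors."""
    fi = matrix.fc.loc[sensor_i].to_numpy(dtype=float)
    fj = matrix.fc.loc[sensor_j].to_numpy(dtype=float)
    si = matrix.se_log.loc[sensor_i].to_numpy(dtype=float)
    sj = matrix.se_log.loc[sensor_j].to_numpy(dtype=float)
    shared = ~(np.isnan(fi) | np.isnan(fj))
    if not shared.any():
        raise UndefinedDistanceError(
            f"sensors {sensor_i!r} and {sensor_j!r} share no measured conditions"
        )
    with np.errstate(invalid="ignore"):
        z = np.abs(np.log(fi) - np.log(fj)) / np.sqrt(si**2 + sj**2)
    return float(np.nanmax(z[shared]))


def dprime_matrix(matrix: ResponseMatrix) -> pd.DataFrame:
    """Full symmetric d' matrix (zero diagonal)."""
    log_fc = np.log(matrix.fc.to_numpy(dtype=float))
    var = matrix.se_log.to_numpy(dtype=float) ** 2
    n = log_fc.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(log_fc[i] - log_fc[i + 1:])
        denom = np.sqrt(var[i] + var[i + 1:])
        z = diff / denom
        if np.isnan(z).all(axis=1).any():
            bad = int(np.flatnonzero(np.isnan(z).all(axis=1))[0]) + i + 1
            raise UndefinedDistanceError(
                f"sensors {matrix.sensors[i]!r} and {matrix.sensors[bad]!r} "
                "share no measured conditions"
            )
        d = np.nanmax(z, axis=1)
        out[i, i + 1:] = d
        out[i + 1:, i] = d
    return pd.DataFrame(out, index=matrix.fc.index, columns=matrix.fc.index)


@dataclass
class ClusterResult:
    labels: pd.Series  # sensor_id -> cluster label (1-based)
    representatives: dict  # label -> sensor_id
    linkage: np.ndarray
    order: list  # sensor ids in linkage order


def cluster_sensors(
    matrix: ResponseMatrix,
    cutoff: float = 3.0,
    abundance: Mapping | None = None,
) -> ClusterResult:
    """Complete-linkage clustering of sensors on d', cut at ``cutoff``.

    Every within-cluster pair is guaranteed d' <= merge height <= cutoff.
    The representative of a cluster is its highest-abundance member (ties,
    or no abundances given: lexically smallest sensor_id).
    """
    if cutoff <= 0:
        raise ConfigurationError("cutoff must be positive")
    sensors = matrix.sensors
    if len(sensors) == 1:
        return ClusterResult(
            labels=pd.Series([1], index=sensors),
            representatives={1: sensors[0]},
            linkage=np.empty((0, 4)),
            order=list(sensors),
        )
    dm = dprime_matrix(matrix)
    condensed = squareform(dm.to_numpy(), checks=False)
    link = hierarchy.linkage(condensed, method="complete")
    flat = hierarchy.fcluster(link, t=cutoff, criterion="distance")
    labels = pd.Series(flat, index=sensors)
    reps = {}
    for lab in sorted(set(flat)):
        members = sorted(labels.index[labels == lab])
        if abundance:
            members.sort(key=lambda s: (-abundance.get(s, 0.0), s))
        reps[lab] = members[0]
    order = [sensors[i] for i in hierarchy.leaves_list(link)]
    return ClusterResult(labels=labels, representatives=reps, linkage=link, order=order)


def linkage_to_newick(linkage: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with d' heights."""
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


@dataclass
class CrossReactivity:
    """Cross-reactivity curves over a fold-change threshold grid."""

    sensor_xr: pd.DataFrame  # sensors x f  (count of compounds with fc >= f)
    compound_xr: pd.DataFrame  # compounds x f (min over responding sensors; NaN if none)

    def cumulative_counts(self, c_grid: Sequence[int]) -> pd.DataFrame:
        """Number of compounds with cross-reactivity <= C, per f (rows) and C."""
        data = {
            c: (self.compound_xr <= c).sum(axis=0) for c in c_grid
        }
        out = pd.DataFrame(data)
        out.index.name = "f"
        out.columns.name = "C"
        return out


def cross_reactivity(matrix: ResponseMatrix, f_grid: Sequence[float]) -> CrossReactivity:
    """Sensor- and compound-level cross-reactivity over thresholds ``f_grid``."""
    fc = matrix.fc.to_numpy(dtype=float)
    sensor_rows, compound_rows = {}, {}
    for f in f_grid:
        hits = fc >= f  # NaN compares False
        xr_sensor = hits.sum(axis=1).astype(float)
        sensor_rows[f] = xr_sensor
        xr_comp = np.full(fc.shape[1], np.nan)
        for j in range(fc.shape[1]):
            responders = np.flatnonzero(hits[:, j])
            if len(responders):
                xr_comp[j] = xr_sensor[responders].min()
        compound_rows[f] = xr_comp
    return CrossReactivity(
        sensor_xr=pd.DataFrame(sensor_rows, index=matrix.fc.index),
        compound_xr=pd.DataFrame(compound_rows, index=matrix.fc.columns),
    )


@dataclass(frozen=True)
class DosePoint:
    concentration_um: float
    fc: float
    ci95: tuple[float, float]


@dataclass
class DoseSeries:
    """A dilution series of one compound against one sensor."""

    sensor_id: str
    compound_id: str
    points: list  # of DosePoint, concentrations strictly decreasing
    companions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        concs = [p.concentration_um for p in self.points]
        if any(b >= a for a, b in zip(concs, concs[1:])):
            raise InputError("dose-series concentrations must be strictly decreasing")


@dataclass
class MinDetection:
    sensor_id: str
    compound_id: str
    min_concentration_um: float | None  # None = ">max tested"
    fc_at_max: float
    masked: bool = False
    mask_reason: str | None = None


def min_detectable_concentration(
    series: DoseSeries,
    fc_threshold: float = 2.0,
    single_compound_matrix: ResponseMatrix | None = None,
    companion_threshold: float = 2.0,
) -> MinDetection:
    """Minimum measured concentration reaching the fold-change threshold.

    A concentration qualifies when fc >= ``fc_threshold`` and the 95% CI
    lower bound exceeds 1.  If the sensor responds (fc >= the companion
    threshold in the single-compound matrix) to any compound co-assayed in
    the same well, the result is withheld as masked.  No interpolation:
    only measured concentrations are reported.
    """
    if not series.points:
        raise InputError("dose series is empty")
    if single_compound_matrix is not None:
        for comp in series.companions:
            if comp in single_compound_matrix.fc.columns:
                fc = single_compound_matrix.fc.loc[series.sensor_id, comp]
                if fc == fc and fc >= companion_threshold:
                    return MinDetection(
                        series.sensor_id,
                        series.compound_id,
                        None,
                        series.points[0].fc,
                        masked=True,
                        mask_reason=f"responds to companion compound {comp}",
                    )
    qualifying = [
        p.concentration_um
        for p in series.points
        if p.fc >= fc_threshold and p.ci95[0] > 1.0
    ]
    return MinDetection(
        series.sensor_id,
        series.compound_id,
        min(qualifying) if qualifying else None,
        series.points[0].fc,
    )
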