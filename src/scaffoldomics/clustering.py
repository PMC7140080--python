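"""Quantification of 3D cell clustering from segmented object volumes.

The drug-response readout is semi-quantitative: density histograms of
segmented object volumes per condition and day, optionally restricted to
the "peak region" domain [0, x̄ + 2σ], plus scalar metrics built on a
calibrated single-cell unit volume (an object is called a cluster when its
volume is at least twice the unit volume).  The scalar metrics are a
declared operationalization of the qualitative clustered/non-clustered
comparison, not a published statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VolumeHistogram",
    "ClusteringMetrics",
    "freedman_diaconis_bin_width",
    "volume_density_histogram",
    "unit_volume_from_mode",
    "clustering_metrics",
    "compare_conditions",
]


@dataclass
class VolumeHistogram:
    """Density histogram of object volumes (µm³)."""

    bin_edges: np.ndarray
    density: np.ndarray
    mean: float
    std: float
    peak_region_domain: tuple[float, float]
    peak_region: bool = False
    condition: str | None = None
    day: str | None = None

    def __post_init__(self) -> None:
        if np.any(self.density < 0):
            raise ValueError("negative density")
        if self.peak_region_domain[0] != 0:
            raise ValueError("peak-region domain must start at 0")

    @property
    def integral(self) -> float:
        return float(np.sum(self.density * np.diff(self.bin_edges)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left": self.bin_edges[:-1],
            "bin_right": self.bin_edges[1:],
            "density": self.density,
            "condition": self.condition,
            "day": self.day,
        })


@dataclass
class ClusteringMetrics:
    """Scalar clustering summary for one set of object volumes."""

    unit_volume: float
    n_objects: int
    singleton_fraction: float
    cluster_fraction: float
    mean_cluster_volume: float
    estimated_cells: int
    condition: str | None = None
    day: str | None = None

    def __post_init__(self) -> None:
        for f in (self.singleton_fraction, self.cluster_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if abs(self.singleton_fraction + self.cluster_fraction - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1")


def freedman_diaconis_bin_width(values: np.ndarray) -> float:
    """Freedman–Diaconis bin width, falling back to a single bin for
    degenerate (zero-IQR) samples."""
    v = np.asarray(values, dtype=float)
    q1, q3 = np.quantile(v, [0.25, 0.75])
    iqr = q3 - q1
    if iqr <= 0 or v.size < 2:
        span = v.max() - v.min()
        return float(span) if span > 0 else max(float(abs(v.max())), 1.0)
    return float(2.0 * iqr / v.size ** (1.0 / 3.0))


def volume_density_histogram(
    volumes,
    bin_width: float | None = None,
    peak_region: bool = False,
    condition: str | None = None,
    day: str | None = None,
) -> VolumeHistogram:
    """Density histogram of volumes; bar areas sum to 1.

    With ``peak_region`` the domain is restricted to ``[0, x̄ + 2σ]`` where
    the sample mean and standard deviation come from the full input sample,
    and the density is normalized over the restricted domain.
    """
    v = np.asarray(volumes, dtype=float)
    if v.size == 0:
        raise ValueError("empty volume list")
    if bin_width is None:
        bin_width = freedman_diaconis_bin_width(v)
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    mean = float(v.mean())
    std = float(v.std(ddof=1)) if v.size > 1 else 0.0
    domain_hi = mean + 2.0 * std

    if peak_region:
        hi = max(domain_hi, bin_width)
        data = v[v <= hi]
        if data.size == 0:
            raise ValueError("no volumes inside the peak-region domain")
        lo = 0.0
    else:
        data = v
        lo = 0.0
        hi = max(v.max(), bin_width)
    n_bins = int(np.ceil((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    if edges[-1] < hi:  # guard against float round-down
        edges = np.append(edges, edges[-1] + bin_width)
    density, edges = np.histogram(data, bins=edges, density=True)
    return VolumeHistogram(
        bin_edges=edges, density=density, mean=mean, std=std,
        peak_region_domain=(0.0, domain_hi), peak_region=peak_region,
        condition=condition, day=day,
    )


def unit_volume_from_mode(volumes, bin_width: float | None = None) -> float:
    """Calibrate the single-cell unit volume as the mode of the volume
    histogram (midpoint of the most occupied bin)."""
    v = np.asarray(volumes, dtype=float)
    if v.size == 0:
        raise ValueError("no objects")
    hist = volume_density_histogram(v, bin_width=bin_width)
    i = int(np.argmax(hist.density))
    return float((hist.bin_edges[i] + hist.bin_edges[i + 1]) / 2.0)


def clustering_metrics(
    table_or_volumes,
    unit_volume: float | None = None,
    condition: str | None = None,
    day: str | None = None,
) -> ClusteringMetrics:
    """Scalar clustering metrics from object volumes.

    An object counts as a singleton when its volume is below
    ``2 * unit_volume``; otherwise it is a cluster.  The estimated total
    cell count is ``round(volume / unit_volume)`` (at least 1) summed over
    objects.
    """
    if isinstance(table_or_volumes, pd.DataFrame):
        v = table_or_volumes["volume_um3"].to_numpy(dtype=float)
    else:
        v = np.asarray(table_or_volumes, dtype=float)
    if v.size == 0:
        raise ValueError("no objects")
    if unit_volume is None:
        unit_volume = unit_volume_from_mode(v)
    if unit_volume <= 0:
        raise ValueError("unit_volume must be > 0")
    is_cluster = v >= 2.0 * unit_volume
    singleton_fraction = float(np.mean(~is_cluster))
    cluster_volumes = v[is_cluster]
    mean_cluster_volume = float(cluster_volumes.mean()) if cluster_volumes.size else 0.0
    cells = np.maximum(1, np.round(v / unit_volume).astype(int))
    return ClusteringMetrics(
        unit_volume=float(unit_volume),
        n_objects=int(v.size),
        singleton_fraction=singleton_fraction,
        cluster_fraction=1.0 - singleton_fraction,
        mean_cluster_volume=mean_cluster_volume,
        estimated_cells=int(cells.sum()),
        condition=condition,
        day=day,
    )


def compare_conditions(metrics: list[ClusteringMetrics]) -> pd.DataFrame:
    """Tabulate metrics across conditions (and days) with differences
    relative to the first condition, ordered by condition then day.

    No inferential statistics are attached: the comparison is descriptive.
    """
    if len({m.condition for m in metrics}) < 2:
        raise ValueError("need at least 2 conditions to compare")
    days_by_cond: dict[str | None, set] = {}
    for m in metrics:
        days_by_cond.setdefault(m.condition, set()).add(m.day)
    day_sets = list(days_by_cond.values())
    if any(s != day_sets[0] for s in day_sets[1:]):
        raise ValueError(f"mismatched day labels across conditions: {days_by_cond}")

    df = pd.DataFrame([{
        "condition": m.condition, "day": m.day, "n_objects": m.n_objects,
        "unit_volume": m.unit_volume,
        "singleton_fraction": m.singleton_fraction,
        "cluster_fraction": m.cluster_fraction,
        "mean_cluster_volume": m.mean_cluster_volume,
        "estimated_cells": m.estimated_cells,
    } for m in metrics]).sort_values(["condition", "day"], kind="stable").reset_index(drop=True)

    ref_cond = df["condition"].iloc[0]
    ref = df[df["condition"] == ref_cond].set_index("day")
    for col in ("singleton_fraction", "cluster_fraction", "mean_cluster_volume"):
        df[f"delta_{col}"] = [
            row[col] - ref.loc[row["day"], col] for _, row in df.iterrows()
        ]
    return df
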