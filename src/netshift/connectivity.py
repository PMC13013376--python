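"""Functional connectivity: Pearson FC, Fisher-z, and the parcel-level seed contrast.

A connectivity matrix is the region-by-region Pearson correlation of ROI
time series; its Fisher-z transform ``z = arctanh(r)`` stabilizes variance
and is the substrate for thresholded graphs and for the seed-based
functional-connectivity contrast (seed row of the z matrix, compared
between conditions across subjects with BH-FDR over the non-seed targets).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateDataError, ZeroVarianceError
from . import group_stats


@dataclass
class ROITimeSeries:
    """Volumes-by-regions time-series table with region labels and TR."""

    values: np.ndarray
    region_labels: list[str]
    tr: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 3:
            raise ConfigurationError("time series must be 2-D with >= 3 volumes")
        if self.values.shape[1] != len(self.region_labels):
            raise ConfigurationError("one label per region required")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("time series contain non-finite values")


@dataclass
class ConnectivityMatrix:
    """Pearson ``r`` and Fisher-z ``z`` matrices with region labels.

    ``r`` is symmetric with unit diagonal; ``z = arctanh(r)`` off-diagonal
    with the diagonal fixed at 0 (arctanh(1) diverges and self-connections
    are excluded from every analysis).
    """

    r: np.ndarray
    region_labels: list[str]
    z: np.ndarray | None = None

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]


def pearson_fc(ts: ROITimeSeries) -> ConnectivityMatrix:
    """Pearson correlation of every pair of regional time series."""
    X = ts.values
    sd = X.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ZeroVarianceError([ts.region_labels[i] for i in dead])
    r = np.corrcoef(X, rowvar=False)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r=r, region_labels=list(ts.region_labels))


def fisher_z(cm: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fill ``z = arctanh(r)`` (off-diagonal), diagonal 0."""
    r = cm.r
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0):
        i, j = np.unravel_index(
            np.argmax(np.abs(np.where(off, r, 0.0))), r.shape
        )
        raise DegenerateDataError(
            f"|r| = 1 between regions {cm.region_labels[i]} and "
            f"{cm.region_labels[j]}; Fisher z undefined"
        )
    z = np.zeros_like(r)
    z[off] = np.arctanh(r[off])
    return ConnectivityMatrix(r=r, z=z, region_labels=list(cm.region_labels))


def connectivity_from_timeseries(ts: ROITimeSeries) -> ConnectivityMatrix:
    """Convenience: Pearson FC with the Fisher-z slot filled."""
    return fisher_z(pearson_fc(ts))


def seed_fc_contrast(
    z_A: Sequence[np.ndarray],
    z_B: Sequence[np.ndarray],
    region_labels: Sequence[str],
    seed_region: int,
    alpha: float = 0.05,
    q: float = 0.05,
) -> pd.DataFrame:
    """Paired contrast of seed-to-target Fisher-z FC across conditions.

    ``z_A``/``z_B`` hold one square z matrix per subject per condition,
    aligned by subject. ``seed_region`` is 1-based. Each non-seed target's
    per-subject seed-target z values are compared with the normality-routed
    paired test and BH-FDR adjusted across the targets. Output rows are in
    fixed atlas order regardless of subject ordering.
    """
    if len(z_A) != len(z_B) or len(z_A) == 0:
        raise ConfigurationError("need the same nonzero number of matrices per condition")
    n_regions = z_A[0].shape[0]
    if not 1 <= seed_region <= n_regions:
        raise ConfigurationError(f"seed region {seed_region} outside 1..{n_regions}")
    s = seed_region - 1

    rows = []
    p_raw = []
    for t in range(n_regions):
        if t == s:
            continue
        x_a = np.array([m[s, t] for m in z_A])
        x_b = np.array([m[s, t] for m in z_B])
        res = group_stats.compare_paired(
            group_stats.PairedSample(x_A=x_a, x_B=x_b), alpha=alpha
        )
        p_raw.append(res.p_raw)
        rows.append(
            {
                "target_region": t + 1,
                "target_label": region_labels[t],
                "method": res.method,
                "statistic": res.statistic,
                "p_raw": res.p_raw,
                "effect_size": res.effect_size,
                "direction": res.direction,
            }
        )
    adjusted, signif = group_stats.bh_fdr(np.array(p_raw), q=q)
    table = pd.DataFrame(rows)
    table["p_fdr"] = adjusted
    table["significant"] = signif
    return table


# ---------------------------------------------------------------------------
# matrix TSV I/O (square, labeled, same dialect as the dataset writer)


def write_matrix_tsv(mat: np.ndarray, labels: Sequence[str], path: str | Path) -> None:
    pd.DataFrame(mat, index=list(labels), columns=list(labels)).to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ConfigurationError(f"{path} is not a square labeled matrix")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]
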