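"""Statistical read-outs on segmented nuclear objects.

Implements the quantitative comparisons used in 3D nuclear-architecture
studies: per-condition chromocenter/foci counts and volumes, fluorescence
intensity comparisons, and radial gene positioning.  A locus signal's radial
position is the distance from the nuclear centre of mass to the signal,
normalized by the centre-to-periphery distance along the same ray, so that
0 is the nuclear centre and 1 the periphery.  Positions are binned into five
concentric shells of 20% relative radius each, and distributions are
compared with the two-sample Kolmogorov-Smirnov test.  Object counts per
nucleus are compared with a pooled-rate z test ("proportions test") and mean
volumes/intensities with Welch's t test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats

from .object_quantification import NucleusMask

__all__ = [
    "OutsideNucleus",
    "RadialRecord",
    "ConditionSummary",
    "SHELL_EDGES",
    "shell_index",
    "radial_fraction",
    "shell_histogram",
    "ks_compare",
    "compare_counts",
    "compare_means",
    "summarize_condition",
]

#: inner edges of the five concentric shells (fractions of nuclear radius)
SHELL_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


class OutsideNucleus(Exception):
    """Signal centre of mass falls outside the nucleus mask."""


@dataclass
class RadialRecord:
    """One locus signal's normalized radial position."""

    nucleus_id: int
    signal_id: int
    fraction: float
    shell: int
    condition: str = ""


@dataclass
class ConditionSummary:
    """Per-condition object statistics (counts, volumes, intensities)."""

    condition: str
    n_nuclei: int
    n_objects: int
    counts_per_nucleus: np.ndarray
    mean_count: float
    mean_volume_um3: float
    se_volume_um3: float
    mean_nuclear_volume_um3: float
    mean_intensity: float
    se_intensity: float


def shell_index(fraction: float) -> int:
    """Shell (1-5) of a radial fraction; bins are [0,.2), ..., [0.8,1.0]."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("radial fraction must lie in [0, 1]")
    return int(np.digitize(fraction, SHELL_EDGES[1:-1])) + 1 if fraction < 1.0 else 5


def radial_fraction(
    signal_com,
    nucleus: NucleusMask,
    step_fraction: float = 0.25,
) -> float:
    """Normalized radial position of a signal inside a segmented nucleus.

    A ray is cast from the nucleus centre of mass through the signal centre
    of mass; the mask boundary along that ray is located by marching in
    quarter-voxel steps on the linearly interpolated mask and refining the
    0.5-crossing.  The returned fraction is the signal's distance divided by
    the boundary distance, clamped to [0, 1].

    Raises
    ------
    OutsideNucleus
        If the signal's nearest voxel is not part of the mask.  Signals
        displaced marginally outside by blur are rejected rather than
        clamped, to avoid silently inflating the outermost shell.
    """
    dx, dy, dz = nucleus.voxel_size
    p = np.asarray(signal_com, dtype=float)
    c = np.asarray(nucleus.center_um, dtype=float)

    nz, ny, nx = nucleus.mask.shape
    ix = min(max(int(p[0] / dx), 0), nx - 1)
    iy = min(max(int(p[1] / dy), 0), ny - 1)
    iz = min(max(int(p[2] / dz), 0), nz - 1)
    if not nucleus.mask[iz, iy, ix]:
        raise OutsideNucleus(f"signal at {tuple(p)} um is outside the nucleus mask")

    v = p - c
    dist = float(np.linalg.norm(v))
    if dist == 0.0:
        return 0.0
    u = v / dist

    step = step_fraction * min(dx, dy, dz)
    mask_f = nucleus.mask.astype(np.float32)

    def interp(ts: np.ndarray) -> np.ndarray:
        pts = c[None, :] + ts[:, None] * u[None, :]
        coords = np.stack(
            [pts[:, 2] / dz - 0.5, pts[:, 1] / dy - 0.5, pts[:, 0] / dx - 0.5]
        )
        return ndimage.map_coordinates(mask_f, coords, order=1, mode="constant")

    # march outward from the centre until the interpolated mask drops below 0.5
    t_max = float(np.linalg.norm([nx * dx, ny * dy, nz * dz]))
    ts = np.arange(0.0, t_max + step, step)
    vals = interp(ts)
    below = np.nonzero(vals < 0.5)[0]
    start = 0
    # if the centre sample itself is below 0.5 (pathological mask) march from
    # the signal instead
    if vals[0] < 0.5:
        start = int(np.searchsorted(ts, dist))
        below = below[below >= start]
    if len(below) == 0:
        boundary = t_max
    else:
        i = int(below[0])
        if i == 0:
            boundary = ts[0]
        else:
            t0, t1 = ts[i - 1], ts[i]
            v0, v1 = vals[i - 1], vals[i]
            # linear refinement of the 0.5-crossing
            boundary = t0 + (0.5 - v0) / (v1 - v0) * (t1 - t0) if v1 != v0 else t1
    if boundary <= 0:
        return 0.0
    return float(min(dist / boundary, 1.0))


def shell_histogram(records) -> tuple[np.ndarray, pd.DataFrame]:
    """Bin radial positions into the five 20%-radius shells.

    Parameters
    ----------
    records : list of RadialRecord or array-like of fractions

    Returns
    -------
    counts : ndarray, shape (5,)
        Counts per shell; sums to the number of records.
    cumulative : DataFrame with columns ``fraction`` and ``ecdf``
        The empirical cumulative distribution of the fractions (for
        cumulative-distribution plots).
    """
    if len(records) and isinstance(records[0], RadialRecord):
        fractions = np.array([r.fraction for r in records], dtype=float)
    else:
        fractions = np.asarray(records, dtype=float)
    counts = np.zeros(5, dtype=int)
    if fractions.size:
        if fractions.min() < 0 or fractions.max() > 1:
            raise ValueError("radial fractions must lie in [0, 1]")
        shells = np.minimum(np.digitize(fractions, SHELL_EDGES[1:-1]), 4)
        shells[fractions >= 1.0] = 4
        counts = np.bincount(shells, minlength=5)
    order = np.sort(fractions)
    cumulative = pd.DataFrame(
        {"fraction": order, "ecdf": (np.arange(len(order)) + 1) / max(len(order), 1)}
    )
    return counts, cumulative


def ks_compare(fractions_a, fractions_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of radial distributions.

    D is the exact supremum of |ECDF_a - ECDF_b| over the pooled sample
    points; the p-value comes from the asymptotic Kolmogorov distribution
    with effective size ``n_a n_b / (n_a + n_b)``.
    """
    a = np.sort(np.asarray(fractions_a, dtype=float))
    b = np.sort(np.asarray(fractions_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    en = a.size * b.size / (a.size + b.size)
    p = float(np.clip(special.kolmogorov(math.sqrt(en) * d), 0.0, 1.0))
    return d, p


def compare_counts(counts_a, counts_b) -> tuple[float, float]:
    """Pooled-rate z test for object counts per nucleus ("proportions test").

    Compares the two groups' rates (total objects over total nuclei) with a
    pooled-variance z statistic; returns (z, two-sided p).
    """
    ca = np.asarray(counts_a, dtype=float)
    cb = np.asarray(counts_b, dtype=float)
    if ca.size == 0 or cb.size == 0:
        raise ValueError("each group needs at least one nucleus")
    na, nb = ca.size, cb.size
    ra, rb = ca.sum() / na, cb.sum() / nb
    pooled = (ca.sum() + cb.sum()) / (na + nb)
    se = math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    if se == 0:
        return 0.0, 1.0
    z = (ra - rb) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def compare_means(values_a, values_b) -> tuple[float, float]:
    """Welch's two-sided t test for mean volumes or mean intensities."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")
    res = stats.ttest_ind(a, b, equal_var=False)
    t = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(p):  # both samples constant and equal
        return 0.0, 1.0
    return t, p


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    if x.size == 0:
        return math.nan, math.nan
    if x.size == 1:
        return float(x[0]), math.nan
    return float(x.mean()), float(x.std(ddof=1) / math.sqrt(x.size))


def summarize_condition(
    objects: pd.DataFrame,
    nuclei: pd.DataFrame,
    condition: str,
    channel: str | None = None,
) -> ConditionSummary:
    """Summarize object statistics for one condition.

    ``objects`` and ``nuclei`` are the tables produced by the quantification
    step with a ``condition`` column; per-nucleus counts include nuclei with
    zero objects.  Means that cannot be computed (no objects) are NaN.
    """
    nuc = nuclei[nuclei["condition"] == condition]
    if len(nuc) == 0:
        raise ValueError(f"condition {condition!r} absent from the nuclei table")
    obj = objects[objects["condition"] == condition] if len(objects) else objects
    if channel is not None and len(obj):
        obj = obj[obj["channel"] == channel]
    per_nucleus = (
        obj.groupby("nucleus_id").size() if len(obj) else pd.Series(dtype=int)
    )
    counts = per_nucleus.reindex(nuc["nucleus_id"], fill_value=0).to_numpy(float)
    volumes = obj["volume_um3"].to_numpy(float) if len(obj) else np.array([])
    intens = obj["mean_intensity"].to_numpy(float) if len(obj) else np.array([])
    mean_v, se_v = _mean_se(volumes)
    mean_i, se_i = _mean_se(intens)
    return ConditionSummary(
        condition=condition,
        n_nuclei=len(nuc),
        n_objects=int(len(obj)),
        counts_per_nucleus=counts,
        mean_count=float(counts.mean()),
        mean_volume_um3=mean_v,
        se_volume_um3=se_v,
        mean_nuclear_volume_um3=float(nuc["volume_um3"].mean()),
        mean_intensity=mean_i,
        se_intensity=se_i,
    )
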