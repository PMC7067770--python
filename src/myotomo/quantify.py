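"""Quantitative read-outs: per-slice voxel sums, area fractions, deltas.

Sign conventions (encoded here once):

* **Baseline deltas** (injury progression within one series):
  ``delta(day) = metric(day 1) - metric(day)``.  For the space volume a more
  severe injury gives a *more negative* delta, so bars extending further below
  zero mean worse damage.
* **Contralateral differences** (injured vs uninjured side, same group/day):
  for muscle *weights* the convention is ``non-injury - injury`` (atrophy makes
  this positive); for *space* metrics it is ``injury - non-injury`` (worse
  ipsilateral injury makes this positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DEFAULT_VOXEL_SIZE_UM, as_bool_mask, check_congruent

__all__ = [
    "SliceProfile",
    "InjuryMeasurement",
    "slice_counts",
    "area_fractions",
    "measure_sample",
    "injury_vs_baseline",
    "contralateral_difference",
    "build_report",
    "REPORT_COLUMNS",
]

#: metrics whose contralateral difference is taken as (non-injury - injury)
_WEIGHT_LIKE_METRICS = {"weight_g"}

REPORT_COLUMNS = ["sample_id", "group", "side", "day", "metric", "value"]


@dataclass
class SliceProfile:
    """Per-slice voxel counts of a segmented mask along the stack axis.

    ``slice_sd`` is the population standard deviation of the per-slice counts;
    it spreads out when the injury is unevenly distributed along the muscle,
    so it reads as the slice-wise degree of injury.
    """

    counts: np.ndarray
    voxel_volume_um3: float = DEFAULT_VOXEL_SIZE_UM**3

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("slice counts must be non-negative")

    @property
    def total_voxels(self) -> int:
        return int(self.counts.sum())

    @property
    def total_um3(self) -> float:
        return self.total_voxels * self.voxel_volume_um3

    @property
    def slice_sd(self) -> float:
        return float(np.std(self.counts))  # population sd over slices

    @property
    def n_slices(self) -> int:
        return len(self.counts)


def slice_counts(
    mask: np.ndarray,
    axis: int = 0,
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM,
    slice_range: tuple[int, int] | None = None,
) -> SliceProfile:
    """Sum segmented voxels per slice along the stack axis.

    ``slice_range`` restricts the profile to ``[start, stop)`` slices (e.g. a
    belly region of the muscle); default is the whole stack.
    """
    m = as_bool_mask(mask)
    axes = tuple(i for i in range(m.ndim) if i != axis)
    counts = m.sum(axis=axes)
    if slice_range is not None:
        start, stop = slice_range
        counts = counts[start:stop]
    return SliceProfile(counts, voxel_size_um**3)


def area_fractions(fiber: np.ndarray, region: np.ndarray) -> tuple[float, float]:
    """Fibre and space area percentages of a measurement region.

    ``fiber_pct = 100 * |fiber| / |region|`` and ``space_pct = 100 -
    fiber_pct`` exactly, so the two always sum to 100.  Works on a single 2D
    histology field or on a 3D mask pair over a slice range.
    """
    f = as_bool_mask(fiber, "fiber")
    r = as_bool_mask(region, "region")
    check_congruent(f, r)
    n_region = int(r.sum())
    if n_region == 0:
        raise ValueError("measurement region is empty")
    if (f & ~r).any():
        raise ValueError("fiber mask extends outside the measurement region")
    fiber_pct = 100.0 * int(f.sum()) / n_region
    return fiber_pct, 100.0 - fiber_pct


@dataclass
class InjuryMeasurement:
    """One (sample, group, side, day) record of the injury metrics."""

    sample_id: str
    group: str
    side: str
    day: int
    space_volume_vox: int
    space_volume_um3: float
    fiber_fraction_pct: float
    space_fraction_pct: float
    space_slice_sd: float
    weight_g: float | None = None

    def __post_init__(self) -> None:
        if self.space_volume_vox < 0:
            raise ValueError("space volume must be >= 0")
        if abs(self.fiber_fraction_pct + self.space_fraction_pct - 100.0) > 1e-9:
            raise ValueError("fiber and space fractions must sum to 100")

    def metrics(self) -> dict[str, float]:
        out = {
            "space_volume_vox": float(self.space_volume_vox),
            "space_volume_um3": self.space_volume_um3,
            "space_slice_sd": self.space_slice_sd,
            "fiber_fraction_pct": self.fiber_fraction_pct,
            "space_fraction_pct": self.space_fraction_pct,
        }
        if self.weight_g is not None:
            out["weight_g"] = self.weight_g
        return out


def measure_sample(
    fiber: np.ndarray,
    contour: np.ndarray,
    space: np.ndarray,
    *,
    sample_id: str,
    group: str,
    side: str,
    day: int,
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM,
    slice_range: tuple[int, int] | None = None,
    weight_g: float | None = None,
) -> InjuryMeasurement:
    """Turn one sample's segmentation masks into an :class:`InjuryMeasurement`.

    Fractions are measured against the bundle contour (the tissue-filled
    region), not the full image frame, over the selected slice range.
    """
    if slice_range is not None:
        sl = slice(*slice_range)
        fiber, contour, space = fiber[sl], contour[sl], space[sl]
    profile = slice_counts(space, voxel_size_um=voxel_size_um)
    fiber_pct, space_pct = area_fractions(fiber & contour, contour)
    return InjuryMeasurement(
        sample_id=sample_id,
        group=str(group),
        side=str(side),
        day=int(day),
        space_volume_vox=profile.total_voxels,
        space_volume_um3=profile.total_um3,
        fiber_fraction_pct=fiber_pct,
        space_fraction_pct=space_pct,
        space_slice_sd=profile.slice_sd,
        weight_g=weight_g,
    )


def _series_day_means(series: list[InjuryMeasurement], metric: str) -> dict[int, float]:
    by_day: dict[int, list[float]] = {}
    for m in series:
        val = m.metrics().get(metric)
        if val is None:
            raise KeyError(f"metric {metric!r} missing on sample {m.sample_id}")
        by_day.setdefault(m.day, []).append(val)
    return {d: float(np.mean(v)) for d, v in by_day.items()}


def injury_vs_baseline(series: list[InjuryMeasurement], metric: str) -> dict[int, float]:
    """Per-day deltas against the day-1 baseline of the same (group, side).

    ``delta(day) = metric(day 1) - metric(day)`` on per-day means; the day-1
    delta is therefore 0 and growing injury drives space-volume deltas
    negative.
    """
    groups = {(m.group, m.side) for m in series}
    if len(groups) > 1:
        raise ValueError(f"series mixes (group, side) cells: {sorted(groups)}")
    means = _series_day_means(series, metric)
    if 1 not in means:
        raise ValueError("series has no day-1 baseline measurement")
    base = means[1]
    return {day: base - means[day] for day in sorted(means)}


def contralateral_difference(
    injury: InjuryMeasurement, noninjury: InjuryMeasurement, metric: str
) -> float:
    """Signed injured-vs-uninjured difference for one (group, day) pair."""
    if injury.group != noninjury.group or injury.day != noninjury.day:
        raise ValueError(
            f"mismatched pair: {injury.group}/d{injury.day} vs "
            f"{noninjury.group}/d{noninjury.day}"
        )
    if injury.side == noninjury.side:
        raise ValueError("pair must have opposite sides")
    vi = injury.metrics().get(metric)
    vn = noninjury.metrics().get(metric)
    if vi is None or vn is None:
        raise KeyError(f"metric {metric!r} missing on one side")
    if metric in _WEIGHT_LIKE_METRICS:
        return vn - vi
    return vi - vn


def build_report(measurements: list[InjuryMeasurement]) -> pd.DataFrame:
    """Tidy long-format table: one row per (sample, metric)."""
    rows = []
    seen = set()
    for m in measurements:
        for metric, value in m.metrics().items():
            key = (m.sample_id, metric)
            if key in seen:
                raise ValueError(f"duplicate sample/metric pair {key}")
            seen.add(key)
            rows.append(
                {
                    "sample_id": m.sample_id,
                    "group": m.group,
                    "side": m.side,
                    "day": m.day,
                    "metric": metric,
                    "value": value,
                }
            )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
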