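"""Per-region density and intensity statistics with replicate aggregation.

Density is reported as puncta per 100 µm² of ROI area; intensity as the
arithmetic mean of per-punctum disc-mean intensities (a.u.).  Aggregation
across biological replicates (animals or post-mortem cases, never images
within a subject) yields mean ± SEM, the summary the marker × region
tables report.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import PunctaSet

__all__ = [
    "RegionROI",
    "MarkerRegionTable",
    "puncta_density",
    "mean_puncta_intensity",
    "aggregate_replicates",
    "build_marker_region_table",
]


@dataclass
class RegionROI:
    """A named region-of-interest mask congruent with a montage.

    Area is derived from the pixel count, matching the pixel-based
    detection domain (not polygon geometry).
    """

    label: str
    mask: np.ndarray
    pixel_size_nm: float = 68.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not self.mask.any():
            raise ValueError(f"ROI {self.label!r} has zero area")

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * (self.pixel_size_nm / 1000.0) ** 2


def puncta_density(ps: PunctaSet) -> float:
    """Puncta per 100 µm² of ROI area."""
    if ps.roi_area_um2 <= 0:
        raise ValueError(
            f"PunctaSet ({ps.marker!r}, {ps.region!r}) has zero ROI area"
        )
    return 100.0 * len(ps) / ps.roi_area_um2


def mean_puncta_intensity(ps: PunctaSet) -> float:
    """Arithmetic mean of per-punctum disc-mean intensities (a.u.).

    Empty sets yield NaN with a warning; NaNs are dropped by replicate
    aggregation rather than propagated.
    """
    if len(ps) == 0:
        warnings.warn(
            f"PunctaSet ({ps.marker!r}, {ps.region!r}) is empty; intensity is NaN"
        )
        return float("nan")
    return float(ps.puncta["mean_intensity"].mean())


def aggregate_replicates(values) -> tuple[float, float]:
    """Mean and SEM (sd/sqrt(n), ddof=1) across biological replicates.

    NaN entries (e.g. empty-region intensities) are excluded.  A single
    replicate yields SEM 0 with a warning, since spread is unmeasurable.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no replicate values to aggregate")
    mean = float(arr.mean())
    if arr.size == 1:
        warnings.warn("single replicate: SEM reported as 0")
        return mean, 0.0
    return mean, float(arr.std(ddof=1) / math.sqrt(arr.size))


@dataclass
class MarkerRegionTable:
    """Marker × region summary: mean, SEM and replicate count per cell.

    ``measure`` names the quantity: ``density_per_100um2``,
    ``mean_intensity_au`` or ``percent``.
    """

    measure: str
    mean: pd.DataFrame
    sem: pd.DataFrame
    n: pd.DataFrame

    def __post_init__(self) -> None:
        for name, df in (("sem", self.sem), ("n", self.n)):
            if df.shape != self.mean.shape:
                raise ValueError(f"{name} table shape differs from mean table")
        if (self.sem.to_numpy(dtype=float) < 0).any():
            raise ValueError("SEM must be >= 0")
        if (self.n.to_numpy(dtype=float) < 1).any():
            raise ValueError("replicate count must be >= 1")
        vals = self.mean.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if self.measure == "percent" and ((finite < 0) | (finite > 100)).any():
            raise ValueError("percent cells must lie in [0, 100]")
        if self.measure != "percent" and (finite < 0).any():
            raise ValueError(f"{self.measure} cells must be >= 0")

    def formatted(self, decimals: int = 0) -> pd.DataFrame:
        """'mean±SEM' strings with half-away-from-zero rounding, as printed."""
        def fmt(m, s):
            if np.isnan(m):
                return ""
            return f"{round_half_away(m, decimals)}±{round_half_away(s, decimals)}"
        return pd.DataFrame(
            np.vectorize(fmt)(self.mean.to_numpy(float), self.sem.to_numpy(float)),
            index=self.mean.index,
            columns=self.mean.columns,
        )

    def to_tidy(self) -> pd.DataFrame:
        def melt(df, name):
            return df.rename_axis("marker").reset_index().melt(
                id_vars="marker", var_name="region", value_name=name
            )

        out = melt(self.mean, "mean")
        out = out.merge(melt(self.sem, "sem"), on=["marker", "region"])
        out = out.merge(melt(self.n, "n"), on=["marker", "region"])
        out.insert(0, "measure", self.measure)
        return out


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    factor = 10.0**decimals
    r = math.floor(abs(x) * factor + 0.5) / factor * math.copysign(1.0, x)
    return r if decimals else int(r)


def build_marker_region_table(
    tidy: pd.DataFrame,
    measure: str,
    markers: list[str] | None = None,
    regions: list[str] | None = None,
    add_mean_column: bool = True,
) -> MarkerRegionTable:
    """Aggregate a tidy per-subject table into a marker × region summary.

    ``tidy`` needs columns marker, region, subject, value, with one row
    per biological replicate (pool images within a subject upstream).
    With ``add_mean_column`` a cross-region ``Mean`` column is appended:
    per marker, each subject's regional values are averaged first, then
    aggregated across subjects, so its SEM is a between-subject SEM.
    """
    required = {"marker", "region", "subject", "value"}
    missing = required - set(tidy.columns)
    if missing:
        raise ValueError(f"tidy table missing columns {sorted(missing)}")
    markers = list(markers or tidy["marker"].unique())
    regions = list(regions or tidy["region"].unique())
    mean = pd.DataFrame(index=markers, columns=regions, dtype=float)
    sem = pd.DataFrame(index=markers, columns=regions, dtype=float)
    n = pd.DataFrame(1, index=markers, columns=regions, dtype=int)
    for m in markers:
        for r in regions:
            vals = tidy.query("marker == @m and region == @r")["value"]
            if vals.empty:
                raise ValueError(f"no values for marker {m!r} in region {r!r}")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mu, se = aggregate_replicates(vals)
            mean.loc[m, r], sem.loc[m, r] = mu, se
            n.loc[m, r] = vals.notna().sum()
    if add_mean_column:
        per_subject = (
            tidy.groupby(["marker", "subject"])["value"].mean().reset_index()
        )
        for m in markers:
            vals = per_subject.query("marker == @m")["value"]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mu, se = aggregate_replicates(vals)
            mean.loc[m, "Mean"], sem.loc[m, "Mean"] = mu, se
            n.loc[m, "Mean"] = vals.notna().sum()
        n = n.fillna(1).astype(int)
    mean.index.name = sem.index.name = n.index.name = "marker"
    return MarkerRegionTable(measure=measure, mean=mean, sem=sem, n=n)
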