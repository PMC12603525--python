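"""Laplacian-of-Gaussian puncta detection, intensity measurement and SNR.

The detector mirrors the classic particle-detection recipe used for
diffraction-limited fluorescent spots: a scale-normalised LoG filter tuned
to the expected punctum radius, non-maximum suppression at roughly one
radius separation, a *quality* threshold on the filter response (with an
"auto" mode that uses the mean quality of all candidate maxima), an
intensity threshold on the disc-mean intensity, and optional subpixel
refinement of the peak by a quadratic fit.  These are the three per-marker
knobs practitioners tune by eye on each antibody before batch processing:
punctum radius, quality threshold, intensity threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .micrograph import Micrograph

__all__ = [
    "DetectionParams",
    "Punctum",
    "PunctaSet",
    "log_response",
    "detect_puncta",
    "measure_intensity",
    "compute_snr",
]

#: Columns of a PunctaSet table.
PUNCTA_COLUMNS = ["x_um", "y_um", "quality", "mean_intensity", "radius_um"]

AUTO = "auto"


@dataclass
class DetectionParams:
    """The per-marker detection knobs.

    punctum_radius_um   : expected punctum radius; sets the LoG scale
                          (sigma = radius / sqrt(2)) and the minimum
                          separation between detections.
    quality_threshold   : absolute cutoff on the LoG response at the peak,
                          or ``"auto"`` to use the mean quality of all
                          candidate maxima.
    intensity_threshold : cutoff on the disc-mean intensity (a.u.).
    subpixel            : refine peak position by a 2-D quadratic fit.
    exclude_border      : drop maxima within one radius of the image edge
                          (avoids truncated-disc intensity bias).
    """

    punctum_radius_um: float = 0.12
    quality_threshold: float | str = AUTO
    intensity_threshold: float = 0.0
    subpixel: bool = True
    exclude_border: bool = True

    def __post_init__(self) -> None:
        if self.punctum_radius_um <= 0:
            raise ValueError("punctum_radius_um must be positive")
        if isinstance(self.quality_threshold, str) and self.quality_threshold != AUTO:
            raise ValueError(f"quality_threshold must be a number or '{AUTO}'")
        if not isinstance(self.quality_threshold, str) and not math.isfinite(
            self.quality_threshold
        ):
            raise ValueError("quality_threshold must be finite")
        if not math.isfinite(self.intensity_threshold):
            raise ValueError("intensity_threshold must be finite")


@dataclass(frozen=True)
class Punctum:
    """One detected spot: centroid (µm), LoG quality, disc-mean intensity."""

    x_um: float
    y_um: float
    quality: float
    mean_intensity: float
    radius_um: float


@dataclass
class PunctaSet:
    """Detected puncta for one marker within one region of interest.

    ``puncta`` is a DataFrame with columns x_um, y_um, quality,
    mean_intensity, radius_um, ordered by descending quality (scan order
    breaks exact ties).  ``roi_area_um2`` is the area over which detection
    ran; densities are counts normalised to 100 µm² of that area.
    """

    marker: str = ""
    region: str = ""
    puncta: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=PUNCTA_COLUMNS)
    )
    roi_area_um2: float = 0.0
    pixel_size_nm: float = 68.0

    def __post_init__(self) -> None:
        missing = [c for c in PUNCTA_COLUMNS if c not in self.puncta.columns]
        if missing:
            raise ValueError(f"puncta table missing columns {missing}")
        if self.roi_area_um2 < 0:
            raise ValueError("roi_area_um2 must be >= 0")

    def __len__(self) -> int:
        return len(self.puncta)

    @property
    def positions(self) -> np.ndarray:
        return self.puncta[["x_um", "y_um"]].to_numpy(dtype=float)

    def __iter__(self):
        for row in self.puncta.itertuples(index=False):
            yield Punctum(row.x_um, row.y_um, row.quality, row.mean_intensity, row.radius_um)

    def to_csv(self, path) -> None:
        out = self.puncta.copy()
        out.insert(0, "region", self.region)
        out.insert(0, "marker", self.marker)
        out["roi_area_um2"] = self.roi_area_um2
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PunctaSet":
        df = pd.read_csv(path)
        marker = str(df["marker"].iloc[0]) if len(df) else ""
        region = str(df["region"].iloc[0]) if len(df) else ""
        area = float(df["roi_area_um2"].iloc[0]) if len(df) else 0.0
        return cls(
            marker=marker,
            region=region,
            puncta=df[PUNCTA_COLUMNS].reset_index(drop=True),
            roi_area_um2=area,
        )


def log_response(image: Micrograph, radius_um: float) -> np.ndarray:
    """Scale-normalised, negated Laplacian-of-Gaussian response map.

    The filter scale is sigma = radius / sqrt(2) (the radius at which a
    matched Gaussian blob maximises the normalised response), and the
    response is multiplied by sigma^2 so peak height tracks blob amplitude
    rather than blob size.  The Laplacian is the exact 5-point second
    difference of the Gaussian-smoothed image, so constants map to
    exactly zero.  Bright blobs give positive peaks; the operator is
    linear in the input.
    """
    s_um = image.pixel_size_um
    radius_px = radius_um / s_um
    if radius_px < 1.0:
        raise ValueError(
            f"radius {radius_um} µm is {radius_px:.2f} px; the minimum usable "
            f"radius is 1 px ({s_um:.3f} µm)"
        )
    sigma_px = radius_px / math.sqrt(2.0)
    smoothed = ndi.gaussian_filter(image.pixels.astype(np.float64), sigma_px)
    return -(sigma_px**2) * ndi.laplace(smoothed)


def _local_maxima(resp: np.ndarray, min_distance: int) -> tuple[np.ndarray, np.ndarray]:
    """Positive local maxima with at least ``min_distance`` separation.

    Non-maximum suppression via a (2d+1)-square maximum filter: one
    detection per radius-sized neighbourhood, the higher response wins.
    Exact-tie plateaus (equal responses within one neighbourhood) are
    resolved in favour of scan order, keeping the result deterministic.
    """
    footprint = 2 * min_distance + 1
    peaks = (resp >= ndi.maximum_filter(resp, size=footprint, mode="nearest")) & (
        resp > 0
    )
    ii, jj = np.nonzero(peaks)
    q = resp[ii, jj]
    if len(ii) < 2:
        return np.column_stack([ii, jj]), q
    # Two surviving candidates can fall in one neighbourhood only when
    # their responses tie exactly (else the maximum filter would have
    # removed the lower).  Resolve such plateau ties by scan order.
    kept = np.ones(len(ii), dtype=bool)
    _, inverse, counts = np.unique(q, return_inverse=True, return_counts=True)
    d = min_distance
    for v_idx in np.nonzero(counts > 1)[0]:
        members = np.nonzero(inverse == v_idx)[0]  # already in scan order
        occupied: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for k in members:
            i, j = int(ii[k]), int(jj[k])
            cell = (i // d, j // d)
            clash = any(
                abs(i - ki) <= d and abs(j - kj) <= d
                for ci in range(cell[0] - 1, cell[0] + 2)
                for cj in range(cell[1] - 1, cell[1] + 2)
                for ki, kj in occupied.get((ci, cj), ())
            )
            if clash:
                kept[k] = False
            else:
                occupied.setdefault(cell, []).append((i, j))
    return np.column_stack([ii[kept], jj[kept]]), q[kept]


def _quadratic_subpixel(resp: np.ndarray, i: int, j: int) -> tuple[float, float]:
    """Per-axis parabolic interpolation of a peak; offsets clamped to ±0.5."""
    h, w = resp.shape
    di = dj = 0.0
    if 0 < i < h - 1:
        denom = resp[i - 1, j] - 2 * resp[i, j] + resp[i + 1, j]
        if denom < 0:
            di = 0.5 * (resp[i - 1, j] - resp[i + 1, j]) / denom
            di = float(np.clip(di, -0.5, 0.5))
    if 0 < j < w - 1:
        denom = resp[i, j - 1] - 2 * resp[i, j] + resp[i, j + 1]
        if denom < 0:
            dj = 0.5 * (resp[i, j - 1] - resp[i, j + 1]) / denom
            dj = float(np.clip(dj, -0.5, 0.5))
    return di, dj


def detect_puncta(
    image: Micrograph,
    params: DetectionParams,
    roi_mask: np.ndarray | None = None,
    marker: str | None = None,
    region: str = "",
) -> PunctaSet:
    """Detect puncta in one channel, optionally restricted to an ROI mask.

    Pipeline: LoG response -> local maxima with minimum separation of one
    punctum radius -> quality threshold (absolute or auto = mean candidate
    quality) -> optional subpixel refinement -> disc-mean intensity
    threshold -> ROI/border filtering.  Output is deterministically ordered
    by descending quality, ties by scan order.
    """
    s_um = image.pixel_size_um
    radius_px = params.punctum_radius_um / s_um
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if roi_mask.shape != image.pixels.shape:
            raise ValueError(
                f"ROI mask shape {roi_mask.shape} != image shape {image.pixels.shape}"
            )
        area_px = int(roi_mask.sum())
    else:
        area_px = image.pixels.size
    roi_area_um2 = area_px * s_um**2
    marker = image.channel_label if marker is None else marker

    if area_px == 0:
        warnings.warn("empty ROI: returning an empty PunctaSet with area 0")
        return PunctaSet(marker=marker, region=region, roi_area_um2=0.0,
                         pixel_size_nm=image.pixel_size_nm)
    if image.pixels.size and image.pixels.max() >= image.max_value:
        warnings.warn(
            f"image contains saturated pixels (>= {image.max_value}); "
            "intensity measurements may be clipped"
        )

    resp = log_response(image, params.punctum_radius_um)
    min_distance = max(1, int(round(radius_px)))
    coords, qualities = _local_maxima(resp, min_distance)
    if params.exclude_border:
        h, w = resp.shape
        inside = (
            (coords[:, 0] >= min_distance)
            & (coords[:, 0] < h - min_distance)
            & (coords[:, 1] >= min_distance)
            & (coords[:, 1] < w - min_distance)
        )
        coords, qualities = coords[inside], qualities[inside]
    if params.quality_threshold == AUTO:
        q_thr = float(qualities.mean()) if len(qualities) else 0.0
    else:
        q_thr = float(params.quality_threshold)
    keep = qualities >= q_thr
    coords, qualities = coords[keep], qualities[keep]

    rows = []
    for (i, j), q in zip(coords, qualities):
        if roi_mask is not None and not roi_mask[i, j]:
            continue
        di, dj = _quadratic_subpixel(resp, i, j) if params.subpixel else (0.0, 0.0)
        x_um = (j + dj + 0.5) * s_um
        y_um = (i + di + 0.5) * s_um
        try:
            mean_int = measure_intensity(image, (x_um, y_um), params.punctum_radius_um)
        except ValueError:
            continue
        if mean_int < params.intensity_threshold:
            continue
        scan_order = i * image.pixels.shape[1] + j
        rows.append((x_um, y_um, float(q), mean_int, params.punctum_radius_um, scan_order))

    df = pd.DataFrame(rows, columns=[*PUNCTA_COLUMNS, "_scan"])
    df = (
        df.sort_values(["quality", "_scan"], ascending=[False, True], kind="mergesort")
        .drop(columns="_scan")
        .reset_index(drop=True)
    )
    return PunctaSet(
        marker=marker,
        region=region,
        puncta=df,
        roi_area_um2=roi_area_um2,
        pixel_size_nm=image.pixel_size_nm,
    )


def measure_intensity(
    image: Micrograph, centroid_um: tuple[float, float], radius_um: float
) -> float:
    """Mean pixel value over the disc of pixels centred on ``centroid_um``.

    A pixel belongs to the disc when its centre lies within ``radius_um``
    of the centroid.  Raises if the disc contains no pixel centres (fully
    outside the image or radius below half the pixel pitch off-grid).
    """
    s = image.pixel_size_um
    x, y = centroid_um
    cx = x / s - 0.5
    cy = y / s - 0.5
    r_px = radius_um / s
    h, w = image.pixels.shape
    i0 = max(int(math.floor(cy - r_px)), 0)
    i1 = min(int(math.ceil(cy + r_px)) + 1, h)
    j0 = max(int(math.floor(cx - r_px)), 0)
    j1 = min(int(math.ceil(cx + r_px)) + 1, w)
    if i0 >= i1 or j0 >= j1:
        raise ValueError(f"disc at {centroid_um} µm lies outside the image")
    ii = np.arange(i0, i1, dtype=float)
    jj = np.arange(j0, j1, dtype=float)
    mask = (ii[:, None] - cy) ** 2 + (jj[None, :] - cx) ** 2 <= r_px**2
    if not mask.any():
        raise ValueError(
            f"no pixel centres within {radius_um} µm of {centroid_um} µm"
        )
    return float(image.pixels[i0:i1, j0:j1][mask].mean())


def _peak_intensity(image: Micrograph, x_um: float, y_um: float) -> float:
    s = image.pixel_size_um
    h, w = image.pixels.shape
    i = min(max(int(round(y_um / s - 0.5)), 0), h - 1)
    j = min(max(int(round(x_um / s - 0.5)), 0), w - 1)
    return float(image.pixels[i, j])


def compute_snr(
    image: Micrograph,
    puncta: PunctaSet,
    background_mask: np.ndarray | None = None,
) -> float:
    """Signal-to-noise ratio of a labelled field.

    SNR = (mean punctum peak intensity - background mean) / background SD.
    The punctum peak is the pixel value at each detected centroid.  If no
    background mask is supplied, the lowest-decile pixels of the image are
    used as a background proxy.  Returns NaN (with a warning) for an empty
    PunctaSet; raises when the background has zero variance.
    """
    if background_mask is None:
        thr = np.quantile(image.pixels, 0.10)
        background_mask = image.pixels <= thr
    background_mask = np.asarray(background_mask, dtype=bool)
    if background_mask.shape != image.pixels.shape:
        raise ValueError("background mask shape differs from image")
    if not background_mask.any():
        raise ValueError("background mask is empty")
    bg = image.pixels[background_mask]
    bg_sd = float(bg.std(ddof=1)) if bg.size > 1 else 0.0
    if bg_sd == 0.0:
        raise ValueError("background has zero variance; SNR undefined")
    if len(puncta) == 0:
        warnings.warn("empty PunctaSet: SNR undefined, returning NaN")
        return float("nan")
    peaks = [
        _peak_intensity(image, row.x_um, row.y_um)
        for row in puncta.puncta.itertuples(index=False)
    ]
    return (float(np.mean(peaks)) - float(bg.mean())) / bg_sd
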