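"""Published summary tables of the SV2A synaptome survey, bundled as inputs.

These are the printed per-region summary statistics (mean over biological
replicates, with SEM where given) of synaptic puncta density and mean
punctum intensity for a panel of presynaptic and postsynaptic markers, in
nine mouse brain regions and in the six layers of human temporal cortex.
They serve two purposes:

* as the worked-example inputs to the fraction-table and heatmap reports
  (the derived SV2A-fraction tables are pure arithmetic on these values);
* to calibrate the synthetic micrograph generator to realistic density
  and intensity regimes.

Densities are puncta per 100 µm²; intensities are arbitrary units (a.u.).
The colocalization tables give the percentage of each marker's puncta
that contain (presynaptic pairs) or sit adjacent to (pre/post pairs) an
SV2A-positive punctum.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "MOUSE_REGIONS",
    "HUMAN_LAYERS",
    "mouse_density_mean",
    "mouse_density_sem",
    "mouse_intensity_mean",
    "mouse_intensity_sem",
    "mouse_colocalization_mean",
    "human_density_mean",
    "human_density_sem",
    "human_intensity_mean",
    "human_colocalization_mean",
]

MOUSE_REGIONS = [
    "CA1sr", "CA2sr", "CA3sr", "DGpo",
    "SMSL2/3", "SMSL5", "ENTIL4/5", "STRcp", "THpo",
]

HUMAN_LAYERS = ["L1", "L2", "L3", "L4", "L5", "L6"]

MOUSE_PRESYNAPTIC = ["SV2A", "SYP", "SYN", "VGLUT1", "VGAT"]
MOUSE_POSTSYNAPTIC = ["PSD95", "GPHN"]
HUMAN_MARKERS = ["SV2A", "SYP", "PSD95", "GPHN"]


def _table(data: dict[str, list[float]], columns: list[str]) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(data, orient="index", columns=columns, dtype=float)
    df.index.name = "marker"
    return df


# Puncta density (puncta / 100 µm²), mouse, mean over n = 7 animals.
# Columns: nine regions plus the printed cross-region mean.
_MOUSE_DENSITY_COLS = MOUSE_REGIONS + ["Mean"]
_MOUSE_DENSITY_MEAN = {
    "SV2A":   [19, 18, 18, 16, 18, 17, 18, 16, 15, 17],
    "SYP":    [17, 15, 14, 12, 13, 13,  9, 13,  9, 13],
    "SYN":    [17, 14, 11, 11, 12, 12, 14, 13,  8, 12],
    "VGLUT1": [19, 19, 17, 16, 16, 18, 14, 15, 12, 16],
    "VGAT":   [10, 10, 11,  5, 12,  9, 16,  9,  6, 10],
    "PSD95":  [39, 37, 28, 18, 34, 33, 35, 29, 27, 31],
    "GPHN":   [27, 25, 22, 22, 23, 22, 21, 18, 22, 22],
}
_MOUSE_DENSITY_SEM = {
    "SV2A":   [1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
    "SYP":    [3, 3, 3, 1, 1, 1, 6, 4, 4, 3],
    "SYN":    [3, 3, 2, 1, 1, 1, 4, 4, 4, 2],
    "VGLUT1": [1, 3, 3, 3, 2, 3, 1, 1, 1, 2],
    "VGAT":   [3, 4, 3, 2, 3, 1, 3, 1, 2, 2],
    "PSD95":  [1, 2, 3, 3, 1, 1, 1, 4, 1, 2],
    "GPHN":   [1, 1, 2, 1, 1, 1, 3, 2, 1, 1],
}

# Mean punctum intensity (a.u.), mouse.
_MOUSE_INTENSITY_MEAN = {
    "SV2A":   [328, 331, 346, 519, 494, 367, 353, 350, 384, 386],
    "SYP":    [378, 358, 349, 377, 321, 330, 279, 341, 298, 337],
    "SYN":    [395, 375, 378, 487, 373, 324, 385, 381, 366, 385],
    "VGLUT1": [232, 250, 229, 240, 230, 224, 226, 255, 238, 236],
    "VGAT":   [276, 301, 293, 270, 301, 271, 338, 272, 293, 291],
    "PSD95":  [325, 283, 214, 231, 309, 259, 264, 266, 208, 262],
    "GPHN":   [257, 252, 243, 260, 280, 270, 267, 258, 260, 261],
}
_MOUSE_INTENSITY_SEM = {
    "SV2A":   [69, 76, 80, 109, 92, 69, 58, 92, 77, 80],
    "SYP":    [74, 41, 38, 93, 36, 22, 7, 73, 26, 46],
    "SYN":    [76, 68, 94, 111, 39, 24, 99, 89, 101, 78],
    "VGLUT1": [22, 21, 11, 19, 14, 13, 14, 30, 22, 18],
    "VGAT":   [37, 51, 41, 27, 36, 15, 71, 20, 20, 35],
    "PSD95":  [55, 59, 29, 34, 65, 44, 50, 42, 20, 44],
    "GPHN":   [5, 9, 3, 1, 2, 2, 8, 6, 7, 5],
}

# Percentage of each marker's puncta containing / adjacent to SV2A, mouse.
_MOUSE_COLOC_MEAN = {
    "SYP":    [65, 70, 78, 85, 74, 69, 77, 75, 79, 75],
    "SYN":    [57, 49, 62, 80, 56, 51, 57, 62, 69, 60],
    "VGLUT1": [57, 70, 65, 84, 77, 64, 57, 64, 61, 67],
    "VGAT":   [74, 68, 72, 52, 62, 92, 59, 71, 76, 69],
    "PSD95":  [32, 33, 39, 49, 44, 42, 41, 48, 43, 41],
    "GPHN":   [41, 44, 43, 34, 45, 44, 38, 40, 40, 41],
}

# Human temporal cortex (BA20/21), mean over n = 3 cases.
_HUMAN_DENSITY_COLS = HUMAN_LAYERS + ["Mean"]
_HUMAN_DENSITY_MEAN = {
    "SV2A":  [18, 19, 19, 18, 18, 17, 18],
    "SYP":   [20, 21, 22, 20, 20, 19, 21],
    "PSD95": [41, 44, 42, 40, 36, 32, 39],
    "GPHN":  [37, 34, 36, 35, 34, 32, 35],
}
_HUMAN_DENSITY_SEM = {
    "SV2A":  [1, 1, 1, 1, 1, 1, 1],
    "SYP":   [5, 2, 2, 4, 3, 3, 3],
    "PSD95": [3, 3, 4, 2, 3, 1, 3],
    "GPHN":  [8, 4, 3, 5, 9, 8, 6],
}
_HUMAN_INTENSITY_MEAN = {
    "SV2A":  [442, 403, 396, 376, 382, 388, 397],
    "SYP":   [300, 270, 282, 276, 280, 296, 284],
    "PSD95": [321, 327, 321, 292, 275, 256, 299],
    "GPHN":  [277, 266, 262, 259, 247, 235, 258],
}
_HUMAN_COLOC_MEAN = {
    "SYP":   [68, 68, 65, 65, 67, 71, 67],
    "PSD95": [27, 26, 30, 29, 32, 34, 30],
    "GPHN":  [21, 26, 25, 22, 22, 22, 23],
}


def mouse_density_mean() -> pd.DataFrame:
    """Marker × region puncta density means (per 100 µm²), mouse brain."""
    return _table(_MOUSE_DENSITY_MEAN, _MOUSE_DENSITY_COLS)


def mouse_density_sem() -> pd.DataFrame:
    return _table(_MOUSE_DENSITY_SEM, _MOUSE_DENSITY_COLS)


def mouse_intensity_mean() -> pd.DataFrame:
    """Marker × region mean punctum intensity (a.u.), mouse brain."""
    return _table(_MOUSE_INTENSITY_MEAN, _MOUSE_DENSITY_COLS)


def mouse_intensity_sem() -> pd.DataFrame:
    return _table(_MOUSE_INTENSITY_SEM, _MOUSE_DENSITY_COLS)


def mouse_colocalization_mean() -> pd.DataFrame:
    """Percentage of marker puncta SV2A-positive (or SV2A-adjacent), mouse."""
    return _table(_MOUSE_COLOC_MEAN, _MOUSE_DENSITY_COLS)


def human_density_mean() -> pd.DataFrame:
    """Marker × layer puncta density means (per 100 µm²), human cortex."""
    return _table(_HUMAN_DENSITY_MEAN, _HUMAN_DENSITY_COLS)


def human_density_sem() -> pd.DataFrame:
    return _table(_HUMAN_DENSITY_SEM, _HUMAN_DENSITY_COLS)


def human_intensity_mean() -> pd.DataFrame:
    return _table(_HUMAN_INTENSITY_MEAN, _HUMAN_DENSITY_COLS)


def human_colocalization_mean() -> pd.DataFrame:
    return _table(_HUMAN_COLOC_MEAN, _HUMAN_DENSITY_COLS)
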