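"""Published summary tables from an aroid (taro) germplasm
characterisation study, used as worked-example inputs and for
internal-consistency checks.

These are summary statistics as printed (two decimals), not raw data:
the per-marker diversity table for 33 polymorphic SSR markers, the
per-trait genetic-parameter table from a three-replicate randomized
block trial, the three-level AMOVA components, and the landrace shares
of a shifting-cultivation (jhum) field census.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ssr_marker_table",
    "genetic_parameter_table",
    "amova_components",
    "jhum_census_proportions",
]

_SSR_ROWS = [
    # marker, NA, NE, ObsHom, ObsHet, Nei, PIC
    ("Ce1A06", 6, 3.41, 0.98, 0.02, 0.71, 0.51),
    ("Ce1B02", 3, 2.83, 1.00, 0.00, 0.65, 0.36),
    ("Ce1B03", 6, 3.60, 0.83, 0.17, 0.72, 0.61),
    ("Ce1B09", 5, 3.72, 0.66, 0.34, 0.73, 0.59),
    ("Ce1D12", 4, 3.24, 0.79, 0.21, 0.69, 0.51),
    ("Ce1F04", 4, 1.56, 0.88, 0.12, 0.36, 0.13),
    ("Ce1F12", 6, 4.88, 0.41, 0.59, 0.79, 0.73),
    ("Ce1H12", 4, 2.63, 0.91, 0.09, 0.62, 0.50),
    ("AC3", 5, 3.64, 0.98, 0.02, 0.73, 0.60),
    ("HK5", 7, 5.10, 0.33, 0.67, 0.80, 0.76),
    ("HK7", 6, 3.32, 0.74, 0.26, 0.70, 0.61),
    ("HK22", 7, 3.25, 0.33, 0.67, 0.69, 0.62),
    ("HK25", 5, 3.85, 0.50, 0.50, 0.74, 0.67),
    ("HK26", 7, 4.04, 0.53, 0.47, 0.75, 0.70),
    ("HK29", 6, 3.48, 0.88, 0.12, 0.71, 0.62),
    ("HK31", 5, 1.83, 0.59, 0.41, 0.45, 0.37),
    ("HK34", 8, 5.09, 0.16, 0.84, 0.80, 0.74),
    ("HK-35", 5, 3.83, 0.52, 0.48, 0.74, 0.66),
    ("HK38", 5, 2.82, 0.98, 0.02, 0.65, 0.54),
    ("Taro01", 5, 4.36, 1.00, 0.00, 0.77, 0.65),
    ("Taro03", 3, 2.94, 1.00, 0.00, 0.66, 0.37),
    ("Taro04", 4, 3.74, 0.98, 0.02, 0.73, 0.59),
    ("Taro11", 4, 2.85, 1.00, 0.00, 0.65, 0.45),
    ("Taro12", 4, 3.36, 0.97, 0.03, 0.70, 0.52),
    ("Taro13", 4, 2.29, 1.00, 0.00, 0.56, 0.32),
    ("Taro14", 6, 5.55, 0.21, 0.79, 0.82, 0.74),
    ("Taro19", 4, 2.59, 1.00, 0.00, 0.61, 0.40),
    ("Xuqtem-84", 7, 4.79, 0.88, 0.12, 0.79, 0.69),
    ("Xuqtem-110", 4, 3.55, 1.00, 0.00, 0.72, 0.54),
    ("Xuqtem-73", 3, 1.94, 0.81, 0.19, 0.48, 0.23),
    ("Xuqtem-55", 5, 4.86, 0.31, 0.69, 0.79, 0.69),
    ("Xuqtem-88", 6, 4.93, 1.00, 0.00, 0.80, 0.72),
    ("Xuqtem-91", 4, 3.00, 1.00, 0.00, 0.67, 0.41),
]

#: printed column means of the marker table
SSR_PRINTED_MEANS = {
    "NA": 5.06,
    "NE": 3.54,
    "Obs Hom": 0.76,
    "Obs Het": 0.24,
    "Nei": 0.69,
    "PIC": 0.55,
}


def ssr_marker_table() -> pd.DataFrame:
    """Per-marker diversity statistics for the 33 polymorphic SSR loci."""
    return pd.DataFrame(
        _SSR_ROWS, columns=["Marker", "NA", "NE", "Obs Hom", "Obs Het", "Nei", "PIC"]
    ).set_index("Marker")


_TRAITS = [
    "Plant height (cm)",
    "Petiole length (cm)",
    "No. of side shoots",
    "Average corm wt. (g)",
    "Average cormel wt. (g)",
    "Yield/plant (kg)",
    "Total sugars (%)",
    "Starch (%)",
    "Oxalate (%)",
    "Dry matter (%)",
]

_GENPAR_ROWS = {
    "Mean": [118.65, 89.35, 3.71, 249.21, 48.14, 0.93, 3.26, 21.65, 0.20, 21.68],
    "GCV": [16.46, 22.14, 24.54, 61.26, 116.90, 39.26, 22.63, 16.14, 32.72, 11.78],
    "PCV": [16.80, 22.33, 27.67, 62.84, 117.19, 40.11, 23.09, 16.54, 48.39, 11.92],
    "h2": [95.91, 98.27, 78.61, 95.03, 99.51, 95.78, 96.06, 95.20, 45.73, 97.70],
    "GA": [39.39, 40.39, 1.66, 306.61, 115.63, 0.75, 1.49, 7.02, 0.09, 5.20],
    "GAM": [33.20, 45.21, 44.81, 123.03, 240.22, 79.01, 45.70, 32.45, 45.59, 23.98],
}


def genetic_parameter_table() -> pd.DataFrame:
    """Per-trait genetic parameters (mean, GCV, PCV, h2, GA, GAM) as
    printed for the replicated trial."""
    return pd.DataFrame(_GENPAR_ROWS, index=_TRAITS).T


def amova_components() -> pd.DataFrame:
    """Printed AMOVA design: df, sums of squares, variance components and
    percent variation for the three strata (average over 33 loci)."""
    rows = [
        ("among_populations", 6, 190.98, 1.26, 10.43),
        ("among_individuals_within", 51, 904.07, 6.90, 57.11),
        ("within_individuals", 58, 227.50, 3.92, 32.46),
    ]
    return pd.DataFrame(
        rows, columns=["source", "df", "SS", "variance_component", "percent"]
    ).set_index("source")


def jhum_census_proportions() -> np.ndarray:
    """Landrace shares of the jhum-field census: the three named dominant
    landraces held 47%, 36% and 12%; the 5% residual is split evenly
    among the remaining three recorded landraces (reconstruction
    convention)."""
    return np.array([0.47, 0.36, 0.12, 0.0167, 0.0167, 0.0166])
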