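"""Published BigBrain cerebellar reference measurements.

The lobule-wise morphometry table published for the BigBrain cerebellum
(20 um histological volume): raw (uncorrected) pial surface area, grey-matter
volume and laminar thickness mean +- std per lobule, plus its printed totals.
These printed numbers serve as *inputs* for the arithmetic this package
recomputes — shrinkage-corrected totals, cerebellar/cerebral area ratio,
regional thickness averages — without access to the 62 GB source volume.

All thicknesses in mm, areas in mm^2, volumes in mm^3, uncorrected for
shrinkage unless stated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .morphometry import ShrinkageFactor, correct_shrinkage

#: linear shrinkage of the histological preparation (dimensionless)
BIGBRAIN_SHRINKAGE = ShrinkageFactor(linear=1.245)

#: published cerebral pial area of the same specimen, uncorrected, cm^2
CEREBRAL_AREA_RAW_CM2 = 1848.0

#: published shrinkage-corrected cerebellar pial area, cm^2
CEREBELLAR_AREA_CORRECTED_CM2 = 1945.0

_TABLE_ROWS = [
    # lobule, area mm^2, GM volume mm^3, granular mean, std, molecular mean, std
    ("Lobules I, II",   230,    95,     0.13, 0.18, 0.36, 0.11),
    ("Lobule III",      1425,   617,    0.29, 0.31, 0.23, 0.10),
    ("Lobule IV",       6101,   2333.7, 0.41, 0.35, 0.34, 0.09),
    ("Lobule V",        6986,   2919.68, 0.40, 0.30, 0.34, 0.08),
    ("Lobule VI",       20551,  8476,   0.61, 0.54, 0.33, 0.08),
    ("Crus I",          27801,  11253,  1.04, 0.95, 0.32, 0.08),
    ("Crus II",         32611,  12608,  1.09, 0.96, 0.31, 0.08),
    ("Lobule VIIB",     6016,   2742,   1.11, 0.93, 0.30, 0.08),
    ("Lobule VIIIA",    6732,   2959,   1.03, 0.85, 0.30, 0.08),
    ("Lobule VIIIB",    6630,   2890,   1.01, 0.84, 0.30, 0.09),
    ("Lobule IX",       5806,   2401,   1.08, 1.09, 0.30, 0.08),
    ("Lobule X",        1079,   359,    0.67, 1.04, 0.17, 0.08),
    ("Vermis VIII",     2262,   996,    0.53, 0.41, 0.35, 0.08),
    ("Vermis IX",       840,    417,    0.67, 0.62, 0.33, 0.09),
    ("Vermis X",        433,    140,    0.35, 0.37, 0.27, 0.09),
]

#: printed totals row (note: the printed column sums differ slightly — see
#: :func:`lobule_table` for recomputed sums)
PUBLISHED_TOTALS = {"area_mm2": 125576.0, "gm_volume_mm3": 51252.0,
                    "granular_mean_mm": 0.88, "granular_std_mm": 0.84,
                    "molecular_mean_mm": 0.32, "molecular_std_mm": 0.08}


def lobule_table() -> pd.DataFrame:
    """The published per-lobule table as a DataFrame (no totals row)."""
    return pd.DataFrame(
        _TABLE_ROWS,
        columns=["lobule", "area_mm2", "gm_volume_mm3",
                 "granular_mean_mm", "granular_std_mm",
                 "molecular_mean_mm", "molecular_std_mm"],
        index=pd.RangeIndex(1, len(_TABLE_ROWS) + 1, name="lobule_id"),
    )


def corrected_cerebral_area_cm2(factor: ShrinkageFactor = BIGBRAIN_SHRINKAGE) -> float:
    """Shrinkage-corrected cerebral pial area of the specimen, cm^2."""
    return correct_shrinkage(CEREBRAL_AREA_RAW_CM2, factor, dimensionality=2)


def cerebellar_cerebral_ratio_pct() -> float:
    """Cerebellar/cerebral pial area ratio, % (corrected areas)."""
    return 100.0 * CEREBELLAR_AREA_CORRECTED_CM2 / corrected_cerebral_area_cm2()


def total_cortical_thickness_mm() -> float:
    """Mean whole-cortex thickness: sum of the two laminar totals."""
    return PUBLISHED_TOTALS["granular_mean_mm"] + PUBLISHED_TOTALS["molecular_mean_mm"]


def granular_share_pct() -> float:
    """Granular contribution to total cortical thickness, %."""
    return 100.0 * PUBLISHED_TOTALS["granular_mean_mm"] / total_cortical_thickness_mm()


_REGIONS = {
    "anterior_I_V": ["Lobules I, II", "Lobule III", "Lobule IV", "Lobule V"],
    "posterior_VI_VIII": ["Lobule VI", "Crus I", "Crus II", "Lobule VIIB",
                          "Lobule VIIIA", "Lobule VIIIB"],
    "inferior_IX_X": ["Lobule IX", "Lobule X"],
}


def regional_granular_means() -> dict[str, float]:
    """Unweighted regional averages of the granular-layer lobule means, mm
    (anterior lobules I–V, posterior VI–VIII, flocculonodular IX–X)."""
    table = lobule_table().set_index("lobule")
    return {region: float(np.mean([table.loc[name, "granular_mean_mm"] for name in names]))
            for region, names in _REGIONS.items()}
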