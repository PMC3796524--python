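"""Univariate ecomorphological measurements on murine M1s.

These are the microscope-style measurements that discriminate the two
Siwalik clades: tooth size as ln(length x width), the VD grazing index
(tooth width over the anteroposterior gap between lingual anterocone and
protocone), the roundness of the anterostyle (minor/major axis ratio of the
ellipse-shaped cusp: ~1 round, <1 oval), and the acute angles that the
anterostyle's major axis and the protocone-enterostyle line make with the
longitudinal reference axis of the tooth (the chord through landmarks 8 and
16).  Cusp centers and ellipse axes are measured inputs, not derived from
the outline landmarks: the protocone lies interior to the outline and these
features are measured directly on the specimen.

All metrics are invariant to rigid motion; the VD index and anterostyle
ratio are additionally scale-invariant, while ln-area deliberately is not
(it proxies body mass).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry_io import LandmarkConfiguration, LandmarkScheme

__all__ = [
    "DentalMetrics",
    "reference_axis",
    "ln_tooth_area",
    "vd_index",
    "anterostyle_ratio",
    "acute_angle",
    "metrics_table",
]


@dataclass
class DentalMetrics:
    length_mm: float
    width_mm: float
    ln_area: float
    vd_index: float
    anterostyle_ratio: float
    anterostyle_angle_deg: float
    enterostyle_angle_deg: float


def reference_axis(
    config: LandmarkConfiguration | np.ndarray,
    scheme: LandmarkScheme,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit direction and anchor of the tooth's longitudinal axis.

    The axis runs through the scheme's two axis landmarks (8 -> 16 in the
    default scheme), following the labial reference line convention.
    """
    pts = config.points if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    a, b = scheme.axis0
    vec = pts[b] - pts[a]
    norm = np.linalg.norm(vec)
    if norm == 0:
        raise ValueError("axis landmarks coincide")
    return vec / norm, pts[a].copy()


def ln_tooth_area(length_mm: float, width_mm: float) -> float:
    """Natural logarithm of occlusal area, ln(length x width); the size proxy."""
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("length and width must be positive")
    return float(np.log(length_mm * width_mm))


def vd_index(width_mm: float, anterocone_protocone_distance_mm: float) -> float:
    """VD grazing index: tooth width / anteroposterior anterocone-protocone gap.

    Greater values mean a narrower space between the chevrons, the
    grazing-adapted condition.
    """
    if width_mm <= 0:
        raise ValueError("width must be positive")
    if anterocone_protocone_distance_mm <= 0:
        raise ValueError("anterocone-protocone distance must be positive")
    return float(width_mm / anterocone_protocone_distance_mm)


def anterostyle_ratio(minor_axis_mm: float, major_axis_mm: float) -> float:
    """Minor/major axis ratio of the ellipse-shaped anterostyle cusp (<= 1)."""
    if minor_axis_mm <= 0 or major_axis_mm <= 0:
        raise ValueError("axis lengths must be positive")
    if minor_axis_mm > major_axis_mm:
        raise ValueError("minor axis exceeds major axis")
    return float(minor_axis_mm / major_axis_mm)


def acute_angle(axis_direction: np.ndarray, feature_direction: np.ndarray) -> float:
    """Acute angle in degrees between two directions, in [0, 90]."""
    u = np.asarray(axis_direction, float)
    v = np.asarray(feature_direction, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-length direction vector")
    cosang = abs(float(u @ v) / (nu * nv))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


def metrics_table(
    configs,
    measurements: pd.DataFrame,
    scheme: LandmarkScheme,
) -> pd.DataFrame:
    """Assemble the per-specimen dental-metrics table.

    *measurements* must carry the microscope measurements by specimen_id:
    length_mm, width_mm, anterocone_protocone_mm, anterostyle_minor_mm,
    anterostyle_major_mm, anterostyle_dir_x/y, protocone_x/y,
    enterostyle_x/y.  Angles are reported to 0.01 degree.
    """
    meas = measurements.set_index("specimen_id")
    rows = []
    for cfg in configs:
        m = meas.loc[cfg.specimen_id]
        axis_dir, _ = reference_axis(cfg, scheme)
        astyle_dir = np.array([m["anterostyle_dir_x"], m["anterostyle_dir_y"]])
        ent_dir = np.array(
            [m["enterostyle_x"] - m["protocone_x"], m["enterostyle_y"] - m["protocone_y"]]
        )
        rows.append(
            {
                "specimen_id": cfg.specimen_id,
                "species_label": cfg.species_label,
                "age_Ma": cfg.age_ma,
                "clade": cfg.clade,
                "length_mm": float(m["length_mm"]),
                "width_mm": float(m["width_mm"]),
                "ln_area": ln_tooth_area(m["length_mm"], m["width_mm"]),
                "vd_index": vd_index(m["width_mm"], m["anterocone_protocone_mm"]),
                "anterostyle_ratio": anterostyle_ratio(
                    m["anterostyle_minor_mm"], m["anterostyle_major_mm"]
                ),
                "anterostyle_angle_deg": round(acute_angle(axis_dir, astyle_dir), 2),
                "enterostyle_angle_deg": round(acute_angle(axis_dir, ent_dir), 2),
            }
        )
    return pd.DataFrame(rows)
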