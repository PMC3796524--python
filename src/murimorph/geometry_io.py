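"""Landmark data input/output for 2D tooth-outline configurations.

The analysis works on upper-first-molar (M1) outlines digitized as 16
ordered points: 7 fixed landmarks at curvature maxima associated with cusps
and inter-cusp valleys, plus 9 sliding semilandmarks along the anterior
outline.  This module defines the landmark scheme, the per-specimen
configuration container, and readers/writers for the tpsDig TPS dialect and
a flat CSV table so that real and simulated data enter the pipeline through
the same door.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkScheme",
    "LandmarkConfiguration",
    "default_scheme",
    "OUTLINE_ORDER",
    "read_tps",
    "write_tps",
    "apply_reflection",
    "configs_to_frame",
    "frame_to_configs",
]

#: Outline traversal order of the 16 landmarks (1-based indices).  The nine
#: semilandmarks (8-16) interleave with the fixed landmarks (1-7) along the
#: tooth margin; landmarks 8 and 16 sit on the labial side and define the
#: longitudinal reference axis.
OUTLINE_ORDER: tuple[int, ...] = (8, 9, 10, 1, 11, 12, 2, 13, 14, 3, 15, 4, 5, 16, 6, 7)

CLADES = ("Karnimata", "Progonomys", "other")


class TPSParseError(ValueError):
    """Raised when a TPS record cannot be parsed."""


@dataclass(frozen=True)
class LandmarkScheme:
    """Fixed/sliding landmark scheme for one configuration layout.

    Indices are 1-based, following the conventional landmark numbering on
    published figures.  ``curve_neighbors`` maps each sliding semilandmark to
    the two outline points that bracket it; the chord between them defines
    the local tangent used during sliding.  ``axis_points`` are the two
    landmarks whose chord is the longitudinal reference axis of the tooth.
    """

    n_points: int = 16
    fixed_indices: tuple[int, ...] = tuple(range(1, 8))
    sliding_indices: tuple[int, ...] = tuple(range(8, 17))
    curve_neighbors: Mapping[int, tuple[int, int]] = field(default_factory=dict)
    axis_points: tuple[int, int] = (8, 16)
    outline_order: tuple[int, ...] = OUTLINE_ORDER

    def __post_init__(self):
        fixed = set(self.fixed_indices)
        sliding = set(self.sliding_indices)
        if fixed & sliding:
            raise ValueError("fixed and sliding index sets overlap")
        if fixed | sliding != set(range(1, self.n_points + 1)):
            raise ValueError("fixed+sliding must cover 1..n_points exactly")
        if not self.curve_neighbors:
            object.__setattr__(
                self, "curve_neighbors", _neighbors_from_order(self.outline_order, sliding)
            )
        for s in self.sliding_indices:
            if s not in self.curve_neighbors:
                raise ValueError(f"sliding index {s} has no curve neighbors")
            a, b = self.curve_neighbors[s]
            if a == b or not (1 <= a <= self.n_points and 1 <= b <= self.n_points):
                raise ValueError(f"invalid neighbors {a, b} for sliding index {s}")
        a, b = self.axis_points
        if a == b or not (1 <= a <= self.n_points and 1 <= b <= self.n_points):
            raise ValueError("axis_points must be two distinct valid indices")

    # 0-based convenience views -------------------------------------------------
    @property
    def sliding0(self) -> np.ndarray:
        return np.asarray(self.sliding_indices, dtype=int) - 1

    @property
    def axis0(self) -> tuple[int, int]:
        return self.axis_points[0] - 1, self.axis_points[1] - 1

    def neighbors0(self, sliding_index: int) -> tuple[int, int]:
        a, b = self.curve_neighbors[sliding_index]
        return a - 1, b - 1


def _neighbors_from_order(order: Sequence[int], sliding: set[int]) -> dict[int, tuple[int, int]]:
    order = list(order)
    n = len(order)
    out = {}
    for pos, idx in enumerate(order):
        if idx in sliding:
            out[idx] = (order[(pos - 1) % n], order[(pos + 1) % n])
    return out


def default_scheme() -> LandmarkScheme:
    """The 16-point M1 scheme: 7 fixed landmarks, 9 sliding, axis 8-16."""
    return LandmarkScheme()


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2D landmark configuration plus metadata.

    Coordinates are in the units the TPS SCALE factor yields (mm for real
    data); downstream shape statistics are scale-free after superimposition
    but the dental metrics need true units.
    """

    points: np.ndarray
    specimen_id: str
    species_label: str = ""
    age_ma: float = float("nan")
    clade: str = "other"
    side_reflected: bool = False
    scale_present: bool = True

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be a (k, 2) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError(f"non-finite coordinates in specimen {self.specimen_id!r}")
        # coincident points break tangent directions and the TPS kernel
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if np.min(d) <= 0.0:
            raise ValueError(f"coincident landmarks in specimen {self.specimen_id!r}")
        self.points = pts

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def validate_scheme(self, scheme: LandmarkScheme) -> None:
        if self.n_points != scheme.n_points:
            raise ValueError(
                f"specimen {self.specimen_id!r} has {self.n_points} points, "
                f"scheme expects {scheme.n_points}"
            )

    def copy_with(self, **changes) -> "LandmarkConfiguration":
        return dataclasses.replace(self, **changes)


def apply_reflection(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Mirror a configuration across the y-axis (antimere correction).

    Negates x-coordinates, keeps point order, and toggles ``side_reflected``.
    Applying twice restores the original configuration.
    """
    pts = config.points.copy()
    pts[:, 0] = -pts[:, 0]
    return config.copy_with(points=pts, side_reflected=not config.side_reflected)


# ---------------------------------------------------------------------------
# TPS format (tpsDig dialect: LM=, coordinate lines, ID=, IMAGE=, SCALE=)
# ---------------------------------------------------------------------------

def read_tps(path, scheme: LandmarkScheme | None = None) -> list[LandmarkConfiguration]:
    """Read landmark configurations from a TPS file.

    Coordinates are multiplied by the record's SCALE factor when present.
    CURVES/POINTS blocks are ignored (semilandmarks are stored as ordinary
    landmarks).  Raises :class:`TPSParseError` naming the record index on a
    malformed record; point-count mismatches against *scheme* raise
    ``ValueError``.
    """
    text = Path(path).read_text()
    records: list[LandmarkConfiguration] = []
    lines = [ln.strip() for ln in text.splitlines()]
    i, rec_index = 0, 0
    while i < len(lines):
        line = lines[i]
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TPSParseError(f"record {rec_index}: expected LM=, got {line!r}")
        try:
            n_lm = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSParseError(f"record {rec_index}: bad LM= line {line!r}") from exc
        i += 1
        coords = []
        while len(coords) < n_lm and i < len(lines):
            ln = lines[i]
            if not ln or "=" in ln:
                break
            parts = ln.split()
            if len(parts) != 2:
                raise TPSParseError(f"record {rec_index}: bad coordinate line {ln!r}")
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise TPSParseError(f"record {rec_index}: bad coordinate line {ln!r}") from exc
            i += 1
        if len(coords) != n_lm:
            raise TPSParseError(
                f"record {rec_index}: expected {n_lm} coordinate pairs, got {len(coords)}"
            )
        spec_id, scale, scale_present = f"record_{rec_index}", 1.0, False
        # trailing key=value lines up to the next LM=
        while i < len(lines):
            ln = lines[i]
            if not ln:
                i += 1
                continue
            up = ln.upper()
            if up.startswith("LM="):
                break
            if "=" not in ln:
                raise TPSParseError(f"record {rec_index}: unexpected line {ln!r}")
            key, val = ln.split("=", 1)
            key = key.strip().upper()
            if key == "ID":
                spec_id = val.strip()
            elif key == "SCALE":
                try:
                    scale = float(val)
                except ValueError as exc:
                    raise TPSParseError(f"record {rec_index}: bad SCALE {val!r}") from exc
                scale_present = True
            # IMAGE=, CURVES=, POINTS= and anything else: ignored
            i += 1
        pts = np.asarray(coords, dtype=float) * scale
        cfg = LandmarkConfiguration(points=pts, specimen_id=spec_id, scale_present=scale_present)
        if scheme is not None:
            cfg.validate_scheme(scheme)
        records.append(cfg)
        rec_index += 1
    return records


def write_tps(configs: Sequence[LandmarkConfiguration], path) -> None:
    """Write configurations as TPS records (LM=, coordinates, ID=).

    Coordinates are written at full precision (repr round-trip faithful).
    """
    if len(configs) == 0:
        raise ValueError("cannot write an empty configuration list")
    out = []
    for cfg in configs:
        out.append(f"LM={cfg.n_points}")
        for x, y in cfg.points:
            out.append(f"{float(x)!r} {float(y)!r}")
        out.append(f"ID={cfg.specimen_id}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Tabular interchange (CSV with specimen metadata + x1..y16 columns)
# ---------------------------------------------------------------------------

def configs_to_frame(
    configs: Sequence[LandmarkConfiguration],
    extra: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Flatten configurations to a tidy table (one row per specimen).

    Columns: specimen_id, species_label, age_Ma, clade, side_reflected,
    x1..xk, y1..yk, joined (on specimen_id) with any *extra* measurement
    columns.
    """
    rows = []
    for cfg in configs:
        row = {
            "specimen_id": cfg.specimen_id,
            "species_label": cfg.species_label,
            "age_Ma": cfg.age_ma,
            "clade": cfg.clade,
            "side_reflected": cfg.side_reflected,
        }
        for j, (x, y) in enumerate(cfg.points, start=1):
            row[f"x{j}"] = x
            row[f"y{j}"] = y
        rows.append(row)
    df = pd.DataFrame(rows)
    if extra is not None:
        extra = extra.drop(columns=[c for c in extra.columns if c in df.columns and c != "specimen_id"])
        df = df.merge(extra, on="specimen_id", how="left")
    return df


def frame_to_configs(df: pd.DataFrame, scheme: LandmarkScheme) -> list[LandmarkConfiguration]:
    """Rebuild configurations from a table produced by :func:`configs_to_frame`."""
    k = scheme.n_points
    xcols = [f"x{j}" for j in range(1, k + 1)]
    ycols = [f"y{j}" for j in range(1, k + 1)]
    missing = [c for c in xcols + ycols if c not in df.columns]
    if missing:
        raise ValueError(f"table is missing coordinate columns: {missing[:4]}...")
    configs = []
    for _, row in df.iterrows():
        pts = np.column_stack([row[xcols].to_numpy(float), row[ycols].to_numpy(float)])
        cfg = LandmarkConfiguration(
            points=pts,
            specimen_id=str(row["specimen_id"]),
            species_label=str(row.get("species_label", "")),
            age_ma=float(row.get("age_Ma", np.nan)),
            clade=str(row.get("clade", "other")),
            side_reflected=bool(row.get("side_reflected", False)),
        )
        cfg.validate_scheme(scheme)
        configs.append(cfg)
    return configs
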