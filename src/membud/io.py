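"""CSV round-tripping for the pipeline's tabular formats.

One dialect everywhere: comma-separated, header row, UTF-8, dot decimal,
no index column.  Schemas:

* radius tables      — vesicle_id, R_alpha_um, R_beta_um
* deformation series — t_s, a_um, b_um, uv_on (0/1)
* contours           — vesicle_id, point_index, x_um, y_um
* elution traces     — volume_mL, absorbance_AU
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .deformation import Contour, DeformationSeries
from .partitioning import ElutionTrace

__all__ = [
    "read_radius_table",
    "write_radius_table",
    "read_deformation_series",
    "write_deformation_series",
    "read_contours",
    "write_contours",
    "read_elution_trace",
    "write_elution_trace",
]

_RADIUS_COLS = ["vesicle_id", "R_alpha_um", "R_beta_um"]
_SERIES_COLS = ["t_s", "a_um", "b_um", "uv_on"]
_CONTOUR_COLS = ["vesicle_id", "point_index", "x_um", "y_um"]
_TRACE_COLS = ["volume_mL", "absorbance_AU"]


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing column(s) {missing}; expected schema {cols}, "
            f"found {list(df.columns)}"
        )


def read_radius_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, _RADIUS_COLS, path)
    bad = df.index[~(df["R_alpha_um"] >= df["R_beta_um"]) | (df["R_beta_um"] <= 0)]
    if len(bad):
        row = int(bad[0])
        raise ValueError(
            f"{path} row {row} (vesicle {df.loc[row, 'vesicle_id']!r}): "
            "requires R_alpha_um >= R_beta_um > 0"
        )
    return df[_RADIUS_COLS]


def write_radius_table(df: pd.DataFrame, path: str | Path) -> None:
    df[_RADIUS_COLS].to_csv(path, index=False)


def read_deformation_series(path: str | Path) -> DeformationSeries:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, _SERIES_COLS, path)
    return DeformationSeries.from_dataframe(df)


def write_deformation_series(series: DeformationSeries, path: str | Path) -> None:
    series.to_dataframe().to_csv(path, index=False)


def read_contours(path: str | Path, shape_label: str = "ellipse") -> dict[str, Contour]:
    """All contours in a file, keyed by vesicle_id, points ordered by point_index."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, _CONTOUR_COLS, path)
    out: dict[str, Contour] = {}
    for vid, grp in df.groupby("vesicle_id", sort=False):
        grp = grp.sort_values("point_index")
        out[str(vid)] = Contour(
            points=np.column_stack([grp["x_um"], grp["y_um"]]),
            shape_label=shape_label,  # type: ignore[arg-type]
        )
    return out


def write_contours(contours: dict[str, Contour], path: str | Path) -> None:
    rows = []
    for vid, c in contours.items():
        for i, (x, y) in enumerate(c.points):
            rows.append(dict(vesicle_id=vid, point_index=i, x_um=x, y_um=y))
    pd.DataFrame(rows, columns=_CONTOUR_COLS).to_csv(path, index=False)


def read_elution_trace(path: str | Path) -> ElutionTrace:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, _TRACE_COLS, path)
    return ElutionTrace.from_dataframe(df)


def write_elution_trace(trace: ElutionTrace, path: str | Path) -> None:
    trace.to_dataframe().to_csv(path, index=False)
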