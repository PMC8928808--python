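"""CSV/JSON round-trips for the analysis inputs and outputs.

Schemas (all plain CSV, distances in um, curvatures in 1/um):

* contours — ``x_um, y_um[, contour_id]``
* curvature samples — ``arc_position_um, kappa_um_inv, regime``
* intensity profiles — ``distance_um, value, channel[, cell_id]``
* sigmoid fit points — ``curvature_um_inv, response[, n_trials]``
* rupture cohorts (long format) — ``cell_id, pore_diameter_um, n_sites,
  condition[, site_curvature_um_inv]``
* dilution measures — ``cell_id, channel, geometry, phi``

Fits serialise to JSON via :meth:`SigmoidFit.to_json`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .contour_geometry import Contour, CurvatureSample
from .filament_model import SigmoidFit
from .intensity_metrics import Channel, DilutionMeasure, IntensityProfile
from .rupture_stats import RuptureRecord

__all__ = [
    "read_contours",
    "write_contour",
    "write_curvature_samples",
    "read_profiles",
    "write_profiles",
    "read_fit_points",
    "write_fit_points",
    "read_cohort",
    "write_cohort",
    "write_dilution_measures",
    "read_sigmoid_fit",
    "write_sigmoid_fit",
]


class SchemaError(ValueError):
    """Input CSV does not match the expected column schema."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}; found {list(df.columns)}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")


def read_contours(path, closed: bool = True) -> dict[str, Contour]:
    df = pd.read_csv(path)
    _require_columns(df, ["x_um", "y_um"], path)
    if "contour_id" not in df.columns:
        df = df.assign(contour_id="contour0")
    out = {}
    for cid, grp in df.groupby("contour_id", sort=False):
        out[str(cid)] = Contour(grp[["x_um", "y_um"]].to_numpy(float), closed=closed)
    return out


def write_contour(path, contour: Contour, contour_id: str = "contour0") -> None:
    pd.DataFrame(
        {
            "x_um": contour.points[:, 0],
            "y_um": contour.points[:, 1],
            "contour_id": contour_id,
        }
    ).to_csv(path, index=False)


def write_curvature_samples(path, samples: Sequence[CurvatureSample]) -> None:
    pd.DataFrame(
        {
            "arc_position_um": [s.arc_position for s in samples],
            "kappa_um_inv": [s.curvature_kappa for s in samples],
            "regime": [s.regime.value for s in samples],
        }
    ).to_csv(path, index=False)


def read_profiles(path) -> dict[tuple[str, Channel], IntensityProfile]:
    df = pd.read_csv(path)
    _require_columns(df, ["distance_um", "value", "channel"], path)
    if "cell_id" not in df.columns:
        df = df.assign(cell_id="cell0")
    out = {}
    for (cid, ch), grp in df.groupby(["cell_id", "channel"], sort=False):
        grp = grp.sort_values("distance_um")
        out[(str(cid), Channel(ch))] = IntensityProfile(
            grp["distance_um"].to_numpy(float), grp["value"].to_numpy(float), Channel(ch)
        )
    return out


def write_profiles(path, profiles: dict, cell_id: str = "cell0") -> None:
    frames = []
    for key, prof in profiles.items():
        cid = cell_id if isinstance(key, Channel) else key[0]
        frames.append(
            pd.DataFrame(
                {
                    "distance_um": prof.distance,
                    "value": prof.value,
                    "channel": prof.channel.value,
                    "cell_id": cid,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_fit_points(path) -> np.ndarray:
    df = pd.read_csv(path)
    _require_columns(df, ["curvature_um_inv", "response"], path)
    cols = ["curvature_um_inv", "response"]
    if "n_trials" in df.columns:
        cols.append("n_trials")
    return df[cols].to_numpy(float)


def write_fit_points(path, points) -> None:
    arr = np.atleast_2d(np.asarray(points, float))
    cols = ["curvature_um_inv", "response", "n_trials"][: arr.shape[1]]
    pd.DataFrame(arr, columns=cols).to_csv(path, index=False)


def read_cohort(path) -> list[RuptureRecord]:
    df = pd.read_csv(path)
    _require_columns(df, ["cell_id", "n_sites"], path)
    if "condition" not in df.columns:
        df = df.assign(condition="untreated")
    if "pore_diameter_um" not in df.columns:
        df = df.assign(pore_diameter_um=np.nan)
    has_sites = "site_curvature_um_inv" in df.columns
    records = []
    for cid, grp in df.groupby("cell_id", sort=False):
        row = grp.iloc[0]
        sites: tuple[float, ...] = ()
        if has_sites:
            vals = grp["site_curvature_um_inv"].dropna().to_numpy(float)
            sites = tuple(vals)
        d = float(row["pore_diameter_um"])
        records.append(
            RuptureRecord(
                cell_id=str(cid),
                n_sites=int(row["n_sites"]),
                imposed_curvature=(2.0 / d if np.isfinite(d) and d > 0 else None),
                site_curvatures=sites,
                condition=str(row["condition"]),
            )
        )
    return records


def write_cohort(path, records: Sequence[RuptureRecord]) -> None:
    rows = []
    for r in records:
        d = 2.0 / r.imposed_curvature if r.imposed_curvature else np.nan
        if r.site_curvatures:
            for k in r.site_curvatures:
                rows.append((r.cell_id, d, r.n_sites, r.condition, k))
        else:
            rows.append((r.cell_id, d, r.n_sites, r.condition, np.nan))
    pd.DataFrame(
        rows,
        columns=["cell_id", "pore_diameter_um", "n_sites", "condition", "site_curvature_um_inv"],
    ).to_csv(path, index=False)


def write_dilution_measures(path, measures: dict[str, DilutionMeasure]) -> None:
    pd.DataFrame(
        {
            "cell_id": list(measures),
            "channel": [m.channel.value for m in measures.values()],
            "geometry": [m.geometry.value for m in measures.values()],
            "phi": [m.phi for m in measures.values()],
        }
    ).to_csv(path, index=False)


def read_sigmoid_fit(path) -> SigmoidFit:
    return SigmoidFit.from_json(Path(path).read_text())


def write_sigmoid_fit(path, fit: SigmoidFit) -> None:
    Path(path).write_text(fit.to_json() + "\n")
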