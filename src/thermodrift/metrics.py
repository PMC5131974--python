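"""Advective temperature differential maps and the atlas product.

The headline metric is the advective temperature differential
ΔT_opt = T_opt(a) − T_opt(na): the optimum temperature of the most abundant
species in a simulation with advection minus that from an otherwise
identical simulation without advection, time-averaged per cell. Poleward
western boundary currents carry warm-selected populations into cooler
water (positive ΔT_opt); equatorward return flows carry cold-selected
populations toward the equator (negative ΔT_opt).

The atlas bundles, per ocean cell and per population-average growth rate:
T_opt(a), T_opt(na), ΔT_opt, the two historical temperatures, the
historical differential ΔT_hist(s) = T_hist(s) − T_loc, the time-mean local
temperature and poleward velocity. Column names encode the growth rate as
a 3-digit suffix of hundredths, e.g. ``TOPTA028`` is T_opt(a) at
0.28 d⁻¹.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .fields import ForcingSeries, OceanGrid
from .simulate import SimulationOutput

__all__ = [
    "DifferentialAtlas",
    "most_abundant_topt",
    "advective_differential",
    "poleward_velocity_map",
    "write_atlas",
    "load_atlas",
    "rate_suffix",
    "parse_rate_suffix",
]

ATLAS_FIELDS = ("TOPTA", "TOPTNA", "DTOPT", "THISTG", "THISTS", "DTHISTS", "TLOC", "VPOL")


def rate_suffix(rate: float) -> str:
    """Growth rate → 3-digit column suffix in hundredths (0.28 → '028')."""
    return f"{int(round(rate * 100)):03d}"


def parse_rate_suffix(suffix: str) -> float:
    if not re.fullmatch(r"\d{3}", suffix):
        raise ValueError(f"malformed rate suffix {suffix!r}")
    return int(suffix) / 100.0


@dataclass
class DifferentialAtlas:
    """Per-cell maps keyed by population-average growth rate.

    ``data`` maps rate (d⁻¹) → {field name → (nlat, nlon) array with NaN on
    land/missing cells}; field names are the bases in :data:`ATLAS_FIELDS`.
    """

    grid: OceanGrid
    data: dict = field(default_factory=dict)

    @property
    def rates(self) -> list[float]:
        return sorted(self.data)

    def get(self, name: str, rate: float) -> np.ndarray:
        key = min(self.data, key=lambda r: abs(r - rate))
        if abs(key - rate) > 5e-3:
            raise KeyError(f"no atlas layer at growth rate {rate}")
        return self.data[key][name]

    def add_layer(self, rate: float, fields_dict: dict) -> None:
        missing = [f for f in ATLAS_FIELDS if f not in fields_dict]
        if missing:
            raise ValueError(f"atlas layer missing fields: {missing}")
        self.data[round(float(rate), 2)] = dict(fields_dict)


def most_abundant_topt(counts: np.ndarray, t_opt: np.ndarray) -> np.ndarray:
    """T_opt of the max-abundance species per cell.

    ``counts`` has species on the last axis; exact ties resolve to the
    lowest T_opt (lowest index — optima are sorted ascending); empty cells
    return NaN. Works on single maps or time stacks.
    """
    counts = np.asarray(counts, dtype=float)
    best = np.argmax(counts, axis=-1)  # first max = lowest T_opt on ties
    vals = np.asarray(t_opt, dtype=float)[best]
    empty = counts.sum(axis=-1) <= 0
    return np.where(empty, np.nan, vals)


def poleward_velocity_map(forcing: ForcingSeries) -> np.ndarray:
    """Time-mean poleward velocity per cell (m s⁻¹): +v in the northern
    hemisphere, −v in the southern — positive means away from the
    equator."""
    vbar = forcing.v.mean(axis=0)
    sign = np.where(forcing.grid.lat_centers >= 0, 1.0, -1.0)[:, None]
    out = vbar * sign
    out = np.where(forcing.grid.land_mask, np.nan, out)
    return out


def _window_slice(times: np.ndarray, window) -> np.ndarray:
    if window is None:
        return np.ones(times.size, dtype=bool)
    t0, t1 = window
    return (times >= t0) & (times <= t1)


def advective_differential(
    output_with: SimulationOutput,
    output_without: SimulationOutput,
    averaging_window: tuple[float, float] | None = None,
    *,
    forcing: ForcingSeries | None = None,
    rate: float | None = None,
) -> DifferentialAtlas:
    """Build a one-rate :class:`DifferentialAtlas` from a paired run.

    Each run's per-snapshot most-abundant-T_opt map is time-averaged over
    the window (default: the full run), then subtracted (with − without).
    Historical-temperature means and ΔT_hist(s) come from the advective
    run. ``rate`` defaults to the runs' target mean growth rate.
    """
    a, na = output_with, output_without
    if not a.grid.same_as(na.grid):
        raise ValueError("paired runs are on different grids")
    if a.t_opt.shape != na.t_opt.shape or not np.allclose(a.t_opt, na.t_opt):
        raise ValueError("paired runs use different species sets")
    if a.times.size != na.times.size:
        raise ValueError("paired runs have different output lengths")

    sel_a = _window_slice(a.times, averaging_window)
    sel_n = _window_slice(na.times, averaging_window)
    topt_a = most_abundant_topt(a.counts[sel_a], a.t_opt).mean(axis=0)
    topt_na = most_abundant_topt(na.counts[sel_n], na.t_opt).mean(axis=0)
    tloc = a.t_loc[sel_a].mean(axis=0)
    tg = a.thist_g[sel_a].mean(axis=0)
    ts = a.thist_s[sel_a].mean(axis=0)

    if rate is None:
        rate = a.meta.get("target_mean_growth")
    if rate is None:
        rate = float(np.mean(a.mean_growth[sel_a]))

    if forcing is not None:
        vpol = poleward_velocity_map(forcing)
    else:
        vpol = np.full((a.grid.nlat, a.grid.nlon), np.nan)

    atlas = DifferentialAtlas(a.grid)
    atlas.add_layer(
        rate,
        {
            "TOPTA": a.map_of(topt_a),
            "TOPTNA": a.map_of(topt_na),
            "DTOPT": a.map_of(topt_a - topt_na),
            "THISTG": a.map_of(tg),
            "THISTS": a.map_of(ts),
            "DTHISTS": a.map_of(ts - tloc),
            "TLOC": a.map_of(tloc),
            "VPOL": vpol,
        },
    )
    return atlas


# ---------------------------------------------------------------------------
# atlas I/O (CSV and netCDF; round-trip exact to float formatting)
# ---------------------------------------------------------------------------


def _atlas_frame(atlas: DifferentialAtlas) -> pd.DataFrame:
    g = atlas.grid
    lon2, lat2 = np.meshgrid(g.lon_centers, g.lat_centers)
    cols = {"lon": lon2.ravel(), "lat": lat2.ravel()}
    for rate in atlas.rates:
        sfx = rate_suffix(rate)
        for name in ATLAS_FIELDS:
            cols[name + sfx] = atlas.data[rate][name].ravel()
    return pd.DataFrame(cols)


def write_atlas(atlas: DifferentialAtlas, path) -> None:
    """Write the atlas; format chosen by extension (.csv or .nc). Missing
    and land cells carry the sentinel 'NA' in CSV, NaN in netCDF."""
    path = str(path)
    if path.endswith(".nc"):
        g = atlas.grid
        data_vars = {
            "lon_edges": (("lon_edge",), g.lon_edges),
            "lat_edges": (("lat_edge",), g.lat_edges),
            "mask": (("lat", "lon"), g.land_mask.astype(np.int8)),
        }
        for rate in atlas.rates:
            sfx = rate_suffix(rate)
            for name in ATLAS_FIELDS:
                data_vars[name + sfx] = (("lat", "lon"), atlas.data[rate][name])
        ds = xr.Dataset(data_vars,
                        coords={"lat": g.lat_centers, "lon": g.lon_centers})
        ds.to_netcdf(path, engine="scipy")
    else:
        _atlas_frame(atlas).to_csv(path, index=False, na_rep="NA",
                                   float_format="%.17g")


_COL_RE = re.compile(r"^([A-Z]+?)(\d{3})$")


def load_atlas(path) -> DifferentialAtlas:
    """Load an atlas written by :func:`write_atlas`, reconstructing the
    growth-rate keys from the column suffixes."""
    path = str(path)
    if path.endswith(".nc"):
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        grid = OceanGrid(ds["lon_edges"].values, ds["lat_edges"].values,
                         ds["mask"].values != 0)
        layers: dict[float, dict] = {}
        for var in ds.data_vars:
            m = _COL_RE.match(str(var))
            if not m:
                continue
            name, sfx = m.groups()
            if name not in ATLAS_FIELDS:
                raise ValueError(f"malformed atlas column {var!r}")
            layers.setdefault(parse_rate_suffix(sfx), {})[name] = np.asarray(
                ds[var].values, float
            )
    else:
        df = pd.read_csv(path, na_values=["NA"])
        lons = np.unique(df["lon"].values)
        lats = np.unique(df["lat"].values)
        dlon = lons[1] - lons[0]
        dlat = lats[1] - lats[0]
        lon_edges = np.concatenate((lons - dlon / 2, [lons[-1] + dlon / 2]))
        lat_edges = np.concatenate((lats - dlat / 2, [lats[-1] + dlat / 2]))
        shape = (lats.size, lons.size)
        layers = {}
        land = np.ones(shape, dtype=bool)
        for col in df.columns:
            if col in ("lon", "lat"):
                continue
            m = _COL_RE.match(col)
            if not m or m.group(1) not in ATLAS_FIELDS:
                raise ValueError(f"malformed atlas column {col!r}")
            name, sfx = m.groups()
            arr = df[col].values.reshape(shape)
            layers.setdefault(parse_rate_suffix(sfx), {})[name] = arr
            if name == "TLOC":
                land &= np.isnan(arr)
        grid = OceanGrid(lon_edges, lat_edges, land)

    atlas = DifferentialAtlas(grid)
    for rate, fields_dict in layers.items():
        atlas.add_layer(rate, fields_dict)
    return atlas
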