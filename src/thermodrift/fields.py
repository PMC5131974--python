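"""Gridded surface-ocean forcing.

A synthetic closed-basin gyre with a western boundary current stands in for
hydrodynamic-model output: a narrow, fast poleward jet on the western wall,
a broad, slow equatorward return flow in the interior/east, a meridional
temperature gradient with a seasonal cycle, and snapshots at a fixed
interval (default 3 days) on a regular lat-lon grid (default 2°).

Conventions
-----------
Longitudes are degrees east in [-180, 180), latitudes degrees north,
cell-center registration. Time is in days since the start of the series.
All fields are 2-D surface-slab quantities. Velocities are ``u`` (eastward)
and ``v`` (northward) in m s⁻¹; temperature is °C. On land cells ``u = v =
0`` and temperature is NaN.

The velocity field is derived from a streamfunction sampled at cell centers
(with a zero ring outside the basin) and differenced with centered
differences in the spherical metric, which makes the discrete divergence
vanish to round-off — particle mass is conserved without a full ocean model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import xarray as xr

EARTH_RADIUS_M = 6_371_000.0
SECONDS_PER_DAY = 86_400.0
DAYS_PER_YEAR = 365.0

__all__ = [
    "OceanGrid",
    "ForcingSeries",
    "ForcingError",
    "generate_double_gyre",
    "write_forcing",
    "load_forcing",
    "sample_field",
    "EARTH_RADIUS_M",
    "SECONDS_PER_DAY",
    "DAYS_PER_YEAR",
]


class ForcingError(ValueError):
    """Invalid or inconsistent forcing input."""


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------


@dataclass
class OceanGrid:
    """Regular lat-lon grid with a land mask.

    Parameters
    ----------
    lon_edges, lat_edges
        Cell edges in degrees, strictly increasing, uniform spacing.
    land_mask
        Boolean array of shape ``(nlat, nlon)``; True marks land.
    """

    lon_edges: np.ndarray
    lat_edges: np.ndarray
    land_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.lon_edges = np.asarray(self.lon_edges, dtype=float)
        self.lat_edges = np.asarray(self.lat_edges, dtype=float)
        if self.land_mask is None:
            self.land_mask = np.zeros((self.nlat, self.nlon), dtype=bool)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        for name, e in (("lon_edges", self.lon_edges), ("lat_edges", self.lat_edges)):
            if e.ndim != 1 or e.size < 2:
                raise ForcingError(f"{name} must be a 1-D array of ≥2 edges")
            d = np.diff(e)
            if np.any(d <= 0):
                raise ForcingError(f"{name} must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-9, atol=1e-9):
                raise ForcingError(f"{name} must be uniformly spaced")
        if self.land_mask.shape != (self.nlat, self.nlon):
            raise ForcingError(
                f"land_mask shape {self.land_mask.shape} does not match grid "
                f"({self.nlat}, {self.nlon})"
            )
        ocean = ~self.land_mask
        if not ocean.any():
            raise ForcingError("grid has no ocean cells")
        if ocean.sum() > 1:
            # every ocean cell needs at least one ocean neighbor
            nb = np.zeros_like(ocean, dtype=int)
            nb[1:, :] += ocean[:-1, :]
            nb[:-1, :] += ocean[1:, :]
            nb[:, 1:] += ocean[:, :-1]
            nb[:, :-1] += ocean[:, 1:]
            if np.any(ocean & (nb == 0)):
                raise ForcingError("isolated ocean cell (no ocean neighbor)")

    # -- geometry -----------------------------------------------------------

    @property
    def nlon(self) -> int:
        return self.lon_edges.size - 1

    @property
    def nlat(self) -> int:
        return self.lat_edges.size - 1

    @property
    def lon_centers(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    @property
    def lat_centers(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    @property
    def dlon(self) -> float:
        return float(self.lon_edges[1] - self.lon_edges[0])

    @property
    def dlat(self) -> float:
        return float(self.lat_edges[1] - self.lat_edges[0])

    @property
    def cell_area(self) -> np.ndarray:
        """Cell areas in m², shape ``(nlat, nlon)``."""
        lam = np.deg2rad(self.lon_edges)
        phi = np.deg2rad(self.lat_edges)
        band = EARTH_RADIUS_M**2 * np.diff(np.sin(phi))  # per radian of lon
        return np.outer(band, np.diff(lam))

    @property
    def n_ocean(self) -> int:
        return int((~self.land_mask).sum())

    def cell_of(self, lon, lat):
        """Map in-domain positions to ``(iy, ix)`` cell indices (outer
        edges inclusive, snapping to the last cell)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        ix = np.clip(((lon - self.lon_edges[0]) / self.dlon).astype(np.int64),
                     0, self.nlon - 1)
        iy = np.clip(((lat - self.lat_edges[0]) / self.dlat).astype(np.int64),
                     0, self.nlat - 1)
        return iy, ix

    def contains(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_edges[0])
            & (lon <= self.lon_edges[-1])
            & (lat >= self.lat_edges[0])
            & (lat <= self.lat_edges[-1])
        )

    def same_as(self, other: "OceanGrid") -> bool:
        return (
            self.lon_edges.shape == other.lon_edges.shape
            and self.lat_edges.shape == other.lat_edges.shape
            and np.allclose(self.lon_edges, other.lon_edges)
            and np.allclose(self.lat_edges, other.lat_edges)
            and np.array_equal(self.land_mask, other.land_mask)
        )


# ---------------------------------------------------------------------------
# forcing series
# ---------------------------------------------------------------------------


@dataclass
class ForcingSeries:
    """Velocity and temperature snapshots on an :class:`OceanGrid`.

    ``u``, ``v`` and ``temperature`` have shape ``(ntime, nlat, nlon)``;
    ``times`` are days since start at a constant interval.
    ``steady_velocity`` marks series whose velocity does not change between
    snapshots (the synthetic gyre), enabling a fast interpolation path.
    """

    grid: OceanGrid
    times: np.ndarray
    u: np.ndarray
    v: np.ndarray
    temperature: np.ndarray
    steady_velocity: bool = False
    #: optional corner-registered streamfunction (ntime, nlat+1, nlon+1),
    #: m² s⁻¹; when present, finite-volume solvers can take face water
    #: fluxes as ψ differences, which are exactly non-divergent
    psi_corners: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("u", "v", "temperature"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (self.times.size, self.grid.nlat, self.grid.nlon):
                raise ForcingError(f"variable {name!r} has shape {arr.shape}, "
                                   f"expected {(self.times.size, self.grid.nlat, self.grid.nlon)}")
        if self.times.size < 1:
            raise ForcingError("forcing needs at least one snapshot")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-8):
                raise ForcingError("snapshot times must be uniform and increasing")
        ocean = ~self.grid.land_mask
        for name in ("u", "v", "temperature"):
            arr = getattr(self, name)
            if not np.isfinite(arr[:, ocean]).all():
                raise ForcingError(f"variable {name!r} has non-finite values on ocean cells")
        land = self.grid.land_mask
        if land.any():
            if np.any(self.u[:, land] != 0) or np.any(self.v[:, land] != 0):
                raise ForcingError("velocities must be zero on land cells")
        if self.psi_corners is not None:
            self.psi_corners = np.asarray(self.psi_corners, dtype=float)
            want = (self.times.size, self.grid.nlat + 1, self.grid.nlon + 1)
            if self.psi_corners.shape != want:
                raise ForcingError(
                    f"psi_corners has shape {self.psi_corners.shape}, expected {want}"
                )

    @property
    def interval(self) -> float:
        """Snapshot interval in days."""
        if self.times.size < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


# ---------------------------------------------------------------------------
# synthetic gyre generator
# ---------------------------------------------------------------------------


def _streamfunction(xh: np.ndarray, yh: np.ndarray, delta: float) -> np.ndarray:
    """Normalized gyre streamfunction on [0,1]²; zero on and outside walls.

    Western intensification comes from the exponential boundary layer of
    width ``delta`` (fraction of basin width) on the western side.
    """
    x = np.clip(xh, 0.0, 1.0)
    y = np.clip(yh, 0.0, 1.0)
    fx = (1.0 - np.exp(-x / delta)) * (1.0 - x)
    return fx * np.sin(np.pi * y)


def generate_double_gyre(
    basin_size: tuple[int, int] = (20, 20),
    gyre_strength: float = 0.4,
    boundary_width: int = 3,
    T_equator: float = 28.0,
    T_pole: float = 4.0,
    seasonal_amplitude: float = 5.0,
    n_years: float = 3.0,
    snapshot_interval: float = 3.0,
    cell_deg: float = 2.0,
    lon0: float = -60.0,
    lat0: float = 8.0,
    meander_amplitude: float = 0.1,
    meander_period: float = DAYS_PER_YEAR,
) -> ForcingSeries:
    """Generate an idealized closed-basin gyre forcing series.

    Parameters
    ----------
    basin_size
        ``(nlon, nlat)`` in cells; each side must be ≥ 10.
    gyre_strength
        Peak poleward jet speed in m s⁻¹ (0 gives a motionless ocean).
    boundary_width
        Width of the western boundary layer in columns.
    T_equator, T_pole
        Baseline temperature (°C) at the equatorward and poleward basin
        edges; requires ``T_equator > T_pole``.
    seasonal_amplitude
        Peak-to-trough amplitude (°C) of the sinusoidal seasonal cycle; the
        cycle adds between 0 and this amount to the baseline, so the field
        stays within ``[T_pole, T_equator + seasonal_amplitude]``.
    n_years, snapshot_interval
        Series length (365-day years) and snapshot spacing (days).
    cell_deg, lon0, lat0
        Cell size and southwest corner of the basin, degrees.
    meander_amplitude, meander_period
        Seasonal meander of the gyre: the streamfunction pattern is
        displaced by up to this fraction of the basin width, oscillating
        with the given period (days), with the zonal and meridional
        displacements in quadrature. Real surface circulation is unsteady;
        a perfectly steady gyre has closed streamlines along which
        selection homogenizes regardless of growth rate, an artifact with
        no analogue in the ocean. The meander stirs water across mean
        streamlines and gives trajectories a finite memory horizon. Set to
        0 for a steady gyre.
    """
    nlon, nlat = basin_size
    if nlon < 10 or nlat < 10:
        raise ForcingError("basin must be at least 10x10 cells for a boundary current")
    if gyre_strength < 0:
        raise ForcingError("gyre_strength must be >= 0")
    if not T_equator > T_pole:
        raise ForcingError("T_equator must exceed T_pole")

    lon_edges = lon0 + cell_deg * np.arange(nlon + 1)
    lat_edges = lat0 + cell_deg * np.arange(nlat + 1)
    grid = OceanGrid(lon_edges, lat_edges)
    xc, yc = grid.lon_centers, grid.lat_centers

    # streamfunction on padded cell centers (zero ring outside the basin)
    delta = boundary_width / nlon
    lam_width = np.deg2rad(nlon * cell_deg)
    phi_mid = np.deg2rad(0.5 * (lat_edges[0] + lat_edges[-1]))
    hemisphere = 1.0 if 0.5 * (lat_edges[0] + lat_edges[-1]) >= 0 else -1.0
    psi0 = hemisphere * gyre_strength * EARTH_RADIUS_M * np.cos(phi_mid) * lam_width * delta

    xpad = np.concatenate(([xc[0] - cell_deg], xc, [xc[-1] + cell_deg]))
    ypad = np.concatenate(([yc[0] - cell_deg], yc, [yc[-1] + cell_deg]))
    xh = (xpad - lon_edges[0]) / (nlon * cell_deg)
    yh = (ypad - lat_edges[0]) / (nlat * cell_deg)

    n_snap = int(np.ceil(n_years * DAYS_PER_YEAR / snapshot_interval)) + 1
    times = snapshot_interval * np.arange(n_snap)
    nt = times.size

    dlam = np.deg2rad(cell_deg)
    dphi = np.deg2rad(cell_deg)
    cosphi = np.cos(np.deg2rad(yc))[:, None]
    x2 = np.broadcast_to(xh[None, :], (nlat + 2, nlon + 2))
    y2 = np.broadcast_to(yh[:, None], (nlat + 2, nlon + 2))
    steady = meander_amplitude == 0.0
    u3 = np.empty((nt, nlat, nlon))
    v3 = np.empty((nt, nlat, nlon))
    # corner-registered ψ (normalized corner coords are exactly 0..1 at the
    # walls, so wall fluxes vanish identically)
    xce = (lon_edges - lon_edges[0]) / (nlon * cell_deg)
    yce = (lat_edges - lat_edges[0]) / (nlat * cell_deg)
    xc2 = np.broadcast_to(xce[None, :], (nlat + 1, nlon + 1))
    yc2 = np.broadcast_to(yce[:, None], (nlat + 1, nlon + 1))
    psi3 = np.empty((nt, nlat + 1, nlon + 1))
    for k, tk in enumerate(times):
        if steady and k > 0:
            u3[k], v3[k] = u3[0], v3[0]
            psi3[k] = psi3[0]
            continue
        ang = 2.0 * np.pi * tk / meander_period
        mx = meander_amplitude * np.sin(ang)
        my = meander_amplitude * np.cos(ang)
        xs = x2 + mx * np.sin(np.pi * np.clip(x2, 0, 1))
        ys = y2 + my * np.sin(np.pi * np.clip(y2, 0, 1))
        psi = psi0 * _streamfunction(xs, ys, delta)
        # u = -ψ_φ / R ; v = ψ_λ / (R cosφ) — centered over 2Δ on padded centers
        u3[k] = -(psi[2:, 1:-1] - psi[:-2, 1:-1]) / (2.0 * EARTH_RADIUS_M * dphi)
        v3[k] = (psi[1:-1, 2:] - psi[1:-1, :-2]) / (2.0 * EARTH_RADIUS_M * dlam * cosphi)
        psi3[k] = psi0 * _streamfunction(xc2 + mx * np.sin(np.pi * xc2),
                                         yc2 + my * np.sin(np.pi * yc2), delta)

    # latitude-linear baseline + seasonal cycle in [0, amplitude]
    abslat = np.abs(yc)
    lo, hi = abslat.min(), abslat.max()
    frac = (abslat - lo) / (hi - lo) if hi > lo else np.zeros_like(abslat)
    baseline = T_equator + (T_pole - T_equator) * frac
    hemi = np.where(yc >= 0, 1.0, -1.0)
    phase = 2.0 * np.pi * (times[:, None] - 105.0) / DAYS_PER_YEAR
    seasonal = 0.5 * seasonal_amplitude * (1.0 + np.sin(phase) * hemi[None, :])
    T = baseline[None, :] + seasonal  # (nt, nlat)
    temperature = np.repeat(T[:, :, None], nlon, axis=2)

    return ForcingSeries(grid, times, u3, v3, temperature,
                         steady_velocity=steady, psi_corners=psi3)


# ---------------------------------------------------------------------------
# netCDF I/O
# ---------------------------------------------------------------------------

_UNITS = {"u": "m s-1", "v": "m s-1", "temperature": "degC"}


def write_forcing(series: ForcingSeries, path) -> None:
    """Write a forcing series to netCDF (CF-style lon/lat/time coords)."""
    g = series.grid
    land = g.land_mask
    temp = series.temperature.copy()
    temp[:, land] = np.nan
    ds = xr.Dataset(
        {
            "u": (("time", "lat", "lon"), series.u, {"units": _UNITS["u"]}),
            "v": (("time", "lat", "lon"), series.v, {"units": _UNITS["v"]}),
            "temperature": (("time", "lat", "lon"), temp, {"units": _UNITS["temperature"]}),
            "mask": (("lat", "lon"), land.astype(np.int8), {"long_name": "land mask (1=land)"}),
            "lon_edges": (("lon_edge",), g.lon_edges),
            "lat_edges": (("lat_edge",), g.lat_edges),
        },
        coords={
            "lon": ("lon", g.lon_centers, {"units": "degrees_east"}),
            "lat": ("lat", g.lat_centers, {"units": "degrees_north"}),
            "time": ("time", series.times, {"units": "days"}),
        },
        attrs={"steady_velocity": int(series.steady_velocity)},
    )
    if series.psi_corners is not None:
        ds["psi"] = (("time", "lat_edge", "lon_edge"), series.psi_corners,
                     {"units": "m2 s-1"})
    ds.to_netcdf(path, engine="scipy")


def load_forcing(path) -> ForcingSeries:
    """Load and validate a forcing series written by :func:`write_forcing`
    (or any netCDF file with the same variable/coordinate names)."""
    path = Path(path)
    if not path.exists():
        raise ForcingError(f"forcing file not found: {path}")
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    for var in ("u", "v", "temperature"):
        if var not in ds:
            raise ForcingError(f"forcing file {path} is missing variable {var!r}")
        units = ds[var].attrs.get("units")
        if units is not None and units != _UNITS[var]:
            raise ForcingError(
                f"variable {var!r} has units {units!r}, expected {_UNITS[var]!r}"
            )
    for coord in ("lon", "lat", "time"):
        if coord not in ds.coords:
            raise ForcingError(f"forcing file {path} is missing coordinate {coord!r}")
    times = np.asarray(ds["time"].values, dtype=float)
    if times.size > 1:
        dt = np.diff(times)
        if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-8):
            raise ForcingError("variable 'time': non-uniform snapshot interval")
    if "lon_edges" in ds and "lat_edges" in ds:
        lon_edges = np.asarray(ds["lon_edges"].values, dtype=float)
        lat_edges = np.asarray(ds["lat_edges"].values, dtype=float)
    else:  # reconstruct from uniform centers
        lon = np.asarray(ds["lon"].values, dtype=float)
        lat = np.asarray(ds["lat"].values, dtype=float)
        dlon, dlat = lon[1] - lon[0], lat[1] - lat[0]
        lon_edges = np.concatenate((lon - dlon / 2, [lon[-1] + dlon / 2]))
        lat_edges = np.concatenate((lat - dlat / 2, [lat[-1] + dlat / 2]))
    if "mask" in ds:
        land = np.asarray(ds["mask"].values) != 0
    else:
        land = np.isnan(np.asarray(ds["temperature"].values)).all(axis=0)
    grid = OceanGrid(lon_edges, lat_edges, land)
    temp = np.asarray(ds["temperature"].values, dtype=float)
    ocean = ~land
    for var in ("u", "v", "temperature"):
        arr = np.asarray(ds[var].values, dtype=float)
        if not np.isfinite(arr[:, ocean]).all():
            raise ForcingError(f"variable {var!r} has NaN/inf on ocean cells")
    temp[:, land] = np.nan
    psi = np.asarray(ds["psi"].values, dtype=float) if "psi" in ds else None
    return ForcingSeries(
        grid,
        times,
        np.asarray(ds["u"].values, dtype=float),
        np.asarray(ds["v"].values, dtype=float),
        temp,
        steady_velocity=bool(ds.attrs.get("steady_velocity", 0)),
        psi_corners=psi,
    )


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------


def _space_stencil(grid: OceanGrid, lon: np.ndarray, lat: np.ndarray):
    """Bilinear stencil in center space, clamped at walls; land cells get
    zero weight and the remaining weights are renormalized."""
    xc, yc = grid.lon_centers, grid.lat_centers
    fx = np.clip((lon - xc[0]) / grid.dlon, 0.0, grid.nlon - 1.0)
    fy = np.clip((lat - yc[0]) / grid.dlat, 0.0, grid.nlat - 1.0)
    i0 = np.minimum(fx.astype(np.int64), grid.nlon - 2) if grid.nlon > 1 else np.zeros_like(fx, dtype=np.int64)
    j0 = np.minimum(fy.astype(np.int64), grid.nlat - 2) if grid.nlat > 1 else np.zeros_like(fy, dtype=np.int64)
    wx = fx - i0
    wy = fy - j0
    i1 = np.minimum(i0 + 1, grid.nlon - 1)
    j1 = np.minimum(j0 + 1, grid.nlat - 1)
    jj = np.stack([j0, j0, j1, j1])
    ii = np.stack([i0, i1, i0, i1])
    ww = np.stack([(1 - wy) * (1 - wx), (1 - wy) * wx, wy * (1 - wx), wy * wx])
    if grid.land_mask.any():
        ww = np.where(grid.land_mask[jj, ii], 0.0, ww)
        tot = ww.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ww = np.where(tot > 0, ww / tot, 0.0)
    return jj, ii, ww


def sample_field(series: ForcingSeries, lon, lat, t, variable: str):
    """Interpolate a stored field at arbitrary points and times.

    Bilinear in space between ocean-cell centers (land cells are dropped
    from the stencil and weights renormalized; clamped within the wall
    half-cell), linear in time between snapshots. Raises on queries over
    land cells or outside the time span.
    """
    if variable not in ("u", "v", "temperature"):
        raise ForcingError(f"unknown variable {variable!r}")
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    scalar = lon.size == 1 and lat.size == 1 and t.size == 1
    lon, lat, t = np.broadcast_arrays(lon, lat, t)
    grid = series.grid

    if not grid.contains(lon, lat).all():
        raise ForcingError("query point outside the model domain")
    iy, ix = grid.cell_of(lon, lat)
    if grid.land_mask[iy, ix].any():
        raise ForcingError("query point on a land cell")

    t0, t1 = series.span
    if np.any(t < t0 - 1e-9) or np.any(t > t1 + 1e-9):
        raise ForcingError("query time outside the forcing span")
    if series.times.size == 1:
        k0 = np.zeros(t.shape, dtype=np.int64)
        k1 = k0
        wt = np.zeros(t.shape)
    else:
        ft = np.clip((t - t0) / series.interval, 0.0, series.times.size - 1.0)
        k0 = np.minimum(ft.astype(np.int64), series.times.size - 2)
        wt = ft - k0
        k1 = k0 + 1

    arr = getattr(series, variable)
    jj, ii, ww = _space_stencil(grid, lon, lat)
    f0 = arr[k0[None, ...], jj, ii]
    f1 = arr[k1[None, ...], jj, ii]
    vals = np.where(ww > 0, (1 - wt)[None, ...] * f0 + wt[None, ...] * f1, 0.0)
    out = (ww * vals).sum(axis=0)
    return float(out[0]) if scalar else out
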