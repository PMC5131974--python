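"""Thermal performance curves, logistic competition and selection rate.

Growth rate versus temperature follows a Thomas-type curve: a quadratic
niche of width ``w`` multiplied by an exponential envelope,

    μ(T) = a · e^{bT} · [1 − ((T − z) / (w/2))²]      [d⁻¹]

where ``z`` is the center of the quadratic, solved per species so that the
maximum of μ sits exactly at the species' optimum temperature ``T_opt``.
Two consequences drive the whole model: the maximum growth rate rises
exponentially with T_opt (μmax ratio between species = e^{bΔT_opt}), so a
species whose optimum equals the local temperature is outcompeted by a
slightly warmer-adapted one; and the curve falls more steeply above the
optimum than below it, penalizing residence above T_opt.

μ may be negative outside the niche; the negative part acts as an extra
per-capita loss on top of the uniform death rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ThermalParams",
    "SpeciesSet",
    "solve_curve_center",
    "thermal_curve",
    "logistic_factor",
    "selection_rate",
]


@dataclass(frozen=True)
class ThermalParams:
    """Shared thermal-curve and demographic parameters.

    envelope_scale ``a`` (d⁻¹) sets the overall growth level and is the
    knob the calibration turns; envelope_exponent ``b`` (°C⁻¹) is the
    Eppley-like exponential slope; niche_width ``w`` (°C) the full width of
    the quadratic niche; death_rate ``d`` (d⁻¹) a uniform per-capita loss;
    carrying_capacity ``K`` (cells per grid cell) is spatially and
    temporally uniform — implicit resource competition.
    """

    envelope_scale: float = 0.2
    envelope_exponent: float = 0.063
    niche_width: float = 30.0
    death_rate: float = 0.1
    carrying_capacity: float = 1000.0

    def __post_init__(self) -> None:
        if self.envelope_scale <= 0 or self.envelope_exponent <= 0:
            raise ValueError("envelope parameters must be positive")
        if self.niche_width <= 0:
            raise ValueError("niche_width must be positive")
        if self.death_rate < 0:
            raise ValueError("death_rate must be >= 0")
        if self.carrying_capacity <= 0:
            raise ValueError("carrying_capacity must be positive")


def solve_curve_center(T_opt, b: float, w: float):
    """Center ``z`` of the quadratic such that argmax_T μ(T) = T_opt.

    With h = w/2 and x = [√(1 + (bh)²) − 1]/(bh), z = T_opt − h·x; the
    stationarity condition b(1 − x²) = 2x/h then holds exactly at T_opt.
    In the b→0 (symmetric-curve) limit z → T_opt; for b > 0, z < T_opt.
    """
    if b <= 0 or w <= 0:
        raise ValueError("b and w must be positive")
    T_opt = np.asarray(T_opt, dtype=float)
    h = 0.5 * w
    bh = b * h
    x = (np.sqrt(1.0 + bh * bh) - 1.0) / bh
    z = T_opt - h * x
    return float(z) if z.ndim == 0 else z


def thermal_curve(T_loc, T_opt, params: ThermalParams, *, a=None, b=None, w=None):
    """Growth rate μ(T_loc) (d⁻¹) for species with optimum ``T_opt``.

    Total function: negative outside the niche (treated as net loss by the
    demography). ``a``/``b``/``w`` override the shared parameters, allowing
    per-species laboratory curves (e.g. ecotype pairs).
    """
    a = params.envelope_scale if a is None else a
    b = params.envelope_exponent if b is None else b
    w = params.niche_width if w is None else w
    T_loc = np.asarray(T_loc, dtype=float)
    z = solve_curve_center(T_opt, b, w) if np.ndim(b) == 0 else None
    if z is None:  # per-species arrays
        z = np.array([solve_curve_center(t, bb, ww) for t, bb, ww in zip(T_opt, b, w)])
    h = 0.5 * np.asarray(w, dtype=float)
    mu = a * np.exp(np.asarray(b) * T_loc) * (1.0 - ((T_loc - z) / h) ** 2)
    return float(mu) if np.ndim(mu) == 0 else mu


@dataclass
class SpeciesSet:
    """Ordered species defined by their optimum temperatures.

    ``t_opt`` is strictly increasing. Per-species curve parameters default
    to the shared :class:`ThermalParams` but can be overridden per species
    (``a``, ``b``, ``w`` arrays), which is how laboratory ecotype curves
    enter the model.
    """

    t_opt: np.ndarray
    params: ThermalParams = field(default_factory=ThermalParams)
    a: np.ndarray | None = None
    b: np.ndarray | None = None
    w: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t_opt = np.asarray(self.t_opt, dtype=float)
        if self.t_opt.ndim != 1 or self.t_opt.size < 1:
            raise ValueError("t_opt must be a 1-D array")
        if np.any(np.diff(self.t_opt) <= 0):
            raise ValueError("t_opt must be strictly increasing")
        n = self.t_opt.size
        self.a = np.full(n, self.params.envelope_scale) if self.a is None else np.asarray(self.a, float)
        self.b = np.full(n, self.params.envelope_exponent) if self.b is None else np.asarray(self.b, float)
        self.w = np.full(n, self.params.niche_width) if self.w is None else np.asarray(self.w, float)
        for name in ("a", "b", "w"):
            arr = getattr(self, name)
            if arr.shape != (n,) or np.any(arr <= 0):
                raise ValueError(f"per-species {name} must be positive with shape ({n},)")
        self.z = np.array(
            [solve_curve_center(t, bb, ww) for t, bb, ww in zip(self.t_opt, self.b, self.w)]
        )

    @classmethod
    def regular(
        cls,
        n_species: int = 50,
        t_min: float = -5.2,
        step: float = 0.8,
        params: ThermalParams | None = None,
    ) -> "SpeciesSet":
        """Uniformly spaced optima (defaults: 50 species from −5.2°C in
        0.8°C steps, i.e. up to 34.0°C)."""
        params = params or ThermalParams()
        return cls(t_min + step * np.arange(n_species), params)

    @classmethod
    def from_params_list(cls, species: list[dict], params: ThermalParams | None = None) -> "SpeciesSet":
        """Build from per-species dicts with keys ``t_opt`` and optional
        ``a``, ``b``, ``w`` (laboratory-curve inputs)."""
        params = params or ThermalParams()
        order = np.argsort([s["t_opt"] for s in species])
        sp = [species[i] for i in order]
        return cls(
            np.array([s["t_opt"] for s in sp]),
            params,
            a=np.array([s.get("a", params.envelope_scale) for s in sp]),
            b=np.array([s.get("b", params.envelope_exponent) for s in sp]),
            w=np.array([s.get("w", params.niche_width) for s in sp]),
        )

    @property
    def n(self) -> int:
        return self.t_opt.size

    def with_params(self, params: ThermalParams) -> "SpeciesSet":
        """Same optima under new shared parameters (per-species overrides
        are rescaled only if they mirrored the old shared values)."""
        shared = (
            np.allclose(self.a, self.params.envelope_scale)
            and np.allclose(self.b, self.params.envelope_exponent)
            and np.allclose(self.w, self.params.niche_width)
        )
        if shared:
            return SpeciesSet(self.t_opt.copy(), params)
        return SpeciesSet(self.t_opt.copy(), params, a=self.a.copy(), b=self.b.copy(), w=self.w.copy())

    def growth_rates(self, T):
        """Growth-rate matrix μ with shape ``T.shape + (n_species,)``."""
        T = np.asarray(T, dtype=float)[..., None]
        h = 0.5 * self.w
        return self.a * np.exp(self.b * T) * (1.0 - ((T - self.z) / h) ** 2)

    def mu_max(self) -> np.ndarray:
        """Maximum growth rate per species (at its T_opt)."""
        return np.array(
            [thermal_curve(t, t, self.params, a=aa, b=bb, w=ww)
             for t, aa, bb, ww in zip(self.t_opt, self.a, self.b, self.w)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species_id": np.arange(self.n), "T_opt": self.t_opt, "z": self.z}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def logistic_factor(n_cell, K):
    """Logistic crowding factor 1 − N/K; multiplies the positive part of
    the growth rate. May be negative when a cell overshoots K (the
    demography clamps realized growth at zero there)."""
    return 1.0 - np.asarray(n_cell, dtype=float) / K


def selection_rate(cell_abundances, cell_growth_rates):
    """Selection rate s (d⁻¹) of one cell.

    s = μ(most abundant) − μ(second most abundant); exact abundance ties
    resolve to the lower species index (lower T_opt). Cells with fewer than
    two species present carry no competition signal: s = 0.
    """
    ab = np.asarray(cell_abundances, dtype=float)
    mu = np.asarray(cell_growth_rates, dtype=float)
    if ab.shape != mu.shape or ab.ndim != 1:
        raise ValueError("abundances and growth rates must be matching 1-D arrays")
    if (ab > 0).sum() < 2:
        return 0.0
    order = np.argsort(-ab, kind="stable")
    return float(mu[order[0]] - mu[order[1]])
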