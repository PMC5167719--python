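"""Process-based peach fruit-quality model.

Simulates three fruit traits over the 87-150 days-after-bloom (DAB) window
from seven genotype-dependent parameters:

* fruit dry mass ``DM`` (g), from a logistic potential-growth curve in
  thermal time (growing degree-days, GDD);
* stone ratio ``SR`` (stone dry mass / fruit dry mass), from a saturating
  stone-allometry curve;
* flesh total sugar concentration ``SU`` (g per 100 g fresh mass), from a
  linear carbon-balance ODE for sugar carbon in the flesh.

The carbon source side of the full fruit biophysics (leaf photosynthesis,
reserves, water flows) is deliberately replaced by a demand-driven closure:
realized growth equals the logistic potential, and the flesh carbon supply
covers structural carbon plus growth respiration,
``F_Csupp = (alpha + beta) * dDM_flesh/dt``.  See ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "PARAMETER_NAMES",
    "FruitParameters",
    "GrowthConfig",
    "WeatherSeries",
    "Trajectory",
    "PhenotypeTriplet",
    "SimulationError",
    "dm_fruit",
    "dm_stone",
    "stone_ratio",
    "flesh_carbon_supply",
    "integrate_sugar",
    "sugar_concentration",
    "simulate_phenotype",
    "simulate_phenotypes",
]

#: Canonical ordering of the seven genotype-dependent parameters.  This is
#: also the layout of continuous decision vectors in the optimization layer.
PARAMETER_NAMES = ("A", "B", "RGRini", "P3", "kstone", "Wstone", "SLA")

# Exponent clip for the logistic terms: exp() saturates instead of overflowing.
_EXP_CLIP = 700.0


class SimulationError(ValueError):
    """Raised when a simulation produces a physically meaningless state."""


@dataclass(frozen=True)
class FruitParameters:
    """The seven genotype-dependent model parameters.

    Attributes
    ----------
    A, B:
        Scale (g) and exponent (dimensionless) of the logistic asymptote;
        the asymptote amplitude is ``A * DM0**B``.
    RGRini:
        Initial relative growth rate (GDD^-1).
    P3:
        Thermal time of the growth-curve inflection point (GDD).
    kstone:
        Curvature of the stone allometry (dimensionless).
    Wstone:
        Potential maximal stone dry mass, the allometry plateau (g).
    SLA:
        Specific leaf area (m^2 g^-1); only active through the optional
        source-limitation hook under the default demand-driven closure.
    """

    A: float
    B: float
    RGRini: float
    P3: float
    kstone: float
    Wstone: float
    SLA: float

    def __post_init__(self) -> None:
        for name in PARAMETER_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"parameter {name} must be finite and > 0, got {value!r}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAMETER_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "FruitParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (7,):
            raise ValueError(f"expected 7 parameter values, got shape {values.shape}")
        return cls(**dict(zip(PARAMETER_NAMES, values)))

    @classmethod
    def from_dict(cls, values: dict) -> "FruitParameters":
        return cls(**{name: float(values[name]) for name in PARAMETER_NAMES})


@dataclass(frozen=True)
class GrowthConfig:
    """Constants of the growth and sugar sub-models.

    These are genotype-independent; none of them is a QTL target.  Defaults
    are literature-scale values for peach (see ``docs/methods.md`` for the
    reasoning behind each one).

    Attributes
    ----------
    DM0:
        Fruit dry mass (g) at the start of the simulated window.
    dj0:
        Thermal time (GDD) at which ``DM0`` holds; ``None`` means "read it
        off the weather series at ``start_dab``".
    start_dab, end_dab:
        Simulation window in days after bloom.
    alpha:
        Growth respiration coefficient (gC per g dry mass).
    beta:
        Carbon concentration of fruit biomass (gC per g dry mass).
    ksugar:
        Relative consumption rate of sugar carbon for non-sugar compounds
        (day^-1).  Genotype-independent here.
    sigma_ts:
        Mean carbon content of the soluble sugars (gC per g sugar).
    dmc:
        Flesh dry-matter content (g dry per g fresh); closes fresh mass as
        ``FM_flesh = DM_flesh / dmc``.
    f0:
        Initial sugar-carbon fraction: ``Csugar(t0) = f0 * beta * DM_flesh(t0)``.
    step:
        Integration step (days) of the fixed-step 4th-order sugar ODE solver.
    asymptote_mode:
        ``"power"`` reads the logistic numerator as ``A*DM0**B`` (default),
        ``"product"`` as ``A*DM0*B``.
    sla_ref:
        Optional source-limitation hook: when set, growth is multiplied by
        ``min(1, SLA/sla_ref)``.  ``None`` (default) = non-limiting source.
    """

    DM0: float = 13.0
    dj0: float | None = None
    start_dab: int = 87
    end_dab: int = 150
    alpha: float = 0.08
    beta: float = 0.44
    ksugar: float = 0.05
    sigma_ts: float = 0.42
    dmc: float = 0.15
    f0: float = 0.5
    step: float = 1.0
    asymptote_mode: str = "power"
    sla_ref: float | None = None

    def __post_init__(self) -> None:
        if self.DM0 <= 0:
            raise ValueError("DM0 must be > 0")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if self.ksugar < 0:
            raise ValueError("ksugar must be >= 0")
        if self.sigma_ts <= 0:
            raise ValueError("sigma_ts must be > 0")
        if not 0 < self.dmc < 1:
            raise ValueError("dmc must lie in (0, 1)")
        if not 0 <= self.f0 <= 1:
            raise ValueError("f0 must lie in [0, 1]")
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.end_dab <= self.start_dab:
            raise ValueError("end_dab must exceed start_dab")
        if self.asymptote_mode not in ("power", "product"):
            raise ValueError("asymptote_mode must be 'power' or 'product'")

    def with_(self, **overrides) -> "GrowthConfig":
        return replace(self, **overrides)

    def asymptote_scale(self, A, B):
        """Amplitude of the logistic term, ``A*DM0**B`` or ``A*DM0*B``."""
        A = np.asarray(A, dtype=float)
        B = np.asarray(B, dtype=float)
        if self.asymptote_mode == "power":
            return A * self.DM0**B
        return A * self.DM0 * B


class WeatherSeries:
    """Daily mean temperatures and the derived thermal-time axis.

    Thermal time (GDD) accumulates daily mean temperature above a base
    temperature; within a day it is interpolated linearly so the simulator
    can query arbitrary (possibly sub-daily) times.
    """

    def __init__(self, days: np.ndarray, tmean: np.ndarray, base_temp: float = 7.0,
                 gdd: np.ndarray | None = None):
        days = np.asarray(days, dtype=float)
        tmean = np.asarray(tmean, dtype=float)
        if days.ndim != 1 or days.shape != tmean.shape or days.size < 2:
            raise ValueError("days and tmean must be 1-d arrays of equal length >= 2")
        if np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing")
        self.days = days
        self.tmean = tmean
        self.base_temp = float(base_temp)
        # Daily GDD increments; clipped at zero (no negative thermal time).
        self._rates = np.clip(tmean - base_temp, 0.0, None)
        if gdd is not None:
            gdd = np.asarray(gdd, dtype=float)
            if gdd.shape != days.shape or np.any(np.diff(gdd) < 0):
                raise ValueError("precomputed gdd must be non-decreasing and match days")
            self._gdd = gdd
        else:
            self._gdd = np.concatenate([[0.0], np.cumsum(self._rates[1:] * np.diff(days))])

    @classmethod
    def constant(cls, tmean: float = 22.0, base_temp: float = 7.0,
                 start: int = 0, end: int = 160) -> "WeatherSeries":
        """Synthetic constant-temperature weather (the packaged default)."""
        days = np.arange(start, end + 1, dtype=float)
        return cls(days, np.full(days.shape, float(tmean)), base_temp=base_temp)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, base_temp: float = 7.0) -> "WeatherSeries":
        gdd = frame["gdd"].to_numpy() if "gdd" in frame.columns else None
        return cls(frame["day"].to_numpy(), frame["tmean"].to_numpy(),
                   base_temp=base_temp, gdd=gdd)

    @classmethod
    def read_csv(cls, path, base_temp: float = 7.0) -> "WeatherSeries":
        return cls.from_frame(pd.read_csv(path), base_temp=base_temp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.days, "tmean": self.tmean, "gdd": self._gdd})

    def _check_window(self, t) -> None:
        t = np.asarray(t, dtype=float)
        if np.any(t < self.days[0]) or np.any(t > self.days[-1]):
            raise ValueError("requested time outside the weather series window")

    def gdd_at(self, t):
        """Cumulative GDD at time ``t`` (days), linearly interpolated."""
        self._check_window(t)
        return np.interp(t, self.days, self._gdd)

    def rate_at(self, t):
        """Instantaneous thermal-time rate (GDD day^-1) at time ``t``."""
        self._check_window(t)
        idx = np.clip(np.searchsorted(self.days, t, side="right") - 1, 0, self.days.size - 2)
        return self._rates[np.minimum(idx + 1, self._rates.size - 1)]


@dataclass
class Trajectory:
    """Per-step state of one simulated fruit (all arrays share one grid)."""

    t: np.ndarray          # days after bloom
    dj: np.ndarray         # thermal time (GDD)
    DMfruit: np.ndarray    # g
    DMstone: np.ndarray    # g
    DMflesh: np.ndarray    # g
    FCsupp: np.ndarray     # gC day^-1
    Csugar: np.ndarray     # gC
    FMflesh: np.ndarray    # g
    SU: np.ndarray         # g per 100 g fresh mass

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({f.name: getattr(self, f.name) for f in fields(self)})


@dataclass(frozen=True)
class PhenotypeTriplet:
    """Final-date values of the three target traits."""

    DM: float   # fruit dry mass, g
    SR: float   # stone dry-mass ratio, dimensionless
    SU: float   # flesh sugar concentration, g per 100 g fresh mass

    def __post_init__(self) -> None:
        if self.DM <= 0 or not 0 < self.SR < 1 or self.SU < 0:
            raise SimulationError(
                f"implausible phenotype DM={self.DM}, SR={self.SR}, SU={self.SU}")

    def to_array(self) -> np.ndarray:
        return np.array([self.DM, self.SR, self.SU], dtype=float)


# ---------------------------------------------------------------------------
# Elementary curves
# ---------------------------------------------------------------------------

def _logistic(dj, RGRini, P3):
    z = np.clip(-np.asarray(RGRini, dtype=float) * (np.asarray(dj, dtype=float) - P3),
                -_EXP_CLIP, _EXP_CLIP)
    return 1.0 / (1.0 + np.exp(z))


def dm_fruit(dj, p: FruitParameters, c: GrowthConfig, dj0: float | None = None):
    """Potential fruit dry mass (g) at thermal time ``dj`` (GDD).

    Logistic growth anchored so that ``dm_fruit(dj0) == DM0`` exactly:
    ``DM0 - S*L(dj0) + S*L(dj)`` with ``L`` the logistic term and
    ``S = A*DM0**B`` the asymptote amplitude.
    """
    if dj0 is None:
        dj0 = c.dj0
    if dj0 is None:
        raise ValueError("dj0 must be given in the config or as an argument")
    scale = c.asymptote_scale(p.A, p.B)
    return c.DM0 - scale * _logistic(dj0, p.RGRini, p.P3) + scale * _logistic(dj, p.RGRini, p.P3)


def dm_stone(dmfruit, p: FruitParameters):
    """Stone dry mass (g): ``Wstone * (1 - exp(-kstone * DMfruit))``."""
    dmfruit = np.asarray(dmfruit, dtype=float)
    if np.any(dmfruit < 0):
        raise ValueError("fruit dry mass must be >= 0")
    return p.Wstone * (-np.expm1(-p.kstone * dmfruit))


def stone_ratio(dj, p: FruitParameters, c: GrowthConfig, dj0: float | None = None):
    """Stone / fruit dry-mass ratio at thermal time ``dj``."""
    dm = dm_fruit(dj, p, c, dj0=dj0)
    if np.any(np.asarray(dm) <= 0):
        raise SimulationError("stone ratio undefined at zero fruit mass")
    return dm_stone(dm, p) / dm


def flesh_carbon_supply(t, p: FruitParameters, c: GrowthConfig, w: WeatherSeries):
    """Flesh carbon supply ``F_Csupp`` (gC day^-1) at time ``t`` (DAB).

    Demand-driven closure: the supply covers structural carbon plus growth
    respiration of the realized flesh growth,
    ``F_Csupp = (alpha + beta) * dDM_flesh/dt``.
    """
    P = p.to_array().reshape(1, 7)
    rates = _flesh_growth_rate(t, P, c, w)[:, 0] * (c.alpha + c.beta)
    return float(rates[0]) if np.ndim(t) == 0 else rates


def _flesh_growth_rate(t, P, c: GrowthConfig, w: WeatherSeries):
    """``dDM_flesh/dt`` (g day^-1); vectorized over times (rows) x fruits (cols)."""
    A, B, RGR, P3, k, W = (P[:, i] for i in range(6))
    scale = c.asymptote_scale(A, B) * _growth_multiplier(P, c)
    dj0 = c.dj0 if c.dj0 is not None else float(w.gdd_at(c.start_dab))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    dj = np.asarray(w.gdd_at(t), dtype=float)[:, None]
    rate = np.asarray(w.rate_at(t), dtype=float)[:, None]
    sig = _logistic(dj, RGR[None, :], P3[None, :])
    ddm_ddj = scale[None, :] * RGR[None, :] * sig * (1.0 - sig)
    dm = c.DM0 - scale[None, :] * _logistic(dj0, RGR, P3)[None, :] + scale[None, :] * sig
    stone_slope = W[None, :] * k[None, :] * np.exp(np.clip(-k[None, :] * dm, -_EXP_CLIP, 0))
    return ddm_ddj * rate * (1.0 - stone_slope)


def _growth_multiplier(P, c: GrowthConfig):
    """Optional source-limitation hook; 1 (non-limiting) by default."""
    if c.sla_ref is None:
        return np.ones(P.shape[0])
    return np.minimum(1.0, P[:, 6] / c.sla_ref)


def integrate_sugar(supply: Callable, c0, t: np.ndarray, c: GrowthConfig):
    """Integrate ``dCsugar/dt = F_Csupp*(1 - alpha/(alpha+beta)) - ksugar*Csugar``.

    Classic fixed-step 4th-order Runge-Kutta on the grid ``t``.  ``supply``
    maps a scalar time to ``F_Csupp`` (scalar or vector over fruits); ``c0``
    is the initial sugar carbon.  Returns the solution on ``t``.

    Raises
    ------
    SimulationError
        If the solution goes negative (a symptom of a too-large step for
        the given consumption rate).
    """
    t = np.asarray(t, dtype=float)
    part = 1.0 - c.alpha / (c.alpha + c.beta)
    ks = c.ksugar
    mids = 0.5 * (t[:-1] + t[1:])
    s_full = _sample_supply(supply, t)
    s_mid = _sample_supply(supply, mids)

    out = np.empty(t.shape + np.shape(c0), dtype=float)
    cur = np.array(c0, dtype=float)
    out[0] = cur
    for i in range(t.size - 1):
        h = t[i + 1] - t[i]
        k1 = part * s_full[i] - ks * cur
        k2 = part * s_mid[i] - ks * (cur + h / 2 * k1)
        k3 = part * s_mid[i] - ks * (cur + h / 2 * k2)
        k4 = part * s_full[i + 1] - ks * (cur + h * k3)
        cur = cur + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i + 1] = cur
    if np.any(out < 0):
        raise SimulationError(
            "sugar carbon went negative during integration; use a smaller step")
    return out


def _sample_supply(supply: Callable, times: np.ndarray) -> np.ndarray:
    """Evaluate the supply on a whole time grid, vectorized when possible."""
    try:
        values = np.asarray(supply(times), dtype=float)
        if values.shape[:1] == times.shape:
            return values
    except Exception:
        pass
    return np.asarray([supply(tq) for tq in times], dtype=float)


def sugar_concentration(csugar, fmflesh, c: GrowthConfig):
    """Total sugar concentration ``SU = 100 * Csugar / (sigma_ts * FM_flesh)``."""
    fmflesh = np.asarray(fmflesh, dtype=float)
    if np.any(fmflesh <= 0):
        raise SimulationError("sugar concentration undefined at zero flesh mass")
    return 100.0 * np.asarray(csugar, dtype=float) / (c.sigma_ts * fmflesh)


# ---------------------------------------------------------------------------
# Whole-fruit simulation
# ---------------------------------------------------------------------------

def _time_grid(c: GrowthConfig) -> np.ndarray:
    n = int(round((c.end_dab - c.start_dab) / c.step))
    if not np.isclose(c.start_dab + n * c.step, c.end_dab):
        raise ValueError("step must divide the simulation window evenly")
    return c.start_dab + c.step * np.arange(n + 1)


def simulate_phenotypes(P: np.ndarray, c: GrowthConfig, w: WeatherSeries) -> np.ndarray:
    """Simulate many fruits at once.

    Parameters
    ----------
    P:
        ``(n, 7)`` array of parameters in ``PARAMETER_NAMES`` order.

    Returns
    -------
    ``(n, 3)`` array of final (DM, SR, SU).
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[1] != 7:
        raise ValueError("P must have shape (n, 7)")
    t = _time_grid(c)
    dj = np.asarray(w.gdd_at(t), dtype=float)
    dj0 = c.dj0 if c.dj0 is not None else float(dj[0])

    A, B, RGR, P3, k, W = (P[:, i] for i in range(6))
    scale = c.asymptote_scale(A, B) * _growth_multiplier(P, c)
    sig = _logistic(dj[:, None], RGR[None, :], P3[None, :])          # (T, n)
    dm = c.DM0 - scale[None, :] * _logistic(dj0, RGR, P3)[None, :] + scale[None, :] * sig
    stone = W[None, :] * (-np.expm1(np.clip(-k[None, :] * dm, -_EXP_CLIP, 0)))
    flesh = dm - stone
    if np.any(flesh <= 0):
        raise SimulationError(
            "flesh dry mass went non-positive: stone allometry exceeds fruit mass "
            "(Wstone*kstone too large for this DM0)")

    c0 = c.f0 * c.beta * flesh[0]
    csugar = integrate_sugar(lambda tq: _flesh_growth_rate(tq, P, c, w) * (c.alpha + c.beta),
                             c0, t, c)
    fm = flesh / c.dmc
    su = sugar_concentration(csugar[-1], fm[-1], c)
    return np.column_stack([dm[-1], stone[-1] / dm[-1], su])


def simulate_phenotype(p: FruitParameters, c: GrowthConfig, w: WeatherSeries,
                       return_trajectory: bool = False):
    """Simulate one fruit; optionally return the full per-step trajectory."""
    P = p.to_array().reshape(1, 7)
    t = _time_grid(c)
    dj = np.asarray(w.gdd_at(t), dtype=float)
    dj0 = c.dj0 if c.dj0 is not None else float(dj[0])
    dm = np.asarray(dm_fruit(dj, p, c, dj0=dj0), dtype=float)
    if c.sla_ref is not None:
        mult = float(_growth_multiplier(P, c)[0])
        dm = c.DM0 + mult * (dm - c.DM0)
    stone = np.asarray(dm_stone(dm, p), dtype=float)
    flesh = dm - stone
    if np.any(flesh <= 0):
        raise SimulationError("flesh dry mass went non-positive")
    supply = lambda tq: _flesh_growth_rate(tq, P, c, w) * (c.alpha + c.beta)
    csugar = integrate_sugar(supply, np.full(1, c.f0 * c.beta * flesh[0]), t, c)[:, 0]
    fm = flesh / c.dmc
    su = np.asarray(sugar_concentration(csugar, fm, c), dtype=float)
    triplet = PhenotypeTriplet(DM=float(dm[-1]), SR=float(stone[-1] / dm[-1]), SU=float(su[-1]))
    if not return_trajectory:
        return triplet
    fcsupp = _flesh_growth_rate(t, P, c, w)[:, 0] * (c.alpha + c.beta)
    traj = Trajectory(t=t, dj=dj, DMfruit=dm, DMstone=stone, DMflesh=flesh,
                      FCsupp=fcsupp, Csugar=csugar, FMflesh=fm, SU=su)
    return triplet, traj
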