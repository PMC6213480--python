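"""Activation thermodynamics from temperature-dependent turnover numbers.

Given kcat measured at several temperatures, the activation energy Ea comes
from an ordinary-least-squares Arrhenius fit,

    kcat = A · exp(−Ea / RT)        (ln kcat linear in 1/T),

and the transition-state parameters follow Feller's treatment of
cold-adapted enzymes (Eyring with Ea = ΔH‡ + RT):

    ΔH‡ = Ea − RT
    ΔS‡ = R · (ln kcat − C − ln T + Ea/RT),   C = ln(kB/h) + 1 ≈ 24.76
    ΔG‡ = ΔH‡ − T·ΔS‡

The constant C is *derived* from kB and h (the +1 absorbs the Ea = ΔH + RT
substitution inside the Eyring logarithm) rather than hard-coded, so the
constants stay mutually consistent; it reproduces the conventional 24.76 to
two decimals.  Temperatures convert as T(K) = T(°C) + 273.15.

ΔS‡ uses the *measured* kcat at each temperature, so with a non-zero fit
residual ΔS (and hence ΔG) varies point-to-point beyond the smooth formula
dependence — that residual is information, not error, in this analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELSIUS_OFFSET = 273.15


@dataclass(frozen=True)
class PhysicalConstants:
    """Gas constant, Boltzmann and Planck constants (SI)."""

    R: float = 8.314            # J mol^-1 K^-1
    kB: float = 1.380649e-23    # J K^-1
    h: float = 6.62607015e-34   # J s

    @property
    def eyring_constant(self) -> float:
        """ln(kB/h) + 1 ≈ 24.76 — the additive constant of the ΔS equation."""
        return math.log(self.kB / self.h) + 1.0


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class RateTemperaturePoint:
    """kcat (s⁻¹) measured at one temperature (°C)."""

    temp_c: float
    kcat: float

    def __post_init__(self) -> None:
        if self.kcat <= 0:
            raise ValueError(f"kcat must be positive, got {self.kcat}")
        if self.temp_kelvin <= 0:
            raise ValueError(f"temperature below absolute zero: {self.temp_c} degC")

    @property
    def temp_kelvin(self) -> float:
        return self.temp_c + CELSIUS_OFFSET


@dataclass(frozen=True)
class ArrheniusFit:
    """Ea (J/mol) and pre-exponential A (s⁻¹) from the ln kcat vs 1/T line."""

    ea_j_mol: float
    a: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.a <= 0 or not math.isfinite(self.ea_j_mol):
            raise ValueError("invalid Arrhenius parameters")

    @property
    def ea_kj_mol(self) -> float:
        return self.ea_j_mol / 1000.0

    def kcat_at(self, temp_c: float, constants: PhysicalConstants = CONSTANTS) -> float:
        t = temp_c + CELSIUS_OFFSET
        return self.a * math.exp(-self.ea_j_mol / (constants.R * t))


@dataclass(frozen=True)
class ActivationPoint:
    """Per-temperature activation parameters (paper-convention units:
    ΔH, ΔG in kJ/mol; ΔS in J/(mol·K))."""

    temp_c: float
    t_kelvin: float
    dh_kj_mol: float
    ds_j_mol_k: float
    dg_kj_mol: float
    kcat: float

    def __post_init__(self) -> None:
        # unit-consistent Gibbs identity, kept as a construction invariant
        recomputed = self.dh_kj_mol - self.t_kelvin * self.ds_j_mol_k / 1000.0
        if abs(recomputed - self.dg_kj_mol) > 0.01:
            raise ValueError("dG inconsistent with dH - T*dS")


def fit_arrhenius(
    points: list[RateTemperaturePoint],
    constants: PhysicalConstants = CONSTANTS,
) -> ArrheniusFit:
    """OLS of ln kcat on 1/T over all supplied points; Ea = −slope·R,
    A = exp(intercept).  Requires ≥ 2 distinct temperatures."""
    temps = np.array([p.temp_kelvin for p in points])
    if len(np.unique(temps)) < 2:
        raise ValueError("need at least 2 distinct temperatures")
    y = np.log([p.kcat for p in points])
    x = 1.0 / temps
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return ArrheniusFit(
        ea_j_mol=float(-slope * constants.R),
        a=float(np.exp(intercept)),
        r_squared=r2,
        n_points=len(points),
    )


def activation_profile(
    points: list[RateTemperaturePoint],
    fit: ArrheniusFit,
    constants: PhysicalConstants = CONSTANTS,
) -> list[ActivationPoint]:
    """ΔH‡, ΔS‡, ΔG‡ at every measured temperature.

    ΔH comes from the fitted Ea alone; ΔS additionally uses the measured
    kcat at that temperature; ΔG closes the Gibbs identity.  Full precision
    is kept — rounding happens only in table renderers.
    """
    r = constants.R
    c = constants.eyring_constant
    out: list[ActivationPoint] = []
    for p in points:
        t = p.temp_kelvin
        dh = fit.ea_j_mol - r * t                                  # J/mol
        ds = r * (math.log(p.kcat) - c - math.log(t) + fit.ea_j_mol / (r * t))
        dg = dh - t * ds                                           # J/mol
        out.append(
            ActivationPoint(
                temp_c=p.temp_c,
                t_kelvin=t,
                dh_kj_mol=dh / 1000.0,
                ds_j_mol_k=ds,
                dg_kj_mol=dg / 1000.0,
                kcat=p.kcat,
            )
        )
    return out


def eyring_roundtrip(
    point: ActivationPoint, constants: PhysicalConstants = CONSTANTS
) -> float:
    """Reconstruct kcat from an activation point by inverting the ΔS formula:

        kcat = exp(ΔS/R + C + ln T − (ΔH + RT)/(RT))

    Exact (to floating point) for profiles built by ``activation_profile``,
    because ΔH + RT reproduces the fitted Ea.
    """
    r = constants.R
    t = point.t_kelvin
    dh = point.dh_kj_mol * 1000.0
    ds = point.ds_j_mol_k
    return math.exp(ds / r + constants.eyring_constant + math.log(t) - (dh + r * t) / (r * t))


# ---------------------------------------------------------------------------
# Tabular I/O


def read_rate_temperature_table(path_or_buffer) -> list[RateTemperaturePoint]:
    """CSV/TSV with columns temp_C, kcat."""
    import io

    if isinstance(path_or_buffer, str) and "\n" in path_or_buffer:
        path_or_buffer = io.StringIO(path_or_buffer)
    frame = pd.read_csv(path_or_buffer, sep=None, engine="python")
    frame.columns = [c.strip().lower() for c in frame.columns]
    if "temp_c" not in frame.columns or "kcat" not in frame.columns:
        raise ValueError("rate-temperature table needs columns temp_C and kcat")
    return [
        RateTemperaturePoint(temp_c=float(r.temp_c), kcat=float(r.kcat))
        for r in frame.itertuples()
    ]


def activation_frame(profile: list[ActivationPoint], fit: ArrheniusFit) -> pd.DataFrame:
    """Two-decimal table (temperature, ΔH, ΔS, ΔG, kcat) with Ea attached as
    frame metadata."""
    frame = pd.DataFrame(
        {
            "temp_C": [p.temp_c for p in profile],
            "dH_kJ_mol": [round(p.dh_kj_mol, 2) for p in profile],
            "dS_J_mol_K": [round(p.ds_j_mol_k, 2) for p in profile],
            "dG_kJ_mol": [round(p.dg_kj_mol, 2) for p in profile],
            "kcat_per_s": [p.kcat for p in profile],
        }
    )
    frame.attrs["ea_kj_mol"] = round(fit.ea_kj_mol, 2)
    return frame
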