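"""Michaelis–Menten kinetics by the Lineweaver–Burk double-reciprocal method.

The reported estimator is ordinary least squares of 1/v on 1/S (the classic
double-reciprocal linearization): slope = Km/Vm, intercept = 1/Vm.  The
linearization distorts the error structure — low-concentration points
dominate — so a direct nonlinear least-squares fit of v = Vm·S/(Km+S) is
provided as a *diagnostic* cross-check; on noise-free data the two agree to
machine precision, on noisy data they differ and the reciprocal fit remains
the reported one because it is the method under study.

kcat is taken as an explicit input when available (the turnover number's
stoichiometric basis — per subunit vs per oligomer — is an experimental
convention the rate data alone cannot settle); a Vm-derived conversion
kcat = Vm · M(kDa) / 60 is available but never substituted silently.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KineticPoint:
    """One (substrate concentration, initial rate) observation.

    S in mM; v in μmol·min⁻¹·mg⁻¹.
    """

    s_mm: float
    v: float

    def __post_init__(self) -> None:
        if self.s_mm <= 0:
            raise ValueError(f"substrate concentration must be positive, got {self.s_mm}")
        if self.v < 0:
            raise ValueError(f"rate must be non-negative, got {self.v}")


@dataclass(frozen=True)
class MichaelisFit:
    """Km/Vm estimates with optional turnover number and efficiency.

    Km in mM, Vm in μmol·min⁻¹·mg⁻¹, kcat in s⁻¹, efficiency in mM⁻¹·s⁻¹.
    """

    km_mm: float
    vm: float
    kcat: float | None = None
    efficiency: float | None = None
    r_squared: float = float("nan")
    n_points: int = 0
    method: str = "lineweaver_burk"

    def __post_init__(self) -> None:
        if self.km_mm <= 0 or self.vm <= 0:
            raise ValueError("Km and Vm must be positive")
        if self.kcat is not None and self.efficiency is not None:
            expected = self.kcat / self.km_mm
            if abs(self.efficiency - expected) > 1e-9 * max(1.0, abs(expected)):
                raise ValueError("efficiency inconsistent with kcat/Km")

    def rate_at(self, s_mm: float) -> float:
        """Fitted Michaelis–Menten rate at concentration S."""
        return self.vm * s_mm / (self.km_mm + s_mm)


def michaelis_menten(s, vm, km):
    return vm * s / (km + s)


def fit_lineweaver_burk(data: list[KineticPoint]) -> MichaelisFit:
    """OLS of 1/v on 1/S; Vm = 1/intercept, Km = slope/intercept.

    Points with v == 0 cannot enter the reciprocal transform and are dropped
    with a warning.  Requires ≥ 3 points at distinct concentrations; a
    non-positive intercept means the data show no saturating behaviour and
    is an error rather than a negative Vm.
    """
    usable = [p for p in data if p.v > 0]
    dropped = len(data) - len(usable)
    if dropped:
        logger.warning("dropping %d zero-rate point(s) from reciprocal fit", dropped)
    s = np.array([p.s_mm for p in usable])
    v = np.array([p.v for p in usable])
    if len(np.unique(s)) < 3:
        raise ValueError("need at least 3 points with distinct substrate concentrations")
    x, y = 1.0 / s, 1.0 / v
    slope, intercept = np.polyfit(x, y, 1)
    if intercept <= 0:
        raise ValueError("no saturating behaviour: reciprocal-plot intercept <= 0")
    vm = 1.0 / intercept
    km = slope / intercept
    if km <= 0:
        raise ValueError(f"fitted Km is non-positive ({km:.3g} mM)")
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return MichaelisFit(km_mm=float(km), vm=float(vm), r_squared=r2, n_points=len(usable))


def fit_michaelis_nonlinear(data: list[KineticPoint]) -> MichaelisFit:
    """Direct nonlinear least squares on the untransformed rate law
    (diagnostic cross-check for the reciprocal estimator)."""
    usable = [p for p in data if p.v > 0]
    s = np.array([p.s_mm for p in usable])
    v = np.array([p.v for p in usable])
    if len(np.unique(s)) < 3:
        raise ValueError("need at least 3 points with distinct substrate concentrations")
    p0 = (float(v.max()), float(np.median(s)))
    (vm, km), _ = curve_fit(michaelis_menten, s, v, p0=p0, maxfev=10000)
    resid = v - michaelis_menten(s, vm, km)
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return MichaelisFit(
        km_mm=float(km), vm=float(vm), r_squared=r2, n_points=len(usable),
        method="nonlinear_ls",
    )


def derive_kcat(
    fit: MichaelisFit,
    kcat_override: float | None = None,
    enzyme_mass_da: float | None = None,
) -> MichaelisFit:
    """Attach a turnover number and recompute kcat/Km.

    Either an explicit kcat (s⁻¹) is stored as given, or it is derived from
    Vm and the enzyme molar mass as

        kcat [s⁻¹] = Vm [μmol·min⁻¹·mg⁻¹] × M [kDa] / 60

    (μmol/min per mg × g/mol cancels to min⁻¹, /60 to s⁻¹).  An explicit
    value always wins; with neither source this is an error.
    """
    if kcat_override is not None:
        kcat = float(kcat_override)
    elif enzyme_mass_da is not None:
        kcat = fit.vm * (enzyme_mass_da / 1000.0) / 60.0
    else:
        raise ValueError("supply either kcat_override or enzyme_mass_da")
    return replace(fit, kcat=kcat, efficiency=kcat / fit.km_mm)


def specificity_table(fits: dict[str, MichaelisFit]) -> pd.DataFrame:
    """Substrate ranking by catalytic efficiency (descending kcat/Km, ties
    broken alphabetically).  Fits lacking kcat rank by Vm/Km as a fallback
    and are marked accordingly."""
    if not fits:
        raise ValueError("need at least one fit")
    rows = []
    for name, fit in fits.items():
        eff = fit.efficiency if fit.efficiency is not None else fit.vm / fit.km_mm
        rows.append(
            {
                "substrate": name,
                "vm": fit.vm,
                "km_mm": fit.km_mm,
                "kcat": fit.kcat if fit.kcat is not None else math.nan,
                "efficiency": eff,
            }
        )
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        ["efficiency", "substrate"], ascending=[False, True]
    ).reset_index(drop=True)
    return frame


# ---------------------------------------------------------------------------
# Tabular I/O


def read_kinetics_table(path_or_buffer) -> dict[str, list[KineticPoint]]:
    """CSV/TSV with columns substrate, S_mM, v → points grouped by substrate.
    A missing substrate column means a single unnamed dataset."""
    if isinstance(path_or_buffer, (str,)) and "\n" in path_or_buffer:
        path_or_buffer = io.StringIO(path_or_buffer)
    frame = pd.read_csv(path_or_buffer, sep=None, engine="python")
    frame.columns = [c.strip().lower() for c in frame.columns]
    if "s_mm" not in frame.columns or "v" not in frame.columns:
        raise ValueError("kinetics table needs columns S_mM and v")
    if "substrate" not in frame.columns:
        frame["substrate"] = "substrate"
    out: dict[str, list[KineticPoint]] = {}
    for name, grp in frame.groupby("substrate", sort=False):
        out[str(name)] = [
            KineticPoint(s_mm=float(r.s_mm), v=float(r.v)) for r in grp.itertuples()
        ]
    return out


def read_kcat_table(path_or_buffer) -> dict[str, float]:
    """CSV/TSV with columns substrate, kcat → explicit turnover numbers."""
    if isinstance(path_or_buffer, (str,)) and "\n" in path_or_buffer:
        path_or_buffer = io.StringIO(path_or_buffer)
    frame = pd.read_csv(path_or_buffer, sep=None, engine="python")
    frame.columns = [c.strip().lower() for c in frame.columns]
    if "substrate" not in frame.columns or "kcat" not in frame.columns:
        raise ValueError("kcat table needs columns substrate and kcat")
    return {str(r.substrate): float(r.kcat) for r in frame.itertuples()}


def specificity_tsv(frame: pd.DataFrame) -> str:
    """Two-decimal TSV rendering of the specificity table."""
    shown = frame.copy()
    for col in ("vm", "km_mm", "kcat", "efficiency"):
        shown[col] = shown[col].map(lambda x: f"{x:.2f}" if pd.notna(x) else "")
    return shown.to_csv(sep="\t", index=False)
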