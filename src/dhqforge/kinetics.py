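"""Enzyme kinetics from microplate progress curves.

The dehydratase assay follows product formation (3-dehydroshikimate) by
absorbance at 234 nm.  The analysis chain is:

1. convert each A234 progress curve to product concentration by
   Beer–Lambert (``P = A / (epsilon * l) * 1e6`` in umol/L),
2. estimate the initial rate ``v`` from the best linear window anchored at
   the start of the curve, restricted to the first 20% of substrate
   conversion,
3. fit the Michaelis–Menten constants by the Lineweaver–Burk double
   reciprocal ``1/v = (Km/Vmax) (1/S) + 1/Vmax`` with ordinary least
   squares,
4. derive kcat = Vmax/[E], catalytic efficiency kcat/Km, and the specific
   activity at 500 umol/L substrate in U/mg (U = umol/min).

Double-reciprocal OLS is kept as the default because it is the classical
plate-assay convention; a direct nonlinear Michaelis–Menten fit is
available as an opt-in cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError, InputError

#: Substrate concentration (umol/L) at which specific activity is reported.
SPECIFIC_ACTIVITY_SUBSTRATE = 500.0


@dataclass(frozen=True)
class AssayConfig:
    """Plate-assay constants.

    epsilon: product extinction coefficient at 234 nm, L mol^-1 cm^-1
        (default 1.2e4, the classical value for 3-dehydroshikimate).
    path_length: optical path in cm (default 0.29, ~100 uL in a standard
        96-well UV plate).
    reaction_volume: well volume in uL.
    enzyme_conc: enzyme concentration in umol/L (None when unknown; kcat
        and efficiency are then unavailable).
    protein_mass: mg protein per well (None disables specific activity).
    """

    epsilon: float = 1.2e4
    path_length: float = 0.29
    reaction_volume: float = 100.0
    enzyme_conc: float | None = None
    protein_mass: float | None = None

    def __post_init__(self) -> None:
        for name in ("epsilon", "path_length", "reaction_volume"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        for name in ("enzyme_conc", "protein_mass"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise InputError(f"{name} must be positive when given")


@dataclass
class ProgressCurve:
    """One well's A234 time series at a known substrate concentration."""

    well: str
    times: np.ndarray  # seconds, strictly increasing
    absorbance: np.ndarray  # A234, same length
    substrate: float  # umol/L

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.times.shape != self.absorbance.shape:
            raise InputError(f"{self.well}: times and absorbance differ in length")
        if self.times.size < 4:
            raise InputError(f"{self.well}: need at least 4 time points")
        if not np.all(np.diff(self.times) > 0):
            raise InputError(f"{self.well}: times must be strictly increasing")
        if self.substrate <= 0:
            raise InputError(f"{self.well}: substrate must be positive")


@dataclass(frozen=True)
class RateEstimate:
    """Initial rate from one progress curve."""

    substrate: float  # umol/L
    v: float  # umol/L/s
    r_squared: float
    window: tuple[int, int]  # half-open index range used for the fit
    flagged: bool = False  # true when the curve was flat/decreasing


@dataclass(frozen=True)
class LineweaverBurkFit:
    """Double-reciprocal OLS fit diagnostics."""

    Km: float
    Vmax: float
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def to_dict(self) -> dict[str, float]:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


@dataclass
class KineticConstants:
    """Per-enzyme kinetic record in the units of the library table."""

    code: str
    Km: float  # umol/L
    Vmax: float  # umol/L/s
    kcat: float | None = None  # s^-1
    efficiency: float | None = None  # L/umol/s
    specific_activity: float | None = None  # U/mg at 500 umol/L
    fit: dict = field(default_factory=dict)


def michaelis_menten_rate(S: float, Km: float, Vmax: float) -> float:
    """v = Vmax * S / (Km + S); accepts scalars or arrays for S."""
    if Km <= 0:
        raise InputError("Km must be positive")
    if Vmax < 0:
        raise InputError("Vmax must be non-negative")
    S_arr = np.asarray(S, dtype=float)
    if np.any(S_arr < 0):
        raise InputError("substrate concentration must be non-negative")
    v = Vmax * S_arr / (Km + S_arr)
    return float(v) if np.isscalar(S) or S_arr.ndim == 0 else v


def _anchored_window_stats(t: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Slope and r^2 of OLS lines over windows [0..k] for all k >= 2.

    Returns arrays indexed by k (entries for k < 2 are NaN).  Uses running
    sums on origin-shifted data for stability.
    """
    t = t - t[0]
    y = y - y[0]
    n = np.arange(1, t.size + 1, dtype=float)
    sx = np.cumsum(t)
    sy = np.cumsum(y)
    sxx = np.cumsum(t * t)
    sxy = np.cumsum(t * y)
    syy = np.cumsum(y * y)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = n * sxy - sx * sy
        var_x = n * sxx - sx * sx
        var_y = n * syy - sy * sy
        slope = cov / var_x
        r2 = np.where(var_y > 0, cov * cov / (var_x * var_y), 0.0)
    slope[:2] = np.nan
    r2[:2] = np.nan
    return slope, r2


def extract_initial_rate(curve: ProgressCurve, cfg: AssayConfig) -> RateEstimate:
    """Initial rate from the best early linear window of a progress curve.

    Candidate windows start at the first time point and end at any later
    point such that no more than 20% of the substrate has been converted
    (at least 3 points are always allowed); the window with the highest
    r^2 wins, longest window on ties.  A flat or decreasing curve yields a
    flagged zero-rate estimate rather than an exception.
    """
    scale = 1e6 / (cfg.epsilon * cfg.path_length)  # A -> umol/L product
    product = curve.absorbance * scale
    converted = product - product[0]
    # admissible prefix: points before conversion first exceeds 20%
    limit_breaks = np.flatnonzero(converted > 0.2 * curve.substrate)
    k_max = int(limit_breaks.min()) - 1 if limit_breaks.size else curve.times.size - 1
    k_max = max(k_max, 2)  # always allow the first three points
    k_max = min(k_max, curve.times.size - 1)
    slope, r2 = _anchored_window_stats(curve.times, curve.absorbance)
    ks = np.arange(2, k_max + 1)
    best_r2 = np.nanmax(r2[ks])
    if not np.isfinite(best_r2):
        best_k = k_max
    else:
        tied = ks[r2[ks] >= best_r2 - 0.0]
        best_k = int(tied.max())
    a_slope = slope[best_k]
    v = float(a_slope * scale) if np.isfinite(a_slope) else 0.0
    flagged = False
    if not np.isfinite(v) or v <= 0:
        v, flagged = 0.0, True
    r_sq = float(r2[best_k]) if np.isfinite(r2[best_k]) else 0.0
    return RateEstimate(
        substrate=curve.substrate,
        v=v,
        r_squared=r_sq,
        window=(0, best_k + 1),
        flagged=flagged,
    )


def fit_lineweaver_burk(rates: Sequence[RateEstimate]) -> LineweaverBurkFit:
    """OLS of 1/v on 1/S; Vmax = 1/intercept, Km = slope/intercept.

    Zero-rate estimates are excluded with a warning; at least 3 usable
    points at distinct substrate concentrations are required; a
    non-positive intercept (which would imply infinite or negative Vmax,
    typically because the substrate range sits far below Km) is rejected.
    """
    usable = [r for r in rates if r.v > 0]
    dropped = len(rates) - len(usable)
    if dropped:
        warnings.warn(
            f"excluded {dropped} zero-rate point(s) from the double-reciprocal fit",
            stacklevel=2,
        )
    if len({r.substrate for r in usable}) < 3:
        raise FitError(
            f"need >=3 usable points at distinct substrate concentrations, "
            f"got {len(usable)}"
        )
    inv_s = np.array([1.0 / r.substrate for r in usable])
    inv_v = np.array([1.0 / r.v for r in usable])
    res = stats.linregress(inv_s, inv_v)
    if res.intercept <= 0:
        raise FitError(
            "non-positive double-reciprocal intercept: the substrate range "
            "likely sits far below Km, so Vmax cannot be resolved"
        )
    return LineweaverBurkFit(
        Km=res.slope / res.intercept,
        Vmax=1.0 / res.intercept,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(usable),
    )


def fit_michaelis_menten_nonlinear(
    rates: Sequence[RateEstimate],
) -> tuple[float, float]:
    """Opt-in cross-check: direct nonlinear least-squares MM fit.

    Returns (Km, Vmax).  Never used by the default pipeline.
    """
    usable = [r for r in rates if r.v > 0]
    if len(usable) < 3:
        raise FitError("need >=3 usable points for the nonlinear fit")
    S = np.array([r.substrate for r in usable])
    v = np.array([r.v for r in usable])
    p0 = (np.median(S), v.max() * 1.5)
    (Km, Vmax), _ = optimize.curve_fit(
        lambda s, km, vmax: vmax * s / (km + s), S, v, p0=p0, maxfev=10000
    )
    return float(Km), float(Vmax)


def derive_constants(
    Km: float,
    Vmax: float,
    cfg: AssayConfig,
    code: str = "",
    fit: LineweaverBurkFit | None = None,
) -> KineticConstants:
    """kcat, kcat/Km and specific activity from fitted Km and Vmax.

    kcat = Vmax / [E] (s^-1); efficiency = kcat/Km (L/umol/s); the specific
    activity is the rate at 500 umol/L substrate converted to product
    umol/min in the well volume per mg protein (U/mg).  Missing enzyme
    concentration or protein mass leaves the dependent quantities as None.
    """
    if Km <= 0:
        raise InputError("Km must be positive")
    kcat = efficiency = specific_activity = None
    if cfg.enzyme_conc is not None:
        kcat = Vmax / cfg.enzyme_conc
        efficiency = kcat / Km
    if cfg.protein_mass is not None:
        v500 = michaelis_menten_rate(SPECIFIC_ACTIVITY_SUBSTRATE, Km, Vmax)
        umol_per_s = v500 * cfg.reaction_volume * 1e-6  # umol/L/s * L
        specific_activity = umol_per_s * 60.0 / cfg.protein_mass
    return KineticConstants(
        code=code,
        Km=Km,
        Vmax=Vmax,
        kcat=kcat,
        efficiency=efficiency,
        specific_activity=specific_activity,
        fit=fit.to_dict() if fit is not None else {},
    )


def analyze_plate(
    curves: Sequence[ProgressCurve], cfg: AssayConfig, code: str = ""
) -> tuple[KineticConstants, list[RateEstimate]]:
    """Progress curves -> initial rates -> LB fit -> derived constants."""
    rates = [extract_initial_rate(c, cfg) for c in curves]
    fit = fit_lineweaver_burk(rates)
    constants = derive_constants(fit.Km, fit.Vmax, cfg, code=code, fit=fit)
    return constants, rates


# ---------------------------------------------------------------------------
# library-level summaries
# ---------------------------------------------------------------------------

#: Reporting precision per column (decimal places), matching library-table
#: conventions: one decimal for Vmax/Km, two for kcat, efficiency and
#: specific activity.
_REPORT_DECIMALS = {
    "Vmax": 1,
    "Km": 1,
    "kcat": 2,
    "efficiency": 2,
    "specific_activity": 2,
}

_PARAMS = ("Vmax", "Km", "kcat", "efficiency", "specific_activity")


def _value(constants: KineticConstants, param: str) -> float | None:
    val = getattr(constants, param)
    if val is None or (isinstance(val, float) and math.isnan(val)):
        return None
    return float(val)


def summarize_library(
    constants: Sequence[KineticConstants],
) -> dict[str, dict[str, float | str]]:
    """Column extremes (value and owning code) per kinetic parameter.

    Values are rounded to the reporting precision of each column; internal
    full-precision values are untouched.  Order of the input does not
    matter.
    """
    if not constants:
        raise InputError("cannot summarize an empty constants list")
    summary: dict[str, dict[str, float | str]] = {}
    for param in _PARAMS:
        rows = [
            (v, c.code)
            for c in constants
            if (v := _value(c, param)) is not None
        ]
        if not rows:
            continue
        nd = _REPORT_DECIMALS[param]
        vmin, argmin = min(rows)
        vmax, argmax = max(rows)
        summary[param] = {
            "min": round(vmin, nd),
            "max": round(vmax, nd),
            "argmin": argmin,
            "argmax": argmax,
        }
    return summary


@dataclass(frozen=True)
class DiversityReport:
    """Each enzyme's parameters as percent of a reference enzyme's."""

    reference_code: str
    ratios: Mapping[str, Mapping[str, float]]  # code -> param -> percent
    omitted: tuple[str, ...] = ()  # codes without usable values

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"code": code, **params} for code, params in sorted(self.ratios.items())
        ]
        return pd.DataFrame(rows)


def diversity_ratios(
    constants: Sequence[KineticConstants],
    reference_code: str = "3001",
    params: Sequence[str] = ("Vmax", "Km", "kcat", "efficiency"),
) -> DiversityReport:
    """ratio = 100 * value / reference value, per parameter per enzyme.

    Enzymes missing any requested parameter are omitted and listed in the
    report; the reference itself maps to 100.0 everywhere.
    """
    by_code = {c.code: c for c in constants}
    ref = by_code.get(reference_code)
    if ref is None:
        raise InputError(f"reference code {reference_code!r} not in constants")
    ref_vals = {p: _value(ref, p) for p in params}
    if any(v is None or v <= 0 for v in ref_vals.values()):
        raise InputError(
            f"reference {reference_code!r} must have positive values for {params}"
        )
    ratios: dict[str, dict[str, float]] = {}
    omitted: list[str] = []
    for code in sorted(by_code):
        vals = {p: _value(by_code[code], p) for p in params}
        if any(v is None for v in vals.values()):
            omitted.append(code)
            continue
        ratios[code] = {
            p: round(100.0 * vals[p] / ref_vals[p], 1) for p in params
        }
    return DiversityReport(
        reference_code=reference_code, ratios=ratios, omitted=tuple(omitted)
    )


# ---------------------------------------------------------------------------
# I/O: long-form plate CSV and constants tables
# ---------------------------------------------------------------------------


def read_plate_csv(path: str | Path) -> list[ProgressCurve]:
    """Read a long-form plate CSV: well,time_s,a234,substrate_umol_l."""
    df = pd.read_csv(path)
    needed = {"well", "time_s", "a234", "substrate_umol_l"}
    missing = needed - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    curves = []
    for well, grp in df.groupby("well", sort=True):
        grp = grp.sort_values("time_s")
        substrates = grp["substrate_umol_l"].unique()
        if len(substrates) != 1:
            raise InputError(f"{path}: well {well} mixes substrate concentrations")
        curves.append(
            ProgressCurve(
                well=str(well),
                times=grp["time_s"].to_numpy(),
                absorbance=grp["a234"].to_numpy(),
                substrate=float(substrates[0]),
            )
        )
    return curves


def write_plate_csv(curves: Iterable[ProgressCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for t, a in zip(c.times, c.absorbance):
            rows.append(
                {"well": c.well, "time_s": t, "a234": a, "substrate_umol_l": c.substrate}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


_CSV_COLUMNS = {
    "Vmax": "vmax_umol_l_s",
    "Km": "km_umol_l",
    "kcat": "kcat_per_s",
    "efficiency": "efficiency_l_umol_s",
    "specific_activity": "specific_activity_u_mg",
}


def constants_to_dataframe(constants: Sequence[KineticConstants]) -> pd.DataFrame:
    """Constants table in library-table column order (code, Vmax, Km, kcat,
    kcat/Km, specific activity)."""
    rows = []
    for c in constants:
        row: dict[str, object] = {"code": c.code}
        for param, col in _CSV_COLUMNS.items():
            row[col] = _value(c, param)
        rows.append(row)
    return pd.DataFrame(rows, columns=["code", *_CSV_COLUMNS.values()])


def constants_from_dataframe(df: pd.DataFrame) -> list[KineticConstants]:
    """Inverse of :func:`constants_to_dataframe`; blank cells become None."""
    out = []
    for _, row in df.iterrows():
        def get(col: str) -> float | None:
            val = row.get(col)
            if val is None or (isinstance(val, float) and math.isnan(val)):
                return None
            return float(val)

        km = get("km_umol_l")
        vmax = get("vmax_umol_l_s")
        if km is None or vmax is None:
            out.append(
                KineticConstants(
                    code=str(row["code"]),
                    Km=float("nan"),
                    Vmax=float("nan"),
                    kcat=get("kcat_per_s"),
                    efficiency=get("efficiency_l_umol_s"),
                    specific_activity=get("specific_activity_u_mg"),
                )
            )
        else:
            out.append(
                KineticConstants(
                    code=str(row["code"]),
                    Km=km,
                    Vmax=vmax,
                    kcat=get("kcat_per_s"),
                    efficiency=get("efficiency_l_umol_s"),
                    specific_activity=get("specific_activity_u_mg"),
                )
            )
    return out
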