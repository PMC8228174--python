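"""Michaelis-Menten kinetics for cyclase activity data.

Guanylyl-cyclase activity is reported as the amount of cGMP produced per mg
of protein per minute, measured over a range of GTP concentrations.  This
module provides the Michaelis-Menten rate law v = Vmax*S/(Km + S), a
nonlinear least-squares fitter for (Vmax, Km), a seeded saturation-curve
simulator for testing the fitter, and small helpers for substrate-
specificity and cofactor-preference arithmetic and activity-unit conversion.

Units: substrate concentration S in mM; rates in pmol mg^-1 min^-1
(numerically identical to fmol ug^-1 min^-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares


@dataclass(frozen=True)
class MMParams:
    """Michaelis-Menten parameters: Vmax (rate units) and Km (mM)."""

    vmax: float
    km: float

    def __post_init__(self):
        if self.vmax <= 0 or self.km <= 0:
            raise ValueError(f"vmax and km must be positive, got {self}")


@dataclass(frozen=True)
class KineticsFit:
    vmax: float
    km: float
    residual_ss: float
    converged: bool
    n_iter: int

    @property
    def params(self) -> MMParams:
        return MMParams(self.vmax, self.km)


@dataclass
class ActivitySeries:
    """Substrate-rate observations from one activity assay."""

    conc: np.ndarray  # mM
    rate: np.ndarray  # pmol mg^-1 min^-1
    substrate_label: str = "GTP"
    cofactor_label: str = "Mn"

    def __post_init__(self):
        self.conc = np.asarray(self.conc, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.conc.shape != self.rate.shape or self.conc.ndim != 1:
            raise ValueError("conc and rate must be 1-D arrays of equal length")
        if self.conc.size == 0:
            raise ValueError("at least one observation required")
        if np.any(self.conc < 0):
            raise ValueError("substrate concentrations must be >= 0")


class NonIdentifiableError(ValueError):
    """The design cannot pin down (Vmax, Km)."""


def mm_rate(params: MMParams, S):
    """Michaelis-Menten rate v = Vmax*S/(Km + S); accepts scalar or array S."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentration must be >= 0")
    v = params.vmax * S / (params.km + S)
    return float(v) if v.ndim == 0 else v


def _default_init(series: ActivitySeries) -> MMParams:
    """Vmax0 = 1.2 x max observed rate; Km0 = concentration at half-maximal
    rate, linearly interpolated along the concentration-sorted curve."""
    vmax0 = 1.2 * float(np.max(series.rate))
    half = float(np.max(series.rate)) / 2.0
    order = np.argsort(series.conc)
    conc, rate = series.conc[order], series.rate[order]
    km0 = None
    for i in range(len(conc) - 1):
        lo, hi = rate[i], rate[i + 1]
        if (lo - half) * (hi - half) <= 0 and lo != hi:
            frac = (half - lo) / (hi - lo)
            km0 = float(conc[i] + frac * (conc[i + 1] - conc[i]))
            break
    if km0 is None or km0 <= 0:
        # no bracketing segment: fall back to the concentration whose rate
        # is nearest half-max
        km0 = float(conc[np.argmin(np.abs(rate - half))])
    if km0 <= 0:
        km0 = float(np.median(conc[conc > 0])) if np.any(conc > 0) else 1.0
    return MMParams(vmax=vmax0, km=km0)


def fit_mm(series: ActivitySeries, init: MMParams | None = None) -> KineticsFit:
    """Fit (Vmax, Km) by unweighted nonlinear least squares.

    Requires at least 3 observations at >= 2 distinct nonzero
    concentrations with a nonzero rate somewhere; otherwise the parameters
    are not identifiable and :class:`NonIdentifiableError` is raised.
    Convergence: relative parameter change below 1e-8, capped at 500
    function evaluations.
    """
    nonzero = series.conc[series.conc > 0]
    if series.conc.size < 3 or np.unique(nonzero).size < 2:
        raise NonIdentifiableError(
            "need >= 3 observations at >= 2 distinct nonzero concentrations"
        )
    if np.all(series.rate == 0):
        raise NonIdentifiableError("all observed rates are zero")
    p0 = init or _default_init(series)

    def resid(theta):
        vmax, km = theta
        return vmax * series.conc / (km + series.conc) - series.rate

    result = least_squares(
        resid,
        x0=[p0.vmax, p0.km],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        xtol=1e-8,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=500,
    )
    vmax, km = result.x
    return KineticsFit(
        vmax=float(vmax),
        km=float(km),
        residual_ss=float(np.sum(result.fun**2)),
        converged=bool(result.success),
        n_iter=int(result.nfev),
    )


def simulate_saturation(
    params: MMParams,
    concentrations,
    noise_sd: float = 0.0,
    seed=None,
    substrate_label: str = "GTP",
    cofactor_label: str = "Mn",
) -> ActivitySeries:
    """Simulate a saturation curve: Michaelis-Menten rates plus additive
    Gaussian noise, truncated at zero.  Same seed, same series."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    conc = np.asarray(concentrations, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = mm_rate(params, conc)
    if noise_sd > 0:
        rates = np.maximum(rates + rng.normal(0.0, noise_sd, size=conc.shape), 0.0)
    return ActivitySeries(
        conc=conc,
        rate=np.atleast_1d(rates),
        substrate_label=substrate_label,
        cofactor_label=cofactor_label,
    )


#: Fold-change threshold separating a clear substrate preference from an
#: ambiguous call.  Fixed tool constant.
SPECIFICITY_FOLD_THRESHOLD = 2.0


@dataclass(frozen=True)
class SpecificityResult:
    fold: float  # rate_gtp / rate_atp; inf when rate_atp == 0
    label: str  # "GTP-preferring" | "ATP-preferring" | "ambiguous"
    infinite: bool = False


def specificity_ratio(rate_gtp: float, rate_atp: float) -> SpecificityResult:
    """GTP-vs-ATP preference from one pair of rates.

    GTP-preferring when the ratio is >= 2, ATP-preferring when <= 0.5,
    ambiguous between.  A zero ATP rate is an infinite-fold GTP preference
    (flagged); both rates zero is an error.
    """
    if rate_gtp < 0 or rate_atp < 0:
        raise ValueError("rates must be non-negative")
    if rate_gtp == 0 and rate_atp == 0:
        raise ValueError("both rates are zero; preference undefined")
    if rate_atp == 0:
        return SpecificityResult(fold=math.inf, label="GTP-preferring", infinite=True)
    fold = rate_gtp / rate_atp
    if fold >= SPECIFICITY_FOLD_THRESHOLD:
        label = "GTP-preferring"
    elif fold <= 1.0 / SPECIFICITY_FOLD_THRESHOLD:
        label = "ATP-preferring"
    else:
        label = "ambiguous"
    return SpecificityResult(fold=fold, label=label)


def cofactor_preference(series_by_cofactor: dict) -> list:
    """Order cofactors by mean rate at a concentration shared by all series.

    Returns tie groups: a list of lists, best first; cofactors with exactly
    equal means share a group rather than being broken arbitrarily.
    Raises when fewer than two cofactors or no shared concentration.
    """
    if len(series_by_cofactor) < 2:
        raise ValueError("need at least two cofactor series")
    conc_sets = [
        set(np.asarray(s.conc, dtype=float).tolist())
        for s in series_by_cofactor.values()
    ]
    shared = set.intersection(*conc_sets)
    if not shared:
        raise ValueError("no substrate concentration shared by every cofactor")
    means = {}
    for label, series in series_by_cofactor.items():
        mask = np.isin(series.conc, sorted(shared))
        means[label] = float(np.mean(series.rate[mask]))
    groups: list = []
    for label in sorted(means, key=lambda k: (-means[k], k)):
        if groups and means[groups[-1][0]] == means[label]:
            groups[-1].append(label)
        else:
            groups.append([label])
    return groups


_UNIT_ALIASES = {
    "pmol mg-1 min-1": "pmol mg-1 min-1",
    "pmol/mg/min": "pmol mg-1 min-1",
    "pmol mg^-1 min^-1": "pmol mg-1 min-1",
    "fmol ug-1 min-1": "fmol ug-1 min-1",
    "fmol/ug/min": "fmol ug-1 min-1",
    "fmol ug^-1 min^-1": "fmol ug-1 min-1",
}


def _normalize_unit(unit: str) -> str:
    key = (
        unit.strip()
        .lower()
        .replace("µ", "u")
        .replace("μ", "u")
        .replace("⁻¹", "-1")
        .replace("−1", "-1")
    )
    try:
        return _UNIT_ALIASES[key]
    except KeyError:
        raise ValueError(f"unknown activity unit {unit!r}") from None


def convert_activity_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert between pmol mg^-1 min^-1 and fmol ug^-1 min^-1.

    The 10^3 factors in numerator and denominator cancel, so the conversion
    is the numeric identity; the function exists to validate unit strings
    and make the unit algebra explicit.
    """
    _normalize_unit(from_unit)
    _normalize_unit(to_unit)
    return value
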