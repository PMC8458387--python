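"""Two-state denaturation models for thermal (CD) and chemical unfolding.

Both models are Boltzmann sigmoids with linear pre- and post-transition
baselines.  For chemical denaturation with denaturant concentration D (M):

    F(D) = [(aN + bN*D) + (aD + bD*D) * exp(-m*(Cm - D)/(R*T))]
           / [1 + exp(-m*(Cm - D)/(R*T))]

where Cm is the midpoint concentration and m (kJ mol^-1 M^-1) the slope of
the unfolding free energy with denaturant.  For thermal denaturation with
temperature T (K):

    F(T) = [(aN + bN*T) + (aD + bD*T) * exp(dHm*(1 - T/Tm)/(R*T))]
           / [1 + exp(dHm*(1 - T/Tm)/(R*T))]

with melting temperature Tm and van't Hoff enthalpy dHm (kJ/mol, negative
for unfolding under this sign convention).  Free-energy differences between
a permutant and a reference protein follow the linear-extrapolation
relations ddG = 0.5*(m + m')*dCm (chemical) and ddG = dHm_ref*dTm/Tm_ref
(thermal), with signs arranged so that positive ddG means the mutant is
destabilised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "R_KJ",
    "CELSIUS_OFFSET",
    "DenaturationCurve",
    "ChemicalFitResult",
    "ThermalFitResult",
    "StabilityComparison",
    "FitError",
    "chemical_model",
    "thermal_model",
    "normalize_fraction_denatured",
    "fit_chemical",
    "fit_thermal",
    "ddG_thermal",
    "ddG_chemical",
    "dG_water",
]

#: Gas constant, kJ mol^-1 K^-1.
R_KJ = 8.314e-3
CELSIUS_OFFSET = 273.15


class FitError(RuntimeError):
    """Least-squares fit failed to converge or is degenerate."""


@dataclass
class DenaturationCurve:
    """A denaturation series: x (deg C or mol/L) against a measured signal.

    replicate_id labels points belonging to the same replicate series; x
    must be strictly increasing within each replicate.
    """

    axis_kind: str  # "temperature" | "denaturant"
    x: np.ndarray
    signal: np.ndarray
    replicate_id: np.ndarray | None = None

    def __post_init__(self):
        if self.axis_kind not in ("temperature", "denaturant"):
            raise ValueError(f"axis_kind must be temperature|denaturant, got {self.axis_kind!r}")
        self.x = np.asarray(self.x, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.x.shape != self.signal.shape:
            raise ValueError("x and signal must have the same shape")
        if self.replicate_id is not None:
            self.replicate_id = np.asarray(self.replicate_id)
        for rep, xs in self.by_replicate():
            if np.any(np.diff(xs) <= 0):
                raise ValueError(f"x not strictly increasing within replicate {rep!r}")

    def by_replicate(self):
        if self.replicate_id is None:
            yield None, self.x
            return
        for rep in pd.unique(self.replicate_id):
            yield rep, self.x[self.replicate_id == rep]

    def to_frame(self) -> pd.DataFrame:
        d = {"x": self.x, "signal": self.signal}
        if self.replicate_id is not None:
            d["replicate"] = self.replicate_id
        return pd.DataFrame(d)


@dataclass
class ChemicalFitResult:
    alpha_N: float
    beta_N: float
    alpha_D: float
    beta_D: float
    m: float          # kJ mol^-1 M^-1
    Cm: float         # mol/L
    stderr: dict[str, float]
    temperature_K: float
    R: float = R_KJ
    covariance: np.ndarray | None = None

    def predict(self, denaturant) -> np.ndarray:
        return chemical_model(
            np.asarray(denaturant, dtype=float),
            self.alpha_N, self.beta_N, self.alpha_D, self.beta_D,
            self.m, self.Cm, self.temperature_K, self.R,
        )


@dataclass
class ThermalFitResult:
    alpha_N: float
    beta_N: float
    alpha_D: float
    beta_D: float
    dHm: float        # kJ/mol
    Tm: float         # deg C
    stderr: dict[str, float]
    R: float = R_KJ
    covariance: np.ndarray | None = None

    @property
    def Tm_K(self) -> float:
        return self.Tm + CELSIUS_OFFSET

    def predict(self, temperature_C) -> np.ndarray:
        return thermal_model(
            np.asarray(temperature_C, dtype=float),
            self.alpha_N, self.beta_N, self.alpha_D, self.beta_D,
            self.dHm, self.Tm, self.R,
        )


@dataclass
class StabilityComparison:
    mutant: str
    reference: str
    ddG: float        # kJ/mol, positive = mutant destabilised
    method: str       # "thermal" | "chemical"
    inputs: dict[str, float] = field(default_factory=dict)


def chemical_model(D, alpha_N, beta_N, alpha_D, beta_D, m, Cm,
                   temperature_K: float, R: float = R_KJ):
    """Two-state linear-baseline sigmoid as a function of denaturant (M)."""
    D = np.asarray(D, dtype=float)
    expo = np.exp(-m * (Cm - D) / (R * temperature_K))
    return ((alpha_N + beta_N * D) + (alpha_D + beta_D * D) * expo) / (1.0 + expo)


def thermal_model(T_C, alpha_N, beta_N, alpha_D, beta_D, dHm, Tm_C,
                  R: float = R_KJ):
    """Two-state linear-baseline sigmoid as a function of temperature (deg C).

    Baselines are linear in kelvin; temperatures are converted internally.
    """
    T = np.asarray(T_C, dtype=float) + CELSIUS_OFFSET
    Tm = Tm_C + CELSIUS_OFFSET
    expo = np.exp(dHm * (1.0 - T / Tm) / (R * T))
    return ((alpha_N + beta_N * T) + (alpha_D + beta_D * T) * expo) / (1.0 + expo)


def normalize_fraction_denatured(
    curves: DenaturationCurve | Sequence[DenaturationCurve],
    blanks: np.ndarray | Sequence[float] | None = None,
    orientation: str = "increasing",
) -> DenaturationCurve:
    """Blank-subtract, replicate-average and rescale a signal to [0, 1].

    Replicates (separate curves or replicate_id groups sharing an x grid)
    are averaged point-wise after blank subtraction, then mapped affinely so
    the minimum is 0 and the maximum 1.  orientation="increasing" means the
    raw signal already rises with denaturation; "decreasing" flips it so
    that 1 = fully denatured either way.
    """
    if orientation not in ("increasing", "decreasing"):
        raise ValueError(f"orientation must be increasing|decreasing, got {orientation!r}")
    if isinstance(curves, DenaturationCurve):
        curve_list = [curves]
    else:
        curve_list = list(curves)
    frames = []
    for c in curve_list:
        frames.append(c.to_frame())
    df = pd.concat(frames, ignore_index=True)
    if blanks is not None:
        blanks = np.asarray(blanks, dtype=float)
        grid = np.sort(pd.unique(df["x"]))
        if blanks.shape != grid.shape:
            raise ValueError("blank series must match the x grid of the samples")
        blank_map = dict(zip(grid, blanks))
        df["signal"] = df["signal"] - df["x"].map(blank_map)
    mean = df.groupby("x", sort=True)["signal"].mean()
    y = mean.to_numpy()
    lo, hi = y.min(), y.max()
    if math.isclose(hi, lo, rel_tol=0.0, abs_tol=1e-12):
        raise ValueError("degenerate signal: max equals min after blank subtraction")
    frac = (y - lo) / (hi - lo)
    if orientation == "decreasing":
        frac = 1.0 - frac
    return DenaturationCurve(
        axis_kind=curve_list[0].axis_kind,
        x=mean.index.to_numpy(),
        signal=frac,
    )


def _collapse_replicates(curve: DenaturationCurve) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (x, signal) sorted by x; replicates stay as separate points."""
    order = np.argsort(curve.x, kind="stable")
    return curve.x[order], curve.signal[order]


def _initial_guesses(x: np.ndarray, y: np.ndarray, slope_scale: float):
    """Reproducible starting values for the six sigmoid parameters.

    Baselines come from OLS on the outer 20% of points at each end; the
    midpoint is where a monotonised transition crosses half range; the
    transition steepness comes from the slope of logit(fraction) across the
    central half of the transition.
    """
    n = len(x)
    k = max(2, n // 5)
    bN, aN = np.polyfit(x[:k], y[:k], 1)
    bD, aD = np.polyfit(x[-k:], y[-k:], 1)
    base_n = aN + bN * x
    base_d = aD + bD * x
    denom = base_d - base_n
    # fraction denatured per point; clip away the baselines' crossing noise
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(np.abs(denom) > 1e-12, (y - base_n) / denom, 0.5)
    f = np.clip(f, 1e-4, 1 - 1e-4)
    fmono = np.maximum.accumulate(f)
    xm = float(np.interp(0.5, fmono, x))
    central = (f > 0.2) & (f < 0.8)
    if central.sum() >= 2:
        slope = np.polyfit(x[central], np.log(f[central] / (1 - f[central])), 1)[0]
    else:
        span = (x[-1] - x[0]) or 1.0
        slope = 10.0 / span
    return aN, bN, aD, bD, float(slope) * slope_scale, xm


def _run_fit(model, x, y, p0, param_names) -> tuple[np.ndarray, np.ndarray]:
    try:
        popt, pcov = curve_fit(
            model, x, y, p0=p0, method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=10_000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"least-squares fit failed: {exc}") from exc
    if not np.all(np.isfinite(pcov)):
        raise FitError("fit covariance is not finite; transition poorly determined")
    # a real transition separates the baselines at the midpoint
    aN, bN, aD, bD, _, xm = popt
    xm_int = xm if param_names[-1] != "Tm" else xm + CELSIUS_OFFSET
    sep = abs((aD + bD * xm_int) - (aN + bN * xm_int))
    span = np.ptp(y) or 1.0
    if sep < 0.05 * span:
        raise FitError(
            "baselines are indistinguishable at the fitted midpoint; "
            "curve shows no transition and the midpoint is undetermined"
        )
    return popt, pcov


def fit_chemical(
    curve: DenaturationCurve,
    temperature_K: float = 293.15,
    R: float = R_KJ,
) -> ChemicalFitResult:
    """Fit the chemical two-state model; returns parameters with standard errors.

    Samples are assumed measured at 20 deg C (293.15 K) unless stated
    otherwise.  Replicates are fitted jointly as pooled points.
    """
    if curve.axis_kind != "denaturant":
        raise ValueError("fit_chemical requires a denaturant-axis curve")
    x, y = _collapse_replicates(curve)
    if len(np.unique(x)) < 8:
        raise ValueError("need >= 8 distinct denaturant concentrations spanning both baselines")
    aN, bN, aD, bD, slope, cm0 = _initial_guesses(x, y, slope_scale=R * temperature_K)
    m0 = abs(slope) if slope != 0 else 1.0
    cm0 = min(max(cm0, x[0]), x[-1])

    def model(D, alpha_N, beta_N, alpha_D, beta_D, m, Cm):
        return chemical_model(D, alpha_N, beta_N, alpha_D, beta_D, m, Cm, temperature_K, R)

    names = ["alpha_N", "beta_N", "alpha_D", "beta_D", "m", "Cm"]
    popt, pcov = _run_fit(model, x, y, [aN, bN, aD, bD, m0, cm0], names)
    if not (x[0] <= popt[5] <= x[-1]):
        raise FitError(
            f"fitted Cm {popt[5]:.3g} M lies outside the sampled range "
            f"[{x[0]:.3g}, {x[-1]:.3g}] M; no transition observed"
        )
    se = np.sqrt(np.diag(pcov))
    return ChemicalFitResult(
        *popt, stderr=dict(zip(names, se)),
        temperature_K=temperature_K, R=R, covariance=pcov,
    )


def fit_thermal(curve: DenaturationCurve, R: float = R_KJ) -> ThermalFitResult:
    """Fit the thermal two-state model to a melting curve (x in deg C)."""
    if curve.axis_kind != "temperature":
        raise ValueError("fit_thermal requires a temperature-axis curve")
    x, y = _collapse_replicates(curve)
    if len(np.unique(x)) < 8:
        raise ValueError("need >= 8 distinct temperatures spanning both baselines")
    xK = x + CELSIUS_OFFSET
    aN, bN, aD, bD, slope, tm0 = _initial_guesses(xK, y, slope_scale=1.0)
    tmK = min(max(tm0, xK[0]), xK[-1])
    # d logit/dT at Tm = -dHm / (R Tm^2)
    dHm0 = -slope * R_KJ * tmK**2
    if dHm0 == 0:
        dHm0 = -100.0

    def model(T_C, alpha_N, beta_N, alpha_D, beta_D, dHm, Tm_C):
        return thermal_model(T_C, alpha_N, beta_N, alpha_D, beta_D, dHm, Tm_C, R)

    names = ["alpha_N", "beta_N", "alpha_D", "beta_D", "dHm", "Tm"]
    popt, pcov = _run_fit(model, x, y, [aN, bN, aD, bD, dHm0, tmK - CELSIUS_OFFSET], names)
    if not (x[0] <= popt[5] <= x[-1]):
        raise FitError(
            f"fitted Tm {popt[5]:.3g} C lies outside the sampled range "
            f"[{x[0]:.3g}, {x[-1]:.3g}] C; no transition observed"
        )
    se = np.sqrt(np.diag(pcov))
    return ThermalFitResult(*popt, stderr=dict(zip(names, se)), R=R, covariance=pcov)


def ddG_thermal(
    Tm_mut_C: float,
    Tm_ref_C: float,
    dHm_ref: float,
    mutant: str = "mutant",
    reference: str = "reference",
) -> StabilityComparison:
    """ddG = dHm_ref * (Tm_mut - Tm_ref) / Tm_ref with Tm_ref in kelvin.

    Uses the reference protein's enthalpy and melting temperature; with the
    unfolding convention dHm < 0, a mutant melting below the reference gives
    positive ddG (destabilised).
    """
    for v in (Tm_mut_C, Tm_ref_C, dHm_ref):
        if not math.isfinite(v):
            raise ValueError("inputs must be finite")
    Tm_ref_K = Tm_ref_C + CELSIUS_OFFSET
    if Tm_ref_K <= 0:
        raise ValueError("reference Tm must be above 0 K")
    ddg = dHm_ref * (Tm_mut_C - Tm_ref_C) / Tm_ref_K
    return StabilityComparison(
        mutant=mutant, reference=reference, ddG=ddg, method="thermal",
        inputs={"Tm_mut_C": Tm_mut_C, "Tm_ref_C": Tm_ref_C, "dHm_ref": dHm_ref},
    )


def ddG_chemical(
    m_mut: float,
    m_ref: float,
    Cm_mut: float,
    Cm_ref: float,
    mutant: str = "mutant",
    reference: str = "reference",
) -> StabilityComparison:
    """ddG = 0.5*(m_mut + m_ref)*(Cm_ref - Cm_mut), positive = destabilised."""
    if m_mut <= 0 or m_ref <= 0:
        raise ValueError("m values must be positive")
    ddg = 0.5 * (m_mut + m_ref) * (Cm_ref - Cm_mut)
    return StabilityComparison(
        mutant=mutant, reference=reference, ddG=ddg, method="chemical",
        inputs={"m_mut": m_mut, "m_ref": m_ref, "Cm_mut": Cm_mut, "Cm_ref": Cm_ref},
    )


def dG_water(m: float, Cm: float,
             m_se: float | None = None, Cm_se: float | None = None):
    """Linear-extrapolation unfolding free energy in water, dG0 = m * Cm.

    Returns the value, or (value, standard error) when both parameter
    standard errors are supplied (first-order propagation, independence
    assumed).
    """
    if not (math.isfinite(m) and math.isfinite(Cm)):
        raise ValueError("m and Cm must be finite")
    dg = m * Cm
    if m_se is not None and Cm_se is not None:
        se = math.hypot(Cm * m_se, m * Cm_se)
        return dg, se
    return dg
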