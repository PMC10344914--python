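"""Assay-side models: thermal inactivation, DSC crystallinity, glycolysis
yields, Michaelis–Menten kinetics and fold-change summaries.

Thermal inactivation follows the single-exponential model
E_t = E_0·exp(−kt) with half-life t½ = ln2/k.  Percent crystallinity uses
the melting and cold-crystallization enthalpies relative to the enthalpy of
a 100% crystalline PET sample (140.1 J/g); dividing by the reference — as
the enthalpy legend defines — rather than by ΔH_m itself keeps the result
sensitive to the melting enthalpy.  BHET purity/yield and the theoretical
maximum hydrolysis yield are simple stoichiometric ratios built on the PET
repeating unit (TPA–EG, 192.2 g/mol) and BHET (254.24 g/mol).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import optimize, stats

log = logging.getLogger(__name__)

M_REPEAT_UNIT = 192.2   # g/mol, TPA-EG repeating unit of PET
M_BHET = 254.24         # g/mol
DH_REF_PET = 140.1      # J/g, 100% crystalline PET melting enthalpy


class FitError(RuntimeError):
    """A model fit failed or produced a non-physical estimate."""


# ---------------------------------------------------------------------------
# Datasets and fits


@dataclass
class DecayDataset:
    """Residual-activity time course; activities are normalized to t = 0."""

    times: np.ndarray      # h
    activities: np.ndarray # fraction of initial (input may be % or fraction)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.activities = np.asarray(self.activities, float)
        if self.times.shape != self.activities.shape or self.times.ndim != 1:
            raise ValueError("times and activities must be matching 1D arrays")
        if len(self.times) < 2:
            raise ValueError("need at least 2 time points")
        if self.times[0] != 0:
            raise ValueError("time course must start at t = 0")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        # accept percent input; normalize to fraction of t=0
        if self.activities[0] != 0:
            self.activities = self.activities / self.activities[0]


@dataclass
class DecayFit:
    k: float          # h^-1
    t_half: float     # h
    r_squared: float
    se_k: float = float("nan")


@dataclass
class KineticsDataset:
    """Initial rates vs substrate concentration (mM)."""

    substrate: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.substrate = np.asarray(self.substrate, float)
        self.rates = np.asarray(self.rates, float)
        if self.substrate.shape != self.rates.shape or self.substrate.ndim != 1:
            raise ValueError("substrate and rates must be matching 1D arrays")
        if np.any(self.substrate <= 0):
            raise ValueError("substrate concentrations must be positive")


@dataclass
class KineticsFit:
    K_M: float                   # mM
    Vmax: float                  # rate units of the input
    se_K_M: float
    se_Vmax: float
    k_cat: float | None = None   # s^-1, only when enzyme concentration given
    se_k_cat: float | None = None

    @property
    def efficiency(self) -> float | None:
        """k_cat/K_M (s⁻¹ mM⁻¹) when k_cat is available."""
        if self.k_cat is None:
            return None
        return self.k_cat / self.K_M


@dataclass
class DSCRecord:
    dH_m: float              # J/g, melting
    dH_c: float              # J/g, cold crystallization
    dH_ref: float = DH_REF_PET

    def __post_init__(self) -> None:
        if self.dH_ref <= 0:
            raise ValueError("reference enthalpy must be positive")


@dataclass
class GlycolysisRecord:
    """Inputs for the glycolysis/hydrolysis bookkeeping equations.

    Only the fields an individual equation needs must be set.
    """

    initial_pet_mass: float = 0.0   # g
    actual_bhet_mass: float = 0.0   # g
    bhet_peak_area: float = 0.0     # HPLC, a.u.
    total_peak_area: float = 0.0    # HPLC, a.u.
    tpa_conc: float = 0.0           # mM
    pet_conc: float = 0.0           # g/L
    m_repeat: float = M_REPEAT_UNIT
    m_bhet: float = M_BHET

    def __post_init__(self) -> None:
        for name in ("initial_pet_mass", "actual_bhet_mass", "bhet_peak_area",
                     "total_peak_area", "tpa_conc", "pet_conc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# Thermal inactivation


def fit_inactivation(d: DecayDataset, method: str = "log_linear") -> DecayFit:
    """Fit E_t = E_0·exp(−kt) and derive the half-life.

    ``log_linear`` regresses ln(activity) on time (exact for the
    single-exponential model with multiplicative noise); ``nonlinear`` runs
    least squares on the raw curve for noisy tails.
    """
    if len(d.times) < 3:
        raise ValueError("need at least 3 points to fit inactivation")
    if method == "log_linear":
        if np.any(d.activities <= 0):
            raise ValueError(
                "non-positive activities cannot be log-fit; use method='nonlinear'"
            )
        res = stats.linregress(d.times, np.log(d.activities))
        k = -res.slope
        r2 = res.rvalue**2
        se = res.stderr
    elif method == "nonlinear":
        def model(t, e0, k):
            return e0 * np.exp(-k * t)
        p0 = (d.activities[0], 0.1)
        popt, pcov = optimize.curve_fit(model, d.times, d.activities, p0=p0, maxfev=10000)
        k = popt[1]
        se = float(np.sqrt(pcov[1, 1]))
        pred = model(d.times, *popt)
        ss_res = np.sum((d.activities - pred) ** 2)
        ss_tot = np.sum((d.activities - d.activities.mean()) ** 2)
        r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    if k <= 0:
        raise FitError(f"inactivation fit gave k = {k:.4g} <= 0 (activity not decaying)")
    return DecayFit(k=float(k), t_half=half_life(float(k)), r_squared=float(r2), se_k=float(se))


def half_life(k: float) -> float:
    """t½ = ln2/k for a first-order inactivation constant (h⁻¹ → h)."""
    if k <= 0:
        raise ValueError("rate constant must be positive")
    return math.log(2) / k


# ---------------------------------------------------------------------------
# DSC and glycolysis bookkeeping


def crystallinity(r: DSCRecord) -> float:
    """Percent crystallinity, (ΔH_m − ΔH_c) / ΔH_ref × 100."""
    value = (r.dH_m - r.dH_c) / r.dH_ref * 100.0
    if value < 0:
        log.warning(
            "cold-crystallization enthalpy exceeds melting enthalpy: "
            "crystallinity %.2f%% is physically suspect", value
        )
    return value


def bhet_purity(r: GlycolysisRecord) -> float:
    """HPLC purity: BHET peak area over total peak area, %."""
    if r.total_peak_area <= 0:
        raise ValueError("total peak area must be positive")
    if r.bhet_peak_area > r.total_peak_area:
        raise ValueError("BHET peak area exceeds total peak area")
    return r.bhet_peak_area / r.total_peak_area * 100.0


def theoretical_bhet_mass(initial_pet_mass: float,
                          m_repeat: float = M_REPEAT_UNIT,
                          m_bhet: float = M_BHET) -> float:
    """Stoichiometric BHET mass (g) from full glycolysis of a PET mass."""
    if initial_pet_mass <= 0:
        raise ValueError("initial PET mass must be positive")
    return initial_pet_mass / m_repeat * m_bhet


def bhet_yield(r: GlycolysisRecord) -> float:
    """Glycolysis yield: actual BHET mass over the stoichiometric maximum, %."""
    theo = theoretical_bhet_mass(r.initial_pet_mass, r.m_repeat, r.m_bhet)
    return r.actual_bhet_mass / theo * 100.0


def theoretical_max_hydrolysis_yield(r: GlycolysisRecord) -> float:
    """TPA formed over the stoichiometric maximum from the PET loading, %.

    The theoretical maximum TPA concentration (mM) is
    pet_conc [g/L] / 192.2 [g/mol] × 1000.
    """
    if r.pet_conc <= 0:
        raise ValueError("PET concentration must be positive")
    theo_mM = r.pet_conc / r.m_repeat * 1000.0
    return r.tpa_conc / theo_mM * 100.0


# ---------------------------------------------------------------------------
# Michaelis–Menten kinetics


def fit_michaelis_menten(
    d: KineticsDataset, enzyme_conc: float | None = None
) -> KineticsFit:
    """Nonlinear least squares of v = Vmax·S/(K_M + S).

    ``enzyme_conc`` (same concentration units as the rates' numerator per
    second) converts Vmax into k_cat.  Designs spanning only S ≫ K_M fit
    fine but report a large K_M standard error — check it.
    """
    if len(np.unique(d.substrate)) < 2:
        raise ValueError("degenerate design: all substrate levels equal")
    if len(d.substrate) < 4:
        raise ValueError("need at least 4 substrate levels")

    def model(s, vmax, km):
        return vmax * s / (km + s)

    vmax0 = float(d.rates.max()) or 1.0
    half = vmax0 / 2
    km0 = float(d.substrate[np.argmin(np.abs(d.rates - half))])
    km0 = max(km0, 1e-3)
    try:
        popt, pcov = optimize.curve_fit(
            model, d.substrate, d.rates, p0=(vmax0, km0),
            bounds=([0, 0], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"Michaelis–Menten fit did not converge: {exc}") from exc
    vmax, km = float(popt[0]), float(popt[1])
    se_vmax, se_km = (float(np.sqrt(pcov[i, i])) for i in (0, 1))
    if km <= 0:
        raise FitError(f"fit gave K_M = {km:.4g} <= 0")
    fit = KineticsFit(K_M=km, Vmax=vmax, se_K_M=se_km, se_Vmax=se_vmax)
    if enzyme_conc is not None:
        if enzyme_conc <= 0:
            raise ValueError("enzyme concentration must be positive")
        fit.k_cat = vmax / enzyme_conc
        fit.se_k_cat = se_vmax / enzyme_conc
    return fit


# ---------------------------------------------------------------------------
# Fold changes


def fold_change(treatment: float, control: float, rounding: int | None = 1) -> float:
    """treatment / control, half-up rounded at ``rounding`` decimals."""
    if control <= 0:
        raise ValueError("control must be positive")
    ratio = treatment / control
    if rounding is None:
        return ratio
    q = Decimal(1).scaleb(-rounding)
    return float(Decimal(repr(ratio)).quantize(q, rounding=ROUND_HALF_UP))
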