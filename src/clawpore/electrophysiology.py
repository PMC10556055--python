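"""Barrier-function arithmetic: TEER, GHK potentials, permeabilities.

The module covers the standard Ussing/Transwell analysis chain for a
monolayer bathed in NaCl Ringer at 37 degrees C:

* blank- and area-corrected transepithelial resistance (Ohm cm^2);
* inversion of the NaCl dilution potential via the Goldman-Hodgkin-Katz
  (GHK) voltage relation to the permeability ratio beta = P_Na/P_Cl;
* inversion of the Na->Li bi-ionic potential to P_Li/P_Na;
* absolute permeabilities from conductance and beta using the
  Kimizuka-Koketsu relation P_Na = (RT/F^2) G beta / ((1+beta) c) (the
  standard route from relative permeabilities and resistance; the source
  for this analysis chain leaves the formula to its own reference);
* apparent permeability P_app = (dQ/dt)/(A C0) from a tracer flux series
  under the sink assumption.

Only the monovalent ions Na+, Cl- and Li+ enter the GHK terms; divalents
and buffer species are treated as GHK-silent.  Activity coefficients are 1.
Potentials are basal minus apical by default (flippable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BathComposition",
    "PermeabilityResult",
    "FluxSeries",
    "RINGER",
    "DILUTED_RINGER",
    "LITHIUM_RINGER",
    "correct_teer",
    "ghk_potential",
    "dilution_ratio",
    "biionic_ratio",
    "absolute_permeabilities",
    "apparent_permeability",
]

R_GAS = 8.31446261815324    # J / (mol K)
FARADAY = 96485.33212       # C / mol
BODY_TEMPERATURE = 310.15   # K (37 C)


class GHKBoundError(ValueError):
    """Measured potential outside the attainable GHK interval."""


@dataclass(frozen=True)
class BathComposition:
    """Monovalent bath concentrations in mM (Na+, Cl-, Li+)."""

    na: float
    cl: float
    li: float = 0.0
    side: str = ""
    temperature: float = BODY_TEMPERATURE

    def __post_init__(self):
        if min(self.na, self.cl, self.li) < 0:
            raise ValueError("concentrations must be non-negative")
        if abs((self.na + self.li) - self.cl) > 1e-6 * max(self.cl, 1.0):
            raise ValueError(
                "monovalent electroneutrality violated: Na + Li != Cl"
            )


#: Standard Ringer saline, 140 mM NaCl.
RINGER = BathComposition(na=140.0, cl=140.0, side="apical")
#: Basolateral 1:4 saline:mannitol replacement -> 28 mM NaCl.
DILUTED_RINGER = BathComposition(na=28.0, cl=28.0, side="basal")
#: Bi-ionic Ringer with 140 mM Li+ replacing Na+.
LITHIUM_RINGER = BathComposition(na=0.0, cl=140.0, li=140.0, side="basal")


@dataclass(frozen=True)
class FluxSeries:
    """Tracer appearance in the receiver chamber over time."""

    timepoints_min: np.ndarray     # strictly increasing, minutes
    receiver_amounts: np.ndarray   # ug (or any amount unit)
    donor_concentration: float     # ug/ml
    area: float                    # cm^2
    receiver_volume: float = None  # ml, optional (sink-condition check)

    def __post_init__(self):
        t = np.asarray(self.timepoints_min, dtype=float)
        q = np.asarray(self.receiver_amounts, dtype=float)
        object.__setattr__(self, "timepoints_min", t)
        object.__setattr__(self, "receiver_amounts", q)
        if t.size < 2:
            raise ValueError("a flux series needs at least 2 timepoints")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if q.shape != t.shape:
            raise ValueError("amounts and timepoints must have equal length")
        if self.area <= 0 or self.donor_concentration <= 0:
            raise ValueError("area and donor concentration must be positive")


@dataclass(frozen=True)
class PermeabilityResult:
    p_na: float                 # cm/s
    p_cl: float
    p_li: float = None
    potentials_mv: dict = field(default_factory=dict)
    conductance_s_cm2: float = None

    @property
    def beta(self) -> float:
        return self.p_na / self.p_cl

    @property
    def p_li_over_p_cl(self) -> float:
        return None if self.p_li is None else self.p_li / self.p_cl

    @property
    def p_li_over_p_na(self) -> float:
        return None if self.p_li is None else self.p_li / self.p_na


def correct_teer(r_total: float, r_blank: float, area: float):
    """Blank- and area-corrected resistance, (R_total - R_blank) * area, Ohm cm^2."""
    if area <= 0:
        raise ValueError("insert area must be positive")
    if r_blank < 0:
        raise ValueError("blank resistance cannot be negative")
    if r_total <= r_blank:
        raise ValueError(
            "total resistance must exceed the blank (non-physical monolayer)"
        )
    return (r_total - r_blank) * area


def _rtf_mv(temperature: float) -> float:
    """RT/F in millivolts."""
    return R_GAS * temperature / FARADAY * 1000.0


def ghk_potential(
    p_na: float,
    p_cl: float,
    apical: BathComposition,
    basal: BathComposition,
    p_li: float = 0.0,
    temperature: float = None,
) -> float:
    """Forward GHK transepithelial potential (basal minus apical), mV."""
    t = temperature or apical.temperature
    num = p_na * basal.na + p_li * basal.li + p_cl * apical.cl
    den = p_na * apical.na + p_li * apical.li + p_cl * basal.cl
    return _rtf_mv(t) * np.log(num / den)


def dilution_ratio(
    v_mv: float,
    apical: BathComposition = RINGER,
    basal: BathComposition = DILUTED_RINGER,
    temperature: float = None,
    sign: int = 1,
) -> float:
    """Invert a NaCl dilution potential to beta = P_Na / P_Cl.

    Solves V = (RT/F) ln[(beta [Na]_b + [Cl]_a) / (beta [Na]_a + [Cl]_b)]
    for beta in closed form.  ``sign=-1`` flips the basal-minus-apical
    convention.  V outside the interval bounded by the single-ion Nernst
    limits raises :class:`GHKBoundError`.
    """
    t = temperature or apical.temperature
    rtf = _rtf_mv(t)
    u = np.exp(sign * v_mv / rtf)
    v_cl = rtf * np.log(apical.cl / basal.cl)   # beta -> 0 (anion-only) limit
    v_na = rtf * np.log(basal.na / apical.na)   # beta -> inf (cation-only) limit
    lo, hi = sorted([v_cl, v_na])
    if not lo < sign * v_mv < hi:
        which = "cation-only (Nernst Na+)" if abs(sign * v_mv - v_na) <= abs(
            sign * v_mv - v_cl) else "anion-only (Nernst Cl-)"
        raise GHKBoundError(
            f"potential {v_mv:.3f} mV at or beyond the {which} limit "
            f"[{lo:.3f}, {hi:.3f}] mV"
        )
    return float((apical.cl - u * basal.cl) / (u * apical.na - basal.na))


def biionic_ratio(
    v_mv: float,
    apical: BathComposition = RINGER,
    basal: BathComposition = LITHIUM_RINGER,
    beta: float = 1.0,
    temperature: float = None,
    sign: int = 1,
) -> float:
    """Invert a Na->Li bi-ionic potential to P_Li / P_Na given beta = P_Na/P_Cl.

    Solves V = (RT/F) ln[(P_Li [Li]_b + P_Cl [Cl]_a) /
    (P_Na [Na]_a + P_Cl [Cl]_b)] for P_Li/P_Na.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if basal.li <= 0:
        raise ValueError("bi-ionic inversion needs Li+ in the basal bath")
    t = temperature or apical.temperature
    rtf = _rtf_mv(t)
    u = np.exp(sign * v_mv / rtf)
    ratio = (u * (apical.na + basal.cl / beta) - apical.cl / beta) / basal.li
    if ratio <= 0:
        raise GHKBoundError(
            f"potential {v_mv:.3f} mV implies a non-positive P_Li/P_Na; "
            "beyond the attainable bi-ionic interval"
        )
    return float(ratio)


def absolute_permeabilities(
    conductance: float,
    beta: float,
    c_nacl_mm: float = 140.0,
    temperature: float = BODY_TEMPERATURE,
):
    """(P_Na, P_Cl) in cm/s from conductance G (S/cm^2) and beta = P_Na/P_Cl.

    Kimizuka-Koketsu: P_Na = (RT/F^2) G beta / ((1+beta) c), P_Cl = P_Na/beta,
    with c the symmetric NaCl concentration in mol/cm^3.
    """
    if conductance <= 0:
        raise ValueError("conductance must be positive")
    if beta <= 0 or c_nacl_mm <= 0 or temperature <= 0:
        raise ValueError("beta, concentration and temperature must be positive")
    c = c_nacl_mm * 1e-6  # mM -> mol/cm^3
    p_na = (R_GAS * temperature / FARADAY**2) * conductance * beta / ((1.0 + beta) * c)
    return float(p_na), float(p_na / beta)


def apparent_permeability(series: FluxSeries) -> float:
    """P_app in cm/s: least-squares slope of Q(t) over (area * donor conc)."""
    t_sec = series.timepoints_min * 60.0
    slope = np.polyfit(t_sec, series.receiver_amounts, 1)[0]
    if series.receiver_volume is not None:
        max_conc = np.max(series.receiver_amounts) / series.receiver_volume
        if max_conc > 0.1 * series.donor_concentration:
            warnings.warn(
                "receiver concentration exceeds 10% of donor; sink condition "
                "violated, P_app may be underestimated",
                stacklevel=2,
            )
    if slope < 0:
        warnings.warn("negative flux slope; returning the (negative) P_app",
                      stacklevel=2)
    return float(slope / (series.area * series.donor_concentration))
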