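"""Bulk in vitro property calculators.

Interfacial assays:

* EAI (emulsifying activity index, m^2/g):
  ``2 * 2.303 * A0 * D / (phi * c * 10000)`` with A0 the 500 nm absorbance
  immediately after homogenization, D the dilution factor, phi the oil
  volume fraction and c the protein concentration in g/mL.
* ESI (emulsion stability index, min): ``A0 / (A0 - A10) * 10``; an
  emulsion whose absorbance has not decayed after 10 min has no measurable
  destabilization and is reported as infinitely stable.
* Foaming capacity/stability: volume ratios in percent.

Antioxidant assays report inhibition percentages,

* DPPH radical scavenging: ``(1 - (A_s - A_0)/A_b) * 100`` (517 nm), and
* ferrous chelation: ``(A_blank - (A_sample - A_blind)) / A_blank * 100``
  (562 nm, ferrozine competition),

and dose--response series are condensed to an IC50/EC50 by ordinary least
squares of inhibition on concentration: IC50 = (50 - intercept) / slope.
Inhibition values are deliberately not clamped to [0, 100] so that assay
problems stay visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

__all__ = [
    "EmulsionReading",
    "FoamReading",
    "DPPHReading",
    "ChelationReading",
    "FoamResult",
    "DoseResponseCurve",
    "eai",
    "esi",
    "foaming",
    "dpph_inhibition",
    "chelation_inhibition",
    "ic50",
]


@dataclass(frozen=True)
class EmulsionReading:
    a0: float              # absorbance at 500 nm, t = 0
    a10: float             # absorbance at t = 10 min
    dilution: float        # dimensionless factor D
    oil_fraction: float    # phi in (0, 1)
    protein_conc: float    # g/mL

    def __post_init__(self):
        if not 0 < self.oil_fraction < 1:
            raise ValueError("oil fraction must be in (0, 1)")
        if self.protein_conc <= 0:
            raise ValueError("protein concentration must be positive")
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")
        if self.a0 < 0 or self.a10 < 0:
            raise ValueError("absorbances must be non-negative")


@dataclass(frozen=True)
class FoamReading:
    v_init: float     # mL, sample volume before homogenization
    v_foam0: float    # mL, foam at t = 0
    v_foam30: float   # mL, foam after 30 min

    def __post_init__(self):
        if min(self.v_init, self.v_foam0, self.v_foam30) < 0:
            raise ValueError("volumes must be non-negative")


@dataclass(frozen=True)
class DPPHReading:
    a_sample: float   # sample + DPPH
    a_control: float  # sample + EtOH negative control
    a_blind: float    # EtOH + DPPH


@dataclass(frozen=True)
class ChelationReading:
    a_blank: float    # iron + ferrozine only
    a_sample: float   # sample + iron + ferrozine
    a_blind: float    # sample only


@dataclass(frozen=True)
class FoamResult:
    fc: float                 # percent
    fs: float | None          # percent; None when no foam formed


@dataclass(frozen=True)
class DoseResponseCurve:
    points: tuple[tuple[float, float], ...]   # (concentration, inhibition %)
    slope: float
    intercept: float
    ic50: float
    extrapolated: bool        # 50 % lies outside the measured inhibition range


def eai(reading: EmulsionReading) -> float:
    """Emulsifying activity index in m^2 of interface per gram of protein."""
    return (2.0 * 2.303 * reading.a0 * reading.dilution
            / (reading.oil_fraction * reading.protein_conc * 10000.0))


def esi(reading: EmulsionReading) -> float:
    """Emulsion stability index in minutes; ``inf`` when A10 == A0."""
    if reading.a10 > reading.a0:
        raise ValueError("A10 exceeds A0; emulsion readings are inconsistent")
    if reading.a10 == reading.a0:
        return math.inf
    return reading.a0 / (reading.a0 - reading.a10) * 10.0


def foaming(reading: FoamReading) -> FoamResult:
    """Foaming capacity and stability in percent.

    When no foam forms (v_foam0 = 0), FC is 0 and FS is undefined (None).
    """
    if reading.v_init <= 0:
        raise ValueError("initial volume must be positive")
    if reading.v_foam30 > reading.v_foam0:
        raise ValueError("foam volume cannot grow during the resting period")
    fc = 100.0 * reading.v_foam0 / reading.v_init
    if reading.v_foam0 == 0:
        return FoamResult(fc=0.0, fs=None)
    return FoamResult(fc=fc, fs=100.0 * reading.v_foam30 / reading.v_foam0)


def dpph_inhibition(reading: DPPHReading) -> float:
    """DPPH radical-scavenging inhibition percentage."""
    if reading.a_blind <= 0:
        raise ValueError("blind absorbance must be positive")
    return (1.0 - (reading.a_sample - reading.a_control) / reading.a_blind) * 100.0


def chelation_inhibition(reading: ChelationReading) -> float:
    """Ferrous-chelation inhibition percentage."""
    if reading.a_blank <= 0:
        raise ValueError("blank absorbance must be positive")
    return ((reading.a_blank - (reading.a_sample - reading.a_blind))
            / reading.a_blank * 100.0)


def ic50(
    points: Sequence[tuple[float, float]],
    target: float = 50.0,
) -> DoseResponseCurve:
    """IC50 (or EC50) by linear regression of inhibition on concentration.

    The dose--response line is fitted by OLS over all provided points (not
    forced through the origin); the concentration at ``target`` percent
    inhibition is read off the line.  A non-positive slope means no dose
    response and is an error.  When the target lies outside the measured
    inhibition range the estimate is an extrapolation and flagged as such.
    """
    pts = [(float(c), float(i)) for c, i in points]
    concs = [c for c, _ in pts]
    if len(set(concs)) < 2:
        raise ValueError("need at least two distinct concentrations")
    inhib = [i for _, i in pts]
    fit = stats.linregress(concs, inhib)
    if fit.slope <= 0:
        raise ValueError("no dose response: regression slope is not positive")
    value = (target - fit.intercept) / fit.slope
    extrapolated = not (min(inhib) <= target <= max(inhib))
    return DoseResponseCurve(
        points=tuple(pts),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        ic50=float(value),
        extrapolated=extrapolated,
    )
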