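"""Oxygen-transport physiology.

Arterial saturation and O2 content from end-tidal O2, the venous
deoxyhemoglobin ratio entering the calibration model, and the shortening of
arterial-blood T1 under hyperoxia.  End-tidal O2 is taken as a direct proxy
for arterial PaO2 (no alveolar-arterial gradient), the convention of the
hypercapnia/hyperoxia calibration literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BloodParams:
    """Blood oxygen-carriage constants.

    hb        : hemoglobin concentration, g Hb / dL blood
    phi       : O2-carrying capacity of hemoglobin, mL O2 / g Hb
    eps       : plasma O2 solubility, mL O2 / dL / mmHg
    t1b_0     : baseline arterial blood T1 at 3 T, s
    kappa     : slope of blood R1 versus PaO2, s^-1 / mmHg.  With t1b_0 it
                reproduces an arterial T1 near 1.56 s at the hyperoxic
                end-tidal O2 reached when breathing 60% O2.
    """

    hb: float = 15.0
    phi: float = 1.34
    eps: float = 0.003
    t1b_0: float = 1.65
    kappa: float = 1.38e-4

    def __post_init__(self) -> None:
        for name in ("hb", "phi", "eps", "t1b_0", "kappa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ArterialState:
    """Arterial oxygenation at one condition."""

    pao2: float  # mmHg
    sao2: float  # fraction
    cao2: float  # mL O2 / dL blood


def severinghaus_saturation(pao2):
    """Hemoglobin O2 saturation (fraction) from PaO2 (mmHg).

    Empirical dissociation curve SaO2 = 1 / (23400 / (P^3 + 150 P) + 1);
    strictly increasing, approaching 1 as PaO2 grows.
    """
    p = np.asarray(pao2, dtype=float)
    if np.any(p <= 0):
        raise ValueError("PaO2 must be positive")
    sat = 1.0 / (23400.0 / (p**3 + 150.0 * p) + 1.0)
    return sat if sat.ndim else float(sat)


def arterial_o2_content(pao2, blood: BloodParams = BloodParams()):
    """Arterial O2 content (hemoglobin-bound plus dissolved).

    CaO2 = phi * Hb * SaO2 + eps * PaO2, in mL O2 / dL blood.
    """
    sao2 = severinghaus_saturation(pao2)
    cao2 = blood.phi * blood.hb * sao2 + blood.eps * np.asarray(pao2, dtype=float)
    if np.ndim(pao2) == 0:
        return ArterialState(pao2=float(pao2), sao2=float(sao2), cao2=float(cao2))
    return cao2


def dhb_ratio(oef0, f, r, cao2_gas, cao2_0, blood: BloodParams = BloodParams()):
    """Venous deoxyhemoglobin ratio [dHb]/[dHb]0 during a gas challenge.

    oef0      : resting oxygen extraction fraction (the model unknown)
    f         : CBF ratio during the challenge (CBF_gas / CBF_0)
    r         : CMRO2 ratio during the challenge (1 = isometabolism)
    cao2_gas  : arterial O2 content during the challenge, mL O2/dL
    cao2_0    : resting arterial O2 content, mL O2/dL

        d = (phi*Hb - CaO2_gas + (r/f)*OEF0*CaO2_0)
            / (phi*Hb - CaO2_0 + OEF0*CaO2_0)

    Venous dissolved O2 is neglected: deoxyhemoglobin is the total-content
    deficit relative to full saturation.  Values d <= 0 are non-physical and
    must be treated as "no solution" by the caller; where the denominator is
    non-positive the result is NaN.
    """
    oef0 = np.asarray(oef0, dtype=float)
    cap = blood.phi * blood.hb
    num = cap - cao2_gas + (r / f) * oef0 * cao2_0
    den = cap - cao2_0 + oef0 * cao2_0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, np.nan), np.nan)
    return d if d.ndim else float(d)


def blood_t1_hyperoxia(pao2_gas, pao2_0, blood: BloodParams = BloodParams()):
    """Arterial blood T1 (s) at elevated PaO2.

    Dissolved molecular O2 is paramagnetic and adds kappa * dPaO2 to blood
    R1: T1 = 1 / (1/T1b_0 + kappa * (PaO2_gas - PaO2_0)).
    """
    dp = np.asarray(pao2_gas, dtype=float) - np.asarray(pao2_0, dtype=float)
    if np.any(dp < 0):
        raise ValueError("PaO2_gas must be >= PaO2_0")
    t1 = 1.0 / (1.0 / blood.t1b_0 + blood.kappa * dp)
    return t1 if t1.ndim else float(t1)
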