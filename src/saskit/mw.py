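"""Molecular-weight estimation from a subtracted scattering profile.

Concentration-independent estimators:

* correlation volume: Vc = I(0) / integral(q I(q) dq, 0..qmax); the mass
  follows from QR = Vc^2/Rg via an empirical power law (protein/RNA).
* Porod volume: Q = integral(q^2 I(q) dq), Vp = 2 pi^2 I(0)/Q, and the mass
  from an apparent protein density of 1/1.66 Da/A^3.

Both need integrals from q = 0 although measurement starts at q > 0; the
missing head is filled analytically with the Guinier form using the fitted
Rg and I(0).  Concentration-based estimates (reference standard or absolute
scale) are simple proportionalities on I(0)/c.

The mass-conversion constants assume q in 1/A; profiles in 1/nm must be
q-rescaled first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .exceptions import ValidationError
from .sasdata import Profile

__all__ = [
    "MWResult",
    "Calibration",
    "guinier_extrapolated_integrals",
    "vc_mw",
    "porod_volume_mw",
    "concentration_mw",
]

#: QR (nm^3) -> kDa for proteins (Rambo & Tainer correlation-volume law);
#: QR computed from q in 1/A is converted by 1 nm^3 = 10^3 A^3 first
VC_PROTEIN_DIVISOR = 0.1231
#: RNA branch constants of the same law: MW = (QR / 0.00934)^0.808
VC_RNA_DIVISOR = 0.00934
VC_RNA_EXPONENT = 0.808
#: apparent macromolecular density, Da per A^3
POROD_DENSITY = 1.0 / 1.66


@dataclass
class MWResult:
    method: str
    mw: float = math.nan           # kDa
    vc: float = math.nan           # A^2
    qr: float = math.nan           # A^3
    porod_invariant: float = math.nan
    vp: float = math.nan           # A^3
    qmax_used: float = math.nan
    success: bool = False
    reason: str = ""


@dataclass
class Calibration:
    """Reference-standard or absolute-scale calibration record."""

    mw_ref: float = None      # kDa
    i0_ref: float = None
    conc_ref: float = None    # mg/ml
    k_absolute: float = None  # kDa per (I0 / (mg/ml)); collapses contrast terms


def guinier_extrapolated_integrals(profile: Profile, rg: float, i0: float,
                                   qmax: float):
    """(integral q I dq, integral q^2 I dq) over [0, qmax].

    Trapezoid rule on the measured points plus the closed-form Guinier
    contribution on [0, q_first], where the profile is not measured:

        int_0^a q  I0 e^(-q^2 Rg^2/3) dq = (3 I0 / 2 Rg^2)(1 - e^(-a^2 Rg^2/3))
        int_0^a q^2 I0 e^(-q^2 Rg^2/3) dq
            = I0 [ sqrt(pi) erf(b a)/(4 b^3) - a e^(-b^2 a^2)/(2 b^2) ],
              b = Rg/sqrt(3)
    """
    if not (rg > 0 and i0 > 0):
        raise ValidationError("rg and i0 must come from a valid Guinier fit")
    a = profile.q[0]
    if qmax < a:
        raise ValidationError("qmax lies below the first measured point")
    b = rg / math.sqrt(3.0)
    head_q1 = 1.5 * i0 / rg ** 2 * (1.0 - math.exp(-(a * b) ** 2))
    head_q2 = i0 * (math.sqrt(math.pi) * erf(b * a) / (4 * b ** 3)
                    - a * math.exp(-(b * a) ** 2) / (2 * b ** 2))
    mask = profile.q <= qmax
    q = profile.q[mask]
    i = profile.intensity[mask]
    int_q1 = head_q1 + (np.trapezoid(q * i, q) if len(q) > 1 else 0.0)
    int_q2 = head_q2 + (np.trapezoid(q * q * i, q) if len(q) > 1 else 0.0)
    return float(int_q1), float(int_q2)


def vc_mw(profile: Profile, rg: float, i0: float, molecule: str = "protein",
          qmax: float | None = None) -> MWResult:
    """Correlation-volume molecular weight.

    Vc = I0 / int q I dq; QR = Vc^2/Rg; MW(protein) = QR/0.1231 kDa,
    MW(RNA) = (QR/0.00934)^0.808 kDa.  The default integration cutoff
    min(0.3 1/A, q_last) sits in the convergence regime for globular
    particles and is configurable.
    """
    if molecule not in ("protein", "rna"):
        raise ValidationError(f"unknown molecule type {molecule!r}")
    if qmax is None:
        qmax = min(0.3, float(profile.q[-1]))
    res = MWResult(method="Vc", qmax_used=qmax)
    int_q1, _ = guinier_extrapolated_integrals(profile, rg, i0, qmax)
    if int_q1 <= 0:
        res.reason = "non-positive integral of q*I (pathological subtraction?)"
        return res
    vc = i0 / int_q1
    qr = vc ** 2 / rg
    qr_nm3 = qr / 1000.0  # A^3 -> nm^3, the units the law was calibrated in
    if molecule == "protein":
        mw = qr_nm3 / VC_PROTEIN_DIVISOR
    else:
        mw = (qr_nm3 / VC_RNA_DIVISOR) ** VC_RNA_EXPONENT
    res.vc, res.qr, res.mw, res.success = vc, qr, mw, True
    return res


def porod_volume_mw(profile: Profile, rg: float, i0: float,
                    qmax: float | None = None,
                    density: float = POROD_DENSITY,
                    qmax_correction: tuple | None = None) -> MWResult:
    """Porod-volume molecular weight: Vp = 2 pi^2 I0 / Q, MW = Vp * density.

    ``qmax_correction`` optionally applies a linear cutoff adjustment
    Vp' = Vp * (c0 + c1*qmax); coefficients are calibration inputs and are
    off by default.
    """
    if qmax is None:
        qmax = min(0.3, float(profile.q[-1]))
    res = MWResult(method="Porod", qmax_used=qmax)
    _, q_invariant = guinier_extrapolated_integrals(profile, rg, i0, qmax)
    if q_invariant <= 0:
        res.reason = "non-positive Porod invariant"
        return res
    vp = 2.0 * math.pi ** 2 * i0 / q_invariant
    if qmax_correction is not None:
        c0, c1 = qmax_correction
        vp = vp * (c0 + c1 * qmax)
    res.porod_invariant = q_invariant
    res.vp = vp
    res.mw = vp * density / 1000.0  # Da -> kDa
    res.success = True
    return res


def concentration_mw(i0: float, conc: float, kind: str,
                     calib: Calibration) -> MWResult:
    """Concentration-based MW from I(0)/c.

    reference: MW = MW_ref * (I0/c) / (I0_ref/c_ref)
    absolute:  MW = (I0/c) * K with K supplied by the calibration record.
    """
    if conc <= 0:
        raise ValidationError("concentration must be positive")
    res = MWResult(method=kind)
    if kind == "reference":
        if None in (calib.mw_ref, calib.i0_ref, calib.conc_ref):
            raise ValidationError("reference calibration needs mw_ref, i0_ref, conc_ref")
        res.mw = calib.mw_ref * (i0 / conc) / (calib.i0_ref / calib.conc_ref)
    elif kind == "absolute":
        if calib.k_absolute is None:
            raise ValidationError("absolute calibration needs k_absolute")
        res.mw = (i0 / conc) * calib.k_absolute
    else:
        raise ValidationError(f"unknown concentration MW kind {kind!r}")
    res.success = True
    return res
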