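"""Single-site isothermal titration calorimetry.

A macromolecule M at total concentration ``M_t`` in a cell of volume ``V0``
is titrated with ligand X.  For ``n`` identical independent sites with
association constant ``Ka`` the bound-ligand concentration after each
injection is the root of

    Ka (n*M_t - MX)(X_t - MX) = MX

which is quadratic in MX; the physically meaningful root is the smaller one.
The cumulative heat content of the cell is Q = V0 * dH * [MX], and the heat
of injection i is the difference of consecutive Q values with the standard
perfusion (displacement) correction for the liquid pushed out of the
overfilled cell:

    dQ_i = Q_i - Q_{i-1} + (dV_i/V0) * (Q_i + Q_{i-1}) / 2

Concentrations follow the usual overfilled-cell bookkeeping: after a total
injected volume dV the cell and syringe species are diluted by
(1 -/+ dV/2V0)/(1 + dV/2V0) factors.

The information content of an isotherm is governed by the Wiseman parameter
c = n*M_t*Ka; isotherms with c outside roughly [1, 1000] constrain n and Kd
poorly, which is why the fitter can fix n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import lmfit
import numpy as np

from .exceptions import FitError, InvalidParameterError, ValidationError

__all__ = [
    "GAS_CONSTANT_KCAL",
    "ITCProtocol",
    "ITCTitration",
    "BindingFit",
    "Thermodynamics",
    "single_site_heats",
    "fit_single_site",
    "derive_thermodynamics",
]

#: Gas constant in kcal·mol⁻¹·K⁻¹.
GAS_CONSTANT_KCAL = 1.9872e-3


@dataclass(frozen=True)
class ITCProtocol:
    """Injection schedule and solution concentrations for one titration."""

    cell_volume_uL: float = 200.0
    cell_conc_uM: float = 20.0  # macromolecule M_t at start
    syringe_conc_uM: float = 300.0  # ligand X_0
    injection_volumes_uL: tuple = tuple([2.0] * 19)
    temperature_K: float = 298.15

    def __post_init__(self):
        if min(self.cell_volume_uL, self.cell_conc_uM,
               self.syringe_conc_uM, self.temperature_K) <= 0:
            raise ValidationError("volumes, concentrations, temperature must be > 0")
        if len(self.injection_volumes_uL) < 5:
            raise ValidationError("need ≥5 injections")
        if any(dv <= 0 for dv in self.injection_volumes_uL):
            raise ValidationError("injection volumes must be > 0")

    def totals(self):
        """Per-injection total concentrations (M) in the cell after mixing.

        Returns (M_t, X_t) arrays in molar units using the overfilled-cell
        displacement bookkeeping.
        """
        V0 = self.cell_volume_uL
        dv = np.asarray(self.injection_volumes_uL, dtype=float)
        dvcum = np.cumsum(dv)
        dil = 1.0 + dvcum / (2.0 * V0)
        Mt = self.cell_conc_uM * 1e-6 * (1.0 - dvcum / (2.0 * V0)) / dil
        Xt = self.syringe_conc_uM * 1e-6 * (dvcum / V0) / dil
        return Mt, Xt

    def molar_ratios(self) -> np.ndarray:
        Mt, Xt = self.totals()
        return Xt / Mt


@dataclass
class ITCTitration:
    """Integrated injection heats (μcal) plus the generating protocol."""

    protocol: ITCProtocol
    heats_ucal: np.ndarray

    def __post_init__(self):
        self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
        if len(self.heats_ucal) != len(self.protocol.injection_volumes_uL):
            raise ValidationError("one heat per injection required")
        if not np.all(np.isfinite(self.heats_ucal)):
            raise ValidationError("heats must be finite")
        mr = self.protocol.molar_ratios()
        if np.any(np.diff(mr) <= 0):
            raise ValidationError("molar ratios must be strictly increasing")

    @property
    def molar_ratios(self) -> np.ndarray:
        return self.protocol.molar_ratios()


@dataclass
class BindingFit:
    """Fitted single-site parameters; Kd in μM, dH in kcal·mol⁻¹."""

    n: float
    Kd_uM: float
    dH_kcal: float
    baseline_ucal: float = 0.0
    standard_errors: Dict[str, float] = field(default_factory=dict)
    flags: List[str] = field(default_factory=list)
    rss: float = np.nan

    @property
    def Ka(self) -> float:
        """Association constant, M⁻¹."""
        return 1.0 / (self.Kd_uM * 1e-6)


@dataclass
class Thermodynamics:
    dG_kcal: float
    dH_kcal: float
    minus_TdS_kcal: float
    temperature_K: float


def _bound_concentration(n: float, Mt: np.ndarray, Xt: np.ndarray,
                         Ka: float) -> np.ndarray:
    """Smaller root of the single-site mass-balance quadratic (molar)."""
    b = n * Mt + Xt + 1.0 / Ka
    disc = b * b - 4.0 * n * Mt * Xt
    if np.any(disc < 0):
        raise InvalidParameterError("negative discriminant: invalid inputs")
    return 0.5 * (b - np.sqrt(disc))


def single_site_heats(protocol: ITCProtocol, n: float, Ka: float,
                      dH_kcal: float) -> np.ndarray:
    """Expected per-injection heats (μcal) for n identical sites.

    ``Ka`` in M⁻¹, ``dH_kcal`` in kcal·mol⁻¹.  Includes the perfusion
    correction for cell-content displacement.
    """
    if not np.isfinite(Ka) or Ka <= 0:
        raise InvalidParameterError("Ka must be finite and > 0")
    if not np.isfinite(dH_kcal):
        raise InvalidParameterError("dH must be finite")
    if n <= 0:
        raise InvalidParameterError("n must be > 0")
    Mt, Xt = protocol.totals()
    MX = _bound_concentration(n, Mt, Xt, Ka)
    V0_L = protocol.cell_volume_uL * 1e-6
    # cumulative heat content of the cell, in μcal (dH kcal/mol -> μcal/mol)
    Q = V0_L * dH_kcal * 1e9 * MX
    dv = np.asarray(protocol.injection_volumes_uL, dtype=float)
    Qprev = np.concatenate([[0.0], Q[:-1]])
    dQ = Q - Qprev + (dv / protocol.cell_volume_uL) * (Q + Qprev) / 2.0
    return dQ


def fit_single_site(titration: ITCTitration, fix_n: Optional[float] = None,
                    discard_first: bool = False,
                    fit_baseline: bool = True) -> BindingFit:
    """Least-squares fit of the single-site isotherm to integrated heats.

    Parameters are stoichiometry n (optionally fixed), Kd (μM), dH
    (kcal·mol⁻¹) and a constant per-injection baseline offset (μcal)
    absorbing dilution heats.  With ``discard_first`` the first injection is
    dropped from the residuals (syringe-tip diffusion artefact).  For
    low-c isotherms (Wiseman c = n·M_t/Kd ≲ 1) the baseline is nearly
    collinear with (Kd, dH); pass ``fit_baseline=False`` when blank heats
    are known to be absent or already subtracted.
    """
    proto = titration.protocol
    heats = titration.heats_ucal
    mask = np.ones(len(heats), dtype=bool)
    if discard_first:
        mask[0] = False
    if mask.sum() < 5:
        raise ValidationError("need ≥5 usable injections")

    scale = float(np.max(np.abs(heats))) if np.any(heats) else 0.0
    flags: List[str] = []
    if scale == 0.0:
        flags.append("zero_heats_Kd_unidentifiable")
        return BindingFit(n=fix_n or 1.0, Kd_uM=np.nan, dH_kcal=0.0,
                          baseline_ucal=0.0, flags=flags, rss=0.0)

    dv = np.asarray(proto.injection_volumes_uL, dtype=float)
    mol_inj_first = proto.syringe_conc_uM * 1e-6 * dv[0] * 1e-6  # mol
    dH0 = heats[0] * 1e-9 / mol_inj_first  # kcal/mol if first shot fully bound
    if not np.isfinite(dH0) or dH0 == 0:
        dH0 = -10.0

    params = lmfit.Parameters()
    if fix_n is None:
        params.add("n", value=1.0, min=0.05, max=20.0)
    else:
        params.add("n", value=float(fix_n), vary=False)
    params.add("logKd", value=math.log10(proto.cell_conc_uM / 2.0),
               min=-4.0, max=7.0)  # Kd in μM, 1e-4 .. 1e7
    params.add("dH", value=dH0)
    params.add("offset", value=0.0, vary=fit_baseline)

    def residual(p):
        Kd_M = 10.0 ** p["logKd"].value * 1e-6
        model = single_site_heats(proto, p["n"].value, 1.0 / Kd_M,
                                  p["dH"].value) + p["offset"].value
        return (heats - model)[mask]

    out = lmfit.minimize(residual, params, method="leastsq")
    if not out.success:
        raise FitError("single-site ITC fit did not converge",
                       details={"residuals": out.residual})
    p = out.params
    Kd = 10.0 ** p["logKd"].value
    ses = {}
    for name in p:
        ses[name] = p[name].stderr if p[name].stderr is not None else np.nan
    # propagate logKd SE to Kd
    if np.isfinite(ses.get("logKd", np.nan)):
        ses["Kd_uM"] = Kd * math.log(10) * ses["logKd"]
    c = p["n"].value * proto.cell_conc_uM / Kd
    if not (0.01 <= c <= 1e6):
        flags.append("low_information_c_parameter")
    return BindingFit(
        n=p["n"].value, Kd_uM=Kd, dH_kcal=p["dH"].value,
        baseline_ucal=p["offset"].value, standard_errors=ses,
        flags=flags, rss=float(np.sum(out.residual ** 2)),
    )


def derive_thermodynamics(fit: BindingFit | float, T: float = 298.15,
                          dH_kcal: Optional[float] = None) -> Thermodynamics:
    """ΔG = RT ln Kd (Kd in molar) and −TΔS = ΔG − ΔH, in kcal·mol⁻¹.

    Accepts a :class:`BindingFit` or a bare Kd in μM (then ``dH_kcal`` must
    be given).
    """
    if isinstance(fit, BindingFit):
        Kd_uM, dH = fit.Kd_uM, fit.dH_kcal
    else:
        Kd_uM, dH = float(fit), dH_kcal
        if dH is None:
            raise InvalidParameterError("dH_kcal required with a bare Kd")
    if not np.isfinite(Kd_uM) or Kd_uM <= 0 or T <= 0:
        raise InvalidParameterError("Kd and T must be finite and > 0")
    dG = GAS_CONSTANT_KCAL * T * math.log(Kd_uM * 1e-6)
    return Thermodynamics(dG_kcal=dG, dH_kcal=dH,
                          minus_TdS_kcal=dG - dH, temperature_K=T)
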