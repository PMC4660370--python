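"""End-to-end orchestration: synthesize or load, analyze, report.

A :class:`RunConfig` (usually parsed from YAML) names which assays to run
and, per assay, either input files or generator truths.  ``run_pipeline``
executes the requested stages and returns a :class:`RunReport` whose blocks
mirror the published table columns: kinetics (mechanism, Km, Ki, α, β),
ITC (Kd, ΔG, ΔH, −TΔS) and SAXS (Rg, Dmax, Vp, MW estimate, oligomer call).
Identical config + seed give byte-identical serialized reports.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict
from pydantic import ValidationError as PydanticValidationError

from . import __version__
from . import io as aio
from . import itc as itc_mod
from . import kinetics as kin
from . import saxs as saxs_mod
from . import synth
from .exceptions import AllokinError, ValidationError

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class KineticsJob(_Strict):
    input: Optional[str] = None
    truth: Optional[Dict[str, float | str]] = None
    weighting: Literal["none", "inv_v2"] = "none"
    replicates: int = 3


class ITCJob(_Strict):
    input: Optional[str] = None
    protocol: Optional[str] = None
    truth: Optional[Dict[str, float]] = None
    fix_n: Optional[float] = None
    discard_first: bool = False


class SAXSJob(_Strict):
    inputs: Optional[List[str]] = None
    truth_state: Optional[Literal["tetramer", "octamer"]] = None
    concentrations: Sequence[float] = synth.DEFAULT_CONCENTRATIONS
    monomer_kda: Optional[float] = None


class ReportOptions(_Strict):
    rounding: bool = True


class RunConfig(_Strict):
    seed: int = 0
    kinetics: Optional[KineticsJob] = None
    itc: Optional[ITCJob] = None
    saxs: Optional[SAXSJob] = None
    report: ReportOptions = ReportOptions()


class PipelineError(AllokinError):
    """A stage failed; names the stage and the offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def load_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(raw)
    except PydanticValidationError as exc:
        raise ValidationError(str(exc)) from exc


def _round(x, ndigits, enabled):
    if x is None or not np.isfinite(x):
        return None if x is None else float(x)
    return round(float(x), ndigits) if enabled else float(x)


def _sig2(x, enabled):
    """Two significant figures, the precision Ki is reported at."""
    if x is None:
        return None
    if not enabled or x == 0:
        return float(x)
    from math import floor, log10

    return round(float(x), -int(floor(log10(abs(x)))) + 1)


def _run_kinetics(job: KineticsJob, seed: int, rounding: bool,
                  warnings: List[str]) -> Dict:
    if job.input:
        path = Path(job.input)
        if not path.exists():
            raise PipelineError("kinetics", f"missing input file {path}")
        data = aio.read_kinetics_table(path)
    elif job.truth:
        data = synth.gen_kinetics_dataset(
            dict(job.truth), synth.NoiseSpec(seed=seed),
            replicates=job.replicates)
    else:
        raise PipelineError("kinetics", "need 'input' or 'truth'")
    fit = kin.fit_inhibition_global(data, weighting=job.weighting)
    if fit.ambiguous:
        warnings.append("kinetics: mechanism selection ambiguous "
                        "(ΔAICc below threshold; simpler model reported)")
    for fl in fit.flags:
        warnings.append(f"kinetics: {fl}")
    return {
        "mechanism": fit.mechanism.value,
        "Km_uM": _round(fit.km, 1, rounding),
        "Ki_mM": _sig2(fit.ki / 1000.0 if fit.ki is not None else None,
                       rounding),
        "alpha": _round(fit.alpha, 2, rounding) if fit.alpha is not None else None,
        "beta": _round(fit.beta, 3, rounding) if fit.beta is not None else None,
        "criterion_aicc": {k: round(v, 3) for k, v in
                           fit.criterion_values.items()},
        "apparent_params": {
            str(lev): {"Vmax_app": v, "Km_app_uM": k}
            for lev, (v, k) in sorted(fit.apparent_params.items())
        },
        "standard_errors": {k: (None if not np.isfinite(v) else float(v))
                            for k, v in fit.standard_errors.items()},
        "units": {"Km_uM": "uM", "Ki_mM": "mM", "alpha": "dimensionless",
                  "beta": "dimensionless"},
    }


def _run_itc(job: ITCJob, seed: int, rounding: bool,
             warnings: List[str]) -> Dict:
    if job.input:
        if not Path(job.input).exists():
            raise PipelineError("itc", f"missing input file {job.input}")
        if job.protocol and not Path(job.protocol).exists():
            raise PipelineError("itc", f"missing protocol file {job.protocol}")
        proto = aio.read_itc_protocol(job.protocol) if job.protocol \
            else itc_mod.ITCProtocol()
        titr = aio.read_itc_table(job.input, proto)
    elif job.truth:
        titr = synth.gen_itc_titration(dict(job.truth),
                                       synth.NoiseSpec(seed=seed))
    else:
        raise PipelineError("itc", "need 'input' or 'truth'")
    fit = itc_mod.fit_single_site(titr, fix_n=job.fix_n,
                                  discard_first=job.discard_first)
    for fl in fit.flags:
        warnings.append(f"itc: {fl}")
    thermo = itc_mod.derive_thermodynamics(fit,
                                           T=titr.protocol.temperature_K)
    return {
        "n": _round(fit.n, 2, rounding),
        "Kd_uM": _sig2(fit.Kd_uM, rounding),
        "dG_kcal_mol": _round(thermo.dG_kcal, 1, rounding),
        "dH_kcal_mol": _round(thermo.dH_kcal, 1, rounding),
        "minus_TdS_kcal_mol": _round(thermo.minus_TdS_kcal, 1, rounding),
        "temperature_K": titr.protocol.temperature_K,
        "units": {"Kd_uM": "uM", "dG_kcal_mol": "kcal/mol",
                  "dH_kcal_mol": "kcal/mol",
                  "minus_TdS_kcal_mol": "kcal/mol"},
    }


def _run_saxs(job: SAXSJob, seed: int, rounding: bool,
              warnings: List[str]) -> Dict:
    if job.inputs:
        curves = []
        for p in job.inputs:
            if not Path(p).exists():
                raise PipelineError("saxs", f"missing input file {p}")
            curves.append(aio.read_scattering_curve(p))
        monomer = job.monomer_kda
    elif job.truth_state:
        model = synth.gen_bead_assembly(job.truth_state)
        curves = synth.gen_saxs_series(model, job.concentrations,
                                       synth.NoiseSpec(proportional_sd=0.01,
                                                       seed=seed))
        monomer = job.monomer_kda or synth.BEAD_MONOMER_MASS_KDA
    else:
        raise PipelineError("saxs", "need 'inputs' or 'truth_state'")
    if any(c.concentration is not None for c in curves) and len(curves) > 1:
        curve = saxs_mod.extrapolate_infinite_dilution(curves)
    else:
        curve = curves[0]
        if len(curves) == 1:
            warnings.append("saxs: single curve, no infinite-dilution "
                            "extrapolation")
    gui = saxs_mod.guinier_fit(curve)
    dmax, dmax_info = saxs_mod.estimate_dmax(curve, full_output=True)
    if dmax_info["flagged"]:
        warnings.append("saxs: no Dmax candidate met the decay criterion; "
                        "best-scoring value reported")
    pr = saxs_mod.ift_pofr(curve, dmax)
    porod = saxs_mod.porod_volume(curve, gui)
    for fl in porod.flags:
        warnings.append(f"saxs: {fl}")
    block = {
        "Rg_A": _round(gui.Rg, 1, rounding),
        "Rg_se_A": _round(gui.Rg_se, 2, rounding),
        "Rg_pr_A": _round(pr.Rg_pr, 1, rounding),
        "Dmax_A": _round(dmax, 0, rounding),
        "porod_volume_A3": _round(porod.Vp, 0, rounding),
        "mw_est_kDa": porod.mw_est_kDa,
        "units": {"Rg_A": "A", "Dmax_A": "A", "porod_volume_A3": "A^3",
                  "mw_est_kDa": "kDa"},
    }
    if monomer:
        call = saxs_mod.classify_oligomer(porod.mw_est_kDa, monomer)
        block["oligomer"] = call.state.value
        block["mw_ratio_vs_tetramer"] = _round(call.mw_ratio, 3, rounding)
    return block


def run_pipeline(config: RunConfig) -> Dict:
    """Execute the configured stages; returns the serializable report."""
    warnings: List[str] = []
    blocks: Dict[str, Dict] = {}
    if config.kinetics:
        blocks["kinetics"] = _run_kinetics(config.kinetics, config.seed,
                                           config.report.rounding, warnings)
    if config.itc:
        blocks["itc"] = _run_itc(config.itc, config.seed,
                                 config.report.rounding, warnings)
    if config.saxs:
        blocks["saxs"] = _run_saxs(config.saxs, config.seed,
                                   config.report.rounding, warnings)
    cfg_json = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    report = {
        "results": blocks,
        "warnings": warnings,
        "provenance": {
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": config.seed,
            "allokin_version": __version__,
        },
    }
    return report


def serialize_report(report: Dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
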