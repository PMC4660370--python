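"""Readers and writers for the plain-text assay formats.

* kinetics: delimited table with columns ``substrate_conc_uM,
  inhibitor_conc_uM, inhibitor_id, velocity, replicate`` — or time courses
  with ``time_s, A340`` instead of ``velocity`` (initial velocities are then
  extracted per condition);
* ITC: table with ``injection_index, volume_uL, heat_ucal`` plus a YAML
  protocol block;
* SAXS: 3-column ASCII ``q I sigma`` with ``#`` comments; the protein
  concentration travels in a ``# conc_mg_ml=`` header comment.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .itc import ITCProtocol, ITCTitration
from .kinetics import (
    KineticDataset,
    KineticObservation,
    TimeCourse,
    estimate_initial_velocity,
)
from .saxs import ScatteringCurve

PathLike = Union[str, Path]


def _read_table(path: PathLike) -> pd.DataFrame:
    """Delimited read (comma/tab/semicolon sniffed) with exact float parsing."""
    import csv

    with open(path) as fh:
        sample = fh.read(4096)
    try:
        sep = csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        sep = ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


# ---------------------------------------------------------------------------
# kinetics


def read_kinetics_table(path: PathLike, enzyme_id: str = "enzyme"
                        ) -> KineticDataset:
    df = _read_table(path)
    cols = set(df.columns)
    if "velocity" in cols:
        required = {"substrate_conc_uM", "inhibitor_conc_uM", "inhibitor_id"}
        if not required <= cols:
            raise ValidationError(f"kinetics table missing {required - cols}")
        if "replicate" not in cols:
            df["replicate"] = 0
        return KineticDataset.from_dataframe(df, enzyme_id=enzyme_id)
    if {"time_s", "A340"} <= cols:
        return _dataset_from_timecourses(df, enzyme_id)
    raise ValidationError(
        "kinetics table needs a 'velocity' column or 'time_s'/'A340' columns")


def _dataset_from_timecourses(df: pd.DataFrame, enzyme_id: str
                              ) -> KineticDataset:
    keys = ["substrate_conc_uM", "inhibitor_conc_uM", "inhibitor_id"]
    if "replicate" in df.columns:
        keys.append("replicate")
    obs: List[KineticObservation] = []
    for vals, grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("time_s")
        tc = TimeCourse(times=grp["time_s"].to_numpy(),
                        absorbance=grp["A340"].to_numpy())
        v0 = estimate_initial_velocity(tc)
        rec = dict(zip(keys, vals if isinstance(vals, tuple) else (vals,)))
        obs.append(KineticObservation(
            substrate_conc=float(rec["substrate_conc_uM"]),
            inhibitor_conc=float(rec["inhibitor_conc_uM"]),
            inhibitor_id=str(rec["inhibitor_id"]),
            velocity=v0,
            replicate=int(rec.get("replicate", 0)),
        ))
    return KineticDataset(enzyme_id, obs)


def write_kinetics_table(dataset: KineticDataset, path: PathLike) -> None:
    # repr round-trips float64 exactly; default formatting does not
    dataset.to_dataframe().to_csv(path, index=False,
                                  float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# ITC


def read_itc_protocol(path: PathLike) -> ITCProtocol:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    known = {"cell_volume_uL", "cell_conc_uM", "syringe_conc_uM",
             "temperature_C", "injection_volumes_uL"}
    unknown = set(cfg) - known
    if unknown:
        raise ValidationError(f"unknown protocol keys: {sorted(unknown)}")
    kwargs = {}
    if "cell_volume_uL" in cfg:
        kwargs["cell_volume_uL"] = float(cfg["cell_volume_uL"])
    if "cell_conc_uM" in cfg:
        kwargs["cell_conc_uM"] = float(cfg["cell_conc_uM"])
    if "syringe_conc_uM" in cfg:
        kwargs["syringe_conc_uM"] = float(cfg["syringe_conc_uM"])
    if "temperature_C" in cfg:
        kwargs["temperature_K"] = float(cfg["temperature_C"]) + 273.15
    if "injection_volumes_uL" in cfg:
        kwargs["injection_volumes_uL"] = tuple(
            float(v) for v in cfg["injection_volumes_uL"])
    return ITCProtocol(**kwargs)


def write_itc_protocol(protocol: ITCProtocol, path: PathLike) -> None:
    cfg = {
        "cell_volume_uL": protocol.cell_volume_uL,
        "cell_conc_uM": protocol.cell_conc_uM,
        "syringe_conc_uM": protocol.syringe_conc_uM,
        "temperature_C": protocol.temperature_K - 273.15,
        "injection_volumes_uL": list(protocol.injection_volumes_uL),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def read_itc_table(path: PathLike, protocol: ITCProtocol) -> ITCTitration:
    df = _read_table(path)
    required = {"injection_index", "volume_uL", "heat_ucal"}
    if not required <= set(df.columns):
        raise ValidationError(f"ITC table missing {required - set(df.columns)}")
    df = df.sort_values("injection_index")
    vols = df["volume_uL"].to_numpy(dtype=float)
    if not np.allclose(vols, protocol.injection_volumes_uL):
        raise ValidationError("table injection volumes disagree with protocol")
    return ITCTitration(protocol=protocol,
                        heats_ucal=df["heat_ucal"].to_numpy(dtype=float))


def write_itc_table(titration: ITCTitration, path: PathLike) -> None:
    pd.DataFrame({
        "injection_index": np.arange(1, len(titration.heats_ucal) + 1),
        "volume_uL": titration.protocol.injection_volumes_uL,
        "heat_ucal": titration.heats_ucal,
    }).to_csv(path, index=False, float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# SAXS


def read_scattering_curve(path: PathLike) -> ScatteringCurve:
    conc: Optional[float] = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("conc_mg_ml="):
                    conc = float(body.split("=", 1)[1])
                continue
            rows.append([float(x) for x in line.split()])
    arr = np.array(rows)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValidationError(f"{path}: expected 2 or 3 numeric columns")
    sigma = arr[:, 2] if arr.shape[1] >= 3 else None
    return ScatteringCurve(arr[:, 0], arr[:, 1], sigma, concentration=conc)


def write_scattering_curve(curve: ScatteringCurve, path: PathLike) -> None:
    with open(path, "w") as fh:
        if curve.concentration is not None:
            fh.write(f"# conc_mg_ml={float(curve.concentration)!r}\n")
        if curve.sigma is None:
            fh.write("# q[1/A] I\n")
            for qv, iv in zip(curve.q, curve.intensity):
                fh.write(f"{float(qv)!r} {float(iv)!r}\n")
        else:
            fh.write("# q[1/A] I sigma\n")
            for qv, iv, sv in zip(curve.q, curve.intensity, curve.sigma):
                fh.write(f"{float(qv)!r} {float(iv)!r} {float(sv)!r}\n")
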