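"""Seeded synthetic datasets emulating the three assay designs.

Each generator is a pure function of (truth, design, seed): identical seeds
give identical datasets.  Defaults mirror the experimental designs used for
the A. gossypii IMPDH system:

* kinetics — IMP two-fold dilution series 19.5–5000 μM at fixed 0.5 mM
  NAD⁺, inhibitor at 0 plus five log-spaced levels 20–5000 μM, 3 replicates,
  2% proportional velocity noise with a small additive floor;
* ITC — 20 μM macromolecule in a 200 μL cell titrated with 300 μM ligand in
  19 × 2 μL injections at 25 °C, 2% heat noise on the fully-bound-injection
  scale;
* SAXS — curves on q ∈ [0.005, 0.35] Å⁻¹ (400 points) from calibrated
  tetramer/octamer bead models, Poisson-like σ ∝ √I with a floor, optional
  weak structure-factor term, concentration series 1.25–20 mg/mL.

``KINETICS_TRUTHS``/``ITC_TRUTHS`` hold the published parameter sets for
wild-type AgIMPDH used as recovery truths throughout the test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from . import itc as itc_mod
from . import kinetics as kin
from . import saxs as saxs_mod
from .exceptions import ValidationError

__all__ = [
    "NoiseSpec",
    "KINETICS_TRUTHS",
    "ITC_TRUTHS",
    "BeadGeometry",
    "BEAD_MONOMER_MASS_KDA",
    "DEFAULT_S_GRID",
    "DEFAULT_I_LEVELS",
    "gen_kinetics_dataset",
    "gen_progress_curve",
    "gen_itc_titration",
    "gen_bead_assembly",
    "gen_saxs_series",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: v_obs = v·(1 + N(0, proportional_sd)) + N(0, additive_sd)."""

    proportional_sd: float = 0.02
    additive_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.proportional_sd < 0 or self.additive_sd < 0:
            raise ValidationError("noise SDs must be ≥ 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


#: Published inhibition parameters for wild-type AgIMPDH (Km = 51 μM;
#: Ki in μM).  Vmax is arbitrary (reported velocities carry no units).
KINETICS_TRUTHS: Dict[str, Dict] = {
    "GMP": {"mechanism": "competitive", "vmax": 1.0, "km": 51.0, "ki": 600.0},
    "GDP": {"mechanism": "mixed", "vmax": 1.0, "km": 51.0, "ki": 210.0,
            "alpha": 6.5, "beta": 0.033},
    "GTP": {"mechanism": "mixed", "vmax": 1.0, "km": 51.0, "ki": 160.0,
            "alpha": 4.1, "beta": 0.24},
}

#: Published IMP-binding thermodynamics of wild-type AgIMPDH, apo and in
#: the presence of 5 mM GTP or GDP (Kd μM, ΔH kcal·mol⁻¹, n sites).
ITC_TRUTHS: Dict[str, Dict] = {
    "apo": {"n": 1.0, "Kd_uM": 1.7, "dH_kcal": -26.4},
    "GTP": {"n": 1.0, "Kd_uM": 26.0, "dH_kcal": -55.0},
    "GDP": {"n": 1.0, "Kd_uM": 63.0, "dH_kcal": -30.9},
}

#: IMP dilution series, μM: 5000 / 2^k, k = 0..8 (19.5–5000 μM).
DEFAULT_S_GRID = tuple(5000.0 / 2 ** k for k in range(9))

#: Inhibitor levels, μM: control plus five log-spaced levels 20–5000.
DEFAULT_I_LEVELS = (0.0,) + tuple(np.geomspace(20.0, 5000.0, 5))


# ---------------------------------------------------------------------------
# kinetics


def gen_kinetics_dataset(truth: Dict, noise: Optional[NoiseSpec] = None,
                         s_grid: Sequence[float] = DEFAULT_S_GRID,
                         i_levels: Sequence[float] = DEFAULT_I_LEVELS,
                         replicates: int = 3,
                         inhibitor_id: str = "inhibitor",
                         enzyme_id: str = "enzyme") -> kin.KineticDataset:
    """Velocity grid from a known rate law plus multiplicative noise."""
    noise = noise or NoiseSpec()
    mech = kin.Mechanism(truth["mechanism"])
    rng = noise.rng()
    additive = noise.additive_sd
    if additive == 0.0 and noise.proportional_sd > 0:
        additive = 0.002 * truth["vmax"]  # small floor on the Vmax scale
    obs = []
    for I in i_levels:
        for S in s_grid:
            v_true = kin.predict_velocity(S, I, truth, mech)
            for rep in range(replicates):
                v = v_true
                if noise.proportional_sd > 0:
                    v = v * (1.0 + rng.normal(0.0, noise.proportional_sd))
                if additive > 0 and noise.proportional_sd > 0:
                    v = v + rng.normal(0.0, additive)
                obs.append(kin.KineticObservation(
                    substrate_conc=float(S), inhibitor_conc=float(I),
                    inhibitor_id=inhibitor_id if I > 0 else "none",
                    velocity=float(v), replicate=rep,
                ))
    return kin.KineticDataset(enzyme_id, obs)


def gen_progress_curve(v0_uM_per_min: float, duration_s: float = 300.0,
                       n_points: int = 61, curvature_s: float = 600.0,
                       noise: Optional[NoiseSpec] = None,
                       extinction_coeff: float = kin.NADH_EPSILON_340,
                       path_length: float = 1.0) -> kin.TimeCourse:
    """Saturating A340 progress curve with known initial velocity.

    A(t) = A_rate·τ·(1 − exp(−t/τ)) has initial slope A_rate = ε·l·v0; the
    exponential approach (time constant ``curvature_s``) mimics substrate
    depletion.  Used solely to exercise initial-velocity extraction.
    """
    noise = noise or NoiseSpec(proportional_sd=0.0)
    t = np.linspace(0.0, duration_s, n_points)
    a_rate = extinction_coeff * path_length * v0_uM_per_min * 1e-6 / 60.0  # A/s
    A = a_rate * curvature_s * (1.0 - np.exp(-t / curvature_s))
    if noise.proportional_sd > 0:
        amp = noise.proportional_sd * max(A.max(), 1e-12)
        A = A + noise.rng().normal(0.0, amp, size=A.shape)
    return kin.TimeCourse(times=t, absorbance=A,
                          path_length=path_length,
                          extinction_coeff=extinction_coeff)


# ---------------------------------------------------------------------------
# ITC


def gen_itc_titration(truth: Dict, noise: Optional[NoiseSpec] = None,
                      protocol: Optional[itc_mod.ITCProtocol] = None
                      ) -> itc_mod.ITCTitration:
    """Integrated injection heats from a single-site isotherm plus noise.

    The noise SD is ``proportional_sd`` times the largest |heat| of the
    noiseless isotherm (the natural scale of the measured thermogram) plus
    any additive floor in μcal.
    """
    noise = noise or NoiseSpec()
    protocol = protocol or itc_mod.ITCProtocol()
    Ka = 1.0 / (truth["Kd_uM"] * 1e-6)
    heats = itc_mod.single_site_heats(protocol, truth.get("n", 1.0), Ka,
                                      truth["dH_kcal"])
    sd = noise.proportional_sd * float(np.abs(heats).max()) \
        + noise.additive_sd
    if sd > 0:
        heats = heats + noise.rng().normal(0.0, sd, size=heats.shape)
    return itc_mod.ITCTitration(protocol=protocol, heats_ucal=heats)


# ---------------------------------------------------------------------------
# SAXS


@dataclass(frozen=True)
class BeadGeometry:
    """Calibrated coarse geometry of the IMPDH tetramer/octamer.

    Each monomer is a core sphere (catalytic domain) plus a smaller finger
    sphere protruding outwards; four monomers sit on a 4-fold axis.  The
    octamer is two such tetramers piled tail-to-tail on the same axis, the
    second rotated by 45°.  The values below were calibrated once against
    the measured hydrodynamics (Rg 45.1/49.7 Å, Dmax 158/159 Å).
    """

    core_radius: float = 23.0
    core_rho: float = 34.58
    finger_radius: float = 14.0
    finger_rho: float = 65.0
    octamer_separation: float = 42.0


#: Mass of one bead-model monomer under the 0.6 Da·Å⁻³ convention (kDa).
BEAD_MONOMER_MASS_KDA = (
    saxs_mod.POROD_MASS_DA_PER_A3
    * (4.0 / 3.0) * math.pi
    * (BeadGeometry.core_radius ** 3 + BeadGeometry.finger_radius ** 3)
    / 1000.0
)


def _tetramer_beads(geom: BeadGeometry, z: float, phase: float):
    centers, radii = [], []
    for k in range(4):
        th = phase + k * math.pi / 2.0
        c, s = math.cos(th), math.sin(th)
        centers.append([geom.core_rho * c, geom.core_rho * s, z])
        radii.append(geom.core_radius)
        centers.append([geom.finger_rho * c, geom.finger_rho * s, z])
        radii.append(geom.finger_radius)
    return centers, radii


def gen_bead_assembly(state: str | saxs_mod.OligomerState,
                      geometry: Optional[BeadGeometry] = None,
                      seed: int = 0) -> saxs_mod.BeadModel:
    """Calibrated tetramer or octamer bead model (deterministic; the seed
    is accepted for interface symmetry with the other generators)."""
    geom = geometry or BeadGeometry()
    state = saxs_mod.OligomerState(state)
    if state is saxs_mod.OligomerState.TETRAMER:
        centers, radii = _tetramer_beads(geom, 0.0, 0.0)
    elif state is saxs_mod.OligomerState.OCTAMER:
        h = geom.octamer_separation
        c1, r1 = _tetramer_beads(geom, +h / 2.0, 0.0)
        c2, r2 = _tetramer_beads(geom, -h / 2.0, math.pi / 4.0)
        centers, radii = c1 + c2, r1 + r2
    else:
        raise ValidationError(f"no calibrated geometry for state {state}")
    return saxs_mod.BeadModel(np.array(centers), np.array(radii))


DEFAULT_Q_GRID = np.linspace(0.005, 0.35, 400)
DEFAULT_CONCENTRATIONS = (1.25, 2.5, 5.0, 10.0, 20.0)


def gen_saxs_series(model: saxs_mod.BeadModel,
                    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
                    noise: Optional[NoiseSpec] = None,
                    q: Optional[np.ndarray] = None,
                    k_sf: float = 0.0, q_sf: float = 0.02):
    """Concentration series of noisy curves from a bead model.

    I(q, c) = c·I_debye(q)·(1 − k_sf·c·exp(−(q/q_sf)²)) + ε, with
    σ(q) = proportional_sd·√(I·I_max) plus an additive floor — a Poisson-like
    error model on an arbitrary intensity scale.  I_debye is normalized to
    I(0) = 1.
    """
    noise = noise or NoiseSpec(proportional_sd=0.01)
    q = DEFAULT_Q_GRID.copy() if q is None else np.asarray(q, dtype=float)
    base = saxs_mod.debye_profile(model, q).intensity
    i0 = float((model.scattering_weights.sum()) ** 2)  # Debye I(0)
    base = base / i0
    rng = noise.rng()
    curves = []
    for c in concentrations:
        I = c * base * (1.0 - k_sf * c * np.exp(-(q / q_sf) ** 2))
        imax = float(np.max(I))
        noise_sd = noise.proportional_sd * np.sqrt(np.clip(I, 0, None) * imax) \
            + noise.additive_sd
        I_obs = I.copy()
        if np.any(noise_sd > 0):
            I_obs += rng.normal(0.0, 1.0, size=I.shape) * noise_sd
        # reported sigma keeps a small floor so weights stay finite
        sigma = noise_sd + 1e-6 * imax
        curves.append(saxs_mod.ScatteringCurve(q.copy(), I_obs, sigma,
                                               concentration=float(c)))
    return curves
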