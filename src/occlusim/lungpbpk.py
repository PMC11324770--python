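"""Generation-resolved lung PBPK simulation of inhaled-compound disposition.

The lung is discretized into 24 airway generations (generation 1 = trachea;
1-16 tracheobronchial, 17-24 alveolar) plus an extra-thoracic sink for
mucociliary-cleared (swallowed) material.  Each generation holds three
tissue compartments — epithelial lining fluid (ELF), epithelium and
sub-epithelium — and, per epithelium/sub-epithelium, a volume-less "deep"
binding compartment with first-order in/out rates.  Fluxes per generation:

* Nernst-Brunner dissolution of deposited solid particles into the ELF
  (monodisperse shrinking spheres; rate clipped at zero, i.e. no
  precipitation on supersaturation);
* first-order mucociliary transport of ELF content (dissolved + solid)
  toward the trachea in the tracheobronchial region, trachea to the
  swallowed sink (cleared material is removed, not reabsorbed);
* bidirectional permeability flux ELF <-> epithelium, P*SA*(C_elf - Cu_epi),
  with no non-specific binding in the ELF (ELF unbound = total); alveolar
  permeability defaults to 10x the tracheobronchial value;
* diffusion-like first-order exchange epithelium <-> sub-epithelium on
  unbound concentrations;
* perfusion-rate-limited exchange sub-epithelium <-> blood with a tissue
  partition coefficient Kp; tracheobronchial generations see the bronchial
  blood flow, alveolar generations the cardiac output, distributed as
  constant flow per tissue volume;
* a one-compartment systemic circulation with clearance CL and volume Vss.

Amounts are in nmol, concentrations in uM (= nmol/ml), volumes in ml,
surface areas in cm^2 and time in hours.  Mass is conserved by construction;
the integrator (LSODA, rtol 1e-8) is checked against a 1e-6 relative
mass-balance budget at every output time.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "AirwayMorphometry",
    "CompoundParams",
    "DoseEvent",
    "LungModelSpec",
    "SimulationResult",
    "build_model",
    "nernst_brunner_rate",
    "simulate",
    "elf_region_summary",
    "map_exposure_to_ic50",
    "DEFAULT_REGIONS",
]

N_GENERATIONS = 24
TB_GENERATIONS = range(1, 17)
ALVEOLAR_GENERATIONS = range(17, 25)
DEFAULT_REGIONS = {"upper_tb": (1, 6), "lower_tb": (7, 16),
                   "alveolar": (17, 24)}

_MORPH_COLUMNS = ["generation", "region", "surface_area_cm2",
                  "elf_volume_ml", "epithelium_volume_ml",
                  "subepithelium_volume_ml", "mucociliary_rate_per_h",
                  "blood_flow_ml_per_h"]


class AirwayMorphometry:
    """24-generation airway morphometry table (plus the implicit
    extra-thoracic sink that receives mucociliary-cleared material).

    The default table is a scalable Weibel-like parameterization: airway
    count doubles per generation, tracheobronchial calibre and length shrink
    geometrically, the alveolar region carries the overwhelming share of
    surface area under a much thinner lining fluid, and mucociliary
    clearance decays toward the periphery and vanishes in the alveoli.
    Every value is overridable by loading a CSV with the same columns.
    """

    def __init__(self, table: pd.DataFrame):
        missing = set(_MORPH_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"morphometry missing columns {sorted(missing)}")
        table = table.sort_values("generation").reset_index(drop=True)
        if list(table["generation"]) != list(range(1, N_GENERATIONS + 1)):
            raise ValueError("morphometry must cover generations 1..24")
        for col in ("surface_area_cm2", "elf_volume_ml",
                    "epithelium_volume_ml", "subepithelium_volume_ml",
                    "blood_flow_ml_per_h"):
            if (table[col] <= 0).any():
                raise ValueError(f"{col} must be positive everywhere")
        if (table["mucociliary_rate_per_h"] < 0).any():
            raise ValueError("mucociliary rates must be >= 0")
        alv = table["generation"] >= 17
        if (table.loc[alv, "mucociliary_rate_per_h"] != 0).any():
            raise ValueError("alveolar generations must have zero "
                             "mucociliary clearance")
        expected_region = np.where(alv, "alveolar", "tracheobronchial")
        if not (table["region"] == expected_region).all():
            raise ValueError("region tags must be tracheobronchial for "
                             "generations 1-16 and alveolar for 17-24")
        self.table = table

    @classmethod
    def default(cls, cardiac_output_ml_per_h: float = 4800.0,
                bronchial_flow_fraction: float = 0.01) -> "AirwayMorphometry":
        g = np.arange(1, N_GENERATIONS + 1)
        tb = g <= 16
        n_airways = 2.0 ** (g - 1)
        # tracheobronchial tube geometry (cm), rat-like scale
        diameter = 0.34 * 0.75 ** (g - 1)
        length = 1.5 * 0.72 ** (g - 1)
        sa = n_airways * math.pi * diameter * length
        # alveolar surface area dominates: ~4000 cm2 split doubling per gen
        alv_w = 2.0 ** (g[~tb] - 17)
        sa[~tb] = 4000.0 * alv_w / alv_w.sum()
        # lining/tissue thicknesses (cm)
        elf_thick = np.where(tb, 10e-4 * (0.2) ** ((g - 1) / 15.0), 0.2e-4)
        epi_thick = np.where(tb, 30e-4 * (8.0 / 30.0) ** ((g - 1) / 15.0),
                             0.5e-4)
        sub_thick = np.where(tb, 50e-4 * (10.0 / 50.0) ** ((g - 1) / 15.0),
                             1.0e-4)
        elf_vol = sa * elf_thick
        epi_vol = sa * epi_thick
        sub_vol = sa * sub_thick
        muco = np.where(tb, 3.0 * 0.75 ** (g - 1), 0.0)
        tissue = epi_vol + sub_vol
        flow = np.empty(N_GENERATIONS)
        q_bronchial = bronchial_flow_fraction * cardiac_output_ml_per_h
        flow[tb] = q_bronchial * tissue[tb] / tissue[tb].sum()
        flow[~tb] = cardiac_output_ml_per_h * tissue[~tb] / tissue[~tb].sum()
        return cls(pd.DataFrame({
            "generation": g,
            "region": np.where(tb, "tracheobronchial", "alveolar"),
            "surface_area_cm2": sa,
            "elf_volume_ml": elf_vol,
            "epithelium_volume_ml": epi_vol,
            "subepithelium_volume_ml": sub_vol,
            "mucociliary_rate_per_h": muco,
            "blood_flow_ml_per_h": flow,
        }))

    @classmethod
    def from_csv(cls, path) -> "AirwayMorphometry":
        return cls(pd.read_csv(path))

    @classmethod
    def shipped(cls) -> "AirwayMorphometry":
        """The packaged copy of the default table
        (``data/default_morphometry.csv``), convenient as a template for
        overrides."""
        import importlib.resources

        ref = (importlib.resources.files("occlusim.data")
               / "default_morphometry.csv")
        with importlib.resources.as_file(ref) as path:
            return cls.from_csv(path)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclasses.dataclass(frozen=True)
class CompoundParams:
    """Compound-specific disposition parameters (SI-annotated units in the
    field names)."""

    solubility_cs_um: float
    diffusion_d_cm2_per_s: float
    diffusion_layer_h_cm: float
    particle_density_g_per_ml: float
    initial_particle_radius_um: float
    permeability_p_tb_cm_per_s: float
    molecular_weight_g_per_mol: float
    alveolar_permeability_multiplier: float = 10.0
    fu_plasma: float = 1.0
    fu_tissue: float = 1.0
    kp_epithelium: float = 1.0
    kp_subepithelium: float = 1.0
    k_in_per_h: float = 0.0
    k_out_per_h: float = 1.0
    k_epi_sub_per_h: float = 10.0
    cl_ml_per_h: float = 1000.0
    vss_ml: float = 2000.0

    def __post_init__(self) -> None:
        positive = ["solubility_cs_um", "diffusion_d_cm2_per_s",
                    "diffusion_layer_h_cm", "particle_density_g_per_ml",
                    "initial_particle_radius_um",
                    "molecular_weight_g_per_mol",
                    "alveolar_permeability_multiplier", "kp_epithelium",
                    "kp_subepithelium", "k_out_per_h", "vss_ml"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("permeability_p_tb_cm_per_s", "k_in_per_h",
                     "k_epi_sub_per_h", "cl_ml_per_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("fu_plasma", "fu_tissue"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")

    @property
    def permeability_alveolar_cm_per_s(self) -> float:
        return (self.alveolar_permeability_multiplier
                * self.permeability_p_tb_cm_per_s)


@dataclasses.dataclass(frozen=True)
class DoseEvent:
    """An inhaled dose.  Deposition fractions are inputs (no aerosol
    physics); the remainder of the dose is swallowed directly.  Within each
    region the deposit is split across generations proportional to surface
    area unless explicit ``generation_fractions`` (length 24, summing to
    <= 1 with the swallowed remainder) are given."""

    total_dose_nmol: float
    deposition_fraction_tb: float = 0.70
    deposition_fraction_alveolar: float = 0.30
    formulation: str = "solid_particles"
    generation_fractions: tuple | None = None

    def __post_init__(self) -> None:
        if self.total_dose_nmol <= 0:
            raise ValueError("dose must be positive")
        if self.formulation not in ("solid_particles", "solution"):
            raise ValueError("formulation must be solid_particles|solution")
        if self.generation_fractions is not None:
            fr = np.asarray(self.generation_fractions, dtype=float)
            if fr.shape != (N_GENERATIONS,) or (fr < 0).any() \
                    or fr.sum() > 1 + 1e-12:
                raise ValueError("generation_fractions must be 24 "
                                 "non-negative values summing to <= 1")
        else:
            if self.deposition_fraction_tb < 0 \
                    or self.deposition_fraction_alveolar < 0 \
                    or (self.deposition_fraction_tb
                        + self.deposition_fraction_alveolar) > 1 + 1e-12:
                raise ValueError("deposition fractions must be >= 0 and "
                                 "sum to <= 1")

    def deposit_per_generation(self, sa: np.ndarray) -> np.ndarray:
        """nmol deposited in each generation."""
        if self.generation_fractions is not None:
            return self.total_dose_nmol * np.asarray(
                self.generation_fractions, dtype=float)
        out = np.zeros(N_GENERATIONS)
        tb = slice(0, 16)
        alv = slice(16, 24)
        out[tb] = (self.total_dose_nmol * self.deposition_fraction_tb
                   * sa[tb] / sa[tb].sum())
        out[alv] = (self.total_dose_nmol * self.deposition_fraction_alveolar
                    * sa[alv] / sa[alv].sum())
        return out


@dataclasses.dataclass
class LungModelSpec:
    """Validated, unit-converted model ready for simulation."""

    morphometry: AirwayMorphometry
    compound: CompoundParams
    sa: np.ndarray                  # cm^2
    v_elf: np.ndarray               # ml
    v_epi: np.ndarray
    v_sub: np.ndarray
    k_mc: np.ndarray                # 1/h
    q_blood: np.ndarray             # ml/h
    p_cm_per_h: np.ndarray          # per-generation permeability


def build_model(morphometry: AirwayMorphometry,
                compound: CompoundParams) -> LungModelSpec:
    """Assemble and validate the generation-resolved model."""
    t = morphometry.table
    p = np.where(t["generation"] <= 16,
                 compound.permeability_p_tb_cm_per_s,
                 compound.permeability_alveolar_cm_per_s) * 3600.0
    return LungModelSpec(
        morphometry=morphometry,
        compound=compound,
        sa=t["surface_area_cm2"].to_numpy(float),
        v_elf=t["elf_volume_ml"].to_numpy(float),
        v_epi=t["epithelium_volume_ml"].to_numpy(float),
        v_sub=t["subepithelium_volume_ml"].to_numpy(float),
        k_mc=t["mucociliary_rate_per_h"].to_numpy(float),
        q_blood=t["blood_flow_ml_per_h"].to_numpy(float),
        p_cm_per_h=p,
    )


def nernst_brunner_rate(undissolved_mass_nmol: float,
                        n_particles: float,
                        cs_um: float,
                        c_elf_um: float,
                        d_cm2_per_s: float,
                        h_cm: float,
                        density_g_per_ml: float,
                        molecular_weight_g_per_mol: float) -> float:
    """Nernst-Brunner dissolution rate (nmol/h) of ``n_particles``
    monodisperse shrinking spheres.

    rate = (D / h) * A(m) * (Cs - C_elf) with A the total surface area at
    the current undissolved mass.  Supersaturation (C_elf > Cs) is clipped
    to zero rather than modelled as precipitation.
    """
    if undissolved_mass_nmol <= 0 or n_particles <= 0:
        return 0.0
    mass_g = undissolved_mass_nmol * 1e-9 * molecular_weight_g_per_mol
    r_cm = (3.0 * mass_g
            / (4.0 * math.pi * density_g_per_ml * n_particles)) ** (1.0 / 3.0)
    area_cm2 = n_particles * 4.0 * math.pi * r_cm ** 2
    rate_nmol_h = (d_cm2_per_s * 3600.0 / h_cm) * area_cm2 \
        * (cs_um - c_elf_um)
    return max(rate_nmol_h, 0.0)


# state vector layout (n = 24):
# [solid(24), elf(24), epi(24), sub(24), deep_epi(24), deep_sub(24),
#  plasma, swallowed, eliminated]
_N = N_GENERATIONS
_I_SOLID = slice(0, _N)
_I_ELF = slice(_N, 2 * _N)
_I_EPI = slice(2 * _N, 3 * _N)
_I_SUB = slice(3 * _N, 4 * _N)
_I_DEEP_E = slice(4 * _N, 5 * _N)
_I_DEEP_S = slice(5 * _N, 6 * _N)
_I_PLASMA = 6 * _N
_I_SWALLOW = 6 * _N + 1
_I_ELIM = 6 * _N + 2
_N_STATE = 6 * _N + 3


@dataclasses.dataclass
class SimulationResult:
    """Concentration-time profiles on the output grid.  Per-generation
    arrays have shape (24, n_times)."""

    t_h: np.ndarray
    undissolved_nmol: np.ndarray
    elf_concentration_um: np.ndarray
    epithelium_concentration_um: np.ndarray
    subepithelium_concentration_um: np.ndarray
    deep_epithelium_nmol: np.ndarray
    deep_subepithelium_nmol: np.ndarray
    plasma_concentration_um: np.ndarray
    swallowed_nmol: np.ndarray
    eliminated_nmol: np.ndarray
    mass_balance_rel_error: float
    model: LungModelSpec

    def to_long_dataframe(self) -> pd.DataFrame:
        frames = []
        for name, arr in (("elf", self.elf_concentration_um),
                          ("epithelium", self.epithelium_concentration_um),
                          ("subepithelium",
                           self.subepithelium_concentration_um)):
            for g in range(_N):
                frames.append(pd.DataFrame({
                    "time_h": self.t_h, "generation": g + 1,
                    "compartment": name, "concentration_um": arr[g]}))
        frames.append(pd.DataFrame({
            "time_h": self.t_h, "generation": 0, "compartment": "plasma",
            "concentration_um": self.plasma_concentration_um}))
        return pd.concat(frames, ignore_index=True)


def _rhs_factory(model: LungModelSpec, n_particles: np.ndarray):
    cp = model.compound
    d_over_h = cp.diffusion_d_cm2_per_s * 3600.0 / cp.diffusion_layer_h_cm
    mw = cp.molecular_weight_g_per_mol
    rho = cp.particle_density_g_per_ml
    sphere_coef = np.zeros(_N)
    ok = n_particles > 0
    # A(m) = k * m^(2/3) with m in nmol
    sphere_coef[ok] = (n_particles[ok] * 4.0 * math.pi
                       * (3.0 * 1e-9 * mw
                          / (4.0 * math.pi * rho * n_particles[ok]))
                       ** (2.0 / 3.0))
    psa = model.p_cm_per_h * model.sa
    q_es = cp.k_epi_sub_per_h * model.v_epi  # ml/h exchange "PS" term

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        solid = np.maximum(y[_I_SOLID], 0.0)
        c_elf = y[_I_ELF] / model.v_elf
        c_epi = y[_I_EPI] / model.v_epi
        c_sub = y[_I_SUB] / model.v_sub
        c_plasma = y[_I_PLASMA] / cp.vss_ml

        # (i) dissolution
        diss = d_over_h * sphere_coef * solid ** (2.0 / 3.0) \
            * (cp.solubility_cs_um - c_elf)
        diss = np.maximum(diss, 0.0)
        dy[_I_SOLID] -= diss
        dy[_I_ELF] += diss

        # (ii) mucociliary transport toward the trachea (solid + dissolved)
        mc_solid = model.k_mc * solid
        mc_elf = model.k_mc * y[_I_ELF]
        dy[_I_SOLID] -= mc_solid
        dy[_I_ELF] -= mc_elf
        dy[_I_SOLID.start:_I_SOLID.stop - 1] += mc_solid[1:]
        dy[_I_ELF.start:_I_ELF.stop - 1] += mc_elf[1:]
        dy[_I_SWALLOW] += mc_solid[0] + mc_elf[0]

        # (iii) ELF <-> epithelium permeability (ELF unbound = total)
        j_perm = psa * (c_elf - cp.fu_tissue * c_epi)
        dy[_I_ELF] -= j_perm
        dy[_I_EPI] += j_perm

        # (iv) epithelium <-> sub-epithelium exchange (unbound gradient)
        j_es = q_es * cp.fu_tissue * (c_epi - c_sub)
        dy[_I_EPI] -= j_es
        dy[_I_SUB] += j_es

        # (v) perfusion-limited sub-epithelium <-> blood
        j_blood = model.q_blood * (c_plasma - c_sub / cp.kp_subepithelium)
        dy[_I_SUB] += j_blood
        dy[_I_PLASMA] -= j_blood.sum()

        # (vi) deep binding compartments
        j_de = cp.k_in_per_h * y[_I_EPI] - cp.k_out_per_h * y[_I_DEEP_E]
        j_ds = cp.k_in_per_h * y[_I_SUB] - cp.k_out_per_h * y[_I_DEEP_S]
        dy[_I_EPI] -= j_de
        dy[_I_DEEP_E] += j_de
        dy[_I_SUB] -= j_ds
        dy[_I_DEEP_S] += j_ds

        # (viii) systemic elimination
        elim = cp.cl_ml_per_h * c_plasma
        dy[_I_PLASMA] -= elim
        dy[_I_ELIM] += elim
        return dy

    return rhs


def simulate(model: LungModelSpec, dose: DoseEvent,
             t_end_h: float = 24.0, dt_output_h: float = 0.1,
             rtol: float = 1e-8) -> SimulationResult:
    """Integrate the model after a single inhaled dose at t = 0."""
    deposit = dose.deposit_per_generation(model.sa)
    swallowed0 = dose.total_dose_nmol - deposit.sum()
    y0 = np.zeros(_N_STATE)
    cp = model.compound
    if dose.formulation == "solid_particles":
        y0[_I_SOLID] = deposit
        r0_cm = cp.initial_particle_radius_um * 1e-4
        particle_mass_g = (cp.particle_density_g_per_ml * 4.0 / 3.0
                           * math.pi * r0_cm ** 3)
        n_particles = (deposit * 1e-9 * cp.molecular_weight_g_per_mol
                       / particle_mass_g)
    else:
        y0[_I_ELF] = deposit
        n_particles = np.zeros(_N)
    y0[_I_SWALLOW] = swallowed0

    t_eval = np.arange(0.0, t_end_h + dt_output_h / 2, dt_output_h)
    sol = solve_ivp(_rhs_factory(model, n_particles), (0.0, t_end_h), y0,
                    method="LSODA", t_eval=t_eval, rtol=rtol,
                    atol=dose.total_dose_nmol * 1e-12)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    y = sol.y
    neg_tol = dose.total_dose_nmol * 1e-9
    if y.min() < -neg_tol:
        raise RuntimeError(
            f"negative state encountered (min {y.min():.3e} nmol)")
    totals = y.sum(axis=0)
    rel_err = float(np.max(np.abs(totals - dose.total_dose_nmol))
                    / dose.total_dose_nmol)
    if rel_err >= 1e-6:
        raise RuntimeError(f"mass balance violated ({rel_err:.2e} relative)")
    return SimulationResult(
        t_h=sol.t,
        undissolved_nmol=y[_I_SOLID],
        elf_concentration_um=y[_I_ELF] / model.v_elf[:, None],
        epithelium_concentration_um=y[_I_EPI] / model.v_epi[:, None],
        subepithelium_concentration_um=y[_I_SUB] / model.v_sub[:, None],
        deep_epithelium_nmol=y[_I_DEEP_E],
        deep_subepithelium_nmol=y[_I_DEEP_S],
        plasma_concentration_um=y[_I_PLASMA] / cp.vss_ml,
        swallowed_nmol=y[_I_SWALLOW],
        eliminated_nmol=y[_I_ELIM],
        mass_balance_rel_error=rel_err,
        model=model,
    )


def elf_region_summary(result: SimulationResult,
                       regions: dict[str, tuple[int, int]] = None
                       ) -> dict[str, float]:
    """Unbound ELF Cmax (uM) per lung region.

    The region concentration at each time is the ELF-volume-weighted mean
    over member generations; Cmax is its maximum over time.
    """
    if regions is None:
        regions = DEFAULT_REGIONS
    out = {}
    v = result.model.v_elf
    for name, (g_lo, g_hi) in regions.items():
        if g_lo < 1 or g_hi > _N or g_lo > g_hi:
            raise ValueError(f"region {name!r} has no generations")
        sel = slice(g_lo - 1, g_hi)
        weights = v[sel]
        conc = (result.elf_concentration_um[sel]
                * weights[:, None]).sum(axis=0) / weights.sum()
        out[name] = float(conc.max())
    return out


def map_exposure_to_ic50(region_cmax_um: dict[str, float], fit,
                         at_risk_fraction: float = 0.5) -> pd.DataFrame:
    """Join regional ELF Cmax onto the in vitro dose-response curve.

    Per region: exposure ratio Cmax/IC50, the predicted fold-change response
    at Cmax from the fitted curve, and an at-risk flag (Cmax >= fraction of
    the IC50, default 0.5).  When no IC50 was established every region is
    flagged ``no_in_vitro_effect_detected``.
    """
    from .doseresponse import predict_response

    rows = []
    established = getattr(fit, "established", False)
    for region, cmax in region_cmax_um.items():
        row = {"region": region, "cmax_um": float(cmax)}
        if established:
            row["ic50_um"] = fit.ic50_um
            row["exposure_ratio"] = cmax / fit.ic50_um
            row["predicted_response"] = predict_response(fit, cmax)
            row["at_risk"] = bool(cmax >= at_risk_fraction * fit.ic50_um)
            row["no_in_vitro_effect_detected"] = False
        else:
            row.update(ic50_um=float("nan"), exposure_ratio=float("nan"),
                       predicted_response=float("nan"), at_risk=False,
                       no_in_vitro_effect_detected=True)
        rows.append(row)
    return pd.DataFrame(rows)
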