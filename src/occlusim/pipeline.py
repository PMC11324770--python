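"""End-to-end workflow: simulate a screening plate, quantify it, fit the
dose-response, classify, score predictivity, simulate lung exposure and map
it onto the in vitro curve.  Deterministic given the master seed."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .doseresponse import (classify_compound, cooper_statistics, fit_ic50,
                           normalize_to_vehicle)
from .io import RunConfig, save_config, write_table
from .lungpbpk import (AirwayMorphometry, CompoundParams, DoseEvent,
                       build_model, elf_region_summary, map_exposure_to_ic50,
                       simulate)
from .quantify import (JunctionParams, NucleiParams, QuantifyParams,
                       aggregate_well, analyze_manifest, field_metrics)
from .synthimg import (MonolayerSpec, default_layout, iter_plate_fields,
                       simulate_plate)

log = logging.getLogger("occlusim")

__all__ = ["run_end_to_end", "fits_table", "quantify_params_from_config",
           "simulate_and_quantify_plate", "recover_ic50"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def quantify_params_from_config(cfg: dict) -> QuantifyParams:
    nuc = NucleiParams(**cfg.get("nuclei", {}))
    jun = JunctionParams(**cfg.get("junction", {}))
    extra = {k: v for k, v in cfg.items() if k not in ("nuclei", "junction")}
    return QuantifyParams(nuclei=nuc, junction=jun, **extra)


def fits_table(fits: list) -> pd.DataFrame:
    rows = []
    for fit in fits:
        rows.append({
            "compound": fit.compound_id,
            "ic50_um": fit.ic50_um if fit.established else float("nan"),
            "established": fit.established,
            "classification": classify_compound(fit),
            "method": fit.method,
            "slope": fit.slope,
            "residual_sd": fit.residual_sd,
        })
    return pd.DataFrame(rows)


def simulate_and_quantify_plate(layout, pharmacology, base_spec,
                                fields_per_well: int, seed: int,
                                params: QuantifyParams = QuantifyParams(),
                                plate_id: str = "P1") -> pd.DataFrame:
    """Stream a simulated plate through the quantification pipeline one
    field at a time (bounded memory) and return the per-well metrics
    table."""
    per_well: dict[str, dict] = {}
    for rec, images, _ in iter_plate_fields(layout, pharmacology, base_spec,
                                            fields_per_well, seed, plate_id):
        fm = field_metrics(images, params)
        entry = per_well.setdefault(rec["well"], {"rec": rec, "fields": []})
        entry["fields"].append(fm)
    rows = []
    for well, entry in per_well.items():
        wm = aggregate_well(entry["fields"], params.normalization)
        rec = entry["rec"]
        rows.append({
            "plate": plate_id, "well": well, "compound": rec["compound"],
            "concentration_um": rec["concentration_um"],
            "role": rec["role"], "n_fields": wm.n_fields,
            "mean_nuclei_count": wm.mean_nuclei_count,
            "membrane_area_per_cell_um2": wm.membrane_area_per_cell_um2,
            "junction_area_per_cell_um2": wm.junction_area_per_cell_um2,
            "undefined_per_cell": wm.undefined_per_cell,
        })
    return pd.DataFrame(rows)


def recover_ic50(true_ic50_um: float, hill: float, seed: int,
                 n_replicates: int = 3, fields_per_well: int = 16,
                 base_spec: MonolayerSpec | None = None,
                 compound_id: str = "CMPD", method: str = "loglinear"):
    """Full in-silico assay for one compound: simulate ``n_replicates``
    plates at the given true junction IC50, quantify them, normalize to
    vehicle and fit.  Returns the :class:`DoseResponseFit`."""
    if base_spec is None:
        base_spec = MonolayerSpec()
    layout = default_layout(compound_id)
    frames = []
    for rep in range(n_replicates):
        wells = simulate_and_quantify_plate(
            layout, {"junction_ic50_um": true_ic50_um,
                     "junction_hill": hill},
            base_spec, fields_per_well, seed=seed + rep,
            plate_id=f"R{rep + 1}")
        frames.append(normalize_to_vehicle(wells))
    resp = pd.concat(frames, ignore_index=True)
    return fit_ic50(resp["concentration_um"].to_numpy(),
                    resp["response"].to_numpy(),
                    resp["viability_response"].to_numpy(),
                    compound_id=compound_id, method=method)


def run_end_to_end(config: RunConfig) -> dict:
    """Run the whole pipeline and return (and write) the summary report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "resolved_config.yaml")

    gen = dict(config.generator)
    pharmacology = gen.pop("pharmacology",
                           {"junction_ic50_um": 27.9, "junction_hill": 1.0})
    fields_per_well = int(gen.pop("fields_per_well", 4))
    compound_id = gen.pop("compound_id", "CMPD")
    base_spec = MonolayerSpec(**gen, seed=config.master_seed)

    try:
        layout = default_layout(compound_id)
        fields, manifest = simulate_plate(
            layout, pharmacology, base_spec, fields_per_well,
            seed=config.master_seed, out_dir=out / "images")
        log.info("simulated %d fields", len(fields))
    except Exception as exc:
        raise StageError("simulate-plate", exc) from exc

    try:
        qparams = quantify_params_from_config(config.quantify)
        field_tbl, well_tbl = analyze_manifest(
            manifest, qparams, base_spec.pixel_size_um, fields=fields)
        write_table(field_tbl, out / "field_metrics.csv", "field_metrics")
        write_table(well_tbl, out / "well_metrics.csv", "well_metrics")
    except Exception as exc:
        raise StageError("analyze-plate", exc) from exc

    try:
        responses = normalize_to_vehicle(well_tbl)
        dr_cfg = dict(config.doseresponse)
        fit = fit_ic50(responses["concentration_um"].to_numpy(),
                       responses["response"].to_numpy(),
                       responses["viability_response"].to_numpy(),
                       compound_id=compound_id,
                       method=dr_cfg.get("method", "loglinear"))
        write_table(fits_table([fit]), out / "fits.csv", "fits")
    except Exception as exc:
        raise StageError("fit-dose-response", exc) from exc

    cooper = None
    truth_path = config.doseresponse.get("truth_table")
    if truth_path:
        try:
            from .io import load_table
            truth = load_table(truth_path, "truth").rename(
                columns={"respiratory_risk": "risk"})
            preds = pd.DataFrame({
                "compound": [fit.compound_id],
                "prediction": [classify_compound(fit)]})
            truth = truth[truth["compound"].isin(preds["compound"])]
            cooper = cooper_statistics(preds, truth)
        except Exception as exc:
            raise StageError("cooper", exc) from exc

    try:
        pb = dict(config.pbpk)
        morphometry = (AirwayMorphometry.from_csv(pb["morphometry"])
                       if "morphometry" in pb else AirwayMorphometry.default())
        compound = CompoundParams(**pb.get(
            "compound", _DEMO_COMPOUND))
        dose = DoseEvent(**pb.get("dose", {"total_dose_nmol": 1000.0}))
        model = build_model(morphometry, compound)
        result = simulate(model, dose,
                          t_end_h=float(pb.get("t_end_h", 24.0)),
                          dt_output_h=float(pb.get("dt_output_h", 0.25)))
        profiles = result.to_long_dataframe()
        write_table(profiles, out / "profiles.csv", "profiles")
        region_cmax = elf_region_summary(result)
    except Exception as exc:
        raise StageError("pbpk-simulate", exc) from exc

    try:
        risk = map_exposure_to_ic50(region_cmax, fit)
        risk.to_csv(out / "risk_map.csv", index=False)
    except Exception as exc:
        raise StageError("risk-map", exc) from exc

    summary = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "n_fields": len(fields),
        "compound": compound_id,
        "ic50_um": fit.ic50_um,
        "established": fit.established,
        "classification": classify_compound(fit),
        "region_cmax_um": {k: round(v, 10) for k, v in region_cmax.items()},
        "exposure_ratio": {
            r["region"]: (None if not fit.established
                          else round(r["exposure_ratio"], 10))
            for r in risk.to_dict("records")},
        "mass_balance_rel_error": float(result.mass_balance_rel_error),
    }
    if cooper is not None:
        summary["cooper"] = {"tp": cooper.tp, "fn": cooper.fn,
                             "tn": cooper.tn, "fp": cooper.fp}
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


_DEMO_COMPOUND = {
    "solubility_cs_um": 50.0,
    "diffusion_d_cm2_per_s": 6e-6,
    "diffusion_layer_h_cm": 30e-4,
    "particle_density_g_per_ml": 1.2,
    "initial_particle_radius_um": 1.5,
    "permeability_p_tb_cm_per_s": 1e-6,
    "molecular_weight_g_per_mol": 450.0,
    "fu_plasma": 0.1,
    "fu_tissue": 0.2,
    "kp_epithelium": 5.0,
    "kp_subepithelium": 5.0,
    "k_in_per_h": 1.0,
    "k_out_per_h": 0.5,
    "cl_ml_per_h": 1500.0,
    "vss_ml": 2000.0,
}
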