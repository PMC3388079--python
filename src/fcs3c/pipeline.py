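"""Stage orchestration: run the configured analysis stages in dependency
order, logging parameters and headline outputs, and writing every
artifact (plus the resolved configuration) into the output directory."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np

from . import calibration, detection, hydrodynamics, synthetic, threec
from .binding import solve_monomer_dimer
from .config import RunConfig
from .errors import ConfigurationError
from .fitting import fit_curve, refit_3d_fixed_a
from .io import read_bands, read_curve, write_bands, write_curve
from .models import ConfocalGeometry, SpeciesParams

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)

#: stage execution order (generators first, then analyses)
_ORDER = (
    "simulate_curve",
    "simulate_gel",
    "fit",
    "refit_3d",
    "calibrate",
    "predict_tau",
    "equilibrium",
    "detect_limit",
    "threec_quant",
)


def _setup_logging(outdir: Path, verbose: bool) -> None:
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("fcs3c")
    root.addHandler(handler)
    root.setLevel(logging.DEBUG if verbose else logging.INFO)


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the configured stages; returns a dict of headline results.

    Artifacts written per stage: generated curves/band tables, fit
    reports, the Kd-exclusion table, and ``results.json`` with every
    headline number. The resolved config lands in ``config_resolved.yaml``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.dump(outdir / "config_resolved.yaml")
    _setup_logging(outdir, cfg.verbose)

    results: dict[str, Any] = {}
    curve = read_curve(cfg.curve_file) if cfg.curve_file else None
    bands = read_bands(cfg.bands_file) if cfg.bands_file else None
    base_fit = None

    for stage in _ORDER:
        if stage not in cfg.stages:
            continue
        block = dict(cfg.blocks.get(stage, {}))
        logger.info("stage %s: params=%s", stage, block)

        if stage == "simulate_curve":
            noise = synthetic.CurveNoiseSpec(
                sigma0=block.get("sigma0", 0.005),
                lag_power=block.get("lag_power", 0.25),
                seed=cfg.seed,
            )
            truth: Any = SpeciesParams(block.get("n", 5.0), block.get("tau_d", 4.0))
            if "tau_d2" in block:
                truth = (
                    truth,
                    SpeciesParams(block.get("n2", truth.n), block["tau_d2"]),
                )
            grid = tuple(block["grid"]) if "grid" in block else None
            curve = synthetic.gen_curve(truth, noise=noise, lag_grid=grid)
            write_curve(curve, outdir / "curve.csv")
            results["simulate_curve"] = {"n_lags": len(curve), "seed": cfg.seed}

        elif stage == "simulate_gel":
            bands = synthetic.gen_band_table(
                true_ratio=block.get("true_ratio", 1.0),
                primer_efficiencies=block.get("primer_efficiencies"),
                condition_scales=block.get("condition_scales"),
                noise_cv=block.get("noise_cv", 0.05),
                replicates=block.get("replicates", 3),
                masses=block.get("masses", (30.0,)),
                seed=cfg.seed,
            )
            write_bands(bands, outdir / "bands.csv")
            results["simulate_gel"] = {"rows": len(bands), "seed": cfg.seed}

        elif stage == "fit":
            if curve is None:
                raise ConfigurationError("fit stage needs curve_file or simulate_curve")
            fixed = {}
            if "structure_param" in block:
                fixed["structure_param"] = block["structure_param"]
            base_fit = fit_curve(
                curve,
                model_id=block.get("model_id", "single_2d"),
                weighted=block.get("weighted", False),
                fit_range=tuple(block["fit_range"]) if "fit_range" in block else
                (1e-2, 1e3),
                fit_baseline=block.get("fit_baseline", False),
                fixed=fixed or None,
            )
            (outdir / "fit.txt").write_text(base_fit.to_text())
            logger.info(
                "fit: model=%s tau_d=%.6g ms N=%.6g converged=%s",
                base_fit.model_id,
                base_fit.tau_d,
                base_fit.params.get("n", base_fit.params.get("n1")),
                base_fit.converged,
            )
            results["fit"] = {
                "tau_d_ms": base_fit.tau_d,
                "converged": base_fit.converged,
                "params": base_fit.params,
            }

        elif stage == "refit_3d":
            if base_fit is None or curve is None:
                raise ConfigurationError("refit_3d stage needs a prior fit stage")
            res = refit_3d_fixed_a(
                curve, base_fit, structure_param=block.get("structure_param", 7.0)
            )
            (outdir / "refit_3d.txt").write_text(res.to_text())
            results["refit_3d"] = {
                "tau_d_ms": res.params["tau_d"],
                "tau_d_rel_change": res.meta["tau_d_rel_change"],
            }

        elif stage == "calibrate":
            if "dye" in block:
                ref = calibration.REFERENCE_DYES[block["dye"]]
                if "tau_d" in block:
                    ref = calibration.ReferenceDye(ref.name, ref.d, block["tau_d"])
            else:
                ref = calibration.ReferenceDye("custom", block["d"], block["tau_d"])
            omega = calibration.beam_radius_from_reference(ref)
            logger.info("calibrate: dye=%s omega=%.4g nm", ref.name, omega)
            results["calibrate"] = {"omega_nm": omega, "dye": ref.name}

        elif stage == "predict_tau":
            assume_keys = {
                k: block[k]
                for k in (
                    "temperature",
                    "viscosity",
                    "partial_specific_volume",
                    "hydration",
                    "dna_rise",
                    "dna_scaling_exponent",
                )
                if k in block
            }
            assume = hydrodynamics.HydroAssumptions(**assume_keys)
            omega = block.get(
                "omega_nm", results.get("calibrate", {}).get("omega_nm")
            )
            if omega is None:
                raise ConfigurationError(
                    "predict_tau needs omega_nm or a prior calibrate stage"
                )
            geom = ConfocalGeometry(omega=omega)
            tau = hydrodynamics.protein_tau_d(block["mass_kda"], geom, assume)
            logger.info(
                "predict_tau: mass=%.4g kDa tau_d=%.4g ms (assumptions %s)",
                block["mass_kda"],
                tau,
                assume,
            )
            out = {"protein_tau_d_ms": tau, "omega_nm": omega}
            if "component_tau_ds" in block:
                lo, hi = hydrodynamics.noninteracting_window(
                    block["component_tau_ds"]
                )
                out["noninteracting_window_ms"] = [lo, hi]
                logger.info("noninteracting window: [%.4g, %.4g] ms", lo, hi)
            results["predict_tau"] = out

        elif stage == "equilibrium":
            eq = solve_monomer_dimer(block.get("c_total", 0.54), block.get("kd", 1.0))
            logger.info(
                "equilibrium: C=%.4g uM Kd=%.4g uM -> %.2f%% of molecules in dimers",
                eq.c_total,
                eq.kd,
                100 * eq.frac_molecules_in_dimers,
            )
            results["equilibrium"] = {
                "monomer_uM": eq.monomer,
                "dimer_uM": eq.dimer,
                "frac_molecules_in_dimers": eq.frac_molecules_in_dimers,
            }

        elif stage == "detect_limit":
            scen = detection.DetectionScenario(
                c_total=block.get("c_total", 0.54),
                kd=block.get("kd", 1.0),
                tau_d_monomer=block.get("tau_d_monomer", 4.0),
                tau_d_dimer=block.get("tau_d_dimer", 15.0),
                n_total=block.get("n_total", 1.0),
            )
            app = detection.apparent_tau_d_at_kd(scen)
            out: dict[str, Any] = {
                "apparent_tau_d_ms": app.params["tau_d"],
                "frac_in_dimers": app.meta["frac_in_dimers"],
            }
            logger.info(
                "detect_limit: Kd=%.4g uM -> apparent tau_d=%.4g ms",
                scen.kd,
                app.params["tau_d"],
            )
            if "kd_grid" in block and "measured_tau_d" in block:
                table = detection.kd_exclusion_curve(
                    scen,
                    np.asarray(block["kd_grid"], dtype=float),
                    measured_tau_d=block["measured_tau_d"],
                    measured_sd=block.get("measured_sd", 0.2),
                    sigma_threshold=block.get("sigma_threshold", 3.0),
                )
                table.to_csv(outdir / "kd_exclusion.csv", index=False)
                out["excluded_kds"] = table.loc[
                    table["distinguishable"], "kd"
                ].tolist()
            results["detect_limit"] = out

        elif stage == "threec_quant":
            if bands is None:
                raise ConfigurationError(
                    "threec_quant stage needs bands_file or simulate_gel"
                )
            ratio = threec.condition_ratio(
                bands,
                test_pair=block.get("test_pair", "a:c"),
                control_pair=block.get("control_pair", "a:b"),
                numerator_condition=block.get("numerator_condition", "plus_T7"),
                denominator_condition=block.get("denominator_condition", "minus_T7"),
            )
            logger.info(
                "threec_quant: condition ratio = %.4g +/- %.4g (%s/%s, norm %s)",
                ratio.value,
                ratio.sd,
                ratio.numerator,
                ratio.denominator,
                ratio.normalizer,
            )
            results["threec_quant"] = {"ratio": ratio.value, "sd": ratio.sd}

    (outdir / "results.json").write_text(json.dumps(results, indent=2, default=float))
    return results
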