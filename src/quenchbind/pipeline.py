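"""Orchestration: simulate -> analyze -> report.

`run_simulate` writes a file bundle (spectra CSV, assay CSVs, ground-
truth manifest) from a config; `run_analyze` consumes spectra and assay
CSVs and runs the full analysis chain — quench ratios, Stern-Volmer and
double-log fits per temperature, mechanism classification, van't Hoff
thermodynamics, peak/shift table, assay indices — into a JSON-
serialisable :class:`AnalysisReport` plus CSV tables.

Every analysis decision (evaluation-wavelength mode, tau0, smoothing
window, EAI convention, shift tolerance) lives in the config dict and
is echoed into the report's provenance block so any number in the
report is reproducible from the report alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assays import EAIMode, process_dpph_table, process_emulsion_table, process_foam_table
from .quenching import (
    DEFAULT_TAU0,
    DIFFUSION_LIMIT,
    classify_mechanism,
    double_log_fit,
    stern_volmer_fit,
)
from .simulate import DesignGrid, GroundTruth, simulate_assays, simulate_titration, write_manifest
from .spectra import (
    EvaluationMode,
    classify_shift,
    find_peak,
    quench_ratios,
    read_spectra_csv,
    write_spectra_csv,
)
from .thermo import analyze_thermodynamics

log = logging.getLogger("quenchbind")

DEFAULT_ANALYSIS_CONFIG = {
    "evaluation_mode": "reference_peak",
    "smoothing_window": 5,
    "tau0_s": DEFAULT_TAU0,
    "diffusion_limit": DIFFUSION_LIMIT,
    "shift_tolerance": 0.5,
    "eai_mode": "pearce_kinsella",
}


class ValidationError(ValueError):
    """Raised for invalid configuration or inputs; maps to exit code 2."""


@dataclass
class AnalysisReport:
    """Machine-readable bundle of every fitted quantity and call."""

    quenching_fits: list  # dicts per temperature
    binding_fits: list
    mechanism: dict
    thermodynamics: dict
    shift_table: list
    assay_tables: dict
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, default=_jsonify)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, path) -> "AnalysisReport":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(**payload)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_simulate(config: dict, out_dir, seed: int | None = None) -> dict:
    """Write a synthetic bundle; returns the paths written.

    ``config`` may hold ``ground_truth`` and ``design`` mappings whose
    keys override the defaults of :class:`GroundTruth` / :class:`DesignGrid`.
    ``seed`` overrides the ground truth's seed.  Deterministic for a
    fixed (config, seed).
    """
    truth_kw = dict(config.get("ground_truth", {}))
    if seed is not None:
        truth_kw["seed"] = int(seed)
    try:
        truth = GroundTruth(**truth_kw)
        design_kw = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in config.get("design", {}).items()
        }
        grid = DesignGrid(**design_kw)
    except (TypeError, ValueError) as exc:
        raise ValidationError(str(exc)) from exc

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series = simulate_titration(truth, grid)
    paths = {
        "spectra": out_dir / "spectra.csv",
        "dpph": out_dir / "dpph.csv",
        "foam": out_dir / "foam.csv",
        "emulsion": out_dir / "emulsion.csv",
        "manifest": out_dir / "manifest.json",
    }
    write_spectra_csv(paths["spectra"], series)
    dpph, foam, emulsion = simulate_assays(truth)
    dpph.to_csv(paths["dpph"], index=False, float_format="%.12g")
    foam.to_csv(paths["foam"], index=False, float_format="%.12g")
    emulsion.to_csv(paths["emulsion"], index=False, float_format="%.12g")
    write_manifest(paths["manifest"], truth, grid)
    log.info("simulated bundle written to %s", out_dir)
    return {k: str(v) for k, v in paths.items()}


def run_analyze(config: dict, out_dir=None) -> AnalysisReport:
    """Run the full analysis chain on the inputs named in ``config``.

    Config keys: ``spectra_csv`` (required unless ``ka_by_temperature``
    supplies binding constants directly in skip-spectra mode), optional
    ``dpph_csv``/``foam_csv``/``emulsion_csv``, plus the analysis
    options of :data:`DEFAULT_ANALYSIS_CONFIG`.
    """
    cfg = {**DEFAULT_ANALYSIS_CONFIG, **config}
    quench_rows, binding_rows, shift_rows = [], [], []
    mechanism_dict: dict = {}
    ka_map: dict = {}

    if cfg.get("spectra_csv"):
        path = Path(cfg["spectra_csv"])
        if not path.exists():
            raise ValidationError(f"missing input file: {path}")
        series_list = read_spectra_csv(path)
        fits = []
        for series in series_list:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = quench_ratios(
                    series,
                    at=EvaluationMode(cfg["evaluation_mode"]),
                    window=int(cfg["smoothing_window"]),
                )
                excluded = table.loc[table["enhancement"]]
                for row in excluded.itertuples():
                    log.warning(
                        "stage=quench_ratios T=%s: enhancement row excluded at Q=%g",
                        series.temperature, row.quencher_conc_M,
                    )
                qfit = stern_volmer_fit(
                    table, tau0=float(cfg["tau0_s"]), temperature=series.temperature
                )
                bfit = double_log_fit(table, temperature=series.temperature)
            fits.append(qfit)
            quench_rows.append(dataclasses.asdict(qfit))
            binding_rows.append(dataclasses.asdict(bfit))
            ka_map[series.temperature] = bfit.Ka

            ref_peak = find_peak(series.reference, window=int(cfg["smoothing_window"]))
            last_peak = find_peak(series.spectra[-1], window=int(cfg["smoothing_window"]))
            call = classify_shift(ref_peak, last_peak, tolerance=float(cfg["shift_tolerance"]))
            shift_rows.append(
                {
                    "temperature_K": series.temperature,
                    "lambda_max_reference": ref_peak.position,
                    "lambda_max_saturated": last_peak.position,
                    "direction": call.direction.value,
                    "delta": call.delta,
                    "description": call.describe(),
                }
            )
        if len(fits) >= 2:
            mech = classify_mechanism(fits, diffusion_limit=float(cfg["diffusion_limit"]))
            mechanism_dict = {
                "verdict": mech.verdict.value,
                "kq_exceeds_diffusion_limit": {
                    str(t): v for t, v in mech.kq_exceeds_diffusion_limit.items()
                },
                "ksv_temperature_trend": mech.ksv_temperature_trend.value,
                "diffusion_limit": mech.diffusion_limit,
            }
    elif cfg.get("ka_by_temperature"):
        ka_map = {float(t): float(ka) for t, ka in cfg["ka_by_temperature"].items()}
    else:
        raise ValidationError("config must name spectra_csv or ka_by_temperature")

    thermo_dict: dict = {}
    if len(ka_map) >= 2:
        thermo = analyze_thermodynamics(ka_map)
        thermo_dict = {
            "delta_H_J_per_mol": thermo.delta_H,
            "delta_S_J_per_mol_K": thermo.delta_S,
            "r_squared": thermo.r_squared,
            "gibbs_J_per_mol": {str(t): g for t, g in thermo.gibbs.items()},
            "gibbs_from_lnKa_J_per_mol": {str(t): g for t, g in thermo.gibbs_from_lnKa.items()},
            "force_call": thermo.force_call.value,
            "spontaneous": {str(t): s for t, s in thermo.spontaneous.items()},
            "gas_constant": thermo.gas_constant,
        }
        # user-supplied (dH, dS) evaluated alongside the fitted ones
        if cfg.get("delta_H_J_per_mol") is not None and cfg.get("delta_S_J_per_mol_K") is not None:
            from .thermo import gibbs_free_energy

            user_g = gibbs_free_energy(
                float(cfg["delta_H_J_per_mol"]),
                float(cfg["delta_S_J_per_mol_K"]),
                sorted(ka_map),
            )
            thermo_dict["gibbs_user_J_per_mol"] = {str(t): g for t, g in user_g.items()}

    assay_tables: dict = {}
    for key, processor, kw in (
        ("dpph_csv", process_dpph_table, {}),
        ("foam_csv", process_foam_table, {}),
        ("emulsion_csv", process_emulsion_table, {"mode": EAIMode(cfg["eai_mode"])}),
    ):
        if cfg.get(key):
            path = Path(cfg[key])
            if not path.exists():
                raise ValidationError(f"missing input file: {path}")
            frame = processor(pd.read_csv(path), **kw)
            assay_tables[key.removesuffix("_csv")] = frame.to_dict(orient="records")

    report = AnalysisReport(
        quenching_fits=quench_rows,
        binding_fits=binding_rows,
        mechanism=mechanism_dict,
        thermodynamics=thermo_dict,
        shift_table=shift_rows,
        assay_tables=assay_tables,
        provenance={
            "config": {k: v for k, v in cfg.items()},
            "config_hash": _config_hash(cfg),
            "tool_version": __version__,
        },
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_json(out_dir / "report.json")
        pd.DataFrame(quench_rows).to_csv(out_dir / "quenching_fits.csv", index=False)
        pd.DataFrame(binding_rows).to_csv(out_dir / "binding_fits.csv", index=False)
        if shift_rows:
            pd.DataFrame(shift_rows).to_csv(out_dir / "shifts.csv", index=False)
    return report


def render_report(report: AnalysisReport) -> str:
    """Human-readable summary of an analysis report."""
    lines = ["quenchbind analysis report", "=" * 26]
    if report.quenching_fits:
        lines.append("\nStern-Volmer fits:")
        for f in report.quenching_fits:
            lines.append(
                f"  T={f['temperature']:.0f} K  K_SV={f['K_SV']:.4g} L/mol  "
                f"kq={f['kq']:.4g} L/mol/s  r2={f['r_squared']:.4f}"
            )
    if report.binding_fits:
        lines.append("\nDouble-log binding fits:")
        for f in report.binding_fits:
            lines.append(
                f"  T={f['temperature']:.0f} K  Ka={f['Ka']:.4g} L/mol  "
                f"n={f['n']:.3f}  r2={f['r_squared']:.4f}"
            )
    if report.mechanism:
        m = report.mechanism
        lines.append(
            f"\nQuenching mechanism: {m['verdict']} "
            f"(K_SV trend {m['ksv_temperature_trend']}, "
            f"diffusion limit {m['diffusion_limit']:g})"
        )
    if report.thermodynamics:
        t = report.thermodynamics
        lines.append(
            f"\nVan't Hoff: dH={t['delta_H_J_per_mol']:.4g} J/mol  "
            f"dS={t['delta_S_J_per_mol_K']:.4g} J/mol/K  r2={t['r_squared']:.4f}"
        )
        lines.append(f"Driving force: {t['force_call']}")
        for temp, g in sorted(t["gibbs_J_per_mol"].items(), key=lambda kv: float(kv[0])):
            spont = "spontaneous" if t["spontaneous"][temp] else "non-spontaneous"
            lines.append(f"  dG({float(temp):.0f} K) = {g:.1f} J/mol  [{spont}]")
    for row in report.shift_table:
        lines.append(
            f"\nPeak shift at {row['temperature_K']:.0f} K: {row['description']} "
            f"({row['lambda_max_reference']:.1f} -> {row['lambda_max_saturated']:.1f})"
        )
    return "\n".join(lines)
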