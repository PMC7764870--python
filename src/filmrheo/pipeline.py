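"""End-to-end pipeline: read inputs, run every analysis stage, write a report.

The report bundle is a directory of CSV tables and JSON documents plus a
``manifest.json`` tagging every output with the tool version and a hash of
the configuration.  All numeric output is written with full repr precision
and sorted keys, so re-running with identical config and inputs reproduces
the bundle byte-for-byte.  Failures of individual inputs are collected and
reported; the run continues past them.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, config_hash
from .errors import FilmRheoError
from .isotherm_analysis import (hysteresis_area, pressure_shift, split_cycles,
                                squeeze_out_pressure, stationarity_index)
from .kinetics_analysis import penetration_features
from .maxwell_model import fit_relaxation, maxwell_elements
from .rheology_spectrum import classify_film, cole_cole, compute_spectrum
from .transients_io import Dialect, read_timeseries

__all__ = ["PipelineReport", "run_pipeline"]


@dataclass
class PipelineReport:
    """Summary of one pipeline run: per-input results and failures."""

    out_dir: Path
    manifest: dict
    failures: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


def _spectrum_frame(spec) -> pd.DataFrame:
    return pd.DataFrame({"freq_hz": spec.freq,
                         "e_real_mn_per_m": spec.e_real,
                         "e_imag_mn_per_m": spec.e_imag})


def _fit_document(fit) -> dict:
    elems = maxwell_elements(fit)
    return {
        "components": [{"amplitude_mn_per_m": a, "tau_s": tau}
                       for a, tau in fit.components],
        "plateau_mn_per_m": fit.plateau,
        "strain": fit.strain,
        "residual_rms_mn_per_m": fit.residual_rms,
        "stderr": fit.stderr,
        "resolvable": fit.resolvable,
        "n_auto": fit.n_auto,
        "elements": [{"e_mn_per_m": e, "eta_mn_s_per_m": eta, "tau_s": tau}
                     for e, eta, tau in elems.elements],
        "e_eq_mn_per_m": elems.e_eq,
    }


def run_pipeline(cfg: RunConfig) -> PipelineReport:
    """Run every configured stage and assemble the report bundle.

    Relaxation inputs produce a spectrum CSV, Cole-Cole peak list,
    elastic/viscous classification and a generalized-Maxwell fit; isotherm
    pairs produce a cycle summary and a shift/squeeze-out comparison;
    kinetics traces produce feature documents.  Per-input exceptions are
    caught, recorded in the manifest and returned in ``failures``.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dialect = Dialect(sep=cfg.sep, decimal=cfg.decimal)
    entries = []
    failures = []

    def guard(name, kind, fn):
        try:
            result = fn()
            entries.append({"input": name, "kind": kind, "status": "ok",
                            "outputs": result})
        except (FilmRheoError, OSError, ValueError) as exc:
            failures.append({"input": name, "kind": kind, "error": str(exc)})
            entries.append({"input": name, "kind": kind, "status": "failed",
                            "error": str(exc),
                            "traceback": traceback.format_exc(limit=3)})

    for item in cfg.relaxation_inputs:
        path = item["path"]
        stem = Path(path).stem

        def do_relaxation(item=item, path=path, stem=stem):
            t = read_timeseries(path, "relaxation", dialect,
                                strain=item.get("strain", cfg.strain),
                                pi0=item.get("pi0"))
            spec = compute_spectrum(t)
            _spectrum_frame(spec).to_csv(out / f"{stem}_spectrum.csv", index=False)
            cc = cole_cole(spec, prominence_frac=cfg.peak_prominence)
            fit = fit_relaxation(t, cfg.n_components, seed=cfg.seed)
            band = cfg.classification_band
            lo = max(band[0], spec.freq[0])
            hi = min(band[1], spec.freq[-1])
            verdict = classify_film(spec, (lo, hi))
            _write_json(out / f"{stem}_fit.json", _fit_document(fit))
            _write_json(out / f"{stem}_colecole.json", {
                "n_peaks": cc.peaks.count,
                "peaks": [{"freq_hz": f, "e_real": er, "e_imag": ei}
                          for f, er, ei in cc.peaks.peaks],
                "classification": verdict.label,
                "elastic_fraction": verdict.elastic_fraction,
            })
            return [f"{stem}_spectrum.csv", f"{stem}_fit.json", f"{stem}_colecole.json"]

        guard(path, "relaxation", do_relaxation)

    for pair in cfg.isotherm_pairs:
        ref_path, test_path = pair["ref"], pair["test"]
        stem = f"{Path(ref_path).stem}_vs_{Path(test_path).stem}"

        def do_pair(ref_path=ref_path, test_path=test_path, stem=stem):
            ref = read_timeseries(ref_path, "trough", dialect)
            test = read_timeseries(test_path, "trough", dialect)
            rc, tc = split_cycles(ref), split_cycles(test)
            doc = {"n_cycles_ref": len(rc), "n_cycles_test": len(tc)}
            if len(rc) >= 2:
                doc["stationarity_index_ref"] = stationarity_index(rc, cfg.stationarity_tol)
            if rc:
                doc["hysteresis_area_ref"] = hysteresis_area(rc[-1])
            if rc and tc:
                cmp_ = pressure_shift(rc[-1].compression, tc[-1].compression)
                so = squeeze_out_pressure(cmp_, cfg.squeeze_out_threshold)
                doc.update({"mean_shift_mn_per_m": cmp_.mean_shift,
                            "max_shift_mn_per_m": cmp_.max_shift,
                            "squeeze_out_pressure_mn_per_m": so,
                            "threshold_mn_per_m": cfg.squeeze_out_threshold})
                pd.DataFrame({"area": cmp_.area_grid,
                              "pi_ref_mn_per_m": cmp_.pi_ref,
                              "pi_test_mn_per_m": cmp_.pi_test,
                              "shift_mn_per_m": cmp_.shift}
                             ).to_csv(out / f"{stem}_shift.csv", index=False)
            _write_json(out / f"{stem}_comparison.json", doc)
            return [f"{stem}_comparison.json", f"{stem}_shift.csv"]

        guard(f"{ref_path} vs {test_path}", "isotherm_pair", do_pair)

    for item in cfg.kinetics_inputs:
        path = item["path"]
        stem = Path(path).stem

        def do_kinetics(item=item, path=path, stem=stem):
            k = read_timeseries(path, "kinetics", dialect, pi0=item.get("pi0"))
            feats = penetration_features(k, tol=cfg.kinetics_tol)
            _write_json(out / f"{stem}_kinetics.json", {
                "delta_pi_max_mn_per_m": feats.delta_pi_max,
                "t_peak_s": feats.t_peak,
                "t_requil_s": feats.t_requil,
                "tol_mn_per_m": feats.tol,
                "pi0_mn_per_m": feats.pi0,
            })
            return [f"{stem}_kinetics.json"]

        guard(path, "kinetics", do_kinetics)

    manifest = {
        "tool": "filmrheo",
        "version": __version__,
        "config_hash": config_hash(cfg),
        "config": cfg.to_dict(),
        "inputs": entries,
        "n_failed": len(failures),
    }
    _write_json(out / "manifest.json", manifest)
    return PipelineReport(out_dir=out, manifest=manifest, failures=failures)
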