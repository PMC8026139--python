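"""End-to-end orchestration: run every analysis stage on the synthetic
fixture library and write deterministic JSON reports.

Stages map one-to-one to the library modules: ``spectra`` (λmax / violet
contribution of the four blues), ``color`` (CIELAB / hue-angle matching),
``titration`` (pK′h fits), ``decay`` (percent-loss kinetics), ``mass``
(exact masses and stoichiometry assignment), ``hplc`` (enzymatic
conversion) and ``seqid`` (screen sequence statistics).  Reports carry
units on every numeric output and never include timestamps, so the same
config + seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from . import (
    chromatography,
    colorimetry,
    equilibria,
    kinetics,
    masscalc,
    seqscreen,
    spectra,
    synthetic,
)

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]

log = logging.getLogger("anthochrome")

ALL_STAGES = ("spectra", "color", "titration", "decay", "mass", "hplc", "seqid")

Stage = Literal["spectra", "color", "titration", "decay", "mass", "hplc", "seqid"]


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    stages: tuple[Stage, ...] = ALL_STAGES
    seed: int = 0
    out_dir: str = "reports"
    simulate: bool = True
    illuminant: str = "D65"
    observer: str = "cie_1931_2deg"
    mass_tol_ppm: float = 10.0
    peak_assign_tol_min: float = 0.5
    titration_noise_sd: float = 0.005
    panel_n: int = 46
    panel_n_active: int = 17
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)


def _stage_spectra(cfg: PipelineConfig) -> dict:
    rows = {}
    for name in ("blue_no1", "spirulina", "rca_pH8", "alp2_pH7"):
        s = synthetic.make_spectrum_fixture(name, seed=cfg.seed)
        m = spectra.find_lambda_max(s)
        rows[name] = {
            "lambda_max_nm": m.lambda_max_nm,
            "a_max_AU": m.a_max,
            "violet_contribution_nm_AU": spectra.violet_contribution(s),
        }
    shift = spectra.bathochromic_shift(
        synthetic.make_spectrum_fixture("P2_0eq", seed=cfg.seed),
        synthetic.make_spectrum_fixture("P2_Al13", seed=cfg.seed),
    )
    return {"samples": rows, "P2_bathochromic_shift_nm": shift}


def _stage_color(cfg: PipelineConfig) -> dict:
    settings = colorimetry.ColorimetrySettings(
        observer=cfg.observer, illuminant=cfg.illuminant
    )
    reports = {}
    cie_grid = np.arange(380.0, 781.0)  # full observer support
    for name in ("blue_no1", "spirulina", "rca_pH8", "alp2_pH7"):
        s = synthetic.make_spectrum_fixture(name, seed=cfg.seed, grid_nm=cie_grid)
        reports[name] = colorimetry.color_report(s, settings, sample=name)
    hue_ref = reports["blue_no1"]["hue_deg"]
    hue_new = reports["alp2_pH7"]["hue_deg"]
    dh = abs(hue_new - hue_ref)
    reports["hue_match_alp2_vs_blue_no1"] = {
        "abs_delta_hue_deg": min(dh, 360.0 - dh),
        "delta_e76": colorimetry.delta_e76(
            colorimetry.LabColor(*reports["blue_no1"]["Lab"]),
            colorimetry.LabColor(*reports["alp2_pH7"]["Lab"]),
        ),
    }
    return reports


def _stage_titration(cfg: PipelineConfig) -> dict:
    out = {}
    for name, fx in synthetic.TITRATION_LIBRARY.items():
        series = synthetic.make_titration_fixture(
            name, seed=cfg.seed, noise_sd=cfg.titration_noise_sd
        )
        fit = equilibria.fit_pkh(series)
        out[name] = fit.to_dict() | {
            "truth_pKh_prime": fx.pKh_prime,
            "units": "log units",
            "seed": cfg.seed,
        }
    return out


def _stage_decay(cfg: PipelineConfig) -> dict:
    out = {}
    for name, fx in synthetic.DECAY_LIBRARY.items():
        series = synthetic.make_decay_fixture(name, seed=cfg.seed)
        fit = kinetics.fit_first_order(series)
        entry = fit.to_dict() | {"units": {"k": "1/day", "half_life": "days"}}
        if fx.calibration is not None:
            t_cal, _ = fx.calibration
            entry["percent_loss_at_calibration_day"] = {
                "t_days": t_cal,
                "percent": kinetics.percent_loss(fit, t_cal),
            }
        out[name] = entry
    return out


def _stage_mass(cfg: PipelineConfig) -> dict:
    p2 = masscalc.compose_anthocyanin(masscalc.BUILDING_BLOCKS["P2"])
    observed = [1478.8629, 985.5760]
    result = masscalc.assign_stoichiometry(
        observed, p2, metal="Al", tol_ppm=cfg.mass_tol_ppm
    )
    return {
        "P2_formula": p2.to_string(),
        "P2_monoisotopic_mz_cation": masscalc.monoisotopic_mass(p2),
        "observed_mz": observed,
        "assignments": result.to_records(),
        "consensus_k": result.consensus_k,
        "tol_ppm": cfg.mass_tol_ppm,
        "units": {"mass": "Da", "mz": "Th"},
    }


def _stage_hplc(cfg: PipelineConfig) -> dict:
    def table(treatment: str):
        c = synthetic.make_rca_chromatogram(treatment, seed=cfg.seed)
        peaks = chromatography.detect_peaks(c)
        peaks = chromatography.integrate_peaks(c, peaks)
        return chromatography.assign_peaks(
            peaks, synthetic.REFERENCE_PEAK_TIMES, tol_min=cfg.peak_assign_tol_min
        )

    before = table("untreated")
    after = table("M73H_complete")
    metrics = chromatography.conversion_metrics(before, after)
    p2_rel = float(
        before.loc[before["peak_id"] == "P2", "relative_area_pct"].iloc[0]
    )
    return {
        "untreated_P2_relative_area_pct": p2_rel,
        "conversion_untreated_to_M73H": metrics,
        "units": {"areas": "mAU·min", "relative_area": "%"},
    }


def _stage_seqid(cfg: PipelineConfig) -> dict:
    panel = synthetic.make_sequence_panel(
        n=cfg.panel_n, n_active=cfg.panel_n_active, seed=cfg.seed
    )
    matrix = seqscreen.identity_matrix(panel)
    active_ids = [r.id for r in panel if r.active]
    return {
        "summary": seqscreen.screen_summary(panel),
        "median_identity_tested_pct": seqscreen.median_identity(matrix),
        "median_identity_active_pct": seqscreen.median_identity(matrix, active_ids),
        "units": "% identity over full alignment length",
    }


_STAGE_FUNCS = {
    "spectra": _stage_spectra,
    "color": _stage_color,
    "titration": _stage_titration,
    "decay": _stage_decay,
    "mass": _stage_mass,
    "hplc": _stage_hplc,
    "seqid": _stage_seqid,
}


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages, writing one JSON report per stage plus a
    combined ``summary.json`` under ``cfg.out_dir``.  Returns the summary.

    A stage failure is logged and re-raised after earlier reports have
    been written, so partial outputs survive.
    """
    logging.basicConfig(level=cfg.log_level)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": cfg.model_dump(mode="json"), "stages": {}}
    for stage in cfg.stages:
        log.info("stage %s (seed=%d)", stage, cfg.seed)
        try:
            report = _STAGE_FUNCS[stage](cfg)
        except Exception:
            log.exception("stage %s failed; earlier reports preserved", stage)
            raise
        summary["stages"][stage] = report
        with (out_dir / f"{stage}.json").open("w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, cls=_JSONEncoder)
            fh.write("\n")
    with (out_dir / "summary.json").open("w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, cls=_JSONEncoder)
        fh.write("\n")
    return summary
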