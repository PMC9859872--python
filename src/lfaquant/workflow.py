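"""End-to-end runs: simulate -> quantify -> calibrate -> report.

A run is driven by a :class:`RunConfig` (YAML on disk), executes its stages
in order under a fixed seed, persists every intermediate artifact as plain
text/PNG and finishes with a manifest (expanded config, seed, package
version, SHA-256 of every artifact) from which the run can be re-executed
bit-identically.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibrate import (calibration_table, confidence_band, detection_limits,
                        fit_4pl, normalize)
from .containers import StripImage, StripLayout
from .errors import ConfigError, ReportError
from .quantify import signals_to_frame, strip_signals
from .simulate import SimulationConfig, default_layout, simulate_batch

__all__ = ["RunConfig", "run_pipeline", "make_report"]

log = logging.getLogger("lfaquant.workflow")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    out_dir: Path
    seed: int = 0
    label: str = "conjugate"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    images_dir: Path | None = None      # quantify existing images instead
    layout_path: Path | None = None
    level: float = 0.95
    mode: str = "ratio"                 # "ratio" | "test"
    band_kind: str = "confidence"
    log_level: str = "info"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.images_dir is not None:
            self.images_dir = Path(self.images_dir)
            if not self.images_dir.is_dir():
                raise ConfigError(f"images_dir does not exist: {self.images_dir}")
            if self.layout_path is None:
                raise ConfigError("images_dir given without layout_path")
        if self.layout_path is not None:
            self.layout_path = Path(self.layout_path)
            if not self.layout_path.is_file():
                raise ConfigError(f"layout file not found: {self.layout_path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        p = Path(path)
        if not p.is_file():
            raise ConfigError(f"config file not found: {p}")
        raw = yaml.safe_load(p.read_text()) or {}
        if "out_dir" not in raw:
            raise ConfigError("config must define out_dir")
        sim = raw.pop("simulation", {})
        try:
            simcfg = SimulationConfig(**sim)
        except TypeError as exc:
            raise ConfigError(f"bad simulation section: {exc}") from None
        seed = int(raw.pop("seed", 0))
        simcfg.seed = seed
        try:
            return cls(seed=seed, simulation=simcfg, **raw)
        except TypeError as exc:
            raise ConfigError(f"bad config: {exc}") from None

    def expanded(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["images_dir"] = str(self.images_dir) if self.images_dir else None
        d["layout_path"] = str(self.layout_path) if self.layout_path else None
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the manifest dictionary."""
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    # -- stage 1: images ---------------------------------------------------
    if config.images_dir is None:
        img_dir = out / "images"
        records = simulate_batch(config.simulation, out_dir=img_dir)
        layout = StripLayout.load(img_dir / "layout.json")
        conc = {t["strip_id"]: t["concentration_ug_per_l"] for _, t in records}
        images = [(img, t["strip_id"]) for img, t in records]
        for f in sorted(img_dir.iterdir()):
            artifacts[str(f.relative_to(out))] = _sha256(f)
        log.info("stage=simulate n_strips=%d out=%s", len(images), img_dir)
    else:
        layout = StripLayout.load(config.layout_path)
        truth = json.loads((config.images_dir / "ground_truth.json").read_text())
        conc = {t["strip_id"]: t["concentration_ug_per_l"]
                for t in truth["strips"]}
        images = [(StripImage.load(config.images_dir / f"{sid}.png"), sid)
                  for sid in conc]
        log.info("stage=load n_strips=%d from=%s", len(images), config.images_dir)

    # -- stage 2: quantification ------------------------------------------
    results = [strip_signals(img, layout, strip_id=sid) for img, sid in images]
    signals = signals_to_frame(results, concentrations=conc)
    sig_path = out / "signals.csv"
    signals.to_csv(sig_path, index=False, float_format="%.10g")
    artifacts["signals.csv"] = _sha256(sig_path)
    log.info("stage=quantify n_rows=%d failures=%d", len(signals),
             sum(len(r.failures) for r in results))

    # -- stage 3: calibration ---------------------------------------------
    table = normalize(calibration_table(signals, mode=config.mode))
    fit = fit_4pl(table["concentration"].to_numpy(),
                  table["normalized"].to_numpy())
    limits = detection_limits(fit, level=config.level, kind=config.band_kind)
    grid = np.concatenate(([0.0], np.geomspace(1e-2, 2e4, 200)))
    lo, hi = confidence_band(fit, grid, config.level, config.band_kind)
    curve = pd.DataFrame({"concentration_ug_per_l": grid,
                          "fit": fit.predict(grid),
                          "band_lower": lo, "band_upper": hi})
    curve_path = out / "curve.csv"
    curve.to_csv(curve_path, index=False, float_format="%.10g")
    report = {"label": config.label, "seed": config.seed,
              "mode": config.mode, "level": config.level,
              "fit": fit.to_dict(), "limits": limits.to_dict()}
    fit_path = out / "fit.json"
    fit_path.write_text(json.dumps(report, indent=1))
    artifacts["curve.csv"] = _sha256(curve_path)
    artifacts["fit.json"] = _sha256(fit_path)
    log.info("stage=calibrate ec50=%.4g mdc=%.4g rdl=%.4g",
             limits.ec50, limits.mdc, limits.rdl)

    manifest = {
        "package": "lfaquant",
        "version": __version__,
        "seed": config.seed,
        "config": config.expanded(),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def make_report(fit_reports: list[dict],
                characterization_reports: list[dict] | None = None
                ) -> pd.DataFrame:
    """Merge calibration and characterization results into one table.

    Each fit report needs a ``label`` plus ``fit``/``limits`` sections (the
    ``fit.json`` written by :func:`run_pipeline`); characterization reports
    are flat dicts with a ``label`` and e.g. yield / peak shift / diameter
    entries.  One row per label.

    Raises
    ------
    ReportError
        Empty input or duplicate labels.
    """
    if not fit_reports:
        raise ReportError("no fit reports to merge")
    labels = [r.get("label") for r in fit_reports]
    if len(set(labels)) != len(labels):
        raise ReportError(f"duplicate labels in fit reports: {labels}")
    rows = []
    for r in fit_reports:
        rows.append({
            "label": r["label"],
            "EC50_ug_per_l": r["fit"]["EC50"],
            "MDC_ug_per_l": r["limits"]["MDC_ug_per_l"],
            "RDL_ug_per_l": r["limits"]["RDL_ug_per_l"],
        })
    df = pd.DataFrame(rows)
    if characterization_reports:
        clabels = [c.get("label") for c in characterization_reports]
        if len(set(clabels)) != len(clabels):
            raise ReportError(f"duplicate labels in characterization: {clabels}")
        cdf = pd.DataFrame(characterization_reports)
        df = df.merge(cdf, on="label", how="left")
    return df
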