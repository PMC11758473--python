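"""Config-driven orchestration of the full dyadic diary analysis.

Stages: (load or simulate) -> exclusions -> per-person emotion summaries
-> descriptives -> four bivariate APIMs (negative/positive valence x
anxious/depressive symptoms) with robust SEs and standardized paths ->
conditional-effect curves for each mean x emodiversity interaction ->
optional multigroup fits by adolescent gender.  All outputs are CSV (plus
a YAML run manifest with checksums); runs are deterministic given the
config and seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .apim import ApimSpec, build_design, fit_apim, fit_multigroup, robust_se, standardize
from .descriptives import TABLE1_ORDER, descriptives, normality_screen, person_table
from .diary import (apply_exclusions, build_dyads, read_baseline_table,
                    read_diary_table, write_baseline_table, write_diary_table)
from .emometrics import summarize_dyads
from .moderation import conditional_effect
from .synthetic import SyntheticConfig, generate_dyads, write_truth

logger = logging.getLogger(__name__)

# the four models of the standard analysis
DEFAULT_MODELS = (
    ("negative", "anxious"),
    ("positive", "anxious"),
    ("negative", "depressive"),
    ("positive", "depressive"),
)


@dataclass
class RunConfig:
    outdir: str = "emodyad_run"
    seed: int = 0
    diary_path: str | None = None
    baseline_path: str | None = None
    synthetic: dict[str, Any] | None = None
    min_days: int = 6
    center: bool = True
    level: float = 0.95
    curve_level: float = 0.99
    group_by: str | None = None
    min_group_n: int = 10
    models: tuple[tuple[str, str], ...] = DEFAULT_MODELS
    write_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "models" in raw:
            raw["models"] = tuple(tuple(m) for m in raw["models"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dict(vars(self))
        d["models"] = [list(m) for m in self.models]
        return d


@dataclass
class RunManifest:
    config: dict[str, Any]
    version: str
    counts: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # file -> sha256
    warnings: list[str] = field(default_factory=list)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({
                "config": self.config, "version": self.version,
                "counts": self.counts, "outputs": self.outputs,
                "warnings": self.warnings,
            }, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every stage; aborts on stage error with partial outputs kept."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.to_dict(), __version__)
    collector = _WarningCollector()
    logging.getLogger("emodyad").addHandler(collector)
    written: list[Path] = []

    def _write(df: pd.DataFrame, name: str, **kwargs) -> None:
        path = outdir / name
        df.to_csv(path, **kwargs)
        written.append(path)

    try:
        # --- stage: input ------------------------------------------------
        if config.synthetic is not None or config.diary_path is None:
            syn = SyntheticConfig(**{"seed": config.seed, **(config.synthetic or {})})
            dyads, truth = generate_dyads(syn)
            write_truth(truth, outdir / "truth.yaml")
            written.append(outdir / "truth.yaml")
            reports = [r for d in dyads for role in ("adolescent", "caregiver")
                       for r in d.diary(role)]
            baselines = [b for d in dyads
                         for b in (d.adolescent_baseline, d.caregiver_baseline) if b]
            write_diary_table(reports, outdir / "diary.csv")
            write_baseline_table(baselines, outdir / "baseline.csv")
            written += [outdir / "diary.csv", outdir / "baseline.csv"]
        else:
            reports = read_diary_table(config.diary_path)
            baselines = read_baseline_table(config.baseline_path) \
                if config.baseline_path else []
            dyads = build_dyads(reports, baselines)
        manifest.counts["input_dyads"] = len(dyads)

        # --- stage: exclusions -------------------------------------------
        retained, report = apply_exclusions(dyads, min_days=config.min_days)
        manifest.counts["retained_dyads"] = report.n_retained_dyads
        excl = pd.DataFrame(
            [{"dyad_id": k, "reasons": ";".join(v)} for k, v in report.reasons.items()],
            columns=["dyad_id", "reasons"])
        _write(excl, "exclusions.csv", index=False)

        # --- stage: summaries --------------------------------------------
        summaries = summarize_dyads(retained)
        _write(summaries.round(6), "summaries.csv", index=False)
        base_df = pd.DataFrame([vars(b) for d in retained
                                for b in (d.adolescent_baseline, d.caregiver_baseline)
                                if b is not None])
        if base_df.empty:
            raise RuntimeError("no baseline records among retained dyads")

        # --- stage: descriptives -----------------------------------------
        persons = person_table(summaries, base_df)
        table1 = descriptives(persons, order=TABLE1_ORDER)
        _write(table1.formatted(), "table1.csv")
        _write(table1.stats.round(6), "descriptives_raw.csv")
        _write(normality_screen(persons).round(4), "normality_screen.csv", index=False)

        # --- stage: models -----------------------------------------------
        for i, (valence, symptom) in enumerate(config.models, start=1):
            spec = ApimSpec(valence=valence, symptom=symptom, grouping=config.group_by)
            design = build_design(summaries, base_df, spec, center=config.center)
            fit = standardize(robust_se(fit_apim(design), design), design)
            tab = fit.summary_table(level=config.level)
            tab.insert(0, "model", f"model{i}_{valence}_{symptom}")
            _write(tab.round(6), f"table2_model{i}_{valence}_{symptom}.csv", index=False)

            for focal, moderator, outcome in (
                    ("a_div", "a_mean", "y_adol"), ("a_div", "a_mean", "y_cg"),
                    ("c_div", "c_mean", "y_adol"), ("c_div", "c_mean", "y_cg")):
                curve = conditional_effect(fit, focal, moderator, outcome=outcome,
                                           level=config.curve_level, design=design)
                name = f"curve_model{i}_{focal}_on_{outcome}"
                _write(curve.to_frame().round(6), name + ".csv", index=False)
                if config.write_plots:
                    curve.plot(outdir / (name + ".png"))

            if config.group_by is not None:
                grouped = fit_multigroup(design, min_group_n=config.min_group_n)
                rows = []
                for label, gfit in grouped.fits.items():
                    gtab = gfit.summary_table(level=config.level)
                    gtab.insert(0, "group", label)
                    gtab.insert(0, "model", f"model{i}_{valence}_{symptom}")
                    rows.append(gtab)
                _write(pd.concat(rows, ignore_index=True).round(6),
                       f"table2_model{i}_{valence}_{symptom}_by_{config.group_by}.csv",
                       index=False)
            manifest.counts[f"model{i}_n"] = design.n
    except Exception as exc:
        manifest.warnings.append(f"aborted: {exc}")
        raise
    finally:
        manifest.warnings.extend(collector.messages)
        logging.getLogger("emodyad").removeHandler(collector)
        for path in written:
            manifest.outputs[path.name] = _sha256(path)
        manifest.to_yaml(outdir / "manifest.yaml")

    return manifest
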