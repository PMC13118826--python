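"""End-to-end report assembly.

Runs the full pre-formulation chain in the order a formulation study
proceeds — miscibility screening, Tg prediction, powder flow / tablet QC,
dissolution similarity and kinetics, then pharmacokinetics — and assembles
one structured report. Sections whose optional inputs are absent are
skipped with a warning rather than aborting (a formulation workflow is
naturally staged: the desk screens exist before any dissolution or in vivo
data do). Numbers are stored at full precision in the JSON rendering;
rounding is applied only in the human-readable text rendering.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import dissolution as diss
from . import pharmacokinetics as pk
from .glass_transition import ScaleMode, gordon_taylor_tg
from .materials import ParameterLibrary, load_material_library, read_materials_table
from .miscibility import assess_pair
from .powder_qc import PowderDensities, carrs_index, classify_flow

logger = logging.getLogger("glasstab")

__all__ = ["RunConfig", "run_full_report", "render_text", "read_config"]


@dataclass
class RunConfig:
    """Inputs and thresholds for one full pipeline run."""

    drug: str = "GLB"
    polymers: tuple[str, ...] = ("PVP K25", "PVP VA64", "SOL")
    w_drug: float = 0.10
    temperature_k: float = 298.0
    scale_mode: ScaleMode = "celsius"
    tg_threshold: float = 4.0
    materials_path: str | None = None  # None -> bundled library
    dissolution_path: str | None = None
    dissolution_reference: str | None = None
    plasma_path: str | None = None
    plasma_reference: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_drug <= 1.0:
            raise ValueError(f"w_drug must be in [0, 1], got {self.w_drug}")
        if self.temperature_k <= 0:
            raise ValueError("temperature_k must be > 0")
        if self.tg_threshold <= 0:
            raise ValueError("tg_threshold must be > 0")


_CONFIG_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}


def read_config(path) -> RunConfig:
    """Read a flat key = value config file (``#`` comments, blank lines ok)."""
    kwargs: dict[str, Any] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in _CONFIG_FIELDS:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        if key == "polymers":
            kwargs[key] = tuple(s.strip() for s in value.split(",") if s.strip())
        elif key in ("w_drug", "temperature_k", "tg_threshold"):
            kwargs[key] = float(value)
        elif key == "seed":
            kwargs[key] = int(value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def _load_library(config: RunConfig) -> ParameterLibrary:
    if config.materials_path is None:
        return load_material_library()
    return read_materials_table(config.materials_path)


def _miscibility_section(config: RunConfig, lib: ParameterLibrary) -> list[dict]:
    drug = lib[config.drug]
    rows = []
    for name in config.polymers:
        a = assess_pair(drug, lib[name], config.temperature_k)
        rows.append(dataclasses.asdict(a))
    return rows


def _tg_section(config: RunConfig, lib: ParameterLibrary) -> list[dict]:
    drug = lib[config.drug]
    rows = []
    for name in config.polymers:
        pred = gordon_taylor_tg(drug, lib[name], config.w_drug, config.scale_mode)
        rows.append(dataclasses.asdict(pred))
    return rows


def _dissolution_section(config: RunConfig) -> dict | None:
    if config.dissolution_path is None:
        return None
    profiles = diss.read_dissolution_table(config.dissolution_path)
    ref_name = config.dissolution_reference or next(iter(profiles))
    ref = profiles[ref_name]
    comparisons = []
    kinetics = []
    for name, profile in profiles.items():
        best, fits = diss.select_model(profile)
        kinetics.append(
            {
                "formulation": name,
                "best_model": best.model,
                "fits": [dataclasses.asdict(f) for f in fits],
            }
        )
        if name == ref_name:
            continue
        decision = diss.similarity_decision(ref, profile)
        comparisons.append(
            {"test": name, "reference": ref_name, **dataclasses.asdict(decision)}
        )
    return {"reference": ref_name, "similarity": comparisons, "kinetics": kinetics}


def _pk_section(config: RunConfig) -> dict | None:
    if config.plasma_path is None:
        return None
    cohorts = pk.read_plasma_table(config.plasma_path)
    ref_name = config.plasma_reference or next(iter(cohorts))
    summaries = {g: pk.group_summary(ps) for g, ps in cohorts.items()}
    ref = summaries[ref_name]
    f_rows = [
        dataclasses.asdict(pk.relative_bioavailability(s, ref))
        for g, s in summaries.items()
    ]
    anova: dict[str, Any] = {}
    if len(cohorts) >= 2 and all(len(ps) >= 2 for ps in cohorts.values()):
        for param in ("cmax", "tmax", "auc_0_t"):
            values = {
                g: [getattr(pk.nca(p), param) for p in ps] for g, ps in cohorts.items()
            }
            try:
                anova[param] = dataclasses.asdict(pk.one_way_anova(values))
            except Exception as exc:  # e.g. zero variance in every group for tmax
                logger.warning("ANOVA on %s failed: %s", param, exc)
    return {
        "reference": ref_name,
        "groups": {g: dataclasses.asdict(s) for g, s in summaries.items()},
        "relative_bioavailability": f_rows,
        "anova": anova,
    }


def run_full_report(config: RunConfig) -> dict:
    """Run every stage the config has inputs for; skip the rest with warnings."""
    lib = _load_library(config)
    report: dict[str, Any] = {
        "config": dataclasses.asdict(config),
        "miscibility": _miscibility_section(config, lib),
        "glass_transition": _tg_section(config, lib),
    }
    for key, builder in (("dissolution", _dissolution_section), ("pharmacokinetics", _pk_section)):
        try:
            section = builder(config)
        except FileNotFoundError as exc:
            logger.warning("%s section skipped: %s", key, exc)
            section = None
        if section is None:
            logger.warning("%s section skipped (no input configured or file missing)", key)
            report[key] = None
        else:
            report[key] = section
    return report


def render_text(report: dict) -> str:
    """Human-readable rendering; every number it shows exists in the JSON."""
    lines = ["glasstab formulation report", "=" * 29, ""]
    lines.append("Miscibility screening (drug vs polymer)")
    for row in report["miscibility"]:
        lines.append(
            f"  {row['drug']} - {row['polymer']}: "
            f"d-delta {row['delta_delta']:.2f} MPa^1/2 ({row['delta_class']}), "
            f"chi {row['chi']:.4f} ({row['chi_class']}) at {row['temperature']:.0f} K"
        )
    lines.append("")
    lines.append("Gordon-Taylor Tg prediction")
    for row in report["glass_transition"]:
        unit = "degC" if row["scale_mode"] == "celsius" else "K"
        lines.append(
            f"  {row['drug']} {row['w_drug']:.0%} in {row['polymer']}: "
            f"K = {row['k']:.4f}, Tg = {row['tg_predicted']:.2f} {unit}"
        )
    lines.append("")
    if report.get("dissolution"):
        sec = report["dissolution"]
        lines.append(f"Dissolution (reference: {sec['reference']})")
        for cmp_row in sec["similarity"]:
            f2 = "waived" if cmp_row["f2"] is None else f"{cmp_row['f2']:.1f}"
            lines.append(
                f"  {cmp_row['test']}: {cmp_row['rule']}, f2 = {f2}, "
                f"similar = {cmp_row['similar']}"
            )
        for kin in sec["kinetics"]:
            lines.append(f"  {kin['formulation']}: best model {kin['best_model']}")
        lines.append("")
    if report.get("pharmacokinetics"):
        sec = report["pharmacokinetics"]
        lines.append(f"Pharmacokinetics (reference: {sec['reference']})")
        for g, s in sec["groups"].items():
            lines.append(
                f"  {g} (n={s['n']}): Cmax {s['cmax_mean']:.2f}+/-{s['cmax_sd']:.2f}, "
                f"Tmax {s['tmax_mean']:.2f}, AUC {s['auc_mean']:.2f}+/-{s['auc_sd']:.2f}"
            )
        for row in sec["relative_bioavailability"]:
            lines.append(f"  F% {row['test_group']} vs {row['reference_group']}: "
                         f"{row['f_percent']:.1f}%")
        lines.append("")
    return "\n".join(lines)


def write_report(report: dict, out_dir) -> tuple[Path, Path]:
    """Write report.json and report.txt under ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "report.json"
    txt_path = out / "report.txt"
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    txt_path.write_text(render_text(report))
    return json_path, txt_path
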