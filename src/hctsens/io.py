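"""File formats, run configuration and plotting glue.

Conventions: CSV is comma-separated, UTF-8, header required, '.' decimal,
parsed strictly.  Reports are written twice — a rounded human-readable
text file and a full-precision JSON file — and every run drops its fully
resolved configuration next to its outputs so results are reproducible
from the output directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import FrontierCurve
from .decision import SensitivityReport
from .simulation import ScenarioConfig

log = logging.getLogger("hctsens")

__all__ = [
    "check_keys",
    "load_yaml",
    "expand_scenario_config",
    "write_resolved_config",
    "write_report",
    "frontier_frame",
    "plot_frontiers",
    "log_run",
]


def check_keys(cfg: dict, allowed: set[str], context: str) -> None:
    """Reject unknown configuration keys, naming the offender."""
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in {context}; allowed: {sorted(allowed)}"
        )


def load_yaml(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return cfg


_SCENARIO_KEYS = {f.name for f in dataclasses.fields(ScenarioConfig)}


def expand_scenario_config(cfg: dict) -> list[ScenarioConfig]:
    """Expand a scenario block into a list of configs.

    Any field given as a list is treated as grid-expansion shorthand; the
    cartesian product over all list-valued fields is returned.
    """
    check_keys(cfg, _SCENARIO_KEYS, "scenario config")
    fixed = {k: v for k, v in cfg.items() if not isinstance(v, list)}
    varying = {k: v for k, v in cfg.items() if isinstance(v, list)}
    configs = [fixed]
    for key, values in varying.items():
        configs = [{**c, key: v} for c in configs for v in values]
    return [ScenarioConfig(**c) for c in configs]


def write_resolved_config(cfg, outdir: Path, name: str = "resolved_config.yaml") -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if dataclasses.is_dataclass(cfg) and not isinstance(cfg, type):
        cfg = dataclasses.asdict(cfg)
    path = outdir / name
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return path


def _round_floats(obj, precision: int):
    if isinstance(obj, float):
        return round(obj, precision)
    if isinstance(obj, dict):
        return {k: _round_floats(v, precision) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, precision) for v in obj]
    return obj


def write_report(report: SensitivityReport, outdir, precision: int = 2) -> dict[str, Path]:
    """Write a sensitivity report as full-precision JSON plus rounded text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    json_path = outdir / "report.json"
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, default=str)
    txt_path = outdir / "report.txt"
    d = _round_floats(report.to_dict(), precision)
    lines = ["Hybrid controlled trial sensitivity analysis", ""]
    for step in report.narrative:
        lines.append(step)
    lines += [
        "",
        f"Verdict (effect estimate):          {report.verdict_effect}",
        f"Verdict (statistical significance): {report.verdict_significance}",
        "",
        f"HC-value (point / CI limit): {d['hc_value_point']} / {d['hc_value_ci']}",
        f"RD-value:                    {d['rd_value_point']}",
    ]
    txt_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    paths = {"json": json_path, "text": txt_path}
    for curve in report.frontiers:
        p = outdir / f"frontier_{curve.kind}.csv"
        frontier_frame(curve).to_csv(p, index=False)
        paths[curve.kind] = p
    return paths


def frontier_frame(curve: FrontierCurve) -> pd.DataFrame:
    df = pd.DataFrame(curve.points, columns=["rr_su", "rr_uy"])
    df.insert(0, "kind", curve.kind)
    return df


def plot_frontiers(curves: list[FrontierCurve], path) -> Path:
    """Plot sensitivity-region frontiers to a vector (SVG) file.

    Requires matplotlib (the ``plots`` extra); plotting is never needed
    for computation.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    labels = {
        "explain_away_effect": "explain away effect",
        "explain_away_significance": "explain away significance",
        "induce_rd": "induce observed RD",
    }
    for curve in curves:
        if not curve.feasible or len(curve.points) == 0:
            continue
        ax.plot(curve.points[:, 0], curve.points[:, 1], label=labels.get(curve.kind, curve.kind))
        ax.plot([curve.threshold], [curve.threshold], marker="o", ms=4, color="black")
    ax.set_xlabel(r"$RR_{SU}$ (confounder-inclusion association)")
    ax.set_ylabel(r"$RR_{UY}$ (confounder-outcome association)")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path


def log_run(command: str, seed=None, config: dict | None = None) -> None:
    """Log the reproducibility context of a run: package version, command,
    seed and resolved configuration."""
    try:
        version = metadata.version("hctsens")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    log.info("hctsens %s | command=%s | numpy=%s", version, command, np.__version__)
    if seed is not None:
        log.info("seed=%s", seed)
    if config:
        log.info("config=%s", json.dumps(config, default=str, sort_keys=True))
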