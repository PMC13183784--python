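"""CSV persistence for simulation output and reports.

All tables are written with a fixed float format so a rerun with the same
seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

import harvestlab

FLOAT_FORMAT = "%.9g"

FRAME_NAMES = ("census", "deaths", "harvests", "cohorts", "abundance", "births")


def write_frames(frames: dict[str, pd.DataFrame], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in FRAME_NAMES:
        if name in frames:
            frames[name].to_csv(outdir / f"{name}.csv", index=False,
                                float_format=FLOAT_FORMAT, lineterminator="\n")


def read_frames(outdir: str | Path) -> dict[str, pd.DataFrame]:
    outdir = Path(outdir)
    frames = {}
    for name in FRAME_NAMES:
        path = outdir / f"{name}.csv"
        if path.exists():
            frames[name] = pd.read_csv(path, keep_default_na=True)
            if frames[name].empty and name == "census":
                frames[name] = pd.DataFrame(columns=[
                    "replicate", "regime", "week", "phase", "id", "sex",
                    "length_mm", "mature"])
    return frames


def write_report(report: dict[str, pd.DataFrame], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in report.items():
        df.to_csv(outdir / f"{name}.csv", index=False,
                  float_format=FLOAT_FORMAT, lineterminator="\n")


def _flatten(prefix: str, obj, lines: list[str]) -> None:
    if dataclasses.is_dataclass(obj):
        for f in dataclasses.fields(obj):
            _flatten(f"{prefix}{f.name}.", getattr(obj, f.name), lines)
    elif isinstance(obj, dict):
        for k, v in obj.items():
            _flatten(f"{prefix}{k}.", v, lines)
    else:
        lines.append(f"{prefix[:-1]}: {obj!r}")


def write_manifest(outdir: str | Path, config, plan=None, seed: int | None = None) -> None:
    """Plain key-value run manifest: config echo, seed, package version."""
    lines = [f"harvestlab_version: {harvestlab.__version__}"]
    if seed is not None:
        lines.append(f"seed: {seed}")
    _flatten("config.", config, lines)
    if plan is not None:
        lines.append(f"plan.replicates: {plan.replicates}")
        lines.append(f"plan.master_seed: {plan.master_seed}")
        for i, ph in enumerate(plan.phases):
            _flatten(f"plan.phase{i}.", ph, lines)
    Path(outdir).mkdir(parents=True, exist_ok=True)
    (Path(outdir) / "manifest.txt").write_text("\n".join(lines) + "\n")
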