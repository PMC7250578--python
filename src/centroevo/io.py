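"""CSV and config readers/writers.

All tabular outputs are plain CSV preceded by ``#``-prefixed metadata
lines recording the package version, the seed and the full parameter
set, so every file is self-describing and reproducible.
"""

from __future__ import annotations

import dataclasses
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import TimeCourseDataset
from .population import PRESETS, FractionTrajectory, PopulationParams, Trajectory

_TIME_COURSE_COLUMNS = ("cell_line", "day", "extra_fraction")


def read_time_course(path: str | Path) -> TimeCourseDataset:
    """Read an observed time course: columns cell_line,day,extra_fraction[,n_cells]."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _TIME_COURSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df.index[(df["extra_fraction"] < 0) | (df["extra_fraction"] > 1)]
    if len(bad):
        raise ValueError(f"{path}: extra_fraction outside [0, 1] at rows {list(bad + 2)}")
    dup = df.index[df.duplicated(subset=["cell_line", "day"])]
    if len(dup):
        raise ValueError(f"{path}: duplicate days at rows {list(dup + 2)}")
    cell_lines = df["cell_line"].unique()
    if len(cell_lines) != 1:
        raise ValueError(f"{path}: expected one cell line per file, found {list(cell_lines)}")
    df = df.sort_values("day")
    n_cells = df["n_cells"].to_numpy() if "n_cells" in df.columns else None
    return TimeCourseDataset(
        cell_line=str(cell_lines[0]),
        days=df["day"].to_numpy(dtype=float),
        extra_fractions=df["extra_fraction"].to_numpy(dtype=float),
        n_cells=n_cells,
    )


def write_time_course(dataset: TimeCourseDataset, path: str | Path, seed: int | None = None) -> None:
    df = pd.DataFrame({
        "cell_line": dataset.cell_line,
        "day": dataset.days,
        "extra_fraction": dataset.extra_fractions,
    })
    if dataset.n_cells is not None:
        df["n_cells"] = dataset.n_cells
    _write_with_header(df, path, seed=seed)


def load_params(source: str | Path, overrides: dict | None = None) -> PopulationParams:
    """Load a parameter set from a named preset or a YAML/key-value file.

    A file may name a ``preset`` to start from and override individual
    fields; otherwise it must supply every field.
    """
    if isinstance(source, str) and source in PRESETS:
        base = PRESETS[source]
        return base.replace(**overrides) if overrides else base
    path = Path(source)
    if not path.exists():
        raise ValueError(f"unknown preset or missing file: {source!r} "
                         f"(presets: {sorted(PRESETS)})")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    preset = data.pop("preset", None)
    # tolerate run-level keys (alpha, model, ...) in config files
    fields = {f.name for f in dataclasses.fields(PopulationParams)}
    data = {k: float(v) for k, v in data.items() if k in fields}
    if overrides:
        data.update(overrides)
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}")
        return PRESETS[preset].replace(**data)
    missing = fields - set(data) - {"v", "r_S"}
    if missing:
        raise ValueError(f"{path}: missing parameter fields {sorted(missing)}")
    return PopulationParams(**data)


def _metadata_lines(seed: int | None = None, params: PopulationParams | None = None) -> list[str]:
    lines = [f"# centroevo {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if params is not None:
        kv = ", ".join(f"{f.name}={getattr(params, f.name)!r}"
                       for f in dataclasses.fields(params))
        lines.append(f"# params: {kv}")
    return lines


def _write_with_header(df: pd.DataFrame, path: str | Path,
                       seed: int | None = None,
                       params: PopulationParams | None = None) -> None:
    buf = _io.StringIO()
    for line in _metadata_lines(seed, params):
        buf.write(line + "\n")
    df.to_csv(buf, index=False, float_format="%.12g")
    Path(path).write_text(buf.getvalue())


def write_trajectory(
    trajectory: Trajectory,
    fractions: FractionTrajectory,
    path: str | Path,
    seed: int | None = None,
    params: PopulationParams | None = None,
) -> None:
    """Write a trajectory with abundances, fractions and derived observables."""
    labels = trajectory.labels
    data = {"time_days": trajectory.times}
    for lab in ("C2", "C4", "SC", "C6"):
        if lab in labels:
            j = labels.index(lab)
            data[lab] = trajectory.states[:, j]
            data[f"f_{lab}"] = fractions.fractions[:, j]
        else:
            data[lab] = np.zeros(len(trajectory.times))
            data[f"f_{lab}"] = np.zeros(len(trajectory.times))
    frac_cols = np.column_stack([data[f"f_{lab}"] for lab in ("C2", "C4", "SC", "C6")])
    if np.any(np.abs(frac_cols.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("fraction columns do not sum to 1 within 1e-9")
    extra = frac_cols[:, 1:].sum(axis=1)
    data["extra_fraction"] = extra
    with np.errstate(invalid="ignore", divide="ignore"):
        data["sc_share_of_extra"] = np.where(extra > 0, frac_cols[:, 2] / extra, np.nan)
    _write_with_header(pd.DataFrame(data), path, seed=seed, params=params)
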