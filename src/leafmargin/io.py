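"""Plain-text I/O: template configs, cell/state tables, silhouettes.

All formats are text: YAML for configuration, delimited CSV for tables,
two-column vertex lists or a line-segment subset of SVG paths for
silhouettes.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import ModelParams, SimulationState
from .morphometry import LeafSilhouette
from .tissue import MarginTissue, ScenarioTemplate, make_template

__all__ = [
    "template_to_dict",
    "template_from_dict",
    "save_template",
    "load_template",
    "save_params",
    "load_params",
    "write_cell_table",
    "read_cell_table",
    "write_state_table",
    "write_silhouette",
    "read_silhouette",
]


# -- scenario templates ------------------------------------------------------

def template_to_dict(template: ScenarioTemplate, settings: dict | None = None) -> dict:
    """Nested config dict with the documented keys.

    ``settings`` supplies the geometry/pattern values used to build the
    template (make_template keyword names); when omitted they are recovered
    from the tissue fields.
    """
    t = template.tissue
    if settings is None:
        settings = template.settings or _recover_settings(t)
    return {
        "grid": {"rows": t.n_rows, "cols": t.n_cols},
        "md": {"width": settings["md_width"]},
        "prox": {
            "start_row": settings["prox_start_row"],
            "ramp_rows": settings["prox_ramp_rows"],
            "end_row": settings.get("prox_end_row"),
            "fall_rows": settings.get("prox_fall_rows", 0),
        },
        "cuc": {"max": settings["cuc_max"]},
        "scenario": {
            "name": template.name,
            "clone_cells": [list(rc) for rc in template.clone_cells],
            "clone_cuc_max": settings.get("clone_cuc_max"),
            "baseline_auxin": template.initial_auxin
            if np.isscalar(template.initial_auxin)
            else list(np.asarray(template.initial_auxin, dtype=float)),
            "initial_pin_allocation": template.initial_pin_allocation,
        },
    }


def _recover_settings(t: MarginTissue) -> dict:
    mid = t.mid_col
    off = t.md[t.cell_index(1, mid + 1)] if t.n_cols > 1 else 0.0
    md_width = 1.0 / (1.0 - off) if off < 1 else 1.0
    prox_rows = np.nonzero(t.prox[t.column_cells(mid)] > 0)[0]
    start = int(prox_rows[0] + 1) if prox_rows.size else t.n_rows
    full = np.nonzero(t.prox[t.column_cells(mid)] >= 1)[0]
    ramp = int(full[0] + 1 - start) if full.size else t.n_rows - start
    cuc_max = float(t.cuc.max() / max(t.md.max() * t.prox.max(), 1e-300)) if t.cuc.max() > 0 else 0.0
    return {
        "md_width": md_width,
        "prox_start_row": start,
        "prox_ramp_rows": max(ramp, 0),
        "cuc_max": cuc_max,
    }


def template_from_dict(cfg: dict) -> ScenarioTemplate:
    sc = cfg["scenario"]
    baseline = sc.get("baseline_auxin", 0.1)
    end_row = cfg["prox"].get("end_row")
    tpl = make_template(
        sc["name"],
        n_rows=int(cfg["grid"]["rows"]),
        n_cols=int(cfg["grid"]["cols"]),
        md_width=float(cfg["md"]["width"]),
        prox_start_row=int(cfg["prox"]["start_row"]),
        prox_ramp_rows=int(cfg["prox"]["ramp_rows"]),
        prox_end_row=None if end_row is None else int(end_row),
        prox_fall_rows=int(cfg["prox"].get("fall_rows", 0)),
        cuc_max=float(cfg["cuc"]["max"]),
        clone_cells=[tuple(rc) for rc in sc.get("clone_cells", [])],
        clone_cuc_max=sc.get("clone_cuc_max"),
        baseline_auxin=baseline if np.isscalar(baseline) else 0.1,
        initial_pin_allocation=sc.get("initial_pin_allocation", "uniform"),
    )
    if not np.isscalar(baseline):
        tpl.initial_auxin = np.asarray(baseline, dtype=float)  # type: ignore[assignment]
    return tpl


def save_template(template: ScenarioTemplate, path, settings: dict | None = None) -> None:
    Path(path).write_text(yaml.safe_dump(template_to_dict(template, settings), sort_keys=False))


def load_template(path) -> ScenarioTemplate:
    return template_from_dict(yaml.safe_load(Path(path).read_text()))


# -- model parameters --------------------------------------------------------

def save_params(params: ModelParams, path) -> None:
    import dataclasses

    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(params), sort_keys=False))


def load_params(path, **overrides) -> ModelParams:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    cfg.update(overrides)
    return ModelParams(**cfg)


# -- tables ------------------------------------------------------------------

def write_cell_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_state_table(state: SimulationState, tissue: MarginTissue, path) -> pd.DataFrame:
    """State export: row, col, auxin, phospho_fraction, pin_{up,down,left,right}."""
    n = tissue.n_cells
    alloc = {k: np.zeros(n) for k in ("pin_up", "pin_down", "pin_left", "pin_right")}
    names = np.where(
        tissue.edge_uy > 0, "pin_up",
        np.where(tissue.edge_uy < 0, "pin_down",
                 np.where(tissue.edge_ux < 0, "pin_left", "pin_right")),
    )
    for key, arr in alloc.items():
        sel = names == key
        np.add.at(arr, tissue.edge_src[sel], state.pin[sel])
    df = pd.DataFrame(
        {
            "row": tissue.rows,
            "col": tissue.cols,
            "auxin": state.auxin,
            "phospho_fraction": state.phospho_fraction,
            **alloc,
        }
    )
    df.to_csv(path, index=False)
    return df


# -- silhouettes -------------------------------------------------------------

_SVG_NUM = r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?"


def _parse_svg_path(d: str) -> np.ndarray:
    """Parse a line-segment-only SVG path (M/L/H/V/Z, absolute or relative)."""
    tokens = re.findall(rf"([A-Za-z])|({_SVG_NUM})", d)
    pts: list[tuple[float, float]] = []
    cmd = None
    cur = np.zeros(2)
    nums: list[float] = []
    closed = False

    def flush() -> None:
        nonlocal cur, nums
        if cmd is None or not nums:
            return
        if cmd in "MmLl":
            for i in range(0, len(nums) - 1, 2):
                p = np.array(nums[i : i + 2])
                cur = cur + p if cmd.islower() else p
                pts.append(tuple(cur))
        elif cmd in "Hh":
            for v in nums:
                cur = np.array([cur[0] + v if cmd == "h" else v, cur[1]])
                pts.append(tuple(cur))
        elif cmd in "Vv":
            for v in nums:
                cur = np.array([cur[0], cur[1] + v if cmd == "v" else v])
                pts.append(tuple(cur))
        nums = []

    for letter, num in tokens:
        if letter:
            if letter in "Zz":
                flush()
                closed = True
                break
            if letter in "CcSsQqTtAa":
                raise ValueError(
                    f"SVG command {letter!r} (curve/arc) unsupported: "
                    "flatten the path to line segments first"
                )
            flush()
            cmd = letter
        else:
            nums.append(float(num))
    flush()
    if not closed:
        raise ValueError("SVG path has no closing Z: only closed subpaths are supported")
    return np.asarray(pts)


def read_silhouette(path, validate: bool = True) -> LeafSilhouette:
    """Read a silhouette from two-column delimited text or an SVG path file."""
    path = Path(path)
    if path.suffix.lower() == ".svg":
        text = path.read_text()
        m = re.search(r'\bd\s*=\s*"([^"]+)"', text)
        if not m:
            raise ValueError(f"no path 'd' attribute found in {path}")
        verts = _parse_svg_path(m.group(1))
    else:
        verts = np.loadtxt(path, delimiter=",", comments="#")
    return LeafSilhouette(verts, name=path.stem, validate=validate)


def write_silhouette(sil: LeafSilhouette, path) -> None:
    np.savetxt(path, sil.vertices, delimiter=",", header="x_mm,y_mm")
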