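"""Minimal SVG diagnostics: auxin heatmap with net-polarity arrows."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .patterns import PolarityField
from .dynamics import SimulationState
from .tissue import MarginTissue

__all__ = ["render_state_svg"]

_CELL = 24  # px per cell


def _color(v: float) -> str:
    """White -> red ramp."""
    g = int(255 * (1 - np.clip(v, 0, 1)))
    return f"rgb(255,{g},{g})"


def render_state_svg(
    state: SimulationState,
    tissue: MarginTissue,
    field: PolarityField,
    path,
) -> None:
    amax = state.auxin.max() or 1.0
    w, h = tissue.n_cols * _CELL, tissue.n_rows * _CELL
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w}" height="{h}" '
        f'viewBox="0 0 {w} {h}">'
    ]
    rows, cols = tissue.rows, tissue.cols
    for i in range(tissue.n_cells):
        x, y = (cols[i] - 1) * _CELL, (rows[i] - 1) * _CELL
        parts.append(
            f'<rect x="{x}" y="{y}" width="{_CELL}" height="{_CELL}" '
            f'fill="{_color(state.auxin[i] / amax)}" stroke="#999" stroke-width="0.5"/>'
        )
        if tissue.cuc[i] > 0:
            parts.append(
                f'<rect x="{x + 1}" y="{y + 1}" width="{_CELL - 2}" height="{_CELL - 2}" '
                f'fill="none" stroke="magenta" stroke-width="1" '
                f'stroke-opacity="{min(1.0, tissue.cuc[i] / max(tissue.cuc.max(), 1e-12)):.2f}"/>'
            )
        if field.magnitude[i] >= field.theta_np * field.p_tot:
            cx, cy = x + _CELL / 2, y + _CELL / 2
            # svg y grows downward; field +y is distal (upward on screen)
            dx = field.vx[i] / field.p_tot * _CELL * 0.45
            dy = -field.vy[i] / field.p_tot * _CELL * 0.45
            parts.append(
                f'<line x1="{cx - dx:.1f}" y1="{cy - dy:.1f}" x2="{cx + dx:.1f}" '
                f'y2="{cy + dy:.1f}" stroke="black" stroke-width="1.5"/>'
            )
            parts.append(f'<circle cx="{cx + dx:.1f}" cy="{cy + dy:.1f}" r="2" fill="black"/>')
    for i in np.nonzero(tissue.source_mask)[0]:
        x, y = (cols[i] - 1) * _CELL, (rows[i] - 1) * _CELL
        parts.append(
            f'<circle cx="{x + _CELL / 2}" cy="{y + _CELL / 2}" r="3" '
            f'fill="white" stroke="black"/>'
        )
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts))
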