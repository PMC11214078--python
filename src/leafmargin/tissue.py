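"""Leaf-margin tissue templates.

The modeled tissue is a flat rectangular strip of cells standing in for the
leaf margin during patterning of the first lateral auxin site: rows run from
the distal tip (row 1) to the proximal base (row ``n_rows``), and the middle
column represents the margin proper along which auxin profiles are read.
Two static identity fields — the middle domain (MD, lateral ramp centred on
the middle column) and the proximal domain (PROX, ramp rising proximally) —
intersect to define the CUC expression domain::

    cuc(i) = cuc_max * md(i) * prox(i)

The tissue is static: no growth, no division, no curvature.  The boundary is
closed (missing neighbors are simply absent), so passive diffusion and polar
transport conserve mass.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarginTissue",
    "ScenarioTemplate",
    "build_grid",
    "assign_identity_fields",
    "set_cuc_pattern",
    "make_template",
]

#: order in which a cell's directed edges are enumerated
_NEIGHBOR_OFFSETS = (
    ("up", -1, 0),     # distal
    ("down", 1, 0),    # proximal
    ("left", 0, -1),
    ("right", 0, 1),
)


@dataclasses.dataclass
class MarginTissue:
    """Static cell-grid geometry, adjacency and identity fields.

    Cells are indexed ``(row-1)*n_cols + (col-1)`` with 1-based ``row`` and
    ``col``.  Directed edges carry unit direction vectors in a frame where
    +y points distally (toward row 1) and +x toward higher column indices;
    every edge has an antiparallel reverse edge (``edge_rev``).
    """

    n_rows: int
    n_cols: int
    edge_src: np.ndarray
    edge_dst: np.ndarray
    edge_ux: np.ndarray
    edge_uy: np.ndarray
    edge_rev: np.ndarray
    md: np.ndarray
    prox: np.ndarray
    cuc: np.ndarray
    source_mask: np.ndarray
    fields_assigned: bool = False

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_edges(self) -> int:
        return int(self.edge_src.size)

    @property
    def mid_col(self) -> int:
        """1-based index of the middle column (n_cols is odd)."""
        return (self.n_cols + 1) // 2

    def cell_index(self, row: int, col: int) -> int:
        if not (1 <= row <= self.n_rows and 1 <= col <= self.n_cols):
            raise IndexError(f"cell ({row}, {col}) outside {self.n_rows}x{self.n_cols} grid")
        return (row - 1) * self.n_cols + (col - 1)

    @property
    def rows(self) -> np.ndarray:
        """Per-cell 1-based row index."""
        return np.repeat(np.arange(1, self.n_rows + 1), self.n_cols)

    @property
    def cols(self) -> np.ndarray:
        """Per-cell 1-based column index."""
        return np.tile(np.arange(1, self.n_cols + 1), self.n_rows)

    @property
    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n_cells, dtype=int)
        np.add.at(deg, self.edge_src, 1)
        return deg

    def column_cells(self, col: int) -> np.ndarray:
        """Cell indices of one column ordered distal -> proximal."""
        if not 1 <= col <= self.n_cols:
            raise IndexError(f"column {col} out of range 1..{self.n_cols}")
        return np.arange(self.n_rows) * self.n_cols + (col - 1)

    def neighbors(self, cell: int) -> np.ndarray:
        return self.edge_dst[self.edge_src == cell]

    def copy(self) -> "MarginTissue":
        return dataclasses.replace(
            self,
            md=self.md.copy(),
            prox=self.prox.copy(),
            cuc=self.cuc.copy(),
            source_mask=self.source_mask.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per cell: ``row,col,md,prox,cuc,is_source`` (1-based indices)."""
        return pd.DataFrame(
            {
                "row": self.rows,
                "col": self.cols,
                "md": self.md,
                "prox": self.prox,
                "cuc": self.cuc,
                "is_source": self.source_mask.astype(int),
            }
        )


def build_grid(n_rows: int, n_cols: int) -> MarginTissue:
    """Construct the bare cell grid with 4-neighborhood adjacency.

    Identity and CUC fields start at zero and no cell is an auxin source.
    """
    if n_rows < 3:
        raise ValueError(f"n_rows must be >= 3 (got {n_rows})")
    if n_cols < 1:
        raise ValueError(f"n_cols must be >= 1 (got {n_cols})")
    if n_cols % 2 == 0:
        raise ValueError(f"n_cols must be odd (got {n_cols})")

    src, dst, ux, uy = [], [], [], []
    for r in range(1, n_rows + 1):
        for c in range(1, n_cols + 1):
            i = (r - 1) * n_cols + (c - 1)
            for _, dr, dc in _NEIGHBOR_OFFSETS:
                rr, cc = r + dr, c + dc
                if 1 <= rr <= n_rows and 1 <= cc <= n_cols:
                    src.append(i)
                    dst.append((rr - 1) * n_cols + (cc - 1))
                    ux.append(float(dc))
                    uy.append(float(-dr))  # +y is distal = decreasing row

    src = np.asarray(src, dtype=np.intp)
    dst = np.asarray(dst, dtype=np.intp)
    lookup = {(int(s), int(d)): e for e, (s, d) in enumerate(zip(src, dst))}
    rev = np.asarray([lookup[(int(d), int(s))] for s, d in zip(src, dst)], dtype=np.intp)

    n = n_rows * n_cols
    return MarginTissue(
        n_rows=n_rows,
        n_cols=n_cols,
        edge_src=src,
        edge_dst=dst,
        edge_ux=np.asarray(ux),
        edge_uy=np.asarray(uy),
        edge_rev=rev,
        md=np.zeros(n),
        prox=np.zeros(n),
        cuc=np.zeros(n),
        source_mask=np.zeros(n, dtype=bool),
    )


def assign_identity_fields(
    tissue: MarginTissue,
    md_width: float,
    prox_start_row: int,
    prox_ramp_rows: int,
    prox_end_row: int | None = None,
    prox_fall_rows: int = 0,
) -> MarginTissue:
    """Set the MD and PROX identity ramps (in place; the tissue is returned).

    ``md = max(0, 1 - lateral_distance/md_width)`` peaks at 1 on the middle
    column.  ``prox`` is 0 distal to ``prox_start_row`` and rises linearly to
    1 over ``prox_ramp_rows`` rows.  With ``prox_end_row=None`` it then stays
    1 to the proximal edge; otherwise it falls linearly back to 0 over
    ``prox_fall_rows`` rows after ``prox_end_row``, bounding the CUC domain
    proximally so that CUC-free cells lie below it (the configuration the
    emergent auxin maximum is read against).
    """
    if md_width < 1:
        raise ValueError(f"md_width must be >= 1 (got {md_width})")
    if not 1 <= prox_start_row <= tissue.n_rows:
        raise ValueError(
            f"prox_start_row must be in 1..{tissue.n_rows} (got {prox_start_row})"
        )
    if prox_ramp_rows < 0:
        raise ValueError(f"prox_ramp_rows must be >= 0 (got {prox_ramp_rows})")
    if prox_start_row + prox_ramp_rows > tissue.n_rows:
        warnings.warn(
            "PROX ramp extends past the proximal grid edge; clipped at "
            f"row {tissue.n_rows}",
            stacklevel=2,
        )

    lateral = np.abs(tissue.cols - tissue.mid_col)
    tissue.md = np.maximum(0.0, 1.0 - lateral / md_width)
    rows = tissue.rows
    if prox_ramp_rows == 0:
        ramp = (rows >= prox_start_row).astype(float)
    else:
        ramp = np.clip((rows - prox_start_row) / prox_ramp_rows, 0.0, 1.0)
    if prox_end_row is not None:
        if prox_end_row < prox_start_row + prox_ramp_rows:
            raise ValueError(
                f"prox_end_row ({prox_end_row}) precedes the end of the ramp "
                f"({prox_start_row + prox_ramp_rows})"
            )
        if prox_fall_rows <= 0:
            raise ValueError("a bounded PROX band requires prox_fall_rows >= 1")
        fall = np.clip((rows - prox_end_row) / prox_fall_rows, 0.0, 1.0)
        ramp = ramp * (1.0 - fall)
    tissue.prox = ramp
    tissue.fields_assigned = True
    return tissue


def set_cuc_pattern(tissue: MarginTissue, cuc_max: float) -> MarginTissue:
    """Set ``cuc = cuc_max * md * prox``; ``cuc_max = 0`` gives the cuc-mutant field."""
    if not tissue.fields_assigned:
        raise ValueError("identity fields must be assigned before the CUC pattern")
    if cuc_max < 0:
        raise ValueError(f"cuc_max must be >= 0 (got {cuc_max})")
    tissue.cuc = cuc_max * tissue.md * tissue.prox
    return tissue


_SCENARIOS = ("wt", "cuc_mutant", "clone")


@dataclasses.dataclass
class ScenarioTemplate:
    """A named simulation scenario: tissue plus initial conditions.

    ``clone_cells`` lists (row, col) cells whose CUC is forced to
    ``clone_cuc_max`` regardless of the MD/PROX pattern (genetic-mosaic
    analog).  ``initial_pin_allocation`` is ``uniform`` (PIN split equally
    over a cell's membranes) or ``apical`` (all PIN on the distal membrane).
    """

    name: str
    tissue: MarginTissue
    clone_cells: tuple[tuple[int, int], ...] = ()
    initial_auxin: float = 0.1
    initial_pin_allocation: str = "uniform"
    settings: dict = dataclasses.field(default_factory=dict)  # build-time geometry keys

    def __post_init__(self) -> None:
        if self.name not in _SCENARIOS:
            raise ValueError(f"scenario name must be one of {_SCENARIOS} (got {self.name!r})")
        if self.initial_pin_allocation not in ("uniform", "apical"):
            raise ValueError(
                f"initial_pin_allocation must be 'uniform' or 'apical' "
                f"(got {self.initial_pin_allocation!r})"
            )
        bad = [
            (r, c)
            for r, c in self.clone_cells
            if not (1 <= r <= self.tissue.n_rows and 1 <= c <= self.tissue.n_cols)
        ]
        if bad:
            raise ValueError(f"clone cells outside the grid: {bad}")
        if self.name == "cuc_mutant":
            if self.clone_cells:
                raise ValueError("cuc_mutant template cannot carry clone cells")
            if np.any(self.tissue.cuc != 0):
                raise ValueError("cuc_mutant template requires cuc_field == 0 everywhere")

    def copy(self) -> "ScenarioTemplate":
        return dataclasses.replace(self, tissue=self.tissue.copy())


def make_template(
    name: str,
    *,
    n_rows: int = 14,
    n_cols: int = 5,
    md_width: float = 2.0,
    prox_start_row: int | None = None,
    prox_ramp_rows: int | None = None,
    prox_end_row: int | None | str = "auto",
    prox_fall_rows: int | None = None,
    cuc_max: float = 1.0,
    clone_cells: Sequence[tuple[int, int]] = (),
    clone_cuc_max: float | None = None,
    baseline_auxin: float = 0.0,
    initial_pin_allocation: str = "apical",
) -> ScenarioTemplate:
    """Build a named scenario template.

    All scenarios place a single auxin source in the central cell of the
    second row (the distal auxin maximum of the young primordium).  ``wt``
    and ``clone`` carry the patterned CUC field (``clone`` additionally
    forces CUC to ``clone_cuc_max`` on the listed cells; pass ``cuc_max=0``
    to study a clone on a CUC-free background); ``cuc_mutant`` has no CUC
    anywhere.
    """
    if name not in _SCENARIOS:
        raise ValueError(f"scenario name must be one of {_SCENARIOS} (got {name!r})")
    if name == "clone" and not clone_cells:
        raise ValueError("clone scenario requires a non-empty clone_cells list")

    # band geometry defaults scale with strip length (14 rows -> CUC on rows 7-11)
    if prox_start_row is None:
        prox_start_row = min(max(2, round(0.43 * n_rows)), n_rows)
    if prox_ramp_rows is None:
        prox_ramp_rows = max(1, round(0.2 * n_rows))
    if prox_end_row == "auto":
        prox_end_row = min(
            n_rows, prox_start_row + prox_ramp_rows + max(1, round(0.07 * n_rows))
        )
    if prox_fall_rows is None:
        prox_fall_rows = max(1, round(0.15 * n_rows))

    tissue = build_grid(n_rows, n_cols)
    assign_identity_fields(
        tissue, md_width, prox_start_row, prox_ramp_rows, prox_end_row, prox_fall_rows
    )
    set_cuc_pattern(tissue, 0.0 if name == "cuc_mutant" else cuc_max)

    clone_cells = tuple((int(r), int(c)) for r, c in clone_cells)
    if name == "clone":
        bad = [(r, c) for r, c in clone_cells
               if not (1 <= r <= n_rows and 1 <= c <= n_cols)]
        if bad:
            raise ValueError(f"clone cells outside the grid: {bad}")
        forced = cuc_max if clone_cuc_max is None else clone_cuc_max
        for r, c in clone_cells:
            tissue.cuc[tissue.cell_index(r, c)] = forced

    tissue.source_mask[tissue.cell_index(2, tissue.mid_col)] = True

    return ScenarioTemplate(
        name=name,
        tissue=tissue,
        clone_cells=clone_cells if name == "clone" else (),
        initial_auxin=baseline_auxin,
        initial_pin_allocation=initial_pin_allocation,
        settings={
            "md_width": md_width,
            "prox_start_row": prox_start_row,
            "prox_ramp_rows": prox_ramp_rows,
            "prox_end_row": prox_end_row,
            "prox_fall_rows": prox_fall_rows,
            "cuc_max": 0.0 if name == "cuc_mutant" else cuc_max,
            "clone_cuc_max": clone_cuc_max,
        },
    )
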