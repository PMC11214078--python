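"""Synthetic microscopy-like cell tables and leaf silhouettes.

These generators stand in for segmented-image exports so every
quantification stage is testable with planted ground truth:

* :func:`gen_cell_table` emulates a margin cell file read along an arc from
  a protrusion tip: apical cells distal of a planted reversal distance d*,
  an explicit reversal front of five basal cells at d* + N(0, sigma_d)
  (a reversal zone read with positional noise — these are the "five cells
  closest to the tip with clear basal polarity"), deeper basal cells
  proximal of the front, membrane-segment signals consistent with each
  class, and two reporter channels with a planted linear relation and a
  planted point-biserial correlation between the first reporter and basal
  polarity.
* :func:`gen_silhouette` emulates a leaf outline: an ellipse carrying k
  sinusoidal lobes of relative depth d (d = 0 is the convex ellipse).

Everything is deterministic given the spec's seed; ground truth is returned
separately, never embedded in the table.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .morphometry import LeafSilhouette
from .quantify import CELL_TABLE_COLUMNS

__all__ = [
    "SynthCellTableSpec",
    "SynthSilhouetteSpec",
    "gen_cell_table",
    "gen_silhouette",
]


@dataclasses.dataclass
class SynthCellTableSpec:
    """Parameters of a synthetic margin cell table (lengths in micrometres)."""

    n_cells: int = 120
    arc_length_um: float = 300.0
    reversal_um: float = 90.0          # planted reversal distance d*
    position_noise_um: float = 4.0     # SD of the reversal-front positions
    mislabel_prob: float = 0.0         # probability a cell's class is flipped
    expr_intercept: float = 0.2        # reporter model y = a + b*x + N(0, sigma)
    expr_slope: float = 2.0
    expr_sigma: float = 0.5
    x_logmean: float = 0.0             # log-normal baseline of reporter x
    x_logsd: float = 0.4
    rho_pb: float = 0.8                # planted point-biserial corr(x, basal)
    dominant_factor: float = 4.0       # dominant membrane signal vs the rest
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 20:
            raise ValueError(f"n_cells must be >= 20 (got {self.n_cells})")
        if not 0 < self.reversal_um < self.arc_length_um:
            raise ValueError("reversal_um must lie inside (0, arc_length_um)")
        if not 0 <= self.mislabel_prob <= 1:
            raise ValueError("mislabel_prob must be in [0, 1]")
        if self.expr_sigma < 0 or self.position_noise_um < 0:
            raise ValueError("noise SDs must be >= 0")
        if not -1 < self.rho_pb < 1:
            raise ValueError(
                f"planted point-biserial correlation must satisfy |rho| < 1 "
                f"(got {self.rho_pb})"
            )


def _segments(cls: str, base: np.ndarray, factor: float) -> dict:
    segs = dict(zip(["seg_distal", "seg_proximal", "seg_lat1", "seg_lat2"], base))
    if cls == "apical":
        segs["seg_distal"] *= factor
    else:
        segs["seg_proximal"] *= factor
    return segs


def gen_cell_table(spec: SynthCellTableSpec):
    """Generate a cell table plus its ground-truth record.

    Returns ``(table, truth)``: the table follows the documented cell-table
    header; ``truth`` holds the planted reversal distance, the exact
    expected value of the five-cell reversal estimator on this table, the
    planted regression coefficients and the planted correlation.
    """
    rng = np.random.default_rng(spec.seed)
    d_star = spec.reversal_um
    n_front = 5
    n_apical = max(5, int(round(spec.n_cells * d_star / spec.arc_length_um)))
    n_apical = min(n_apical, spec.n_cells - n_front - 5)
    n_deep = spec.n_cells - n_apical - n_front

    # apical cells distal of d*; kept clear of the front by one noise SD
    apical_hi = max(d_star - 3 * spec.position_noise_um, 0.5 * d_star)
    d_apical = np.sort(rng.uniform(0.0, apical_hi, n_apical))
    # the reversal front: five basal cells straddling d*
    d_front = d_star + spec.position_noise_um * rng.standard_normal(n_front)
    d_front = np.abs(d_front)
    # deeper basal cells strictly proximal of the front
    deep_lo = max(d_front.max(), d_star) + max(spec.position_noise_um, 1.0)
    deep_hi = max(spec.arc_length_um, deep_lo + 1.0)
    d_deep = np.sort(rng.uniform(deep_lo, deep_hi, n_deep))

    dist = np.concatenate([d_apical, d_front, d_deep])
    cls = np.array(["apical"] * n_apical + ["basal"] * (n_front + n_deep), dtype=object)
    order = np.argsort(dist, kind="mergesort")
    dist, cls = dist[order], cls[order]

    if spec.mislabel_prob > 0:
        flip = rng.uniform(size=spec.n_cells) < spec.mislabel_prob
        cls[flip] = np.where(cls[flip] == "apical", "basal", "apical")

    basal = (cls == "basal").astype(float)
    p = basal.mean()
    if p in (0.0, 1.0):
        raise ValueError("degenerate table: a single polarity class was generated")

    # reporter x: log-normal baseline plus a class shift delta chosen so the
    # population point-biserial correlation equals rho_pb
    sigma_x0 = np.sqrt((np.exp(spec.x_logsd**2) - 1.0) * np.exp(2 * spec.x_logmean + spec.x_logsd**2))
    q = 1.0 - p
    delta = spec.rho_pb * sigma_x0 / np.sqrt(p * q * (1.0 - spec.rho_pb**2))
    x = rng.lognormal(spec.x_logmean, spec.x_logsd, spec.n_cells) + delta * basal
    y = spec.expr_intercept + spec.expr_slope * x + spec.expr_sigma * rng.standard_normal(spec.n_cells)

    base_signals = rng.lognormal(0.0, 0.08, (spec.n_cells, 4))
    seg_rows = [
        _segments(c, base_signals[i], spec.dominant_factor) for i, c in enumerate(cls)
    ]

    # gentle planar arc for the centroids
    s = dist / max(spec.arc_length_um, dist.max())
    table = pd.DataFrame(
        {
            "cell_id": [f"c{i:04d}" for i in range(spec.n_cells)],
            "x_um": dist,
            "y_um": 0.05 * spec.arc_length_um * np.sin(np.pi * s),
            "dist_tip_um": dist,
            "ch_cuc": x,
            "ch_wag": y,
            "ch_pin": rng.lognormal(0.0, 0.1, spec.n_cells),
            "seg_distal": [r["seg_distal"] for r in seg_rows],
            "seg_proximal": [r["seg_proximal"] for r in seg_rows],
            "seg_lat1": [r["seg_lat1"] for r in seg_rows],
            "seg_lat2": [r["seg_lat2"] for r in seg_rows],
            "group": "synthetic",
        }
    )[CELL_TABLE_COLUMNS]

    basal_d = np.sort(dist[cls == "basal"])
    truth = {
        "reversal_um": d_star,
        "expected_reversal_estimate_um": float(basal_d[:5].mean()),
        "position_noise_um": spec.position_noise_um,
        "classes": cls.astype(str).tolist(),
        "expr_intercept": spec.expr_intercept,
        "expr_slope": spec.expr_slope,
        "expr_sigma": spec.expr_sigma,
        "rho_pb": spec.rho_pb,
        "basal_fraction": float(p),
        "seed": spec.seed,
    }
    return table, truth


@dataclasses.dataclass
class SynthSilhouetteSpec:
    """Parameters of a synthetic lobed leaf silhouette (millimetres)."""

    semi_axis_a: float = 40.0
    semi_axis_b: float = 25.0
    lobe_count: int = 7
    lobe_depth: float = 0.3        # fraction of local radius removed in sinuses
    vertices_per_lobe: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.semi_axis_a <= 0 or self.semi_axis_b <= 0:
            raise ValueError("semi-axes must be > 0")
        if self.lobe_count < 1:
            raise ValueError("lobe_count must be >= 1")
        if not 0 <= self.lobe_depth < 1:
            raise ValueError(
                f"lobe_depth must be in [0, 1): depth 1 collapses the sinus "
                f"radius to zero and self-intersects (got {self.lobe_depth})"
            )
        if self.vertices_per_lobe < 8:
            raise ValueError("vertices_per_lobe must be >= 8")


def gen_silhouette(spec: SynthSilhouetteSpec) -> LeafSilhouette:
    """Ellipse with k sinusoidal lobes of relative depth d (d=0: convex ellipse).

    The radial modulation 1 - d*(1 - cos(k*theta))/2 keeps the polygon
    star-shaped, hence simple, for every d < 1.
    """
    n = spec.lobe_count * spec.vertices_per_lobe
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    mod = 1.0 - spec.lobe_depth * (1.0 - np.cos(spec.lobe_count * theta)) / 2.0
    x = spec.semi_axis_a * np.cos(theta) * mod
    y = spec.semi_axis_b * np.sin(theta) * mod
    return LeafSilhouette(np.column_stack([x, y]), name=f"synthetic-k{spec.lobe_count}-d{spec.lobe_depth}")
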