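"""Cell-resolution quantification of polarity and reporter expression.

Operates on generic cell tables (one record per cell, MorphographX-style
export): per-membrane-segment PIN signal in four orientation classes
(distal, proximal, lateral_1, lateral_2), reporter channel intensities,
and an along-margin arc distance to a landmark (e.g. a protrusion tip).

Provided analyses:

* membrane-dominance polarity calls (apical / basal, optional "-lateral",
  bipolar, nonpolar);
* reversal-position estimation: mean distance of the five cells closest to
  the landmark with clear basal polarity;
* polarity frequency tables across groups with a Pearson chi-squared test;
* point-biserial correlation between a reporter and the binary polarity;
* per-sample ordinary least-squares regression between two reporters;
* 4x4-cell region-of-interest selection on gridded tables.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CELL_TABLE_COLUMNS",
    "SEGMENT_COLUMNS",
    "PolarityCall",
    "classify_cell_polarity",
    "classify_table",
    "reversal_position",
    "polarity_frequencies",
    "point_biserial",
    "PointBiserialResult",
    "point_biserial_ci",
    "expression_regression",
    "RegressionResult",
    "select_roi_grid",
]

#: documented delimited-text header for cell tables
CELL_TABLE_COLUMNS = [
    "cell_id", "x_um", "y_um", "dist_tip_um",
    "ch_cuc", "ch_wag", "ch_pin",
    "seg_distal", "seg_proximal", "seg_lat1", "seg_lat2",
    "group",
]

SEGMENT_COLUMNS = ["seg_distal", "seg_proximal", "seg_lat1", "seg_lat2"]

#: opposite membrane segment of each segment
_OPPOSITE = {
    "seg_distal": "seg_proximal",
    "seg_proximal": "seg_distal",
    "seg_lat1": "seg_lat2",
    "seg_lat2": "seg_lat1",
}

BASAL_CLASSES = ("basal", "basal-lateral")


@dataclasses.dataclass
class PolarityCall:
    """Polarity class of one cell; ``cls`` is None when the cell is excluded."""

    cell_id: str
    cls: Optional[str]
    confidence: float = np.nan   # dominant / subdominant segment signal
    reason: Optional[str] = None


def classify_cell_polarity(
    record,
    dominance_ratio: float = 1.5,
    bipolar_ratio: float = 1.5,
) -> PolarityCall:
    """Classify one cell from its four membrane-segment signals.

    The strongest segment must exceed ``dominance_ratio`` times the mean of
    the other three to call a direction; if the opposite segment is within
    ``bipolar_ratio`` of the strongest the cell is bipolar; a lateral
    segment within ``bipolar_ratio`` of the strongest appends "-lateral".
    Cells with a missing segment are excluded with a reason code.  Calls
    are invariant to rescaling all four signals by a common factor.
    """
    cell_id = str(record.get("cell_id", ""))
    segs = {}
    for name in SEGMENT_COLUMNS:
        v = record.get(name, None)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return PolarityCall(cell_id, None, reason=f"missing_segment:{name}")
        segs[name] = float(v)
    if any(v < 0 for v in segs.values()):
        return PolarityCall(cell_id, None, reason="negative_segment_signal")

    ordered = sorted(segs, key=segs.get, reverse=True)
    top = ordered[0]
    s_max = segs[top]
    s_second = segs[ordered[1]]
    confidence = s_max / s_second if s_second > 0 else np.inf
    others_mean = (sum(segs.values()) - s_max) / 3.0

    if s_max < dominance_ratio * others_mean or s_max <= 0:
        return PolarityCall(cell_id, "nonpolar", confidence)
    if segs[_OPPOSITE[top]] >= s_max / bipolar_ratio:
        return PolarityCall(cell_id, "bipolar", confidence)

    if top == "seg_distal":
        base = "apical"
    elif top == "seg_proximal":
        base = "basal"
    else:
        # dominant lateral membrane: axis taken from the stronger of the
        # proximodistal segments; the lateral qualifier is then automatic
        base = "apical" if segs["seg_distal"] >= segs["seg_proximal"] else "basal"
    lateral_max = max(segs["seg_lat1"], segs["seg_lat2"])
    if lateral_max >= s_max / bipolar_ratio:
        base += "-lateral"
    return PolarityCall(cell_id, base, confidence)


def classify_table(
    table: pd.DataFrame,
    dominance_ratio: float = 1.5,
    bipolar_ratio: float = 1.5,
) -> pd.DataFrame:
    """Polarity calls for every record: columns cell_id, cls, confidence, reason."""
    calls = [
        classify_cell_polarity(row, dominance_ratio, bipolar_ratio)
        for row in table.to_dict("records")
    ]
    return pd.DataFrame([dataclasses.asdict(c) for c in calls])


def reversal_position(
    table: pd.DataFrame,
    dominance_ratio: float = 1.5,
    bipolar_ratio: float = 1.5,
) -> float:
    """Distance from the landmark to the PIN polarity reversal (micrometers).

    Mean ``dist_tip_um`` of the five qualifying cells (class basal or
    basal-lateral, i.e. "clear basal polarity") closest to the landmark;
    ties at the fifth rank break by cell_id.
    """
    calls = classify_table(table, dominance_ratio, bipolar_ratio)
    merged = table[["cell_id", "dist_tip_um"]].copy()
    merged["cell_id"] = merged["cell_id"].astype(str)
    merged = merged.merge(calls[["cell_id", "cls"]], on="cell_id")
    basal = merged[merged["cls"].isin(BASAL_CLASSES)]
    if len(basal) < 5:
        raise ValueError(f"insufficient basal cells: found {len(basal)}, need 5")
    basal = basal.sort_values(["dist_tip_um", "cell_id"], kind="mergesort")
    return float(basal["dist_tip_um"].head(5).mean())


def polarity_frequencies(
    calls: pd.DataFrame,
    group_col: str = "group",
    class_col: str = "cls",
):
    """Polarity-class contingency table across groups, with chi-squared test.

    Pearson chi-squared without continuity correction; class columns with
    all-zero totals are dropped (with a warning).  Returns
    ``(counts, chi2, dof, p)``.
    """
    valid = calls.dropna(subset=[class_col])
    counts = pd.crosstab(valid[group_col], valid[class_col])
    zero_cols = [c for c in counts.columns if counts[c].sum() == 0]
    if zero_cols:
        warnings.warn(f"dropping all-zero polarity classes: {zero_cols}", stacklevel=2)
        counts = counts.drop(columns=zero_cols)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError(
            f"degenerate contingency table {counts.shape}: need >= 2 groups "
            f"and >= 2 classes with nonzero totals"
        )
    chi2, p, dof, _ = stats.chi2_contingency(counts.to_numpy(), correction=False)
    return counts, float(chi2), int(dof), float(p)


class PointBiserialResult(NamedTuple):
    r: float
    zero_variance: bool


def point_biserial(x: Sequence[float], y: Sequence[int]) -> PointBiserialResult:
    """Point-biserial correlation between a continuous x and binary y.

    r_pb = (M1 - M0)/s_n * sqrt(n1*n0/n^2) with s_n the population SD of x;
    numerically equal to the Pearson correlation of x with 0/1-coded y.
    Zero variance in x returns r = 0 with the zero-variance flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"need n >= 3 (got {x.size})")
    levels = np.unique(y)
    if levels.size != 2:
        raise ValueError(f"degenerate grouping: y has {levels.size} distinct value(s)")
    y01 = (y == levels[1]).astype(float)
    s_n = x.std()  # population SD
    if s_n == 0:
        return PointBiserialResult(0.0, True)
    n = x.size
    n1 = y01.sum()
    n0 = n - n1
    m1 = x[y01 == 1].mean()
    m0 = x[y01 == 0].mean()
    r = (m1 - m0) / s_n * np.sqrt(n1 * n0 / n**2)
    return PointBiserialResult(float(r), False)


def point_biserial_ci(
    x: Sequence[float],
    y: Sequence[int],
    confidence: float = 0.95,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """BCa bootstrap confidence interval for the point-biserial r.

    Bias-corrected and accelerated rather than normal-theory: reporter
    intensities are right-skewed and r is bounded, which makes the Fisher-z
    interval slightly too narrow here.
    """
    x = np.asarray(x, dtype=float)
    y01 = np.asarray(y)
    levels = np.unique(y01)
    if levels.size != 2:
        raise ValueError(f"degenerate grouping: y has {levels.size} distinct value(s)")
    y01 = (y01 == levels[1]).astype(float)
    rng = np.random.default_rng(seed)
    n = x.size
    r_hat = point_biserial(x, y01.astype(int)).r

    rs = np.empty(n_boot)
    filled = 0
    while filled < n_boot:
        idx = rng.integers(0, n, size=(n_boot, n))
        xb, yb = x[idx], y01[idx]
        keep = (yb.sum(axis=1) > 0) & (yb.sum(axis=1) < n) & (xb.std(axis=1) > 0)
        xb, yb = xb[keep], yb[keep]
        n1 = yb.sum(axis=1)
        n0 = n - n1
        m1 = (xb * yb).sum(axis=1) / n1
        m0 = (xb * (1 - yb)).sum(axis=1) / n0
        r = (m1 - m0) / xb.std(axis=1) * np.sqrt(n1 * n0) / n
        take = min(r.size, n_boot - filled)
        rs[filled:filled + take] = r[:take]
        filled += take

    # jackknife acceleration (leave-one-out r, all in O(n) via running sums)
    loo = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        xi, yi = x[mask], y01[mask]
        n1 = yi.sum()
        if n1 == 0 or n1 == n - 1 or xi.std() == 0:
            loo[i] = r_hat
            continue
        m1 = xi[yi == 1].mean()
        m0 = xi[yi == 0].mean()
        loo[i] = (m1 - m0) / xi.std() * np.sqrt(n1 * (n - 1 - n1)) / (n - 1)
    diff = loo.mean() - loo
    denom = (diff**2).sum() ** 1.5
    a = (diff**3).sum() / (6 * denom) if denom > 0 else 0.0

    from scipy.stats import norm

    frac = np.clip(np.mean(rs < r_hat), 1e-6, 1 - 1e-6)
    z0 = norm.ppf(frac)
    alpha = (1.0 - confidence) / 2.0
    lo_q = norm.cdf(z0 + (z0 + norm.ppf(alpha)) / (1 - a * (z0 + norm.ppf(alpha))))
    hi_q = norm.cdf(z0 + (z0 + norm.ppf(1 - alpha)) / (1 - a * (z0 + norm.ppf(1 - alpha))))
    return float(np.quantile(rs, lo_q)), float(np.quantile(rs, hi_q))


class RegressionResult(NamedTuple):
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def expression_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Per-sample OLS of reporter y on reporter x (slope, intercept, R^2, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"need n >= 3 (got {x.size})")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    fit = stats.linregress(x, y)
    return RegressionResult(
        float(fit.slope), float(fit.intercept), float(fit.rvalue**2), float(fit.pvalue)
    )


def select_roi_grid(
    table: pd.DataFrame,
    origin_cell_id: str,
    rows: int = 4,
    cols: int = 4,
):
    """4x4-cell region of interest extending proximally/inward from an origin.

    The table must carry integer grid coordinates in columns ``row`` and
    ``col`` (rows increase proximally).  Returns ``(subset, missing)``:
    cells of the block rows r..r+rows-1, cols c..c+cols-1 present in the
    table, and the (row, col) pairs of the block that are absent.
    """
    if "row" not in table.columns or "col" not in table.columns:
        raise ValueError("table must carry grid coordinates in 'row' and 'col' columns")
    ids = table["cell_id"].astype(str)
    hit = table[ids == str(origin_cell_id)]
    if hit.empty:
        raise ValueError(f"origin cell {origin_cell_id!r} absent from the table")
    r0, c0 = int(hit.iloc[0]["row"]), int(hit.iloc[0]["col"])
    wanted = {(r0 + dr, c0 + dc) for dr in range(rows) for dc in range(cols)}
    in_block = table.apply(lambda rec: (int(rec["row"]), int(rec["col"])) in wanted, axis=1)
    subset = table[in_block]
    have = {(int(r), int(c)) for r, c in zip(subset["row"], subset["col"])}
    missing = sorted(wanted - have)
    return subset, missing
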