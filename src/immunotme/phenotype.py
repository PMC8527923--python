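"""Single-cell layer: intensity normalization, identity assignment, gating.

The cell table is a pandas DataFrame with one row per segmented cell:
``cell_id``, centroid ``x_um``/``y_um``, ``area_um2``, ``compartment``
(tumor/stroma), one raw-intensity column per marker, and after processing
normalized intensities (``<marker>_norm``), a ``lineage`` label and boolean
subpopulation flag columns (e.g. ``CD8_GzB``).

Gating follows the published threshold-on-normalized-expression procedure:
a named subpopulation is the subset of a parent population whose normalized
marker intensity reaches a fixed gate (inclusive >=), e.g. CD74 >= 0.1 on
all macrophages defines CD68+CD74+ cells, GzB >= 0.05 and Ki67 >= 0.15 on
CD8 T cells define the cytotoxic and proliferating subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pixels import Mask
from .stats import ComparisonResult, attach_bh, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

__all__ = [
    "GateSpec",
    "LINEAGE_PRIORITY",
    "normalize_intensities",
    "assign_identity",
    "apply_gates",
    "population_proportions",
    "marker_positive_percentage",
    "mean_intensity_contrast",
]

# fixed tie-break order for identity assignment
LINEAGE_PRIORITY = ["T_cell", "macrophage", "B_cell", "dendritic", "neutrophil", "tumor"]

CLIP_PERCENTILE = 99.9
FOLD_CHANGE_FLOOR = 1e-6


@dataclass(frozen=True)
class GateSpec:
    """One threshold gate: flag ``name`` on ``parent`` where marker >= threshold.

    ``parent`` is either a lineage label (row's ``lineage`` equals it) or the
    name of a previously applied gate's flag column, so gates chain
    (CD8_T -> CD8_GzB -> CD8_GzB_PD1).
    """

    name: str
    parent: str
    marker: str
    threshold: float

    def __post_init__(self):
        if not 0 <= self.threshold <= 1:
            raise ValueError("gate threshold must lie in [0, 1]")


def normalize_intensities(
    cells: pd.DataFrame,
    markers: list[str],
    clip_percentile: float = CLIP_PERCENTILE,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Per-marker min-max normalization to [0, 1] with percentile clipping.

    Values are clipped at the ``clip_percentile`` (99.9th) percentile, then
    min-max scaled. Normalized values are written to ``<marker>_norm``
    columns. A constant marker normalizes to zeros with a logged warning.
    Returns the augmented table and the per-marker (min, clip) constants so
    the scaling is reproducible. Applying the normalization to an already
    normalized column is idempotent.
    """
    out = cells.copy()
    constants: dict[str, tuple[float, float]] = {}
    for marker in markers:
        if marker not in cells.columns:
            raise KeyError(f"marker column {marker!r} missing from cell table")
        vals = cells[marker].to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValueError(f"marker {marker!r} has negative raw intensities")
        # order-statistic percentile (an actual data value) keeps the
        # transform exactly idempotent
        hi = float(np.percentile(vals, clip_percentile, method="higher")) if len(vals) else 0.0
        lo = vals.min() if len(vals) else 0.0
        if hi <= lo:
            logger.warning("marker %r is constant; normalized to 0", marker)
            out[f"{marker}_norm"] = 0.0
            constants[marker] = (float(lo), float(lo))
            continue
        clipped = np.minimum(vals, hi)
        out[f"{marker}_norm"] = (clipped - lo) / (hi - lo)
        constants[marker] = (float(lo), float(hi))
    return out, constants


def assign_identity(
    label_raster: np.ndarray,
    lineage_masks: dict[str, Mask],
    priority: list[str] = LINEAGE_PRIORITY,
) -> dict[int, str]:
    """Assign each segmented cell the lineage of highest mask overlap.

    For every cell label, the fraction of its pixels covered by each
    lineage's marker mask is computed; the cell takes the lineage with the
    largest overlap. Zero overlap everywhere yields "other". Exact ties are
    broken by the fixed ``priority`` order.
    """
    labels = np.asarray(label_raster)
    if labels.size == 0 or labels.max() == 0:
        raise ValueError("label raster contains no cells")
    n_labels = int(labels.max())
    cell_px = np.bincount(labels.ravel(), minlength=n_labels + 1)
    ranked = [l for l in priority if l in lineage_masks] + [
        l for l in lineage_masks if l not in priority
    ]
    overlaps = np.zeros((len(ranked), n_labels + 1))
    for i, lineage in enumerate(ranked):
        mask = lineage_masks[lineage]
        if mask.data.shape != labels.shape:
            raise ValueError("mask and label raster shapes disagree")
        overlaps[i] = np.bincount(
            labels[mask.data].ravel(), minlength=n_labels + 1
        )
    result = {}
    for cell in range(1, n_labels + 1):
        if cell_px[cell] == 0:
            continue
        col = overlaps[:, cell]
        if col.max() == 0:
            result[cell] = "other"
        else:
            # argmax returns the first maximum, i.e. the highest priority
            result[cell] = ranked[int(np.argmax(col))]
    return result


def apply_gates(cells: pd.DataFrame, gates: list[GateSpec]) -> pd.DataFrame:
    """Set boolean subpopulation flags per the gate specifications.

    A flag is set iff the parent condition holds and the normalized marker
    intensity is >= the threshold (inclusive). Gates are applied in order so
    later gates may reference earlier flags as parents.
    """
    out = cells.copy()
    for gate in gates:
        col = f"{gate.marker}_norm"
        if col not in out.columns:
            raise KeyError(
                f"gate {gate.name!r} references marker {gate.marker!r} with no "
                f"normalized intensity column {col!r}"
            )
        if gate.parent in out.columns and out[gate.parent].dtype == bool:
            parent_ok = out[gate.parent]
        elif "lineage" in out.columns and (out["lineage"] == gate.parent).any():
            parent_ok = out["lineage"] == gate.parent
        elif "lineage" in out.columns:
            parent_ok = out["lineage"] == gate.parent   # empty parent is fine
        else:
            raise KeyError(
                f"gate {gate.name!r} parent {gate.parent!r} is neither a flag "
                "column nor a lineage"
            )
        out[gate.name] = parent_ok & (out[col] >= gate.threshold)
    return out


def _population_mask(cells: pd.DataFrame, population: str) -> pd.Series:
    if population in cells.columns and cells[population].dtype == bool:
        return cells[population]
    if "lineage" in cells.columns:
        return cells["lineage"] == population
    raise KeyError(f"unknown population {population!r}")


def population_proportions(
    cells: pd.DataFrame, numerator: str, denominator: str
) -> float | None:
    """Proportion of a subpopulation over a parent population.

    Returns None (missing, never zero) when the denominator population is
    empty, so cohort-level statistics can exclude the region.
    """
    den = _population_mask(cells, denominator)
    if den.sum() == 0:
        return None
    num = _population_mask(cells, numerator)
    return float((num & den).sum() / den.sum())


def marker_positive_percentage(
    cells: pd.DataFrame,
    markers: list[str],
    thresholds: dict[str, float] | float,
    m1_markers: list[str] | None = None,
    m2_markers: list[str] | None = None,
) -> dict[str, float] | None:
    """Percentage of cells positive for each marker (and dual M1∧M2).

    ``cells`` is already the subpopulation of interest (e.g. CD68+CD74+
    cells). Positivity is normalized intensity >= threshold. When M1 and M2
    marker panels are given, also reports ``M1_and_M2``: the percentage of
    cells positive for at least one marker from each panel. Returns None for
    an empty subpopulation (missing, not 0).
    """
    if len(cells) == 0:
        return None
    out = {}
    pos = {}
    for marker in markers:
        thr = thresholds if np.isscalar(thresholds) else thresholds[marker]
        col = f"{marker}_norm"
        if col not in cells.columns:
            raise KeyError(f"no normalized intensity column {col!r}")
        pos[marker] = cells[col] >= thr
        out[marker] = float(pos[marker].mean() * 100)
    if m1_markers and m2_markers:
        m1_any = np.logical_or.reduce([pos[m] for m in m1_markers])
        m2_any = np.logical_or.reduce([pos[m] for m in m2_markers])
        out["M1_and_M2"] = float(np.mean(m1_any & m2_any) * 100)
    return out


def mean_intensity_contrast(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    markers: list[str],
    family: str = "markers",
    family_size: int | None = None,
) -> pd.DataFrame:
    """Per-marker mean intensities, fold change and Wilcoxon p/q.

    Fold change is mean(a)/mean(b) on the normalized scale with a pseudo
    floor of 1e-6 on the denominator to avoid division by zero. BH
    correction is applied over the declared family size (default: the number
    of markers tested).
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    rows = []
    results: list[ComparisonResult] = []
    for marker in markers:
        col = f"{marker}_norm"
        a = group_a[col].to_numpy(dtype=float)
        b = group_b[col].to_numpy(dtype=float)
        res = wilcoxon_rank_sum(a, b)
        results.append(res)
        mean_a, mean_b = float(a.mean()), float(b.mean())
        rows.append({
            "marker": marker,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": mean_a / max(mean_b, FOLD_CHANGE_FLOOR),
            "p": res.p,
        })
    attach_bh(results, family=family,
              family_size=family_size if family_size is not None else len(markers))
    df = pd.DataFrame(rows)
    df["q"] = [r.q for r in results]
    return df
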