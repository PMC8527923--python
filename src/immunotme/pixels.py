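"""Pixel-level analysis of multi-channel marker-intensity images.

Threshold-based marker masks, boolean mask algebra, marker-positive areas
normalized to a tissue or compartment mask, and tumor/stroma compartment
masks derived from tumor-associated markers (e.g. E-cadherin, pan-keratin).

Threshold comparisons are inclusive (>=) throughout: a pixel exactly at a
gate belongs to the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import closing, disk, remove_small_objects

__all__ = [
    "RegionImage",
    "Mask",
    "marker_mask",
    "combine_masks",
    "normalized_area",
    "compartment_masks",
]

TISSUE_FLOOR = 0.01   # intensity floor defining "tissue" pixels


@dataclass
class RegionImage:
    """Multi-channel marker-intensity raster with physical scale.

    ``channels`` maps marker name to a 2-D float array; all channels share
    one shape. ``um_per_pixel`` converts pixel areas to μm².
    """

    channels: dict[str, np.ndarray]
    um_per_pixel: float
    region_id: str = ""
    patient_id: str = ""
    group: str = ""

    def __post_init__(self):
        if not self.channels:
            raise ValueError("RegionImage needs at least one channel")
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be positive")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on shape: {sorted(shapes)}")
        for name, ch in self.channels.items():
            if ch.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")
            if not np.all(np.isfinite(ch)) or np.any(ch < 0):
                raise ValueError(f"channel {name!r} has non-finite or negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def marker_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"unknown channel {name!r}; available: {sorted(self.channels)}"
            )
        return self.channels[name]


@dataclass
class Mask:
    """Binary raster aligned to a RegionImage, with provenance."""

    data: np.ndarray
    label: str
    provenance: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.dtype != bool:
            uniq = np.unique(self.data)
            if not np.all(np.isin(uniq, [0, 1])):
                raise ValueError("mask must be strictly binary")
            self.data = self.data.astype(bool)

    @property
    def area_px(self) -> int:
        return int(self.data.sum())

    def area_um2(self, um_per_pixel: float) -> float:
        return self.area_px * um_per_pixel**2


def marker_mask(
    image: RegionImage,
    channel: str,
    threshold: float,
    min_object_px: int = 0,
) -> Mask:
    """Pixels with marker intensity >= threshold, despeckled.

    Connected components (8-connectivity) smaller than ``min_object_px`` are
    removed; despeckling is off by default (``min_object_px=0``).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    data = image.channel(channel) >= threshold
    if min_object_px > 1:
        # drop components with fewer than min_object_px pixels
        data = remove_small_objects(data, connectivity=2,
                                    max_size=min_object_px - 1)
    return Mask(
        data=data,
        label=f"{channel}+",
        provenance=f"{channel}>={threshold}" + (
            f"|min_object_px={min_object_px}" if min_object_px else ""
        ),
    )


def combine_masks(masks: list[Mask], op: str, label: str | None = None) -> Mask:
    """Boolean algebra over masks: AND, OR, or NOT (unary)."""
    op = op.upper()
    if not masks:
        raise ValueError("no masks given")
    shapes = {m.data.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"mask shapes disagree: {sorted(shapes)}")
    if op == "NOT":
        if len(masks) != 1:
            raise ValueError("NOT takes exactly one mask")
        data = ~masks[0].data
        prov = f"NOT({masks[0].provenance})"
    elif op in ("AND", "OR"):
        data = masks[0].data.copy()
        for m in masks[1:]:
            data = data & m.data if op == "AND" else data | m.data
        prov = f" {op} ".join(f"({m.provenance})" for m in masks)
    else:
        raise ValueError(f"unknown op {op!r}; use AND, OR or NOT")
    return Mask(data=data, label=label or op.lower(), provenance=prov)


def normalized_area(numerator: Mask, denominator: Mask) -> float:
    """Positive area normalized over a reference area: |num ∩ den| / |den|.

    An empty denominator is an error — the normalization is undefined, and
    silently reporting zero would bias cohort averages.
    """
    if numerator.data.shape != denominator.data.shape:
        raise ValueError("mask shapes disagree")
    den = denominator.area_px
    if den == 0:
        raise ValueError(
            f"denominator mask {denominator.label!r} is empty; "
            "normalized area undefined"
        )
    return float((numerator.data & denominator.data).sum() / den)


def compartment_masks(
    image: RegionImage,
    tumor_channels: tuple[str, ...] = ("Ecad", "PanK"),
    thresholds: dict[str, float] | float = 0.2,
    closing_radius_px: int = 3,
    tissue_floor: float = TISSUE_FLOOR,
) -> tuple[Mask, Mask]:
    """Tumor and stroma masks partitioning the tissue area.

    The tissue mask is the union of all channels above a low intensity floor
    after morphological closing. The tumor mask is the union of
    tumor-associated marker masks (after closing) restricted to tissue;
    stroma is tissue minus tumor, so the two are disjoint and together cover
    the tissue exactly.
    """
    for ch in tumor_channels:
        image.channel(ch)   # raises with the available names
    tissue = np.zeros(image.shape, dtype=bool)
    for ch in image.channels.values():
        tissue |= ch >= tissue_floor
    footprint = disk(closing_radius_px) if closing_radius_px > 0 else None
    if footprint is not None:
        tissue = closing(tissue, footprint)
    if not tissue.any():
        raise ValueError("tissue mask is empty; no pixel above the tissue floor")
    tumor = np.zeros(image.shape, dtype=bool)
    for ch in tumor_channels:
        thr = thresholds if np.isscalar(thresholds) else thresholds[ch]
        tumor |= image.channel(ch) >= thr
    if footprint is not None:
        tumor = closing(tumor, footprint)
    tumor &= tissue
    stroma = tissue & ~tumor
    thr_desc = thresholds if np.isscalar(thresholds) else dict(thresholds)
    tumor_mask = Mask(tumor, "tumor",
                      provenance=f"union({tumor_channels})>={thr_desc}|closed r={closing_radius_px}")
    stroma_mask = Mask(stroma, "stroma", provenance="tissue AND NOT tumor")
    return tumor_mask, stroma_mask
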