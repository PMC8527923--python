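"""Reading and writing the pipeline's on-disk formats.

Multi-page TIFF region images (one page per marker, channel names and
physical scale in the image description, with an optional YAML sidecar for
files lacking metadata), cell tables and catalogs as CSV/TSV, masks as
0/255 single-page TIFFs with a JSON provenance sidecar, and gene sets as
plain text or GMT.

Missing values are written as empty fields, never as 0 — several operations
distinguish "missing" from zero by contract.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .genomics import MUTATION_COLUMNS, MutationCatalog
from .pixels import Mask, RegionImage

__all__ = [
    "write_region_image",
    "read_region_image",
    "write_cell_table",
    "read_cell_table",
    "write_mask",
    "read_mutation_catalog",
    "write_mutation_catalog",
    "read_clonotype_table",
    "write_clonotype_table",
    "read_gene_set",
    "read_expression",
]

CELL_TABLE_REQUIRED = ["cell_id", "x_um", "y_um"]


def write_region_image(image: RegionImage, path) -> None:
    """Write a RegionImage as a multi-page TIFF (one page per marker)."""
    path = Path(path)
    meta = {
        "channels": image.marker_names,
        "um_per_pixel": image.um_per_pixel,
        "region_id": image.region_id,
        "patient_id": image.patient_id,
        "group": image.group,
    }
    stack = np.stack([image.channels[m] for m in image.marker_names]).astype(np.float32)
    tifffile.imwrite(path, stack, description=json.dumps(meta))


def read_region_image(path, sidecar=None) -> RegionImage:
    """Read a multi-page TIFF as a RegionImage.

    Channel names and μm-per-pixel come from the embedded JSON description;
    a YAML ``sidecar`` (mapping with ``channels`` and ``um_per_pixel``) is
    accepted when the metadata is absent. The page count must match the
    declared channel names.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    if sidecar is not None and not {"channels", "um_per_pixel"} <= set(meta):
        with open(sidecar) as fh:
            meta = {**yaml.safe_load(fh), **{k: v for k, v in meta.items() if v}}
    if "um_per_pixel" not in meta:
        raise ValueError(
            f"{path}: no um_per_pixel metadata; supply a YAML sidecar with an "
            "explicit physical scale"
        )
    if stack.ndim == 2:
        stack = stack[None]
    names = meta.get("channels")
    if not names:
        raise ValueError(f"{path}: no channel names in metadata or sidecar")
    if len(names) != stack.shape[0]:
        raise ValueError(
            f"{path}: {stack.shape[0]} pages but {len(names)} declared channel names"
        )
    return RegionImage(
        channels={n: stack[i].astype(float) for i, n in enumerate(names)},
        um_per_pixel=float(meta["um_per_pixel"]),
        region_id=meta.get("region_id", ""),
        patient_id=meta.get("patient_id", ""),
        group=meta.get("group", ""),
    )


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def write_cell_table(cells: pd.DataFrame, path) -> None:
    path = Path(path)
    cells.to_csv(path, sep=_sep_for(path), index=False)


def read_cell_table(path) -> pd.DataFrame:
    """Read a cell table, validating required centroid columns.

    Unknown columns are preserved untouched.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in CELL_TABLE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required columns {missing}; required header "
            f"starts with {CELL_TABLE_REQUIRED}"
        )
    return df


def write_mask(mask: Mask, path, um_per_pixel: float | None = None) -> None:
    """Write a mask as a 0/255 TIFF plus a JSON provenance sidecar."""
    path = Path(path)
    tifffile.imwrite(path, (mask.data.astype(np.uint8) * 255))
    sidecar = {
        "label": mask.label,
        "provenance": mask.provenance,
        "area_px": mask.area_px,
    }
    if um_per_pixel is not None:
        sidecar["area_um2"] = mask.area_um2(um_per_pixel)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def write_mutation_catalog(catalog: MutationCatalog, path) -> None:
    path = Path(path)
    catalog.records.to_csv(path, sep="\t", index=False)
    meta = {"exome_mb": catalog.exome_mb}
    path.with_suffix(".meta.json").write_text(json.dumps(meta))


def read_mutation_catalog(path, exome_mb: float | None = None) -> MutationCatalog:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: mutation catalog missing columns {missing}")
    if exome_mb is None:
        meta_path = path.with_suffix(".meta.json")
        if not meta_path.exists():
            raise ValueError(
                f"{path}: exome_mb not given and no {meta_path.name} sidecar found"
            )
        exome_mb = json.loads(meta_path.read_text())["exome_mb"]
    return MutationCatalog(records=df, exome_mb=float(exome_mb))


def write_clonotype_table(table: pd.DataFrame, path) -> None:
    table.to_csv(Path(path), sep="\t", index=False)


def read_clonotype_table(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t")
    for col in ("rearrangement_id", "productive", "templates"):
        if col not in df.columns:
            raise ValueError(f"{path}: clonotype table missing column {col!r}")
    if df["rearrangement_id"].duplicated().any():
        raise ValueError(f"{path}: duplicated rearrangement ids")
    return df


def read_gene_set(path) -> dict[str, list[str]]:
    """Read gene sets: GMT (name, description, genes...) or one gene per line."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if path.suffix.lower() == ".gmt":
        sets = {}
        for ln in lines:
            parts = ln.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed GMT line {ln[:50]!r}")
            sets[parts[0]] = parts[2:]
        return sets
    return {path.stem: lines}


def read_expression(path) -> pd.DataFrame:
    """Gene × sample expression matrix (genes as the first/index column)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: expression matrix has no sample columns")
    return df
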