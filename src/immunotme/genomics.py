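"""Sequence-derived statistics for tumor immunogenomics.

Tumor mutational burden (TMB) with hypermutation classification, the
neoantigenic index, cancer-cell-fraction (CCF) based clonality of
immunogenic mutations, and productive clonality of TCR beta repertoires.

Immunogenicity is an input flag (produced upstream by neoantigen binding
prediction); this module consumes annotated mutation catalogs, it never
calls variants or predicts binding.

The CCF estimator is the standard closed-form purity/copy-number correction
of the variant allele fraction:

    CCF = VAF * (purity * CN_t + (1 - purity) * 2) / (purity * m)

with CN_t the local total tumor copy number and m the mutation multiplicity.
A mutation is called clonal when the CCF point estimate is >= ``clonal_ccf``
(default 0.8) or the upper bound of the binomial 95% CI on the VAF, pushed
through the same transform, reaches 1. Regions with tumor purity <= 0.3 are
excluded from clonality analysis because low purity makes the VAF-to-CCF
mapping unreliable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "MutationCatalog",
    "TmbResult",
    "CcfResult",
    "tmb",
    "neoantigenic_index",
    "ccf",
    "clonal_immunogenic_summary",
    "productive_clonality",
    "patient_aggregate",
]

HYPERMUTATION_TMB = 12.0  # mutations/Mb; >= is hypermutated
PURITY_FLOOR = 0.3        # regions at or below are excluded from clonality
CLONAL_CCF = 0.8

MUTATION_COLUMNS = [
    "region_id", "gene", "consequence", "immunogenic",
    "vaf", "depth", "tumor_purity", "total_copy_number", "multiplicity",
]


@dataclass
class MutationCatalog:
    """Per-mutation records plus the callable exome size in megabases."""

    records: pd.DataFrame
    exome_mb: float

    def __post_init__(self):
        if self.exome_mb <= 0:
            raise ValueError("exome_mb must be positive")
        missing = [c for c in MUTATION_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"mutation catalog missing columns: {missing}")

    def region(self, region_id) -> pd.DataFrame:
        return self.records[self.records["region_id"] == region_id]

    @property
    def region_ids(self) -> list:
        return list(pd.unique(self.records["region_id"]))


@dataclass
class TmbResult:
    tmb: float
    n_mutations: int
    exome_mb: float
    hypermutated: bool


@dataclass
class CcfResult:
    ccf: float
    ci_low: float
    ci_high: float
    clonal: bool


def tmb(catalog: MutationCatalog, region_id, threshold: float = HYPERMUTATION_TMB) -> TmbResult:
    """Mutations per callable megabase for one region.

    Counts every cataloged mutation in the region (the catalog is the
    exonic/splicing call set). Hypermutated iff TMB >= ``threshold``
    (inclusive: TMB below the threshold marks the non-hypermutated group).
    """
    n = int(len(catalog.region(region_id)))
    value = n / catalog.exome_mb
    return TmbResult(
        tmb=value, n_mutations=n, exome_mb=catalog.exome_mb,
        hypermutated=bool(value >= threshold),
    )


def neoantigenic_index(catalog: MutationCatalog, region_id) -> float | None:
    """Predicted-immunogenic mutations over all nonsilent mutations.

    Returns None (missing, not zero) when the region has no nonsilent
    mutations.
    """
    reg = catalog.region(region_id)
    nonsilent = reg[reg["consequence"] == "nonsilent"]
    if len(nonsilent) == 0:
        return None
    return float(nonsilent["immunogenic"].astype(bool).sum() / len(nonsilent))


def ccf(
    vaf: float,
    purity: float,
    total_copy_number: int = 2,
    multiplicity: int = 1,
    depth: int | None = None,
    clonal_ccf: float = CLONAL_CCF,
) -> CcfResult:
    """Closed-form cancer cell fraction of one mutation, capped at 1.

    When ``depth`` is given, a Clopper-Pearson 95% CI on the VAF is
    propagated through the same transform; the mutation is clonal when the
    point estimate reaches ``clonal_ccf`` or the CI upper bound reaches 1.
    """
    if purity <= 0 or purity > 1:
        raise ValueError("purity must lie in (0, 1]")
    if not 0 <= vaf <= 1:
        raise ValueError("vaf must lie in [0, 1]")
    if multiplicity < 1 or total_copy_number < 1:
        raise ValueError("multiplicity and total_copy_number must be >= 1")
    scale = (purity * total_copy_number + (1 - purity) * 2) / (purity * multiplicity)
    point = min(vaf * scale, 1.0)
    if depth is not None:
        if depth <= 0:
            raise ValueError("depth must be positive")
        alt = int(round(vaf * depth))
        lo, hi = proportion_confint(alt, depth, alpha=0.05, method="beta")
        ci_low, ci_high = min(lo * scale, 1.0), min(hi * scale, 1.0)
    else:
        ci_low = ci_high = point
    clonal = point >= clonal_ccf or ci_high >= 1.0
    return CcfResult(ccf=point, ci_low=ci_low, ci_high=ci_high, clonal=bool(clonal))


def clonal_immunogenic_summary(
    catalog: MutationCatalog,
    region_id,
    clonal_ccf: float = CLONAL_CCF,
    purity_floor: float = PURITY_FLOOR,
) -> tuple[int, float | None]:
    """Count and fraction of immunogenic mutations classified clonal.

    The region must pass the purity filter (purity strictly above
    ``purity_floor``); the fraction is missing (None) when the region has no
    immunogenic mutations.
    """
    reg = catalog.region(region_id)
    if len(reg) == 0:
        return 0, None
    purity = float(reg["tumor_purity"].iloc[0])
    if purity <= purity_floor:
        raise ValueError(
            f"region {region_id!r} has purity {purity:.2f} <= {purity_floor}; "
            "excluded from clonality analysis"
        )
    imm = reg[reg["immunogenic"].astype(bool)]
    if len(imm) == 0:
        return 0, None
    clonal_flags = [
        ccf(
            row.vaf, row.tumor_purity, int(row.total_copy_number),
            int(row.multiplicity), int(row.depth), clonal_ccf=clonal_ccf,
        ).clonal
        for row in imm.itertuples()
    ]
    n_clonal = int(sum(clonal_flags))
    return n_clonal, n_clonal / len(imm)


def productive_clonality(clonotypes: pd.DataFrame) -> float:
    """Productive clonality of a TCR repertoire, in [0, 1].

    Restricts to productive clonotypes with positive template counts; with
    frequencies p_i, clonality = 1 - H / ln(R) where H is Shannon entropy
    (natural log) and R the number of productive clonotypes. A monoclonal
    repertoire (R = 1) has clonality 1 by convention; a perfectly even one
    has clonality 0.

    Expects columns ``productive`` (bool) and ``templates`` (counts).
    """
    prod = clonotypes[clonotypes["productive"].astype(bool)]
    counts = prod["templates"].to_numpy(dtype=float)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("no productive clonotype with positive template count")
    if counts.size == 1:
        return 1.0
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    return min(max(1.0 - h / math.log(counts.size), 0.0), 1.0)


def patient_aggregate(values, method: str = "mean") -> float:
    """Per-patient aggregate of per-region values (missing regions dropped)."""
    if method != "mean":
        raise ValueError(f"unsupported aggregation {method!r}")
    arr = np.asarray(
        [v for v in values if v is not None], dtype=float
    )
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no non-missing region value to aggregate")
    return float(arr.mean())
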