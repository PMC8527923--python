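"""Synthetic imaging, mutation, repertoire, and expression inputs.

Generates every input kind the analysis pipeline consumes, with known
planted ground truth, so each downstream stage is testable end to end
without patient data:

* imaging regions — multi-channel marker rasters where each cell is a
  constant-radius disk with per-population marker intensities, plus a
  ground-truth cell table with exact centroids, compartments and phenotypes;
* cohorts — durable-benefit (DB) vs no-durable-benefit (nDB) patient groups
  with planted effect sizes (e.g. a CD74+ macrophage proportion difference,
  or PD1+ T cells placed as satellites of macrophage clusters at
  group-specific distances);
* mutation catalogs with controlled immunogenic and clonal fractions and
  binomially sampled variant allele fractions;
* TCR repertoires whose geometric-decay abundance profile is solved
  numerically to hit a target productive clonality.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so identical seeds give
bit-identical outputs and sub-generators remain independently testable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from skimage.draw import disk as disk_pixels

from .pixels import RegionImage

logger = logging.getLogger(__name__)

__all__ = [
    "CompartmentLayout",
    "UniformPlacement",
    "ClusteredPlacement",
    "SatellitePlacement",
    "PopulationSpec",
    "RegionSpec",
    "CohortSpec",
    "RegionRecord",
    "generate_region",
    "generate_cohort",
    "generate_mutation_catalog",
    "generate_repertoire",
    "generate_expression",
    "tme_scenario",
    "DEFAULT_SCENARIO",
]

CELL_RADIUS_UM = 4.0
BACKGROUND_SD = 0.02
MAX_PACKING = 0.4          # max fraction of region area covered by cell discs
OVERSAMPLE_CAP = 10        # rejection-sampling attempts per requested cell


@dataclass(frozen=True)
class CompartmentLayout:
    """Tumor-vs-stroma geometry; ``half_plane`` splits at x = fraction*width."""

    kind: str = "half_plane"
    tumor_fraction: float = 0.5

    def compartment_of(self, x: np.ndarray, y: np.ndarray, width: float,
                       height: float) -> np.ndarray:
        if self.kind != "half_plane":
            raise ValueError(f"unknown layout kind {self.kind!r}")
        return np.where(x < self.tumor_fraction * width, "tumor", "stroma")


@dataclass(frozen=True)
class UniformPlacement:
    compartment: str = "any"   # any | tumor | stroma


@dataclass(frozen=True)
class ClusteredPlacement:
    n_clusters: int
    cluster_radius_um: float
    cells_per_cluster: int
    compartment: str = "any"


@dataclass(frozen=True)
class SatellitePlacement:
    """Place cells at a folded-normal distance from a random parent cell."""

    parent_population: str
    distance_mean_um: float
    distance_sd_um: float


@dataclass
class PopulationSpec:
    """One synthetic cell population.

    ``intensity_means`` gives per-marker expected normalized intensity in
    [0, 1] (markers absent from the dict default to a low background mean);
    ``abundance`` is expected cells per mm² (ignored for clustered
    placement, where the count is n_clusters * cells_per_cluster).
    """

    name: str
    lineage: str
    intensity_means: dict[str, float]
    placement: UniformPlacement | ClusteredPlacement | SatellitePlacement
    abundance: float = 0.0
    intensity_noise: float = 0.05   # dispersion of markers listed in intensity_means
    baseline_mean: float = 0.01     # mean of unlisted (negative) markers
    baseline_noise: float = 0.01

    def __post_init__(self):
        if self.abundance < 0:
            raise ValueError(f"population {self.name!r}: abundance must be >= 0")
        for m, v in self.intensity_means.items():
            if not 0 <= v <= 1:
                raise ValueError(
                    f"population {self.name!r}: intensity mean for {m!r} outside [0, 1]"
                )


@dataclass
class RegionSpec:
    """Physical extent, scale, compartment layout and marker panel of one region."""

    width_um: float
    height_um: float
    um_per_pixel: float
    marker_panel: list[str]
    compartment_layout: CompartmentLayout = field(default_factory=CompartmentLayout)
    seed: int = 0

    def __post_init__(self):
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("region extent must be positive")
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be positive")
        if len(set(self.marker_panel)) != len(self.marker_panel):
            raise ValueError("marker names must be unique")

    @property
    def area_mm2(self) -> float:
        return self.width_um * self.height_um / 1e6


def _sample_uniform(rng, n, spec: RegionSpec, compartment: str):
    w, h = spec.width_um, spec.height_um
    split = spec.compartment_layout.tumor_fraction * w
    if compartment == "tumor":
        x = rng.uniform(0, split, n)
    elif compartment == "stroma":
        x = rng.uniform(split, w, n)
    else:
        x = rng.uniform(0, w, n)
    y = rng.uniform(0, h, n)
    return x, y


def _place_population(
    pop: PopulationSpec,
    spec: RegionSpec,
    rng: np.random.Generator,
    occupied: list[np.ndarray],
    placed: dict[str, np.ndarray],
    min_sep: float,
) -> np.ndarray:
    """Rejection-sample centroid positions for one population."""

    pts: list[tuple[float, float]] = []

    def free(pt) -> bool:
        for block in occupied:
            if len(block) and np.min(np.hypot(block[:, 0] - pt[0], block[:, 1] - pt[1])) < min_sep:
                return False
        for q in pts:
            if math.hypot(q[0] - pt[0], q[1] - pt[1]) < min_sep:
                return False
        return True
    pl = pop.placement
    if isinstance(pl, (UniformPlacement,)):
        n_req = int(round(pop.abundance * spec.area_mm2))
        attempts = 0
        while len(pts) < n_req and attempts < OVERSAMPLE_CAP * n_req:
            x, y = _sample_uniform(rng, 1, spec, pl.compartment)
            attempts += 1
            if free((x[0], y[0])):
                pts.append((x[0], y[0]))
        shortfall = n_req - len(pts)
    elif isinstance(pl, ClusteredPlacement):
        n_req = pl.n_clusters * pl.cells_per_cluster
        shortfall = 0
        for _ in range(pl.n_clusters):
            # keep the whole disc inside the region
            margin = pl.cluster_radius_um
            cx = rng.uniform(margin, max(spec.width_um - margin, margin))
            cy = rng.uniform(margin, max(spec.height_um - margin, margin))
            got = 0
            attempts = 0
            while got < pl.cells_per_cluster and attempts < OVERSAMPLE_CAP * pl.cells_per_cluster:
                attempts += 1
                r = pl.cluster_radius_um * math.sqrt(rng.uniform())
                theta = rng.uniform(0, 2 * math.pi)
                pt = (cx + r * math.cos(theta), cy + r * math.sin(theta))
                if not (0 <= pt[0] < spec.width_um and 0 <= pt[1] < spec.height_um):
                    continue
                if free(pt):
                    pts.append(pt)
                    got += 1
            shortfall += pl.cells_per_cluster - got
    elif isinstance(pl, SatellitePlacement):
        if pl.parent_population not in placed:
            raise ValueError(
                f"satellite population {pop.name!r} references undefined parent "
                f"{pl.parent_population!r}"
            )
        parents = placed[pl.parent_population]
        if len(parents) == 0:
            logger.warning("satellite %r: parent population empty; no cells placed", pop.name)
            return np.empty((0, 2))
        n_req = int(round(pop.abundance * spec.area_mm2))
        attempts = 0
        while len(pts) < n_req and attempts < OVERSAMPLE_CAP * n_req:
            attempts += 1
            parent = parents[rng.integers(len(parents))]
            # folded normal: positive distances with controllable mean
            d = abs(rng.normal(pl.distance_mean_um, pl.distance_sd_um))
            theta = rng.uniform(0, 2 * math.pi)
            pt = (parent[0] + d * math.cos(theta), parent[1] + d * math.sin(theta))
            if not (0 <= pt[0] < spec.width_um and 0 <= pt[1] < spec.height_um):
                continue
            if free(pt):
                pts.append(pt)
        shortfall = n_req - len(pts)
    else:
        raise TypeError(f"unknown placement {pl!r}")

    if shortfall > 0:
        logger.warning(
            "population %r: %d of %d requested cells could not be placed "
            "(packing rejections)", pop.name, shortfall, shortfall + len(pts)
        )
    arr = np.asarray(pts, dtype=float).reshape(-1, 2)
    occupied.append(arr)
    return arr


def generate_region(
    spec: RegionSpec,
    populations: list[PopulationSpec],
    cell_radius_um: float = CELL_RADIUS_UM,
    background_sd: float = BACKGROUND_SD,
    render: bool = True,
    max_packing: float = MAX_PACKING,
    region_id: str = "R1",
    patient_id: str = "P1",
    group: str = "",
) -> tuple[RegionImage | None, pd.DataFrame]:
    """Render one synthetic imaging region with ground truth.

    Returns the multi-channel image (or None with ``render=False``) and a
    cell table holding exact centroids, compartment, lineage, population
    label and the per-marker intensities drawn for each cell (these are the
    values painted into the raster, before background noise). Deterministic
    given ``spec.seed``.

    Raises when the requested populations exceed ``max_packing`` (fraction
    of the region covered by non-overlapping cell discs) — rejection
    sampling cannot satisfy such a request.
    """
    names = [p.name for p in populations]
    if len(set(names)) != len(names):
        raise ValueError("population names must be unique")
    area_um2 = spec.width_um * spec.height_um
    min_sep = 2 * cell_radius_um
    # feasibility: total requested disc area vs the packing cap
    for pop in populations:
        if isinstance(pop.placement, ClusteredPlacement):
            # discs of radius r centred in a disc of radius R occupy the
            # dilated disc of radius R + r; one cell always fits
            ratio = ((pop.placement.cluster_radius_um + cell_radius_um)
                     / cell_radius_um) ** 2
            allowed = max(1, math.floor(max_packing * ratio))
            if pop.placement.cells_per_cluster > allowed:
                raise ValueError(
                    f"population {pop.name!r} infeasible: "
                    f"{pop.placement.cells_per_cluster} cells per cluster exceed "
                    f"max packing {max_packing} of the cluster area (~{allowed})"
                )
    total_req = sum(
        p.placement.n_clusters * p.placement.cells_per_cluster
        if isinstance(p.placement, ClusteredPlacement)
        else int(round(p.abundance * spec.area_mm2))
        for p in populations
    )
    if total_req * math.pi * cell_radius_um**2 > max_packing * area_um2:
        raise ValueError(
            f"requested {total_req} cells exceed max packing {max_packing} "
            "of the region area"
        )

    ss = np.random.SeedSequence(spec.seed)
    place_rng, intens_rng, bg_rng = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    occupied: list[np.ndarray] = []
    placed: dict[str, np.ndarray] = {}
    rows = []
    for pop in populations:
        pts = _place_population(pop, spec, place_rng, occupied, placed, min_sep)
        placed[pop.name] = pts
        for x, y in pts:
            row = {
                "x_um": x,
                "y_um": y,
                "lineage": pop.lineage,
                "population": pop.name,
            }
            for m in spec.marker_panel:
                if m in pop.intensity_means:
                    mean, sd = pop.intensity_means[m], pop.intensity_noise
                else:
                    mean, sd = pop.baseline_mean, pop.baseline_noise
                row[m] = float(np.clip(intens_rng.normal(mean, sd), 0, 1))
            rows.append(row)

    cells = pd.DataFrame(
        rows, columns=["x_um", "y_um", "lineage", "population"] + spec.marker_panel
    )
    cells.insert(0, "cell_id", [f"c{i:05d}" for i in range(len(cells))])
    cells.insert(3, "area_um2", math.pi * cell_radius_um**2)
    comp = spec.compartment_layout.compartment_of(
        cells["x_um"].to_numpy(), cells["y_um"].to_numpy(),
        spec.width_um, spec.height_um,
    ) if len(cells) else np.array([], dtype=object)
    cells.insert(4, "compartment", comp)

    image = None
    if render:
        h = int(round(spec.height_um / spec.um_per_pixel))
        w = int(round(spec.width_um / spec.um_per_pixel))
        channels = {
            m: np.abs(bg_rng.normal(0.0, background_sd, size=(h, w)))
            for m in spec.marker_panel
        }
        r_px = cell_radius_um / spec.um_per_pixel
        for row in cells.itertuples():
            rr, cc = disk_pixels(
                (row.y_um / spec.um_per_pixel, row.x_um / spec.um_per_pixel),
                r_px, shape=(h, w),
            )
            for m in spec.marker_panel:
                channels[m][rr, cc] = getattr(row, m)
        image = RegionImage(
            channels=channels, um_per_pixel=spec.um_per_pixel,
            region_id=region_id, patient_id=patient_id, group=group,
        )
    return image, cells


# --- cohort generation -----------------------------------------------------

#: Baseline tumor-microenvironment scenario (the study conditions): a 0.36-mm²
#: region, tumor/stroma half-plane, macrophages with a CD74+ subset of which
#: half aggregates in dense clusters, CD8 T cells with cytotoxic (GzB+) and
#: proliferating (Ki67+) subsets, and PD1+ GzB+ cells placed as satellites of
#: the macrophage clusters. Densities are cells/mm².
DEFAULT_SCENARIO: dict[str, float] = {
    "width_um": 600.0,
    "height_um": 600.0,
    "um_per_pixel": 1.0,
    "tumor_fraction": 0.5,
    "tumor_density": 400.0,
    "b2m_positive_fraction": 0.5,
    "macrophage_density": 250.0,
    "cd74_fraction": 0.4,
    "cd74_clustered_fraction": 0.5,
    "n_mac_clusters": 3,
    "mac_cluster_radius_um": 40.0,
    "cd8_density": 200.0,
    "gzb_fraction": 0.3,
    "ki67_fraction": 0.25,
    "pd1_fraction": 0.3,
    "pd1_distance_um": 20.0,
    "pd1_distance_sd_um": 6.0,
    "t_helper_density": 150.0,
}

MARKER_PANEL = [
    "CD3", "CD8", "CD68", "CD74", "GzB", "Ki67", "PD1", "PDL1",
    "Ecad", "PanK", "B2M",
]

HI = 0.6   # mean normalized intensity of a positive marker


def tme_scenario(params: dict | None = None, seed: int = 0
                 ) -> tuple[RegionSpec, list[PopulationSpec]]:
    """Build a RegionSpec and populations from named scenario parameters.

    Unknown parameter names raise, so cohort effect sizes cannot silently
    miss their target.
    """
    p = dict(DEFAULT_SCENARIO)
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise KeyError(f"unknown scenario parameters: {sorted(unknown)}")
        p.update(params)
    spec = RegionSpec(
        width_um=p["width_um"], height_um=p["height_um"],
        um_per_pixel=p["um_per_pixel"], marker_panel=list(MARKER_PANEL),
        compartment_layout=CompartmentLayout("half_plane", p["tumor_fraction"]),
        seed=seed,
    )
    area = spec.area_mm2
    mac = p["macrophage_density"]
    n_cd74 = mac * p["cd74_fraction"]
    n_cd74_clustered = n_cd74 * p["cd74_clustered_fraction"]
    n_clusters = int(p["n_mac_clusters"])
    cells_per_cluster = (
        int(round(n_cd74_clustered * area / n_clusters)) if n_clusters else 0
    )
    cd8 = p["cd8_density"]
    n_gzb = cd8 * p["gzb_fraction"]
    n_gzb_pd1 = n_gzb * p["pd1_fraction"]

    pops: list[PopulationSpec] = [
        PopulationSpec(
            "tumor_b2m_pos", "tumor",
            {"Ecad": HI, "PanK": HI, "B2M": 0.55},
            UniformPlacement("tumor"),
            abundance=p["tumor_density"] * p["b2m_positive_fraction"],
        ),
        PopulationSpec(
            "tumor_b2m_neg", "tumor",
            {"Ecad": HI, "PanK": HI},
            UniformPlacement("tumor"),
            abundance=p["tumor_density"] * (1 - p["b2m_positive_fraction"]),
        ),
    ]
    have_clusters = n_clusters > 0 and cells_per_cluster > 0
    if have_clusters:
        pops.append(PopulationSpec(
            "mac_cd74_clustered", "macrophage",
            {"CD68": HI, "CD74": 0.5, "PDL1": 0.5},
            ClusteredPlacement(n_clusters, p["mac_cluster_radius_um"], cells_per_cluster),
        ))
    pops += [
        PopulationSpec(
            "mac_cd74_uniform", "macrophage",
            {"CD68": HI, "CD74": 0.5},
            UniformPlacement(),
            abundance=n_cd74 * (1 - p["cd74_clustered_fraction"])
            + (0 if have_clusters else n_cd74 * p["cd74_clustered_fraction"]),
        ),
        PopulationSpec(
            "mac_cd74_neg", "macrophage",
            {"CD68": HI},
            UniformPlacement(),
            abundance=mac * (1 - p["cd74_fraction"]),
        ),
        PopulationSpec(
            "cd8_gzb_pd1", "T_cell",
            {"CD3": HI, "CD8": HI, "GzB": 0.45, "PD1": 0.5},
            SatellitePlacement("mac_cd74_clustered", p["pd1_distance_um"],
                               p["pd1_distance_sd_um"])
            if have_clusters else UniformPlacement(),
            abundance=n_gzb_pd1,
        ),
        PopulationSpec(
            "cd8_gzb", "T_cell",
            {"CD3": HI, "CD8": HI, "GzB": 0.45},
            UniformPlacement(),
            abundance=n_gzb * (1 - p["pd1_fraction"]),
        ),
        PopulationSpec(
            "cd8_ki67", "T_cell",
            {"CD3": HI, "CD8": HI, "Ki67": 0.5},
            UniformPlacement(),
            abundance=cd8 * p["ki67_fraction"],
        ),
        PopulationSpec(
            "cd8_rest", "T_cell",
            {"CD3": HI, "CD8": HI},
            UniformPlacement(),
            abundance=max(cd8 * (1 - p["gzb_fraction"] - p["ki67_fraction"]), 0.0),
        ),
        PopulationSpec(
            "t_helper", "T_cell",
            {"CD3": HI},
            UniformPlacement(),
            abundance=p["t_helper_density"],
        ),
    ]
    return spec, pops


@dataclass
class CohortSpec:
    """Two patient groups with planted effect sizes.

    ``effect_sizes`` maps scenario parameter names to the planted DB - nDB
    difference of means: the DB group runs the base scenario shifted by
    +Δ/2 and the nDB group by -Δ/2 on each named parameter.
    """

    n_db: int
    n_ndb: int
    regions_per_patient: int
    base_scenario: dict = field(default_factory=dict)
    effect_sizes: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_db < 1 or self.n_ndb < 1:
            raise ValueError("each group needs at least one patient")
        if self.regions_per_patient < 1:
            raise ValueError("regions_per_patient must be >= 1")

    def group_scenario(self, group: str) -> dict:
        base = dict(DEFAULT_SCENARIO)
        base.update(self.base_scenario)
        sign = 0.5 if group == "DB" else -0.5
        out = dict(base)
        for key, delta in self.effect_sizes.items():
            if key not in base:
                raise KeyError(f"effect size targets unknown scenario parameter {key!r}")
            out[key] = base[key] + sign * delta
        return out


@dataclass
class RegionRecord:
    patient_id: str
    group: str
    region_id: str
    cells: pd.DataFrame
    image: RegionImage | None = None


def generate_cohort(spec: CohortSpec, render: bool = False) -> list[RegionRecord]:
    """Generate per-patient region inputs for both groups.

    With ``render=False`` (default) only ground-truth cell tables are
    produced; rasters are rendered on demand for imaging-stage tests.
    Deterministic given ``spec.seed``.
    """
    ss = np.random.SeedSequence(spec.seed)
    records = []
    patients = [("DB", i) for i in range(spec.n_db)] + [
        ("nDB", i) for i in range(spec.n_ndb)
    ]
    seeds = ss.spawn(len(patients) * spec.regions_per_patient)
    k = 0
    for group, i in patients:
        pid = f"{group}{i + 1:02d}"
        scenario = spec.group_scenario(group)
        for r in range(spec.regions_per_patient):
            region_seed = int(seeds[k].generate_state(1)[0] % (2**31))
            k += 1
            rspec, pops = tme_scenario(scenario, seed=region_seed)
            rid = f"{pid}_R{r + 1}"
            image, cells = generate_region(
                rspec, pops, render=render,
                region_id=rid, patient_id=pid, group=group,
            )
            records.append(RegionRecord(pid, group, rid, cells, image))
    return records


# --- mutation catalogs -----------------------------------------------------

def generate_mutation_catalog(
    n_nonsilent: int,
    immunogenic_fraction: float,
    clonal_fraction: float,
    purity: float,
    exome_mb: float,
    seed: int = 0,
    depth: int = 500,
    total_copy_number: int = 2,
    multiplicity: int = 1,
    n_silent: int = 0,
    region_id: str = "R1",
) -> pd.DataFrame:
    """Mutation records with controlled immunogenic and clonal fractions.

    Clonal mutations carry cancer-cell fraction 1; subclonal mutations draw
    CCF ~ Uniform(0.1, 0.6). The observed VAF is binomial at ``depth`` around
    the expected VAF = CCF * purity * m / (purity * CN_t + (1 - purity) * 2).
    Ground-truth columns ``true_ccf`` and ``true_clonal`` are included.
    """
    for name, frac in [("immunogenic_fraction", immunogenic_fraction),
                       ("clonal_fraction", clonal_fraction)]:
        if not 0 <= frac <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    if not 0 < purity <= 1:
        raise ValueError("purity must lie in (0, 1]")
    if exome_mb <= 0:
        raise ValueError("exome_mb must be positive")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = n_nonsilent + n_silent
    consequence = np.array(["nonsilent"] * n_nonsilent + ["silent"] * n_silent)
    immunogenic = np.zeros(n, dtype=bool)
    immunogenic[:n_nonsilent] = rng.uniform(size=n_nonsilent) < immunogenic_fraction
    clonal = rng.uniform(size=n) < clonal_fraction
    ccf_true = np.where(clonal, 1.0, rng.uniform(0.1, 0.6, size=n))
    expected_vaf = ccf_true * purity * multiplicity / (
        purity * total_copy_number + (1 - purity) * 2
    )
    vaf = rng.binomial(depth, expected_vaf) / depth
    return pd.DataFrame({
        "region_id": region_id,
        "gene": [f"GENE{i + 1:05d}" for i in range(n)],
        "consequence": consequence,
        "immunogenic": immunogenic,
        "vaf": vaf,
        "depth": depth,
        "tumor_purity": purity,
        "total_copy_number": total_copy_number,
        "multiplicity": multiplicity,
        "true_ccf": ccf_true,
        "true_clonal": clonal,
    })


# --- TCR repertoires -------------------------------------------------------

def _geometric_clonality(decay: float, n: int) -> float:
    """Productive clonality of frequencies p_i ∝ exp(-decay * i)."""
    if n == 1:
        return 1.0
    if decay == 0:
        return 0.0
    w = np.exp(-decay * np.arange(n))
    p = w / w.sum()
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    return 1.0 - h / math.log(n)


def generate_repertoire(
    n_clonotypes: int,
    target_clonality: float,
    seed: int = 0,
    total_templates: int = 100_000,
    nonproductive_fraction: float = 0.1,
) -> pd.DataFrame:
    """TCR clonotype table whose productive clonality hits a target.

    Template counts follow a geometric-decay abundance profile whose decay
    rate is solved numerically so the recomputed productive clonality lands
    within ~0.02 of ``target_clonality``. A fraction of extra nonproductive
    clonotypes is appended (they must be ignored by downstream clonality).
    """
    if n_clonotypes < 1:
        raise ValueError("n_clonotypes must be >= 1")
    if not 0 <= target_clonality < 1:
        if n_clonotypes == 1 and target_clonality == 1:
            pass
        else:
            raise ValueError(
                "target_clonality must lie in [0, 1): values >= 1 are "
                "unreachable with more than one clonotype"
            )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if n_clonotypes == 1:
        counts = np.array([total_templates])
    elif target_clonality == 0:
        counts = np.full(n_clonotypes, max(total_templates // n_clonotypes, 1))
    else:
        decay = brentq(
            lambda lam: _geometric_clonality(lam, n_clonotypes) - target_clonality,
            1e-9, 50.0,
        )
        w = np.exp(-decay * np.arange(n_clonotypes))
        p = w / w.sum()
        counts = np.maximum(np.round(p * total_templates).astype(int), 1)
    n_nonprod = int(round(nonproductive_fraction * n_clonotypes))
    rows = pd.DataFrame({
        "rearrangement_id": [f"TCRB{i + 1:06d}" for i in range(len(counts) + n_nonprod)],
        "productive": [True] * len(counts) + [False] * n_nonprod,
        "templates": np.concatenate([
            counts, rng.integers(1, 50, size=n_nonprod)
        ]),
    })
    return rows.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)


# --- expression matrices ---------------------------------------------------

def generate_expression(
    n_genes: int,
    samples: list[str],
    signature_genes: list[str] | None = None,
    up_in: list[str] | None = None,
    effect: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Log-normal gene × sample expression with an optionally planted signature.

    ``signature_genes`` (subset of the generated gene names, or new names to
    append) are shifted upward by ``effect`` log2 units in the ``up_in``
    samples, giving ssGSEA a known direction to recover.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    base = rng.normal(6, 2, size=(n_genes, 1)) + rng.normal(
        0, 0.5, size=(n_genes, len(samples))
    )
    df = pd.DataFrame(base, index=genes, columns=samples)
    if signature_genes:
        for g in signature_genes:
            if g not in df.index:
                raise KeyError(f"signature gene {g!r} not in the generated matrix")
        if up_in:
            df.loc[signature_genes, up_in] += effect
    return df
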