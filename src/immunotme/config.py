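"""Pipeline configuration: every fixed constant of the analysis in one place.

Defaults encode the published analysis choices: the CD74 gates (0.1 on all
macrophages for the combined-cohort analysis, 0.35 on CD68+ cells for the
deep phenotyping panel), the GzB 0.05 and Ki67 0.15 gates on CD8 T cells,
the 1.1-μm distance bin width, the >=5 cells/10,000 μm² density criterion,
the 12 mutations/Mb hypermutation cutoff, the 0.8 clonal-CCF rule and the
0.3 purity floor. All are plain data and round-trip losslessly through
YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from . import genomics, spatial

__all__ = ["PipelineConfig"]


def _default_gates() -> list[dict]:
    return [
        {"name": "CD8_T", "parent": "T_cell", "marker": "CD8", "threshold": 0.2},
        {"name": "CD68_mac", "parent": "macrophage", "marker": "CD68", "threshold": 0.2},
        {"name": "CD68_CD74", "parent": "CD68_mac", "marker": "CD74", "threshold": 0.1},
        {"name": "CD8_GzB", "parent": "CD8_T", "marker": "GzB", "threshold": 0.05},
        {"name": "CD8_Ki67", "parent": "CD8_T", "marker": "Ki67", "threshold": 0.15},
        {"name": "CD8_GzB_PD1", "parent": "CD8_GzB", "marker": "PD1", "threshold": 0.2},
        {"name": "mac_PDL1", "parent": "CD68_CD74", "marker": "PDL1", "threshold": 0.2},
    ]


@dataclass
class PipelineConfig:
    """Thresholds, spatial parameters and statistical family sizes."""

    # imaging / gating
    tumor_channels: tuple[str, ...] = ("Ecad", "PanK")
    pixel_threshold: float = 0.2          # default per-marker pixel threshold
    min_object_px: int = 4                # despeckling (0 disables)
    gates: list[dict] = field(default_factory=_default_gates)
    cd74_gate_all_macrophages: float = 0.1
    cd74_gate_deep_panel: float = 0.35

    # spatial
    eps_um: float = spatial.DEFAULT_EPS_UM
    min_pts: int = spatial.DEFAULT_MIN_PTS
    bin_width_um: float = spatial.BIN_WIDTH_UM
    density_criterion: float = spatial.DENSITY_CRITERION

    # genomics
    exome_mb: float = 30.0                # callable exome size, config input
    hypermutation_tmb: float = genomics.HYPERMUTATION_TMB
    clonal_ccf: float = genomics.CLONAL_CCF
    purity_floor: float = genomics.PURITY_FLOOR

    # statistics
    family_sizes: dict = field(default_factory=lambda: {
        "macrophage_clusters": 9,
        "macrophage_marker_combinations": 9,
        "deep_panel_markers": 14,
    })

    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self):
        if not 0 <= self.cd74_gate_all_macrophages <= 1:
            raise ValueError("CD74 gate must lie in [0, 1]")
        if self.eps_um <= 0 or self.min_pts < 2:
            raise ValueError("invalid DBSCAN parameters")
        if self.bin_width_um <= 0:
            raise ValueError("bin width must be positive")
        if self.exome_mb <= 0:
            raise ValueError("exome_mb must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "tumor_channels" in data:
            data["tumor_channels"] = tuple(data["tumor_channels"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tumor_channels"] = list(self.tumor_channels)
        return d

    @property
    def config_hash(self) -> str:
        """Stable hash embedded in outputs so mixed-config results refuse to merge."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
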