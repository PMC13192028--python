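"""Run configuration: every stage's tunables with the published defaults.

Defaults collect the analysis thresholds: presence in > 4 cells, VMR > 0.01,
strand concordance > 0.65, 310T>C blacklist, 1.5-fold change with BH alpha
0.05, KS gating at 100 cells, 10-Mb/2-Mb CNV windows, burden downsampling to
100 cells.  The whole object round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # variant filters
    min_coverage: int = 5
    detection_threshold: float = 0.01
    min_cells: int = 4  # pass requires strictly more cells than this
    vmr_threshold: float = 0.01
    concordance_threshold: float = 0.65
    homoplasmy_cutoff: float = 0.9
    blacklist: tuple[str, ...] = ("310T>C",)
    # burden
    burden_downsample: int = 100
    # clonotyping
    knn_k: int = 20
    resolution: float = 1.0
    min_marker_het: float = 0.02
    merge_threshold: float = 0.1
    # stability
    stability_fractions: tuple[float, ...] = (0.75, 0.50)
    stability_reps: int = 25
    stability_threshold: float = 0.7
    # clone dynamics / shift screens
    dynamics_min_cells: int = 10
    fc_threshold: float = 1.5
    alpha: float = 0.05
    ks_min_cells: int = 100
    ks_gate: str = "both"
    # CNV windows
    bin_size: int = 10_000_000
    step: int = 2_000_000
    min_ref_cells: int = 50
    min_bins: int = 5
    z_threshold: float = 3.0
    # trees
    tree_max_leaves: int = 500
    seed: int = 0

    def validate(self) -> None:
        if self.ks_gate not in ("both", "any"):
            raise ValueError("ks_gate must be 'both' or 'any'")
        if not 0 < self.step <= self.bin_size:
            raise ValueError("need 0 < step <= bin_size")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        out = asdict(self)
        out["blacklist"] = list(self.blacklist)
        out["stability_fractions"] = list(self.stability_fractions)
        return out

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if "blacklist" in data:
            data["blacklist"] = tuple(data["blacklist"])
        if "stability_fractions" in data:
            data["stability_fractions"] = tuple(data["stability_fractions"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class Sample:
    """One row of the sample sheet."""

    id: str
    donor: str
    timepoint: str
    compartment: str  # physiologic_b | monoclonal | t_reference
    counts: str | None = None
    fragments: str | None = None
    bcr: str | None = None


@dataclass
class SampleSheet:
    samples: list[Sample]
    chrom_sizes: str | None = None

    def validate(self, base: Path | None = None) -> None:
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        base = base or Path(".")
        for s in self.samples:
            for attr in ("counts", "fragments", "bcr"):
                path = getattr(s, attr)
                if path is not None and not (base / path).exists():
                    raise FileNotFoundError(f"sample {s.id}: {attr} path {path} not found")
        if self.chrom_sizes is not None and not (base / self.chrom_sizes).exists():
            raise FileNotFoundError(f"chrom_sizes path {self.chrom_sizes} not found")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SampleSheet":
        data = yaml.safe_load(Path(path).read_text())
        samples = [Sample(**row) for row in data["samples"]]
        return cls(samples=samples, chrom_sizes=data.get("chrom_sizes"))

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "samples": [asdict(s) for s in self.samples],
            "chrom_sizes": self.chrom_sizes,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
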