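"""Run configuration: YAML schema with every pipeline constant overridable.

Defaults equal the thresholds the pipeline is built around (DP >= 15,
DP <= 2x mean autosomal coverage, GQ >= 30, 3-site block pruning,
5/10 kb resolution classes, the NCO filter constants, 2 kb promoters,
100 kb hot-spot pairing, 1 Mb CoC windows).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .genome import Chromosome, GenomeLayout
from .simulate import ErrorModel, MeiosisModel

CONFIG_VERSION = 1


@dataclass
class Thresholds:
    dp_min: int = 15
    dp_max_factor: float = 2.0
    gq_min: int = 30
    min_sites: int = 3
    max_event_window_bp: int = 1_000_000
    resolution_fine_bp: int = 5_000
    resolution_coarse_bp: int = 10_000
    indel_proximity_bp: int = 10
    cluster_window_bp: int = 30
    cluster_max_snps: int = 3
    deviating_window_bp: int = 5_000
    deviating_max_sites: int = 2
    min_allele_fraction: float = 0.25
    promoter_bp: int = 2_000
    hotspot_pair_bp: int = 100_000
    coc_window_bp: int = 1_000_000

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ValueError(f"threshold {name} must be positive, got {value}")
        if not 0 < self.min_allele_fraction < 1:
            raise ValueError("min_allele_fraction must be in (0, 1)")


@dataclass
class RunConfig:
    version: int = CONFIG_VERSION
    layout: GenomeLayout = field(default_factory=lambda: _default_layout())
    meiosis: MeiosisModel = field(default_factory=MeiosisModel)
    errors: ErrorModel = field(default_factory=ErrorModel)
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 1
    paths: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.thresholds.validate()

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "layout": {
                "snp_density": self.layout.snp_density,
                "chromosomes": [
                    {"name": c.name, "length": c.length, "is_z": c.is_z,
                     "par": list(c.par) if c.par else None}
                    for c in self.layout],
            },
            "meiosis": asdict(self.meiosis),
            "errors": asdict(self.errors),
            "thresholds": asdict(self.thresholds),
            "paths": dict(self.paths),
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        layout_d = d.get("layout")
        if layout_d:
            layout = GenomeLayout(
                chromosomes=[Chromosome(
                    name=str(c["name"]), length=int(c["length"]),
                    is_z=bool(c.get("is_z", False)),
                    par=tuple(c["par"]) if c.get("par") else None)
                    for c in layout_d["chromosomes"]],
                snp_density=float(layout_d.get("snp_density", 1e-4)))
        else:
            layout = _default_layout()
        cfg = cls(
            version=int(d.get("version", CONFIG_VERSION)),
            layout=layout,
            meiosis=MeiosisModel(**d.get("meiosis", {})),
            errors=ErrorModel(**d.get("errors", {})),
            thresholds=Thresholds(**d.get("thresholds", {})),
            seed=int(d.get("seed", 1)),
            paths=dict(d.get("paths", {})),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _default_layout() -> GenomeLayout:
    from .genome import default_layout
    return default_layout()
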