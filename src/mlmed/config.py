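"""Run configuration: one serialisable object driving every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .design import DesignSpec
from .synth import SimConfig


@dataclass
class RoiSpec:
    name: str
    center_mm: tuple[float, float, float]


@dataclass
class RunConfig:
    """Everything a full pipeline run needs, with explicit per-stage seeds."""

    n_subjects: int = 20
    design: DesignSpec = field(default_factory=DesignSpec)
    sim: SimConfig = field(default_factory=SimConfig)
    # GLM options
    glm_duration_s: float = 3.0
    vif_threshold: float = 2.5
    # mediation options
    n_boot: int = 10_000
    x_coding: str = "extremes"
    voxel_p: float = 0.001
    cluster_extent: int = 5
    connectivity: int = 26
    svc_radius_mm: float = 10.0
    svc_alpha: float = 0.05
    rois: tuple[RoiSpec, ...] = (RoiSpec("center", (0.0, 0.0, 0.0)),)
    # moderation options
    moderation_path: str = "a"
    moderation_n_boot: int = 2000
    # per-stage seeds
    seed_simulate: int = 11
    seed_mediate: int = 12
    seed_moderate: int = 13

    def reseed(self, base_seed: int) -> "RunConfig":
        """Derive all stage seeds (and the sim seed) from one base seed."""
        import copy
        import dataclasses
        cfg = copy.deepcopy(self)
        cfg.seed_simulate = (base_seed * 1000 + 1) % (2 ** 31)
        cfg.seed_mediate = (base_seed * 1000 + 2) % (2 ** 31)
        cfg.seed_moderate = (base_seed * 1000 + 3) % (2 ** 31)
        cfg.sim = dataclasses.replace(cfg.sim, seed=base_seed % (2 ** 31))
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"].pop("hrf", None)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "design" in d and not isinstance(d["design"], DesignSpec):
            des = dict(d["design"])
            for k in ("iti_jitter_s", "isi_jitter_s", "mid_jitter_s"):
                if k in des:
                    des[k] = tuple(des[k])
            d["design"] = DesignSpec(**des)
        if "sim" in d and not isinstance(d["sim"], SimConfig):
            simd = dict(d["sim"])
            if "grid_shape" in simd:
                simd["grid_shape"] = tuple(simd["grid_shape"])
            d["sim"] = SimConfig(**simd)
        if "rois" in d:
            d["rois"] = tuple(
                r if isinstance(r, RoiSpec)
                else RoiSpec(r["name"], tuple(r["center_mm"])) for r in d["rois"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _plain(obj):
    """Recursively convert tuples to lists so YAML round-trips cleanly."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
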