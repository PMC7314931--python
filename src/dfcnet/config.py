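"""Analysis configuration: every tunable the pipeline consumes, with the
study defaults, loadable from flat JSON or YAML."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

from ._utils import config_hash


@dataclass
class AnalysisConfig:
    """Flat pipeline configuration.

    Defaults are the study conditions: 35-TR windows at step 1 on 170
    retained volumes (TR 3 s), k-means over k = 2..12 with 50 restarts,
    voxel FWE alpha 0.01 with >= 50-voxel clusters inside a 0.9 gray-matter
    probability mask, edgewise alpha 0.05 per window, 5,000 permutations at
    group alpha 0.05, and the Broca/Wernicke 3-mm seeds.
    """

    window_length_tr: int = 35
    window_step_tr: int = 1
    tr_seconds: float = 3.0
    discard_volumes: int = 10
    bandpass_low_hz: float = 0.01
    bandpass_high_hz: float = 0.08
    k_min: int = 2
    k_max: int = 12
    kmeans_restarts: int = 50
    node_alpha: float = 0.01
    min_cluster_voxels: int = 50
    gm_prob_threshold: float = 0.9
    edge_alpha: float = 0.05
    group_alpha: float = 0.05
    n_perm: int = 5000
    master_seed: int = 0
    seed_broca: tuple = (-53.0, 20.0, 15.0)
    seed_wernicke: tuple = (-51.0, -51.0, 30.0)
    seed_radius_mm: float = 3.0
    run_preprocess: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("seed_broca", "seed_wernicke"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
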