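"""Run configuration: one flat, serializable record of every knob.

All stochastic stages derive their seeds from the single ``seed`` field via
a fixed spawning order, so a config fully determines a run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml


@dataclass
class RunConfig:
    # design
    n_real_sets: int = 33
    n_catch_sets: int = 6
    n_runs: int = 14
    # generator
    n_subjects: int = 18
    n_sensors: int = 64
    sampling_rate: float = 100.0
    band: str = "erf"
    amp_stim: float = 6.0
    amp_rec: float = 6.0
    amp_att: float = 4.0
    amp_evoked: float = 8.0
    noise_scale: float = 1.0
    # behavior
    p_spontaneous: float = 0.34
    p_post_recognize: float = 0.87
    lapse: float = 0.1
    # analysis
    subset: str = "all"  # all | subjective | verbal | catch
    decoder_cost: float = 1.0
    metric: str = "one_minus_r"
    roi_profiles: dict = field(
        default_factory=lambda: {
            "V1": [1.0, 0.1, 0.05],
            "LOC": [0.7, 0.5, 0.2],
            "Frontal": [0.15, 1.0, 0.3],
            "Parietal": [0.1, 0.3, 1.0],
        }
    )
    # inference
    n_perm_decoding: int = 500
    n_perm_rdm: int = 5000
    n_perm_model: int = 1000
    # master seed
    seed: int = 0

    def stage_seeds(self) -> dict[str, int]:
        """Named per-stage child seeds derived from the master seed."""
        rng = np.random.default_rng(self.seed)
        names = (
            "design",
            "ground_truth",
            "epochs",
            "behavior",
            "roi",
            "decoding_stats",
            "rdm_stats",
            "model_stats",
            "fusion",
        )
        return {n: int(rng.integers(0, 2**31 - 1)) for n in names}

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f)
        return cls(**data)
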