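"""Run configuration: a fully serializable description of one pipeline run.

Every stochastic stage derives its random stream from the global seed plus
a stage tag, so a config reproduces a run bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict

import numpy as np
import yaml

from .optics import OpticalModel

__all__ = ["RunConfig", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the global seed."""
    h = np.uint32(2166136261)
    for b in f"{stage}:{global_seed}".encode():
        h = np.uint32((int(h) ^ b) * 16777619 & 0xFFFFFFFF)
    return int(h % np.uint32(2**31))


@dataclass
class RunConfig:
    """Small end-to-end pipeline configuration (defaults run in seconds)."""

    # optics
    na: float = 0.16
    focal_length_mm: float = 1.0
    conjugate_mm: float = 6.0
    wavelengths_nm: tuple = (470.0, 530.0, 590.0)
    pixel_pitch_um: float = 3.0
    depth_range_um: float = 150.0
    depth_step_um: float = 75.0
    alpha: float = 0.01
    psf_size: int = 65
    field_grid_side: int = 3
    field_grid_radius: float = 0.7
    # factorization
    rank: int = 9
    nmf_iterations: int = 100
    channel_uniform: bool = True
    # scenes
    n_scenes: int = 1
    scene_kind: str = "mixed"
    scene_size: int = 128
    scene_density: float = 0.05
    # noise (empty dict = noiseless)
    noise: dict = dc_field(default_factory=dict)
    # deconvolution
    deconv_method: str = "rltv"
    lambda_tv: float = 0.00015
    deconv_iterations: int = 20
    # bookkeeping
    seed: int = 0
    out_dir: str = "run_out"

    def optical_model(self) -> OpticalModel:
        return OpticalModel(
            na=self.na, focal_length_mm=self.focal_length_mm,
            conjugate_mm=self.conjugate_mm,
            wavelengths_nm=tuple(self.wavelengths_nm),
            pixel_pitch_um=self.pixel_pitch_um,
            depth_range_um=self.depth_range_um,
            depth_step_um=self.depth_step_um)

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["wavelengths_nm"] = list(self.wavelengths_nm)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as f:
                    data = yaml.safe_load(f)
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        data["wavelengths_nm"] = tuple(data.get("wavelengths_nm",
                                                (470.0, 530.0, 590.0)))
        return cls(**data)
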