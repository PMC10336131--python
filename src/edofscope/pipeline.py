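"""End-to-end orchestration: simulate PSFs, factorize, build training
pairs, deconvolve, evaluate — writing every artifact plus a checksum
manifest so reruns with the same config are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np

from . import io as eio
from .config import RunConfig, stage_seed
from .deconvolution import DeconvParams, admm_tv_deconv, rl_tv_shift_variant
from .factorization import assemble_psf_matrix, hals_nmf
from .metrics import psnr, ssim
from .optics import CubicPhaseMask, field_grid, simulate_psf_grid
from .training_data import make_training_pair, synth_scene

__all__ = ["run_pipeline", "content_checksum"]


def content_checksum(path) -> str:
    """SHA-256 over the file's array/JSON content (not raw bytes), so the
    hash is independent of container-level metadata."""
    path = Path(path)
    h = hashlib.sha256()
    if path.suffix in (".tif", ".tiff"):
        arr = eio.read_image(path)
        h.update(np.ascontiguousarray(arr).tobytes())
        h.update(str(arr.shape).encode())
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            def visit(name, obj):
                if isinstance(obj, h5py.Dataset):
                    h.update(name.encode())
                    h.update(np.ascontiguousarray(obj[()]).tobytes())
            f.visititems(visit)
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage, exc):
        super().__init__(f"pipeline stage '{stage}' failed: {exc}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate-psf -> factorize -> make-pairs -> deconvolve ->
    evaluate and return the artifact manifest (also written to
    ``manifest.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = config.optical_model()
    mask = CubicPhaseMask(config.alpha,
                          semi_diameter=model.pupil_semidiameter_mm) \
        if config.alpha else None
    files = []
    stage = "simulate-psf"
    try:
        fuv = field_grid(config.field_grid_side, config.field_grid_radius)
        grid = simulate_psf_grid(model, mask, fuv, size=config.psf_size)
        psf_path = out / "psfs.h5"
        eio.write_psf_grid(psf_path, grid)
        files.append(psf_path)

        stage = "factorize"
        bases = {}
        for zi, z in enumerate(grid.z_um):
            pm = assemble_psf_matrix(grid.data[:, zi], grid.field_uv)
            bm = hals_nmf(pm, config.rank, config.nmf_iterations,
                          seed=stage_seed(config.seed, f"nmf{zi}"),
                          channel_uniform=config.channel_uniform)
            bm.z_um = float(z)
            bases[float(z)] = bm
        basis_path = out / "basis.h5"
        eio.write_bases(basis_path, bases)
        files.append(basis_path)

        stage = "make-pairs"
        results = []
        for si in range(config.n_scenes):
            scene = synth_scene(config.scene_kind, config.scene_size,
                                config.scene_density,
                                seed=stage_seed(config.seed, f"scene{si}"),
                                depth_range_um=config.depth_range_um,
                                pixel_pitch_um=config.pixel_pitch_um)
            pair = make_training_pair(scene, model, bases,
                                      noise=config.noise or None,
                                      seed=stage_seed(config.seed, f"noise{si}"))
            in_path = out / f"input_{si:03d}.tif"
            lb_path = out / f"label_{si:03d}.tif"
            eio.write_image(in_path, pair.input)
            eio.write_image(lb_path, pair.label)
            files.extend([in_path, lb_path])
            results.append((si, pair, bases))

        stage = "deconvolve"
        params = DeconvParams(lambda_tv=config.lambda_tv,
                              iterations=config.deconv_iterations)
        estimates = []
        for si, pair, bs in results:
            if config.deconv_method == "rltv":
                mid = sorted(bs)[len(bs) // 2]
                est, _ = rl_tv_shift_variant(pair.input, bs[mid], params)
            else:
                mid = sorted(bs)[len(bs) // 2]
                from .factorization import reconstruct_psf
                est = np.stack([
                    admm_tv_deconv(pair.input[c],
                                   reconstruct_psf(bs[mid], 0, channel=min(
                                       c, bs[mid].n_channels - 1)),
                                   params)[0]
                    for c in range(pair.input.shape[0])])
            est_path = out / f"estimate_{si:03d}.tif"
            eio.write_image(est_path, est)
            files.append(est_path)
            estimates.append((si, pair, est))

        stage = "evaluate"
        report = {}
        for si, pair, est in estimates:
            peak = float(max(pair.label.max(), 1e-12))
            report[f"scene_{si:03d}"] = {
                "psnr_capture_db": psnr(pair.input, pair.label, peak),
                "psnr_estimate_db": psnr(est, pair.label, peak),
                "ssim_capture": np.mean([ssim(pair.input[c], pair.label[c])
                                         for c in range(pair.label.shape[0])]),
                "ssim_estimate": np.mean([ssim(est[c], pair.label[c])
                                          for c in range(pair.label.shape[0])]),
            }
        rep_path = out / "report.json"
        rep_path.write_text(json.dumps(report, indent=2, sort_keys=True))
        files.append(rep_path)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest = {
        "config": json.loads(json.dumps(yaml_dict(config))),
        "files": {p.name: content_checksum(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest


def yaml_dict(config: RunConfig) -> dict:
    import yaml
    return yaml.safe_load(config.to_yaml())
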