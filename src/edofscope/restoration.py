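"""Restoration network family: architecture descriptions, parameter
accounting, channel pruning reports, losses, and a toy trainer.

The generator is a U-Net: four 4x4 stride-2 convolution encoder blocks
(LeakyReLU), a residual bottleneck (two 3x3 convolutions per block with a
shortcut), and four decoder blocks (bilinear upsample + 3x3 convolution,
ReLU) with skip connections fused by channel concatenation.  The
discriminator is the standard 70x70 PatchGAN.  Layer graphs and parameter
counts are pure functions of the spec — no deep-learning framework is
needed to build or count them; the optional toy trainer requires torch.

Counting convention: convolution weights plus biases, generator only,
no normalization layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = [
    "LayerSpec",
    "NetworkDescription",
    "GeneratorSpec",
    "PruneReport",
    "MissingDependencyError",
    "build_generator",
    "build_discriminator",
    "prune_report",
    "composite_loss",
    "train_toy",
]


class MissingDependencyError(ImportError):
    pass


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a network description."""

    name: str
    kind: str              # conv | upsample | concat | activation
    kernel: int = 0
    stride: int = 1
    in_channels: int = 0
    out_channels: int = 0

    @property
    def parameters(self) -> int:
        if self.kind != "conv":
            return 0
        return self.kernel ** 2 * self.in_channels * self.out_channels \
            + self.out_channels


@dataclass
class NetworkDescription:
    layers: list

    @property
    def parameter_count(self) -> int:
        return sum(l.parameters for l in self.layers)

    @property
    def receptive_field(self) -> int:
        """Receptive field of one output unit, from the convolution chain
        (skip/parallel branches ignored)."""
        rf = 1
        for layer in reversed([l for l in self.layers if l.kind == "conv"]):
            rf = rf * layer.stride + (layer.kernel - layer.stride)
        return rf

    def conv_widths(self) -> list:
        return [(l.name, l.in_channels, l.out_channels)
                for l in self.layers if l.kind == "conv"]


@dataclass(frozen=True)
class GeneratorSpec:
    """U-Net generator hyper-parameters.

    ``decoder_widths`` defaults to the mirror of the encoder with the last
    stage at half the first encoder width (the full-resolution stage has no
    skip partner); ``residual_width`` defaults to the bottleneck width.
    """

    encoder_widths: tuple = (128, 256, 512, 512)
    residual_blocks: int = 9
    residual_width: int | None = None
    decoder_widths: tuple | None = None
    in_channels: int = 3
    out_channels: int = 3
    encoder_kernel: int = 4
    decoder_kernel: int = 3
    residual_kernel: int = 3
    skip_connections: bool = True
    output_activation: str = "tanh"

    def __post_init__(self):
        if len(self.encoder_widths) != 4:
            raise ValueError("four encoder blocks expected")
        if any(w <= 0 for w in self.encoder_widths):
            raise ValueError("encoder widths must be positive")
        if self.residual_blocks < 0:
            raise ValueError("residual block count must be >= 0")

    @property
    def res_width(self) -> int:
        return self.residual_width or self.encoder_widths[-1]

    @property
    def dec_widths(self) -> tuple:
        if self.decoder_widths is not None:
            if len(self.decoder_widths) != 4:
                raise ValueError("four decoder blocks expected")
            return tuple(self.decoder_widths)
        e = self.encoder_widths
        return (e[2], e[1], e[0], max(e[0] // 2, 1))


def build_generator(spec: GeneratorSpec) -> NetworkDescription:
    """Layer graph of the U-Net generator (input size divisible by 16)."""
    layers = []
    e = spec.encoder_widths
    c = spec.in_channels
    for i, w in enumerate(e):
        layers.append(LayerSpec(f"enc{i + 1}", "conv", spec.encoder_kernel, 2, c, w))
        layers.append(LayerSpec(f"enc{i + 1}_lrelu", "activation"))
        c = w
    rw = spec.res_width
    if spec.residual_blocks and rw != c:
        # channel adapter when the bottleneck width differs from enc4
        layers.append(LayerSpec("res_in", "conv", 1, 1, c, rw))
        c = rw
    for b in range(spec.residual_blocks):
        layers.append(LayerSpec(f"res{b + 1}_conv1", "conv", spec.residual_kernel, 1, c, rw))
        layers.append(LayerSpec(f"res{b + 1}_relu", "activation"))
        layers.append(LayerSpec(f"res{b + 1}_conv2", "conv", spec.residual_kernel, 1, rw, rw))
        layers.append(LayerSpec(f"res{b + 1}_skip", "concat"))
    # decoder: upsample + conv; skips concatenate enc3, enc2, enc1 features
    skips = [e[2], e[1], e[0], 0] if spec.skip_connections else [0, 0, 0, 0]
    for i, w in enumerate(spec.dec_widths):
        layers.append(LayerSpec(f"dec{i + 1}_up", "upsample"))
        cin = c + skips[i]
        if skips[i]:
            layers.append(LayerSpec(f"dec{i + 1}_skip", "concat"))
        layers.append(LayerSpec(f"dec{i + 1}", "conv", spec.decoder_kernel, 1, cin, w))
        layers.append(LayerSpec(f"dec{i + 1}_relu", "activation"))
        c = w
    layers.append(LayerSpec("out", "conv", spec.decoder_kernel, 1, c, spec.out_channels))
    layers.append(LayerSpec(f"out_{spec.output_activation}", "activation"))
    return NetworkDescription(layers)


def build_discriminator(in_channels: int = 6,
                        widths=(64, 128, 256, 512)) -> NetworkDescription:
    """Standard PatchGAN: 4x4 convolutions, strides (2, 2, 2, 1, 1); the
    output is a patch map whose units have a 70x70 receptive field."""
    layers = []
    c = in_channels
    strides = [2, 2, 2, 1]
    for i, (w, s) in enumerate(zip(widths, strides)):
        layers.append(LayerSpec(f"d{i + 1}", "conv", 4, s, c, w))
        layers.append(LayerSpec(f"d{i + 1}_lrelu", "activation"))
        c = w
    layers.append(LayerSpec("d_out", "conv", 4, 1, c, 1))
    return NetworkDescription(layers)


@dataclass(frozen=True)
class PruneReport:
    full_parameters: int
    pruned_parameters: int

    @property
    def reduction(self) -> float:
        return 1.0 - self.pruned_parameters / self.full_parameters

    @property
    def unchanged(self) -> bool:
        return self.pruned_parameters == self.full_parameters


def prune_report(full: GeneratorSpec, pruned: GeneratorSpec) -> PruneReport:
    """Parameter-reduction report between a full and a channel-pruned
    generator of identical topology."""
    if (full.residual_blocks != pruned.residual_blocks
            or full.skip_connections != pruned.skip_connections):
        raise ValueError("generator topologies differ; pruning only changes widths")
    nf = build_generator(full).parameter_count
    np_ = build_generator(pruned).parameter_count
    return PruneReport(nf, np_)


def composite_loss(output: np.ndarray, label: np.ndarray,
                   weights: dict | None = None, discriminator=None,
                   feature_extractor=None):
    """Weighted GAN + L2 + perceptual loss.

    ``weights`` maps {"gan", "l2", "perceptual"} to non-negative floats
    (defaults: l2 = 1, others 0).  The GAN term is least-squares
    (``mean((D(output) - 1)^2)``) and needs ``discriminator``; the
    perceptual term is the mean squared feature distance and needs
    ``feature_extractor``.  A zero weight disables a term and its
    dependency.  Returns ``(total, breakdown)``.
    """
    output = np.asarray(output, dtype=float)
    label = np.asarray(label, dtype=float)
    if output.shape != label.shape:
        raise ValueError("output/label shape mismatch")
    w = {"gan": 0.0, "l2": 1.0, "perceptual": 0.0}
    if weights:
        w.update(weights)
    breakdown = {}
    if w["l2"]:
        breakdown["l2"] = w["l2"] * float(np.mean((output - label) ** 2))
    if w["gan"]:
        if discriminator is None:
            raise ValueError("gan weight > 0 requires a discriminator callable")
        d = np.asarray(discriminator(output), dtype=float)
        breakdown["gan"] = w["gan"] * float(np.mean((d - 1.0) ** 2))
    if w["perceptual"]:
        if feature_extractor is None:
            raise ValueError("perceptual weight > 0 requires a feature extractor")
        fo = np.asarray(feature_extractor(output), dtype=float)
        fl = np.asarray(feature_extractor(label), dtype=float)
        breakdown["perceptual"] = w["perceptual"] * float(np.mean((fo - fl) ** 2))
    total = float(sum(breakdown.values()))
    return total, breakdown


def _torch_generator(spec: GeneratorSpec):
    import torch
    from torch import nn

    class Res(nn.Module):
        def __init__(self, w, k):
            super().__init__()
            p = k // 2
            self.c1 = nn.Conv2d(w, w, k, padding=p)
            self.c2 = nn.Conv2d(w, w, k, padding=p)

        def forward(self, x):
            return x + self.c2(torch.relu(self.c1(x)))

    class Gen(nn.Module):
        def __init__(self):
            super().__init__()
            e = spec.encoder_widths
            k = spec.encoder_kernel
            self.encs = nn.ModuleList()
            c = spec.in_channels
            for w in e:
                self.encs.append(nn.Conv2d(c, w, k, stride=2, padding=k // 2 - 1))
                c = w
            rw = spec.res_width
            self.adapt = nn.Conv2d(c, rw, 1) if rw != c else nn.Identity()
            self.res = nn.Sequential(*[Res(rw, spec.residual_kernel)
                                       for _ in range(spec.residual_blocks)])
            dk = spec.decoder_kernel
            skips = [e[2], e[1], e[0], 0] if spec.skip_connections else [0] * 4
            self.decs = nn.ModuleList()
            c = rw
            for w, sk in zip(spec.dec_widths, skips):
                self.decs.append(nn.Conv2d(c + sk, w, dk, padding=dk // 2))
                c = w
            self.out = nn.Conv2d(c, spec.out_channels, dk, padding=dk // 2)
            self.act = torch.tanh if spec.output_activation == "tanh" else torch.sigmoid

        def forward(self, x):
            import torch.nn.functional as F
            feats = []
            for enc in self.encs:
                x = F.leaky_relu(enc(x), 0.2)
                feats.append(x)
            x = self.res(self.adapt(x))
            skips = [feats[2], feats[1], feats[0], None]
            for dec, sk in zip(self.decs, skips):
                x = F.interpolate(x, scale_factor=2, mode="bilinear",
                                  align_corners=False)
                if sk is not None:
                    x = torch.cat([x, sk], dim=1)
                x = torch.relu(dec(x))
            return self.act(self.out(x))

    return Gen()


def train_toy(pairs, spec: GeneratorSpec, epochs: int = 30, seed: int = 0,
              lr: float = 2e-4, betas=(0.9, 0.999)):
    """Small-scale L2 training of the generator on (input, label) pairs.

    ``pairs`` is a sequence of ((C, H, W), (C, H, W)) arrays with H, W
    divisible by 16.  Requires the optional torch dependency; raises
    :class:`MissingDependencyError` with installation advice otherwise.
    Returns ``(state_dict, loss_trace)``; ``epochs == 0`` returns the
    initial weights untouched.
    """
    try:
        import torch
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise MissingDependencyError(
            "train_toy requires torch; install the 'torch' extra "
            "(pip install edofscope[torch]) to enable network training"
        ) from exc
    if len(pairs) < 4:
        raise ValueError("at least 4 training pairs required")
    torch.manual_seed(seed)
    gen = _torch_generator(spec)
    opt = torch.optim.AdamW(gen.parameters(), lr=lr, betas=tuple(betas))
    xs = torch.stack([torch.as_tensor(np.asarray(a), dtype=torch.float32)
                      for a, _ in pairs])
    ys = torch.stack([torch.as_tensor(np.asarray(b), dtype=torch.float32)
                      for _, b in pairs])
    trace = []
    for _ in range(epochs):
        opt.zero_grad()
        loss = torch.mean((gen(xs) - ys) ** 2)
        loss.backward()
        opt.step()
        trace.append(float(loss.detach()))
    return gen.state_dict(), trace
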