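"""Minimal reimplementations of the three evaluation backbones.

Three contract-conforming EEG classification networks, each consuming raw
(batch, C, TP) epochs and returning (batch, n_classes) scores:

* ``shallow`` — temporal convolution, spatial convolution, squared-signal
  average pooling with a log nonlinearity, dense classifier (the
  FBCSP-inspired shallow architecture).
* ``deep`` — four convolution/max-pool blocks (the first split into a
  temporal and a spatial convolution) and a dense classifier.  For inputs
  too short for the standard temporal cascade, per-block temporal kernels
  and pools shrink to the largest sizes that fit, and the resolved
  architecture is reported on the instance.
* ``compact`` — a depthwise/separable-convolution network without a hidden
  dense layer, at least an order of magnitude fewer parameters than the
  other two at comparable input sizes.

Class scores are raw logits; softmax lives inside the loss.  A registry
enumerates the nine run configurations per montage layout: each backbone in
its original form and with a TRM-(5,5) or TRM-(3,3) front-end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .montage import MontageGrid
from .trm import CombinedNetwork, build_trm

__all__ = [
    "BackboneSpec",
    "build_backbone",
    "registry_list",
    "resolve_identifier",
    "build_from_registry",
    "BACKBONE_NAMES",
    "TRM_VARIANTS",
]

BACKBONE_NAMES = ("shallow", "deep", "compact")
TRM_VARIANTS = (None, 5, 3)


@dataclass(frozen=True)
class BackboneSpec:
    """Input contract plus a seed; architecture hyperparameters are the
    published defaults of the respective reference designs."""

    name: str
    expected_channels: int
    expected_timepoints: int
    n_classes: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in BACKBONE_NAMES:
            raise LookupError(
                f"unknown backbone {self.name!r}; available: {list(BACKBONE_NAMES)}"
            )
        if min(self.expected_channels, self.expected_timepoints, self.n_classes) < 1:
            raise ValueError("channels, timepoints and n_classes must be >= 1")


class _To4D(nn.Module):
    """(N, C, TP) -> (N, 1, C, TP): treat the raw epoch as a 1-channel image."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x[:, None, :, :]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad[:, 0, :, :]


class _Backbone(nn.Module):
    """Common shell: contract attributes + an internal Sequential."""

    def __init__(self, spec: BackboneSpec, net: nn.Sequential, architecture: dict):
        self.spec = spec
        self.name = spec.name
        self.expected_channels = spec.expected_channels
        self.expected_timepoints = spec.expected_timepoints
        self.n_classes = spec.n_classes
        self.net = net
        self.architecture = architecture  # resolved layer sizes, loggable

    def children(self):
        return [self.net]

    def parameters(self) -> list[nn.Parameter]:
        return self.net.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != self.expected_channels:
            raise ValueError(
                f"{self.name} expects (batch, {self.expected_channels}, TP) input, "
                f"got {x.shape}"
            )
        return self.net.forward(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)


def _build_shallow(spec: BackboneSpec) -> _Backbone:
    c, tp, k = spec.expected_channels, spec.expected_timepoints, spec.n_classes
    t_kernel, pool, stride, filters = 25, 75, 15, 40
    t_conv = tp - t_kernel + 1
    if t_conv < pool:
        raise ValueError(
            f"shallow backbone needs TP >= {t_kernel + pool - 1}, got {tp}"
        )
    t_pool = (t_conv - pool) // stride + 1
    rng = np.random.default_rng(spec.seed)
    net = nn.Sequential(
        _To4D(),
        nn.Conv2d(1, filters, (1, t_kernel), bias=True, rng=rng, name="shallow.tconv"),
        nn.Conv2d(filters, filters, (c, 1), bias=False, rng=rng, name="shallow.sconv"),
        nn.BatchNorm2d(filters, name="shallow.bn"),
        nn.Square(),
        nn.AvgPool2d((1, pool), (1, stride)),
        nn.SafeLog(),
        nn.Dropout(0.5, rng=rng),
        nn.Flatten(),
        nn.Linear(filters * t_pool, k, rng=rng, name="shallow.fc"),
    )
    arch = {"filters": filters, "temporal_kernel": t_kernel, "pool": pool,
            "pool_stride": stride, "pooled_timepoints": t_pool}
    return _Backbone(spec, net, arch)


def _deep_cascade(tp: int, t_kernel: int, pool: int) -> list[tuple[int, int, int]]:
    """Per-block (kernel_t, pool_t, out_t) for the four-block deep cascade,
    shrinking kernels/pools where the remaining length is too short."""
    blocks = []
    t = tp
    for _ in range(4):
        kt = min(t_kernel, t)
        t = t - kt + 1
        pt = min(pool, t)
        t = (t - pt) // pt + 1
        blocks.append((kt, pt, t))
    return blocks


def _build_deep(spec: BackboneSpec, *, adaptive: bool = True) -> _Backbone:
    c, tp, k = spec.expected_channels, spec.expected_timepoints, spec.n_classes
    t_kernel, pool, filters = 10, 3, (25, 50, 100, 200)
    blocks = _deep_cascade(tp, t_kernel, pool)
    if not adaptive and any(kt < t_kernel or pt < pool for kt, pt, _ in blocks):
        min_tp = next(
            t for t in range(t_kernel, 4096)
            if all(kt == t_kernel and pt == pool for kt, pt, _ in _deep_cascade(t, t_kernel, pool))
        )
        raise ValueError(
            f"deep backbone (non-adaptive) needs TP >= {min_tp}, got {tp}"
        )
    rng = np.random.default_rng(spec.seed)
    layers: list[nn.Module] = [_To4D()]
    kt0, pt0, _ = blocks[0]
    layers += [
        nn.Conv2d(1, filters[0], (1, kt0), bias=True, rng=rng, name="deep.tconv"),
        nn.Conv2d(filters[0], filters[0], (c, 1), bias=False, rng=rng, name="deep.sconv"),
        nn.BatchNorm2d(filters[0], name="deep.bn0"),
        nn.ELU(),
        nn.MaxPool2d((1, pt0), (1, pt0)),
        nn.Dropout(0.5, rng=rng),
    ]
    for i in range(1, 4):
        kt, pt, _ = blocks[i]
        layers += [
            nn.Conv2d(filters[i - 1], filters[i], (1, kt), bias=False, rng=rng,
                      name=f"deep.conv{i}"),
            nn.BatchNorm2d(filters[i], name=f"deep.bn{i}"),
            nn.ELU(),
            nn.MaxPool2d((1, pt), (1, pt)),
            nn.Dropout(0.5, rng=rng),
        ]
    out_t = blocks[-1][2]
    layers += [nn.Flatten(), nn.Linear(filters[-1] * out_t, k, rng=rng, name="deep.fc")]
    arch = {"filters": filters, "blocks": blocks, "final_timepoints": out_t}
    return _Backbone(spec, nn.Sequential(*layers), arch)


def _build_compact(spec: BackboneSpec) -> _Backbone:
    c, tp, k = spec.expected_channels, spec.expected_timepoints, spec.n_classes
    f1, d, f2, t_kernel, sep_kernel = 8, 2, 16, 64, 16
    if tp < 32:
        raise ValueError(f"compact backbone needs TP >= 32, got {tp}")
    out_t = (tp // 4) // 8
    rng = np.random.default_rng(spec.seed)
    net = nn.Sequential(
        _To4D(),
        nn.Conv2d(1, f1, (1, t_kernel), bias=False, padding="same", rng=rng,
                  name="compact.tconv"),
        nn.BatchNorm2d(f1, name="compact.bn0"),
        nn.DepthwiseConv2d(f1, d, (c, 1), bias=False, rng=rng, name="compact.dwconv"),
        nn.BatchNorm2d(f1 * d, name="compact.bn1"),
        nn.ELU(),
        nn.AvgPool2d((1, 4)),
        nn.Dropout(0.5, rng=rng),
        nn.DepthwiseConv2d(f1 * d, 1, (1, sep_kernel), bias=False, padding="same",
                           rng=rng, name="compact.sepdw"),
        nn.Conv2d(f1 * d, f2, (1, 1), bias=False, rng=rng, name="compact.seppw"),
        nn.BatchNorm2d(f2, name="compact.bn2"),
        nn.ELU(),
        nn.AvgPool2d((1, 8)),
        nn.Dropout(0.5, rng=rng),
        nn.Flatten(),
        nn.Linear(f2 * out_t, k, rng=rng, name="compact.fc"),
    )
    arch = {"F1": f1, "D": d, "F2": f2, "temporal_kernel": t_kernel,
            "separable_kernel": sep_kernel, "pooled_timepoints": out_t}
    return _Backbone(spec, net, arch)


_BUILDERS = {"shallow": _build_shallow, "deep": _build_deep, "compact": _build_compact}


def build_backbone(spec: BackboneSpec) -> _Backbone:
    """Build the backbone described by ``spec``; deterministic given its seed."""
    return _BUILDERS[spec.name](spec)


def registry_list() -> list[str]:
    """The nine run configurations per layout: backbone x {original, trm-5, trm-3}."""
    ids = []
    for name in BACKBONE_NAMES:
        for k in TRM_VARIANTS:
            ids.append(name if k is None else f"{name}+trm-{k}")
    return ids


def resolve_identifier(identifier: str) -> tuple[str, int | None]:
    """Split a registry id into (backbone_name, trm_base_kernel_or_None)."""
    if identifier not in registry_list():
        raise LookupError(
            f"unknown run configuration {identifier!r}; available: {registry_list()}"
        )
    if "+" not in identifier:
        return identifier, None
    name, variant = identifier.split("+", 1)
    return name, int(variant.split("-", 1)[1])


def build_from_registry(
    identifier: str,
    montage: MontageGrid,
    timepoints: int,
    n_classes: int,
    *,
    seed: int = 0,
) -> nn.Module:
    """Instantiate a registry configuration for a montage and input length."""
    name, k = resolve_identifier(identifier)
    spec = BackboneSpec(name, montage.n_channels, timepoints, n_classes, seed=seed)
    backbone = build_backbone(spec)
    if k is None:
        return backbone
    trm = build_trm(montage, k, seed=seed + 1)
    return CombinedNetwork(trm, backbone)
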