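"""The topographic representation module (TRM).

The TRM is a size-preserving front-end for EEG classification networks.  Its
forward pass (i) maps each raw epoch (C channels x TP time points) onto an
H x W scalp grid, one 2-D topographic map per time point, with unassigned
cells zero-filled; (ii) reduces every map to a single value per channel with
a stack of stride-1 valid 2-D convolutions whose kernel sizes follow a fixed
schedule derived from the grid size and a base kernel k (5x5 or 3x3); and
(iii) applies batch normalization and reshapes back to C x TP.  Because the
output has exactly the input's shape, the TRM can be prepended to any
network that consumes raw C x TP epochs without touching that network.

Kernel-size rule: starting from the full grid, while the current feature map
exceeds k in some dimension, use a (min(k, h), min(k, w)) kernel; once the
feature map is no larger than k x k, use a kernel of exactly the feature-map
size, which terminates the stack at 1 x 1.  Every layer outputs C feature
maps; the first layer sees a single input channel (the topographic map).

Under the default policy — bias-free convolutions and a single affine
channel normalization after the stack — the trainable-parameter total has
the closed form  C·k1h·k1w + Σ_{l≥2} C²·klh·klw + 2C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .montage import MontageGrid

__all__ = [
    "KernelSchedule",
    "TRMSpec",
    "plan_schedule",
    "count_parameters",
    "build_trm",
    "embed",
    "TRM",
    "CombinedNetwork",
]

NORM_POLICIES = ("final-affine", "per-layer-affine", "none")


@dataclass(frozen=True)
class KernelSchedule:
    """Ordered kernel sizes reducing an (H, W) grid to a 1x1 feature map.

    ``feature_maps[i]`` is the spatial size after ``layers[i]`` under
    stride-1 valid convolution; the last entry is always (1, 1).
    """

    base_kernel: int
    input_grid: tuple[int, int]
    layers: tuple[tuple[int, int], ...]
    feature_maps: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("schedule must contain at least one layer")
        h, w = self.input_grid
        for (kh, kw), (fh, fw) in zip(self.layers, self.feature_maps):
            if not (1 <= kh <= h and 1 <= kw <= w):
                raise ValueError(
                    f"kernel ({kh},{kw}) does not fit feature map ({h},{w})"
                )
            if (fh, fw) != (h - kh + 1, w - kw + 1):
                raise ValueError("feature_maps inconsistent with valid-conv arithmetic")
            h, w = fh, fw
        if (h, w) != (1, 1):
            raise ValueError(f"schedule terminates at ({h},{w}), not (1,1)")

    @property
    def n_layers(self) -> int:
        return len(self.layers)


def plan_schedule(height: int, width: int, k: int = 5) -> KernelSchedule:
    """Derive the TRM kernel schedule for an ``height`` x ``width`` grid.

    Parameters
    ----------
    height, width : grid dimensions, each >= 1.
    k : base kernel size; 5 and 3 are the two standard choices.  Other odd
        sizes >= 1 are accepted with a warning.
    """
    if height < 1 or width < 1:
        raise ValueError(f"grid dimensions must be >= 1, got {height}x{width}")
    if k not in (3, 5):
        if k < 1 or k % 2 == 0:
            raise ValueError(f"base kernel must be a positive odd integer, got {k}")
        warnings.warn(
            f"base kernel {k} is nonstandard (the usual choices are 3 and 5)",
            stacklevel=2,
        )
    h, w = height, width
    layers: list[tuple[int, int]] = []
    fmaps: list[tuple[int, int]] = []
    while True:
        if h > k or w > k:
            kh, kw = min(k, h), min(k, w)
        else:
            kh, kw = h, w  # kernel == feature map: next map is 1x1
        h, w = h - kh + 1, w - kw + 1
        layers.append((kh, kw))
        fmaps.append((h, w))
        if (h, w) == (1, 1):
            break
    return KernelSchedule(k, (height, width), tuple(layers), tuple(fmaps))


@dataclass(frozen=True)
class TRMSpec:
    """Full structural description of a TRM instance.

    Defaults (``conv_bias=False``, ``norm_policy='final-affine'``) are the
    policy under which the parameter total takes the closed form documented
    in the module docstring.
    """

    montage: MontageGrid
    base_kernel: int = 5
    conv_bias: bool = False
    norm_policy: str = "final-affine"
    schedule: KernelSchedule = field(init=False)

    def __post_init__(self) -> None:
        if self.norm_policy not in NORM_POLICIES:
            raise ValueError(
                f"norm_policy must be one of {NORM_POLICIES}, got {self.norm_policy!r}"
            )
        object.__setattr__(
            self,
            "schedule",
            plan_schedule(self.montage.height, self.montage.width, self.base_kernel),
        )

    @property
    def channels(self) -> int:
        return self.montage.n_channels

    @property
    def trainable_parameter_count(self) -> int:
        return count_parameters(self)


def count_parameters(spec: TRMSpec) -> int:
    """Exact trainable-parameter total of the TRM described by ``spec``.

    Computed in closed form from the schedule; must (and, in the test suite,
    does) agree with brute-force enumeration of the assembled module's
    trainable arrays.
    """
    c = spec.channels
    total = 0
    for i, (kh, kw) in enumerate(spec.schedule.layers):
        in_ch = 1 if i == 0 else c
        total += c * in_ch * kh * kw
        if spec.conv_bias:
            total += c
    if spec.norm_policy == "final-affine":
        total += 2 * c
    elif spec.norm_policy == "per-layer-affine":
        total += 2 * c * spec.schedule.n_layers
    return total


class TRM(nn.Module):
    """Assembled topographic representation module.

    Input and output are (batch, C, TP); the input channel axis must follow
    the montage's canonical channel order.  Time is folded into the batch
    axis so the scheduled 2-D convolutions act identically and independently
    on every time point — the module is purely spatial and therefore
    equivariant to any permutation of time points.
    """

    def __init__(self, spec: TRMSpec, *, activation: str | None = None, seed: int = 0):
        self.spec = spec
        self.montage = spec.montage
        self.channels = spec.channels
        rng = np.random.default_rng(seed)
        rows, cols = self.montage.grid_indices()
        self._rows, self._cols = rows, cols
        c = self.channels
        layers: list[nn.Module] = []
        for i, (kh, kw) in enumerate(spec.schedule.layers):
            in_ch = 1 if i == 0 else c
            layers.append(
                nn.Conv2d(in_ch, c, (kh, kw), bias=spec.conv_bias, rng=rng,
                          name=f"trm.conv{i}")
            )
            if spec.norm_policy == "per-layer-affine":
                layers.append(nn.BatchNorm2d(c, name=f"trm.bn{i}"))
            if activation == "elu" and i < spec.schedule.n_layers - 1:
                layers.append(nn.ELU())
            elif activation not in (None, "identity", "elu"):
                raise ValueError(f"unknown activation {activation!r}")
        if spec.norm_policy == "final-affine":
            layers.append(nn.BatchNorm2d(c, name="trm.bn"))
        self.stack = nn.Sequential(*layers)

    def children(self):
        return [self.stack]

    def parameters(self) -> list[nn.Parameter]:
        return self.stack.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != self.channels:
            raise ValueError(
                f"expected (batch, {self.channels}, TP) input, got {x.shape}"
            )
        n, c, tp = x.shape
        self._in_shape = x.shape
        grid = np.zeros((n, tp, self.montage.height, self.montage.width), dtype=x.dtype)
        grid[:, :, self._rows, self._cols] = np.moveaxis(x, 1, 2)
        out = self.stack.forward(grid.reshape(n * tp, 1, self.montage.height, self.montage.width))
        return np.ascontiguousarray(np.moveaxis(out.reshape(n, tp, c), 2, 1))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, tp = self._in_shape
        g = np.moveaxis(grad, 1, 2).reshape(n * tp, c, 1, 1)
        dgrid = self.stack.backward(g).reshape(n, tp, self.montage.height, self.montage.width)
        return np.ascontiguousarray(
            np.moveaxis(dgrid[:, :, self._rows, self._cols], 2, 1)
        )


def build_trm(
    montage: MontageGrid,
    k: int = 5,
    *,
    conv_bias: bool = False,
    norm_policy: str = "final-affine",
    activation: str | None = None,
    seed: int = 0,
) -> TRM:
    """Build a TRM for ``montage`` with base kernel ``k``; see :class:`TRM`."""
    spec = TRMSpec(montage, k, conv_bias=conv_bias, norm_policy=norm_policy)
    return TRM(spec, activation=activation, seed=seed)


class CombinedNetwork(nn.Module):
    """A backbone with a TRM prepended; the backbone is untouched."""

    def __init__(self, trm: TRM, backbone: nn.Module):
        expected = getattr(backbone, "expected_channels", None)
        if expected is not None and expected != trm.channels:
            raise ValueError(
                f"composition error: TRM outputs {trm.channels} channels but the "
                f"backbone expects {expected}"
            )
        self.trm = trm
        self.backbone = backbone
        self.expected_channels = trm.channels
        self.expected_timepoints = getattr(backbone, "expected_timepoints", None)
        self.n_classes = getattr(backbone, "n_classes", None)

    def children(self):
        return [self.trm, self.backbone]

    def parameters(self) -> list[nn.Parameter]:
        return self.trm.parameters() + self.backbone.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.backbone.forward(self.trm.forward(x))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.trm.backward(self.backbone.backward(grad))


def embed(trm: TRM, backbone: nn.Module) -> CombinedNetwork:
    """Prepend ``trm`` to ``backbone``; parameter counts are additive."""
    return CombinedNetwork(trm, backbone)
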