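"""Declarative layer specifications and dimension propagation.

Spatial dimensions follow standard convolution/pooling arithmetic,
``out = floor((in + 2 * pad - kernel) / stride) + 1``, and fully connected
layers flatten ``width * height * depth`` of the previous activation.  Each
spec row may declare its expected output dimensions (and, for fully connected
rows, the expected flattened input size); :func:`propagate_dims` verifies the
computed dimensions against every declaration and raises a structural error
naming the first offending layer.
"""

from __future__ import annotations

from dataclasses import dataclass

from vineprep.errors import NetworkStructureError

__all__ = ["LayerSpec", "alexnet_layers", "small_backbone_layers",
           "propagate_dims"]

KINDS = ("input", "conv", "relu", "crossnorm", "maxpool", "fc", "dropout",
         "softmax", "classification")


@dataclass(frozen=True)
class LayerSpec:
    """One architecture row: kind, geometry and optional declared dims."""

    name: str
    kind: str
    depth: int | None = None  # conv out-channels / fc units
    kernel: int | None = None
    stride: int | None = None
    padding: int | None = None
    dropout_p: float | None = None
    out_dims: tuple[int, int, int] | None = None  # declared (width, height, depth)
    fc_in: int | None = None  # declared flattened input size

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("conv", "maxpool") and (
            self.kernel is None or self.stride is None
        ):
            raise ValueError(f"layer {self.name}: conv/pool rows need "
                             "kernel and stride")


def alexnet_layers(n_classes: int = 1000) -> list[LayerSpec]:
    """The 25-row reference architecture with its printed dimensions.

    ``n_classes`` resizes the classification head (final fc / softmax /
    classification rows); the five convolutional layers, three overlapping
    max-poolings, local response normalizations and two dropout layers keep
    the classic geometry (input 227 x 227 x 3, conv1 11/4/0 -> 55,
    pool 3/2 -> 27, fc6 input 6 * 6 * 256 = 9216).
    """
    L = LayerSpec
    head = n_classes
    return [
        L("data", "input", out_dims=(227, 227, 3)),
        L("conv1", "conv", 96, 11, 4, 0, out_dims=(55, 55, 96)),
        L("relu1", "relu", out_dims=(55, 55, 96)),
        L("norm1", "crossnorm", out_dims=(55, 55, 96)),
        L("pool1", "maxpool", kernel=3, stride=2, padding=0,
          out_dims=(27, 27, 96)),
        L("conv2", "conv", 256, 5, 1, 2, out_dims=(27, 27, 256)),
        L("relu2", "relu", out_dims=(27, 27, 256)),
        L("norm2", "crossnorm", out_dims=(27, 27, 256)),
        L("pool2", "maxpool", kernel=3, stride=2, padding=0,
          out_dims=(13, 13, 256)),
        L("conv3", "conv", 384, 3, 1, 1, out_dims=(13, 13, 384)),
        L("relu3", "relu", out_dims=(13, 13, 384)),
        L("conv4", "conv", 384, 3, 1, 1, out_dims=(13, 13, 384)),
        L("relu4", "relu", out_dims=(13, 13, 384)),
        L("conv5", "conv", 256, 3, 1, 1, out_dims=(13, 13, 256)),
        L("relu5", "relu", out_dims=(13, 13, 256)),
        L("pool5", "maxpool", kernel=3, stride=2, padding=0,
          out_dims=(6, 6, 256)),
        L("fc6", "fc", 4096, out_dims=(1, 1, 4096), fc_in=9216),
        L("relu6", "relu", out_dims=(1, 1, 4096)),
        L("drop6", "dropout", dropout_p=0.5, out_dims=(1, 1, 4096)),
        L("fc7", "fc", 4096, out_dims=(1, 1, 4096), fc_in=4096),
        L("relu7", "relu", out_dims=(1, 1, 4096)),
        L("drop7", "dropout", dropout_p=0.5, out_dims=(1, 1, 4096)),
        L("fc8", "fc", head, out_dims=(1, 1, head), fc_in=4096),
        L("prob", "softmax", out_dims=(1, 1, head)),
        L("output", "classification", out_dims=(1, 1, head)),
    ]


def small_backbone_layers(input_size: int = 32, n_classes: int = 6,
                          width: int = 8) -> list[LayerSpec]:
    """A reduced backbone with the same layer kinds for desk-scale training.

    Three convolutional layers (so the freeze-first-two scheme remains
    meaningful), one cross-channel normalization, two poolings, an fc6-
    analogue feature layer and a classification head.
    """
    L = LayerSpec
    return [
        L("data", "input", out_dims=(input_size, input_size, 3)),
        L("conv1", "conv", width, 5, 2, 0),
        L("relu1", "relu"),
        L("norm1", "crossnorm"),
        L("pool1", "maxpool", kernel=3, stride=2, padding=0),
        L("conv2", "conv", 2 * width, 3, 1, 1),
        L("relu2", "relu"),
        L("conv3", "conv", 2 * width, 3, 1, 1),
        L("relu3", "relu"),
        L("pool5", "maxpool", kernel=2, stride=2, padding=0),
        L("fc6", "fc", 6 * width),
        L("relu6", "relu"),
        L("fc8", "fc", n_classes),
        L("prob", "softmax"),
        L("output", "classification"),
    ]


def _spatial(inp: int, kernel: int, stride: int, padding: int) -> int:
    out = (inp + 2 * padding - kernel) // stride + 1
    if out < 1:
        raise NetworkStructureError(
            f"kernel {kernel}/stride {stride} does not fit input size {inp}"
        )
    return out


def propagate_dims(
    layers: list[LayerSpec],
    input_dims: tuple[int, int, int] = (227, 227, 3),
) -> list[tuple[int, int, int]]:
    """Compute (width, height, depth) after every layer; verify declarations.

    Raises :class:`NetworkStructureError` naming the layer whose declared
    ``out_dims`` (or ``fc_in``) disagrees with the computed arithmetic.
    """
    if not layers or layers[0].kind != "input":
        raise NetworkStructureError("layer list must start with an input row")
    dims: list[tuple[int, int, int]] = []
    cur = tuple(input_dims)
    for spec in layers:
        w, h, d = cur
        if spec.kind == "input":
            cur = tuple(input_dims)
        elif spec.kind == "conv":
            pad = spec.padding or 0
            cur = (
                _spatial(w, spec.kernel, spec.stride, pad),
                _spatial(h, spec.kernel, spec.stride, pad),
                spec.depth,
            )
        elif spec.kind == "maxpool":
            pad = spec.padding or 0
            cur = (
                _spatial(w, spec.kernel, spec.stride, pad),
                _spatial(h, spec.kernel, spec.stride, pad),
                d,
            )
        elif spec.kind == "fc":
            flat = w * h * d
            if spec.fc_in is not None and spec.fc_in != flat:
                raise NetworkStructureError(
                    f"layer {spec.name}: declared input size {spec.fc_in} "
                    f"but previous activation flattens to {flat}"
                )
            cur = (1, 1, spec.depth)
        elif spec.kind in ("relu", "crossnorm", "dropout", "softmax",
                           "classification"):
            cur = (w, h, d)
        if spec.out_dims is not None and tuple(spec.out_dims) != cur:
            raise NetworkStructureError(
                f"layer {spec.name}: declared dims {spec.out_dims} but "
                f"computed {cur}"
            )
        dims.append(cur)
    return dims
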