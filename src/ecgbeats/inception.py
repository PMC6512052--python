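"""Declarative 1-D inception network designs and their numpy realization.

Three designs are supported, all ending in two fully connected layers
([100, 50] units by default) and a 5-way softmax:

* **Design I** — one inception layer on the raw normalized beat.
* **Design II** — two stacked inception layers.
* **Design III** — a front convolution stage (15 filters, kernel 5,
  stride 1, no padding, followed by 2/2 max-pooling) and then one
  inception layer.

An inception layer runs parallel convolution branches with different
kernel sizes (basic [1, 3, 5]; expanded [10, 50, 100] to capture R–R-scale
timing structure) plus a stride-1 max-pool branch, concatenated along the
channel axis.  Branches use same-padding so their temporal lengths agree;
expanded kernels are only legal in the layer that sees the raw ECG input,
where absolute timing still has meaning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import CLASS_ORDER, ClassLabel
from .layers import (
    Conv1D,
    Dense,
    Flatten,
    InceptionLayer,
    Layer,
    MaxPool1D,
    ReLU,
    softmax,
)
from .segmentation import NormalizedBeat

__all__ = [
    "InceptionSpec",
    "ModelSpec",
    "NetworkInstance",
    "build_model",
    "BASIC_KERNELS",
    "EXPANDED_KERNELS",
]

BASIC_KERNELS = (1, 3, 5)
EXPANDED_KERNELS = (10, 50, 100)

#: kernel sizes above this are "expanded" and restricted to the input layer
_EXPANDED_THRESHOLD = 5


@dataclass(frozen=True)
class InceptionSpec:
    """One inception layer: branch kernel sizes, filters per branch, pool."""

    branch_kernel_sizes: tuple[int, ...] = BASIC_KERNELS
    filters_per_branch: int = 15
    pool_size: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "branch_kernel_sizes", tuple(self.branch_kernel_sizes)
        )
        if len(self.branch_kernel_sizes) < 1:
            raise ValueError("need at least one convolution branch")
        if any(k < 1 for k in self.branch_kernel_sizes):
            raise ValueError("kernel sizes must be positive")
        if self.filters_per_branch < 1:
            raise ValueError("filters_per_branch must be positive")
        if self.pool_size < 2:
            raise ValueError("pool_size must be >= 2")

    @property
    def is_expanded(self) -> bool:
        return max(self.branch_kernel_sizes) > _EXPANDED_THRESHOLD


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a Design I/II/III network."""

    design: str = "I"
    input_length: int = 200
    inception_specs: tuple[InceptionSpec, ...] = (InceptionSpec(),)
    cnn_filters: int = 15
    cnn_kernel: int = 5
    cnn_stride: int = 1
    cnn_pool_size: int = 2
    cnn_pool_stride: int = 2
    fc_widths: tuple[int, ...] = (100, 50)
    n_classes: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "inception_specs", tuple(self.inception_specs))
        object.__setattr__(self, "fc_widths", tuple(self.fc_widths))
        if self.design not in {"I", "II", "III"}:
            raise ValueError(f"design must be I, II or III, got {self.design!r}")
        need = 2 if self.design == "II" else 1
        if len(self.inception_specs) != need:
            raise ValueError(
                f"design {self.design} requires exactly {need} inception "
                f"spec(s), got {len(self.inception_specs)}"
            )
        if self.input_length < 2:
            raise ValueError("input_length must be >= 2")
        # expanded kernels only in the layer fed directly by the ECG input
        for i, spec in enumerate(self.inception_specs):
            first = i == 0 and self.design != "III"
            if spec.is_expanded and not first:
                raise ValueError(
                    "expanded kernel sizes are only allowed in the first "
                    "inception layer computed directly on the ECG input"
                )

    # ------------------------------------------------------------------
    @classmethod
    def design_i(
        cls, input_length: int = 200, filters: int = 15, expanded: bool = False
    ) -> "ModelSpec":
        kernels = EXPANDED_KERNELS if expanded else BASIC_KERNELS
        return cls(
            design="I",
            input_length=input_length,
            inception_specs=(
                InceptionSpec(branch_kernel_sizes=kernels, filters_per_branch=filters),
            ),
        )

    @classmethod
    def design_ii(
        cls, input_length: int = 200, filters: int = 15, expanded: bool = False
    ) -> "ModelSpec":
        first = EXPANDED_KERNELS if expanded else BASIC_KERNELS
        return cls(
            design="II",
            input_length=input_length,
            inception_specs=(
                InceptionSpec(branch_kernel_sizes=first, filters_per_branch=filters),
                InceptionSpec(filters_per_branch=filters),
            ),
        )

    @classmethod
    def design_iii(cls, input_length: int = 200, filters: int = 15) -> "ModelSpec":
        return cls(
            design="III",
            input_length=input_length,
            inception_specs=(InceptionSpec(filters_per_branch=filters),),
        )

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["inception_specs"] = tuple(
            InceptionSpec(**s) if isinstance(s, dict) else s
            for s in d["inception_specs"]
        )
        return cls(**d)


class NetworkInstance:
    """A built network: ordered layers plus the spec and seed that made it."""

    def __init__(self, spec: ModelSpec, layers: list[Layer], rng_seed: int):
        self.spec = spec
        self.layers = layers
        self.rng_seed = rng_seed

    # ------------------------------------------------------------------
    def _to_batch(self, batch) -> np.ndarray:
        if isinstance(batch, np.ndarray):
            x = batch
        else:
            x = np.stack([np.asarray(b.values, dtype=float) for b in batch])
        if x.ndim == 2:
            x = x[:, None, :]
        if x.shape[2] != self.spec.input_length:
            raise ValueError(
                f"input length {x.shape[2]} != model input_length "
                f"{self.spec.input_length}"
            )
        return x

    def forward_logits(self, batch) -> np.ndarray:
        x = self._to_batch(batch)
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def forward(self, batch) -> np.ndarray:
        """Class-probability matrix, one row per beat, rows summing to 1."""
        return softmax(self.forward_logits(batch))

    def backward(self, grad_logits: np.ndarray) -> None:
        g = grad_logits
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict(self, batch) -> list[ClassLabel]:
        idx = self.forward(batch).argmax(axis=1)
        return [CLASS_ORDER[i] for i in idx]

    # ------------------------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def zero_grad(self) -> None:
        for g in self.gradients():
            g[...] = 0.0

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write ``<path>.json`` (spec + seed + shapes) and ``<path>.npy``.

        The parameter vector is a single float64 .npy file, so identical
        models serialize to identical bytes.
        """
        path = Path(path)
        base = path.with_suffix("") if path.suffix in {".json", ".npy"} else path
        params = self.parameters()
        meta = {
            "spec": self.spec.to_dict(),
            "rng_seed": self.rng_seed,
            "shapes": [list(p.shape) for p in params],
        }
        base.parent.mkdir(parents=True, exist_ok=True)
        base.with_suffix(".json").write_text(json.dumps(meta, indent=1) + "\n")
        flat = np.concatenate([p.ravel() for p in params])
        np.save(base.with_suffix(".npy"), flat)

    @classmethod
    def load(cls, path: str | Path) -> "NetworkInstance":
        path = Path(path)
        base = path.with_suffix("") if path.suffix in {".json", ".npy"} else path
        meta = json.loads(base.with_suffix(".json").read_text())
        model = build_model(ModelSpec.from_dict(meta["spec"]), meta["rng_seed"])
        flat = np.load(base.with_suffix(".npy"))
        offset = 0
        for p in model.parameters():
            p[...] = flat[offset : offset + p.size].reshape(p.shape)
            offset += p.size
        if offset != flat.size:
            raise ValueError("parameter file does not match model spec")
        return model


def build_model(spec: ModelSpec, seed: int) -> NetworkInstance:
    """Instantiate a network from its spec with seeded Glorot-uniform init.

    The same (spec, seed) pair always yields bit-identical parameters:
    layers draw from one ``default_rng(seed)`` stream in construction order.
    """
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    c, length = 1, spec.input_length

    if spec.design == "III":
        layers.append(
            Conv1D(
                c,
                spec.cnn_filters,
                spec.cnn_kernel,
                stride=spec.cnn_stride,
                padding="valid",
                rng=rng,
            )
        )
        layers.append(ReLU())
        length = (length - spec.cnn_kernel) // spec.cnn_stride + 1
        c = spec.cnn_filters
        layers.append(
            MaxPool1D(spec.cnn_pool_size, spec.cnn_pool_stride, padding="valid")
        )
        length = (length - spec.cnn_pool_size) // spec.cnn_pool_stride + 1

    for inc_spec in spec.inception_specs:
        block = InceptionLayer(
            c,
            list(inc_spec.branch_kernel_sizes),
            inc_spec.filters_per_branch,
            inc_spec.pool_size,
            rng,
        )
        layers.append(block)
        c = block.c_out

    layers.append(Flatten())
    n_in = c * length
    for width in spec.fc_widths:
        layers.append(Dense(n_in, width, rng=rng))
        layers.append(ReLU())
        n_in = width
    layers.append(Dense(n_in, spec.n_classes, rng=rng))
    return NetworkInstance(spec, layers, seed)
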