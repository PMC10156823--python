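"""The encoder–decoder–discriminator model with adaptive latent fusion.

One encoder/decoder/discriminator triple per modality, all encoders
projecting into a shared latent space of dimension ``d``.  The fused code
is a convex combination of the per-modality codes with trainable simplex
weights η (parameterized as a softmax over free logits, so nonnegativity
and unit sum hold by construction).  A two-layer group-identification
head maps the fused code to an intermediate representation ``h`` and a
softmax soft assignment α over K groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .data import MultiModalDataset
from .nn import BatchNorm, Dense, Layer, ReLU, Sequential, mlp

CHECKPOINT_VERSION = 1

__all__ = ["ModelConfig", "UnitedNetModel", "LatentBundle", "assign_groups"]


@dataclass
class ModelConfig:
    n_groups: int = 2  # K
    latent_dim: int = 32  # d, shared across modalities
    head_dim: int = 64  # d_h
    hidden: tuple[int, ...] = (128, 128)
    sigma_rel: float = 0.3  # similarity bandwidth, relative to median pairwise distance
    tau: float = 0.1  # contrastive temperature
    delta: float = 1.0  # contrastive loss weight
    neg_sample_size: int = 256
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 256
    seed: int = 0
    mode: str = "unsupervised"  # or "supervised"
    clustering_repeat: int = 1  # c: the step runs c·V times per minibatch
    grad_clip: float = 10.0
    batch_norm: bool = True
    include_positive_in_denominator: bool = False  # standard-InfoNCE toggle
    inverse_frequency_weights: bool = False  # classification-loss weighting option

    def __post_init__(self):
        if self.n_groups < 2:
            raise ValueError("K must be ≥ 2")
        if min(self.latent_dim, self.head_dim) < 1:
            raise ValueError("dimensions must be ≥ 1")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.delta < 0:
            raise ValueError("delta must be ≥ 0")
        if self.mode not in ("unsupervised", "supervised"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.hidden = tuple(int(h) for h in self.hidden)


@dataclass
class LatentBundle:
    """Per-modality codes, fused code, head intermediate, soft assignments."""

    codes: list[np.ndarray]
    fused: np.ndarray
    h: np.ndarray
    alpha: np.ndarray


def assign_groups(alpha: np.ndarray) -> np.ndarray:
    """Hard group index per cell: argmax of α, ties to the lowest index.

    Returns labels in {1..K} (np.argmax already takes the first maximum).
    """
    alpha = np.asarray(alpha)
    return np.argmax(alpha, axis=1) + 1


class UnitedNetModel:
    """Model parameters plus forward operations.

    Parameters fall into three disjoint optimizer groups: the group
    -identification path (encoders + fusion logits + head), the generator
    (encoders + decoders), and the discriminators.
    """

    def __init__(
        self,
        config: ModelConfig,
        input_dims: list[int],
        binary_flags: list[bool] | None = None,
        modality_names: list[str] | None = None,
    ):
        self.config = config
        self.input_dims = list(input_dims)
        V = len(input_dims)
        if V < 2:
            raise ValueError("need at least two modalities")
        self.binary_flags = list(binary_flags) if binary_flags else [False] * V
        self.modality_names = (
            list(modality_names) if modality_names else [f"mod{v}" for v in range(V)]
        )
        rng = np.random.default_rng(config.seed)
        hid = list(config.hidden)
        bn = config.batch_norm
        self.encoders = [
            mlp(p, hid, config.latent_dim, rng, batch_norm=bn) for p in input_dims
        ]
        self.decoders = [
            mlp(
                config.latent_dim,
                hid[::-1],
                p,
                rng,
                batch_norm=bn,
                out_sigmoid=self.binary_flags[v],
            )
            for v, p in enumerate(input_dims)
        ]
        self.discriminators = [
            mlp(p, hid, 1, rng, batch_norm=False) for p in input_dims
        ]
        self.fusion_logits = Tensor(np.zeros(V), requires_grad=True)
        head1_layers: list[Layer] = [Dense(config.latent_dim, config.head_dim, rng)]
        if bn:
            head1_layers.append(BatchNorm(config.head_dim))
        head1_layers.append(ReLU())
        self.head1 = Sequential(*head1_layers)
        # the soft assignment is a bare inner-product softmax W_k·h: no bias
        self.head2 = Dense(config.head_dim, config.n_groups, rng)
        self.head2.b.requires_grad = False  # stays zero

    # ------------------------------------------------------------ properties
    @property
    def n_modalities(self) -> int:
        return len(self.encoders)

    @property
    def eta(self) -> np.ndarray:
        """Simplex fusion weights η = softmax(fusion logits)."""
        z = self.fusion_logits.data
        e = np.exp(z - z.max())
        return e / e.sum()

    def eta_tensor(self) -> Tensor:
        return self.fusion_logits.softmax(axis=-1)

    # ----------------------------------------------------- parameter groups
    def group_identification_parameters(self) -> list[Tensor]:
        params = [p for enc in self.encoders for p in enc.parameters()]
        params += [self.fusion_logits]
        params += self.head1.parameters() + self.head2.parameters()
        return params

    def generator_parameters(self) -> list[Tensor]:
        return [
            p
            for net in (*self.encoders, *self.decoders)
            for p in net.parameters()
        ]

    def discriminator_parameters(self) -> list[Tensor]:
        return [p for d in self.discriminators for p in d.parameters()]

    # ------------------------------------------------------------- forwards
    def _check_dim(self, v: int, X, kind: str) -> None:
        p = self.input_dims[v]
        if X.shape[-1] != p:
            raise ValueError(
                f"{kind} for modality {v}: expected {p} columns, got {X.shape[-1]}"
            )

    def encode(self, v: int, X, train: bool = False) -> Tensor:
        self._check_dim(v, X, "encode input")
        X = X if isinstance(X, Tensor) else Tensor(np.asarray(X, dtype=np.float64))
        return self.encoders[v](X, train=train)

    def decode(self, v: int, codes, train: bool = False) -> Tensor:
        codes = (
            codes
            if isinstance(codes, Tensor)
            else Tensor(np.asarray(codes, dtype=np.float64))
        )
        if codes.shape[-1] != self.config.latent_dim:
            raise ValueError(
                f"decode input for modality {v}: expected {self.config.latent_dim} "
                f"columns, got {codes.shape[-1]}"
            )
        return self.decoders[v](codes, train=train)

    def discriminate(self, v: int, X, train: bool = False) -> Tensor:
        self._check_dim(v, X, "discriminator input")
        X = X if isinstance(X, Tensor) else Tensor(np.asarray(X, dtype=np.float64))
        return self.discriminators[v](X, train=train)

    def fuse(self, codes: list[Tensor], eta: Tensor | None = None) -> Tensor:
        eta = self.eta_tensor() if eta is None else eta
        if not isinstance(eta, Tensor):
            eta = Tensor(np.asarray(eta, dtype=np.float64))
            if abs(float(eta.data.sum()) - 1.0) > 1e-6 or (eta.data < -1e-12).any():
                raise ValueError("fusion weights must lie on the simplex")
        fused = codes[0] * eta[0]
        for v in range(1, len(codes)):
            fused = fused + codes[v] * eta[v]
        return fused

    def head_forward(self, fused, train: bool = False) -> tuple[Tensor, Tensor]:
        fused = (
            fused
            if isinstance(fused, Tensor)
            else Tensor(np.asarray(fused, dtype=np.float64))
        )
        h = self.head1(fused, train=train)
        logits = self.head2(h, train=train)
        return h, logits.softmax(axis=-1)

    def forward_bundle(self, dataset: MultiModalDataset, train: bool = False):
        """Full group-identification forward pass; numpy LatentBundle."""
        codes = [
            self.encode(v, dataset.modalities[v].values, train=train)
            for v in range(self.n_modalities)
        ]
        fused = self.fuse(codes)
        h, alpha = self.head_forward(fused, train=train)
        return LatentBundle(
            codes=[c.data for c in codes],
            fused=fused.data,
            h=h.data,
            alpha=alpha.data,
        )

    # ------------------------------------------------------------ checkpoint
    def _named_arrays(self):
        def walk(prefix: str, seq: Sequential):
            for i, layer in enumerate(seq.layers):
                tag = f"{prefix}.{i}"
                if isinstance(layer, Dense):
                    yield f"{tag}.W", layer, "W"
                    yield f"{tag}.b", layer, "b"
                elif isinstance(layer, BatchNorm):
                    yield f"{tag}.gamma", layer, "gamma"
                    yield f"{tag}.beta", layer, "beta"
                    yield f"{tag}.running_mean", layer, "running_mean"
                    yield f"{tag}.running_var", layer, "running_var"

        for v in range(self.n_modalities):
            yield from walk(f"enc{v}", self.encoders[v])
            yield from walk(f"dec{v}", self.decoders[v])
            yield from walk(f"dis{v}", self.discriminators[v])
        yield from walk("head1", self.head1)
        yield "head2.W", self.head2, "W"
        yield "head2.b", self.head2, "b"
        yield "fusion_logits", self, "fusion_logits"

    def save(self, path: str | Path) -> None:
        """Single-archive checkpoint: parameter tensors + JSON config."""
        arrays = {}
        for name, obj, attr in self._named_arrays():
            val = getattr(obj, attr)
            arrays[name] = val.data if isinstance(val, Tensor) else val
        meta = {
            "version": CHECKPOINT_VERSION,
            "config": asdict(self.config),
            "input_dims": self.input_dims,
            "binary_flags": self.binary_flags,
            "modality_names": self.modality_names,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "UnitedNetModel":
        with np.load(path) as archive:
            meta = json.loads(archive["__meta__"].tobytes().decode())
            if meta["version"] != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta['version']}")
            cfg = ModelConfig(**{
                k: tuple(v) if k == "hidden" else v for k, v in meta["config"].items()
            })
            model = cls(
                cfg,
                meta["input_dims"],
                meta["binary_flags"],
                meta["modality_names"],
            )
            for name, obj, attr in model._named_arrays():
                val = getattr(obj, attr)
                stored = archive[name]
                if isinstance(val, Tensor):
                    val.data = stored.copy()
                else:
                    setattr(obj, attr, stored.copy())
        return model
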