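"""The four seizure-detection architectures as explicit layer graphs.

All variants share one convolutional encoder: four blocks of
same-padded (3 x 2) convolution (ReLU), batch normalization, and max
pooling that reduce a (256 * duration, 24, 1) segment to a
(16 * duration, 1, 64) latent map.  The autoencoder (DCAE) variants add a
mirror decoder of four nearest-neighbour upsampling + convolution blocks
ending in a sigmoid so the reconstruction lives in [0, 1] like the input.
Classification heads: an MLP (50 -> 32 -> 1) on the flattened latent, or
a single bidirectional LSTM layer (50 units per direction) over the
latent read as a sequence, time-averaged, with dropout 0.1 and a sigmoid
output unit.  DCNN variants are the same graphs with every decoder layer
removed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ..types import SdcaeError
from . import layers as L

__all__ = ["VARIANTS", "ConfigError", "ModelConfig", "infer_shapes", "build_model", "SeizureNet"]

VARIANTS = ("DCAE_MLP", "DCAE_BiLSTM", "DCNN_MLP", "DCNN_BiLSTM")


class ConfigError(SdcaeError, ValueError):
    """Inconsistent or unknown model configuration."""


@dataclass(frozen=True)
class ModelConfig:
    """Complete architecture description; defaults are the full-scale models."""

    variant: str
    duration_s: int = 2
    sample_rate_hz: int = 256
    width: int = 24
    encoder_filters: tuple[int, ...] = (32, 32, 64, 64)
    decoder_filters: tuple[int, ...] = (64, 32, 32, 1)
    kernel: tuple[int, int] = (3, 2)
    pools: tuple[tuple[int, int], ...] = ((2, 2), (2, 2), (2, 2), (2, 3))
    upsamples: tuple[tuple[int, int], ...] = ((2, 3), (2, 2), (2, 2), (2, 2))
    mlp_units: tuple[int, ...] = (50, 32)
    lstm_units: int = 50
    dropout: float = 0.1

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.duration_s not in (1, 2, 4):
            raise ConfigError(f"duration must be 1, 2 or 4 s, got {self.duration_s}")
        if len(self.encoder_filters) != len(self.pools):
            raise ConfigError("encoder_filters and pools must have equal length")
        if self.is_dcae and len(self.decoder_filters) != len(self.upsamples):
            raise ConfigError("decoder_filters and upsamples must have equal length")
        if self.is_dcae and self.decoder_filters[-1] != 1:
            raise ConfigError("last decoder layer must have a single filter")

    @property
    def is_dcae(self) -> bool:
        return self.variant.startswith("DCAE")

    @property
    def is_bilstm(self) -> bool:
        return self.variant.endswith("BiLSTM")

    @property
    def input_shape(self) -> tuple[int, int, int]:
        return (self.sample_rate_hz * self.duration_s, self.width, 1)

    def tiny(self, divisor: int = 8) -> "ModelConfig":
        """Desk-scale variant: convolutional filter counts divided by ``divisor``."""
        return replace(
            self,
            encoder_filters=tuple(max(1, f // divisor) for f in self.encoder_filters),
            decoder_filters=tuple(max(1, f // divisor) for f in self.decoder_filters[:-1]) + (1,),
        )


def infer_shapes(config: ModelConfig) -> list[tuple[str, tuple[int, ...]]]:
    """Deterministic per-layer output shape chain (no batch axis).

    Raises :class:`ConfigError` if a pooling window does not divide its
    input or the decoder does not restore the input shape.
    """
    h, w, c = config.input_shape
    chain: list[tuple[str, tuple[int, ...]]] = [("input", (h, w, c))]
    for k, (f, (ph, pw)) in enumerate(zip(config.encoder_filters, config.pools), 1):
        chain.append((f"enc{k}.conv", (h, w, f)))
        chain.append((f"enc{k}.bn", (h, w, f)))
        if h % ph or w % pw:
            raise ConfigError(f"pool {k} window ({ph},{pw}) does not divide ({h},{w})")
        h, w, c = h // ph, w // pw, f
        chain.append((f"enc{k}.pool", (h, w, c)))
    latent = (h, w, c)
    chain.append(("latent", latent))

    if config.is_dcae:
        dh, dw, dc = latent
        for k, (f, (uh, uw)) in enumerate(zip(config.decoder_filters, config.upsamples), 1):
            dh, dw = dh * uh, dw * uw
            chain.append((f"dec{k}.upsample", (dh, dw, dc)))
            dc = f
            chain.append((f"dec{k}.conv", (dh, dw, dc)))
        if (dh, dw, dc) != config.input_shape:
            raise ConfigError(
                f"decoder output {(dh, dw, dc)} does not restore input {config.input_shape}"
            )
        chain.append(("reconstruction", (dh, dw, dc)))

    if config.is_bilstm:
        if latent[1] != 1:
            raise ConfigError(f"latent width must be 1 for the Bi-LSTM head, got {latent[1]}")
        chain.append(("head.sequence", (latent[0], latent[2])))
        chain.append(("head.bilstm", (latent[0], 2 * config.lstm_units)))
        chain.append(("head.average", (2 * config.lstm_units,)))
    else:
        flat = latent[0] * latent[1] * latent[2]
        chain.append(("head.flatten", (flat,)))
        for k, u in enumerate(config.mlp_units, 1):
            chain.append((f"head.dense{k}", (u,)))
    chain.append(("probability", (1,)))
    return chain


class SeizureNet:
    """A built model: encoder, optional decoder, classification head.

    ``forward`` returns ``(probability, reconstruction)`` where the
    reconstruction is ``None`` for DCNN variants; ``backward`` accepts the
    matching output gradients and accumulates parameter gradients.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        infer_shapes(config)  # validate geometry up front
        self.config = config
        rng = np.random.default_rng(seed)
        self.seed = seed

        enc: list[L.Layer] = []
        c_in = 1
        for k, (f, pool) in enumerate(zip(config.encoder_filters, config.pools), 1):
            enc += [
                L.Conv2DSame(c_in, f, config.kernel, rng, name=f"enc{k}.conv"),
                L.ReLU(),
                L.BatchNorm(f, name=f"enc{k}.bn"),
                L.MaxPool(pool),
            ]
            c_in = f
        self.encoder = L.Sequential(enc)

        self.decoder: L.Sequential | None = None
        if config.is_dcae:
            dec: list[L.Layer] = []
            d_in = c_in
            for k, (f, up) in enumerate(zip(config.decoder_filters, config.upsamples), 1):
                dec.append(L.Upsample(up))
                dec.append(L.Conv2DSame(d_in, f, config.kernel, rng, name=f"dec{k}.conv"))
                dec.append(L.Sigmoid() if k == len(config.decoder_filters) else L.ReLU())
                d_in = f
            self.decoder = L.Sequential(dec)

        latent_h = config.input_shape[0] // int(np.prod([p[0] for p in config.pools]))
        latent_c = config.encoder_filters[-1]
        if config.is_bilstm:
            head: list[L.Layer] = [
                L.SqueezeWidth(),
                L.BiLSTM(latent_c, config.lstm_units, rng),
                L.TimeAverage(),
                L.Dropout(config.dropout, np.random.default_rng(seed + 1)),
                L.Dense(2 * config.lstm_units, 1, rng, name="head.out"),
                L.Sigmoid(),
            ]
        else:
            head = [L.Flatten()]
            n_in = latent_h * latent_c
            for k, u in enumerate(config.mlp_units, 1):
                head += [L.Dense(n_in, u, rng, name=f"head.dense{k}"), L.ReLU()]
                n_in = u
            head += [L.Dense(n_in, 1, rng, name="head.out"), L.Sigmoid()]
        self.head = L.Sequential(head)

    # -- parameters ---------------------------------------------------------

    def params(self) -> list[L.Param]:
        ps = self.encoder.params()
        if self.decoder is not None:
            ps += self.decoder.params()
        return ps + self.head.params()

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def zero_grads(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True):
        latent = self.encoder.forward(x, train)
        prob = self.head.forward(latent, train)[:, 0]
        recon = self.decoder.forward(latent, train) if self.decoder is not None else None
        return prob, recon

    def backward(self, dprob: np.ndarray, drecon: np.ndarray | None = None) -> None:
        dlatent = self.head.backward(dprob[:, None])
        if self.decoder is not None:
            if drecon is None:
                raise ConfigError("DCAE variants need a reconstruction gradient")
            dlatent = dlatent + self.decoder.backward(drecon)
        self.encoder.backward(dlatent)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Inference-mode class probabilities (running batch-norm statistics)."""
        out = np.empty(x.shape[0])
        for lo in range(0, x.shape[0], batch_size):
            prob, _ = self.forward(x[lo: lo + batch_size], train=False)
            out[lo: lo + batch_size] = prob
        return out

    # -- introspection / persistence ----------------------------------------

    def manifest(self) -> dict:
        """Structural summary: layer counts per section and parameter totals."""
        def describe(seq: L.Sequential | None) -> list[dict]:
            if seq is None:
                return []
            return [
                {"type": type(l).__name__, "n_params": sum(p.size for p in l.params())}
                for l in seq.layers
            ]

        return {
            "variant": self.config.variant,
            "duration_s": self.config.duration_s,
            "seed": self.seed,
            "n_params": self.n_params,
            "encoder": describe(self.encoder),
            "decoder": describe(self.decoder),
            "head": describe(self.head),
            "shapes": [
                {"layer": name, "shape": list(shape)} for name, shape in infer_shapes(self.config)
            ],
        }

    def save(self, path: str | Path) -> Path:
        """Checkpoint: .npz weight blobs plus a JSON manifest alongside."""
        path = Path(path)
        arrays = {}
        for idx, p in enumerate(self.params()):
            arrays[f"{idx:04d}:{p.name}"] = p.value
        np.savez_compressed(path, **arrays)
        manifest_path = path.with_suffix(".manifest.json")
        manifest_path.write_text(json.dumps(self.manifest(), indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path, config: ModelConfig) -> "SeizureNet":
        path = Path(path)
        model = cls(config, seed=0)
        with np.load(path if path.suffix else path.with_suffix(".npz")) as blob:
            keys = sorted(blob.files)
            params = model.params()
            if len(keys) != len(params):
                raise ConfigError(
                    f"checkpoint has {len(keys)} tensors, model expects {len(params)}"
                )
            for key, p in zip(keys, params):
                value = blob[key]
                if value.shape != p.value.shape:
                    raise ConfigError(f"shape mismatch for {p.name}: {value.shape}")
                p.value[...] = value
        return model


def build_model(config: ModelConfig, seed: int = 0) -> SeizureNet:
    """Construct a :class:`SeizureNet` with seeded Glorot initialization."""
    return SeizureNet(config, seed=seed)
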